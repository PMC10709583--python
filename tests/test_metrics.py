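"""Metrics: Dice, area errors, Bland-Altman, curve distances (validated
against brute-force enumeration oracles), and the paired Wilcoxon test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from aortacine.cine_io import MaskSequence
from aortacine.distensibility import AreaCurve
from aortacine.metrics import (absolute_area_error, bland_altman, dice,
                               dtw_distance, evaluate_cohort, frechet_distance,
                               hausdorff_distance, paired_comparison,
                               EvaluationReport)


# ---------------------------------------------------------------------------
# independent oracles


def frechet_bruteforce(p, q):
    """Minimax Euclidean leash over all monotone couplings (exponential)."""
    p, q = np.asarray(p, float), np.asarray(q, float)

    def dist(i, j):
        return np.linalg.norm(p[i] - q[j])

    best = [np.inf]

    def walk(i, j, leash):
        leash = max(leash, dist(i, j))
        if leash >= best[0]:
            return
        if i == len(p) - 1 and j == len(q) - 1:
            best[0] = leash
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(p) and nj < len(q):
                walk(ni, nj, leash)

    walk(0, 0, 0.0)
    return best[0]


def dtw_bruteforce(p, q):
    """Minimum total cost over all admissible warping paths (exponential)."""
    p, q = np.asarray(p, float), np.asarray(q, float)

    def dist(i, j):
        return np.linalg.norm(p[i] - q[j])

    best = [np.inf]

    def walk(i, j, cost):
        cost += dist(i, j)
        if cost >= best[0]:
            return
        if i == len(p) - 1 and j == len(q) - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(p) and nj < len(q):
                walk(ni, nj, cost)

    walk(0, 0, 0.0)
    return best[0]


def hausdorff_bruteforce(p, q):
    p, q = np.asarray(p, float), np.asarray(q, float)
    d = np.linalg.norm(p[:, None] - q[None, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def wilcoxon_exact_enumeration(a, b):
    """Two-sided exact signed-rank p-value by enumerating all 2^n sign flips."""
    d = np.asarray(b, float) - np.asarray(a, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    t_minus = ranks[d < 0].sum()
    t_lo, t_hi = min(t_plus, t_minus), max(t_plus, t_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if t <= t_lo or t >= t_hi:
            count += 1
    return count / 2 ** n


# ---------------------------------------------------------------------------
# Dice and area error


@pytest.mark.parametrize("a, b, expected", [
    (np.ones((2, 4, 4), bool), np.ones((2, 4, 4), bool), 1.0),
    (np.eye(4, dtype=bool)[None], ~np.eye(4, dtype=bool)[None], 0.0),
    (np.zeros((1, 3, 3), bool), np.zeros((1, 3, 3), bool), 1.0),
])
def test_dice_examples(a, b, expected):
    assert dice(a, b) == expected


def test_dice_half_overlap():
    a = np.zeros((1, 10, 20), bool)
    b = np.zeros((1, 10, 20), bool)
    a[0, :, :10] = True       # |A| = 100
    b[0, :, 5:15] = True      # |B| = 100, overlap 50
    assert dice(a, b) == pytest.approx(2 * 50 / 200)


def test_dice_shape_mismatch():
    with pytest.raises(ValueError):
        dice(np.zeros((1, 4, 4), bool), np.zeros((1, 5, 5), bool))


def test_absolute_area_error():
    same = AreaCurve("AAo", [100.0, 110.0])
    assert absolute_area_error(same, same) == 0.0
    offset = AreaCurve("AAo", [107.0, 117.0])
    assert absolute_area_error(offset, same) == pytest.approx(7.0)
    pred = AreaCurve("AAo", [100.0, 110.0])
    truth = AreaCurve("AAo", [105.0, 100.0])
    assert absolute_area_error(pred, truth) == pytest.approx(7.5)
    with pytest.raises(ValueError):
        absolute_area_error(AreaCurve("AAo", [1.0]), same)


# ---------------------------------------------------------------------------
# Bland-Altman


def test_bland_altman_identity_and_offset():
    x = np.arange(10.0)
    ba = bland_altman(x, x)
    assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)
    ba = bland_altman(x, x + 3.0)
    assert (ba.bias, ba.loa_low, ba.loa_high) == (3.0, 3.0, 3.0)


def test_bland_altman_recovers_gaussian_limits(rng):
    """y = x + N(0, sigma): recovered bias ~ 0 and limits ~ +-1.96 sigma."""
    n = 100_000
    sigma = 1.0
    x = rng.uniform(0, 100, size=n)
    y = x + rng.normal(0, sigma, size=n)
    ba = bland_altman(x, y)
    se_bias = sigma / np.sqrt(n)
    se_loa = sigma * np.sqrt(3 / n)  # SE of bias +- 1.96 SD
    assert abs(ba.bias) < 3 * se_bias
    assert abs(ba.loa_high - 1.96 * sigma) < 3 * se_loa
    assert abs(ba.loa_low + 1.96 * sigma) < 3 * se_loa


def test_bland_altman_needs_pairs():
    with pytest.raises(ValueError):
        bland_altman([1.0], [2.0])


# ---------------------------------------------------------------------------
# curve distances vs oracles


def test_distance_trivial_cases():
    seq = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]])
    assert frechet_distance(seq, seq) == 0.0
    assert hausdorff_distance(seq, seq) == 0.0
    assert dtw_distance(seq, seq) == 0.0
    assert frechet_distance([[0, 0]], [[3, 4]]) == pytest.approx(5.0)
    assert hausdorff_distance([[0, 0]], [[3, 4]]) == pytest.approx(5.0)


def test_dtw_constant_shift_1d():
    # (0,0,0) vs (1,1,1) as 1-D curves: three diagonal matches of cost 1
    p = np.array([[0.0], [0.0], [0.0]])
    q = np.array([[1.0], [1.0], [1.0]])
    assert dtw_distance(p, q) == pytest.approx(3.0)


def test_curve_distances_match_bruteforce_oracles(rng):
    """100 random short sequence pairs: DP results equal exhaustive search."""
    for _ in range(100):
        n, m = rng.integers(1, 6, size=2)
        p = rng.uniform(-5, 5, size=(n, 2))
        q = rng.uniform(-5, 5, size=(m, 2))
        assert frechet_distance(p, q) == pytest.approx(frechet_bruteforce(p, q))
        assert dtw_distance(p, q) == pytest.approx(dtw_bruteforce(p, q))
        assert hausdorff_distance(p, q) == pytest.approx(hausdorff_bruteforce(p, q))
        # the coupling minimax dominates the set-level max-min
        assert frechet_distance(p, q) >= hausdorff_distance(p, q) - 1e-12


def test_distance_symmetry_and_diagonal_bound(rng):
    p = rng.uniform(0, 10, size=(6, 2))
    q = rng.uniform(0, 10, size=(6, 2))
    assert frechet_distance(p, q) == pytest.approx(frechet_distance(q, p))
    assert dtw_distance(p, q) == pytest.approx(dtw_distance(q, p))
    assert hausdorff_distance(p, q) == pytest.approx(hausdorff_distance(q, p))
    diagonal = np.linalg.norm(p - q, axis=1).sum()
    assert dtw_distance(p, q) <= diagonal + 1e-12


def test_empty_inputs_rejected():
    with pytest.raises(ValueError):
        frechet_distance(np.empty((0, 2)), [[0, 0]])
    with pytest.raises(ValueError):
        dtw_distance([[0, 0]], np.empty((0, 2)))
    with pytest.raises(ValueError):
        hausdorff_distance(np.empty((0, 2)), [[0, 0]])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def test_wilcoxon_constant_shift_minimal_p():
    a = np.arange(1.0, 11.0)
    res = paired_comparison(a, a + 1.0, n_comparisons=1)
    assert res.p_raw == pytest.approx(2 / 2 ** 10)


def test_wilcoxon_matches_exact_enumeration(rng):
    for _ in range(20):
        n = int(rng.integers(6, 13))
        a = rng.normal(0, 1, size=n)
        b = a + rng.normal(0.3, 1, size=n)
        res = paired_comparison(a, b, n_comparisons=1)
        assert res.p_raw == pytest.approx(wilcoxon_exact_enumeration(a, b))
        swapped = paired_comparison(b, a, n_comparisons=1)
        assert swapped.p_raw == pytest.approx(res.p_raw)


def test_bonferroni_caps_at_one(rng):
    a = rng.normal(size=20)
    b = a + rng.normal(0, 1, size=20)
    res = paired_comparison(a, b, n_comparisons=6)
    assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 6))
    assert res.p_adjusted <= 1.0
    assert res.p_adjusted >= res.p_raw


def test_wilcoxon_degenerate_rejected():
    a = np.arange(5.0)
    with pytest.raises(ValueError):
        paired_comparison(a, a)


# ---------------------------------------------------------------------------
# cohort evaluation


def _toy_masks(labels, study_id, spacing=(1.0, 1.0)):
    return MaskSequence(labels=labels, pixel_spacing=spacing, study_id=study_id)


def test_evaluate_cohort_identity(phantom_study):
    _, masks, _ = phantom_study
    report = evaluate_cohort([masks, masks], [masks, masks], [48.0, 48.0])
    for vessel in ("AAo", "DAo"):
        assert report.cohort[f"{vessel}_dice_mean"] == 1.0
        assert report.cohort[f"{vessel}_area_error_mm2_mean"] == 0.0
        assert report.cohort[f"{vessel}_ad_error_1e3_mean"] == 0.0
        assert report.cohort[f"{vessel}_frechet_mean"] == 0.0
        assert report.cohort[f"{vessel}_dtw_mean"] == 0.0
    assert report.bland_altman["ad"].bias == 0.0


def test_evaluate_cohort_hand_computed_mean_sd():
    """Two-study toy cohort: mean and sample SD against the closed form."""
    base = np.zeros((2, 16, 16), dtype=np.uint8)
    base[:, 2:6, 2:6] = 1    # AAo 16 px
    base[:, 10:14, 10:13] = 2  # DAo 12 px
    truth = [_toy_masks(base.copy(), "s0"), _toy_masks(base.copy(), "s1")]
    pred0 = base.copy()
    pred1 = base.copy()
    pred1[:, 2:6, 2] = 0  # remove a 4-px column of AAo in study 1, all frames
    preds = [_toy_masks(pred0, "s0"), _toy_masks(pred1, "s1")]
    report = evaluate_cohort(preds, truth, [50.0, 50.0])
    errors = [0.0, 4.0]  # per-study mean |area error| in mm^2
    assert report.cohort["AAo_area_error_mm2_mean"] == pytest.approx(np.mean(errors))
    assert report.cohort["AAo_area_error_mm2_sd"] == pytest.approx(np.std(errors, ddof=1))
    d0, d1 = 1.0, 2 * 12 / (12 + 16)
    assert report.cohort["AAo_dice_mean"] == pytest.approx((d0 + d1) / 2)


def test_report_round_trip(phantom_study, tmp_path):
    _, masks, _ = phantom_study
    report = evaluate_cohort([masks], [masks], [48.0])
    restored = EvaluationReport.from_json(report.to_json())
    pd.testing.assert_frame_equal(report.per_study, restored.per_study)
    assert restored.cohort == pytest.approx(report.cohort)
    report.save(tmp_path / "report.csv")
    assert (tmp_path / "report.csv").exists()


def test_evaluate_cohort_with_baseline_pvalues(phantom_study):
    _, masks, _ = phantom_study
    worse = masks.labels.copy()
    worse[:, :, ::7] = 0  # strip columns: strictly worse prediction
    n = 6
    preds = [_toy_masks(masks.labels.copy(), f"s{i}", masks.pixel_spacing)
             for i in range(n)]
    base = [_toy_masks(worse.copy(), f"s{i}", masks.pixel_spacing) for i in range(n)]
    truths = [_toy_masks(masks.labels.copy(), f"s{i}", masks.pixel_spacing)
              for i in range(n)]
    report = evaluate_cohort(preds, truths, [48.0] * n, baseline_masks=base)
    assert "AAo_dice" in report.p_values
    p = report.p_values["AAo_dice"]
    assert p["p_adjusted"] >= p["p_raw"]
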