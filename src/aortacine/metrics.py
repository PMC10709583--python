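"""Segmentation accuracy, agreement and curve-distance metrics.

Per study and vessel: Dice overlap over the full cine stack, mean absolute
area error over frames, absolute distensibility error, and three
dissimilarities between predicted and reference time-area curves (discrete
Fréchet, Hausdorff, dynamic time warping).  At cohort level: mean +- SD,
Bland-Altman agreement statistics (bias and 1.96-SD limits of agreement),
and two-sided Wilcoxon signed-rank comparisons with Bonferroni correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from .cine_io import MaskSequence
from .distensibility import (VESSEL_LABELS, AreaCurve, aortic_distensibility,
                             area_curve)

# ---------------------------------------------------------------------------
# overlap and error metrics


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between binary stacks.

    Both empty counts as perfect agreement (1); empty vs non-empty is 0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def absolute_area_error(pred: AreaCurve, truth: AreaCurve) -> float:
    """Mean over frames of |area_pred(t) - area_truth(t)| in mm^2."""
    if len(pred) != len(truth):
        raise ValueError(f"curve lengths differ: {len(pred)} vs {len(truth)}")
    return float(np.mean(np.abs(pred.areas_mm2 - truth.areas_mm2)))


# ---------------------------------------------------------------------------
# Bland-Altman agreement


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray

    def as_dict(self) -> dict:
        return {"bias": self.bias, "loa_low": self.loa_low, "loa_high": self.loa_high}


def bland_altman(x, y) -> BlandAltman:
    """Agreement between paired measurements: differences are y - x.

    Limits of agreement are bias +- 1.96 * sample SD of the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equally sized inputs with n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                       means=(x + y) / 2.0, differences=d)


# ---------------------------------------------------------------------------
# curve distances


def frechet_distance(p, q) -> float:
    """Discrete Fréchet distance between two point sequences.

    Standard dynamic-programming coupling recursion with the Euclidean
    ground metric: the minimax leash length over monotone couplings.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.size == 0 or q.size == 0:
        raise ValueError("sequences must be non-empty")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                prev = 0.0
            elif i == 0:
                prev = ca[0, j - 1]
            elif j == 0:
                prev = ca[i - 1, 0]
            else:
                prev = min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1])
            ca[i, j] = max(prev, d[i, j])
    return float(ca[-1, -1])


def hausdorff_distance(p, q) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.size == 0 or q.size == 0:
        raise ValueError("point sets must be non-empty")
    return float(max(directed_hausdorff(p, q)[0], directed_hausdorff(q, p)[0]))


def dtw_distance(p, q) -> float:
    """Dynamic time warping distance (total unnormalized path cost).

    Classic DP with Euclidean local cost and the symmetric step pattern
    (match / insert / delete), no window constraint.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.size == 0 or q.size == 0:
        raise ValueError("sequences must be non-empty")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = d[i - 1, j - 1] + min(acc[i - 1, j], acc[i, j - 1],
                                              acc[i - 1, j - 1])
    return float(acc[n, m])


# ---------------------------------------------------------------------------
# paired comparison


@dataclass
class PairedComparison:
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


def paired_comparison(errors_a, errors_b, n_comparisons: int = 6,
                      alpha: float = 0.05) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test with Bonferroni correction.

    Zero differences are dropped; tied ranks are mid-ranked; the exact null
    distribution is used for n <= 25 non-zero pairs, the normal
    approximation with continuity correction otherwise.  The Bonferroni
    multiplicity defaults to 6 (one per metric column of a typical
    comparison table); the adjusted p is capped at 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equally sized inputs with n >= 5")
    d = b - a
    n_nonzero = np.count_nonzero(d)
    if n_nonzero == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return PairedComparison(statistic=float(res.statistic),
                            p_raw=float(res.pvalue), p_adjusted=p_adj,
                            significant=p_adj < alpha)


# ---------------------------------------------------------------------------
# cohort evaluation


@dataclass
class EvaluationReport:
    """Per-study metrics table plus cohort summaries."""

    per_study: pd.DataFrame
    cohort: dict
    bland_altman: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        payload = {
            "per_study": self.per_study.to_dict(orient="records"),
            "cohort": clean(self.cohort),
            "bland_altman": clean({k: (v.as_dict() if isinstance(v, BlandAltman) else v)
                                   for k, v in self.bland_altman.items()}),
            "p_values": clean(self.p_values),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(per_study=pd.DataFrame(d["per_study"]), cohort=d["cohort"],
                   bland_altman=d["bland_altman"], p_values=d["p_values"])

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix == ".csv":
            self.per_study.to_csv(path, index=False)
        else:
            path.write_text(self.to_json())


def _study_metrics(pred: MaskSequence, truth: MaskSequence,
                   pulse_pressure: float) -> dict:
    rec: dict = {"study_id": truth.study_id or pred.study_id}
    for vessel, label in VESSEL_LABELS.items():
        pc = area_curve(pred, vessel)
        tc = area_curve(truth, vessel)
        rec[f"{vessel}_dice"] = dice(pred.labels == label, truth.labels == label)
        rec[f"{vessel}_area_error_mm2"] = absolute_area_error(pc, tc)
        try:
            ad_p = aortic_distensibility(pc, pulse_pressure).distensibility
        except ValueError:
            ad_p = np.nan
        ad_t = aortic_distensibility(tc, pulse_pressure).distensibility
        rec[f"{vessel}_ad_pred_1e3"] = ad_p * 1e3
        rec[f"{vessel}_ad_truth_1e3"] = ad_t * 1e3
        rec[f"{vessel}_ad_error_1e3"] = abs(ad_p - ad_t) * 1e3
        rec[f"{vessel}_a_max_pred"] = float(pc.areas_mm2.max())
        rec[f"{vessel}_a_max_truth"] = float(tc.areas_mm2.max())
        rec[f"{vessel}_a_min_pred"] = float(pc.areas_mm2.min())
        rec[f"{vessel}_a_min_truth"] = float(tc.areas_mm2.min())
        pp_pts, tp_pts = pc.as_points(), tc.as_points()
        rec[f"{vessel}_frechet"] = frechet_distance(pp_pts, tp_pts)
        rec[f"{vessel}_hausdorff"] = hausdorff_distance(pp_pts, tp_pts)
        rec[f"{vessel}_dtw"] = dtw_distance(pp_pts, tp_pts)
    return rec


def evaluate_cohort(pred_masks: list[MaskSequence], truth_masks: list[MaskSequence],
                    pulse_pressures: list[float],
                    baseline_masks: list[MaskSequence] | None = None,
                    n_comparisons: int = 6, alpha: float = 0.05) -> EvaluationReport:
    """Assemble the evaluation report for matched prediction/truth studies.

    ``baseline_masks`` (optional) enables paired Wilcoxon comparisons of the
    per-study Dice / area / AD errors between the two prediction sets.
    """
    if not (len(pred_masks) == len(truth_masks) == len(pulse_pressures)):
        raise ValueError("prediction, truth and pulse-pressure lists must match")
    for p, t in zip(pred_masks, truth_masks):
        if p.study_id and t.study_id and p.study_id != t.study_id:
            raise ValueError(f"study pairing mismatch: {p.study_id} vs {t.study_id}")

    rows = [_study_metrics(p, t, pp)
            for p, t, pp in zip(pred_masks, truth_masks, pulse_pressures)]
    table = pd.DataFrame(rows)

    cohort: dict = {}
    for vessel in VESSEL_LABELS:
        for metric in ("dice", "area_error_mm2", "ad_error_1e3",
                       "frechet", "hausdorff", "dtw"):
            col = table[f"{vessel}_{metric}"]
            cohort[f"{vessel}_{metric}_mean"] = float(col.mean())
            cohort[f"{vessel}_{metric}_sd"] = float(col.std(ddof=1)) if len(col) > 1 else 0.0

    ba = {}
    if len(table) >= 2:
        for quantity in ("a_max", "a_min"):
            pred_vals = np.concatenate([table[f"{v}_{quantity}_pred"].to_numpy()
                                        for v in VESSEL_LABELS])
            truth_vals = np.concatenate([table[f"{v}_{quantity}_truth"].to_numpy()
                                         for v in VESSEL_LABELS])
            ba[quantity] = bland_altman(truth_vals, pred_vals)
        ad_pred = np.concatenate([table[f"{v}_ad_pred_1e3"].to_numpy()
                                  for v in VESSEL_LABELS])
        ad_truth = np.concatenate([table[f"{v}_ad_truth_1e3"].to_numpy()
                                   for v in VESSEL_LABELS])
        ok = np.isfinite(ad_pred)
        if ok.sum() >= 2:
            ba["ad"] = bland_altman(ad_truth[ok], ad_pred[ok])

    p_values: dict = {}
    if baseline_masks is not None:
        base_rows = [_study_metrics(p, t, pp)
                     for p, t, pp in zip(baseline_masks, truth_masks, pulse_pressures)]
        base = pd.DataFrame(base_rows)
        for vessel in VESSEL_LABELS:
            for metric in ("dice", "area_error_mm2", "ad_error_1e3"):
                col = f"{vessel}_{metric}"
                try:
                    cmp = paired_comparison(table[col], base[col],
                                            n_comparisons=n_comparisons, alpha=alpha)
                    p_values[col] = {"p_raw": cmp.p_raw, "p_adjusted": cmp.p_adjusted,
                                     "significant": cmp.significant}
                except ValueError:
                    p_values[col] = {"p_raw": np.nan, "p_adjusted": np.nan,
                                     "significant": False}
    return EvaluationReport(per_study=table, cohort=cohort,
                            bland_altman=ba, p_values=p_values)
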