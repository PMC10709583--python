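"""End-to-end experiment wiring: phantoms -> training -> segmentation ->
distensibility -> evaluation.

`desk_experiment` runs the whole pipeline at workstation scale (64 x 64
grid, T = 12 frames, filter widths [4, 8, 16, 32, 64], 20 epochs) on a
synthetic cohort and evaluates on the held-out test split.  It is the
backbone of the reproduction script and of the scaled-down recovery test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .cine_io import CineSequence, MaskSequence, normalize_intensities
from .metrics import EvaluationReport, evaluate_cohort
from .nn.network import (NetworkConfig, SegmentationNetwork, binarize_and_label,
                         build_network, segment_sequence)
from .phantom import CohortVariability, PhantomTruth, generate_cohort
from .training import EpochRecord, TrainConfig, desk_network_config, desk_preset, split_dataset, train


@dataclass
class ExperimentResult:
    report: EvaluationReport
    history: list[EpochRecord]
    network: SegmentationNetwork
    test_truths: list[PhantomTruth]
    n_studies: dict


def prepare_study(cine: CineSequence) -> CineSequence:
    """Intensity-normalise a study for the network."""
    return normalize_intensities(cine)


def segment_and_label(network: SegmentationNetwork, cine: CineSequence,
                      threshold: float = 0.5) -> MaskSequence:
    probs = segment_sequence(network, cine)
    masks = binarize_and_label(probs, threshold=threshold,
                               pixel_spacing=cine.pixel_spacing,
                               study_id=cine.study_id)
    return masks


def desk_experiment(seed: int = 0, n_studies: int = 20, epochs: int = 20,
                    network_config: NetworkConfig | None = None,
                    train_config: TrainConfig | None = None,
                    variability: CohortVariability | None = None) -> ExperimentResult:
    """Train on a phantom cohort and evaluate on the held-out studies.

    Every random draw (cohort sampling, initialisation, augmentation,
    shuffling, dropout) derives from ``seed``.
    """
    cohort = generate_cohort(n_studies, variability=variability, seed=seed)
    studies = [(prepare_study(cine), masks, truth) for cine, masks, truth in cohort]

    train_set, val_set, test_set = split_dataset(studies, seed=seed + 1)
    if not test_set:
        raise ValueError("test split is empty; increase n_studies")

    net_cfg = network_config or desk_network_config()
    cfg = train_config or desk_preset(seed=seed + 2)
    network = build_network(net_cfg, seed=seed + 3)
    _, history = train(network,
                       [(c, m) for c, m, _ in train_set],
                       [(c, m) for c, m, _ in val_set],
                       cfg)

    pred_masks, truth_masks, pps, truths = [], [], [], []
    for cine, masks, truth in test_set:
        pred_masks.append(segment_and_label(network, cine))
        truth_masks.append(masks)
        pps.append(cine.pulse_pressure)
        truths.append(truth)
    report = evaluate_cohort(pred_masks, truth_masks, pps)
    return ExperimentResult(report=report, history=history, network=network,
                            test_truths=truths,
                            n_studies={"train": len(train_set), "val": len(val_set),
                                       "test": len(test_set)})


def ablation_configs() -> dict[str, tuple[NetworkConfig, str]]:
    """The configuration variants of the ablation study.

    Returns {name: (network config, loss kind)} at desk-scale widths; the
    "proposed" entry is the resource-efficient default.
    """
    base = desk_network_config()
    return {
        "proposed": (base, "focal_tversky"),
        "no_focal_tversky": (base, "dice"),
        "no_non_linearities": (dataclasses.replace(base, merge_mode="concat"),
                               "focal_tversky"),
        "no_dense_pruning": (dataclasses.replace(base, dense_blocks_final_encode=3),
                             "focal_tversky"),
        "no_filter_pruning": (dataclasses.replace(base, filter_multiplier=4),
                              "focal_tversky"),
        "no_bconvlstm_pruning": (dataclasses.replace(
            base, bconvlstm_levels=frozenset({1, 2, 3})), "focal_tversky"),
    }
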