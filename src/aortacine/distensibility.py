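"""Time-area curves and aortic distensibility.

Aortic distensibility is the maximum relative change of the lumen
cross-sectional area over the cardiac cycle per unit pulse pressure:

    AD = (A_max - A_min) / (A_min * PP)     [mmHg^-1]

where the per-frame area is the number of vessel pixels multiplied by the
pixel dimensions, and A_max/A_min are the frame-wise extrema of that
curve (no temporal smoothing by default; the frame attaining the extremum
need not coincide with the nominal systolic/diastolic phase).  Displays
conventionally report AD in units of 10^-3 mmHg^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cine_io import (LABEL_AAO, LABEL_DAO, CineSequence, MaskSequence,
                      MetadataError)

VESSEL_LABELS = {"AAo": LABEL_AAO, "DAo": LABEL_DAO}


class UndefinedADError(ValueError):
    """A_min is zero (empty segmentation) so AD is undefined."""


@dataclass
class AreaCurve:
    """Per-frame cross-sectional area (mm^2) of one vessel."""

    vessel: str
    areas_mm2: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if (self.areas_mm2 < 0).any():
            raise ValueError("areas must be non-negative")

    def __len__(self):
        return len(self.areas_mm2)

    def as_points(self) -> np.ndarray:
        """(frame index, area) points for curve-distance metrics."""
        t = np.arange(len(self.areas_mm2), dtype=float)
        return np.column_stack([t, self.areas_mm2])

    def smoothed(self, window: int = 3) -> "AreaCurve":
        """Optional cyclic moving-average smoothing (off by default)."""
        kernel = np.ones(window) / window
        padded = np.concatenate([self.areas_mm2[-(window // 2):],
                                 self.areas_mm2,
                                 self.areas_mm2[:window // 2]])
        smooth = np.convolve(padded, kernel, mode="valid")
        return AreaCurve(self.vessel, smooth, self.frame_times)


@dataclass
class ADResult:
    vessel: str
    a_max_mm2: float
    a_min_mm2: float
    pulse_pressure: float
    distensibility: float  # mmHg^-1
    missing: bool = False

    @property
    def distensibility_display(self) -> float:
        """AD in the conventional display units of 10^-3 mmHg^-1."""
        return self.distensibility * 1e3


def area_curve(masks: MaskSequence, vessel: str) -> AreaCurve:
    """Pixel-count area curve: n_pixels(t) * row_mm * col_mm."""
    if masks.pixel_spacing is None:
        raise MetadataError("mask sequence lacks pixel spacing")
    label = VESSEL_LABELS[vessel]
    counts = (masks.labels == label).sum(axis=(1, 2))
    px_area = masks.pixel_spacing[0] * masks.pixel_spacing[1]
    return AreaCurve(vessel=vessel, areas_mm2=counts.astype(float) * px_area)


def aortic_distensibility(curve: AreaCurve, pulse_pressure: float) -> ADResult:
    """AD = (A_max - A_min) / (A_min * PP) from the frame-wise extrema."""
    if pulse_pressure is None or pulse_pressure <= 0:
        raise ValueError(f"pulse pressure must be positive, got {pulse_pressure}")
    a_max = float(curve.areas_mm2.max())
    a_min = float(curve.areas_mm2.min())
    if a_min <= 0:
        raise UndefinedADError(
            f"{curve.vessel}: minimum area is zero, distensibility undefined")
    ad = (a_max - a_min) / (a_min * pulse_pressure)
    return ADResult(vessel=curve.vessel, a_max_mm2=a_max, a_min_mm2=a_min,
                    pulse_pressure=pulse_pressure, distensibility=ad)


@dataclass
class StudyQuantification:
    study_id: str
    curves: dict[str, AreaCurve]
    results: dict[str, ADResult]

    def to_record(self) -> dict:
        rec: dict = {"study_id": self.study_id}
        for vessel, res in self.results.items():
            rec[f"{vessel}_a_max_mm2"] = res.a_max_mm2
            rec[f"{vessel}_a_min_mm2"] = res.a_min_mm2
            rec[f"{vessel}_ad_1e3_mmHg"] = (np.nan if res.missing
                                            else res.distensibility_display)
            rec[f"{vessel}_missing"] = res.missing
        rec["pulse_pressure_mmHg"] = next(iter(self.results.values())).pulse_pressure
        return rec


def quantify_study(cine: CineSequence, masks: MaskSequence) -> StudyQuantification:
    """Per-vessel area curves and AD for one study.

    A vessel absent from the masks is flagged ``missing`` rather than
    failing the whole study.
    """
    if cine.pulse_pressure is None:
        raise MetadataError(f"study {cine.study_id!r} lacks a pulse pressure")
    if masks.shape != cine.shape:
        raise ValueError(f"mask shape {masks.shape} does not match cine {cine.shape}")
    curves: dict[str, AreaCurve] = {}
    results: dict[str, ADResult] = {}
    for vessel in VESSEL_LABELS:
        curve = area_curve(masks, vessel)
        curves[vessel] = curve
        try:
            results[vessel] = aortic_distensibility(curve, cine.pulse_pressure)
        except UndefinedADError:
            results[vessel] = ADResult(vessel=vessel, a_max_mm2=0.0, a_min_mm2=0.0,
                                       pulse_pressure=cine.pulse_pressure,
                                       distensibility=float("nan"), missing=True)
    return StudyQuantification(study_id=cine.study_id or masks.study_id,
                               curves=curves, results=results)
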