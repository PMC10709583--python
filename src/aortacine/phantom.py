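"""Synthetic cine phantoms of the ascending and descending aorta.

Each phantom emulates the structure a single-slice aortic cine study:
two bright elliptical lumens (AAo and DAo) pulsating over one cardiac
cycle on a darker thorax-like background, with smooth intra-lumen
brightness heterogeneity (a stand-in for flow-related signal variation)
and additive Gaussian noise.  Ground truth is exact: rasterized label
maps, analytic time-area curves, and the distensibility implied by the
pulsatility and pulse pressure.

Default study conditions follow the imaging regime the pipeline targets:
mean AAo cross-sectional area near 679 mm^2 and DAo near 371 mm^2, pulse
pressure near 48 mmHg (systolic minus diastolic brachial pressure of a
mixed clinical cohort), and a foreground occupying only a few percent of
the grid, which is the class-imbalance regime the focal Tversky loss is
designed for.  The default grid is 64 x 64 with a 2.5 mm pixel so that
real-world areas are preserved at desk scale; 256 x 256 with a ~1.25 mm
pixel matches the clinical matrix.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cine_io import LABEL_AAO, LABEL_DAO, CineSequence, MaskSequence, save_cine, save_masks

AAO_MEAN_AREA_MM2 = 679.0  # cohort mean ascending aorta area
DAO_MEAN_AREA_MM2 = 371.0  # cohort mean descending aorta area


class PhantomConfigError(ValueError):
    """The requested phantom geometry is invalid (e.g. overlapping vessels)."""


@dataclass
class VesselSpec:
    """Geometry and dynamics of one elliptical lumen.

    ``semi_axes`` are the end-diastolic (baseline) semi-axes in pixels;
    during systole both axes scale by ``1 + pulsatility * profile(t)`` with
    profile in [0, 1], so the area swings between pi*a*b and
    pi*a*b*(1+pulsatility)^2.  ``phase_offset`` shifts the profile as a
    fraction of the cycle (the descending aorta peaks slightly later).
    """

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    pulsatility: float = 0.08
    phase_offset: float = 0.0
    orientation_deg: float = 0.0

    def axes_at(self, profile_value: float) -> tuple[float, float]:
        s = 1.0 + self.pulsatility * profile_value
        return self.semi_axes[0] * s, self.semi_axes[1] * s

    @property
    def max_radius(self) -> float:
        return max(self.semi_axes) * (1.0 + self.pulsatility)


@dataclass
class BrightnessSpec:
    lumen_mean: float = 0.8
    background_mean: float = 0.2
    heterogeneity: float = 0.15  # amplitude of the smooth intra-lumen gradient
    noise_std: float = 0.03


@dataclass
class PhantomConfig:
    grid: tuple[int, int, int] = (12, 64, 64)  # (T, H, W)
    pixel_spacing: tuple[float, float] = (2.5, 2.5)
    aao: VesselSpec = field(default_factory=lambda: VesselSpec(
        centre=(24.0, 22.0),
        semi_axes=_axes_for_area(AAO_MEAN_AREA_MM2, (2.5, 2.5), 0.85)))
    dao: VesselSpec = field(default_factory=lambda: VesselSpec(
        centre=(40.0, 42.0),
        semi_axes=_axes_for_area(DAO_MEAN_AREA_MM2, (2.5, 2.5), 0.9),
        phase_offset=0.05))
    pulse_pressure: float = 48.0
    brightness: BrightnessSpec = field(default_factory=BrightnessSpec)
    systolic_fraction: float = 0.35  # fraction of the cycle spent on the upstroke
    seed: int = 0

    def validate(self) -> None:
        t, h, w = self.grid
        if t < 2 or h < 16 or w < 16:
            raise PhantomConfigError(f"grid {self.grid} too small")
        for v in (self.aao, self.dao):
            if not 0.0 <= v.pulsatility < 1.0:
                raise PhantomConfigError("pulsatility must be in [0, 1)")
        if self.brightness.noise_std < 0:
            raise PhantomConfigError("noise std must be >= 0")
        gap = np.hypot(self.aao.centre[0] - self.dao.centre[0],
                       self.aao.centre[1] - self.dao.centre[1])
        if gap <= self.aao.max_radius + self.dao.max_radius:
            raise PhantomConfigError(
                "vessel footprints overlap at maximal dilation "
                f"(centre gap {gap:.1f} px <= {self.aao.max_radius + self.dao.max_radius:.1f} px)")


def _axes_for_area(area_mm2: float, spacing: tuple[float, float],
                   aspect: float) -> tuple[float, float]:
    """Semi-axes (px) of an ellipse with the given baseline area and b/a ratio."""
    area_px = area_mm2 / (spacing[0] * spacing[1])
    a = np.sqrt(area_px / (np.pi * aspect))
    return float(a), float(a * aspect)


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom study."""

    area_curves_mm2: dict[str, np.ndarray]  # "AAo"/"DAo" -> per-frame areas
    a_max_mm2: dict[str, float]
    a_min_mm2: dict[str, float]
    distensibility: dict[str, float]  # (A_max - A_min) / (A_min * PP), mmHg^-1
    pulse_pressure: float

    def to_json(self) -> str:
        payload = {
            "pulse_pressure": self.pulse_pressure,
            "vessels": {
                v: {
                    "area_curve_mm2": list(map(float, self.area_curves_mm2[v])),
                    "a_max_mm2": self.a_max_mm2[v],
                    "a_min_mm2": self.a_min_mm2[v],
                    "distensibility": self.distensibility[v],
                }
                for v in self.area_curves_mm2
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        vessels = d["vessels"]
        return cls(
            area_curves_mm2={v: np.asarray(vessels[v]["area_curve_mm2"]) for v in vessels},
            a_max_mm2={v: vessels[v]["a_max_mm2"] for v in vessels},
            a_min_mm2={v: vessels[v]["a_min_mm2"] for v in vessels},
            distensibility={v: vessels[v]["distensibility"] for v in vessels},
            pulse_pressure=d["pulse_pressure"],
        )


def cardiac_profile(t_frac: np.ndarray, systolic_fraction: float = 0.35) -> np.ndarray:
    """Asymmetric raised-sine area profile in [0, 1].

    Fast systolic upstroke over ``systolic_fraction`` of the cycle, slower
    diastolic decay over the remainder; smooth and unimodal.
    """
    t_frac = np.mod(np.asarray(t_frac, dtype=float), 1.0)
    r = systolic_fraction
    rise = 0.5 * (1.0 - np.cos(np.pi * t_frac / r))
    decay = 0.5 * (1.0 + np.cos(np.pi * (t_frac - r) / (1.0 - r)))
    return np.where(t_frac < r, rise, decay)


def _ellipse_mask(h: int, w: int, centre, semi_axes, orientation_deg: float) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - centre[0]
    dx = cols - centre[1]
    th = np.deg2rad(orientation_deg)
    u = np.cos(th) * dy + np.sin(th) * dx
    v = -np.sin(th) * dy + np.cos(th) * dx
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> tuple[CineSequence, MaskSequence, PhantomTruth]:
    """Generate one synthetic cine study with exact ground truth.

    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t_n, h, w = config.grid
    spacing = config.pixel_spacing
    px_area = spacing[0] * spacing[1]
    bright = config.brightness

    frames = np.empty((t_n, h, w), dtype=np.float64)
    labels = np.zeros((t_n, h, w), dtype=np.uint8)
    curves = {"AAo": np.empty(t_n), "DAo": np.empty(t_n)}

    # static background: darker thorax with a broad smooth modulation
    rows, cols = np.mgrid[0:h, 0:w]
    background = bright.background_mean * (
        1.0 + 0.25 * np.sin(2 * np.pi * rows / h) * np.cos(np.pi * cols / w))

    # smooth intra-lumen heterogeneity field (flow-like brightness gradient)
    hetero_phase = rng.uniform(0, 2 * np.pi, size=2)
    hetero = np.sin(2 * np.pi * rows / h + hetero_phase[0]) * \
        np.cos(2 * np.pi * cols / w + hetero_phase[1])

    t_frac = np.arange(t_n) / t_n
    vessels = {"AAo": (config.aao, LABEL_AAO), "DAo": (config.dao, LABEL_DAO)}
    for name, (spec, _) in vessels.items():
        profile = cardiac_profile(t_frac - spec.phase_offset, config.systolic_fraction)
        a0, b0 = spec.semi_axes
        scale = (1.0 + spec.pulsatility * profile) ** 2
        curves[name] = np.pi * a0 * b0 * scale * px_area

    for t in range(t_n):
        img = background.copy()
        for name, (spec, label) in vessels.items():
            profile = cardiac_profile(t_frac[t] - spec.phase_offset,
                                      config.systolic_fraction)
            mask = _ellipse_mask(h, w, spec.centre, spec.axes_at(profile),
                                 spec.orientation_deg)
            img[mask] = bright.lumen_mean * (1.0 + bright.heterogeneity * hetero[mask])
            labels[t][mask] = label
        frames[t] = img
    if bright.noise_std > 0:
        frames += rng.normal(0.0, bright.noise_std, size=frames.shape)

    study_id = f"phantom-{config.seed:06d}"
    cine = CineSequence(frames=frames, pixel_spacing=spacing,
                        pulse_pressure=config.pulse_pressure, study_id=study_id)
    masks = MaskSequence(labels=labels, pixel_spacing=spacing, study_id=study_id)
    truth = PhantomTruth(
        area_curves_mm2=curves,
        a_max_mm2={v: float(c.max()) for v, c in curves.items()},
        a_min_mm2={v: float(c.min()) for v, c in curves.items()},
        distensibility={v: float((c.max() - c.min()) / (c.min() * config.pulse_pressure))
                        for v, c in curves.items()},
        pulse_pressure=config.pulse_pressure,
    )
    return cine, masks, truth


@dataclass
class CohortVariability:
    """Sampling ranges for per-study phantom randomisation."""

    area_sigma: float = 0.18          # lognormal sigma of baseline areas
    aspect_range: tuple[float, float] = (0.72, 0.95)
    # radius pulsatility spanning distensibilities ~2-7 x 10^-3 mmHg^-1 at PP 48
    pulsatility_range: tuple[float, float] = (0.05, 0.15)
    centre_jitter_px: float = 2.0
    orientation_range_deg: tuple[float, float] = (0.0, 180.0)
    pulse_pressure_mean: float = 48.0
    pulse_pressure_sd: float = 10.0
    noise_std_range: tuple[float, float] = (0.01, 0.04)


def generate_cohort(n: int, base_config: PhantomConfig | None = None,
                    variability: CohortVariability | None = None,
                    seed: int = 0) -> list[tuple[CineSequence, MaskSequence, PhantomTruth]]:
    """Generate ``n`` randomised phantom studies, reproducible from ``seed``.

    Baseline areas are sampled lognormally around the cohort means (AAo
    ~679 mm^2, DAo ~371 mm^2); geometry draws that would overlap at maximal
    dilation, or whose joint footprint would exceed the severe
    class-imbalance regime (foreground >= 5% of the grid), are rejected and
    resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_config or PhantomConfig()
    var = variability or CohortVariability()
    rng = np.random.default_rng(seed)
    spacing = base.pixel_spacing
    studies = []
    for i in range(n):
        for _attempt in range(100):
            cfg = _sample_config(base, var, rng)
            try:
                cfg.validate()
                if _max_foreground_fraction(cfg) >= 0.05:
                    raise PhantomConfigError("foreground fraction >= 5%")
                break
            except PhantomConfigError:
                continue
        else:
            raise PhantomConfigError("could not sample non-overlapping vessels")
        studies.append(generate_phantom(cfg))
    return studies


def _max_foreground_fraction(cfg: PhantomConfig) -> float:
    _, h, w = cfg.grid
    total = sum(np.pi * v.semi_axes[0] * v.semi_axes[1] * (1 + v.pulsatility) ** 2
                for v in (cfg.aao, cfg.dao))
    return total / (h * w)


def _sample_config(base: PhantomConfig, var: CohortVariability,
                   rng: np.random.Generator) -> PhantomConfig:
    def sample_vessel(spec: VesselSpec, target_area: float) -> VesselSpec:
        area = target_area * np.exp(
            np.clip(rng.normal(0.0, var.area_sigma), -2 * var.area_sigma, 2 * var.area_sigma))
        aspect = rng.uniform(*var.aspect_range)
        centre = (spec.centre[0] + rng.uniform(-var.centre_jitter_px, var.centre_jitter_px),
                  spec.centre[1] + rng.uniform(-var.centre_jitter_px, var.centre_jitter_px))
        return dataclasses.replace(
            spec,
            centre=centre,
            semi_axes=_axes_for_area(area, base.pixel_spacing, aspect),
            pulsatility=rng.uniform(*var.pulsatility_range),
            orientation_deg=rng.uniform(*var.orientation_range_deg),
            phase_offset=spec.phase_offset + rng.uniform(0.0, 0.03),
        )

    brightness = dataclasses.replace(
        base.brightness,
        noise_std=rng.uniform(*var.noise_std_range))
    return dataclasses.replace(
        base,
        aao=sample_vessel(base.aao, AAO_MEAN_AREA_MM2),
        dao=sample_vessel(base.dao, DAO_MEAN_AREA_MM2),
        pulse_pressure=float(np.clip(rng.normal(var.pulse_pressure_mean,
                                                var.pulse_pressure_sd), 20.0, 100.0)),
        brightness=brightness,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_study(directory, cine: CineSequence, masks: MaskSequence,
                truth: PhantomTruth, format: str = "nifti") -> None:
    """Write one phantom study (images, masks, truth.json) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "nifti":
        save_cine(cine, directory / "cine.nii", format="nifti")
        save_masks(masks, directory / "masks.nii", format="nifti")
    else:
        save_cine(cine, directory / "cine", format="stack")
        save_masks(masks, directory / "masks", format="stack")
    (directory / "truth.json").write_text(truth.to_json())
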