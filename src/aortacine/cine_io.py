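"""Reading, writing and geometric normalisation of aortic cine studies.

A study is a single-slice cine acquisition: ``T`` frames spanning one
cardiac cycle on a fixed ``H x W`` grid, with an in-plane pixel spacing in
millimetres and (for distensibility) a brachial pulse pressure in mmHg.
Supported on-disk forms:

* NIfTI-1 volumes with the last (or configured) axis as time, via nibabel;
  pulse pressure and study id travel in a ``<stem>.meta.json`` sidecar.
* DICOM series (one file per frame) via pydicom, ordered by trigger time
  when present, else by instance number.
* Lossless frame stacks (TIFF for float data, PNG/TIFF for integer data)
  in a directory with a ``meta.json`` sidecar.

Masks use integer labels 0 = background, 1 = ascending aorta (AAo),
2 = descending aorta (DAo).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

LABEL_BACKGROUND = 0
LABEL_AAO = 1
LABEL_DAO = 2

DEFAULT_GRID = 256


class GeometryError(ValueError):
    """Frames in a series disagree on shape, or content exceeds the grid."""


class MetadataError(ValueError):
    """Required acquisition metadata (e.g. pixel spacing) is missing."""


class DataError(ValueError):
    """Image intensities are unusable (NaN/Inf)."""


@dataclass
class CineSequence:
    """One study's cine image time series.

    ``frames`` is a real-valued (T, H, W) stack ordered by cardiac phase;
    ``pixel_spacing`` is (row_mm, col_mm); ``pulse_pressure`` (mmHg) may be
    absent until quantification; ``pad_offsets`` records where the original
    image sits inside a zero-padded grid.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    pulse_pressure: float | None = None
    study_id: str = ""
    pad_offsets: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise GeometryError(f"frames must be (T, H, W), got {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 2 or h < 8 or w < 8:
            raise GeometryError(f"degenerate cine geometry {self.frames.shape}")
        if any(s <= 0 for s in self.pixel_spacing):
            raise MetadataError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class MaskSequence:
    """Per-frame label maps aligned to a :class:`CineSequence`."""

    labels: np.ndarray
    pixel_spacing: tuple[float, float]
    study_id: str = ""
    pad_offsets: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError(f"labels must be (T, H, W), got {self.labels.shape}")
        extra = set(np.unique(self.labels)) - {LABEL_BACKGROUND, LABEL_AAO, LABEL_DAO}
        if extra:
            raise DataError(f"unexpected mask labels {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def vessel_mask(self, label: int) -> np.ndarray:
        """Binary (T, H, W) mask of one vessel."""
        return self.labels == label


# ---------------------------------------------------------------------------
# loading


def load_cine(path, format_hint: Literal["dicom", "nifti", "stack", "auto"] = "auto",
              pixel_spacing_fallback: tuple[float, float] | None = None,
              time_axis: int = -1) -> CineSequence:
    """Load a cine study from NIfTI, a DICOM series, or a frame stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format_hint)
    if fmt == "nifti":
        return _load_nifti(path, time_axis)
    if fmt == "dicom":
        return _load_dicom(path, pixel_spacing_fallback)
    return _load_stack(path, pixel_spacing_fallback)


def _resolve_format(path: Path, hint: str) -> str:
    if hint != "auto":
        return hint
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return "nifti"
    if path.is_dir():
        if any(path.glob("*.dcm")):
            return "dicom"
        return "stack"
    raise ValueError(f"cannot infer format of {path}")


def _load_nifti(path: Path, time_axis: int) -> CineSequence:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[2] == 1:  # (H, W, 1, T) NIfTI convention
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise GeometryError(f"expected a 3-D cine volume in {path}, got {data.shape}")
    frames = np.moveaxis(data, time_axis, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    meta = _read_sidecar(path.with_name(_nifti_stem(path) + ".meta.json"))
    if "pixel_spacing" in meta:
        spacing = tuple(float(v) for v in meta["pixel_spacing"])
    return CineSequence(
        frames=np.ascontiguousarray(frames),
        pixel_spacing=spacing,
        pulse_pressure=meta.get("pulse_pressure"),
        study_id=meta.get("study_id", path.stem),
        pad_offsets=tuple(meta.get("pad_offsets", (0, 0))),
    )


def _nifti_stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _read_sidecar(path: Path) -> dict:
    if path.exists():
        return json.loads(path.read_text())
    return {}


def _load_dicom(path: Path, spacing_fallback) -> CineSequence:
    import pydicom

    files = sorted(path.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        trigger = getattr(ds, "TriggerTime", None)
        if trigger is not None:
            return (0, float(trigger))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    arrays = [ds.pixel_array.astype(np.float64) for ds in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GeometryError(f"inconsistent frame shapes in series: {sorted(shapes)}")
    ds0 = datasets[0]
    spacing = getattr(ds0, "PixelSpacing", None)
    if spacing is not None:
        spacing = (float(spacing[0]), float(spacing[1]))
    elif spacing_fallback is not None:
        spacing = tuple(spacing_fallback)
    else:
        raise MetadataError("DICOM series lacks PixelSpacing and no fallback given")
    return CineSequence(
        frames=np.stack(arrays),
        pixel_spacing=spacing,
        study_id=str(getattr(ds0, "StudyInstanceUID", path.name)),
    )


_FRAME_RE = re.compile(r"(\d+)")


def _load_stack(path: Path, spacing_fallback) -> CineSequence:
    import imageio.v3 as iio
    import tifffile

    files = sorted(
        [f for f in path.iterdir()
         if f.suffix.lower() in (".png", ".tif", ".tiff")],
        key=lambda f: [int(s) if s.isdigit() else s
                       for s in _FRAME_RE.split(f.stem)],
    )
    if not files:
        raise FileNotFoundError(f"no image frames in {path}")
    arrays = []
    for f in files:
        if f.suffix.lower() in (".tif", ".tiff"):
            arrays.append(np.asarray(tifffile.imread(str(f))))
        else:
            arrays.append(np.asarray(iio.imread(f)))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GeometryError(f"inconsistent frame shapes in stack: {sorted(shapes)}")
    meta = _read_sidecar(path / "meta.json")
    if "pixel_spacing" in meta:
        spacing = tuple(float(v) for v in meta["pixel_spacing"])
    elif spacing_fallback is not None:
        spacing = tuple(spacing_fallback)
    else:
        raise MetadataError(f"stack {path} lacks pixel spacing (no meta.json, no fallback)")
    return CineSequence(
        frames=np.stack(arrays),
        pixel_spacing=spacing,
        pulse_pressure=meta.get("pulse_pressure"),
        study_id=meta.get("study_id", path.name),
        pad_offsets=tuple(meta.get("pad_offsets", (0, 0))),
    )


def load_masks(path, format_hint: Literal["nifti", "stack", "auto"] = "auto",
               pixel_spacing_fallback=None) -> MaskSequence:
    """Load a label-map sequence saved by :func:`save_masks`."""
    seq = load_cine(path, "auto" if format_hint == "auto" else format_hint,
                    pixel_spacing_fallback=pixel_spacing_fallback)
    return MaskSequence(
        labels=np.rint(seq.frames).astype(np.uint8),
        pixel_spacing=seq.pixel_spacing,
        study_id=seq.study_id,
        pad_offsets=seq.pad_offsets,
    )


# ---------------------------------------------------------------------------
# saving


def save_cine(seq: CineSequence, path, format: Literal["nifti", "stack"] = "nifti",
              time_axis: int = -1) -> None:
    """Write a cine study losslessly (NIfTI volume or TIFF frame stack)."""
    _save_array(seq.frames, _meta_dict(seq), Path(path), format, time_axis)


def save_masks(masks: MaskSequence, path,
               format: Literal["nifti", "stack"] = "nifti") -> None:
    """Write a mask sequence losslessly; labels are stored as uint8."""
    _save_array(masks.labels.astype(np.uint8), _meta_dict(masks), Path(path), format, -1)


def _meta_dict(seq) -> dict:
    meta = {
        "pixel_spacing": list(seq.pixel_spacing),
        "study_id": seq.study_id,
        "pad_offsets": list(seq.pad_offsets),
    }
    pp = getattr(seq, "pulse_pressure", None)
    if pp is not None:
        meta["pulse_pressure"] = float(pp)
    return meta


def _save_array(frames: np.ndarray, meta: dict, path: Path, format: str,
                time_axis: int) -> None:
    if format == "nifti":
        import nibabel as nib

        data = np.moveaxis(frames, 0, time_axis)
        affine = np.diag([meta["pixel_spacing"][0], meta["pixel_spacing"][1], 1.0, 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((meta["pixel_spacing"][0], meta["pixel_spacing"][1], 1.0))
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(path))
        sidecar = path.with_name(_nifti_stem(path) + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2))
    elif format == "stack":
        import tifffile

        path.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(frames):
            tifffile.imwrite(str(path / f"frame_{t:03d}.tif"), frame)
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# geometry and intensity normalisation


def pad_to_grid(seq, target: int = DEFAULT_GRID):
    """Zero-pad a cine or mask sequence to ``target x target``.

    Content is centred, with ties broken toward the top-left; the placement
    is recorded in ``pad_offsets`` so :func:`crop_to_original` inverts it.
    Masks are padded with background.
    """
    arr, kind = _payload(seq)
    t, h, w = arr.shape
    if h > target or w > target:
        raise GeometryError(f"frame {h}x{w} exceeds target grid {target}")
    r0, c0 = (target - h) // 2, (target - w) // 2
    out = np.zeros((t, target, target), dtype=arr.dtype)
    out[:, r0:r0 + h, c0:c0 + w] = arr
    return _replace(seq, kind, out, (r0, c0))


def _payload(seq):
    if isinstance(seq, CineSequence):
        return seq.frames, "frames"
    if isinstance(seq, MaskSequence):
        return seq.labels, "labels"
    raise TypeError(type(seq))


def _replace(seq, kind, arr, offsets):
    return dataclasses.replace(seq, **{kind: arr, "pad_offsets": offsets})


def crop_to_original(seq, original_shape: tuple[int, int]):
    """Invert :func:`pad_to_grid` using the recorded ``pad_offsets``."""
    arr, kind = _payload(seq)
    r0, c0 = seq.pad_offsets
    h, w = original_shape
    return _replace(seq, kind, arr[:, r0:r0 + h, c0:c0 + w], (0, 0))


def normalize_intensities(seq: CineSequence) -> CineSequence:
    """Linearly rescale a study's intensities to [0, 1] (per study).

    A constant stack maps to all zeros; non-finite intensities raise
    :class:`DataError`.
    """
    frames = seq.frames.astype(np.float64)
    if not np.isfinite(frames).all():
        raise DataError(f"study {seq.study_id!r} contains NaN/Inf intensities")
    lo, hi = frames.min(), frames.max()
    if hi > lo:
        frames = (frames - lo) / (hi - lo)
    else:
        frames = np.zeros_like(frames)
    return dataclasses.replace(seq, frames=frames)
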