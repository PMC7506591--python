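"""CT volume I/O and the soft-tissue display window.

Volumes are held as ``CTVolume`` objects: a ``(slice, row, col)`` array of
Hounsfield units ordered inferior to superior, together with the voxel
spacing ``(slice thickness, row pitch, col pitch)`` in millimetres.

All segmentation operates on 8-bit images produced by the soft-tissue
window: HU in [-140, 260] are mapped linearly onto gray levels [0, 255],
values outside the window are clamped to 0 / 255.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .categories import ID_TO_CATEGORY

#: Lower / upper bound of the soft-tissue window in Hounsfield units.
HU_WINDOW = (-140.0, 260.0)


class VolumeLoadError(RuntimeError):
    """The input files are missing, unreadable or not HU-convertible."""


class GeometryError(RuntimeError):
    """Slices of a series disagree on shape, spacing or orientation."""


@dataclass(frozen=True)
class CTVolume:
    """A CT scan in Hounsfield units.

    Attributes
    ----------
    voxels
        ``(slice, row, col)`` float array of HU values, slice axis ordered
        inferior to superior.
    spacing
        ``(slice thickness, row pitch, col pitch)`` in mm, all positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("voxels must be a 3D (slice, row, col) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("HU values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "voxels", v.astype(np.float64, copy=False))

    @property
    def slice_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class WindowedSlice:
    """One CT slice after the soft-tissue window: gray levels in [0, 255]."""

    pixels: np.ndarray
    slice_index: int

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("pixels must be 2D")
        if p.min(initial=0) < 0 or p.max(initial=0) > 255:
            raise ValueError("windowed gray levels must lie in [0, 255]")
        object.__setattr__(self, "pixels", p.astype(np.uint8, copy=False))


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, half-open pixel ranges.

    The ROI covers rows ``row_min:row_max`` and columns ``col_min:col_max``
    (0-based, end exclusive).
    """

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError("ROI must have positive extent")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("ROI must lie inside the image")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    def contains(self, row: int, col: int) -> bool:
        return (self.row_min <= row < self.row_max
                and self.col_min <= col < self.col_max)

    def crop(self, image: np.ndarray) -> np.ndarray:
        if self.row_max > image.shape[0] or self.col_max > image.shape[1]:
            raise ValueError("ROI exceeds image bounds")
        return image[self.row_min:self.row_max, self.col_min:self.col_max]


def window_soft_tissue(slice_hu: np.ndarray, slice_index: int = 0) -> WindowedSlice:
    """Apply the soft-tissue window to one HU slice.

    ``g = round(255 * (HU + 140) / 400)`` for HU inside [-140, 260]; values
    below the window map to 0, values above to 255.  Rounding is
    half-away-from-zero (equivalently half-up, the scaled value being
    non-negative) so the mapping is deterministic across platforms.
    """
    hu = np.asarray(slice_hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    lo, hi = HU_WINDOW
    scaled = 255.0 * (hu - lo) / (hi - lo)
    gray = np.floor(scaled + 0.5)
    gray = np.clip(gray, 0.0, 255.0)
    return WindowedSlice(pixels=gray.astype(np.uint8), slice_index=slice_index)


def window_volume(volume: CTVolume) -> list[WindowedSlice]:
    """Window every slice of a volume with the single global window."""
    return [window_soft_tissue(volume.voxels[s], s)
            for s in range(volume.slice_count)]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred from the path (directory -> DICOM series, ``.nii``/``.nii.gz``
    -> NIfTI).  DICOM stored values are converted to HU with the mandatory
    RescaleSlope/RescaleIntercept; files lacking them are rejected.  Slices
    are ordered inferior to superior (ascending patient z).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"no such file or directory: {path}")
    if format is None:
        if path.is_dir():
            format = "dicom_series"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise VolumeLoadError(f"cannot infer volume format of {path}")
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise VolumeLoadError(f"cannot read NIfTI {path}: {exc}") from exc
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(voxels=data, spacing=(float(zooms[0]), float(zooms[1]),
                                          float(zooms[2])))


def _load_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise VolumeLoadError(f"empty DICOM directory {path}")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise VolumeLoadError(f"cannot read DICOM file {f}: {exc}") from exc
        if "PixelData" not in ds:
            continue
        datasets.append(ds)
    if not datasets:
        raise VolumeLoadError(f"no image slices found in {path}")

    def z_of(ds) -> float:
        try:
            return float(ds.ImagePositionPatient[2])
        except Exception:
            raise GeometryError("slice lacks ImagePositionPatient") from None

    datasets.sort(key=z_of)  # ascending z = inferior -> superior
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise GeometryError(f"inconsistent slice shapes: {sorted(shapes)}")
    spacings = {tuple(float(x) for x in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise GeometryError(f"inconsistent pixel spacing: {sorted(spacings)}")
    row_mm, col_mm = spacings.pop()

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise VolumeLoadError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; "
                "stored values cannot be converted to HU")
        hu = (ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
              + float(ds.RescaleIntercept))
        slices.append(hu)
    if len(datasets) > 1:
        zs = [z_of(ds) for ds in datasets]
        dz = np.diff(zs)
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3):
            raise GeometryError("non-uniform or duplicated slice positions")
        slice_mm = float(dz[0])
    else:
        slice_mm = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    return CTVolume(voxels=np.stack(slices), spacing=(slice_mm, row_mm, col_mm))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI (array stored as (slice, row, col))."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32),
                          _affine(volume.spacing))
    nib.save(img, str(path))


def write_masks(labels: np.ndarray,
                path: str | Path,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                per_category: bool = False) -> list[Path]:
    """Write a label stack as a NIfTI multi-label volume plus a sidecar.

    Parameters
    ----------
    labels
        ``(slice, row, col)`` integer label stack using the package's
        category ids.
    path
        Output directory; created if missing.  Files written: ``labels.nii``,
        ``labels_legend.txt`` and, when ``per_category`` is set, one binary
        mask ``mask_<category>.nii`` per category present.

    Returns the list of written paths.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("label stack must be 3D (slice, row, col)")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    label_file = out / "labels.nii"
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(spacing)),
             str(label_file))
    written.append(label_file)

    legend = out / "labels_legend.txt"
    with legend.open("w") as fh:
        fh.write("# label id <TAB> category\n")
        for lid in sorted(ID_TO_CATEGORY):
            fh.write(f"{lid}\t{ID_TO_CATEGORY[lid]}\n")
    written.append(legend)

    if per_category:
        for lid, name in sorted(ID_TO_CATEGORY.items()):
            if lid == 0 or not np.any(labels == lid):
                continue
            mask_file = out / f"mask_{name}.nii"
            nib.save(nib.Nifti1Image((labels == lid).astype(np.uint8),
                                     _affine(spacing)), str(mask_file))
            written.append(mask_file)
    return written


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a label stack written by :func:`write_masks` (or any NIfTI)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def write_contours_json(contours: dict, path: str | Path) -> None:
    """Serialize a contour set as JSON: slice -> category -> polygons."""
    serialisable = {
        str(s): {cat: [np.asarray(p).tolist() for p in polys]
                 for cat, polys in per_cat.items()}
        for s, per_cat in contours.items()
    }
    Path(path).write_text(json.dumps(
        {"coordinate_convention": "0-based (row, col), pixel-corner vertices",
         "slices": serialisable}))
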