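"""Agreement metrics between a predicted and a reference label stack.

Per category the voxel confusion counts give the Dice coefficient
``2TP / (FP + 2TP + FN)`` and false-positive / false-negative rates; both
rates are normalised by the reference-positive count (FP/refpos,
FN/refpos), the convention under which an over-inclusive contour can show
an FPR above 0.5 while keeping a reasonable Dice.  Contour distance is the
symmetric Hausdorff distance ``max(h(A,B), h(B,A))`` with
``h(A,B) = max_a min_b d(a, b)`` between boundary voxels, reported both in
index units and in millimetres.

Slices on which the reference does not delineate a category are excluded
from that category's counts, mirroring partial clinical contouring; a
category absent from the reference everywhere is reported as
not-applicable (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .categories import CATEGORY_IDS, ORGAN_CATEGORIES


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level confusion counts for one category."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_masks(cls, pred: np.ndarray, ref: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        ref = np.asarray(ref, dtype=bool)
        if pred.shape != ref.shape:
            raise ValueError("mask shapes differ")
        tp = int(np.sum(pred & ref))
        fp = int(np.sum(pred & ~ref))
        fn = int(np.sum(~pred & ref))
        tn = pred.size - tp - fp - fn
        return cls(tp, fp, fn, tn)


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient 2TP / (FP + 2TP + FN); NaN when both masks empty."""
    denom = counts.fp + 2 * counts.tp + counts.fn
    if denom == 0:
        return float("nan")
    return 2.0 * counts.tp / denom


def fpr_fnr(counts: ConfusionCounts) -> tuple[float, float]:
    """(FP, FN) normalised by the reference-positive count; NaN if empty."""
    refpos = counts.tp + counts.fn
    if refpos == 0:
        return float("nan"), float("nan")
    return counts.fp / refpos, counts.fn / refpos


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary voxels (those with a face-neighbour outside)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, mask.ndim), dtype=np.intp)
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Symmetric Euclidean Hausdorff distance between two point sets."""
    a = np.asarray(set_a, dtype=np.float64)
    b = np.asarray(set_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class MetricReport:
    """Per-category metric table plus volume-level summary statistics."""

    table: pd.DataFrame  # index: category; columns: dice, fpr, fnr, ...

    @property
    def summary(self) -> pd.DataFrame:
        num = self.table[["dice", "fpr", "fnr", "hd_px", "hd_mm"]]
        return pd.DataFrame({"mean": num.mean(), "std": num.std(ddof=1)}).T

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "category", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MetricReport":
        df = pd.read_csv(path).set_index("category")
        df.index.name = None
        return cls(table=df)

    def __getitem__(self, category: str) -> pd.Series:
        return self.table.loc[category]


def compare_stacks(pred: np.ndarray, ref: np.ndarray,
                   spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                   categories: tuple[str, ...] = ORGAN_CATEGORIES,
                   ) -> MetricReport:
    """Compare two label stacks category by category.

    Counts are accumulated over the slices where the reference delineates
    the category; the Hausdorff distance uses 3D boundary voxels of the
    same slice subset.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")

    rows = {}
    for name in categories:
        cid = CATEGORY_IDS[name]
        ref_mask = ref == cid
        slices = np.flatnonzero(ref_mask.reshape(ref.shape[0], -1).any(axis=1))
        if slices.size == 0:
            rows[name] = dict(dice=np.nan, fpr=np.nan, fnr=np.nan,
                              hd_px=np.nan, hd_mm=np.nan, n_slices=0,
                              note="no reference delineations")
            continue
        pm = (pred == cid)[slices]
        rm = ref_mask[slices]
        counts = ConfusionCounts.from_masks(pm, rm)
        d = dice(counts)
        fpr, fnr = fpr_fnr(counts)
        bp = boundary_points(pm)
        br = boundary_points(rm)
        hd_px = hausdorff(bp, br)
        hd_mm = hausdorff(bp * np.asarray(spacing), br * np.asarray(spacing))
        rows[name] = dict(dice=d, fpr=fpr, fnr=fnr, hd_px=hd_px,
                          hd_mm=hd_mm, n_slices=int(slices.size), note="")
    return MetricReport(table=pd.DataFrame.from_dict(rows, orient="index"))
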