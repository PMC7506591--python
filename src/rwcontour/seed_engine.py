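"""Automatic seed generation and vanishing between consecutive slices.

Between two neighbouring CT slices, organ cross-sections change little, so
the previous slice's segmentation can seed the next one.  Two seed sources
are used per 4-connected component of each category:

* *boundary erosion* (primary): the region is eroded by a disk (radius 12
  for regions larger than 1000 px, radius 1 otherwise) and seeds are
  sampled from the eroded region's edge;
* *skeleton* (rescue): when erosion annihilates a thin region, the region
  is thinned to a pruned 1-px skeleton and seeds are sampled from it.

Candidate seeds are then checked against an anatomical gray-level
knowledge table on the *next* slice (air-filled categories must be nearly
black, soft tissue must not be, the cord must not sit on bone-white), and
offending seeds vanish.  If sampling left a component with no surviving
seed while admissible candidate pixels exist, the sample is re-drawn from
the admissible candidates so a live organ never silently loses tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import erosion as _gray_erosion
from skimage.morphology import skeletonize

from .categories import CATEGORY_IDS, ID_TO_CATEGORY
from .image_io import WindowedSlice
from .rw_core import Seed, SeedSet

#: 4-connected structuring element used for component analysis.
_CROSS = ndimage.generate_binary_structure(2, 1)


def disk_footprint(radius: int) -> np.ndarray:
    """Disk structuring element: pixels with squared distance <= radius^2."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


@dataclass(frozen=True)
class ErosionPolicy:
    """Disk radii of the boundary erosion, switched on region area."""

    area_threshold: int = 1000
    large_radius: int = 12
    small_radius: int = 1

    def __post_init__(self) -> None:
        if self.large_radius <= 0 or self.small_radius <= 0 or \
           self.area_threshold <= 0:
            raise ValueError("erosion policy parameters must be positive")

    def radius_for(self, area: int) -> int:
        return self.large_radius if area > self.area_threshold else self.small_radius


@dataclass(frozen=True)
class HUKnowledgeTable:
    """Admissible windowed gray levels per category.

    Air-filled categories (lungs, airway, background) admit gray levels of
    at most ``air_gray_max`` (default 10); body and tumor must exceed it;
    the spinal cord rejects the bone-white level 255.  The heart (with its
    neighbouring vessels) is muscle/blood, so its seeds must fall in the
    soft-tissue band — in particular *fat* gray levels are inadmissible,
    which lets heart tracking shrink with the organ near its apex/base
    instead of lingering in mediastinal fat.  Predicates are pure
    functions of the gray level.
    """

    air_gray_max: int = 10
    bone_gray: int = 255
    soft_tissue_gray: tuple[int, int] = (85, 200)
    predicates: dict[str, Callable[[np.ndarray], np.ndarray]] = field(
        default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.predicates is None:
            a, b = self.air_gray_max, self.bone_gray
            lo, hi = self.soft_tissue_gray
            object.__setattr__(self, "predicates", {
                "lungs": lambda g: g <= a,
                "airway": lambda g: g <= a,
                "body": lambda g: g >= a,
                "gtv": lambda g: g >= a,
                "heart": lambda g: (g >= lo) & (g <= hi),
                "spinal_cord": lambda g: g != b,
                "background": lambda g: g <= a,
            })

    def admits(self, label: str, gray) -> np.ndarray:
        if label not in self.predicates:
            raise ValueError(f"no gray-level predicate for category {label!r}")
        return np.asarray(self.predicates[label](np.asarray(gray)))

    @classmethod
    def default(cls) -> "HUKnowledgeTable":
        return cls()


def erode_region(mask: np.ndarray, policy: ErosionPolicy | None = None) -> np.ndarray:
    """Erode one category region with the area-dependent disk.

    Regions larger than the policy's area threshold use the large disk,
    smaller regions the 1-px disk.  The result may be empty; that is the
    legal signal for the skeleton fallback, not an error.
    """
    policy = policy or ErosionPolicy()
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return np.zeros_like(mask)
    radius = policy.radius_for(area)
    # pad with background so regions touching the image border erode from
    # the outside too
    padded = np.pad(mask, radius).astype(np.uint8)
    eroded = _gray_erosion(padded, disk_footprint(radius)).astype(bool)
    return eroded[radius:-radius, radius:-radius]


def absorb_small_components(labelmap: np.ndarray, min_size: int) -> np.ndarray:
    """Merge category components smaller than ``min_size`` pixels into the
    label surrounding them (majority vote over the component's border
    ring).  Suppresses single-pixel speckle in label maps."""
    if min_size <= 1:
        return labelmap
    out = np.asarray(labelmap).copy()
    for cid in np.unique(out):
        comps, n = ndimage.label(out == cid, structure=_CROSS)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comps), comps,
                                   index=np.arange(1, n + 1))
        for i in np.flatnonzero(sizes < min_size):
            comp = comps == i + 1
            ring = ndimage.binary_dilation(comp, structure=_CROSS) & ~comp
            vals = out[ring]
            if vals.size:
                out[comp] = int(np.argmax(np.bincount(vals)))
    return out


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Inner edge of a region: pixels with a 4-neighbour outside."""
    mask = np.asarray(mask, dtype=bool)
    return mask & ~ndimage.binary_erosion(mask, structure=_CROSS,
                                          border_value=0)


def _sample_points(points_rc: np.ndarray, count_ratio: float,
                   rng: np.random.Generator, max_seeds: int) -> np.ndarray:
    n = len(points_rc)
    count = max(1, int(round(count_ratio * n)))
    count = min(count, max_seeds, n)
    if count == n:
        return points_rc
    # order points deterministically before sampling so the draw depends
    # only on the rng state, not on nonzero() ordering quirks
    idx = rng.choice(n, size=count, replace=False)
    return points_rc[np.sort(idx)]


def sample_boundary_seeds(eroded: np.ndarray, label: str, count_ratio: float,
                          rng: np.random.Generator, slice_index: int,
                          max_seeds: int = 20) -> list[Seed]:
    """Uniformly sample seeds from the edge of an eroded region.

    Returns ``max(1, round(count_ratio * boundary length))`` seeds (capped
    at ``max_seeds``), all lying on the eroded mask's inner boundary.  An
    empty mask returns no seeds, signalling the skeleton fallback.
    """
    eroded = np.asarray(eroded, dtype=bool)
    if not eroded.any():
        return []
    pts = np.argwhere(boundary_pixels(eroded))
    chosen = _sample_points(pts, count_ratio, rng, max_seeds)
    return [Seed(slice_index, int(r), int(c), label) for r, c in chosen]


def prune_skeleton(skel: np.ndarray, min_branch: int = 5) -> np.ndarray:
    """Remove spur branches shorter than ``min_branch`` pixels (one pass).

    End points are walked toward the nearest junction; if the junction is
    reached in fewer than ``min_branch`` steps the walked spur is deleted.
    A skeleton with no junction (a bare arc or a single pixel) is kept.
    """
    skel = np.asarray(skel, dtype=bool).copy()
    nb = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3), np.int8),
                          mode="constant") - skel
    endpoints = np.argwhere(skel & (nb == 1))
    h, w = skel.shape
    for r0, c0 in endpoints:
        path = [(int(r0), int(c0))]
        prev = None
        cur = (int(r0), int(c0))
        while len(path) < min_branch:
            neigh = [(cur[0] + dr, cur[1] + dc)
                     for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                     if (dr or dc)
                     and 0 <= cur[0] + dr < h and 0 <= cur[1] + dc < w
                     and skel[cur[0] + dr, cur[1] + dc]
                     and (cur[0] + dr, cur[1] + dc) != prev]
            if len(neigh) == 0:
                path = []  # isolated arc shorter than the threshold: keep
                break
            if len(neigh) > 1:
                # reached a junction: delete the walked spur
                for r, c in path:
                    skel[r, c] = False
                path = []
                break
            prev, cur = cur, neigh[0]
            path.append(cur)
    return skel


def skeleton_seeds(mask: np.ndarray, label: str, count_ratio: float,
                   rng: np.random.Generator, slice_index: int,
                   max_seeds: int = 20, prune_len: int = 5) -> list[Seed]:
    """Sample seeds from the pruned 1-px skeleton of a region.

    An empty mask yields an empty list (the category has vanished).  A
    single-pixel region returns that pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    skel = skeletonize(mask)
    pruned = prune_skeleton(skel, prune_len)
    if not pruned.any():
        pruned = skel  # pruning must never erase the whole skeleton
    if not pruned.any():
        pruned = mask
    pts = np.argwhere(pruned)
    chosen = _sample_points(pts, count_ratio, rng, max_seeds)
    return [Seed(slice_index, int(r), int(c), label) for r, c in chosen]


def filter_bad_seeds(seeds: Sequence[Seed], next_slice: WindowedSlice,
                     table: HUKnowledgeTable | None = None) -> list[Seed]:
    """Keep exactly the seeds whose gray level on the next slice is
    admissible for their category; order is preserved.  Idempotent."""
    table = table or HUKnowledgeTable.default()
    gray = next_slice.pixels
    out = []
    for s in seeds:
        if bool(table.admits(s.label, int(gray[s.row, s.col]))):
            out.append(s)
    return out


@dataclass
class PropagationReport:
    """Per-category bookkeeping of one seed propagation step."""

    seed_counts: dict[str, int] = field(default_factory=dict)
    skeleton_fallbacks: list[str] = field(default_factory=list)
    rescued: list[str] = field(default_factory=list)
    vanished: list[str] = field(default_factory=list)

    @property
    def all_starved(self) -> bool:
        return all(v == 0 for v in self.seed_counts.values())


def _component_seeds(comp_mask: np.ndarray, label: str, policy: ErosionPolicy,
                     table: HUKnowledgeTable, next_slice: WindowedSlice,
                     count_ratio: float, max_seeds: int,
                     rng: np.random.Generator, slice_index: int,
                     report: PropagationReport) -> list[Seed]:
    # both seed sources run on every component: the eroded edge hugs the
    # region outline while the skeleton covers its medial line, so thin
    # stretches of ring-like regions (body wall, mediastinum) stay seeded
    eroded = erode_region(comp_mask, policy)
    if eroded.any():
        cands = sample_boundary_seeds(eroded, label, count_ratio, rng,
                                      slice_index, max_seeds)
    else:
        report.skeleton_fallbacks.append(label)
        cands = []
    cands += skeleton_seeds(comp_mask, label, count_ratio, rng,
                            slice_index, max_seeds)
    kept = filter_bad_seeds(cands, next_slice, table)
    if kept:
        return kept
    # last resort: sample directly from the admissible candidate pixels of
    # either source, so that a component only vanishes when no admissible
    # pixel exists at all
    pool = boundary_pixels(eroded) if eroded.any() else np.zeros_like(comp_mask)
    pool = pool | skeletonize(comp_mask)
    pts = np.argwhere(pool)
    if len(pts):
        ok = table.admits(label, next_slice.pixels[pts[:, 0], pts[:, 1]])
        pts = pts[np.asarray(ok, dtype=bool)]
    if len(pts):
        chosen = _sample_points(pts, count_ratio, rng, max_seeds)
        report.rescued.append(label)
        return [Seed(slice_index, int(r), int(c), label) for r, c in chosen]
    return []


def propagate_seeds(labelmap: np.ndarray, next_slice: WindowedSlice,
                    policy: ErosionPolicy | None = None,
                    table: HUKnowledgeTable | None = None,
                    count_ratio: float = 0.05,
                    max_seeds: int = 20,
                    rng_seed: int = 0,
                    component_presplit: dict[str, Callable[[np.ndarray], list[np.ndarray]]] | None = None,
                    ) -> tuple[SeedSet, PropagationReport]:
    """Generate the next slice's seeds from the previous slice's label map.

    Every category present in ``labelmap`` is processed per 4-connected
    component: erosion-edge sampling first, skeleton rescue when erosion
    empties the component, gray-level filtering against ``next_slice``
    last.  ``component_presplit`` optionally splits a category's component
    masks further before sampling (used at the tracheal bifurcation).

    Randomness is drawn from ``rng_seed`` split deterministically per
    (slice, category, component), so reruns are bit-identical.
    """
    policy = policy or ErosionPolicy()
    table = table or HUKnowledgeTable.default()
    labelmap = np.asarray(labelmap)
    slice_index = next_slice.slice_index
    report = PropagationReport()
    entries: list[Seed] = []

    for cat_id in sorted(np.unique(labelmap)):
        label = ID_TO_CATEGORY[int(cat_id)]
        cat_mask = labelmap == cat_id
        comps, n_comp = ndimage.label(cat_mask, structure=_CROSS)
        masks = [comps == i for i in range(1, n_comp + 1)]
        if component_presplit and label in component_presplit:
            masks = [m for mask in masks
                     for m in component_presplit[label](mask)]
        total = 0
        for ci, comp_mask in enumerate(masks):
            rng = np.random.default_rng(
                np.random.SeedSequence(rng_seed,
                                       spawn_key=(slice_index, int(cat_id), ci)))
            got = _component_seeds(comp_mask, label, policy, table,
                                   next_slice, count_ratio, max_seeds, rng,
                                   slice_index, report)
            entries.extend(got)
            total += len(got)
        report.seed_counts[label] = total
        if total == 0:
            report.vanished.append(label)
    return SeedSet(entries=entries), report
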