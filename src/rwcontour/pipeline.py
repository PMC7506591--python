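"""Slice-by-slice orchestration of the whole-volume contouring run.

Starting from one user-seeded slice, the pipeline segments that slice with
the random walker, refines the spinal cord with the Hough circle fitter,
then propagates seeds bidirectionally (superior and inferior) through the
volume, re-segmenting every slice.  The heart category is only active on
the user-declared slice range where the heart exists, and below the
trachea/bronchus junction slice the airway is tracked as two separate
bronchial components.  Outputs are the full label stack, per-slice contour
polygons and a JSON-serialisable run log (seed counts, fallbacks, flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy import ndimage

from .categories import CATEGORY_IDS, ID_TO_CATEGORY, ORGAN_CATEGORIES
from .contours import trace_contours
from .image_io import (ROI, CTVolume, WindowedSlice, window_soft_tissue,
                       write_contours_json, write_masks)
from .rw_core import (DEFAULT_BETA, Seed, SeedSet, segment_slice)
from .seed_engine import (ErosionPolicy, HUKnowledgeTable,
                          absorb_small_components, propagate_seeds)
from .spine_fitter import Circle, SpineParams, refine_spine

_CROSS = ndimage.generate_binary_structure(2, 1)
_AIRWAY_ID = CATEGORY_IDS["airway"]
_HEART = "heart"
_CORD = "spinal_cord"
_BG_ID = CATEGORY_IDS["background"]


class ConfigError(ValueError):
    """The run configuration or initial seeds are inconsistent."""


@dataclass
class RunConfig:
    """Everything a reproducible run needs besides the volume and seeds."""

    initial_slice: int
    heart_range: tuple[int, int]
    junction_slice: int
    roi: ROI | None = None
    beta: float = DEFAULT_BETA
    rng_seed: int = 0
    categories: tuple[str, ...] = ORGAN_CATEGORIES
    count_ratio: float = 0.05
    max_seeds: int = 20
    erosion: ErosionPolicy = field(default_factory=ErosionPolicy)
    spine: SpineParams = field(default_factory=SpineParams)
    min_component: int = 5
    background_seed_stride: int = 5

    def __post_init__(self) -> None:
        if self.heart_range[0] > self.heart_range[1]:
            raise ConfigError("heart_range must be (appear, disappear) ordered")

    # YAML round trip ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            "beta": float(self.beta),
            "initial_slice": int(self.initial_slice),
            "heart_range": [int(x) for x in self.heart_range],
            "junction_slice": int(self.junction_slice),
            "rng_seed": int(self.rng_seed),
            "categories": list(self.categories),
            "min_component": int(self.min_component),
            "background_seed_stride": int(self.background_seed_stride),
            "seed_engine": {
                "count_ratio": float(self.count_ratio),
                "max_seeds": int(self.max_seeds),
                "area_threshold": int(self.erosion.area_threshold),
                "large_radius": int(self.erosion.large_radius),
                "small_radius": int(self.erosion.small_radius),
            },
            "spine": {k: (float(v) if isinstance(v, float) else int(v))
                      for k, v in asdict(self.spine).items()},
        }
        if self.roi is not None:
            data["roi"] = [self.roi.row_min, self.roi.row_max,
                           self.roi.col_min, self.roi.col_max]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        se = data.get("seed_engine", {})
        sp = data.get("spine", {})
        roi = data.get("roi")
        return cls(
            initial_slice=int(data["initial_slice"]),
            heart_range=tuple(int(x) for x in data["heart_range"]),
            junction_slice=int(data["junction_slice"]),
            roi=ROI(*(int(x) for x in roi)) if roi else None,
            beta=float(data.get("beta", DEFAULT_BETA)),
            rng_seed=int(data.get("rng_seed", 0)),
            categories=tuple(data.get("categories", ORGAN_CATEGORIES)),
            count_ratio=float(se.get("count_ratio", 0.05)),
            max_seeds=int(se.get("max_seeds", 20)),
            erosion=ErosionPolicy(
                area_threshold=int(se.get("area_threshold", 1000)),
                large_radius=int(se.get("large_radius", 12)),
                small_radius=int(se.get("small_radius", 1))),
            spine=SpineParams(**{k: sp[k] for k in sp}) if sp else SpineParams(),
            min_component=int(data.get("min_component", 5)),
            background_seed_stride=int(data.get("background_seed_stride", 5)),
        )


@dataclass
class RunResult:
    """Label stack, contours and bookkeeping of one pipeline run."""

    labels: np.ndarray  # (slice, row, col) category ids
    contours: dict[int, dict[str, list[np.ndarray]]]
    log: dict
    config: RunConfig

    def save(self, outdir: str | Path,
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
             per_category_masks: bool = False) -> None:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_masks(self.labels, outdir, spacing,
                    per_category=per_category_masks)
        write_contours_json(self.contours, outdir / "contours.json")
        (outdir / "runlog.json").write_text(json.dumps(self.log, indent=1))
        self.config.to_yaml(outdir / "run.yaml")


def suggest_roi(wslice: WindowedSlice, margin: int = 10,
                body_gray_min: int = 10) -> ROI:
    """Bounding box of body-range gray levels, dilated by ``margin``."""
    mask = wslice.pixels > body_gray_min
    if not mask.any():
        raise ConfigError("cannot suggest an ROI on an empty slice")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h, w = wslice.pixels.shape
    return ROI(max(int(rows[0]) - margin, 0),
               min(int(rows[-1]) + 1 + margin, h),
               max(int(cols[0]) - margin, 0),
               min(int(cols[-1]) + 1 + margin, w))


def handle_junction(labelmap: np.ndarray, slice_index: int,
                    junction_slice: int) -> tuple[np.ndarray, list[str]]:
    """Enforce the bronchial component budget below the junction slice.

    Inferior to the junction the airway is expected to consist of the two
    bronchi: any additional components are absorbed into their surrounding
    label and logged.  At or above the junction nothing is altered.
    """
    flags: list[str] = []
    if slice_index >= junction_slice:
        return labelmap, flags
    airway = labelmap == _AIRWAY_ID
    comps, n = ndimage.label(airway, structure=_CROSS)
    if n <= 2:
        return labelmap, flags
    sizes = ndimage.sum_labels(np.ones_like(comps), comps,
                               index=np.arange(1, n + 1))
    keep = set((np.argsort(sizes)[::-1][:2] + 1).tolist())
    out = labelmap.copy()
    for i in range(1, n + 1):
        if i in keep:
            continue
        comp = comps == i
        ring = ndimage.binary_dilation(comp, structure=_CROSS) & ~comp
        vals = out[ring]
        out[comp] = int(np.argmax(np.bincount(vals))) if vals.size else _BG_ID
        flags.append(f"airway: dropped extra component of {int(sizes[i-1])} px")
    return out, flags


def _split_at_centroid_col(mask: np.ndarray) -> list[np.ndarray]:
    """Split one component into left/right halves at its centroid column.

    Used when seed propagation crosses the junction in the inferior
    direction, so that each prospective bronchus gets its own seeds.  If
    either half would be empty the component is kept whole.
    """
    cols = np.nonzero(mask)[1]
    pivot = cols.mean()
    left = mask & (np.arange(mask.shape[1])[None, :] <= pivot)
    right = mask & ~left
    if left.any() and right.any():
        return [left, right]
    return [mask]


def _background_border_seeds(wslice: WindowedSlice, roi: ROI,
                             stride: int, air_gray_max: int = 10) -> list[Seed]:
    """Automatic background seeds on ROI-border pixels outside the body."""
    patch = roi.crop(wslice.pixels)
    h, w = patch.shape
    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border &= patch <= air_gray_max
    pts = np.argwhere(border)[::max(stride, 1)]
    return [Seed(wslice.slice_index, int(r) + roi.row_min,
                 int(c) + roi.col_min, "background") for r, c in pts]


def _segment_one(wslice: WindowedSlice, roi: ROI, seeds: list[Seed],
                 config: RunConfig, prev_circle: Circle | None,
                 cord_hint: tuple[int, int] | None = None,
                 ) -> tuple[np.ndarray, Circle | None, list[str]]:
    """Random walker + cleanup + junction budget + spine refinement for one
    slice.  Returns the full-size label map and the tracked cord circle."""
    lm_roi, _ = segment_slice(wslice, roi, seeds, beta=config.beta)
    full = np.full(wslice.pixels.shape, _BG_ID, dtype=np.int16)
    full[roi.row_min:roi.row_max, roi.col_min:roi.col_max] = lm_roi
    full = absorb_small_components(full, config.min_component)
    full, flags = handle_junction(full, wslice.slice_index,
                                  config.junction_slice)
    circle = prev_circle
    if any(s.label == _CORD for s in seeds) or prev_circle is not None:
        full, circle, spine_flags = refine_spine(
            full, wslice, prev_circle, config.spine, center_hint=cord_hint)
        flags.extend(spine_flags)
    return full, circle, flags


def run(volume: CTVolume, initial_seeds: SeedSet, config: RunConfig,
        table: HUKnowledgeTable | None = None) -> RunResult:
    """Segment a whole CT volume from one seeded slice.

    The initial slice is segmented from the user seeds; seeds for every
    other slice are derived from the neighbouring slice's result by the
    erosion/skeleton propagation scheme, moving superior and inferior from
    the initial slice.  Deterministic for a fixed ``config.rng_seed``.
    """
    table = table or HUKnowledgeTable.default()
    n_slices = volume.slice_count
    init = config.initial_slice
    if not 0 <= init < n_slices:
        raise ConfigError(f"initial slice {init} outside volume")
    if not (config.heart_range[0] <= init <= config.heart_range[1]):
        raise ConfigError("the initial slice must lie within heart_range so "
                          "heart seeds can propagate outward")

    on_init = initial_seeds.for_slice(init)
    if len(on_init) != len(initial_seeds.entries):
        raise ConfigError("initial seeds must all lie on the initial slice")
    present = {s.label for s in on_init}
    missing = [c for c in config.categories if c not in present]
    if missing:
        raise ConfigError(f"no initial seeds for categories: {missing}")

    windows: dict[int, WindowedSlice] = {}

    def window(s: int) -> WindowedSlice:
        if s not in windows:
            windows[s] = window_soft_tissue(volume.voxels[s], s)
        return windows[s]

    roi = config.roi or suggest_roi(window(init))
    if roi.row_max > volume.shape[1] or roi.col_max > volume.shape[2]:
        raise ConfigError("ROI exceeds the image bounds")

    labels = np.full(volume.shape, _BG_ID, dtype=np.int16)
    log: dict = {"rng_seed": config.rng_seed, "slices": {}, "warnings": []}

    cord_seeds = [s for s in on_init if s.label == _CORD]
    cord_hint = (cord_seeds[0].row, cord_seeds[0].col) if cord_seeds else None

    init_seeds = list(on_init) + _background_border_seeds(
        window(init), roi, config.background_seed_stride, table.air_gray_max)
    lm0, circle0, flags0 = _segment_one(window(init), roi, init_seeds,
                                        config, None, cord_hint)
    labels[init] = lm0
    log["slices"][init] = {
        "seed_counts": _count_by_label(init_seeds), "flags": flags0,
        "source": "initial"}

    for direction in (+1, -1):
        prev_lm = lm0
        prev_circle = circle0
        stop = init + direction
        end = n_slices if direction > 0 else -1
        for s in range(stop, end, direction):
            prev_roi_lm = prev_lm[roi.row_min:roi.row_max,
                                  roi.col_min:roi.col_max]
            presplit: dict[str, Callable] | None = None
            if direction < 0 and s == config.junction_slice - 1:
                presplit = {"airway": _split_at_centroid_col}
            local_window = WindowedSlice(roi.crop(window(s).pixels), s)
            seedset, rep = propagate_seeds(
                prev_roi_lm, local_window, policy=config.erosion, table=table,
                count_ratio=config.count_ratio, max_seeds=config.max_seeds,
                rng_seed=config.rng_seed, component_presplit=presplit)
            seeds = [Seed(s, e.row + roi.row_min, e.col + roi.col_min,
                          e.label) for e in seedset]
            if not (config.heart_range[0] <= s <= config.heart_range[1]):
                seeds = [e for e in seeds if e.label != _HEART]
            seeds += _background_border_seeds(window(s), roi,
                                              config.background_seed_stride,
                                              table.air_gray_max)
            organ_labels = {e.label for e in seeds} - {"background"}
            if not organ_labels:
                log["warnings"].append(
                    f"propagation starved at slice {s} (direction "
                    f"{'superior' if direction > 0 else 'inferior'}); "
                    "remaining slices left as background")
                break
            lm, prev_circle, flags = _segment_one(window(s), roi, seeds,
                                                  config, prev_circle)
            labels[s] = lm
            log["slices"][s] = {
                "seed_counts": _count_by_label(seeds),
                "skeleton_fallbacks": rep.skeleton_fallbacks,
                "rescued": rep.rescued,
                "vanished": rep.vanished,
                "flags": flags,
                "source": "propagated",
            }
            prev_lm = lm

    contour_set = {s: trace_contours(labels[s]) for s in range(n_slices)
                   if (labels[s] != _BG_ID).any()}
    log["roi"] = [roi.row_min, roi.row_max, roi.col_min, roi.col_max]
    return RunResult(labels=labels, contours=contour_set, log=log,
                     config=config)


def _count_by_label(seeds: list[Seed]) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in seeds:
        out[s.label] = out.get(s.label, 0) + 1
    return out
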