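"""Seeded multi-label random-walker segmentation of one windowed slice.

The random-walker model treats the image as a 4-connected lattice whose
edge weights decay with the squared gray-level difference,

    w_ij = exp(-beta * (g_i - g_j)^2),

with gray levels rescaled to [0, 1].  For each category the probability
that an unbiased-but-weighted random walk released at a pixel reaches one
of that category's seeds first is the harmonic function solving the
combinatorial Dirichlet problem: the graph Laplacian restricted to
unseeded pixels, with boundary value 1 on the category's seeds and 0 on
all other seeds.  Each pixel is then assigned the category of highest
probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .categories import CATEGORY_IDS, TIE_PRIORITY, category_id
from .image_io import ROI, WindowedSlice

#: Additive floor on edge weights; keeps flat-zero regions connected.
WEIGHT_EPSILON = 1e-6

#: Default free parameter of the Gaussian weighting function.
DEFAULT_BETA = 70.0


class SolverError(RuntimeError):
    """The Dirichlet system is singular (some pixels see no seed)."""


class Seed(NamedTuple):
    """A labeled pixel acting as a Dirichlet boundary condition."""

    slice_index: int
    row: int
    col: int
    label: str


@dataclass
class SeedSet:
    """Labeled pixel coordinates, usually for a single slice."""

    entries: list[Seed] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int, int], str] = {}
        for e in self.entries:
            category_id(e.label)  # validates the label
            key = (e.slice_index, e.row, e.col)
            if seen.setdefault(key, e.label) != e.label:
                raise ValueError(f"pixel {key} carries two labels")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def labels(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.label not in out:
                out.append(e.label)
        return out

    def for_slice(self, slice_index: int) -> list[Seed]:
        return [e for e in self.entries if e.slice_index == slice_index]

    def for_label(self, label: str) -> list[Seed]:
        return [e for e in self.entries if e.label == label]

    # JSON round trip -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        slices = sorted({e.slice_index for e in self.entries})
        payload = {
            "slice": slices[0] if len(slices) == 1 else slices,
            "coordinate_convention": "0-based (row, col)",
            "seeds": [{"label": e.label, "slice": e.slice_index,
                       "row": e.row, "col": e.col} for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SeedSet":
        payload = json.loads(Path(path).read_text())
        default_slice = payload.get("slice", 0)
        if isinstance(default_slice, list):
            default_slice = default_slice[0] if default_slice else 0
        entries = [Seed(int(s.get("slice", default_slice)), int(s["row"]),
                        int(s["col"]), str(s["label"]))
                   for s in payload["seeds"]]
        return cls(entries=entries)


def edge_weight(g_i, g_j, beta: float = DEFAULT_BETA):
    """Gaussian weight of the edge joining gray levels ``g_i`` and ``g_j``.

    Gray levels are given on the 8-bit [0, 255] scale and are rescaled to
    [0, 1] before the exponential, so that beta values in the tens retain
    contrast.  Symmetric in its arguments; result in (0, 1].
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = (np.asarray(g_i, dtype=np.float64) - np.asarray(g_j, dtype=np.float64)) / 255.0
    return np.exp(-beta * d * d)


@dataclass
class PixelGraph:
    """4-connected weighted lattice over the pixels of one ROI.

    Edge weights are stored as two arrays: ``w_h[r, c]`` for the edge
    between local pixels (r, c) and (r, c+1), ``w_v[r, c]`` for the edge
    between (r, c) and (r+1, c).  ``roi`` maps image coordinates onto the
    local grid; it is ``None`` for graphs built directly from weights.
    """

    shape: tuple[int, int]
    w_h: np.ndarray
    w_v: np.ndarray
    roi: ROI | None = None

    def __post_init__(self) -> None:
        h, w = self.shape
        if self.w_h.shape != (h, max(w - 1, 0)) or self.w_v.shape != (max(h - 1, 0), w):
            raise ValueError("weight array shapes do not match the grid")
        if (self.w_h.size and self.w_h.min() <= 0) or \
           (self.w_v.size and self.w_v.min() <= 0):
            raise ValueError("edge weights must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def n_edges(self) -> int:
        return self.w_h.size + self.w_v.size

    def node_of(self, row: int, col: int) -> int:
        """Local node index of an image-coordinate pixel."""
        if self.roi is not None:
            row, col = row - self.roi.row_min, col - self.roi.col_min
        h, w = self.shape
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"pixel ({row}, {col}) outside the graph")
        return row * w + col

    def adjacency(self) -> sp.csr_matrix:
        h, w = self.shape
        idx = np.arange(h * w).reshape(h, w)
        rows = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
        cols = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
        vals = np.concatenate([self.w_h.ravel(), self.w_v.ravel()])
        a = sp.coo_matrix((vals, (rows, cols)), shape=(h * w, h * w))
        return (a + a.T).tocsr()

    def laplacian(self) -> sp.csr_matrix:
        a = self.adjacency()
        deg = np.asarray(a.sum(axis=1)).ravel()
        return (sp.diags(deg) - a).tocsr()

    @classmethod
    def from_slice(cls, wslice: WindowedSlice, roi: ROI,
                   beta: float = DEFAULT_BETA,
                   epsilon: float = WEIGHT_EPSILON) -> "PixelGraph":
        """Build the lattice over ``roi`` with Gaussian gray-level weights."""
        patch = roi.crop(wslice.pixels).astype(np.float64)
        w_h = edge_weight(patch[:, :-1], patch[:, 1:], beta) + epsilon
        w_v = edge_weight(patch[:-1, :], patch[1:, :], beta) + epsilon
        return cls(shape=patch.shape, w_h=w_h, w_v=w_v, roi=roi)

    @classmethod
    def from_weights(cls, shape: tuple[int, int], w_h: np.ndarray,
                     w_v: np.ndarray) -> "PixelGraph":
        return cls(shape=shape, w_h=np.asarray(w_h, float),
                   w_v=np.asarray(w_v, float))


# Alias mirroring the operation-style API.
def build_graph(wslice: WindowedSlice, roi: ROI,
                beta: float = DEFAULT_BETA) -> PixelGraph:
    return PixelGraph.from_slice(wslice, roi, beta)


@dataclass
class ProbabilityMaps:
    """Per-category random-walker probabilities over one ROI grid.

    ``probs[k]`` is the probability field of ``labels[k]``; fields sum to 1
    at every pixel and equal exactly 1/0 at seeded pixels.
    """

    labels: list[str]
    probs: np.ndarray  # (K, h, w)
    roi: ROI | None = None

    def __getitem__(self, label: str) -> np.ndarray:
        return self.probs[self.labels.index(label)]


def _seed_arrays(graph: PixelGraph, seeds: Iterable[Seed] | SeedSet,
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    nodes, names = [], []
    for e in seeds:
        nodes.append(graph.node_of(e.row, e.col))
        names.append(e.label)
    node_arr = np.asarray(nodes, dtype=np.intp)
    if len(np.unique(node_arr)) != len(node_arr):
        # duplicate coordinates with the same label are harmless; collapse
        seen: dict[int, str] = {}
        keep = []
        for i, (n, lab) in enumerate(zip(node_arr, names)):
            if n in seen:
                if seen[n] != lab:
                    raise ValueError("conflicting labels at one pixel")
                continue
            seen[n] = lab
            keep.append(i)
        node_arr = node_arr[keep]
        names = [names[i] for i in keep]
    labels = sorted(set(names), key=lambda n: CATEGORY_IDS[n])
    label_idx = np.asarray([labels.index(n) for n in names], dtype=np.intp)
    return node_arr, label_idx, labels


def solve_dirichlet(graph: PixelGraph,
                    seeds: Iterable[Seed] | SeedSet) -> ProbabilityMaps:
    """Solve the combinatorial Dirichlet problem for every seeded category.

    For each category the probability field is harmonic on unseeded pixels
    with value 1 on that category's seeds and 0 on all others.  Only K-1
    systems are solved; the last field is obtained as the complement, so
    probabilities sum to exactly 1.  The sparse symmetric system is solved
    by direct LU factorization (one factorization, K-1 right-hand sides).
    """
    seed_nodes, seed_label_idx, labels = _seed_arrays(graph, seeds)
    if len(labels) < 2:
        raise SolverError("need seeds of at least two distinct categories")

    n = graph.n_nodes
    adjacency = graph.adjacency()
    n_comp, comp = connected_components(adjacency, directed=False)
    if n_comp > 1:
        seeded_comps = set(comp[seed_nodes])
        orphans = [c for c in range(n_comp) if c not in seeded_comps]
        if orphans:
            sizes = [int(np.sum(comp == c)) for c in orphans]
            raise SolverError(
                f"{len(orphans)} connected component(s) contain no seed "
                f"(sizes {sizes}); every pixel must reach a seed")

    laplacian = graph.laplacian().tocsr()
    is_seed = np.zeros(n, dtype=bool)
    is_seed[seed_nodes] = True
    unseeded = np.flatnonzero(~is_seed)

    k = len(labels)
    probs = np.zeros((k, n), dtype=np.float64)
    probs[seed_label_idx, seed_nodes] = 1.0

    if unseeded.size:
        l_uu = laplacian[unseeded][:, unseeded].tocsc()
        b_us = laplacian[unseeded][:, seed_nodes].tocsr()
        lu = splu(l_uu)
        acc = np.zeros(unseeded.size)
        for j in range(k - 1):
            m = (seed_label_idx == j).astype(np.float64)
            x = lu.solve(-b_us @ m)
            # harmonic functions obey the maximum principle; clip only the
            # solver's rounding spill
            x = np.clip(x, 0.0, 1.0)
            probs[j, unseeded] = x
            acc += x
        probs[k - 1, unseeded] = np.clip(1.0 - acc, 0.0, 1.0)

    h, w = graph.shape
    return ProbabilityMaps(labels=labels, probs=probs.reshape(k, h, w),
                           roi=graph.roi)


def assign_labels(maps: ProbabilityMaps,
                  seeds: Iterable[Seed] | SeedSet | None = None) -> np.ndarray:
    """Per-pixel argmax of the probability maps, as category ids.

    Seeded pixels keep their seeded category.  Exact ties are broken by the
    fixed priority order ``body < lungs < airway < heart < spinal_cord <
    gtv < background``.
    """
    order = [lab for lab in TIE_PRIORITY if lab in maps.labels]
    stacked = np.stack([maps[lab] for lab in order])
    winner = np.argmax(stacked, axis=0)
    ids = np.asarray([CATEGORY_IDS[lab] for lab in order], dtype=np.int16)
    labelmap = ids[winner]
    if seeds is not None:
        for e in seeds:
            r, c = e.row, e.col
            if maps.roi is not None:
                r, c = r - maps.roi.row_min, c - maps.roi.col_min
            labelmap[r, c] = CATEGORY_IDS[e.label]
    return labelmap


def segment_slice(wslice: WindowedSlice, roi: ROI,
                  seeds: Sequence[Seed] | SeedSet,
                  beta: float = DEFAULT_BETA,
                  ) -> tuple[np.ndarray, ProbabilityMaps]:
    """Convenience wrapper: graph construction, solve, argmax for one slice."""
    graph = PixelGraph.from_slice(wslice, roi, beta)
    maps = solve_dirichlet(graph, seeds)
    return assign_labels(maps, seeds), maps
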