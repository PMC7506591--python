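"""Exact pixel-boundary ("crack") contour tracing and rasterization.

Polygons follow the cracks between pixels: vertices sit on pixel corners at
half-integer (row, col) coordinates, so a mask -> polygon -> mask round
trip is exact for hole-free regions (holes are filled, since only outer
boundaries are exported).  Loops are traced with the interior on the right
and a right-turn preference at checkerboard corners, which keeps
diagonally-touching 4-connected components in separate loops.
"""

from __future__ import annotations

import numpy as np

from .categories import CATEGORY_IDS, ORGAN_CATEGORIES

# direction index -> (dr, dc): E, S, W, N
_DIRS = ((0, 1), (1, 0), (0, -1), (-1, 0))


def trace_boundaries(mask: np.ndarray) -> list[np.ndarray]:
    """Outer boundary polygons of every 4-connected component of ``mask``.

    Returns closed ``(N, 2)`` float arrays of (row, col) vertices at pixel
    corners (half-integers); first vertex equals the last.  Collinear runs
    are merged, so a filled rectangle yields its four corners.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    m = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    m[1:-1, 1:-1] = mask

    # Directed crack edges with the interior on the right.  Vertex (i, j)
    # is the top-left corner of padded pixel (i, j).
    edges: dict[tuple[int, int], list[tuple[tuple[int, int], int]]] = {}

    def add(v0, v1, d):
        edges.setdefault(v0, []).append((v1, d))

    ins = m
    top = ins & ~np.roll(ins, 1, axis=0)
    bot = ins & ~np.roll(ins, -1, axis=0)
    lef = ins & ~np.roll(ins, 1, axis=1)
    rig = ins & ~np.roll(ins, -1, axis=1)
    for i, j in zip(*np.nonzero(top)):
        add((i, j), (i, j + 1), 0)            # east along the top side
    for i, j in zip(*np.nonzero(rig)):
        add((i, j + 1), (i + 1, j + 1), 1)    # south along the right side
    for i, j in zip(*np.nonzero(bot)):
        add((i + 1, j + 1), (i + 1, j), 2)    # west along the bottom side
    for i, j in zip(*np.nonzero(lef)):
        add((i + 1, j), (i, j), 3)            # north along the left side

    loops: list[list[tuple[int, int]]] = []
    while edges:
        start = next(iter(edges))
        v = start
        prev_dir = None
        loop = [v]
        while True:
            cands = edges[v]
            if len(cands) == 1 or prev_dir is None:
                nxt, d = cands.pop()
            else:
                # right turn first (rotating (dr,dc) -> (dc,-dr) turns right
                # in screen coordinates), then straight, then left
                pref = ((prev_dir + 1) % 4, prev_dir, (prev_dir - 1) % 4)
                choice = min(range(len(cands)),
                             key=lambda i: pref.index(cands[i][1]))
                nxt, d = cands.pop(choice)
            if not cands:
                del edges[v]
            v, prev_dir = nxt, d
            if v == start:
                break
            loop.append(v)
        loops.append(loop)

    polys = []
    for loop in loops:
        arr = np.asarray(loop, dtype=np.float64)
        # shoelace with (r, c): outer loops (interior on right) are negative
        r, c = arr[:, 0], arr[:, 1]
        area2 = np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c)
        if area2 >= 0:
            continue  # hole loop
        arr = arr - 1.5  # unpad and shift corners to half-integer coords
        arr = _merge_collinear(arr)
        polys.append(np.vstack([arr, arr[:1]]))
    return polys


def _merge_collinear(vertices: np.ndarray) -> np.ndarray:
    keep = []
    n = len(vertices)
    for i in range(n):
        a, b, c = vertices[i - 1], vertices[i], vertices[(i + 1) % n]
        if not np.array_equal(b - a, c - b):
            keep.append(i)
    return vertices[keep]


def rasterize_polygons(polys: list[np.ndarray],
                       shape: tuple[int, int]) -> np.ndarray:
    """Fill crack-coordinate polygons back into a pixel mask (even-odd).

    Exact inverse of :func:`trace_boundaries` for hole-free regions: pixel
    centers sit at integer coordinates, polygon edges at half-integers, so
    no center ever lies on an edge.
    """
    out = np.zeros(shape, dtype=bool)
    for poly in polys:
        poly = np.asarray(poly, dtype=np.float64)
        for k in range(len(poly) - 1):
            (r0, c0), (r1, c1) = poly[k], poly[k + 1]
            if c0 != c1:
                continue  # horizontal edges never toggle a horizontal ray
            ra, rb = sorted((r0, r1))
            i0 = int(np.ceil(ra + 0.5 - 1e-9))
            i1 = int(np.floor(rb - 0.5 + 1e-9))
            j0 = int(np.ceil(c0 + 1e-9))
            if i1 < i0 or j0 >= shape[1]:
                continue
            i0 = max(i0, 0)
            i1 = min(i1, shape[0] - 1)
            out[i0:i1 + 1, max(j0, 0):] ^= True
    return out


def trace_contours(labelmap: np.ndarray,
                   categories: tuple[str, ...] = ORGAN_CATEGORIES,
                   ) -> dict[str, list[np.ndarray]]:
    """Outer boundary polygons per category of one label map."""
    out: dict[str, list[np.ndarray]] = {}
    for name in categories:
        mask = labelmap == CATEGORY_IDS[name]
        if mask.any():
            out[name] = trace_boundaries(mask)
    return out
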