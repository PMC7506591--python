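"""Hough-circle refinement of the spinal-cord contour.

The thoracic spinal cord is quasi-circular in cross-section, so instead of
keeping the raw random-walker region the cord contour is re-fitted each
slice: Sobel edges are extracted in a small square search window that
tracks the cord, and a Hough circle transform votes for the best (center,
radius) over an anatomically plausible radius range.  The cord label is
then replaced by the fitted disk.  The voting is robust to noise and
outlier edges; when too few edge points are found, or the fitted center
jumps implausibly far, the previous slice's circle is reused and the slice
is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.transform import hough_circle

from .categories import CATEGORY_IDS
from .image_io import WindowedSlice

_CORD_ID = CATEGORY_IDS["spinal_cord"]


@dataclass(frozen=True)
class Circle:
    """A fitted cord cross-section: center (row, col) and radius, pixels."""

    row: float
    col: float
    radius: float

    def distance_to(self, other: "Circle") -> float:
        return float(np.hypot(self.row - other.row, self.col - other.col))


@dataclass(frozen=True)
class SpineParams:
    """Tunables of the cord fitter (pixel units, ~1 mm pixels)."""

    r_min: int = 4
    r_max: int = 12
    roi_halfwidth: int = 25
    edge_percentile: float = 90.0
    max_drift: float = 10.0
    min_edge_points: int = 10


@dataclass(frozen=True)
class SpineROI:
    """Square search window centered on the tracked cord center."""

    center_row: int
    center_col: int
    halfwidth: int

    def bounds(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        r0 = max(self.center_row - self.halfwidth, 0)
        r1 = min(self.center_row + self.halfwidth + 1, shape[0])
        c0 = max(self.center_col - self.halfwidth, 0)
        c1 = min(self.center_col + self.halfwidth + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            raise ValueError("spine search window lies outside the image")
        return r0, r1, c0, c1


def spine_edges(wslice: WindowedSlice, roi: SpineROI,
                edge_percentile: float = 90.0) -> tuple[np.ndarray, tuple[int, int]]:
    """Binary Sobel edge points inside the search window.

    The gradient magnitude is thresholded at the given percentile of its
    values within the window; a constant window yields no edge points.
    Returns the local boolean edge map and the (row, col) offset of its
    origin in image coordinates.
    """
    r0, r1, c0, c1 = roi.bounds(wslice.pixels.shape)
    patch = wslice.pixels[r0:r1, c0:c1].astype(np.float64)
    mag = sobel(patch)
    if mag.max() <= 0:
        return np.zeros_like(mag, dtype=bool), (r0, c0)
    thr = np.percentile(mag, edge_percentile)
    if thr <= 0:
        thr = np.finfo(float).tiny
    return mag >= thr, (r0, c0)


def fit_circle_hough(edges: np.ndarray, r_min: int, r_max: int,
                     min_edge_points: int = 10) -> Circle | None:
    """Best-voted circle among binary edge points, or None if too sparse.

    The accumulator cell with the most votes over radii ``r_min..r_max``
    wins; exact ties resolve to the smallest radius, then the
    lexicographically smallest (row, col) center.
    """
    edges = np.asarray(edges, dtype=bool)
    if int(edges.sum()) < min_edge_points:
        return None
    radii = np.arange(int(r_min), int(r_max) + 1)
    acc = hough_circle(edges, radii)
    # C-order argmax = smallest radius first, then row, then col
    flat = int(np.argmax(acc))
    k, row, col = np.unravel_index(flat, acc.shape)
    return Circle(row=float(row), col=float(col), radius=float(radii[k]))


def rasterize_disk(circle: Circle, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose center lies within the circle (inclusive)."""
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return ((rr - circle.row) ** 2 + (cc - circle.col) ** 2
            <= circle.radius ** 2)


def refine_spine(labelmap: np.ndarray, wslice: WindowedSlice,
                 prev: Circle | None,
                 params: SpineParams | None = None,
                 center_hint: tuple[int, int] | None = None,
                 ) -> tuple[np.ndarray, Circle | None, list[str]]:
    """Replace the cord label in ``labelmap`` by the Hough-fitted disk.

    The search window is centered on ``prev`` when given, else on
    ``center_hint`` (the user's single cord seed on the first slice), else
    on the centroid of the current cord label.  On fit failure (or a center jump
    beyond ``max_drift``) the previous circle is reused and the slice is
    flagged; with no previous circle the label map is left untouched.

    Returns the refined label map, the circle to track on the next slice,
    and a list of flag strings.
    """
    params = params or SpineParams()
    labelmap = np.asarray(labelmap).copy()
    flags: list[str] = []

    if prev is not None:
        center = (int(round(prev.row)), int(round(prev.col)))
    elif center_hint is not None:
        center = (int(center_hint[0]), int(center_hint[1]))
    else:
        cord = labelmap == _CORD_ID
        if not cord.any():
            return labelmap, None, ["spine: no cord label and no prior circle"]
        com = ndimage.center_of_mass(cord)
        center = (int(round(com[0])), int(round(com[1])))

    roi = SpineROI(center[0], center[1], params.roi_halfwidth)
    edges, (r_off, c_off) = spine_edges(wslice, roi, params.edge_percentile)
    local = fit_circle_hough(edges, params.r_min, params.r_max,
                             params.min_edge_points)

    circle = None
    if local is not None:
        circle = Circle(row=local.row + r_off, col=local.col + c_off,
                        radius=local.radius)
        if prev is not None and circle.distance_to(prev) > params.max_drift:
            flags.append("spine: fitted center drifted "
                         f"{circle.distance_to(prev):.1f} px; keeping previous")
            circle = None
    else:
        flags.append("spine: too few edge points")

    if circle is None:
        if prev is None:
            flags.append("spine: fit failed with no prior circle; "
                         "cord left as random-walker output")
            return labelmap, None, flags
        circle = prev

    disk = rasterize_disk(circle, labelmap.shape)
    orphaned = (labelmap == _CORD_ID) & ~disk
    labelmap[disk] = _CORD_ID
    if orphaned.any():
        # hand former cord pixels outside the disk to their nearest
        # non-cord neighbour label
        others = labelmap != _CORD_ID
        _, (ir, ic) = ndimage.distance_transform_edt(~others,
                                                     return_indices=True)
        labelmap[orphaned] = labelmap[ir[orphaned], ic[orphaned]]
        labelmap[disk] = _CORD_ID
    return labelmap, circle, flags
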