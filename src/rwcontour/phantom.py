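"""Synthetic thoracic CT phantoms with known ground truth.

The phantom emulates the gross geometry and attenuation of a thoracic CT
at the soft-tissue window: an elliptic-cylinder body of fat-range tissue,
two ellipsoidal lungs, an air-filled trachea that bifurcates into two
walled bronchi at a junction slice, an ellipsoidal heart restricted to a
slice range, a circular spinal cord inside a bone-bright vertebral
annulus, a soft-tissue tumor inside one lung, and a deliberately thin
(2-px) detached chest-wall muscle sheet that exercises the
skeleton-fallback seed path.  Tissue HU means sit in the standard
anatomical ranges (air -1000, lung -400..-600, fat -30..-70, muscle and
other soft tissue 20..40, bone far above the window) and additive
Gaussian noise (default sigma 20 HU) is applied everywhere.

Organ cross-sections vary smoothly from slice to slice, matching the
anatomical prior the seed-propagation scheme relies on.  Geometry is
specified as fractions of the volume shape so the same spec scales to
smaller test volumes; fine structures (cord, airway calibres, wall and
sheet thicknesses) are in absolute pixels at the nominal ~1 mm pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import erosion as _gray_erosion

from .categories import CATEGORY_IDS
from .image_io import ROI, CTVolume, save_volume, write_masks
from .pipeline import RunConfig
from .rw_core import Seed, SeedSet
from .seed_engine import absorb_small_components, disk_footprint

_ID = CATEGORY_IDS


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue HU means and noise of one synthetic thorax."""

    shape: tuple[int, int, int] = (80, 256, 256)
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)
    rng_seed: int = 0
    noise_sigma: float = 20.0

    # tissue HU means
    hu: dict = field(default_factory=lambda: {
        "air": -1000.0, "fat": -50.0, "muscle": 30.0, "lung": -500.0,
        "heart": 45.0, "cord": 40.0, "bone": 700.0, "airway_wall": 60.0,
        "tumor": 30.0,
    })

    # fine structure calibres, absolute pixels
    trachea_radius: int = 6
    bronchus_radius: int = 4
    airway_wall: int = 2
    cord_radius: int = 6
    vertebra_radius: int = 16
    sheet_thickness: int = 2
    bronchus_col_slope: float = 1.3  # px of lateral drift per slice

    def validate(self) -> None:
        s, r, c = self.shape
        if s < 8 or r < 64 or c < 64:
            raise ValueError("phantom volume too small for the geometry")
        if self.cord_radius >= self.vertebra_radius:
            raise ValueError("cord must fit inside the vertebral annulus")
        if not (self.hu["lung"] <= -400 and self.hu["lung"] >= -600):
            raise ValueError("lung HU mean must lie in [-600, -400]")


@dataclass
class PhantomOutput:
    """Generated volume plus everything a pipeline run needs."""

    volume: CTVolume
    truth: np.ndarray  # (slice, row, col) category ids
    config: RunConfig
    seeds: SeedSet
    spec: PhantomSpec

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_volume(self.volume, outdir / "volume.nii")
        write_masks(self.truth, outdir / "truth", self.volume.spacing)
        self.seeds.to_json(outdir / "seeds.json")
        self.config.to_yaml(outdir / "run.yaml")


def _ellipse(rr, cc, center, semi):
    return (((rr - center[0]) / semi[0]) ** 2
            + ((cc - center[1]) / semi[1]) ** 2) <= 1.0


def _ellipsoid_section(rr, cc, s, center, semi):
    """Cross-section of an axis-aligned ellipsoid at slice ``s``."""
    t = (s - center[0]) / semi[0]
    if abs(t) >= 1.0:
        return np.zeros_like(rr, dtype=bool)
    scale = np.sqrt(1.0 - t * t)
    return _ellipse(rr, cc, (center[1], center[2]),
                    (semi[1] * scale, semi[2] * scale))


def _disk(rr, cc, center, radius):
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius ** 2


def generate(spec: PhantomSpec | None = None) -> PhantomOutput:
    """Build a phantom volume, its ground-truth labels, seeds and config.

    Deterministic for a fixed ``spec.rng_seed``.  The returned RunConfig
    carries the true heart slice range, the true airway junction slice, an
    ROI enclosing the anatomy with a 10-px margin, and the generator's rng
    seed; the SeedSet holds a valid user-style seeding of the mid-thorax
    initial slice (a handful of interior points per category, a single
    point for the spinal cord).
    """
    spec = spec or PhantomSpec()
    spec.validate()
    s_n, r_n, c_n = spec.shape
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    rr, cc = np.mgrid[0:r_n, 0:c_n].astype(np.float64)

    labels = np.zeros(spec.shape, dtype=np.int16)
    hu = np.full(spec.shape, spec.hu["air"], dtype=np.float64)

    # geometry (fractions of shape)
    body_c = (0.5 * r_n, 0.5 * c_n)
    body_semi = (0.305 * r_n, 0.39 * c_n)
    lung_centers = ((0.5 * s_n, 0.46 * r_n, 0.30 * c_n),
                    (0.5 * s_n, 0.46 * r_n, 0.70 * c_n))
    lung_semi = (0.425 * s_n, 0.205 * r_n, 0.17 * c_n)
    heart_center = (0.425 * s_n, 0.55 * r_n, 0.5 * c_n)
    heart_semi = (0.175 * s_n, 0.133 * r_n, 0.133 * c_n)
    tumor_center = (0.425 * s_n, 0.46 * r_n, 0.27 * c_n)
    tumor_semi = (0.0625 * s_n, 0.047 * r_n, 0.047 * r_n)
    airway_row = 0.36 * r_n
    cord_c = (0.72 * r_n, 0.5 * c_n)
    junction = int(round(0.5 * s_n))
    bronchi_term = int(round(0.15 * s_n))
    sheet_row = int(round(0.172 * r_n))
    sheet_slices = range(int(round(0.25 * s_n)), int(round(0.75 * s_n)))
    sheet_cols = slice(int(round(0.35 * c_n)), int(round(0.65 * c_n)))

    for s in range(s_n):
        lab = labels[s]
        f = hu[s]

        taper = 1.0 - 0.08 * ((s - 0.5 * s_n) / (0.5 * s_n)) ** 2
        semi = (body_semi[0] * taper, body_semi[1] * taper)
        body = _ellipse(rr, cc, body_c, semi)
        lab[body] = _ID["body"]
        f[body] = spec.hu["fat"]
        # muscular body wall under the skin: fat core, muscle rind
        rind = body & ~_ellipse(rr, cc, body_c, (semi[0] * 0.93,
                                                 semi[1] * 0.93))
        f[rind] = spec.hu["muscle"]

        if s in sheet_slices:
            sheet = np.zeros_like(body)
            sheet[sheet_row:sheet_row + spec.sheet_thickness, sheet_cols] = True
            sheet &= ~body  # detached: an air gap separates it from the skin
            lab[sheet] = _ID["body"]
            f[sheet] = spec.hu["muscle"]

        for lc in lung_centers:
            lung = _ellipsoid_section(rr, cc, s, lc, lung_semi) & body
            # pleural / chest-wall muscle lining around each lung
            lining = _ellipsoid_section(
                rr, cc, s, lc, (lung_semi[0], lung_semi[1] * 1.08,
                                lung_semi[2] * 1.08)) & body & ~lung
            f[lining] = spec.hu["muscle"]
            lab[lung] = _ID["lungs"]
            f[lung] = spec.hu["lung"]

        heart = _ellipsoid_section(rr, cc, s, heart_center, heart_semi) & body
        lab[heart] = _ID["heart"]
        f[heart] = spec.hu["heart"]

        vert = _disk(rr, cc, cord_c, spec.vertebra_radius) & body
        cord = _disk(rr, cc, cord_c, spec.cord_radius) & body
        lab[vert] = _ID["body"]
        f[vert] = spec.hu["bone"]
        lab[cord] = _ID["spinal_cord"]
        f[cord] = spec.hu["cord"]

        # airway: single trachea at and above the junction, two diverging
        # walled bronchi below it; the lumen pair still overlaps on the
        # junction slice itself so the transition is smooth
        if s >= junction:
            centers = [(airway_row, 0.5 * c_n)]
            radius = spec.trachea_radius
        elif s >= bronchi_term:
            d_col = spec.bronchus_radius + spec.bronchus_col_slope * (junction - s)
            d_row = 0.10 * r_n * (junction - s) / max(junction - bronchi_term, 1)
            centers = [(airway_row + d_row, 0.5 * c_n - d_col),
                       (airway_row + d_row, 0.5 * c_n + d_col)]
            radius = spec.bronchus_radius
        else:
            centers = []
            radius = 0
        if centers and s == junction:
            # widen the first bronchial pair into the trachea footprint
            centers = [(airway_row, 0.5 * c_n - spec.bronchus_radius),
                       (airway_row, 0.5 * c_n + spec.bronchus_radius)]
            radius = spec.bronchus_radius + 1
        for ctr in centers:
            wall = _disk(rr, cc, ctr, radius + spec.airway_wall) & body
            lab[wall] = _ID["body"]
            f[wall] = spec.hu["airway_wall"]
        for ctr in centers:
            lumen = _disk(rr, cc, ctr, radius) & body
            lab[lumen] = _ID["airway"]
            f[lumen] = spec.hu["air"]

        tumor = _ellipsoid_section(rr, cc, s, tumor_center, tumor_semi)
        tumor &= lab == _ID["lungs"]  # strictly inside a lung
        lab[tumor] = _ID["gtv"]
        f[tumor] = spec.hu["tumor"]

        # painting overlaps can leave 1-2 px slivers; fold them into their
        # surrounding structure so the ground truth is anatomically clean
        labels[s] = absorb_small_components(lab, 5)

    hu += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    volume = CTVolume(voxels=hu, spacing=spec.spacing)

    heart_slices = np.flatnonzero(
        (labels == _ID["heart"]).reshape(s_n, -1).any(axis=1))
    if heart_slices.size == 0:
        raise ValueError("phantom geometry produced no heart")
    heart_range = (int(heart_slices[0]), int(heart_slices[-1]))

    any_fg = np.flatnonzero((labels != 0).reshape(s_n, -1).any(axis=1))
    rows = np.flatnonzero((labels != 0).any(axis=(0, 2)))
    cols = np.flatnonzero((labels != 0).any(axis=(0, 1)))
    roi = ROI(max(int(rows[0]) - 10, 0), min(int(rows[-1]) + 11, r_n),
              max(int(cols[0]) - 10, 0), min(int(cols[-1]) + 11, c_n))
    del any_fg

    initial_slice = int(round(0.425 * s_n))
    config = RunConfig(initial_slice=initial_slice, heart_range=heart_range,
                       junction_slice=junction, roi=roi,
                       rng_seed=spec.rng_seed)
    seeds = _initial_seeds(labels[initial_slice], initial_slice, rng)
    return PhantomOutput(volume=volume, truth=labels, config=config,
                         seeds=seeds, spec=spec)


def _initial_seeds(truth_slice: np.ndarray, slice_index: int,
                   rng: np.random.Generator) -> SeedSet:
    """A user-style seeding of one slice.

    Each category component receives 1..12 interior points, scaled with
    component size and spread across the region the way a user dots an
    organ; the spinal cord gets exactly one seed.
    """
    cross = ndimage.generate_binary_structure(2, 1)
    entries: list[Seed] = []
    for name, cid in CATEGORY_IDS.items():
        if name == "background":
            continue
        mask = truth_slice == cid
        if not mask.any():
            continue
        comps, n = ndimage.label(mask, structure=cross)
        for i in range(1, n + 1):
            comp = comps == i
            core = _gray_erosion(comp.astype(np.uint8),
                                 disk_footprint(2)).astype(bool)
            if not core.any():
                core = comp
            pts = np.argwhere(core)
            if name == "spinal_cord":
                n_pts = 1
            else:
                n_pts = int(np.clip(round(np.sqrt(comp.sum()) / 7), 1, 12))
            if n_pts >= len(pts):
                chosen = pts
            else:
                # stride sampling of the row-major pixel list spreads the
                # points over the region; jitter the phase with the rng
                stride = len(pts) / n_pts
                start = rng.uniform(0, stride)
                chosen = pts[(start + stride * np.arange(n_pts)).astype(int)]
            for r, c in chosen:
                entries.append(Seed(slice_index, int(r), int(c), name))
            if name == "spinal_cord":
                break  # a single cord seed in total
    return SeedSet(entries=entries)


def degrade(phantom: PhantomOutput, weak_edge_sigma: float = 1.5,
            noise_sigma: float = 10.0) -> PhantomOutput:
    """Blur organ boundaries and add extra noise; ground truth unchanged.

    ``weak_edge_sigma`` is the in-plane Gaussian blur (px) applied to the
    HU field, lowering boundary gradients the way partial-volume averaging
    and low-dose acquisition do; ``noise_sigma`` is added on top of the
    phantom's own noise.  Zero for both returns an identical copy.
    """
    hu = phantom.volume.voxels.copy()
    if weak_edge_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=(0.0, weak_edge_sigma,
                                                weak_edge_sigma))
    if noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(phantom.spec.rng_seed,
                                   spawn_key=(int(1e6),)))
        hu = hu + rng.normal(0.0, noise_sigma, size=hu.shape)
    volume = CTVolume(voxels=hu, spacing=phantom.volume.spacing)
    return PhantomOutput(volume=volume, truth=phantom.truth,
                         config=phantom.config, seeds=phantom.seeds,
                         spec=replace(phantom.spec))
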