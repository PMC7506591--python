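import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rwcontour as rw
from rwcontour.categories import ORGAN_CATEGORIES
from rwcontour.rw_core import (PixelGraph, Seed, SeedSet, SolverError,
                               assign_labels, edge_weight, solve_dirichlet)

from .oracles import monte_carlo_absorption, random_lattice_instance

NAMES = list(ORGAN_CATEGORIES) + ["background"]


class TestEdgeWeight:
    def test_zero_gradient_is_one(self):
        assert edge_weight(128, 128, beta=70.0) == 1.0
        assert edge_weight(0, 0, beta=5.0) == 1.0

    def test_known_value(self):
        # normalized difference 0.1 (25.5 gray levels) at beta = 70
        w = edge_weight(100.0, 125.5, beta=70.0)
        assert w == pytest.approx(np.exp(-0.7), rel=1e-12)

    @given(st.floats(0, 255), st.floats(0, 255))
    def test_symmetry(self, a, b):
        assert edge_weight(a, b) == edge_weight(b, a)

    @given(st.floats(0, 255), st.floats(0, 255), st.floats(0, 255))
    def test_monotone_in_gradient(self, g, a, b):
        lo, hi = sorted([abs(g - a), abs(g - b)])
        assert edge_weight(g, g + hi) <= edge_weight(g, g + lo)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            edge_weight(1, 2, beta=0.0)


class TestGraph:
    def test_2x2_uniform(self):
        ws = rw.WindowedSlice(np.full((2, 2), 7, np.uint8), 0)
        g = PixelGraph.from_slice(ws, rw.ROI(0, 2, 0, 2), beta=70.0)
        assert g.n_edges == 4
        assert np.allclose(g.w_h, 1.0, atol=1e-5)
        lap = g.laplacian().toarray()
        assert np.allclose(lap.sum(axis=1), 0.0)

    def test_3x3_edge_count(self):
        ws = rw.WindowedSlice(np.arange(9, dtype=np.uint8).reshape(3, 3), 0)
        g = PixelGraph.from_slice(ws, rw.ROI(0, 3, 0, 3))
        assert g.n_edges == 12  # 2 * 3 * (3 - 1) on a 4-connected lattice

    def test_laplacian_psd_with_ones_nullspace(self, rng):
        g = PixelGraph.from_weights((4, 5), rng.uniform(0.1, 1, (4, 4)),
                                    rng.uniform(0.1, 1, (3, 5)))
        lap = g.laplacian().toarray()
        assert np.allclose(lap, lap.T)
        eig = np.linalg.eigvalsh(lap)
        assert eig.min() > -1e-10
        assert np.allclose(lap @ np.ones(20), 0.0)

    def test_roi_outside_image(self):
        ws = rw.WindowedSlice(np.zeros((4, 4), np.uint8), 0)
        with pytest.raises(ValueError):
            PixelGraph.from_slice(ws, rw.ROI(0, 8, 0, 8))


class TestSolve:
    def test_chain_midpoint_is_half(self):
        g = PixelGraph.from_weights((1, 3), np.array([[1.0, 1.0]]),
                                    np.zeros((0, 3)))
        maps = solve_dirichlet(g, [Seed(0, 0, 0, "lungs"),
                                   Seed(0, 0, 2, "body")])
        assert maps["lungs"][0, 1] == pytest.approx(0.5)
        assert maps["body"][0, 1] == pytest.approx(0.5)

    def test_probability_conservation_and_max_principle(self, rng):
        for _ in range(5):
            h, w, wh, wv, sn, sl, k = random_lattice_instance(rng)
            g = PixelGraph.from_weights((h, w), wh, wv)
            seeds = [Seed(0, int(n // w), int(n % w), NAMES[l])
                     for n, l in zip(sn, sl)]
            maps = solve_dirichlet(g, seeds)
            np.testing.assert_allclose(maps.probs.sum(axis=0), 1.0, atol=1e-6)
            assert maps.probs.min() >= 0.0 and maps.probs.max() <= 1.0

    def test_seed_pixels_are_exact(self):
        g = PixelGraph.from_weights((3, 3), np.full((3, 2), 0.5),
                                    np.full((2, 3), 0.5))
        maps = solve_dirichlet(g, [Seed(0, 0, 0, "lungs"),
                                   Seed(0, 2, 2, "heart")])
        assert maps["lungs"][0, 0] == 1.0 and maps["heart"][0, 0] == 0.0
        assert maps["heart"][2, 2] == 1.0 and maps["lungs"][2, 2] == 0.0

    def test_matches_monte_carlo_absorption(self, rng):
        # unit-scale version of the oracle equivalence: a single 8x8
        # instance against 2e4 weighted walks per pixel
        h, w = 8, 8
        wh = rng.uniform(0.1, 1.0, (8, 7))
        wv = rng.uniform(0.1, 1.0, (7, 8))
        sn = np.array([0, 63], dtype=np.int64)
        sl = np.array([0, 1], dtype=np.int64)
        g = PixelGraph.from_weights((h, w), wh, wv)
        maps = solve_dirichlet(g, [Seed(0, 0, 0, NAMES[0]),
                                   Seed(0, 7, 7, NAMES[1])])
        mc = monte_carlo_absorption(h, w, wh, wv, sn, sl, 2, 20000, 3)
        sig = np.sqrt(np.clip(mc * (1 - mc), 1e-12, None) / 20000)
        diff = np.abs(maps.probs.reshape(2, -1) - mc)
        assert np.all(diff <= 5 * sig + 5 / 20000)

    def test_label_permutation_invariance(self, rng):
        h, w, wh, wv, sn, sl, k = random_lattice_instance(rng)
        g = PixelGraph.from_weights((h, w), wh, wv)
        perm = rng.permutation(len(NAMES))
        a = solve_dirichlet(g, [Seed(0, int(n // w), int(n % w), NAMES[l])
                                for n, l in zip(sn, sl)])
        b = solve_dirichlet(g, [Seed(0, int(n // w), int(n % w),
                                     NAMES[perm[l]])
                                for n, l in zip(sn, sl)])
        for l in range(k):
            np.testing.assert_allclose(a[NAMES[l]], b[NAMES[perm[l]]],
                                       atol=1e-12)

    def test_single_label_rejected(self):
        g = PixelGraph.from_weights((1, 3), np.ones((1, 2)), np.zeros((0, 3)))
        with pytest.raises(SolverError):
            solve_dirichlet(g, [Seed(0, 0, 0, "body")])

    def test_conflicting_seed_labels_rejected(self):
        g = PixelGraph.from_weights((1, 3), np.ones((1, 2)), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            solve_dirichlet(g, [Seed(0, 0, 0, "body"), Seed(0, 0, 0, "lungs"),
                                Seed(0, 0, 2, "heart")])


class TestAssign:
    def _maps(self, probs, labels):
        return rw.ProbabilityMaps(labels=labels, probs=np.asarray(probs))

    def test_argmax(self):
        maps = self._maps(np.array([[[0.7]], [[0.2]], [[0.1]]]),
                          ["lungs", "heart", "body"])
        lm = assign_labels(maps)
        assert lm[0, 0] == rw.CATEGORY_IDS["lungs"]

    def test_seed_dominance(self):
        maps = self._maps(np.array([[[0.9, 0.9]], [[0.1, 0.1]]]),
                          ["lungs", "gtv"])
        lm = assign_labels(maps, [Seed(0, 0, 1, "gtv")])
        assert lm[0, 0] == rw.CATEGORY_IDS["lungs"]
        assert lm[0, 1] == rw.CATEGORY_IDS["gtv"]

    def test_tie_breaks_by_priority(self):
        # body precedes lungs precedes background in the documented order
        maps = self._maps(np.array([[[0.5]], [[0.5]]]), ["lungs", "body"])
        assert assign_labels(maps)[0, 0] == rw.CATEGORY_IDS["body"]
        maps = self._maps(np.array([[[0.5]], [[0.5]]]),
                          ["background", "lungs"])
        assert assign_labels(maps)[0, 0] == rw.CATEGORY_IDS["lungs"]


class TestSeedSet:
    def test_json_round_trip(self, tmp_path):
        ss = SeedSet([Seed(4, 10, 12, "lungs"), Seed(4, 3, 5, "gtv")])
        ss.to_json(tmp_path / "seeds.json")
        back = SeedSet.from_json(tmp_path / "seeds.json")
        assert back.entries == ss.entries

    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError):
            SeedSet([Seed(0, 1, 1, "lungs"), Seed(0, 1, 1, "body")])
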