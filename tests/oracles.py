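"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the dense Dirichlet
solver assembles the Laplacian with explicit loops and uses a dense
factorization; the Monte-Carlo oracle simulates weighted random walks to
absorption; the Hausdorff oracle is the O(|A||B|) double loop.
"""

from __future__ import annotations

import numpy as np


def dense_dirichlet(h: int, w: int, w_h: np.ndarray, w_v: np.ndarray,
                    seed_nodes: np.ndarray, seed_labels: np.ndarray,
                    n_labels: int) -> np.ndarray:
    """Dense direct solve of the Dirichlet problem on an h x w lattice.

    Returns (n_labels, h*w) probabilities; seeds carry exact 0/1.
    """
    n = h * w
    lap = np.zeros((n, n))
    for r in range(h):
        for c in range(w - 1):
            i, j = r * w + c, r * w + c + 1
            lap[i, j] -= w_h[r, c]
            lap[j, i] -= w_h[r, c]
    for r in range(h - 1):
        for c in range(w):
            i, j = r * w + c, (r + 1) * w + c
            lap[i, j] -= w_v[r, c]
            lap[j, i] -= w_v[r, c]
    np.fill_diagonal(lap, -lap.sum(axis=1))

    is_seed = np.zeros(n, dtype=bool)
    is_seed[seed_nodes] = True
    u = np.flatnonzero(~is_seed)
    probs = np.zeros((n_labels, n))
    probs[seed_labels, seed_nodes] = 1.0
    if u.size:
        l_uu = lap[np.ix_(u, u)]
        l_us = lap[np.ix_(u, seed_nodes)]
        for k in range(n_labels):
            m = (seed_labels == k).astype(float)
            probs[k, u] = np.linalg.solve(l_uu, -l_us @ m)
    return probs


def _mc_kernel_py(nbr, cumw, seed_label, starts, n_labels, n_walks, rng_seed):
    rng = np.random.default_rng(rng_seed)
    counts = np.zeros((len(starts), n_labels), dtype=np.int64)
    for i, start in enumerate(starts):
        for _ in range(n_walks):
            node = start
            while seed_label[node] < 0:
                u = rng.random() * cumw[node, -1]
                k = 0
                while cumw[node, k] < u:
                    k += 1
                node = nbr[node, k]
            counts[i, seed_label[node]] += 1
    return counts


try:
    import numba

    @numba.njit(cache=False)
    def _mc_kernel(nbr, cumw, seed_label, starts, n_labels, n_walks,
                   rng_seed):  # pragma: no cover - exercised via wrapper
        np.random.seed(rng_seed)
        counts = np.zeros((len(starts), n_labels), dtype=np.int64)
        for i in range(len(starts)):
            start = starts[i]
            for _ in range(n_walks):
                node = start
                while seed_label[node] < 0:
                    u = np.random.random() * cumw[node, 3]
                    k = 0
                    while cumw[node, k] < u:
                        k += 1
                    node = nbr[node, k]
                counts[i, seed_label[node]] += 1
        return counts

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _mc_kernel = None
    _HAVE_NUMBA = False


def monte_carlo_absorption(h: int, w: int, w_h: np.ndarray, w_v: np.ndarray,
                           seed_nodes: np.ndarray, seed_labels: np.ndarray,
                           n_labels: int, n_walks: int,
                           rng_seed: int) -> np.ndarray:
    """Estimate label probabilities by simulating weighted random walks.

    From every unseeded node, ``n_walks`` walkers step to a 4-neighbour
    with probability proportional to the edge weight until they hit a
    seed; the fraction absorbed per label estimates the harmonic
    probability.  Returns (n_labels, h*w) with exact 0/1 at seeds.
    """
    n = h * w
    nbr = np.full((n, 4), -1, dtype=np.int64)
    wgt = np.zeros((n, 4))
    for r in range(h):
        for c in range(w):
            i = r * w + c
            k = 0
            if c + 1 < w:
                nbr[i, k] = i + 1
                wgt[i, k] = w_h[r, c]
                k += 1
            if c > 0:
                nbr[i, k] = i - 1
                wgt[i, k] = w_h[r, c - 1]
                k += 1
            if r + 1 < h:
                nbr[i, k] = i + w
                wgt[i, k] = w_v[r, c]
                k += 1
            if r > 0:
                nbr[i, k] = i - w
                wgt[i, k] = w_v[r - 1, c]
                k += 1
    cumw = np.cumsum(wgt, axis=1)
    # pad so cumw[:, 3] is always the total weight
    for k in range(1, 4):
        pad = nbr[:, k] < 0
        cumw[pad, k] = cumw[pad, k - 1]

    seed_label = np.full(n, -1, dtype=np.int64)
    seed_label[seed_nodes] = seed_labels
    starts = np.flatnonzero(seed_label < 0).astype(np.int64)

    kernel = _mc_kernel if _HAVE_NUMBA else _mc_kernel_py
    counts = kernel(nbr, cumw, seed_label, starts, n_labels,
                    n_walks, rng_seed)
    probs = np.zeros((n_labels, n))
    probs[seed_labels, seed_nodes] = 1.0
    probs[:, starts] = (counts / n_walks).T
    return probs


def brute_hausdorff(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """O(|A||B|) symmetric Hausdorff distance."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    d_ab = max(min(np.hypot(*(p - q)) if len(p) == 2
                   else np.linalg.norm(p - q) for q in b) for p in a)
    d_ba = max(min(np.hypot(*(p - q)) if len(p) == 2
                   else np.linalg.norm(p - q) for q in a) for p in b)
    return float(max(d_ab, d_ba))


def random_lattice_instance(rng: np.random.Generator):
    """One random weighted-lattice Dirichlet instance (up to 8x8)."""
    h = int(rng.integers(2, 9))
    w = int(rng.integers(2, 9))
    w_h = rng.uniform(0.05, 1.0, size=(h, w - 1))
    w_v = rng.uniform(0.05, 1.0, size=(h - 1, w))
    n = h * w
    n_labels = int(rng.integers(2, min(4, n) + 1))
    n_seeds = int(rng.integers(n_labels, min(max(n // 3, n_labels), 8) + 1))
    seed_nodes = rng.choice(n, size=n_seeds, replace=False).astype(np.int64)
    seed_labels = np.concatenate([
        np.arange(n_labels),
        rng.integers(0, n_labels, size=n_seeds - n_labels)]).astype(np.int64)
    return h, w, w_h, w_v, seed_nodes, seed_labels, n_labels
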