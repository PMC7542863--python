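"""Shared fixtures: small lattices, the study-scale 640-cell fixture, and
independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import numpy as np
import pytest

import spatscreen as ss


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no reuse of package internals)
# ---------------------------------------------------------------------------


def brute_force_moran(x: np.ndarray, w_dense: np.ndarray) -> float:
    """O(n^2) double-loop Moran's I straight from the printed formula."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    s0 = w_dense.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * z[i] * z[j]
    return (n / s0) * num / (z ** 2).sum()


def brute_force_queen(geoms, snap: float = 0.0) -> list[set[int]]:
    """Pairwise boundary-distance queen adjacency."""
    n = len(geoms)
    nb = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].boundary.distance(geoms[j].boundary) <= snap:
                nb[i].add(j)
                nb[j].add(i)
    return nb


def brute_force_lag(w: ss.SpatialWeights, x: np.ndarray) -> np.ndarray:
    wd = w.dense()
    return np.array(
        [sum(wd[i, j] * x[j] for j in range(w.n)) for i in range(w.n)]
    )


@pytest.fixture(scope="session")
def lattice3():
    ids, geoms = ss.make_lattice(ss.LatticeSpec(rows=3, cols=3))
    return ids, geoms


@pytest.fixture(scope="session")
def w3(lattice3):
    ids, geoms = lattice3
    return ss.build_queen_weights(geoms, ids)


@pytest.fixture(scope="session")
def w10_row():
    ids, geoms = ss.make_lattice(ss.LatticeSpec(rows=10, cols=10))
    return ss.build_queen_weights(geoms, ids).row_standardized()


@pytest.fixture(scope="session")
def study_fixture():
    """20x32 lattice with Table-1-style covariates and the default design.

    Returns (weights_row, X, beta_true, names, ids, geoms); the module-level
    eigenvalue cache makes repeated ML fits cheap.
    """
    spec = ss.LatticeSpec()
    ids, geoms = ss.make_lattice(spec)
    w = ss.build_queen_weights(geoms, ids).row_standardized()
    w.eigenvalues()  # warm the spectral cache shared by all fits
    tab = ss.simulate_covariates(ss.default_variable_specs(), spec.n, seed=7)
    xmat, beta_true, names = ss.study_design(tab)
    return w, xmat, beta_true, names, ids, geoms


def random_weights(rng: np.random.Generator, n: int, style: str) -> ss.SpatialWeights:
    """Random symmetric connected-ish binary weights for property tests."""
    adj = np.triu((rng.random((n, n)) < 0.35).astype(float), k=1)
    adj = adj + adj.T
    # ensure no islands: wire each empty row to a random other unit
    for i in range(n):
        if adj[i].sum() == 0:
            j = (i + 1 + rng.integers(n - 1)) % n
            adj[i, j] = adj[j, i] = 1.0
    neighbors = [np.flatnonzero(adj[i]) for i in range(n)]
    w = ss.SpatialWeights(
        ids=[str(i) for i in range(n)],
        neighbors=neighbors,
        weights=[np.ones(len(nb)) for nb in neighbors],
        style="binary",
    )
    return w.row_standardized() if style == "row" else w
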