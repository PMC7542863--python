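"""Global and local spatial autocorrelation with permutation inference.

Global Moran's I,

    I = (n / S0) * sum_i sum_j w_ij z_i z_j / sum_i z_i^2,   z_i = x_i - xbar,

ranges from about -1 (dispersed) to 1 (clustered) with null expectation
-1/(n-1).  Significance uses a Monte-Carlo permutation test: the values are
randomly reassigned to units and the pseudo p-value is (M+1)/(R+1) where M of
R permuted statistics are at least as extreme as the observed one, in the
direction of the observed deviation.

The local decomposition (LISA) is reported in the scaled form

    I_i = (z_i / m2) * sum_j w_ij z_j,   m2 = sum z^2 / n,

whose total over units equals S0 * I; the raw cross-product form
z_i * sum_j w_ij z_j is available by flag.  Local inference holds z_i fixed
and permutes the remaining values onto i's neighbor positions (conditional
permutation), then classifies each significant unit into the Moran-scatter
quadrant HH, LL, HL or LH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .weights import SpatialWeights, spatial_lag

QUADRANTS = ("HH", "LH", "LL", "HL")
NOT_SIGNIFICANT = "NS"


def _check_input(x: np.ndarray, w: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != w.n:
        raise ValueError(f"x must be a length-{w.n} vector, got shape {x.shape}")
    if np.any(~np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    n_live = w.n - len(w.islands)
    if n_live < 3:
        raise ValueError("need at least 3 non-island units")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; Moran statistics undefined")
    return x


@dataclass
class MoranResult:
    """Global Moran's I with its permutation null."""

    i: float
    expected_i: float
    z_score: float
    p_sim: float
    n_perm: int
    perm_mean: float
    perm_sd: float
    perm_min: float
    perm_max: float
    seed: int

    @property
    def significant(self) -> bool:
        return self.p_sim < 0.05

    def to_dict(self) -> dict:
        return {
            "I": self.i,
            "expected_I": self.expected_i,
            "z_score": self.z_score,
            "p_sim": self.p_sim,
            "n_perm": self.n_perm,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "seed": self.seed,
        }


@dataclass
class LisaResult:
    """Local Moran statistics, conditional-permutation p-values, and
    cluster labels at level ``alpha``."""

    local_i: np.ndarray
    quadrant: np.ndarray  # strings in {HH, LL, HL, LH}
    p_sim: np.ndarray
    label: np.ndarray  # quadrant where p_sim < alpha else NS
    alpha: float
    n_perm: int
    seed: int


def moran_i(x: np.ndarray, w: SpatialWeights) -> float:
    """Exact double-sum Moran's I under the given weight style."""
    x = _check_input(x, w)
    z = x - x.mean()
    s0 = w.s0
    if s0 <= 0:
        raise ValueError("weights have S0 = 0 (all islands?)")
    num = float(z @ spatial_lag(w, z))
    return (w.n / s0) * num / float(z @ z)


def moran_permutation_test(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    two_sided: bool = False,
) -> MoranResult:
    """Monte-Carlo permutation test for global Moran's I.

    The default pseudo p-value is one-sided toward the observed direction
    (counting permuted I at least as large as observed when I exceeds its
    expectation -1/(n-1), at least as small otherwise); ``two_sided`` doubles
    it, capped at 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _check_input(x, w)
    n = w.n
    obs = moran_i(x, w)
    e_i = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)), axis=1)
    z = perms - perms.mean(axis=1, keepdims=True)
    lag = (w.sparse() @ z.T).T
    sim = (n / w.s0) * np.einsum("ij,ij->i", z, lag) / np.einsum("ij,ij->i", z, z)

    if obs >= e_i:
        m = int(np.sum(sim >= obs))
    else:
        m = int(np.sum(sim <= obs))
    p = (m + 1) / (n_perm + 1)
    if two_sided:
        p = min(1.0, 2 * p)
    sd = float(sim.std(ddof=1))
    return MoranResult(
        i=obs,
        expected_i=e_i,
        z_score=(obs - float(sim.mean())) / sd,
        p_sim=p,
        n_perm=n_perm,
        perm_mean=float(sim.mean()),
        perm_sd=sd,
        perm_min=float(sim.min()),
        perm_max=float(sim.max()),
        seed=seed,
    )


def local_moran(
    x: np.ndarray, w: SpatialWeights, form: str = "scaled"
) -> np.ndarray:
    """Per-unit local Moran I_i.

    ``form="scaled"`` (default): I_i = (z_i/m2) sum_j w_ij z_j, which sums to
    S0 * I over units.  ``form="zproduct"``: the bare cross-product
    z_i * sum_j w_ij z_j.  Islands get I_i = 0.
    """
    if form not in ("scaled", "zproduct"):
        raise ValueError(f"unknown form {form!r}")
    x = _check_input(x, w)
    z = x - x.mean()
    lag = spatial_lag(w, z)
    if form == "zproduct":
        return z * lag
    m2 = float(z @ z) / w.n
    return z * lag / m2


def moran_quadrant(x: np.ndarray, w: SpatialWeights) -> np.ndarray:
    """Moran-scatter quadrant per unit from the signs of the mean-centered
    value and the mean-centered spatial lag (lag of z, not of raw x)."""
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    lag = spatial_lag(w, z)
    quad = np.empty(w.n, dtype=object)
    hi_x, hi_l = z >= 0, lag >= 0
    quad[hi_x & hi_l] = "HH"
    quad[~hi_x & ~hi_l] = "LL"
    quad[hi_x & ~hi_l] = "HL"
    quad[~hi_x & hi_l] = "LH"
    return quad.astype(str)


def lisa_conditional_permutation(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> LisaResult:
    """Conditional-permutation inference for the local Moran.

    For each unit i the value z_i stays put while ``n_perm`` random draws of
    the other n-1 values (without replacement) fill i's neighbor positions;
    the pseudo p-value is computed as in the global test, toward the side of
    the permutation mean the observed I_i falls on.  Each unit consumes its
    own counter-keyed random stream so results do not depend on iteration
    order.  Islands are labeled NS with I_i = 0 and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = _check_input(x, w)
    n = w.n
    z = x - x.mean()
    m2 = float(z @ z) / n
    obs = local_moran(x, w, form="scaled")
    quad = moran_quadrant(x, w)

    p_sim = np.ones(n)
    others = np.arange(n - 1)
    for i in range(n):
        k = len(w.neighbors[i])
        if k == 0:
            continue
        pool = np.delete(z, i)
        rng = np.random.default_rng([seed, i])
        # n_perm draws of k distinct indices into the n-1 remaining values
        u = rng.random((n_perm, n - 1))
        idx = np.argpartition(u, k - 1, axis=1)[:, :k] if k < n - 1 else np.broadcast_to(others, (n_perm, n - 1))
        lag_sim = pool[idx] @ w.weights[i]
        sim = (z[i] / m2) * lag_sim
        mu = sim.mean()
        if obs[i] >= mu:
            m = int(np.sum(sim >= obs[i]))
        else:
            m = int(np.sum(sim <= obs[i]))
        p_sim[i] = (m + 1) / (n_perm + 1)

    label = quad.copy()
    label[p_sim >= alpha] = NOT_SIGNIFICANT
    for i in w.islands:
        label[i] = NOT_SIGNIFICANT
    return LisaResult(
        local_i=obs,
        quadrant=quad,
        p_sim=p_sim,
        label=label,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )
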