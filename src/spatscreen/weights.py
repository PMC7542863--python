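"""Spatial contiguity weights.

Queen contiguity on polygon collections: two areal units are neighbors when
their boundaries come within a snap distance of each other (shared edges and
single shared corners both qualify).  The resulting binary matrix may be
row-standardized, which is the default style for every statistic and model in
this package.  Weights serialize to the GAL text format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from shapely import STRtree

logger = logging.getLogger(__name__)

BINARY = "binary"
ROW_STANDARDIZED = "row_standardized"


@dataclass
class SpatialWeights:
    """Sparse neighbor structure over ``n`` areal units.

    Attributes
    ----------
    ids : list of str
        Unit identifiers, index-aligned with the neighbor lists.
    neighbors : list of int arrays
        Per-unit neighbor indices, sorted ascending for deterministic
        serialization.  Self-neighbors are never stored.
    weights : list of float arrays
        Per-unit weights aligned to ``neighbors``.
    style : str
        ``"binary"`` (all stored weights 1, symmetric) or
        ``"row_standardized"`` (each non-island row sums to 1).
    """

    ids: list[str]
    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    style: str = BINARY
    _eigs: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> list[int]:
        """Indices of units with no neighbors."""
        return [i for i, nb in enumerate(self.neighbors) if len(nb) == 0]

    @property
    def s0(self) -> float:
        """Aggregate of all stored weights (S0 in Moran's I)."""
        return float(sum(w.sum() for w in self.weights))

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    def sparse(self) -> sp.csr_matrix:
        """CSR matrix form of W."""
        indptr = np.cumsum([0] + [len(nb) for nb in self.neighbors])
        indices = (
            np.concatenate(self.neighbors)
            if indptr[-1]
            else np.empty(0, dtype=int)
        )
        data = (
            np.concatenate(self.weights) if indptr[-1] else np.empty(0)
        )
        return sp.csr_matrix(
            (data, indices, indptr), shape=(self.n, self.n)
        )

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()

    # -- transforms ---------------------------------------------------------

    def row_standardized(self) -> "SpatialWeights":
        """Return a copy with each non-island row scaled to sum to 1.

        Idempotent; islands keep empty rows and are excluded from S0.
        """
        new_w = []
        for w in self.weights:
            s = w.sum()
            new_w.append(w / s if s > 0 else w.copy())
        return SpatialWeights(
            ids=list(self.ids),
            neighbors=[nb.copy() for nb in self.neighbors],
            weights=new_w,
            style=ROW_STANDARDIZED,
        )

    # -- spectral quantities ------------------------------------------------

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalue spectrum of the row-standardized matrix.

        For W derived from a symmetric binary matrix A with degrees d_i, the
        row-standardized D^-1 A is similar to the symmetric D^-1/2 A D^-1/2,
        so its spectrum is real and computed stably with a symmetric solver.
        Island rows contribute zero eigenvalues.  Cached on the instance.
        """
        if self._eigs is None:
            deg = np.array([len(nb) for nb in self.neighbors], dtype=float)
            live = deg > 0
            if not live.any():
                raise ValueError("all units are islands; no spectrum")
            a = self.sparse()
            if self.style == ROW_STANDARDIZED:
                # undo standardization to recover the symmetric binary A
                a = sp.diags(np.where(live, deg, 1.0)) @ a
            a = a.toarray()
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError(
                    "queen-style weights expected: binary matrix not symmetric"
                )
            d_isqrt = np.zeros(self.n)
            d_isqrt[live] = 1.0 / np.sqrt(deg[live])
            sym = d_isqrt[:, None] * a * d_isqrt[None, :]
            vals = eigh(sym, eigvals_only=True)
            self._eigs = np.sort(vals)
        return self._eigs

    def stationary_interval(self) -> tuple[float, float]:
        """Open interval of spatial parameters for which I - param*W is
        invertible with positive determinant: (1/omega_min, 1/omega_max) from
        the extreme real eigenvalues of the row-standardized W.

        For a connected row-standardized W the upper bound is exactly 1
        (Perron root of a row-stochastic matrix).
        """
        if self.n < 2:
            raise ValueError("need at least 2 units")
        vals = self.eigenvalues()
        live = vals[np.abs(vals) > 1e-12]
        wmin, wmax = live.min(), live.max()
        if wmin >= 0:
            raise ValueError("weight spectrum has no negative part")
        return (1.0 / wmin, 1.0 / wmax)


def build_queen_weights(
    geometries, ids: list[str] | None = None, snap_distance: float = 1e-7
) -> SpatialWeights:
    """Queen-contiguity binary weights from polygon geometries.

    Units i and j are neighbors iff at least one point of one boundary lies
    within ``snap_distance`` of the other (so exact edge sharing and single
    corner touches both qualify, as do near-misses within the snap
    tolerance).

    Parameters
    ----------
    geometries : sequence of shapely geometries
    ids : unit identifiers; defaults to stringified indices
    snap_distance : nonnegative tolerance in map units

    Returns
    -------
    SpatialWeights in binary style.  Islands (empty rows) are logged.
    """
    geoms = list(geometries)
    n = len(geoms)
    if n < 2:
        raise ValueError(f"need at least 2 geometries, got {n}")
    if snap_distance < 0:
        raise ValueError("snap_distance must be nonnegative")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids and geometries length mismatch")

    tree = STRtree(geoms)
    neighbors: list[np.ndarray] = []
    for i, g in enumerate(geoms):
        if snap_distance > 0:
            cand = tree.query(g, predicate="dwithin", distance=snap_distance)
        else:
            cand = tree.query(g, predicate="intersects")
        nb = np.sort(cand[cand != i])
        neighbors.append(nb.astype(int))
    w = SpatialWeights(
        ids=list(ids),
        neighbors=neighbors,
        weights=[np.ones(len(nb)) for nb in neighbors],
        style=BINARY,
    )
    if w.islands:
        logger.warning(
            "%d island unit(s) with no neighbors: %s",
            len(w.islands),
            [ids[i] for i in w.islands],
        )
    return w


def spatial_lag(w: SpatialWeights, x: np.ndarray) -> np.ndarray:
    """(Wx)_i = sum_j w_ij x_j; islands get 0."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != w.n:
        raise ValueError(f"x has length {x.shape[-1]}, weights have n={w.n}")
    ws = w.sparse()
    return ws @ x if x.ndim == 1 else (ws @ x.T).T


def write_gal(w: SpatialWeights, path) -> None:
    """Serialize to GAL: header line with n, then per-unit 'id k' and a
    neighbor-ID line.  Style is recorded in a leading comment."""
    lines = [f"# style={w.style}", str(w.n)]
    for i, nb in enumerate(w.neighbors):
        lines.append(f"{w.ids[i]} {len(nb)}")
        lines.append(" ".join(w.ids[j] for j in nb))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gal(path) -> SpatialWeights:
    """Read a GAL neighbor file written by :func:`write_gal` (or by hand).

    Weights are binary unless the header comment declares
    ``style=row_standardized``, in which case rows are re-standardized.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    style = BINARY
    lineno = 0
    lines = []
    for k, ln in enumerate(raw, start=1):
        s = ln.strip()
        if s.startswith("#"):
            if "style=" in s:
                style = s.split("style=")[1].strip()
            continue
        lines.append((k, s))
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    lineno, header = lines[0]
    try:
        n = int(header.split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:{lineno}: malformed GAL header {header!r}")
    ids: list[str] = []
    nb_ids: list[list[str]] = []
    pos = 1
    while pos < len(lines):
        lineno, head = lines[pos]
        parts = head.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id count', got {head!r}")
        uid, cnt_s = parts
        try:
            cnt = int(cnt_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad neighbor count {cnt_s!r}")
        pos += 1
        if cnt == 0:
            # islands may or may not have an (empty) neighbor line
            if pos < len(lines) and lines[pos][1] == "":
                pos += 1
            nbs: list[str] = []
        else:
            if pos >= len(lines):
                raise ValueError(f"{path}:{lineno}: missing neighbor line for {uid}")
            lineno2, row = lines[pos]
            nbs = row.split()
            if len(nbs) != cnt:
                raise ValueError(
                    f"{path}:{lineno2}: expected {cnt} neighbors for {uid}, got {len(nbs)}"
                )
            pos += 1
        ids.append(uid)
        nb_ids.append(nbs)
    if len(ids) != n:
        raise ValueError(f"{path}: header declares {n} units, found {len(ids)}")
    index = {u: i for i, u in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError(f"{path}: duplicate unit ids")
    neighbors = []
    for uid, nbs in zip(ids, nb_ids):
        try:
            nb = np.sort(np.array([index[v] for v in nbs], dtype=int))
        except KeyError as exc:
            raise ValueError(f"{path}: unknown neighbor id {exc} for unit {uid}")
        neighbors.append(nb)
    w = SpatialWeights(
        ids=ids,
        neighbors=neighbors,
        weights=[np.ones(len(nb)) for nb in neighbors],
        style=BINARY,
    )
    return w.row_standardized() if style == ROW_STANDARDIZED else w
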