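"""Global and local Moran's I with permutation inference and LISA classes.

Global Moran's I for values x_i with spatial weights w_ij:

    I = n / S0 * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the sum of all weights; E[I] = -1/(n-1) under the randomisation
null.  Local Moran's I_i = z_i * sum_j w_ij z_j with z the values
standardised using the population (n-divisor) standard deviation, so
that sum_i I_i / S0 equals the global index.  Significance for both is
obtained by permutation: full permutation of the values for the global
index, conditional permutation (holding unit i fixed, permuting the
rest among its neighbours) for the local indices.  Significant units
are classified HH / LL / LH / HL from the signs of (z_i, lag_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

SCHEMES = ("queen", "rook", "distance_band")

CLUSTER_NS = "ns"


@dataclass
class SpatialWeightMatrix:
    ids: list
    w: sparse.csr_matrix
    scheme: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    def neighbor_counts(self) -> np.ndarray:
        return np.asarray((self.w != 0).sum(axis=1)).ravel()


def _grid_indices(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map centroids of a (possibly gappy) regular grid to integer rows/cols."""
    def axis_index(v):
        u = np.unique(v)
        if len(u) == 1:
            return np.zeros(len(v), dtype=int)
        step = np.min(np.diff(u))
        return np.rint((v - u[0]) / step).astype(int)

    return axis_index(xs), axis_index(ys)


def build_weights(
    cells,
    scheme: str = "queen",
    row_standardize: bool = True,
    band: float | None = None,
) -> SpatialWeightMatrix:
    """Contiguity or distance-band weights on demand-cell centroids.

    Queen/rook contiguity is inferred from the grid layout of the
    centroids; ``distance_band`` links every pair within ``band``
    metres.  Isolated units keep a zero row (logged).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    n = len(cells)
    if n < 2:
        raise ValueError("need at least two units")
    xs = np.array([c.x for c in cells], dtype=float)
    ys = np.array([c.y for c in cells], dtype=float)

    rows, cols, vals = [], [], []
    if scheme == "distance_band":
        if band is None:
            raise ValueError("distance_band needs a band distance")
        d2 = (xs[:, None] - xs[None, :]) ** 2 + (ys[:, None] - ys[None, :]) ** 2
        adj = (d2 <= band * band) & ~np.eye(n, dtype=bool)
        rows, cols = np.nonzero(adj)
        vals = np.ones(len(rows))
    else:
        ix, iy = _grid_indices(xs, ys)
        pos = {(a, b): i for i, (a, b) in enumerate(zip(ix, iy))}
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        for i, (a, b) in enumerate(zip(ix, iy)):
            for da, db in offsets:
                j = pos.get((a + da, b + db))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(1.0)

    w = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    iso = np.asarray(w.sum(axis=1)).ravel() == 0
    if iso.any():
        logger.warning("%d isolated units retained with zero weight rows", int(iso.sum()))
    if row_standardize:
        rs = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(rs > 0, 1.0 / np.where(rs > 0, rs, 1.0), 0.0)
        w = sparse.diags(inv) @ w
    return SpatialWeightMatrix([c.id for c in cells], w.tocsr(), scheme, row_standardize)


@dataclass
class MoranResult:
    global_I: float | None = None
    expected_I: float | None = None
    p_value: float | None = None
    local_I: np.ndarray | None = None
    local_p: np.ndarray | None = None
    clusters: list[str] | None = None
    ids: list = field(default_factory=list)
    n_permutations: int = 0
    seed: int | None = None
    permuted_I: np.ndarray | None = None


def _moran_stat(x: np.ndarray, w: sparse.csr_matrix) -> float:
    z = x - x.mean()
    ss = float(z @ z)
    if ss <= 0:
        raise ValueError("constant surface: Moran's I undefined (zero variance)")
    s0 = float(w.sum())
    return len(x) / s0 * float(z @ (w @ z)) / ss


def global_moran(
    surface,
    weights: SpatialWeightMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with a full-permutation p-value.

    ``surface`` may be an AccessibilitySurface or a plain array aligned
    with the weights' ids.  The p-value is one-sided toward the observed
    departure from E[I] = -1/(n-1).
    """
    x = np.asarray(getattr(surface, "values", surface), dtype=float)
    if len(x) != weights.n:
        raise ValueError("surface and weights are not aligned")
    I_obs = _moran_stat(x, weights.w)
    n = weights.n
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_permutations)
    for b in range(n_permutations):
        sims[b] = _moran_stat(rng.permutation(x), weights.w)
    if I_obs >= e_i:
        extreme = int(np.sum(sims >= I_obs))
    else:
        extreme = int(np.sum(sims <= I_obs))
    p = (extreme + 1) / (n_permutations + 1)
    return MoranResult(
        global_I=I_obs,
        expected_I=e_i,
        p_value=p,
        ids=list(weights.ids),
        n_permutations=n_permutations,
        seed=seed,
        permuted_I=sims,
    )


def local_moran(
    surface,
    weights: SpatialWeightMatrix,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MoranResult:
    """Local Moran's I with conditional-permutation significance and LISA classes."""
    x = np.asarray(getattr(surface, "values", surface), dtype=float)
    if len(x) != weights.n:
        raise ValueError("surface and weights are not aligned")
    n = weights.n
    sd = x.std()  # population (n-divisor) standard deviation
    if sd <= 0:
        raise ValueError("constant surface: local Moran undefined")
    z = (x - x.mean()) / sd
    w = weights.w
    lag = w @ z
    local_I = z * lag

    rng = np.random.default_rng(seed)
    local_p = np.ones(n)
    indptr, indices, data = w.indptr, w.indices, w.data
    for i in range(n):
        nbr = indices[indptr[i]:indptr[i + 1]]
        wts = data[indptr[i]:indptr[i + 1]]
        k = len(nbr)
        if k == 0:
            continue
        others = np.delete(z, i)
        # conditional permutation: draw k values from the n-1 others
        picks = rng.random((n_permutations, n - 1)).argsort(axis=1)[:, :k]
        sim_lag = others[picks] @ wts
        sim_I = z[i] * sim_lag
        larger = int(np.sum(sim_I >= local_I[i]))
        extreme = min(larger, n_permutations - larger)
        local_p[i] = (extreme + 1) / (n_permutations + 1)

    clusters = []
    for i in range(n):
        if local_p[i] >= alpha:
            clusters.append(CLUSTER_NS)
        elif z[i] >= 0 and lag[i] >= 0:
            clusters.append("HH")
        elif z[i] < 0 and lag[i] < 0:
            clusters.append("LL")
        elif z[i] < 0:
            clusters.append("LH")
        else:
            clusters.append("HL")

    return MoranResult(
        global_I=float(local_I.sum() / weights.s0),
        expected_I=-1.0 / (n - 1),
        local_I=local_I,
        local_p=local_p,
        clusters=clusters,
        ids=list(weights.ids),
        n_permutations=n_permutations,
        seed=seed,
    )
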