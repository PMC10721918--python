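"""Global and local Moran's I on a raster, with permutation inference.

Spatial weights are queen (8-neighbour) or rook (4-neighbour) contiguity on
the grid, optionally restricted to a subset of valid cells; rows are either
binary or row-standardized.  Global Moran's I is

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z_i = x_i - mean(x)

with expectation -1/(n-1) under spatial randomness and a pseudo p-value from
random permutations of the values.  Anselin's Local Moran's I decomposes it:

    I_i = (z_i / m2) * sum_j w_ij z_j,   m2 = sum_k z_k^2 / n

with the identity sum_i I_i = n * I for row-standardized weights.  Local
significance uses conditional permutation (cell i held fixed, the remaining
values permuted among its neighbours), the standard LISA procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grid import GridSpec

__all__ = ["SpatialWeights", "build_contiguity_weights", "global_morans_i",
           "local_morans_i", "classify_clusters", "GlobalMoranResult",
           "LocalMoranResult"]


@dataclass
class SpatialWeights:
    """Sparse contiguity weights over a list of cell ids."""

    W: sp.csr_matrix            # possibly standardized
    ids: np.ndarray             # flat cell indices the rows refer to
    scheme: str
    standardization: str
    islands: np.ndarray         # positions (into ids) with no neighbours

    @property
    def n(self):
        return len(self.ids)

    @property
    def S0(self):
        return float(self.W.sum())


def build_contiguity_weights(spec: GridSpec, scheme="queen",
                             standardization="row",
                             valid=None) -> SpatialWeights:
    """Contiguity weights on the raster.

    ``valid`` optionally restricts the graph to a boolean mask over flat cell
    indices (cells with missing indices are excluded, not imputed).  Islands
    are flagged, and left as zero rows under row standardization.
    """
    if scheme not in ("queen", "rook"):
        raise ValueError("scheme must be 'queen' or 'rook'")
    if standardization not in ("row", "binary"):
        raise ValueError("standardization must be 'row' or 'binary'")
    if valid is None:
        valid = np.ones(spec.n_cells, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
    ids = np.nonzero(valid)[0]
    if len(ids) < 2:
        raise ValueError("need at least two cells for spatial weights")
    pos = -np.ones(spec.n_cells, dtype=int)
    pos[ids] = np.arange(len(ids))

    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows_i, cols_j = [], []
    r, c = np.divmod(ids, spec.n_cols)
    for dr, dc in offsets:
        nr, nc = r + dr, c + dc
        ok = (nr >= 0) & (nr < spec.n_rows) & (nc >= 0) & (nc < spec.n_cols)
        nb = spec.cell_index(nr[ok], nc[ok])
        ok2 = pos[nb] >= 0
        rows_i.append(np.nonzero(ok)[0][ok2])
        cols_j.append(pos[nb[ok2]])
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    W = sp.csr_matrix((np.ones(len(i)), (i, j)),
                      shape=(len(ids), len(ids)))
    deg = np.asarray(W.sum(axis=1)).ravel()
    islands = np.nonzero(deg == 0)[0]
    if standardization == "row":
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        W = sp.diags(inv) @ W
    W = W.tocsr()
    W.sort_indices()      # canonical storage: matvec order is reproducible
    return SpatialWeights(W=W, ids=ids, scheme=scheme,
                          standardization=standardization, islands=islands)


@dataclass
class GlobalMoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class LocalMoranResult:
    ids: np.ndarray
    I: np.ndarray               # per-cell I_i
    quadrant: np.ndarray        # 'HH' | 'LL' | 'HL' | 'LH'
    p_value: np.ndarray         # conditional-permutation pseudo p
    global_I: float
    n_permutations: int
    seed: int | None


def _prep(values, weights):
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError("values length does not match weights")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0:
        raise ValueError("constant field has no autocorrelation")
    return z, ss


def _moran_stat(z, ss, weights):
    lag = weights.W @ z
    return float(len(z) / weights.S0 * (z @ lag) / ss)


def global_morans_i(values, weights: SpatialWeights, n_permutations=999,
                    seed=None) -> GlobalMoranResult:
    """Global Moran's I with a permutation pseudo p-value (one-sided, in the
    direction of the observed departure from the expectation)."""
    z, ss = _prep(values, weights)
    n = len(z)
    I = _moran_stat(z, ss, weights)
    p = np.nan
    if n_permutations:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(z, (n_permutations, 1)), axis=1)
        lags = perms @ weights.W.T
        I_sim = n / weights.S0 * (perms * lags).sum(axis=1) / ss
        ge = int((I_sim >= I).sum())
        le = int((I_sim <= I).sum())
        p = (min(ge, le) + 1) / (n_permutations + 1)
    return GlobalMoranResult(I=I, expected_I=-1.0 / (n - 1), p_value=p,
                             n_permutations=n_permutations, seed=seed)


def local_morans_i(values, weights: SpatialWeights, n_permutations=999,
                   seed=None) -> LocalMoranResult:
    """Anselin Local Moran's I with conditional-permutation pseudo p-values.

    I_i itself is deterministic given the data; only the pseudo p depends on
    the seed.
    """
    z, ss = _prep(values, weights)
    n = len(z)
    m2 = ss / n
    lag = weights.W @ z
    I_i = z / m2 * lag
    quad = np.where(z >= 0, np.where(lag >= 0, "HH", "HL"),
                    np.where(lag >= 0, "LH", "LL")).astype(object)

    p = np.full(n, np.nan)
    if n_permutations:
        rng = np.random.default_rng(seed)
        W = weights.W
        others = np.arange(n - 1)
        for i in range(n):
            s, e = W.indptr[i], W.indptr[i + 1]
            nb_w = W.data[s:e]
            k = len(nb_w)
            if k == 0:
                continue
            # sample k of the other n-1 values, without replacement, per draw
            keys = rng.random((n_permutations, n - 1))
            pick = np.argpartition(keys, k - 1, axis=1)[:, :k]
            pool = np.concatenate([z[:i], z[i + 1:]])
            lag_sim = pool[others[pick]] @ nb_w
            I_sim = z[i] / m2 * lag_sim
            ge = int((I_sim >= I_i[i]).sum())
            le = int((I_sim <= I_i[i]).sum())
            p[i] = (min(ge, le) + 1) / (n_permutations + 1)
    return LocalMoranResult(ids=weights.ids, I=I_i, quadrant=quad,
                            p_value=p, global_I=_moran_stat(z, ss, weights),
                            n_permutations=n_permutations, seed=seed)


def classify_clusters(result: LocalMoranResult, alpha=0.05) -> np.ndarray:
    """LISA cluster labels: quadrant where pseudo p <= alpha, else
    'not-significant'."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    sig = result.p_value <= alpha
    return np.where(sig, result.quadrant, "not-significant").astype(object)
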