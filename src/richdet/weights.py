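"""Distance-band spatial weights and Moran's I.

Units are neighbors when their planar centroid distance is positive
fraction-free and at most ``lag_km`` (distinct units at distance zero
count as neighbors; a unit is never its own neighbor).  Binary adjacency
is row-standardized so every non-isolate row sums to one; isolates keep
zero rows and are reported.

The candidate band radii used throughout the analysis are
``CANDIDATE_LAGS_KM`` = (50, 100, 200, 400, 600, 800, 1000) km.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

CANDIDATE_LAGS_KM: tuple[float, ...] = (50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0)


@dataclass
class SpatialWeights:
    """Row-standardized distance-band weights on an ordered set of units.

    Attributes
    ----------
    ids : ndarray
        Unit identifiers, in matrix row order.
    w : scipy.sparse.csr_matrix
        Row-standardized weights; isolate rows are identically zero.
    lag_km : float
        Band radius used to define adjacency.
    isolate_ids : ndarray
        Identifiers of units with no neighbor within the band.
    """

    ids: np.ndarray
    w: sparse.csr_matrix
    lag_km: float
    isolate_ids: np.ndarray
    _eigs: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (isolates excluded by construction)."""
        return float(self.w.sum())

    @property
    def n_isolates(self) -> int:
        return len(self.isolate_ids)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardized weight matrix.

        Uses the similarity of D^-1 A to the symmetric D^-1/2 A D^-1/2
        (A the binary adjacency, D the degree matrix), so a symmetric
        eigensolver applies; isolate rows contribute zero eigenvalues.
        """
        if self._eigs is None:
            a = (self.w != 0).astype(float)
            deg = np.asarray(a.sum(axis=1)).ravel()
            d = np.where(deg > 0, deg, 1.0)
            s = np.sqrt(d)
            sym = a.toarray() / np.outer(s, s)
            self._eigs = np.linalg.eigvalsh(sym)
        return self._eigs

    def to_triplets(self, path) -> None:
        """Write weights as '# lag_km=... n=... isolates=...' + 'i j w' rows."""
        coo = self.w.tocoo()
        with open(path, "w") as fh:
            fh.write(
                f"# lag_km={self.lag_km} n={self.n} isolates={self.n_isolates}\n"
            )
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{v:.17g}\n")


def build_distance_band_weights(
    centroids: np.ndarray, lag_km: float, ids: np.ndarray | None = None
) -> SpatialWeights:
    """Build row-standardized distance-band weights on planar km coordinates.

    Parameters
    ----------
    centroids : (n, 2) array
        Planar coordinates in km.
    lag_km : float
        Positive band radius; i ~ j iff d(i, j) <= lag_km and i != j.
    ids : array, optional
        Unit identifiers (defaults to 0..n-1).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != 2 or centroids.shape[0] < 2:
        raise ValueError("centroids must be an (n>=2, 2) array of planar km points")
    if not lag_km > 0:
        raise ValueError(f"lag_km must be positive, got {lag_km}")
    n = centroids.shape[0]
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)

    tree = cKDTree(centroids)
    pairs = tree.query_pairs(r=lag_km, output_type="ndarray")
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        a = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
    else:
        a = sparse.csr_matrix((n, n))
    deg = np.asarray(a.sum(axis=1)).ravel()
    isolates = ids[deg == 0]
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    w = sparse.diags(inv) @ a
    return SpatialWeights(ids=ids, w=w.tocsr(), lag_km=float(lag_km), isolate_ids=isolates)


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Moran's I with a permutation p-value.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values.  The p-value is two-sided against the permutation
    distribution: the fraction of permuted |I - E[I]| at least as large
    as observed, E[I] = -1/(n-1), with the +1 continuity correction.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[0] != weights.n:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for a constant vector")
    s0 = weights.s0
    if s0 == 0.0:
        raise ValueError("all units are isolates; Moran's I undefined")
    n = weights.n

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ (weights.w @ zv)) / (zv @ zv))

    i_obs = stat(z)
    if permutations <= 0:
        return i_obs, float("nan")
    rng = np.random.default_rng(seed)
    e_i = -1.0 / (n - 1)
    count = 0
    for _ in range(permutations):
        zp = rng.permutation(z)
        if abs(stat(zp) - e_i) >= abs(i_obs - e_i):
            count += 1
    p = (count + 1) / (permutations + 1)
    return i_obs, p
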