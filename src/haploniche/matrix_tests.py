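"""Distance matrices and Mantel / partial Mantel tests.

Builds the three matrices used to partition genetic structure between
geography and ecology — pairwise F_ST (two-population AMOVA per pair),
great-circle geographic distance, and Euclidean ecological distance on
the first two PCA axes of the population sites — and tests their
association by Mantel correlation with object (row + column)
permutations of the first matrix. The partial Mantel test correlates
the residuals of A and B after regressing each on the control matrix C
(Smouse-Long-Sokal style), with one-tailed p-values for a positive
association, the isolation-by-distance convention.
"""

from __future__ import annotations

import numpy as np

from .config import PopulationMeta
from .haplostats import HaplotypeTable, HaplotypeDistances
from .amova import _one_level_components
from .niche import PcaResult

EARTH_RADIUS_KM = 6371.0088


def great_circle_matrix(meta: list[PopulationMeta]) -> np.ndarray:
    """Haversine distances in km between population coordinates."""
    lon = np.radians([m.longitude for m in meta])
    lat = np.radians([m.latitude for m in meta])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def ecological_distance_matrix(pca: PcaResult, site_indices) -> np.ndarray:
    """Euclidean distances between sites in (PC1, PC2) space."""
    idx = np.asarray(site_indices, dtype=int)
    if idx.max() >= pca.scores.shape[0] or idx.min() < 0:
        raise ValueError("site index outside the PCA score table")
    pts = pca.scores[idx][:, :2]
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def pairwise_fst(table: HaplotypeTable, dist: HaplotypeDistances | None = None,
                 ) -> np.ndarray:
    """Two-population AMOVA F_ST for every population pair (negatives kept)."""
    if table.n_populations < 2:
        raise ValueError("need >= 2 populations")
    d2 = (dist.aligned_to(table) if dist is not None
          else (1.0 - np.eye(table.n_haplotypes)))
    P = table.n_populations
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            counts = table.counts[[i, j]]
            sigma_a, sigma_w, _ = _one_level_components(counts, d2)
            total = sigma_a + sigma_w
            out[i, j] = out[j, i] = sigma_a / total if total > 0 else 0.0
    return out


def _offdiag(A: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(A.shape[0], k=1)
    return A[iu]


def _check_matrix(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T):
        raise ValueError(f"{name} must be a square symmetric matrix")
    if n < 4:
        raise ValueError("Mantel tests need >= 4 objects")
    if np.ptp(_offdiag(A)) == 0:
        raise ValueError(f"{name} is constant; Mantel r undefined")
    return A


def mantel(A: np.ndarray, B: np.ndarray, n_perm: int = 10_000,
           rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal vectorizations; the
    one-tailed p-value permutes the objects (rows and columns together)
    of A.
    """
    A = _check_matrix(A, "A")
    B = _check_matrix(B, "B")
    rng = rng or np.random.default_rng()
    a, b = _offdiag(A), _offdiag(B)
    r_obs = float(np.corrcoef(a, b)[0, 1])
    n = A.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = np.corrcoef(_offdiag(A[np.ix_(perm, perm)]), b)[0, 1]
        if r >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def partial_mantel(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                   n_perm: int = 10_000,
                   rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Partial Mantel correlation of A and B controlling for C.

    Correlates the residuals of A and B after linear regression of each
    on C; significance by object permutations of A (residuals recomputed
    per permutation)."""
    A = _check_matrix(A, "A")
    B = _check_matrix(B, "B")
    C = _check_matrix(C, "C")
    rng = rng or np.random.default_rng()
    b, c = _offdiag(B), _offdiag(C)
    X = np.column_stack([np.ones_like(c), c])
    res_b = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]

    def partial_r(a_vec):
        res_a = a_vec - X @ np.linalg.lstsq(X, a_vec, rcond=None)[0]
        return float(np.corrcoef(res_a, res_b)[0, 1])

    r_obs = partial_r(_offdiag(A))
    n = A.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_r(_offdiag(A[np.ix_(perm, perm)])) >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)
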