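"""Maximum-entropy-style species distribution modelling and niche overlap.

The SDM is a Gibbs distribution over background cells: suitability is
exp(w . f(x)) normalized over the background, with standardized linear
and quadratic features per environmental variable and an L1 penalty on
the weights. This captures the core of the maximum-entropy approach
(hinge/product features and adaptive regularization of the full Maxent
program are deliberately not replicated, so published overlap values
from Maxent runs are qualitative references only).

Niche overlap between two normalized suitability surfaces uses
Schoener's D = 1 - 0.5 * sum |p1 - p2| and Warren's Hellinger-based
I = 1 - 0.5 * sum (sqrt(p1) - sqrt(p2))^2. The niche-identity test
reshuffles pooled occurrences into pseudo-niches, refits both models per
pseudoreplicate, and ranks the observed (D, I) in the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .raster import EnvRaster
from .niche import OccurrenceSet


@dataclass
class SdmModel:
    coefficients: np.ndarray
    feature_names: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    variable_names: list[str]
    log_partition: float
    loglik_path: list[float] = field(default_factory=list)

    def _features(self, env: np.ndarray) -> np.ndarray:
        raw = np.concatenate([env, env**2], axis=1)
        return (raw - self.feature_mean) / self.feature_scale

    def score_env(self, env: np.ndarray) -> np.ndarray:
        """Unnormalized log-suitability of environment rows."""
        return self._features(env) @ self.coefficients

    def predict(self, raster: EnvRaster) -> "SuitabilityGrid":
        env = raster.env_matrix()
        logit = self.score_env(env)
        p = np.exp(logit - logsumexp(logit))
        grid = np.full(raster.n_rows * raster.n_cols, np.nan)
        grid[raster.unmasked_flat_indices()] = p
        return SuitabilityGrid(
            values=grid.reshape(raster.n_rows, raster.n_cols),
            mask=raster.mask.copy(), xllcorner=raster.xllcorner,
            yllcorner=raster.yllcorner, cellsize=raster.cellsize)


@dataclass
class SuitabilityGrid:
    """Per-cell habitat suitability, normalized to sum 1 over unmasked cells."""

    values: np.ndarray
    mask: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float

    def same_geometry(self, other: "SuitabilityGrid") -> bool:
        return (self.values.shape == other.values.shape
                and self.xllcorner == other.xllcorner
                and self.yllcorner == other.yllcorner
                and self.cellsize == other.cellsize)

    def normalized_over(self, mask: np.ndarray) -> np.ndarray:
        v = np.where(mask, 0.0, np.nan_to_num(self.values))
        s = v.sum()
        if s <= 0:
            raise ValueError("suitability is zero over the requested mask")
        return v / s


@dataclass
class OverlapResult:
    schoener_D: float
    warren_I: float
    identity_null: list[tuple[float, float]] = field(default_factory=list)
    p_D: float | None = None
    p_I: float | None = None


def _build_features(env: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    raw = np.concatenate([env, env**2], axis=1)
    mean = raw.mean(axis=0)
    scale = raw.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return (raw - mean) / scale, mean, scale


def fit_sdm(occ: OccurrenceSet, raster: EnvRaster,
            n_background: int = 10_000, l1_penalty: float = 0.05,
            rng: np.random.Generator | None = None) -> SdmModel:
    """Fit the penalized Gibbs SDM.

    Maximizes mean presence log-suitability minus the background
    log-partition, minus l1_penalty * ||w||_1 (smoothed for the
    gradient). Background cells are a uniform seeded sample of unmasked
    cells (all of them when the raster is small).
    """
    rng = rng or np.random.default_rng()
    lon = occ.data["longitude"].to_numpy(float)
    lat = occ.data["latitude"].to_numpy(float)
    if len(lon) < 10:
        raise ValueError("need >= 10 occurrence points")
    inside = raster.contains(lon, lat)
    if np.any(~inside):
        raise ValueError(
            f"occurrences off-raster: rows {np.flatnonzero(~inside).tolist()}")
    variables = raster.variable_names
    env_bg_all = raster.env_matrix()
    if env_bg_all.shape[0] > n_background:
        pick = rng.choice(env_bg_all.shape[0], size=n_background, replace=False)
        env_bg = env_bg_all[pick]
    else:
        env_bg = env_bg_all
    env_pres = raster.extract(lon, lat)

    bg_feat, mean, scale = _build_features(env_bg)
    pres_raw = np.concatenate([env_pres, env_pres**2], axis=1)
    pres_feat = (pres_raw - mean) / scale
    pres_mean = pres_feat.mean(axis=0)
    eps = 1e-8
    path: list[float] = []

    def objective(w):
        log_z = logsumexp(bg_feat @ w) - np.log(len(bg_feat))
        loglik = pres_mean @ w - log_z
        path.append(float(loglik))
        pen = l1_penalty * np.sum(np.sqrt(w**2 + eps))
        # gradient
        probs = np.exp(bg_feat @ w - logsumexp(bg_feat @ w))
        grad = pres_mean - probs @ bg_feat - l1_penalty * w / np.sqrt(w**2 + eps)
        return -(loglik - pen), -grad

    w0 = np.zeros(bg_feat.shape[1])
    res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                   options=dict(maxiter=500))
    w = res.x
    names = [f"{v}" for v in variables] + [f"{v}^2" for v in variables]
    log_z = float(logsumexp(bg_feat @ w))
    return SdmModel(coefficients=w, feature_names=names, feature_mean=mean,
                    feature_scale=scale, variable_names=list(variables),
                    log_partition=log_z, loglik_path=path)


def evaluate_auc(model: SdmModel, occ: OccurrenceSet, raster: EnvRaster,
                 test_fraction: float = 0.25,
                 rng: np.random.Generator | None = None) -> tuple[float, float]:
    """ROC AUC of presence scores against background-cell scores for the
    training (1 - test_fraction) and held-out test splits."""
    rng = rng or np.random.default_rng()
    n = len(occ)
    n_test = max(1, int(round(test_fraction * n)))
    if n_test < 4:
        raise ValueError("need >= 4 test points for a stable AUC")
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    env = raster.extract(occ.data["longitude"].to_numpy(float),
                         occ.data["latitude"].to_numpy(float))
    bg_scores = model.score_env(raster.env_matrix())
    out = []
    for idx in (train_idx, test_idx):
        pres_scores = model.score_env(env[idx])
        y = np.concatenate([np.ones(len(pres_scores)), np.zeros(len(bg_scores))])
        s = np.concatenate([pres_scores, bg_scores])
        out.append(float(roc_auc_score(y, s)))
    return out[0], out[1]


def auc_band(auc: float) -> str:
    """Swets' qualitative interpretation bands for AUC."""
    if auc > 0.9:
        return "good"
    if auc > 0.7:
        return "useful"
    return "poor"


def select_threshold(presence_scores, background_scores,
                     criterion: str = "maximize") -> float:
    """Suitability threshold optimizing sensitivity + specificity.

    criterion="maximize" (the conventional max sens+spec rule) is the
    default; criterion="minimize" reproduces the literal min-sum reading.
    Candidates are the midpoints between consecutive distinct scores.
    """
    pres = np.sort(np.asarray(presence_scores, dtype=float))
    bg = np.sort(np.asarray(background_scores, dtype=float))
    allv = np.unique(np.concatenate([pres, bg]))
    if allv.size == 1:
        return float(allv[0])
    cands = np.concatenate([[allv[0] - 1e-9],
                            (allv[:-1] + allv[1:]) / 2,
                            [allv[-1] + 1e-9]])
    sens = 1.0 - np.searchsorted(pres, cands, side="right") / len(pres)
    spec = np.searchsorted(bg, cands, side="right") / len(bg)
    total = sens + spec
    best = np.argmax(total) if criterion == "maximize" else np.argmin(total)
    return float(cands[best])


def niche_overlap(surface1: SuitabilityGrid, surface2: SuitabilityGrid,
                  ) -> tuple[float, float]:
    """Schoener's D and Warren's I between two suitability surfaces.

    Surfaces are renormalized over the intersection of their unmasked
    cells before comparison.
    """
    if not surface1.same_geometry(surface2):
        raise ValueError("suitability surfaces have different geometry")
    joint_mask = surface1.mask | surface2.mask
    p1 = surface1.normalized_over(joint_mask)
    p2 = surface2.normalized_over(joint_mask)
    D = 1.0 - 0.5 * np.sum(np.abs(p1 - p2))
    I = 1.0 - 0.5 * np.sum((np.sqrt(p1) - np.sqrt(p2)) ** 2)
    return float(D), float(I)


def identity_test(occ1: OccurrenceSet, occ2: OccurrenceSet, raster: EnvRaster,
                  n_reps: int = 100, n_background: int = 10_000,
                  l1_penalty: float = 0.05,
                  rng: np.random.Generator | None = None) -> OverlapResult:
    """Niche-identity randomization test.

    Pools the two occurrence sets, reshuffles them into pseudo-sets of
    the original sizes, refits both SDMs per pseudoreplicate, and ranks
    the observed overlap in the null: p = fraction of null (D, I) <=
    observed (one-tailed; low p rejects niche identity).
    """
    if n_reps < 20:
        raise ValueError("n_reps must be >= 20")
    rng = rng or np.random.default_rng()

    def overlap_of(a: OccurrenceSet, b: OccurrenceSet) -> tuple[float, float]:
        m1 = fit_sdm(a, raster, n_background=n_background,
                     l1_penalty=l1_penalty, rng=rng)
        m2 = fit_sdm(b, raster, n_background=n_background,
                     l1_penalty=l1_penalty, rng=rng)
        return niche_overlap(m1.predict(raster), m2.predict(raster))

    d_obs, i_obs = overlap_of(occ1, occ2)
    pooled = OccurrenceSet(pd.concat([occ1.data, occ2.data], ignore_index=True))
    n1 = len(occ1)
    null: list[tuple[float, float]] = []
    for _ in range(n_reps):
        perm = rng.permutation(len(pooled))
        a = pooled.subset(np.isin(np.arange(len(pooled)), perm[:n1]))
        b = pooled.subset(np.isin(np.arange(len(pooled)), perm[n1:]))
        null.append(overlap_of(a, b))
    d_null = np.array([d for d, _ in null])
    i_null = np.array([i for _, i in null])
    p_d = (np.sum(d_null <= d_obs + 1e-12) + 1) / (n_reps + 1)
    p_i = (np.sum(i_null <= i_obs + 1e-12) + 1) / (n_reps + 1)
    return OverlapResult(schoener_D=d_obs, warren_I=i_obs, identity_null=null,
                         p_D=float(p_d), p_I=float(p_i))
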