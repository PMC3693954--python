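"""Ecological niche space: variable screening, ecotype clustering,
discriminant analysis, PCA ordination, and the background divergence test.

The workflow mirrors the standard niche-divergence toolkit for
occurrence data: prune collinear environmental variables (|r| below a
cutoff), cluster occurrences into ecotypes by a BIC-selected Gaussian
mixture (a reproducible stand-in for commercial TwoStep clustering,
agreeing with it on well-separated data), quantify pairwise ecotype
separation by two-group discriminant analysis with Wilks' lambda, ordain
occurrences by correlation-matrix PCA with a between-class inertia
randomization, and distinguish niche divergence from mere background
(habitat-availability) differences by comparing observed divergence d_n
with background divergence d_b on each retained principal axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

GEO_COLUMNS = ("longitude", "latitude", "altitude")


@dataclass
class OccurrenceSet:
    """Georeferenced occurrence points with environmental vectors."""

    data: pd.DataFrame  # longitude, latitude, altitude + env columns

    def __post_init__(self):
        for col in GEO_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"occurrence table lacks required column {col!r}")
        if len(self.data) == 0:
            raise ValueError("empty occurrence set")
        env = self.env()
        if env.isna().any().any():
            bad = self.data.index[env.isna().any(axis=1)].tolist()
            raise ValueError(f"missing environmental values in rows {bad}")
        names = self.variable_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate environmental variable names")

    @property
    def variable_names(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in GEO_COLUMNS and c != "ecotype"]

    def env(self, variables: list[str] | None = None) -> pd.DataFrame:
        return self.data[variables or self.variable_names]

    def geo(self) -> pd.DataFrame:
        return self.data[list(GEO_COLUMNS)]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.data[np.asarray(mask)].reset_index(drop=True))

    def with_variables(self, variables: list[str]) -> "OccurrenceSet":
        keep = [c for c in self.data.columns
                if c in GEO_COLUMNS or c == "ecotype" or c in variables]
        return OccurrenceSet(self.data[keep].copy())


@dataclass
class EcotypeClustering:
    assignments: np.ndarray
    n_clusters: int
    BIC_by_k: list[tuple[int, float]]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    scores: np.ndarray          # points x axes
    loadings: np.ndarray        # variables x axes (variable-axis correlations)
    var_explained: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def n_retained(self, eigenvalue_threshold: float = 1.0) -> int:
        return int(np.sum(self.eigenvalues > eigenvalue_threshold))


@dataclass
class BackgroundTestResult:
    per_axis: list[dict]  # axis, d_n_mean, d_b_CI, d_n_p, verdict
    top_loading_variables: list[list[str]]
    var_explained: np.ndarray
    eigenvalues: np.ndarray


def screen_variables(occ: OccurrenceSet | pd.DataFrame, cutoff: float = 0.70) -> list[str]:
    """Greedy collinearity pruning: while any variable pair has |r| >= cutoff,
    drop the member of the worst pair with the larger mean absolute
    correlation (ties resolved toward the later column). Returns retained
    variable names in input order."""
    df = occ.env() if isinstance(occ, OccurrenceSet) else occ
    names = list(df.columns)
    if len(names) < 2:
        return names
    corr = df.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(names)))
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() < cutoff:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[i_loc], alive[j_loc]
        mean_i = corr[i, alive].sum() / (len(alive) - 1)
        mean_j = corr[j, alive].sum() / (len(alive) - 1)
        drop = j if (mean_j > mean_i or (mean_j == mean_i and j > i)) else i
        alive.remove(drop)
    return [names[i] for i in sorted(alive)]


def ecotype_cluster(occ: OccurrenceSet | np.ndarray, k_range=range(1, 7),
                    seed: int = 0) -> EcotypeClustering:
    """BIC-selected full-covariance Gaussian mixture on standardized
    environmental variables; assignments are MAP labels."""
    X = occ.env().to_numpy(float) if isinstance(occ, OccurrenceSet) else np.asarray(occ, float)
    if len(X) < max(k_range):
        raise ValueError(f"{len(X)} points cannot support up to {max(k_range)} clusters")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    bic_by_k, fits = [], {}
    for k in k_range:
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=5, random_state=seed).fit(Xs)
        bic_by_k.append((k, float(gm.bic(Xs))))
        fits[k] = gm
    best_k = min(bic_by_k, key=lambda t: t[1])[0]
    labels = fits[best_k].predict(Xs)
    return EcotypeClustering(assignments=labels, n_clusters=int(best_k),
                             BIC_by_k=bic_by_k)


def dfa(occ: OccurrenceSet | np.ndarray, labels, pair: tuple = (0, 1),
        ) -> tuple[float, float, pd.Series]:
    """Two-group canonical discriminant analysis.

    Returns (Wilks' lambda = |W|/|T|, F-approximation p-value,
    standardized canonical coefficients per variable).
    """
    if isinstance(occ, OccurrenceSet):
        X = occ.env().to_numpy(float)
        names = occ.variable_names
    else:
        X = np.asarray(occ, float)
        names = [f"v{i}" for i in range(X.shape[1])]
    labels = np.asarray(labels)
    m = np.isin(labels, list(pair))
    X, labels = X[m], labels[m]
    g1, g2 = X[labels == pair[0]], X[labels == pair[1]]
    n, p = X.shape
    if min(len(g1), len(g2)) < p + 2:
        raise ValueError("each cluster needs at least n_variables + 2 points")
    W = ((len(g1) - 1) * np.atleast_2d(np.cov(g1, rowvar=False, ddof=1))
         + (len(g2) - 1) * np.atleast_2d(np.cov(g2, rowvar=False, ddof=1)))
    T = (n - 1) * np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        warnings.warn("singular within-class covariance; ridge-regularized")
        W = W + 1e-8 * np.trace(W) / p * np.eye(p)
        sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    lam = float(np.exp(logdet_w - logdet_t))
    df2 = n - p - 1
    F = (1.0 - lam) / lam * df2 / p
    pval = float(stats.f.sf(F, p, df2))
    a = np.linalg.solve(W, g1.mean(axis=0) - g2.mean(axis=0))
    std = a * np.sqrt(np.diag(W) / (n - 2))
    # scale to unit norm for comparability across pairs
    if np.linalg.norm(std) > 0:
        std = std / np.linalg.norm(std)
    return lam, pval, pd.Series(std, index=names)


def pca_ordination(occ: OccurrenceSet | pd.DataFrame) -> PcaResult:
    """Correlation-matrix PCA of the environmental variables.

    Eigenvalues are those of the correlation matrix (uniform 1/n row
    weights), so var_explained = eigenvalue / n_variables.
    """
    df = occ.env() if isinstance(occ, OccurrenceSet) else occ
    X = df.to_numpy(float)
    n, p = X.shape
    if p < 2:
        raise ValueError("PCA needs >= 2 variables")
    if n <= p:
        raise ValueError("PCA needs more points than variables")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [df.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant environmental columns: {bad}")
    mean = X.mean(axis=0)
    Xs = (X - mean) / sd
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s**2 / n
    scores = u * s
    loadings = vt.T * np.sqrt(eig)
    return PcaResult(eigenvalues=eig, scores=scores, loadings=loadings,
                     var_explained=eig / eig.sum(),
                     variable_names=list(df.columns), mean_=mean, scale_=sd)


def between_class_inertia(X, labels, n_rand: int = 999,
                          rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Between-class share of the total inertia of (scaled) data, with a
    label-permutation randomization p-value."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = rng or np.random.default_rng()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if np.any(counts < 2):
        warnings.warn("classes with a single member make the inertia ratio unstable")
    grand = X.mean(axis=0)
    total = np.sum((X - grand) ** 2)

    def ratio(lbl):
        between = 0.0
        for c in classes:
            sub = X[lbl == c]
            between += len(sub) * np.sum((sub.mean(axis=0) - grand) ** 2)
        return between / total

    obs = ratio(labels)
    hits = sum(ratio(rng.permutation(labels)) >= obs - 1e-12 for _ in range(n_rand))
    return float(obs), (hits + 1) / (n_rand + 1)


def _perm_ttest(a: np.ndarray, b: np.ndarray, n_perm: int,
                rng: np.random.Generator) -> float:
    """Two-sided permutation test on the difference of means."""
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, k = len(a), len(pooled)
    total = pooled.sum()
    idx = np.argsort(rng.random((n_perm, k)), axis=1)[:, :na]
    sums = pooled[idx].sum(axis=1)
    diffs = np.abs(sums / na - (total - sums) / (k - na))
    hits = int(np.sum(diffs >= obs - 1e-12))
    return (hits + 1) / (n_perm + 1)


def background_test(occ1: OccurrenceSet, occ2: OccurrenceSet,
                    bg1: np.ndarray | pd.DataFrame, bg2: np.ndarray | pd.DataFrame,
                    n_resamples: int = 1000, subsample_fraction: float = 0.75,
                    n_perm: int = 10_000, eigenvalue_threshold: float = 1.0,
                    rng: np.random.Generator | None = None) -> BackgroundTestResult:
    """Niche divergence vs background divergence (d_n vs d_b) per PCA axis.

    The PCA is fitted on the pooled occurrence + background environments.
    On each axis with eigenvalue above the threshold, d_n is the mean
    absolute difference of mean scores over 75% occurrence subsamples and
    d_b the same over background subsamples; divergence is called when
    d_n exceeds the upper 95% bound of the d_b distribution and the
    occurrence score difference is significant by a permutation t-test,
    conservatism when d_n falls below the lower bound.
    """
    rng = rng or np.random.default_rng()
    variables = occ1.variable_names
    if occ2.variable_names != variables:
        raise ValueError("occurrence sets disagree on variables")
    e1, e2 = occ1.env().to_numpy(float), occ2.env().to_numpy(float)
    b1 = np.asarray(bg1 if not isinstance(bg1, pd.DataFrame) else bg1[variables], float)
    b2 = np.asarray(bg2 if not isinstance(bg2, pd.DataFrame) else bg2[variables], float)
    pooled = np.vstack([e1, e2, b1, b2])
    pca = pca_ordination(pd.DataFrame(pooled, columns=variables))
    n_axes = pca.n_retained(eigenvalue_threshold)
    if n_axes == 0:
        raise ValueError("no PCA axis exceeds the eigenvalue threshold")
    splits = np.cumsum([len(e1), len(e2), len(b1)])
    s1, s2, sb1, sb2 = np.split(pca.scores[:, :n_axes], splits)

    def subsample_diffs(a, b):
        na, nb = max(2, int(round(subsample_fraction * len(a)))), \
                 max(2, int(round(subsample_fraction * len(b))))
        out = np.empty((n_resamples, n_axes))
        for r in range(n_resamples):
            ia = rng.choice(len(a), size=na, replace=False)
            ib = rng.choice(len(b), size=nb, replace=False)
            out[r] = np.abs(a[ia].mean(axis=0) - b[ib].mean(axis=0))
        return out

    dn = subsample_diffs(s1, s2)
    db = subsample_diffs(sb1, sb2)
    per_axis, top_vars = [], []
    for ax in range(n_axes):
        dn_mean = float(dn[:, ax].mean())
        lo, hi = np.percentile(db[:, ax], [2.5, 97.5])
        p = _perm_ttest(s1[:, ax], s2[:, ax], n_perm, rng)
        if dn_mean > hi and p < 0.05:
            verdict = "divergence"
        elif dn_mean < lo:
            verdict = "conservatism"
        else:
            verdict = "ns"
        per_axis.append(dict(axis=ax + 1, d_n_mean=dn_mean,
                             d_b_CI=(float(lo), float(hi)), d_n_p=float(p),
                             verdict=verdict))
        order = np.argsort(-np.abs(pca.loadings[:, ax]))
        top_vars.append([variables[i] for i in order[:2]])
    return BackgroundTestResult(per_axis=per_axis, top_loading_variables=top_vars,
                                var_explained=pca.var_explained[:n_axes],
                                eigenvalues=pca.eigenvalues[:n_axes])


def geo_correlation(scores: np.ndarray, geo: pd.DataFrame, n_perm: int = 10_000,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Spearman correlation of each PCA axis with each geographic variable,
    with two-sided permutation p-values."""
    rng = rng or np.random.default_rng()
    scores = np.asarray(scores, dtype=float)
    rows = []
    n = scores.shape[0]
    score_ranks = np.apply_along_axis(stats.rankdata, 0, scores)
    score_ranks = (score_ranks - score_ranks.mean(axis=0)) / score_ranks.std(axis=0)
    for gname in geo.columns:
        g = stats.rankdata(geo[gname].to_numpy(float))
        g = (g - g.mean()) / g.std()
        # permuted rank correlations for all axes at once
        perm_r = np.empty((n_perm, scores.shape[1]))
        for i in range(n_perm):
            perm_r[i] = rng.permutation(g) @ score_ranks / n
        for ax in range(scores.shape[1]):
            rho = float(g @ score_ranks[:, ax] / n)
            hits = int(np.sum(np.abs(perm_r[:, ax]) >= abs(rho) - 1e-12))
            rows.append(dict(geo=gname, axis=ax + 1, rho=rho,
                             p=(hits + 1) / (n_perm + 1)))
    return pd.DataFrame(rows)
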