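"""Variable screening, ecotype clustering, DFA, PCA and the background
divergence test."""

import numpy as np
import pandas as pd
import pytest

from haploniche import (
    OccurrenceSet, screen_variables, ecotype_cluster, dfa, pca_ordination,
    between_class_inertia, background_test, geo_correlation,
)
from haploniche.simulate import NicheSimSpec, simulate_niche_world


def make_occ(X, names=None):
    names = names or [f"v{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "altitude", 1000.0)
    df.insert(0, "latitude", np.linspace(20, 30, len(df)))
    df.insert(0, "longitude", np.linspace(95, 107, len(df)))
    return OccurrenceSet(df)


class TestScreening:
    def test_uncorrelated_all_retained(self, rng):
        X = rng.standard_normal((300, 5))
        occ = make_occ(X)
        assert screen_variables(occ) == occ.variable_names

    def test_duplicated_column_dropped(self, rng):
        X = rng.standard_normal((100, 3))
        X = np.column_stack([X, X[:, 0]])
        retained = screen_variables(make_occ(X))
        assert len(retained) == 3

    def test_output_satisfies_cutoff(self, rng):
        base = rng.standard_normal((200, 3))
        mix = rng.standard_normal((3, 8))
        X = base @ mix + 0.3 * rng.standard_normal((200, 8))
        occ = make_occ(X)
        retained = screen_variables(occ, cutoff=0.7)
        corr = occ.env(retained).corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.7


class TestClustering:
    def test_three_separated_blobs_perfect(self, rng):
        centers = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0]], dtype=float)
        X = np.vstack([c + rng.standard_normal((40, 3)) for c in centers])
        truth = np.repeat([0, 1, 2], 40)
        res = ecotype_cluster(make_occ(X), k_range=range(1, 6), seed=0)
        assert res.n_clusters == 3
        # MAP labels are a relabelling of the truth
        table = pd.crosstab(truth, res.assignments).to_numpy()
        assert (table > 0).sum() == 3

    def test_single_blob_selects_one(self, rng):
        X = rng.standard_normal((120, 3))
        res = ecotype_cluster(make_occ(X), k_range=range(1, 5), seed=0)
        assert res.n_clusters == 1

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            ecotype_cluster(make_occ(rng.standard_normal((4, 2))),
                            k_range=range(1, 7))


class TestDfa:
    def test_identical_clusters_lambda_near_one(self, rng):
        X = rng.standard_normal((120, 4))
        labels = np.repeat([0, 1], 60)
        lam, p, _ = dfa(make_occ(X), labels)
        assert lam > 0.85
        assert p > 0.01  # no real separation: p behaves like a uniform draw

    def test_separated_clusters_lambda_near_zero(self, rng):
        X = rng.standard_normal((120, 1))
        X[60:] += 12.0
        labels = np.repeat([0, 1], 60)
        lam, p, coef = dfa(make_occ(X), labels)
        assert lam < 0.05
        assert p < 1e-6

    def test_coefficients_point_at_discriminating_variable(self, rng):
        X = rng.standard_normal((160, 4))
        X[80:, 2] += 5.0
        labels = np.repeat([0, 1], 80)
        lam, p, coef = dfa(make_occ(X), labels)
        assert coef.abs().idxmax() == "v3"

    def test_small_groups_rejected(self, rng):
        X = rng.standard_normal((8, 4))
        with pytest.raises(ValueError):
            dfa(make_occ(X), np.repeat([0, 1], 4))


class TestPca:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.standard_normal(100)
        occ = make_occ(np.column_stack([x, 2 * x + 1]))
        res = pca_ordination(occ)
        assert res.var_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_identity_covariance_axes_near_equal_share(self, rng):
        X = rng.standard_normal((4000, 5))
        res = pca_ordination(make_occ(X))
        assert np.allclose(res.var_explained, 0.2, atol=0.03)

    def test_eigenvalues_non_increasing_and_sum(self, rng):
        X = rng.standard_normal((60, 4)) @ rng.standard_normal((4, 4))
        res = pca_ordination(make_occ(X))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.var_explained.sum() == pytest.approx(1.0)
        assert res.eigenvalues.sum() == pytest.approx(4.0, abs=1e-9)

    def test_constant_column_named_in_error(self, rng):
        X = rng.standard_normal((50, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="v2"):
            pca_ordination(make_occ(X))


class TestInertia:
    def test_perfect_separation_minimal_p(self, rng):
        X = np.vstack([np.zeros((30, 2)), 10 + np.zeros((30, 2))])
        X += 0.01 * rng.standard_normal(X.shape)
        labels = np.repeat([0, 1], 30)
        ratio, p = between_class_inertia(X, labels, n_rand=99, rng=rng)
        assert ratio > 0.95
        assert p == pytest.approx(1 / 100)

    def test_random_labels_not_significant(self, rng):
        X = rng.standard_normal((80, 3))
        ps = []
        for _ in range(20):
            labels = rng.integers(0, 2, size=80)
            ps.append(between_class_inertia(X, labels, n_rand=99, rng=rng)[1])
        assert min(ps) > 0.001
        assert np.mean(ps) > 0.2


class TestBackgroundTest:
    def _null_world(self, rng, n_occ=60, n_bg=400):
        cov = np.eye(4)
        occ1 = make_occ(rng.multivariate_normal(np.zeros(4), cov, n_occ))
        occ2 = make_occ(rng.multivariate_normal(np.zeros(4), cov, n_occ))
        bg1 = rng.multivariate_normal(np.zeros(4), cov, n_bg)
        bg2 = rng.multivariate_normal(np.zeros(4), cov, n_bg)
        return occ1, occ2, bg1, bg2

    def test_null_case_not_divergent(self, rng):
        occ1, occ2, bg1, bg2 = self._null_world(rng)
        res = background_test(occ1, occ2, bg1, bg2, n_resamples=200,
                              n_perm=999, rng=rng)
        assert all(ax["verdict"] != "divergence" or ax["d_n_p"] < 0.05
                   for ax in res.per_axis)

    def test_constructed_shift_detected(self, rng):
        occ1, occ2, bg1, bg2 = self._null_world(rng)
        shifted = occ2.data.copy()
        shifted["v1"] += 3.0  # displace occurrences, backgrounds unchanged
        occ2 = OccurrenceSet(shifted)
        res = background_test(occ1, occ2, bg1, bg2, n_resamples=200,
                              n_perm=999, rng=rng)
        assert any(ax["verdict"] == "divergence" for ax in res.per_axis)

    def test_variable_mismatch_rejected(self, rng):
        occ1, occ2, bg1, bg2 = self._null_world(rng)
        occ2 = occ2.with_variables(occ2.variable_names[:3])
        with pytest.raises(ValueError):
            background_test(occ1, occ2, bg1, bg2, rng=rng)


class TestGeoCorrelation:
    def test_axis_equal_to_longitude_gives_unit_rho(self, rng):
        lon = np.linspace(95, 107, 50)
        geo = pd.DataFrame({"longitude": lon, "latitude": rng.random(50),
                            "altitude": rng.random(50)})
        scores = np.column_stack([lon, rng.standard_normal(50)])
        res = geo_correlation(scores, geo, n_perm=199, rng=rng)
        row = res[(res.geo == "longitude") & (res.axis == 1)].iloc[0]
        assert row.rho == pytest.approx(1.0, abs=1e-9)
        assert row.p == pytest.approx(1 / 200)

    def test_independent_noise_small_rho(self, rng):
        geo = pd.DataFrame({"longitude": rng.random(200),
                            "latitude": rng.random(200),
                            "altitude": rng.random(200)})
        scores = rng.standard_normal((200, 2))
        res = geo_correlation(scores, geo, n_perm=99, rng=rng)
        assert res.rho.abs().max() < 0.25


class TestWorldIntegration:
    def test_simulated_world_recovers_three_ecotypes(self):
        raster, occ = simulate_niche_world(NicheSimSpec(seed=2))
        res = ecotype_cluster(occ, k_range=range(1, 6), seed=0)
        assert res.n_clusters == 3
        truth = occ.data["ecotype"].to_numpy()
        table = pd.crosstab(truth, res.assignments).to_numpy()
        # each true ecotype maps onto a single mixture component
        assert (table > 2).sum() == 3
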