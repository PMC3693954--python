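"""SDM fitting, AUC, threshold selection, niche overlap and identity test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from haploniche import (
    OccurrenceSet, EnvRaster,
    fit_sdm, evaluate_auc, select_threshold, niche_overlap, identity_test,
)
from haploniche.sdm import SuitabilityGrid, auc_band
from haploniche.simulate import NicheSimSpec, simulate_niche_world


def flat_raster(value=0.0, n=20):
    return EnvRaster(0.0, 0.0, 0.5, layers={"env1": np.full((n, n), value)})


def grid_pair(p1, p2):
    a = SuitabilityGrid(np.array(p1, dtype=float), np.zeros_like(
        np.array(p1, dtype=float), dtype=bool), 0.0, 0.0, 1.0)
    b = SuitabilityGrid(np.array(p2, dtype=float), np.zeros_like(
        np.array(p2, dtype=float), dtype=bool), 0.0, 0.0, 1.0)
    return a, b


@pytest.fixture(scope="module")
def bump_world():
    return simulate_niche_world(NicheSimSpec(seed=4))


class TestFit:
    def test_constant_raster_gives_uniform_surface(self, rng):
        raster = flat_raster()
        df = pd.DataFrame({
            "longitude": rng.uniform(0.2, 9.8, 30),
            "latitude": rng.uniform(0.2, 9.8, 30),
            "altitude": 0.0, "env1": 0.0})
        model = fit_sdm(OccurrenceSet(df), raster, rng=rng)
        s = model.predict(raster).values
        assert np.nanmax(s) / np.nanmin(s) < 1.001

    def test_gaussian_bump_recovered(self, bump_world, rng):
        """Occurrences sampled from a known suitability bump: fitted
        surface correlates strongly with the generating suitability."""
        raster, occ = bump_world
        truth_label = occ.data["ecotype"].to_numpy()
        o = occ.subset(truth_label == 0)
        model = fit_sdm(o, raster, rng=rng)
        pred = model.predict(raster).values.ravel()
        # generating suitability for ecotype 0 (same construction as the
        # simulator: Gaussian in environment space)
        env = raster.env_matrix()
        # reconstruct the generator's niche centre for ecotype 0
        spec = NicheSimSpec(seed=4)
        dirs = np.eye(spec.n_ecotypes, spec.n_variables)
        centres = dirs * spec.niche_separation / np.sqrt(2.0)
        centres -= centres.mean(axis=0)
        truth = np.exp(-0.5 * np.sum((env - centres[0]) ** 2, axis=1)
                       / spec.niche_sd**2)
        # rank correlation: suitability is a relative cell ranking, and the
        # L1-regularized surface flattens the extreme tails of the truth
        corr = stats.spearmanr(pred, truth).statistic
        assert corr > 0.9

    def test_loglik_improves_over_optimization(self, bump_world, rng):
        raster, occ = bump_world
        model = fit_sdm(occ.subset(occ.data["ecotype"] == 1), raster, rng=rng)
        assert model.loglik_path[-1] >= model.loglik_path[0]

    def test_off_raster_occurrence_rejected(self, rng):
        raster = flat_raster()
        df = pd.DataFrame({
            "longitude": np.concatenate([rng.uniform(1, 9, 12), [99.0]]),
            "latitude": np.concatenate([rng.uniform(1, 9, 12), [0.5]]),
            "altitude": 0.0, "env1": 0.0})
        with pytest.raises(ValueError, match="off-raster"):
            fit_sdm(OccurrenceSet(df), raster, rng=rng)

    def test_suitability_sums_to_one(self, bump_world, rng):
        raster, occ = bump_world
        model = fit_sdm(occ.subset(occ.data["ecotype"] == 2), raster, rng=rng)
        assert np.nansum(model.predict(raster).values) == pytest.approx(1.0)


class TestAuc:
    def test_high_auc_on_simulated_niche(self, bump_world, rng):
        raster, occ = bump_world
        o = occ.subset(occ.data["ecotype"] == 0)
        model = fit_sdm(o, raster, rng=rng)
        train, test = evaluate_auc(model, o, raster, rng=rng)
        assert train > 0.9 and test > 0.85
        assert auc_band(train) == "good"

    def test_permuted_control_auc_is_lower(self, bump_world, rng):
        raster, occ = bump_world
        o = occ.subset(occ.data["ecotype"] == 0)
        model = fit_sdm(o, raster, rng=rng)
        train, _ = evaluate_auc(model, o, raster, rng=rng)
        # control: random points on the raster instead of the real presences
        lonr = rng.uniform(raster.xllcorner + 0.01,
                           raster.xllcorner + raster.n_cols * raster.cellsize - 0.01, len(o))
        latr = rng.uniform(raster.yllcorner + 0.01,
                           raster.yllcorner + raster.n_rows * raster.cellsize - 0.01, len(o))
        ctrl = OccurrenceSet(pd.DataFrame({
            "longitude": lonr, "latitude": latr, "altitude": 0.0,
            **{v: 0.0 for v in raster.variable_names}}))
        ctrain, _ = evaluate_auc(model, ctrl, raster, rng=rng)
        assert ctrain < train

    def test_bands(self):
        assert auc_band(0.6) == "poor"
        assert auc_band(0.8) == "useful"


class TestThreshold:
    def test_separable_scores_split(self):
        thr = select_threshold([0.8, 0.9, 0.95], [0.1, 0.2, 0.3])
        assert 0.3 < thr < 0.8

    def test_degenerate_equal_scores(self):
        assert select_threshold([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_minimize_flag_reproduces_literal_rule(self):
        thr_max = select_threshold([0.8, 0.9], [0.1, 0.2], "maximize")
        thr_min = select_threshold([0.8, 0.9], [0.1, 0.2], "minimize")
        assert thr_min != thr_max


class TestOverlap:
    def test_identical_surfaces(self):
        a, b = grid_pair([[0.5, 0.3], [0.1, 0.1]], [[0.5, 0.3], [0.1, 0.1]])
        D, I = niche_overlap(a, b)
        assert D == pytest.approx(1.0) and I == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a, b = grid_pair([[1.0, 0.0]], [[0.0, 1.0]])
        D, I = niche_overlap(a, b)
        assert D == pytest.approx(0.0) and I == pytest.approx(0.0)

    def test_two_cell_hand_computation(self):
        a, b = grid_pair([[0.8, 0.2]], [[0.2, 0.8]])
        D, I = niche_overlap(a, b)
        assert D == pytest.approx(0.4)
        assert I == pytest.approx(1.0 - (np.sqrt(0.8) - np.sqrt(0.2)) ** 2)

    def test_symmetry(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(12)).reshape(3, 4)
            q = rng.dirichlet(np.ones(12)).reshape(3, 4)
            a, b = grid_pair(p, q)
            assert niche_overlap(a, b) == niche_overlap(b, a)
            D, I = niche_overlap(a, b)
            assert D <= I + 1e-12  # empirical ordering on random surfaces

    def test_geometry_mismatch(self):
        a, _ = grid_pair([[1.0, 0.0]], [[0.0, 1.0]])
        c = SuitabilityGrid(np.array([[1.0, 0.0]]),
                            np.zeros((1, 2), dtype=bool), 5.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="geometry"):
            niche_overlap(a, c)


class TestIdentity:
    def test_displaced_niches_rejected(self, bump_world):
        raster, occ = bump_world
        truth = occ.data["ecotype"].to_numpy()
        res = identity_test(occ.subset(truth == 0), occ.subset(truth == 1),
                            raster, n_reps=20, rng=np.random.default_rng(0))
        null_d = [d for d, _ in res.identity_null]
        assert res.schoener_D < min(null_d)  # observed below the whole null
        assert res.p_D == pytest.approx(1 / 21)
        assert res.p_I == pytest.approx(1 / 21)

    def test_same_distribution_not_rejected(self, bump_world):
        raster, occ = bump_world
        truth = occ.data["ecotype"].to_numpy()
        one = occ.subset(truth == 0)
        half = len(one) // 2
        a = one.subset(np.arange(len(one)) < half)
        b = one.subset(np.arange(len(one)) >= half)
        res = identity_test(a, b, raster, n_reps=20,
                            rng=np.random.default_rng(1))
        assert res.p_D > 0.10

    def test_too_few_reps_rejected(self, bump_world):
        raster, occ = bump_world
        truth = occ.data["ecotype"].to_numpy()
        with pytest.raises(ValueError):
            identity_test(occ.subset(truth == 0), occ.subset(truth == 1),
                          raster, n_reps=5)
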