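import numpy as np
import pandas as pd
import pytest

import irtkit as ik
from irtkit.calibrate import EMControl, free_param_layout, validate_response_matrix
from irtkit.latent import LatentDist
from irtkit.metadata import param_arrays

D = 1.702


def _simulate(meta, n, seed, theta_dist=(0.0, 1.0)):
    design = ik.SimDesign(n_persons=n, meta=meta, theta_dist=theta_dist, D=D, seed=seed)
    return ik.simulate_responses(design)


class TestEStep:
    def test_empty_person_keeps_prior(self, random_3pl_meta):
        dist = ik.make_quadrature(21, 4.0)
        data = np.full((1, 12), np.nan)
        es = ik.e_step(data, random_3pl_meta, dist, D)
        np.testing.assert_allclose(es.posterior[0], dist.weights, atol=1e-12)

    def test_two_node_posterior_by_hand(self):
        # one 2PL item (a=1, b=0, D=1), two equally weighted nodes at +-1:
        # P(-1) = 1/(1+e), P(1) = e/(1+e); for x=1 the posterior is
        # proportional to (P(-1), P(1))
        meta = ik.build_item_meta([1.0], [0.0], model="2PLM")
        dist = LatentDist(np.array([-1.0, 1.0]), np.array([0.5, 0.5]))
        es = ik.e_step(np.array([[1.0]]), meta, dist, 1.0)
        p_lo, p_hi = 1 / (1 + np.e), np.e / (1 + np.e)
        np.testing.assert_allclose(
            es.posterior[0], [p_lo / (p_lo + p_hi), p_hi / (p_lo + p_hi)], rtol=1e-12
        )
        assert es.loglik == pytest.approx(np.log(0.5 * (p_lo + p_hi)))

    def test_posteriors_normalize_and_counts_conserve(self, random_3pl_meta, rng):
        sim = _simulate(random_3pl_meta, 150, seed=3)
        data = sim.data.copy()
        miss = rng.random(data.shape) < 0.2
        data[miss] = np.nan
        dist = ik.make_quadrature(31, 5.0)
        es = ik.e_step(data, random_3pl_meta, dist, D)
        np.testing.assert_allclose(es.posterior.sum(axis=1), 1.0, atol=1e-10)
        observed = np.isfinite(data).sum(axis=0)
        np.testing.assert_allclose(es.expected_n.sum(axis=1), observed, atol=1e-8)
        assert (es.expected_n >= es.expected_correct - 1e-12).all()


class TestMStep:
    def test_fixed_g_returned_exactly(self):
        dist = ik.make_quadrature(31, 5.0)
        nodes = dist.nodes
        p = ik.three_pl_prob(nodes, 1.2, 0.3, 0.2, D)
        n = 500 * dist.weights
        a, b, g, ok = ik.m_step_item(
            n * p, n, nodes, "3PLM", D=D, fix_g=True, g_val=0.2
        )
        assert g == 0.2
        assert ok

    def test_recovers_parameters_from_exact_expected_counts(self):
        # expected counts generated directly from a known 2PL on a fine grid
        # act as a weighted-logistic oracle
        dist = ik.make_quadrature(81, 5.0)
        nodes = dist.nodes
        true_a, true_b = 1.35, -0.6
        p = ik.three_pl_prob(nodes, true_a, true_b, 0.0, D)
        n = 5000 * dist.weights
        a, b, g, ok = ik.m_step_item(n * p, n, nodes, "2PLM", D=D)
        assert a == pytest.approx(true_a, abs=1e-4)
        assert b == pytest.approx(true_b, abs=1e-4)
        assert np.isnan(g)

    def test_all_correct_item_hits_bound_and_is_flagged(self):
        dist = ik.make_quadrature(21, 4.0)
        n = 100 * dist.weights
        a, b, g, ok = ik.m_step_item(n, n, dist.nodes, "2PLM", D=D)
        assert not ok
        assert b <= -9.9  # difficulty driven to its lower bound

    def test_count_domination_enforced(self):
        dist = ik.make_quadrature(21, 4.0)
        n = np.ones(21)
        with pytest.raises(ValueError):
            ik.m_step_item(n + 1.0, n, dist.nodes, "2PLM", D=D)


class TestFreeParameterCounting:
    @pytest.mark.parametrize(
        "models, control, expected",
        [
            (["1PLM"] * 30, EMControl(), 31),
            (["1PLM"] * 30, EMControl(fix_a_1pl=True), 30),
            (["2PLM"] * 10 + ["3PLM"] * 20, EMControl(), 80),
            (["2PLM"] * 10 + ["3PLM"] * 20, EMControl(fix_g=True), 60),
        ],
    )
    def test_layout_sizes(self, models, control, expected):
        meta = ik.build_item_meta(
            np.ones(30), np.zeros(30),
            [0.2 if m in ("3PLM", "DRM") else np.nan for m in models],
            model=models,
        )
        assert len(free_param_layout(meta, control)) == expected


@pytest.fixture(scope="module")
def small_2pl():
    meta = ik.build_item_meta(
        [0.8, 1.1, 1.4, 0.9, 1.2, 1.6, 1.0, 1.3],
        [-1.2, -0.6, -0.2, 0.0, 0.3, 0.7, 1.1, 1.5],
        model="2PLM",
    )
    sim = _simulate(meta, 1500, seed=11)
    fit = ik.estimate_mmle_em(sim.data, "2PLM", 2, EMControl(D=D))
    return sim, fit


class TestEstimateMmleEm:
    def test_marginal_loglik_non_decreasing(self, small_2pl):
        _, fit = small_2pl
        assert np.min(np.diff(fit.loglik_history)) > -1e-8

    def test_recovers_2pl_parameters(self, small_2pl):
        sim, fit = small_2pl
        ta, tb, _ = param_arrays(sim.meta)
        ea, eb, _ = param_arrays(fit.est_meta)
        assert np.sqrt(np.mean((ea - ta) ** 2)) < 0.15
        assert np.sqrt(np.mean((eb - tb) ** 2)) < 0.12

    def test_information_criteria_consistency(self, small_2pl):
        _, fit = small_2pl
        assert fit.aic == pytest.approx(fit.neg2ll + 2 * fit.n_free_params)
        assert fit.bic == pytest.approx(
            fit.neg2ll + fit.n_free_params * np.log(fit.n_persons)
        )
        assert fit.neg2ll == pytest.approx(-2 * fit.loglik)

    def test_shared_1pl_discrimination(self):
        meta = ik.build_item_meta(
            np.full(6, 1.1), np.linspace(-1.5, 1.5, 6), model="1PLM"
        )
        sim = _simulate(meta, 1200, seed=5)
        fit = ik.estimate_mmle_em(sim.data, "1PLM", 2, EMControl(D=D))
        assert fit.est_meta["par.1"].nunique() == 1
        assert fit.est_meta["par.1"].iat[0] == pytest.approx(1.1, abs=0.15)
        # shared slope SE reported once, on the first row
        assert np.isfinite(fit.se_meta["par.1"].iat[0])
        assert fit.se_meta["par.1"].iloc[1:].isna().all()

    def test_fix_a_1pl_constrains_value(self):
        meta = ik.build_item_meta(
            np.full(5, 1.0), np.linspace(-1, 1, 5), model="1PLM"
        )
        sim = _simulate(meta, 600, seed=6)
        fit = ik.estimate_mmle_em(
            sim.data, "1PLM", 2, EMControl(D=D, fix_a_1pl=True, a_val_1pl=1.0)
        )
        assert (fit.est_meta["par.1"] == 1.0).all()
        assert fit.se_meta["par.1"].isna().all()
        assert fit.n_free_params == 5

    def test_fixed_g_has_no_standard_error(self, rng):
        meta = ik.build_item_meta(
            rng.uniform(0.8, 1.6, 6), rng.normal(0, 1, 6), np.full(6, 0.2),
            model="3PLM",
        )
        sim = _simulate(meta, 800, seed=7)
        fit = ik.estimate_mmle_em(
            sim.data, "3PLM", 2, EMControl(D=D, fix_g=True, g_val=0.2)
        )
        assert (fit.est_meta["par.3"] == 0.2).all()
        assert fit.se_meta["par.3"].isna().all()

    def test_rejects_bad_codes_and_empty_items(self):
        with pytest.raises(ValueError, match="0/1/missing"):
            ik.estimate_mmle_em(np.array([[0.0, 2.0]]), "2PLM")
        data = np.array([[0.0, np.nan], [1.0, np.nan], [1.0, np.nan]])
        with pytest.raises(ValueError, match="2"):
            ik.estimate_mmle_em(data, "2PLM")

    def test_emp_hist_keeps_unit_scale(self, simdat30):
        fit = ik.estimate_mmle_em(
            simdat30.data[:800], "3PLM", 2,
            EMControl(D=D, emp_hist=True, Etol=1e-3, fix_g=True, g_val=0.2),
        )
        assert abs(fit.latent.mu) < 1e-6
        assert abs(fit.latent.sigma2 - 1.0) < 1e-6
        assert len(fit.latent.nodes) == 49

    def test_standard_errors_match_monte_carlo_spread(self):
        # scaled-down Monte-Carlo check: the reported SE should match the
        # sampling SD of repeated estimates to within ~30%
        meta = ik.build_item_meta(
            [0.9, 1.2, 1.5, 1.0], [-0.8, -0.2, 0.4, 1.0], model="2PLM"
        )
        reps = []
        se0 = None
        for seed in range(20):
            sim = _simulate(meta, 2000, seed=100 + seed)
            fit = ik.estimate_mmle_em(sim.data, "2PLM", 2, EMControl(D=D))
            reps.append(param_arrays(fit.est_meta)[1])  # difficulties
            if se0 is None:
                se0 = fit.se_meta["par.2"].to_numpy()
        sd = np.std(np.array(reps), axis=0, ddof=1)
        ratio = sd / se0
        assert (ratio > 0.6).all() and (ratio < 1.55).all()


class TestExtract:
    def test_component_layouts(self, simdat30_3pl_fit):
        fit = simdat30_3pl_fit
        par = ik.extract(fit, "par.est")
        assert list(par.columns) == ["id", "cats", "model", "par.1", "par.2", "par.3"]
        assert par["id"].iat[0] == "V1"
        w = ik.extract(fit, "weights")
        assert list(w.columns) == ["theta", "weight"] and len(w) == 49
        assert ik.extract(fit, "loglik") == fit.loglik

    def test_unknown_key_lists_valid_ones(self, simdat30_3pl_fit):
        with pytest.raises(KeyError, match="par.est"):
            ik.extract(simdat30_3pl_fit, "bogus")


class TestFitIndices:
    def test_degenerate_no_parameters(self):
        neg2ll, aic, bic = ik.fit_indices(-100.0, 0, 50)
        assert neg2ll == aic == bic == 200.0

    def test_summary_text_contains_key_sections(self, simdat30_3pl_fit):
        text = simdat30_3pl_fit.summary()
        for token in (
            "Number of Items: 30", "Number of Cases: 2000",
            "Number of free parameters: 90", "-2loglikelihood",
            "Group Parameters",
        ):
            assert token in text


def test_response_matrix_validation_shapes():
    with pytest.raises(ValueError, match="2-D"):
        validate_response_matrix(np.zeros(5))
    arr = validate_response_matrix(pd.DataFrame([[0, 1], [1, np.nan]]))
    assert arr.shape == (2, 2)
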