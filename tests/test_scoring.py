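import itertools

import numpy as np
import pytest

import irtkit as ik
from irtkit.metadata import param_arrays
from irtkit.scoring import ScoreConfig, _tcc

D = 1.702


@pytest.fixture
def pattern_data(random_3pl_meta, rng):
    design = ik.SimDesign(
        n_persons=40, meta=random_3pl_meta, theta_dist=(0, 1), D=D, seed=21
    )
    return ik.simulate_responses(design).data


class TestLordWingersky:
    def test_single_item(self):
        meta = ik.build_item_meta([1.0], [0.0], model="2PLM")
        # P(theta=0) = 0.5 -> distribution (0.5, 0.5); shift b for 0.4
        m = ik.build_item_meta([1.0], [np.log(1.5)], model="2PLM")
        p = ik.prob_correct(0.0, m.iloc[0], 1.0)
        dist = ik.lord_wingersky(m, 0.0, 1.0)
        np.testing.assert_allclose(dist, [1 - p, p])

    def test_two_coin_items(self):
        meta = ik.build_item_meta([1.0, 1.0], [0.0, 0.0], model="2PLM")
        np.testing.assert_allclose(
            ik.lord_wingersky(meta, 0.0, 1.0), [0.25, 0.5, 0.25]
        )

    def test_matches_exhaustive_enumeration(self, random_3pl_meta):
        theta = 0.37
        dist = ik.lord_wingersky(random_3pl_meta, theta, D)
        a, b, g = param_arrays(random_3pl_meta)
        P = ik.three_pl_prob(theta, a, b, g, D)
        brute = np.zeros(13)
        for pattern in itertools.product((0, 1), repeat=12):
            x = np.array(pattern)
            brute[x.sum()] += np.prod(np.where(x, P, 1 - P))
        np.testing.assert_allclose(dist, brute, atol=1e-12)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestEapSum:
    def test_conversion_table_is_monotone(self, random_3pl_meta):
        _, table = ik.eap_sum(random_3pl_meta, [0], ScoreConfig(D=D))
        assert (np.diff(table["est.theta"]) > 0).all()

    def test_identical_scores_identical_estimates(self, random_3pl_meta):
        res, _ = ik.eap_sum(random_3pl_meta, [4, 4, 9, 4], ScoreConfig(D=D))
        assert res.est_theta[0] == res.est_theta[1] == res.est_theta[3]
        assert res.est_theta[2] > res.est_theta[0]

    def test_perfect_score_above_prior_mean(self):
        meta = ik.build_item_meta([1.2], [0.0], model="2PLM")
        res, _ = ik.eap_sum(meta, [1], ScoreConfig(D=D))
        assert res.est_theta[0] > 0.0

    def test_out_of_range_score_rejected(self, random_3pl_meta):
        with pytest.raises(ValueError, match="0..12"):
            ik.eap_sum(random_3pl_meta, [13], ScoreConfig(D=D))

    def test_agrees_with_direct_posterior_computation(self, random_3pl_meta):
        # independent oracle: posterior over a dense grid computed from
        # first principles for one summed score
        cfg = ScoreConfig(D=D, nquad=41)
        res, table = ik.eap_sum(random_3pl_meta, [5], cfg)
        nodes = np.linspace(-6, 6, 41)
        w = np.exp(-0.5 * nodes**2)
        like = np.array([ik.lord_wingersky(random_3pl_meta, t, D)[5] for t in nodes])
        post = w * like
        post /= post.sum()
        assert res.est_theta[0] == pytest.approx(post @ nodes, abs=1e-10)


class TestInvTcc:
    def test_forward_inverse_identity(self, random_3pl_meta):
        a, b, g = param_arrays(random_3pl_meta)
        s = _tcc(0.7, a, b, g, D)
        res = ik.inv_tcc_score(random_3pl_meta, [s], ScoreConfig(D=D))
        assert res.est_theta[0] == pytest.approx(0.7, abs=1e-6)

    def test_sub_guessing_score_clamps_to_lower_bound(self, random_3pl_meta):
        res = ik.inv_tcc_score(random_3pl_meta, [0], ScoreConfig(D=D))
        assert res.est_theta[0] == -5.0

    def test_matches_dense_grid_argmin(self, random_3pl_meta, rng):
        a, b, g = param_arrays(random_3pl_meta)
        grid = np.linspace(-5, 5, 20001)
        tcc = np.array([_tcc(t, a, b, g, D) for t in grid])
        for s in rng.uniform(tcc[0] + 0.5, tcc[-1] - 0.5, 5):
            res = ik.inv_tcc_score(random_3pl_meta, [s], ScoreConfig(D=D))
            oracle = grid[np.argmin(np.abs(tcc - s))]
            assert res.est_theta[0] == pytest.approx(oracle, abs=1e-3)


class TestEstScore:
    def test_eap_with_no_responses_returns_prior_moments(self, random_3pl_meta):
        res = ik.est_score(
            random_3pl_meta, np.full((1, 12), np.nan), ScoreConfig(method="EAP", D=D)
        )
        assert res.est_theta[0] == pytest.approx(0.0, abs=1e-9)
        assert res.se_theta[0] == pytest.approx(1.0, abs=1e-3)

    def test_ml_with_no_responses_is_missing(self, random_3pl_meta):
        res = ik.est_score(
            random_3pl_meta, np.full((1, 12), np.nan), ScoreConfig(method="ML", D=D)
        )
        assert np.isnan(res.est_theta[0]) and np.isnan(res.se_theta[0])

    def test_perfect_pattern_clamps_and_flags_under_ml(self, random_3pl_meta):
        res = ik.est_score(
            random_3pl_meta, np.ones((1, 12)), ScoreConfig(method="ML", D=D)
        )
        assert res.est_theta[0] == pytest.approx(5.0, abs=1e-6)
        assert res.flags == [0]

    def test_mlf_pulls_perfect_pattern_inward(self, random_3pl_meta):
        ml = ik.est_score(random_3pl_meta, np.ones((1, 12)), ScoreConfig(method="ML", D=D))
        mlf = ik.est_score(random_3pl_meta, np.ones((1, 12)), ScoreConfig(method="MLF", D=D))
        assert mlf.est_theta[0] < ml.est_theta[0]
        assert np.isfinite(mlf.se_theta[0])

    def test_map_converges_to_ml_for_flat_prior(self, random_3pl_meta, pattern_data):
        ml = ik.est_score(random_3pl_meta, pattern_data, ScoreConfig(method="ML", D=D))
        mp = ik.est_score(
            random_3pl_meta, pattern_data,
            ScoreConfig(method="MAP", norm_prior=(0.0, 1e3), D=D),
        )
        interior = ~np.isin(np.arange(len(ml.frame)), ml.flags)
        np.testing.assert_allclose(
            ml.est_theta[interior], mp.est_theta[interior], atol=1e-3
        )

    def test_wl_solves_weighted_score_equation(self, random_3pl_meta, pattern_data):
        from irtkit.scoring import _warm_terms

        res = ik.est_score(random_3pl_meta, pattern_data, ScoreConfig(method="WL", D=D))
        a, b, g = param_arrays(random_3pl_meta)
        for i in range(5):
            th = res.est_theta[i]
            if i in res.flags:
                continue
            x = pattern_data[i]
            P, Q, dP, d2P = _warm_terms(th, a, b, g, D)
            S = np.sum((x - P) * dP / (P * Q))
            info = np.sum(dP**2 / (P * Q))
            J = np.sum(dP * d2P / (P * Q))
            assert abs(S + J / (2 * info)) < 1e-8

    def test_eap_estimates_inside_quadrature_span(self, random_3pl_meta, pattern_data):
        cfg = ScoreConfig(method="EAP", D=D)
        res = ik.est_score(random_3pl_meta, pattern_data, cfg)
        assert (res.est_theta > -6).all() and (res.est_theta < 6).all()

    @pytest.mark.parametrize("method", ["ML", "EAP"])
    def test_monotone_in_nested_response_patterns(self, method):
        meta = ik.build_item_meta(
            [1.0, 1.2, 0.8, 1.5, 1.1], [-1.0, -0.5, 0.0, 0.5, 1.0], model="2PLM"
        )
        patterns = np.tril(np.ones((6, 5)))  # 0, 1, ..., 5 correct (nested)
        res = ik.est_score(meta, patterns, ScoreConfig(method=method, D=D))
        assert (np.diff(res.est_theta) >= -1e-9).all()

    def test_score_csv_round_trip(self, random_3pl_meta, pattern_data, tmp_path):
        res = ik.est_score(random_3pl_meta, pattern_data, ScoreConfig(method="EAP", D=D))
        path = tmp_path / "scores.csv"
        res.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == ["est.theta", "se.theta"]
        np.testing.assert_allclose(back["est.theta"], res.est_theta, rtol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScoreConfig(method="XXX")
        with pytest.raises(ValueError):
            ScoreConfig(range=(2.0, -2.0))
        with pytest.raises(ValueError):
            ScoreConfig(norm_prior=(0.0, 0.0))
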