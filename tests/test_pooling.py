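"""Fixed/random-effects pooling, heterogeneity statistics and funnel rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_pool
from thyrocv.errors import FunnelRuleError, PoolingError
from thyrocv.harmonization import HarmonizedEstimate
from thyrocv.pooling import (
    MetaAnalysis,
    cochran_q,
    dersimonian_laird,
    fixed_effect,
    funnel,
    i_squared,
    pool,
    random_effects,
)


def hzd(study_id, y, se):
    return HarmonizedEstimate(
        study_id=study_id, predictor="FT4_CONTINUOUS", log_hr=y, se_log_hr=se
    )


def make_set(ys, ses):
    return [hzd(f"s{i}", y, s) for i, (y, s) in enumerate(zip(ys, ses))]


class TestFixedEffect:
    def test_identical_effects_pool_to_themselves(self):
        mu, _ = fixed_effect([0.2, 0.2], [0.1, 0.3])
        assert mu == pytest.approx(0.2)

    def test_symmetric_weights(self):
        mu, se = fixed_effect([0.0, 1.0], [0.1, 0.1])
        assert mu == pytest.approx(0.5)
        assert se == pytest.approx(0.1 / math.sqrt(2))

    def test_inverse_variance_arithmetic(self):
        mu, _ = fixed_effect([0.0, 1.0], [0.1, 0.2])
        assert mu == pytest.approx((100 * 0.0 + 25 * 1.0) / 125)

    def test_single_study_rejected(self):
        with pytest.raises(PoolingError, match="two studies"):
            fixed_effect([0.2], [0.1])


class TestHeterogeneity:
    def test_no_dispersion_gives_zero_q(self):
        q, df, p = cochran_q([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_study_closed_form(self):
        y, se = [0.1, 0.7], [0.15, 0.25]
        w1, w2 = 1 / 0.15**2, 1 / 0.25**2
        q, df, _ = cochran_q(y, se)
        assert df == 1
        assert q == pytest.approx(w1 * w2 / (w1 + w2) * (0.1 - 0.7) ** 2)

    def test_q_p_value_is_chi_square_tail(self):
        from scipy.stats import chi2

        # a 5-study set engineered to have Q = 16 on df = 4: equal SEs 1
        # and effects at mean 0 with sum of squares 16
        y = [2.0, -2.0, 2.0, -2.0, 0.0]
        q, df, p = cochran_q(y, [1.0] * 5)
        assert (q, df) == (pytest.approx(16.0), 4)
        assert p == pytest.approx(chi2.sf(16.0, 4))

    def test_dl_truncates_at_zero(self):
        assert dersimonian_laird([0.3, 0.31], [0.2, 0.2]) == 0.0

    def test_dl_two_study_equal_se_closed_form(self):
        y, s = [0.1, 0.9], 0.2
        expected = max(0.0, (y[0] - y[1]) ** 2 / 2 - s**2)
        assert dersimonian_laird(y, [s, s]) == pytest.approx(expected)

    def test_dl_recovers_tau_in_large_k_simulation(self):
        """Mean DL estimate over 2,000 replicates at k=200 and true
        tau=0.3 sits within Monte-Carlo error of 0.09."""
        vals = []
        for i in range(2000):
            rng = np.random.default_rng(i)
            se = rng.uniform(0.1, 0.3, 200)
            y = rng.normal(0.3, np.sqrt(0.09 + se**2))
            vals.append(dersimonian_laird(y, se))
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - 0.09) < 3 * mc_se

    @pytest.mark.parametrize(
        "q, df, expected",
        [(4.0, 4, 0.0), (16.0, 4, 75.0), (2.0, 4, 0.0), (0.0, 3, 0.0)],
    )
    def test_i_squared_algebra(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)


class TestRandomEffects:
    def test_zero_tau2_equals_fixed_effect(self):
        y, se = [0.1, 0.5, 0.3], [0.1, 0.2, 0.15]
        assert random_effects(y, se, 0.0) == pytest.approx(fixed_effect(y, se))

    def test_infinite_tau2_limit_is_unweighted_mean(self):
        y, se = [0.0, 1.0, 0.2], [0.1, 0.3, 0.2]
        mu, _ = random_effects(y, se, 1e6)
        assert mu == pytest.approx(np.mean(y), abs=1e-3)

    def test_hand_computed_two_study_value(self):
        y, se, tau2 = [0.0, 1.0], [0.1, 0.2], 0.05
        w = [1 / (0.1**2 + tau2), 1 / (0.2**2 + tau2)]
        mu, _ = random_effects(y, se, tau2)
        assert mu == pytest.approx(w[1] / (w[0] + w[1]))


class TestPoolOracle:
    def test_matches_brute_force_on_random_instances(self):
        """200 random meta-analyses with k in 2..8 agree with the
        independent loop-based evaluation to 1e-10 on every field."""
        rng = np.random.default_rng(12345)
        for _ in range(200):
            k = int(rng.integers(2, 9))
            y = rng.normal(0.2, 0.5, k)
            se = rng.uniform(0.05, 0.5, k)
            res = pool(make_set(y, se))
            ora = brute_force_pool(list(y), list(se))
            for field in ("mu_fe", "se_fe", "Q", "tau2", "i2", "mu_re", "se_re"):
                assert getattr(res, field if field != "Q" else "Q") == pytest.approx(
                    ora[field], abs=1e-10
                ), field
            assert res.df == ora["df"] and res.k == ora["k"]
            np.testing.assert_allclose(res.weights_fe, ora["weights_fe"], atol=1e-10)
            np.testing.assert_allclose(res.weights_re, ora["weights_re"], atol=1e-10)

    def test_matches_statsmodels_combine_effects(self):
        """Independent library cross-check of the DL pipeline."""
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(7)
        y = rng.normal(0.3, 0.4, 6)
        se = rng.uniform(0.1, 0.4, 6)
        res = pool(make_set(y, se))
        sm = combine_effects(y, se**2, method_re="dl")
        assert res.tau2 == pytest.approx(sm.tau2, abs=1e-10)
        frame = sm.summary_frame()
        assert res.mu_fe == pytest.approx(frame.loc["fixed effect", "eff"])
        assert res.mu_re == pytest.approx(frame.loc["random effect", "eff"])

    def test_single_study_and_duplicate_study_rejected(self):
        with pytest.raises(PoolingError):
            pool([hzd("a", 0.2, 0.1)])
        with pytest.raises(PoolingError, match="dup"):
            pool([hzd("dup", 0.2, 0.1), hzd("dup", 0.3, 0.2)])

    def test_identical_estimates_are_degenerate_fixture(self):
        res = pool(make_set([0.4] * 4, [0.2] * 4))
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.mu_fe == pytest.approx(0.4)
        assert res.mu_re == pytest.approx(0.4)
        assert res.se_re == pytest.approx(res.se_fe)

    def test_preference_rule_follows_i2_cutoff(self):
        hom = pool(make_set([0.2, 0.21, 0.19], [0.1, 0.1, 0.1]))
        assert hom.preferred_model == "fixed"
        het = pool(make_set([2.0, -2.0, 2.0, -2.0, 0.0], [1.0] * 5))
        assert het.i2 == pytest.approx(75.0)
        assert het.preferred_model == "random"


class TestPoolingProperties:
    @settings(max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-1, 1), st.floats(0.05, 0.5)),
            min_size=2, max_size=8,
        ),
        c=st.floats(-2, 2),
    )
    def test_shift_equivariance(self, data, c):
        y = [d[0] for d in data]
        se = [d[1] for d in data]
        base = pool(make_set(y, se))
        shifted = pool(make_set([v + c for v in y], se))
        assert shifted.mu_fe == pytest.approx(base.mu_fe + c, abs=1e-9)
        assert shifted.mu_re == pytest.approx(base.mu_re + c, abs=1e-9)
        assert shifted.Q == pytest.approx(base.Q, abs=1e-8)
        assert shifted.tau2 == pytest.approx(base.tau2, abs=1e-9)
        assert shifted.i2 == pytest.approx(base.i2, abs=1e-6)

    @settings(max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-1, 1), st.floats(0.05, 0.5)),
            min_size=2, max_size=6,
        ),
        seed=st.integers(0, 1000),
    )
    def test_permutation_invariance(self, data, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(data))
        base = pool(make_set([d[0] for d in data], [d[1] for d in data]))
        permuted = pool(
            make_set([data[i][0] for i in perm], [data[i][1] for i in perm])
        )
        for field in ("mu_fe", "se_fe", "mu_re", "se_re", "Q", "tau2", "i2"):
            assert getattr(permuted, field) == pytest.approx(
                getattr(base, field), abs=1e-10
            )

    @settings(max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-1, 1), st.floats(0.05, 0.5)),
            min_size=2, max_size=6,
        ),
        factor=st.floats(1.0, 5.0),
    )
    def test_se_inflation_never_shrinks_pooled_se(self, data, factor):
        y = [d[0] for d in data]
        se = [d[1] for d in data]
        _, se_base = fixed_effect(y, se)
        _, se_wide = fixed_effect(y, [s * factor for s in se])
        assert se_wide >= se_base - 1e-12

    def test_pooled_mean_bounded_by_extremes(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 7)
        se = rng.uniform(0.05, 0.4, 7)
        res = pool(make_set(y, se))
        assert min(y) <= res.mu_fe <= max(y)
        assert min(y) <= res.mu_re <= max(y)
        assert np.sum(res.weights_fe) == pytest.approx(1.0)
        assert np.sum(res.weights_re) == pytest.approx(1.0)


class TestMetaAnalysisEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        m = MetaAnalysis(i2_preference_cutoff=40.0)
        params = m.get_params()
        assert params["i2_preference_cutoff"] == 40.0
        m2 = clone(m).set_params(knapp_hartung=True)
        assert m2.get_params()["knapp_hartung"] is True

    def test_fitted_attributes_present(self):
        m = MetaAnalysis().fit([0.1, 0.5, 0.3], [0.1, 0.2, 0.15])
        for attr in ("mu_fe_", "mu_re_", "tau2_", "Q_", "i2_", "ci_re_", "p_re_"):
            assert hasattr(m, attr)

    def test_knapp_hartung_widens_small_sample_interval(self):
        y, se = [0.0, 0.5, 0.9, 0.2], [0.1, 0.15, 0.2, 0.12]
        plain = MetaAnalysis().fit(y, se)
        kh = MetaAnalysis(knapp_hartung=True).fit(y, se)
        assert kh.ci_re_[1] - kh.ci_re_[0] > plain.ci_re_[1] - plain.ci_re_[0]


class TestFunnel:
    def test_refused_below_five_studies(self):
        ests = make_set([0.1, 0.2, 0.3, 0.4], [0.1] * 4)
        res = pool(ests)
        with pytest.raises(FunnelRuleError, match="five or more"):
            funnel(ests, res)

    def test_five_study_contour_symmetric_about_center(self):
        ests = make_set([0.1, 0.2, 0.3, 0.4, 0.5], [0.1, 0.2, 0.15, 0.12, 0.3])
        res = pool(ests)
        fd = funnel(ests, res)
        assert len(fd.points) == 5
        np.testing.assert_allclose(
            fd.contour_upper - res.mu_fe, res.mu_fe - fd.contour_lower, atol=1e-12
        )

    def test_equal_ses_give_degenerate_point_cloud_width(self):
        ests = make_set([0.1, 0.2, 0.3, 0.4, 0.5], [0.2] * 5)
        fd = funnel(ests, pool(ests))
        assert {se for _, se in fd.points} == {0.2}
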