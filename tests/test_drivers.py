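"""Poisson background models, exact Poisson test, BH, and driver calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apohm.drivers import (
    IN_LOOP,
    OUTSIDE_LOOP,
    PoissonBackgroundModel,
    _fit_glm,
    _loo_lambdas_exact,
    _loo_lambdas_onestep,
    bh_adjust,
    call_drivers,
    exact_poisson_test,
    fit_background,
    mcfadden_r2,
)


def pmf_sum_sf(n_obs, lam, k_max=400):
    """Direct pmf summation oracle for the upper-tail Poisson probability."""
    total = 0.0
    for k in range(n_obs):
        total += math.exp(-lam) * lam**k / math.factorial(k)
    return 1.0 - total


class TestExactPoissonTest:
    def test_zero_observations_certain(self):
        assert exact_poisson_test(0, 2.5) == 1.0

    def test_direct_summation_examples(self):
        assert exact_poisson_test(5, 0.5) == pytest.approx(1.7216e-4, rel=1e-3)
        assert exact_poisson_test(2, 2.0) == pytest.approx(1 - 3 * math.exp(-2), abs=1e-12)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            exact_poisson_test(3, 0.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(0, 30), lam=st.floats(0.05, 15))
    def test_matches_pmf_summation(self, n, lam):
        assert exact_poisson_test(n, lam) == pytest.approx(pmf_sum_sf(n, lam), abs=1e-12)

    def test_monotone_in_n_and_lambda(self):
        lams = np.linspace(0.2, 8, 12)
        for lam in lams:
            p = exact_poisson_test(np.arange(0, 20), lam)
            assert np.all(np.diff(p) < 0)
        for n in range(1, 15):
            p = exact_poisson_test(n, lams)
            assert np.all(np.diff(p) > 0)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_calculation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_clamped_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert np.all(adj <= 1) and np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= 0)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(60):
            p = rng.random(rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_per_group_correction(self):
        p = np.array([0.01, 0.02, 0.04, 0.01, 0.02, 0.04])
        g = np.array(["a"] * 3 + ["b"] * 3)
        np.testing.assert_allclose(bh_adjust(p, groups=g), [0.03, 0.03, 0.04] * 2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def synthetic_catalog(
    n,
    rng,
    in_loop=True,
    context="TCA",
    beta=None,
    lam=2.0,
):
    decile = rng.integers(1, 11, size=n)
    delta_g = -(0.5 + rng.exponential(1.5, size=n))
    pattern = rng.random(n) < 0.3
    if beta is None:
        mu = np.full(n, lam)
    else:
        eta = beta[0] + beta[1] * decile + beta[2] * delta_g + beta[3] * pattern
        mu = np.exp(eta)
    counts = rng.poisson(mu)
    group = "TpC" if context.startswith("TC") else context
    return pd.DataFrame(
        {
            "chrom": "sim",
            "pos": np.arange(1, n + 1),
            "n_mut": counts,
            "trinucleotide": context,
            "context_group": group,
            "in_loop": in_loop,
            "delta_g": delta_g,
            "loop_pattern": pattern,
            "accessibility_decile": decile,
        }
    )


class TestFitBackground:
    def test_constant_counts_intercept_only(self):
        rng = np.random.default_rng(1)
        cat = synthetic_catalog(30, rng, in_loop=False)
        cat["n_mut"] = 2
        cat["accessibility_decile"] = 5  # single covariate level
        model = fit_background(cat, cat.index[0], OUTSIDE_LOOP)
        assert model.intercept_only
        assert model.predict(cat.iloc[0]) == pytest.approx(2.0)

    def test_focal_site_excluded(self):
        rng = np.random.default_rng(2)
        cat = synthetic_catalog(20, rng, in_loop=False)
        cat["n_mut"] = 2
        cat["accessibility_decile"] = 5
        cat.loc[cat.index[0], "n_mut"] = 50  # outlier must not inflate its own background
        model = fit_background(cat, cat.index[0], OUTSIDE_LOOP)
        assert model.predict(cat.iloc[0]) == pytest.approx(2.0)
        assert model.n_background == 19

    def test_thin_stratum_falls_back(self):
        rng = np.random.default_rng(3)
        main = synthetic_catalog(30, rng, in_loop=False, context="TCA")
        rare = synthetic_catalog(2, rng, in_loop=False, context="TCG")
        rare.index = range(100, 102)
        cat = pd.concat([main, rare])
        model = fit_background(cat, 100, OUTSIDE_LOOP)
        assert model.fallback
        assert model.stratum == "pooled"
        assert model.n_background == 31

    def test_parameter_recovery_small(self):
        """Smoke-scale parameter recovery (acceptance runs the 5,000-site version)."""
        rng = np.random.default_rng(8)
        beta = np.array([0.6, 0.06, -0.12, 0.25])
        cat = synthetic_catalog(1200, rng, beta=beta)
        model = fit_background(cat, cat.index[0], IN_LOOP)
        assert model.covariates == ("const", "accessibility_decile", "delta_g", "loop_pattern")
        np.testing.assert_allclose(model.coefficients, beta, atol=0.25)


class TestLeaveOneOut:
    def test_onestep_matches_exact_refit(self):
        rng = np.random.default_rng(5)
        cat = synthetic_catalog(250, rng, beta=np.array([0.5, 0.05, -0.1, 0.2]))
        cov = ("const", "accessibility_decile", "delta_g", "loop_pattern")
        exact = _loo_lambdas_exact(cat, cov)
        onestep = _loo_lambdas_onestep(cat, cov)
        np.testing.assert_allclose(onestep, exact, rtol=5e-3)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(6)
        cat = synthetic_catalog(50, rng)
        cat["accessibility_decile"] = 3
        cat["delta_g"] = -2.0
        cat["loop_pattern"] = False
        cov = ("const", "accessibility_decile", "delta_g", "loop_pattern")
        y = cat["n_mut"].to_numpy(float)
        expected = (y.sum() - y) / (len(y) - 1)
        np.testing.assert_allclose(_loo_lambdas_onestep(cat, cov), expected, atol=1e-12)


class TestCallDrivers:
    def test_non_tpc_outside_loops_never_tested(self):
        rng = np.random.default_rng(7)
        tpc = synthetic_catalog(40, rng, in_loop=False, context="TCA")
        apc = synthetic_catalog(40, rng, in_loop=False, context="ApC")
        apc.index = range(1000, 1040)
        calls = call_drivers(pd.concat([tpc, apc]))
        assert set(calls.index) <= set(tpc.index)

    def test_spiked_site_called_driver(self):
        rng = np.random.default_rng(9)
        cat = synthetic_catalog(400, rng, in_loop=False, lam=2.2)
        cat.loc[cat.index[0], "n_mut"] = 20
        calls = call_drivers(cat)
        assert bool(calls.loc[cat.index[0], "is_driver"])

    def test_row_order_invariance(self):
        rng = np.random.default_rng(10)
        cat = pd.concat(
            [
                synthetic_catalog(60, rng, in_loop=False, context="TCA"),
                synthetic_catalog(60, rng, in_loop=True, context="ApC").set_index(
                    pd.RangeIndex(500, 560)
                ),
            ]
        )
        calls1 = call_drivers(cat)
        shuffled = cat.sample(frac=1, random_state=1)
        calls2 = call_drivers(shuffled).sort_index()
        pd.testing.assert_frame_equal(calls1.sort_index(), calls2)

    def test_empty_group_ok(self):
        rng = np.random.default_rng(11)
        cat = synthetic_catalog(30, rng, in_loop=False)
        calls = call_drivers(cat)  # no in-loop sites at all
        assert (calls["group"] == OUTSIDE_LOOP).all()

    def test_adjusted_ge_raw(self):
        rng = np.random.default_rng(12)
        cat = synthetic_catalog(100, rng, in_loop=True)
        calls = call_drivers(cat)
        assert (calls["adj_p"] >= calls["p"] - 1e-15).all()


class TestMcFaddenR2:
    def test_null_model_is_zero(self):
        assert mcfadden_r2(-100.0, -100.0) == 0.0

    def test_informative_covariate_increases_r2(self):
        rng = np.random.default_rng(13)
        cat = synthetic_catalog(800, rng, beta=np.array([0.3, 0.15, 0.0, 0.0]))
        cov_full = ("const", "accessibility_decile")
        from apohm.drivers import _design

        y = cat["n_mut"].to_numpy(float)
        _, _, llf_full, _ = _fit_glm(y, _design(cat, cov_full), cov_full)
        _, _, llf_null, _ = _fit_glm(y, _design(cat, ("const",)), ("const",))
        r2 = mcfadden_r2(llf_full, llf_null)
        assert r2 > 0

    def test_matches_independent_loglik(self):
        """R2 agrees with an independently coded Poisson log-likelihood."""
        from apohm.drivers import _design

        rng = np.random.default_rng(14)
        cat = synthetic_catalog(500, rng, beta=np.array([0.4, 0.1, -0.1, 0.3]))
        y = cat["n_mut"].to_numpy(float)
        cov = ("const", "accessibility_decile", "delta_g", "loop_pattern")
        beta, names, llf, _ = _fit_glm(y, _design(cat, cov), cov)
        beta0, _, llf0, _ = _fit_glm(y, _design(cat, ("const",)), ("const",))

        def loglik(mu):
            return float(np.sum(-mu + y * np.log(mu) - [math.lgamma(v + 1) for v in y]))

        mu_full = np.exp(_design(cat, names) @ beta)
        mu_null = np.full(len(y), y.mean())
        expected = 1 - loglik(mu_full) / loglik(mu_null)
        assert mcfadden_r2(llf, llf0) == pytest.approx(expected, abs=1e-10)

    def test_zero_null_loglik_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_r2(-1.0, 0.0)
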