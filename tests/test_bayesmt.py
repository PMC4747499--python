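"""Tests of the spike-and-slab multiple-testing machinery.

Closed-form results are cross-checked against independent oracles: direct
density evaluation, numeric integration of the slab marginal, and a plain
grid search over the hyperparameter surface.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from ctbayes.bayesmt import (
    GibbsPrior,
    HyperParams,
    decide,
    fit_two_groups_eb,
    fit_two_groups_gibbs,
    group_statistics,
    posterior_null,
)
from ctbayes.errors import InputError


def simulate_z(m, pi0, tau, seed):
    rng = np.random.default_rng(seed)
    null = rng.random(m) < pi0
    mu = np.where(null, 0.0, rng.normal(0.0, tau, m))
    return mu + rng.normal(size=m), null


# ---------------------------------------------------------------------------
# statistics


class TestGroupStatistics:
    def _frame(self, a_vals, b_vals):
        expr = pd.DataFrame({"G": a_vals + b_vals},
                            index=[f"s{i}" for i in range(len(a_vals) + len(b_vals))])
        samples = pd.DataFrame(
            {
                "age_years": [10.0] * len(expr),
                "age_group": ["child"] * len(expr),
                "status": ["CD"] * len(a_vals) + ["control"] * len(b_vals),
            },
            index=expr.index,
        )
        return expr, samples

    def test_difference_of_means(self):
        expr, samples = self._frame([4.0, 5.0, 6.0], [7.0, 8.0, 9.0])
        st = group_statistics(expr, samples, {"status": "CD"}, {"status": "control"})
        assert st.at["G", "t"] == pytest.approx(-3.0)

    def test_welch_se_and_z(self):
        # var 1 in both groups of 3: se = sqrt(1/3 + 1/3)
        expr, samples = self._frame([4.0, 5.0, 6.0], [7.0, 8.0, 9.0])
        st = group_statistics(expr, samples, {"status": "CD"}, {"status": "control"})
        assert st.at["G", "se"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert st.at["G", "z"] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert st.at["G", "z"] == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups_zero(self):
        expr, samples = self._frame([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        st = group_statistics(expr, samples, {"status": "CD"}, {"status": "control"})
        assert st.at["G", "t"] == 0.0
        assert st.at["G", "z"] == 0.0

    def test_empty_selector_rejected(self):
        expr, samples = self._frame([4.0, 5.0], [6.0, 7.0])
        with pytest.raises(InputError, match="matches no samples"):
            group_statistics(expr, samples, {"status": "CD", "age_group": "adult"},
                             {"status": "control"})

    def test_underpowered_gene_flagged_not_dropped(self):
        expr, samples = self._frame([4.0, 5.0, np.nan], [7.0, 8.0, 9.0])
        st = group_statistics(expr, samples, {"status": "CD"}, {"status": "control"},
                              min_per_group=3)
        assert "G" in st.index
        assert not st.at["G", "eligible"]
        assert st.at["G", "n_a"] == 2

    def test_detected_samples_only(self):
        expr, samples = self._frame([4.0, 6.0, np.nan], [7.0, 9.0, np.nan])
        st = group_statistics(expr, samples, {"status": "CD"}, {"status": "control"},
                              min_per_group=2)
        assert st.at["G", "t"] == pytest.approx(5.0 - 8.0)
        assert st.at["G", "n_a"] == 2 and st.at["G", "n_b"] == 2


# ---------------------------------------------------------------------------
# empirical Bayes


class TestFitEB:
    def test_all_zero_z_gives_pure_null(self):
        h = fit_two_groups_eb(np.zeros(50))
        assert h.pi0 == pytest.approx(1.0)

    def test_too_few_genes(self):
        with pytest.raises(InputError, match=">= 5"):
            fit_two_groups_eb(np.array([0.1, 0.2, 0.3, 0.4]))

    def test_grid_search_oracle(self):
        z = np.array([-3.2, -1.1, -0.4, 0.0, 0.2, 0.5, 0.9, 1.4, 2.1, 2.8, 4.0, -2.5])
        h = fit_two_groups_eb(z)

        # independent oracle: dense grid over the penalized objective
        pi0_grid = np.linspace(0.01, 1.0, 200)
        tau2_grid = np.linspace(0.0, 25.0, 200)
        best = (None, None, np.inf)
        for pi0 in pi0_grid:
            for tau2 in tau2_grid:
                dens = pi0 * stats.norm.pdf(z, 0, 1) + (1 - pi0) * stats.norm.pdf(
                    z, 0, np.sqrt(1 + tau2)
                )
                nll = -np.sum(np.log(dens)) - np.log(pi0)
                if nll < best[2]:
                    best = (pi0, tau2, nll)
        d_pi0 = pi0_grid[1] - pi0_grid[0]
        d_tau2 = tau2_grid[1] - tau2_grid[0]
        assert abs(h.pi0 - best[0]) <= d_pi0
        assert abs(h.tau2 - best[1]) <= d_tau2

    def test_parameter_recovery_smoke(self):
        # the full 20-replicate criterion lives in test_acceptance
        z, _ = simulate_z(2000, 0.8, 3.0, seed=0)
        h = fit_two_groups_eb(z)
        assert abs(h.pi0 - 0.8) <= 0.05
        assert abs(h.tau2 - 9.0) <= 2.0

    def test_accepts_statistic_table(self):
        z, _ = simulate_z(500, 0.8, 3.0, seed=1)
        table = pd.DataFrame({"z": z, "eligible": True})
        table.loc[table.index[:5], "eligible"] = False
        h1 = fit_two_groups_eb(table)
        h2 = fit_two_groups_eb(z[5:])
        assert h1.pi0 == pytest.approx(h2.pi0)


# ---------------------------------------------------------------------------
# Gibbs


class TestGibbs:
    def test_degenerate_prior_all_null(self):
        z, _ = simulate_z(100, 0.5, 3.0, seed=2)
        res = fit_two_groups_gibbs(z, prior=GibbsPrior(pi0_fixed=1.0),
                                   n_iter=200, burn_in=50, seed=0)
        assert (res.p_null == 1.0).all()

    def test_seeded_determinism(self):
        z, _ = simulate_z(200, 0.8, 3.0, seed=3)
        r1 = fit_two_groups_gibbs(z, n_iter=300, burn_in=100, seed=11)
        r2 = fit_two_groups_gibbs(z, n_iter=300, burn_in=100, seed=11)
        np.testing.assert_array_equal(r1.chains["pi0"], r2.chains["pi0"])
        np.testing.assert_array_equal(r1.chains["tau2"], r2.chains["tau2"])
        pd.testing.assert_series_equal(r1.p_null, r2.p_null)

    def test_recovery_and_eb_agreement(self):
        z, _ = simulate_z(2000, 0.8, 3.0, seed=4)
        gibbs = fit_two_groups_gibbs(z, n_iter=1200, burn_in=300, seed=0)
        eb = fit_two_groups_eb(z)
        assert abs(gibbs.hyper.pi0 - 0.8) <= 0.05
        assert abs(gibbs.hyper.pi0 - eb.pi0) <= 0.05

    def test_bad_iteration_counts(self):
        with pytest.raises(InputError):
            fit_two_groups_gibbs(np.zeros(10), n_iter=0)
        with pytest.raises(InputError):
            fit_two_groups_gibbs(np.zeros(10), n_iter=100, burn_in=100)


# ---------------------------------------------------------------------------
# posterior and decision


class TestPosteriorNull:
    def test_pure_null_prior(self):
        p = posterior_null(np.array([0.0, 1.0, -4.0]), HyperParams(1.0, 5.0))
        assert (p["p_null"] == 1.0).all()

    def test_zero_slab_variance(self):
        p = posterior_null(np.array([0.0, 2.0, -3.0]), HyperParams(0.7, 0.0))
        assert np.allclose(p["p_null"], 0.7)

    def test_closed_form_two_thirds(self):
        p = posterior_null(np.array([0.0]), HyperParams(0.5, 3.0))
        assert p["p_null"].iloc[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_monotone_decreasing_in_abs_z(self):
        z = np.linspace(0, 6, 50)
        p = posterior_null(z, HyperParams(0.8, 4.0))["p_null"].to_numpy()
        assert (np.diff(p) < 0).all()
        p_neg = posterior_null(-z, HyperParams(0.8, 4.0))["p_null"].to_numpy()
        np.testing.assert_allclose(p, p_neg, atol=1e-12)

    def test_complement_sums_to_one(self):
        z, _ = simulate_z(100, 0.6, 2.0, seed=5)
        p = posterior_null(z, HyperParams(0.6, 4.0))
        np.testing.assert_array_equal(p["p_null"] + p["p_alt"], 1.0)

    def test_numeric_integration_oracle_sample(self):
        # 50 triples here; the 1,000-triple criterion runs in test_acceptance
        rng = np.random.default_rng(6)
        for _ in range(50):
            z = float(rng.uniform(-6, 6))
            pi0 = float(rng.uniform(0.05, 0.99))
            tau2 = float(rng.uniform(0.05, 30.0))
            tau = np.sqrt(tau2)
            lim = max(abs(z), 10.0 * tau) + 12.0
            inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
            slab, _ = integrate.quad(
                lambda mu: (inv_sqrt2pi * np.exp(-0.5 * (z - mu) ** 2)
                            * inv_sqrt2pi / tau * np.exp(-0.5 * (mu / tau) ** 2)),
                -lim, lim, points=[0.0, z], epsabs=0.0, epsrel=1e-10, limit=200,
            )
            expected = pi0 * stats.norm.pdf(z) / (
                pi0 * stats.norm.pdf(z) + (1 - pi0) * slab
            )
            got = posterior_null(np.array([z]), HyperParams(pi0, tau2))["p_null"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-8)

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValueError):
            HyperParams(0.5, -1.0)

    def test_ineligible_gene_nan(self):
        table = pd.DataFrame({"z": [0.0, 2.0], "eligible": [True, False]})
        p = posterior_null(table, HyperParams(0.8, 4.0))
        assert np.isfinite(p["p_null"].iloc[0])
        assert np.isnan(p["p_null"].iloc[1])


class TestDecide:
    def _post(self, p_alt):
        return pd.DataFrame({"p_null": 1 - np.asarray(p_alt),
                             "p_alt": np.asarray(p_alt)})

    def test_boundary_not_rejected(self):
        dec = decide(self._post([0.50]))
        assert not dec["reject"].iloc[0]

    def test_above_half_rejected(self):
        dec = decide(self._post([0.73]))
        assert dec["reject"].iloc[0]

    def test_asymmetric_costs_threshold(self):
        dec = decide(self._post([0.3]), c_fp=3.0, c_fn=1.0)
        assert dec["threshold"].iloc[0] == pytest.approx(0.25)
        assert dec["reject"].iloc[0]

    def test_invalid_costs(self):
        with pytest.raises(InputError):
            decide(self._post([0.5]), c_fp=0.0)

    def test_bayes_fdr_is_mean_p_null_of_rejections(self):
        dec = decide(self._post([0.9, 0.8, 0.2]))
        assert dec.attrs["bayes_fdr"] == pytest.approx(np.mean([0.1, 0.2]))


class TestPowerAgainstBH:
    def test_posterior_rule_dominates_bh(self):
        z, null = simulate_z(2000, 0.8, 3.0, seed=1)
        h = fit_two_groups_eb(z)
        dec = decide(posterior_null(z, h))
        tp_bayes = int((dec["reject"].to_numpy() & ~null).sum())
        pvals = 2 * stats.norm.sf(np.abs(z))
        rej_bh = multipletests(pvals, alpha=0.05, method="fdr_bh")[0]
        tp_bh = int((rej_bh & ~null).sum())
        assert tp_bayes >= tp_bh
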