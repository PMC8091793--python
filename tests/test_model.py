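"""NB regression fitting, LRT, fold-change sampling, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from sitemut import (
    CohortTabulator,
    bh_fdr,
    estimate_fold_change,
    fit_nb,
    lrt,
    rm2_test,
)
from sitemut import test_cofactor_interaction as cofactor_interaction

from sitemut.model import FittedNB
from sitemut.mutations import subset_mask

import oracles


def synthetic_nb_table(seed, coef_site=np.log(1.5), theta=10.0, n_classes=8,
                       n_bins=10, exposure=30_000, slope=0.8):
    """Counts drawn from a known NB model on a table-shaped design."""
    rng = np.random.default_rng(seed)
    rows = []
    class_effects = rng.normal(-8.0, 0.4, size=n_classes)
    rates = np.linspace(50, 800, n_bins)
    for b in range(1, n_bins + 1):
        for s in (0, 1):
            for k in range(n_classes):
                npos = exposure + int(rng.integers(0, 5000))
                eta = (
                    np.log(npos)
                    + class_effects[k]
                    + slope * np.log1p(rates[b - 1])
                    + coef_site * s
                )
                mu = np.exp(eta)
                y = rng.negative_binomial(theta, theta / (theta + mu))
                rows.append((b, s, 0, k, int(y), npos, rates[b - 1]))
    return pd.DataFrame(
        rows, columns=["bin", "is_site", "cofac", "class_id", "n_mut", "n_posits", "mbp_rate"]
    )


class TestFitNB:
    def test_wald_coverage_of_known_site_effect(self):
        """Known-model recovery: the true coefficient should fall inside the
        95% Wald interval in ~95% of replicates (require >= 90/100)."""
        true = np.log(1.5)
        hits = 0
        for seed in range(100):
            t = synthetic_nb_table(seed)
            f = fit_nb(t, include_site=True)
            se = f.dense_se["is_site"]
            hits += int(abs(f.coef("is_site") - true) < 1.96 * se)
        assert hits >= 90

    def test_null_construction_gives_tiny_site_coef(self):
        t = synthetic_nb_table(5, coef_site=0.0, theta=1e9, exposure=3_000_000)
        f = fit_nb(t, include_site=True)
        assert abs(f.coef("is_site")) < 0.01

    def test_offset_identity(self):
        t = synthetic_nb_table(3)
        f1 = fit_nb(t, include_site=True)
        t2 = t.assign(n_posits=t["n_posits"] * 2)
        f2 = fit_nb(t2, include_site=True)
        c1, c2 = f1.coefficients, f2.coefficients
        assert c2["intercept"] - c1["intercept"] == pytest.approx(-np.log(2), abs=1e-6)
        for k in c1:
            if k != "intercept":
                assert c2[k] == pytest.approx(c1[k], abs=1e-6)

    def test_matches_statsmodels_glm_at_fitted_dispersion(self):
        """Dual-route check: IRLS coefficients equal a statsmodels GLM fit at
        the same dispersion, and the dispersion is the likelihood argmax."""
        import statsmodels.api as sm

        t = synthetic_nb_table(11, theta=12.0)
        f = fit_nb(t, include_site=True)
        assert f.alpha > 0
        X = pd.get_dummies(t["class_id"], prefix="c", dtype=float)
        X["mbp"] = np.log1p(t["mbp_rate"])
        X["site"] = t["is_site"].astype(float)
        glm = sm.GLM(
            t["n_mut"].to_numpy(float), X,
            family=sm.families.NegativeBinomial(alpha=f.alpha),
            offset=np.log(t["n_posits"].to_numpy(float)),
        ).fit()
        assert glm.params["site"] == pytest.approx(f.coef("is_site"), abs=1e-6)
        assert glm.params["mbp"] == pytest.approx(f.coef("log1p_mbp_rate"), abs=1e-6)
        # profile likelihood peaks at our alpha
        def ll_at(alpha):
            r = sm.GLM(
                t["n_mut"].to_numpy(float), X,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(t["n_posits"].to_numpy(float)),
            ).fit()
            return r.llf

        assert ll_at(f.alpha) >= ll_at(f.alpha * 1.5) - 1e-6
        assert ll_at(f.alpha) >= ll_at(f.alpha / 1.5) - 1e-6

    def test_poisson_data_snaps_to_poisson(self):
        rng = np.random.default_rng(0)
        t = synthetic_nb_table(7, theta=1e12)
        f = fit_nb(t, include_site=True)
        assert f.alpha == 0.0 and np.isinf(f.theta) and f.converged

    def test_interaction_requires_cofactor(self):
        t = synthetic_nb_table(1)
        with pytest.raises(ValueError):
            fit_nb(t, include_site=True, include_interaction=True)


class TestLRT:
    def _fit(self, ll, n_obs=10, y_sum=100):
        return FittedNB(
            class_levels=np.array([0]), class_coefs=np.zeros(1), dense_names=[],
            dense_coefs=np.zeros(0), dense_se={}, theta=np.inf, alpha=0.0,
            log_likelihood=ll, converged=True, fallback_used="none",
            mu=np.zeros(n_obs), n_obs=n_obs, y_sum=y_sum, n_params=1,
        )

    def test_equal_likelihood_gives_p_one(self):
        assert lrt(self._fit(-10.0), self._fit(-10.0)) == 1.0

    def test_chi_square_closed_form(self):
        p = lrt(self._fit(-10.0), self._fit(-10.0 + 3.841 / 2))
        assert p == pytest.approx(chi2.sf(3.841, 1))
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_monotone_in_deviance(self):
        ps = [lrt(self._fit(-10.0), self._fit(-10.0 + d / 2)) for d in (0.5, 1, 2, 4, 8)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_mismatched_tables_raise(self):
        with pytest.raises(ValueError):
            lrt(self._fit(-10.0, n_obs=10), self._fit(-9.0, n_obs=12))

    def test_negative_deviance_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert lrt(self._fit(-9.0), self._fit(-10.0)) == 1.0


def _const_fit(mu):
    return FittedNB(
        class_levels=np.array([0]), class_coefs=np.zeros(1), dense_names=[],
        dense_coefs=np.zeros(0), dense_se={}, theta=np.inf, alpha=0.0,
        log_likelihood=0.0, converged=True, fallback_used="none",
        mu=np.asarray(mu, float), n_obs=len(mu), y_sum=0, n_params=1,
    )


def _fc_table(site_counts, flank_counts):
    rows = [(1, 1, 0, 0, c, 1000, 1.0) for c in site_counts]
    rows += [(1, 0, 0, 0, c, 1000, 1.0) for c in flank_counts]
    return pd.DataFrame(
        rows, columns=["bin", "is_site", "cofac", "class_id", "n_mut", "n_posits", "mbp_rate"]
    )


class TestFoldChange:
    def test_fc_exactly_one_at_median(self):
        mu = np.full(8, 50.0)
        draws = np.random.default_rng(1).poisson(50, size=(1000, 8)).sum(axis=1)
        med = int(np.median(draws))
        q, r = divmod(med, 8)
        t = _fc_table([q + (1 if i < r else 0) for i in range(8)], [10] * 16)
        fc, lo, hi = estimate_fold_change(_const_fit(np.r_[mu, np.full(16, 10.0)]), t, seed=1)
        assert fc == 1.0

    def test_homogeneity_under_doubling(self):
        t1 = _fc_table([40] * 8, [10] * 16)
        t2 = _fc_table([80] * 8, [10] * 16)
        mu = np.r_[np.full(8, 50.0), np.full(16, 10.0)]
        a = estimate_fold_change(_const_fit(mu), t1, seed=3)
        b = estimate_fold_change(_const_fit(mu), t2, seed=3)
        assert b == tuple(2 * x for x in a)

    def test_seed_reproducibility(self):
        t = _fc_table([40] * 8, [10] * 16)
        mu = np.r_[np.full(8, 50.0), np.full(16, 10.0)]
        assert estimate_fold_change(_const_fit(mu), t, seed=9) == estimate_fold_change(
            _const_fit(mu), t, seed=9
        )

    def test_zero_observed_degenerates_with_warning(self):
        t = _fc_table([0] * 8, [10] * 16)
        mu = np.r_[np.full(8, 50.0), np.full(16, 10.0)]
        with pytest.warns(UserWarning, match="degenerate"):
            fc, lo, hi = estimate_fold_change(_const_fit(mu), t, seed=2)
        assert fc == 0.0

    def test_default_draw_count(self):
        import inspect

        assert inspect.signature(estimate_fold_change).parameters["n_draws"].default == 1000


class TestRM2OnSimulatedCohorts:
    def test_recovers_injected_enrichment(self, small_cohort):
        from conftest import small_spec
        from sitemut import simulate_cohort, simulate_genome, simulate_sites

        spec = small_spec(seed=4, site_fold_change=1.5, n_tumours=20)
        g = simulate_genome(spec)
        sites = simulate_sites(spec, g)
        ms, truth = simulate_cohort(spec, g, sites)
        tab = CohortTabulator(sites, g, ms)
        res = rm2_test(tab.table_for_mask(subset_mask(ms, "total")), seed=4)
        assert res.p_site < 1e-6 and res.coef_site > 0
        assert res.fc == pytest.approx(truth.expected_snv_site_flank_ratio(), rel=0.08)
        assert res.fc_ci[0] <= res.fc <= res.fc_ci[1]
        assert np.exp(res.coef_site) == pytest.approx(res.fc, rel=0.10)

    def test_conservation_of_totals(self, small_cohort):
        _, g, sites, ms, _ = small_cohort
        tab = CohortTabulator(sites, g, ms)
        table = tab.table_for_mask(subset_mask(ms, "total"))
        res = rm2_test(table, n_draws=0)
        assert res.n_mut_site + res.n_mut_flank == table["n_mut"].sum()

    def test_interaction_symmetric_under_relabelling(self):
        from conftest import small_spec
        from sitemut import build_cofactor_table, simulate_cohort, simulate_genome, simulate_sites

        spec = small_spec(seed=6, n_tumours=30, carrier_fraction=0.4, carrier_fold_change=1.4)
        g = simulate_genome(spec)
        sites = simulate_sites(spec, g)
        ms, truth = simulate_cohort(spec, g, sites)
        carriers = set(truth.carriers)
        cof = {t: int(t in carriers) for t in ms.tumours}
        t1 = build_cofactor_table(sites, g, ms, ms, cof)
        t2 = build_cofactor_table(sites, g, ms, ms, {t: 1 - v for t, v in cof.items()})
        r1 = cofactor_interaction(t1, n_draws=0, per_group=False)
        r2 = cofactor_interaction(t2, n_draws=0, per_group=False)
        assert r1.p_interaction == pytest.approx(r2.p_interaction, abs=1e-6)
        assert r1.coef_interaction == pytest.approx(-r2.coef_interaction, abs=1e-4)
        assert r1.p_interaction < 0.05 and r1.coef_interaction > 0

    def test_single_level_cofactor_rejected(self, small_cohort):
        _, g, sites, ms, _ = small_cohort
        tab = CohortTabulator(sites, g, ms)
        table = tab.table_for_mask(subset_mask(ms, "total"))
        with pytest.raises(ValueError):
            cofactor_interaction(table)


class TestBH:
    def test_singleton_identity(self):
        assert bh_fdr([0.05]).tolist() == [0.05]

    def test_step_up_with_monotone_floor(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_direct_formula(self):
        np.testing.assert_allclose(bh_fdr([0.001, 0.5]), [0.002, 0.5])

    def test_agrees_with_formula_oracle(self):
        rng = np.random.default_rng(12)
        p = rng.random(37)
        np.testing.assert_allclose(bh_fdr(p), oracles.bh_oracle(list(p)))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
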