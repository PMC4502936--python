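import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from wolbprev import (
    BetaParams,
    InflatedBetaParams,
    ScreenTable,
    beta_pdf,
    curvature_ci,
    fit_ml,
    incidence,
    log_likelihood,
    marginal_pmf,
    mean_prevalence,
    simulate_screens,
)
from wolbprev.prevalence_model import expected_bin_fractions
from wolbprev.synthetic import SimConfig

from conftest import make_record


def quad_marginal(k, n, model):
    """Independent oracle: numerical quadrature of the mixing integral."""
    comb = special.comb(n, k)

    def integrand(q):
        return beta_pdf(q, model) * comb * q**k * (1 - q) ** (n - k)

    val, _ = integrate.quad(integrand, 0, 1, epsabs=1e-12, epsrel=1e-12, limit=200)
    if isinstance(model, InflatedBetaParams):
        if k == 0:
            val += model.mass_at_zero
        if k == n:
            val += model.mass_at_one
    return val


class TestBetaPdf:
    def test_uniform_density(self):
        assert beta_pdf(0.5, BetaParams(1, 1)) == pytest.approx(1.0)

    def test_closed_form_symmetric(self):
        # Γ(4)/(Γ(2)Γ(2)) · 0.5 · 0.5 = 6 · 0.25
        assert beta_pdf(0.5, BetaParams(2, 2)) == pytest.approx(1.5)

    def test_normalizes(self):
        val, _ = integrate.quad(lambda q: beta_pdf(q, BetaParams(0.24, 0.63)), 0, 1)
        assert val == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, q):
        with pytest.raises(ValueError):
            beta_pdf(q, BetaParams(2, 2))


class TestMarginalPmf:
    def test_uniform_prevalence_gives_discrete_uniform(self):
        assert marginal_pmf(1, 2, BetaParams(1, 1)) == pytest.approx(1 / 3)

    def test_pure_point_masses(self):
        m = InflatedBetaParams(1, 1, gamma=0.3, phi=1 - 1e-12)
        assert marginal_pmf(0, 5, m) == pytest.approx(0.3, abs=1e-9)
        assert marginal_pmf(5, 5, m) == pytest.approx(0.7, abs=1e-9)
        assert marginal_pmf(2, 5, m) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "model",
        [
            BetaParams(0.24, 0.63),
            BetaParams(3.0, 1.2),
            InflatedBetaParams(1.0, 2.0, 0.5, 0.4),
            InflatedBetaParams(0.24, 0.63, 0.9, 0.1),
        ],
        ids=["beta-u", "beta-conc", "inflated", "inflated-skew"],
    )
    def test_matches_quadrature(self, model):
        for n in (1, 3, 10):
            for k in range(n + 1):
                assert marginal_pmf(k, n, model) == pytest.approx(
                    quad_marginal(k, n, model), abs=1e-8
                )

    def test_matches_scipy_betabinom(self):
        # independent closed-form cross-check for the beta family
        a, b, n = 0.7, 2.3, 17
        ks = np.arange(n + 1)
        ours = marginal_pmf(ks, np.full(n + 1, n), BetaParams(a, b))
        assert np.allclose(ours, stats.betabinom(n, a, b).pmf(ks), atol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=st.floats(0.05, 10),
        b=st.floats(0.05, 10),
        g=st.floats(0.01, 0.99),
        phi=st.floats(0.0, 0.99),
        n=st.integers(1, 100),
    )
    def test_sums_to_one(self, a, b, g, phi, n):
        ks = np.arange(n + 1)
        for model in (BetaParams(a, b), InflatedBetaParams(a, b, g, phi)):
            total = marginal_pmf(ks, np.full(n + 1, n), model).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_kn_rejected(self):
        with pytest.raises(ValueError):
            marginal_pmf(5, 3, BetaParams(1, 1))


class TestLogLikelihood:
    def test_all_mass_at_zero(self):
        t = ScreenTable([make_record(k=0, n=3)])
        m = InflatedBetaParams(1, 1, gamma=1 - 1e-12, phi=1 - 1e-12)
        assert log_likelihood(t, m) == pytest.approx(0.0, abs=1e-9)

    def test_additive_over_records(self, toy_table):
        m = BetaParams(0.5, 1.5)
        total = sum(np.log(marginal_pmf(r.n_infected, r.n_sampled, m)) for r in toy_table)
        assert log_likelihood(toy_table, m) == pytest.approx(total, abs=1e-12)
        doubled = ScreenTable(toy_table.records * 2)
        assert log_likelihood(doubled, m) == pytest.approx(2 * total, abs=1e-12)

    def test_inflated_with_phi_zero_equals_beta(self, toy_table):
        beta = BetaParams(0.7, 1.9)
        inflated = InflatedBetaParams(0.7, 1.9, gamma=0.5, phi=0.0)
        assert log_likelihood(toy_table, inflated) == log_likelihood(toy_table, beta)


class TestFunctionals:
    def test_mu_closed_form(self):
        assert mean_prevalence(BetaParams(0.24, 0.63)) == pytest.approx(0.24 / 0.87)

    def test_mu_point_masses_only(self):
        assert mean_prevalence(InflatedBetaParams(1, 1, 0.4, 1.0)) == pytest.approx(0.6)

    def test_mu_symmetry(self):
        assert mean_prevalence(BetaParams(3.7, 3.7)) == pytest.approx(0.5)

    def test_mu_matches_quadrature(self):
        m = InflatedBetaParams(0.8, 1.7, 0.3, 0.25)
        cont, _ = integrate.quad(lambda q: q * beta_pdf(q, m), 0, 1, epsabs=1e-12)
        assert mean_prevalence(m) == pytest.approx(cont + m.mass_at_one, abs=1e-10)

    def test_incidence_uniform_tail(self):
        assert incidence(BetaParams(1, 1), 0.5) == pytest.approx(0.5)

    def test_incidence_point_masses(self):
        m = InflatedBetaParams(1, 1, 0.25, 1.0)
        for c in (0.001, 0.5, 0.999):
            assert incidence(m, c) == pytest.approx(0.75)

    def test_incidence_matches_quadrature(self):
        m = BetaParams(0.24, 0.63)
        val, _ = integrate.quad(lambda q: beta_pdf(q, m), 0.001, 1, epsabs=1e-12, limit=200)
        assert incidence(m, 0.001) == pytest.approx(val, abs=1e-8)

    def test_incidence_monotone_in_c(self):
        m = InflatedBetaParams(0.5, 1.5, 0.4, 0.3)
        cs = np.logspace(-5, -0.05, 25)
        vals = [incidence(m, c) for c in cs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        # limit as c -> 0: all mass except the point mass at zero
        assert incidence(m, 1e-12) == pytest.approx(1 - m.mass_at_zero, abs=1e-6)

    def test_incidence_domain(self):
        with pytest.raises(ValueError):
            incidence(BetaParams(1, 1), 0.0)


class TestFitMl:
    def test_recovers_beta_parameters(self):
        # seed-averaged recovery at the simulation sizes used throughout
        errs = []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_species=300, populations_per_species=(2, 2),
                            n_per_population=(10, 50),
                            prevalence_model=BetaParams(0.5, 1.5))
            table, _ = simulate_screens(cfg)
            fit = fit_ml(table, "beta", n_restarts=3, seed=seed, compute_ci=False)
            errs.append((abs(fit.model.alpha - 0.5) / 0.5, abs(fit.model.beta - 1.5) / 1.5))
        mean_err = np.mean(errs, axis=0)
        assert (mean_err < 0.2).all()

    def test_aic_identity_and_optimum_beats_moment_start(self):
        cfg = SimConfig(seed=7, n_species=200)
        table, _ = simulate_screens(cfg)
        fit = fit_ml(table, "beta", n_restarts=3, seed=0, compute_ci=False)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.log_likelihood)
        from wolbprev import moment_fit

        est = moment_fit(table)
        if est.valid:
            start = BetaParams(est.alpha_hat, est.beta_hat)
            assert fit.log_likelihood >= log_likelihood(table, start) - 1e-6

    def test_model_selection_prefers_inflated_truth(self):
        cfg = SimConfig(seed=11, n_species=300,
                        prevalence_model=InflatedBetaParams(1, 2, 0.5, 0.4))
        table, _ = simulate_screens(cfg)
        fb = fit_ml(table, "beta", n_restarts=3, seed=0, compute_ci=False)
        fi = fit_ml(table, "doubly_inflated", n_restarts=5, seed=0, compute_ci=False)
        assert fi.aic < fb.aic

    def test_degenerate_all_negative_warns(self):
        t = ScreenTable([make_record(f"s{i}", k=0, n=10) for i in range(10)])
        with pytest.warns(UserWarning, match="negative"):
            fit_ml(t, "beta", n_restarts=2, seed=0, compute_ci=False)

    def test_unknown_family_rejected(self, toy_table):
        with pytest.raises(ValueError, match="family"):
            fit_ml(toy_table, "gaussian")


class TestCurvatureCi:
    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n_sp in (150, 1500):
            cfg = SimConfig(seed=3, n_species=n_sp, populations_per_species=(1, 1),
                            n_per_population=(10, 50),
                            prevalence_model=BetaParams(0.5, 1.5))
            table, _ = simulate_screens(cfg)
            fit = fit_ml(table, "beta", n_restarts=3, seed=0)
            lo, hi = fit.ci_mu
            assert 0.0 <= lo <= hi <= 1.0
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_interval_contains_point_estimate(self):
        cfg = SimConfig(seed=5, n_species=200)
        table, _ = simulate_screens(cfg)
        fit = fit_ml(table, "beta", n_restarts=3, seed=0)
        lo, hi = curvature_ci(fit, "mu")
        assert lo <= fit.mu <= hi
        for c, x in fit.incidence_by_threshold.items():
            lo, hi = curvature_ci(fit, ("incidence", c))
            assert lo <= x <= hi


class TestExpectedBins:
    def test_fractions_sum_to_one(self, toy_table):
        frac = expected_bin_fractions(toy_table, BetaParams(0.24, 0.63))
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)
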