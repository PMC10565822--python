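import numpy as np
import pytest

from gkvisc import (
    FitError,
    ValidationError,
    aggregate_set_values,
    aggregate_sets,
    fit_multiexponential,
    fit_power_law,
    truncation_check,
)
from gkvisc.time_decomposition import MultiExpFit


def saturating_curve(t, B, amps, taus):
    out = np.zeros_like(t)
    for a, tau in zip(amps, taus):
        out += a * tau * (1.0 - np.exp(-t / tau))
    return B * out


def make_grid(t_max=100.0, n=2001):
    return np.linspace(0.0, t_max, n)


class TestPowerLaw:
    def test_exact_recovery_to_machine_precision(self):
        t = make_grid()
        fit = fit_power_law((t, np.where(t > 0, 2.0 * t**0.5, 0.0)))
        assert fit.A == pytest.approx(2.0, rel=1e-12)
        assert fit.b == pytest.approx(0.5, rel=1e-12)

    def test_noisy_exponent_recovered_within_002(self, rng):
        t = np.linspace(0.1, 100.0, 1000)
        sigma = 3.0 * t**0.7 * np.exp(0.01 * rng.standard_normal(1000))
        fit = fit_power_law((t, sigma))
        assert fit.b == pytest.approx(0.7, abs=0.02)

    def test_rescaling_sigma_changes_A_not_b(self):
        t = make_grid()
        sigma = np.where(t > 0, 1.3 * t**0.6, 0.0)
        f1 = fit_power_law((t, sigma))
        f2 = fit_power_law((t, 10.0 * sigma))
        assert f2.b == pytest.approx(f1.b, rel=1e-12)
        assert f2.A == pytest.approx(10.0 * f1.A, rel=1e-10)

    def test_degenerate_sigma_rejected(self):
        t = make_grid()
        with pytest.raises(FitError, match="degenerate"):
            fit_power_law((t, np.zeros_like(t)))

    def test_too_few_points_rejected(self):
        t = np.linspace(0.0, 5.0, 6)
        with pytest.raises(FitError, match=">= 10"):
            fit_power_law((t, t + 1.0))

    def test_decaying_sigma_rejected(self):
        t = make_grid()
        sigma = np.ones_like(t)
        sigma[1:] = t[1:] ** -0.5
        with pytest.raises(FitError, match="does not grow"):
            fit_power_law((t, sigma))


class TestMultiExponential:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_noiseless_triexponential_recovery(self, seed):
        # eta_inf = 0.5*0.1 + 0.3*1 + 0.2*10 = 2.35
        t = make_grid()
        y = saturating_curve(t, 1.0, (0.5, 0.3, 0.2), (0.1, 1.0, 10.0))
        fit = fit_multiexponential((t, y), b=0.5, seed=seed)
        assert fit.eta_infinity == pytest.approx(2.35, rel=1e-3)
        assert fit.converged

    def test_degenerate_single_exponential_with_biexp_form(self):
        # alpha = 1: eta(t) = B tau1 (1 - e^{-t/tau1}), asymptote B tau1
        t = make_grid()
        y = saturating_curve(t, 2.0, (1.0,), (5.0,))
        fit = fit_multiexponential((t, y), b=0.5, form="biexponential")
        assert fit.eta_infinity == pytest.approx(10.0, rel=1e-3)

    def test_taus_sorted_and_amplitudes_in_simplex(self, rng):
        t = make_grid()
        y = saturating_curve(t, 1.0, (0.2, 0.5, 0.3), (0.3, 3.0, 30.0))
        y *= np.exp(0.01 * rng.standard_normal(t.size))
        fit = fit_multiexponential((t, y), b=0.6)
        assert fit.taus == tuple(sorted(fit.taus))
        assert 0 <= fit.alpha <= 1 and 0 <= fit.beta <= 1
        assert fit.alpha + fit.beta <= 1 + 1e-12
        # asymptote of the fitted form equals the reported eta_infinity
        assert fit(np.array([1e9]))[0] == pytest.approx(fit.eta_infinity, rel=1e-9)

    def test_triexponential_residual_never_worse_than_biexponential(self):
        # slow-rise curve: three well-separated timescales
        t = make_grid(t_max=400.0, n=4001)
        y = saturating_curve(t, 1.0, (0.6, 0.3, 0.1), (0.5, 10.0, 150.0))
        bi = fit_multiexponential((t, y), b=0.5, form="biexponential")
        tri = fit_multiexponential((t, y), b=0.5, form="triexponential")
        assert tri.residual_norm <= bi.residual_norm * (1 + 1e-8)

    def test_invalid_form_and_short_range_rejected(self):
        t = make_grid()
        y = saturating_curve(t, 1.0, (1.0,), (5.0,))
        with pytest.raises(ValidationError, match="form"):
            fit_multiexponential((t, y), b=0.5, form="quadexponential")
        with pytest.raises(FitError, match=">= 10"):
            fit_multiexponential((t[:5], y[:5]), b=0.5)

    def test_warm_start_is_honoured(self):
        t = make_grid()
        y = saturating_curve(t, 1.0, (0.5, 0.3, 0.2), (0.1, 1.0, 10.0))
        warm = fit_multiexponential((t, y), b=0.5)
        refit = fit_multiexponential((t, y), b=0.5, restarts=1, x0=warm)
        assert refit.eta_infinity == pytest.approx(warm.eta_infinity, rel=1e-6)


class TestAggregation:
    @pytest.mark.parametrize(
        "values, expected",
        [([7.5, 14.4, 7.2], 5.8), ([31.2, 20.3, 24.4], 7.8)],
    )
    def test_set_spread_convention(self, values, expected):
        # root-sum-of-squared-deviations over the per-set estimates
        _, unc = aggregate_set_values(values)
        assert round(unc, 1) == expected

    def test_identical_sets_give_zero_uncertainty(self):
        _, unc = aggregate_set_values([5.0, 5.0, 5.0])
        assert unc == 0.0

    def test_permutation_invariance(self):
        a = aggregate_set_values([7.5, 14.4, 7.2])[1]
        b = aggregate_set_values([14.4, 7.2, 7.5])[1]
        assert a == pytest.approx(b, rel=1e-14)

    def test_std_convention_exposed(self):
        _, unc = aggregate_set_values([7.5, 14.4, 7.2], convention="std")
        assert unc == pytest.approx(np.std([7.5, 14.4, 7.2], ddof=1), rel=1e-12)
        # rss = std * sqrt(n - 1) for n values
        assert aggregate_set_values([7.5, 14.4, 7.2])[1] == pytest.approx(
            unc * np.sqrt(2.0), rel=1e-12
        )

    def test_aggregate_sets_requires_two_fits(self):
        fit = MultiExpFit(
            form="triexponential", B=1.0, alpha=0.5, beta=0.3,
            taus=(0.1, 1.0, 10.0), eta_infinity=2.35, weight_exponent_b=0.5,
            fit_range=(0.1, 100.0), residual_norm=0.0, converged=True,
        )
        with pytest.raises(ValidationError, match=">= 2"):
            aggregate_sets([fit], fit)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_set_values([1.0])


class TestTruncation:
    def test_information_complete_truncation_agrees(self):
        # tau_max = 5 << 100 ps truncation: nothing is lost
        t = make_grid(t_max=400.0, n=8001)
        y = saturating_curve(t, 1.0, (0.5, 0.5), (0.5, 5.0))
        full = fit_multiexponential((t, y), b=0.5)
        trunc = truncation_check((t, y), b=0.5, truncated_range=(0.0, 100.0))
        assert trunc.eta_infinity == pytest.approx(full.eta_infinity, rel=1e-3)

    def test_truncation_near_slowest_timescale_biases_low(self):
        # slow mode tau = 300 ps vs 100 ps window: asymptote underestimated
        t = make_grid(t_max=2000.0, n=8001)
        true_eta = 1.0 * (0.5 * 1.0 + 0.5 * 300.0)
        y = saturating_curve(t, 1.0, (0.5, 0.5), (1.0, 300.0))
        trunc = truncation_check((t, y), b=0.5, truncated_range=(0.0, 100.0))
        assert trunc.eta_infinity < true_eta

    def test_truncated_range_must_be_shorter(self):
        t = make_grid()
        y = saturating_curve(t, 1.0, (1.0,), (5.0,))
        with pytest.raises(ValidationError, match="shorter"):
            truncation_check((t, y), b=0.5, truncated_range=(0.0, 200.0))
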