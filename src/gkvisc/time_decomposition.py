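"""Time-decomposition extraction of the asymptotic viscosity.

Running Green-Kubo integrals are exact at short lag but noise-dominated at
long lag; the inter-trajectory standard deviation grows roughly as a power
law. The time-decomposition protocol therefore proceeds in two stages:

1. Fit sigma(t) = A * t^b (A, b > 0) by linear regression in log-log space.
2. Fit the ensemble mean <eta(t)> with a saturating sum of exponentials

       eta(t) = B * [ alpha tau1 (1 - e^{-t/tau1})
                    + beta  tau2 (1 - e^{-t/tau2})
                    + (1 - alpha - beta) tau3 (1 - e^{-t/tau3}) ]

   weighted by t^{-b}, so the statistically accurate short-time data
   dominate while the slow rise still constrains the long time constants.
   The viscosity estimate is the analytic long-time limit
   eta_inf = B (alpha tau1 + beta tau2 + (1-alpha-beta) tau3).

The biexponential variant drops the beta term (amplitudes alpha, 1-alpha).
The functional form is empirical — it is what integrating a tri(bi)-
exponential ACF decay produces — and no physical meaning is attached to
the time constants.

Per-set estimates from repeat simulation sets are aggregated with a
root-sum-of-squared-deviations uncertainty (see :func:`aggregate_sets`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .green_kubo import RunningViscosityEnsemble

_FORMS = ("biexponential", "triexponential")


@dataclass
class PowerLawFit:
    """sigma(t) = A t^b fitted in log-log space."""

    A: float  # mPa.s / ps^b
    b: float
    fit_range: tuple[float, float]
    residual_norm: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.A * np.asarray(t, dtype=float) ** self.b


@dataclass
class MultiExpFit:
    """Weighted multi-exponential fit of <eta(t)> and its long-time limit.

    Amplitude fractions ``alpha`` (and ``beta`` for the triexponential) obey
    0 <= alpha, beta, alpha + beta <= 1; time constants are sorted
    tau1 <= tau2 (<= tau3). ``eta_infinity`` is the analytic asymptote of
    the fitted curve, i.e. the viscosity estimate in mPa.s.
    """

    form: str
    B: float
    alpha: float
    beta: float
    taus: tuple[float, ...]
    eta_infinity: float
    weight_exponent_b: float
    fit_range: tuple[float, float]
    residual_norm: float
    converged: bool

    @property
    def amplitudes(self) -> tuple[float, ...]:
        if self.form == "biexponential":
            return (self.alpha, 1.0 - self.alpha)
        return (self.alpha, self.beta, 1.0 - self.alpha - self.beta)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, tau in zip(self.amplitudes, self.taus):
            out += a * tau * (1.0 - np.exp(-t / tau))
        return self.B * out


@dataclass
class ViscosityEstimate:
    """Combined viscosity with the per-set spread as uncertainty."""

    combined_eta: float
    set_etas: list[float]
    uncertainty: float
    n_sets: int
    sample_std: float  # plain (N-1) standard deviation, for reference


def _curve_arrays(curve, attr: str = "eta") -> tuple[np.ndarray, np.ndarray]:
    """Accept (times, values) pairs or objects with .times/.eta arrays."""
    if hasattr(curve, "times"):
        return np.asarray(curve.times, float), np.asarray(getattr(curve, attr), float)
    t, y = curve
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def _range_mask(
    t: np.ndarray, fit_range: tuple[float, float] | None
) -> np.ndarray:
    mask = t > 0.0  # t = 0 always excluded: sigma(0) = 0 and t^-b diverges
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (t >= lo) & (t <= hi)
    return mask


def fit_power_law(
    sigma_curve,
    fit_range: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Fit A t^b to the inter-trajectory standard deviation sigma(t).

    ``sigma_curve`` is a ``(times, sigma)`` pair or any object with
    ``.times`` / ``.eta``. Ordinary least squares of log sigma on log t:
    exact on noiseless power laws, and A > 0 by construction. Raises
    :class:`FitError` for non-positive sigma inside the range (degenerate
    ensemble) or a non-positive fitted exponent.
    """
    t, sigma = _curve_arrays(sigma_curve)
    mask = _range_mask(t, fit_range)
    t, sigma = t[mask], sigma[mask]
    if t.size < 10:
        raise FitError(f"power-law fit needs >= 10 points with t > 0, got {t.size}")
    if np.any(sigma <= 0):
        raise FitError(
            "sigma(t) <= 0 inside the fit range: degenerate (e.g. identical-"
            "trajectory) ensemble has no power-law noise growth"
        )
    logt, logs = np.log(t), np.log(sigma)
    design = np.column_stack([np.ones_like(logt), logt])
    coef, res, *_ = np.linalg.lstsq(design, logs, rcond=None)
    intercept, slope = coef
    if slope <= 0:
        raise FitError(f"fitted exponent b = {slope:.3g} <= 0; sigma(t) does not grow")
    resid = logs - design @ coef
    return PowerLawFit(
        A=float(np.exp(intercept)),
        b=float(slope),
        fit_range=(float(t[0]), float(t[-1])),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def _saturating_model(t: np.ndarray, B: float, amps: np.ndarray, taus: np.ndarray):
    return B * np.sum(
        amps[:, None] * taus[:, None] * (1.0 - np.exp(-t[None, :] / taus[:, None])),
        axis=0,
    )


def _unpack(params: np.ndarray, n_exp: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Internal parameterisation -> (B, amplitude fractions, taus).

    Amplitudes use a stick-breaking map (p1, p2 in [0,1]) so the simplex
    constraint alpha + beta <= 1 becomes plain box bounds; taus and B live
    in log space so positivity is automatic.
    """
    B = np.exp(params[0])
    if n_exp == 2:
        p1 = params[1]
        amps = np.array([p1, 1.0 - p1])
        taus = np.exp(params[2:4])
    else:
        p1, p2 = params[1], params[2]
        amps = np.array([p1, (1.0 - p1) * p2, (1.0 - p1) * (1.0 - p2)])
        taus = np.exp(params[3:6])
    return B, amps, taus


def _initial_guesses(
    t: np.ndarray,
    y: np.ndarray,
    n_exp: int,
    restarts: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Multi-start grid: tau triplets log-spaced over [10 dt, t_max / 2]."""
    dt = t[1] - t[0] if t.size > 1 else t[0]
    lo, hi = np.log(10.0 * dt), np.log(max(t[-1] / 2.0, 20.0 * dt))
    y_end = max(y[-1], np.max(np.abs(y)) * 1e-3, 1e-12)
    guesses = []
    for k in range(restarts):
        if k == 0:
            log_taus = np.linspace(lo, hi, n_exp)
        else:
            log_taus = np.sort(rng.uniform(lo, hi, size=n_exp))
        amps = rng.dirichlet(np.ones(n_exp)) if k else np.full(n_exp, 1.0 / n_exp)
        denom = float(np.sum(amps * np.exp(log_taus)))
        logB = np.log(y_end / denom)
        if n_exp == 2:
            guesses.append(np.array([logB, amps[0], *log_taus]))
        else:
            p1 = amps[0]
            p2 = amps[1] / (1.0 - p1) if p1 < 1.0 else 0.5
            guesses.append(np.array([logB, p1, np.clip(p2, 0.0, 1.0), *log_taus]))
    return guesses


def fit_multiexponential(
    mean_curve,
    b: float,
    form: str = "triexponential",
    fit_range: tuple[float, float] | None = None,
    restarts: int = 16,
    seed: int = 0,
    max_fit_points: int = 4000,
    x0: MultiExpFit | None = None,
) -> MultiExpFit:
    """t^{-b}-weighted nonlinear least-squares fit of <eta(t)>.

    Parameters
    ----------
    mean_curve:
        ``(times, eta)`` pair or object with ``.times`` / ``.eta``;
        eta(0) = 0 expected, t = 0 excluded from the fit.
    b:
        Weight exponent from :func:`fit_power_law`; weights are t^{-b}.
    form:
        ``"triexponential"`` (default) or ``"biexponential"``.
    restarts:
        Number of multi-start initialisations; the best weighted residual
        wins. Raises :class:`FitError` only if every start fails.
    max_fit_points:
        The uniform lag grid is strided down to at most this many points
        before fitting; the curve is heavily oversampled relative to its
        smooth parameterisation, so striding bounds cost without changing
        the solution beyond optimizer tolerance.
    x0:
        Optional warm start (e.g. the full-ensemble fit when refitting
        bootstrap subsets); tried in addition to the multi-start grid.
    """
    if form not in _FORMS:
        raise ValidationError(f"form must be one of {_FORMS}")
    n_exp = 2 if form == "biexponential" else 3
    t_all, y_all = _curve_arrays(mean_curve)
    mask = _range_mask(t_all, fit_range)
    t, y = t_all[mask], y_all[mask]
    if t.size < 10:
        raise FitError(f"multi-exponential fit needs >= 10 points, got {t.size}")
    if max_fit_points and t.size > max_fit_points:
        stride = int(np.ceil(t.size / max_fit_points))
        t, y = t[::stride], y[::stride]
    w = t ** (-b)
    w /= w.max()

    def residuals(params: np.ndarray) -> np.ndarray:
        B, amps, taus = _unpack(params, n_exp)
        return w * (_saturating_model(t, B, amps, taus) - y)

    def jacobian(params: np.ndarray) -> np.ndarray:
        # analytic derivatives w.r.t. the internal (logB, sticks, log tau)
        # parameterisation; ~5x cheaper than finite differences here
        B, amps, taus = _unpack(params, n_exp)
        e = np.exp(-t[None, :] / taus[:, None])           # (n_exp, n)
        g = taus[:, None] * (1.0 - e)                      # tau_i (1 - e)
        m = B * np.sum(amps[:, None] * g, axis=0)
        dg_dtau = (1.0 - e) - (t[None, :] / taus[:, None]) * e
        cols = [m]  # d/dlogB
        if n_exp == 2:
            cols.append(B * (g[0] - g[1]))                             # d/dp1
        else:
            p1, p2 = params[1], params[2]
            cols.append(B * (g[0] - p2 * g[1] - (1.0 - p2) * g[2]))    # d/dp1
            cols.append(B * (1.0 - p1) * (g[1] - g[2]))                # d/dp2
        for i in range(n_exp):
            cols.append(B * amps[i] * taus[i] * dg_dtau[i])            # d/dlogtau_i
        return w[:, None] * np.column_stack(cols)

    rng = np.random.default_rng(seed)
    guesses = _initial_guesses(t, y, n_exp, max(restarts, 1), rng)
    if x0 is not None and x0.form == form:
        guesses.insert(0, _pack(x0, n_exp))
    # Time constants are confined to [t_min/10, 2 t_max]: the window carries
    # no information on much longer timescales, and an unbounded slow mode
    # can ride tail noise to an arbitrarily inflated asymptote.
    log_tau_lo, log_tau_hi = np.log(t[0] / 10.0), np.log(2.0 * t[-1])
    if n_exp == 2:
        lb = np.array([-50.0, 0.0, log_tau_lo, log_tau_lo])
        ub = np.array([50.0, 1.0, log_tau_hi, log_tau_hi])
    else:
        lb = np.array([-50.0, 0.0, 0.0, log_tau_lo, log_tau_lo, log_tau_lo])
        ub = np.array([50.0, 1.0, 1.0, log_tau_hi, log_tau_hi, log_tau_hi])
    best = None
    failures: list[str] = []
    for guess in guesses:
        try:
            sol = least_squares(
                residuals,
                np.clip(guess, lb + 1e-12, ub - 1e-12),
                jac=jacobian,
                bounds=(lb, ub),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.x)):
            failures.append("non-finite solution")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            f"all {len(guesses)} restarts of the {form} fit failed: {failures[:3]}"
        )
    B, amps, taus = _unpack(best.x, n_exp)
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    eta_inf = float(B * np.sum(amps * taus))
    if form == "biexponential":
        alpha, beta = float(amps[0]), 0.0
    else:
        alpha, beta = float(amps[0]), float(amps[1])
    return MultiExpFit(
        form=form,
        B=float(B),
        alpha=alpha,
        beta=beta,
        taus=tuple(float(x) for x in taus),
        eta_infinity=eta_inf,
        weight_exponent_b=float(b),
        fit_range=(float(t[0]), float(t[-1])),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
    )


def _pack(fit: MultiExpFit, n_exp: int) -> np.ndarray:
    """MultiExpFit -> internal parameter vector (inverse of _unpack)."""
    log_taus = np.log(np.asarray(fit.taus))
    if n_exp == 2:
        return np.array([np.log(fit.B), fit.alpha, *log_taus])
    p1 = fit.alpha
    p2 = fit.beta / (1.0 - p1) if p1 < 1.0 else 0.5
    return np.array([np.log(fit.B), p1, np.clip(p2, 0.0, 1.0), *log_taus])


def fit_ensemble(
    ensemble: RunningViscosityEnsemble,
    form: str = "triexponential",
    fit_range: tuple[float, float] | None = None,
    power_law_range: tuple[float, float] | None = None,
    restarts: int = 16,
    seed: int = 0,
    max_fit_points: int = 4000,
) -> tuple[PowerLawFit, MultiExpFit, ViscosityEstimate | None]:
    """Run both fit stages on an ensemble and aggregate its repeat sets.

    Convenience wrapper: power-law fit of sigma(t), weighted multi-
    exponential fit of the combined mean, one fit per set mean, and (when
    >= 2 sets exist) the aggregated estimate with per-set spread.
    """
    plaw = fit_power_law(
        (ensemble.times, ensemble.sigma_curve), fit_range=power_law_range or fit_range
    )
    combined = fit_multiexponential(
        (ensemble.times, ensemble.mean_curve),
        b=plaw.b,
        form=form,
        fit_range=fit_range,
        restarts=restarts,
        seed=seed,
        max_fit_points=max_fit_points,
    )
    estimate = None
    if len(ensemble.set_means) >= 2:
        set_fits = [
            fit_multiexponential(
                (ensemble.times, mean),
                b=plaw.b,
                form=form,
                fit_range=fit_range,
                restarts=restarts,
                seed=seed,
                max_fit_points=max_fit_points,
                x0=combined,
            )
            for mean in ensemble.set_means.values()
        ]
        estimate = aggregate_sets(set_fits, combined)
    return plaw, combined, estimate


def aggregate_sets(
    set_fits: Sequence[MultiExpFit],
    combined_fit: MultiExpFit,
    convention: str = "rss",
) -> ViscosityEstimate:
    """Combine per-set viscosities with the repeat-set spread as uncertainty.

    The default ``"rss"`` convention reports sqrt(sum_i (eta_i - mean)^2)
    over the set values — for n sets this equals the sample standard
    deviation times sqrt(n-1), a deliberately conservative spread for a
    small number of repeats. ``convention="std"`` reports the plain sample
    standard deviation instead; both are retained on the result.
    """
    if len(set_fits) < 2:
        raise ValidationError("aggregation needs >= 2 per-set fits")
    if convention not in ("rss", "std"):
        raise ValidationError("convention must be 'rss' or 'std'")
    etas = np.array([f.eta_infinity for f in set_fits], dtype=float)
    dev = etas - etas.mean()
    rss = float(np.sqrt(np.sum(dev**2)))
    std = float(etas.std(ddof=1))
    return ViscosityEstimate(
        combined_eta=float(combined_fit.eta_infinity),
        set_etas=[float(e) for e in etas],
        uncertainty=rss if convention == "rss" else std,
        n_sets=len(set_fits),
        sample_std=std,
    )


def aggregate_set_values(
    set_etas: Sequence[float], convention: str = "rss"
) -> tuple[float, float]:
    """(mean, uncertainty) of bare per-set viscosity values.

    Same conventions as :func:`aggregate_sets`, for use when only the
    numbers (not full fit objects) are at hand.
    """
    etas = np.asarray(set_etas, dtype=float)
    if etas.size < 2:
        raise ValidationError("need >= 2 set values")
    dev = etas - etas.mean()
    if convention == "rss":
        unc = float(np.sqrt(np.sum(dev**2)))
    elif convention == "std":
        unc = float(etas.std(ddof=1))
    else:
        raise ValidationError("convention must be 'rss' or 'std'")
    return float(etas.mean()), unc


def truncation_check(
    mean_curve,
    b: float,
    form: str = "triexponential",
    truncated_range: tuple[float, float] | None = None,
    **fit_kwargs,
) -> MultiExpFit:
    """Refit on a truncated lag range as a convergence robustness check.

    Comparing the truncated asymptote with the full-range one reveals how
    much of the estimate rides on slow dynamics beyond the truncation time:
    a fit blind to a time constant longer than the window is biased low.
    """
    t, _ = _curve_arrays(mean_curve)
    if truncated_range is None:
        raise ValidationError("truncated_range is required")
    if truncated_range[1] >= float(t[-1]):
        raise ValidationError(
            f"truncated range end {truncated_range[1]} ps is not shorter than "
            f"the full range {float(t[-1])} ps"
        )
    return fit_multiexponential(
        mean_curve, b=b, form=form, fit_range=truncated_range, **fit_kwargs
    )
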