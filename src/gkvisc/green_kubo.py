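"""Green-Kubo running viscosity integrals.

The shear viscosity of an equilibrium system follows from the time integral
of the pressure-tensor autocorrelation function,

    eta = V / (k_B T) * integral_0^inf <P_ab(t0) P_ab(t0 + t)> dt,

with V the box volume and T the temperature. The running integral eta(t)
truncates the upper limit at lag t; the viscosity is its long-time plateau.
This module converts ACFs in (bar^2, ps) into running integrals in mPa.s
and aggregates per-trajectory curves into ensemble mean and inter-trajectory
standard deviation sigma(t) — the two inputs of the time-decomposition fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .correlation import EnsembleAcf
from .errors import ValidationError

#: Boltzmann constant [J/K], exact (2019 SI).
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass
class RunningViscosityCurve:
    """Running Green-Kubo integral eta(t) of one ACF, in mPa.s."""

    times: np.ndarray
    eta: np.ndarray
    volume: float
    temperature: float
    source: str = "ensemble"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.times.shape != self.eta.shape:
            raise ValidationError("times and eta must have the same shape")
        if self.eta[0] != 0.0:
            raise ValidationError("running integral must start at eta(0) = 0")
        if not np.all(np.isfinite(self.eta)):
            raise ValidationError("running integral contains non-finite values")


@dataclass
class RunningViscosityEnsemble:
    """Per-trajectory running integrals with their pointwise mean and spread.

    ``sigma_curve`` is the inter-trajectory standard deviation sigma(t)
    (sample, N-1 divisor); its growth ~ A t^b quantifies how noise
    accumulates in the tail of the integral. ``set_means`` holds the mean
    curve of each repeat set for the conservative per-set error estimate.
    """

    times: np.ndarray
    per_trajectory: np.ndarray  # shape (N, n_lags)
    mean_curve: np.ndarray
    sigma_curve: np.ndarray
    n: int
    set_means: dict[str, np.ndarray] = field(default_factory=dict)
    sources: list[str] = field(default_factory=list)


def unit_factor(volume: float, temperature: float) -> float:
    """Green-Kubo prefactor in mPa.s per (bar^2 . ps).

    With V in nm^3 and T in K, V/(k_B T) * (1 bar)^2 * (1 ps) equals
    V * 1e-29 / (k_B T) Pa.s, i.e. the returned factor times an ACF
    integral in bar^2.ps gives the viscosity in mPa.s.
    """
    if volume <= 0 or temperature <= 0:
        raise ValidationError("volume and temperature must be positive")
    # 1 nm^3 = 1e-27 m^3, 1 bar^2 = 1e10 Pa^2, 1 ps = 1e-12 s -> 1e-29 net,
    # then 1e3 for Pa.s -> mPa.s
    return volume * 1e-26 / (BOLTZMANN_J_PER_K * temperature)


def running_integral(
    acf: EnsembleAcf | tuple[np.ndarray, np.ndarray],
    volume: float,
    temperature: float,
    source: str = "ensemble",
) -> RunningViscosityCurve:
    """Cumulative trapezoidal Green-Kubo integral of an ACF.

    Accepts an :class:`EnsembleAcf` or a bare ``(lags, values)`` pair on a
    uniform grid. eta(0) = 0 by construction.
    """
    if isinstance(acf, EnsembleAcf):
        lags, values = acf.lags, acf.values
    else:
        lags, values = (np.asarray(a, dtype=float) for a in acf)
    if lags.shape != values.shape or lags.ndim != 1 or lags.shape[0] < 2:
        raise ValidationError("ACF must be two equal-length 1-D arrays, n >= 2")
    diffs = np.diff(lags)
    if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=0.0):
        raise ValidationError("ACF lag grid is not uniform")
    factor = unit_factor(volume, temperature)
    eta = factor * cumulative_trapezoid(values, dx=float(diffs[0]), initial=0.0)
    return RunningViscosityCurve(
        times=lags, eta=eta, volume=volume, temperature=temperature, source=source
    )


def build_ensemble(
    per_trajectory_curves: list[RunningViscosityCurve],
    sets: dict[str, list[int]] | None = None,
) -> RunningViscosityEnsemble:
    """Pointwise mean and sigma(t) over per-trajectory running integrals.

    ``sets`` optionally partitions curve indices into repeat sets whose mean
    curves are retained for per-set viscosity estimates.
    """
    if len(per_trajectory_curves) < 2:
        raise ValidationError("need N >= 2 curves for an ensemble sigma(t)")
    times = per_trajectory_curves[0].times
    for c in per_trajectory_curves[1:]:
        if c.times.shape != times.shape or not np.allclose(
            c.times, times, rtol=1e-9, atol=0.0
        ):
            raise ValidationError("curves do not share one time grid")
    stack = np.vstack([c.eta for c in per_trajectory_curves])
    set_means = {}
    if sets:
        for label, idx in sets.items():
            set_means[label] = stack[idx].mean(axis=0)
    return RunningViscosityEnsemble(
        times=times,
        per_trajectory=stack,
        mean_curve=stack.mean(axis=0),
        sigma_curve=stack.std(axis=0, ddof=1),
        n=stack.shape[0],
        set_means=set_means,
        sources=[c.source for c in per_trajectory_curves],
    )
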