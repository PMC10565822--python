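"""Synthetic pressure fluctuations with exactly known viscosity.

Sums of stationary Ornstein-Uhlenbeck (OU) modes have the closed-form
autocorrelation sum_i c_i exp(-t/tau_i), so the Green-Kubo integral — and
hence the target viscosity unit_factor(V, T) * sum_i c_i tau_i — is known
analytically. Short-tau modes mimic the fast collisional oscillations of a
real pressure ACF, long-tau modes its slowly decaying tail; a spread of two
or more decades in tau reproduces the slow rise of eta(t) that makes the
time-decomposition fit necessary in the first place.

Each mode is sampled with the exact discrete update

    x_{n+1} = x_n e^{-dt/tau} + sqrt(c (1 - e^{-2 dt/tau})) xi_n

initialised from the stationary distribution, so the generator has no
time-discretisation bias: the sampled process *is* the stationary OU
process observed on the grid, not an Euler approximation of it.

The three off-diagonal components are independent OU sums with amplitudes
c_i. The three diagonal components are independent OU sums with amplitudes
2 c_i, so that every half-difference channel (P_aa - P_bb)/2 again has the
exact target ACF sum_i c_i exp(-t/tau_i). The three difference channels are
then pairwise cross-correlated — as they are for a real pressure tensor,
where they satisfy a linear identity — but each channel's marginal ACF, and
therefore the ensemble-averaged ACF and the analytic viscosity, is exact.
The raw synthetic diagonals themselves carry no physical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter, lfiltic

from .errors import ValidationError
from .green_kubo import unit_factor
from .pressure_io import EnsembleLayout, PressureTensorSeries

_OFF_DIAGONAL = ("xy", "xz", "yz")
_DIAGONAL = ("xx", "yy", "zz")


@dataclass
class OuSpec:
    """Specification of an OU-sum pressure-fluctuation ensemble.

    ``modes`` is a list of ``(c_i [bar^2], tau_i [ps])`` pairs; the analytic
    channel ACF is sum_i c_i exp(-t/tau_i) and the analytic viscosity is
    ``unit_factor(volume, temperature) * sum_i c_i tau_i``.
    """

    modes: list[tuple[float, float]]
    time_step: float
    n_steps: int
    volume: float
    temperature: float
    n_channels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValidationError("OuSpec needs at least one (c, tau) mode")
        for c, tau in self.modes:
            if c <= 0 or tau <= 0:
                raise ValidationError(f"mode amplitudes/timescales must be > 0, got ({c}, {tau})")
        if self.time_step <= 0:
            raise ValidationError("time_step must be > 0")
        if self.n_steps < 2:
            raise ValidationError("n_steps must be >= 2")
        if self.volume <= 0 or self.temperature <= 0:
            raise ValidationError("volume and temperature must be > 0")
        if self.n_channels not in (3, 6):
            raise ValidationError("n_channels must be 3 (off-diagonals) or 6")

    def analytic_acf(self, lags: np.ndarray) -> np.ndarray:
        """Closed-form channel ACF sum_i c_i exp(-t/tau_i) [bar^2]."""
        lags = np.asarray(lags, dtype=float)
        out = np.zeros_like(lags)
        for c, tau in self.modes:
            out += c * np.exp(-lags / tau)
        return out


def analytic_viscosity(spec: OuSpec) -> float:
    """Exact Green-Kubo viscosity of the spec, in mPa.s."""
    gk_integral = sum(c * tau for c, tau in spec.modes)  # bar^2 . ps
    return unit_factor(spec.volume, spec.temperature) * gk_integral


def _ou_mode(
    rng: np.random.Generator, c: float, tau: float, dt: float, n: int
) -> np.ndarray:
    """One stationary OU mode via the exact AR(1) recursion (lfilter)."""
    a = np.exp(-dt / tau)
    x0 = np.sqrt(c) * rng.standard_normal()
    innov = np.sqrt(c * (1.0 - a * a)) * rng.standard_normal(n - 1)
    # x_k = a x_{k-1} + innov_k with initial condition x_0
    zi = lfiltic([1.0], [1.0, -a], [x0])
    rest, _ = lfilter([1.0], [1.0, -a], innov, zi=zi)
    return np.concatenate([[x0], rest])


def generate_channel(
    rng: np.random.Generator,
    modes: list[tuple[float, float]],
    dt: float,
    n: int,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Sum of independent OU modes with amplitudes scaled by amplitude_scale."""
    out = np.zeros(n)
    for c, tau in modes:
        out += _ou_mode(rng, amplitude_scale * c, tau, dt, n)
    return out


def generate_series(
    spec: OuSpec,
    rng: np.random.Generator,
    trajectory_id: str = "synthetic",
    set_id: str = "set0",
) -> PressureTensorSeries:
    """One synthetic trajectory.

    Off-diagonals xy, xz, yz are independent OU sums with amplitudes c_i;
    with ``n_channels = 6``, diagonals xx, yy, zz are independent OU sums
    with amplitudes 2 c_i so that each half-difference channel has the
    exact target ACF (see module docstring).
    """
    components: dict[str, np.ndarray] = {}
    for label in _OFF_DIAGONAL:
        components[label] = generate_channel(
            rng, spec.modes, spec.time_step, spec.n_steps
        )
    if spec.n_channels == 6:
        for label in _DIAGONAL:
            components[label] = generate_channel(
                rng, spec.modes, spec.time_step, spec.n_steps, amplitude_scale=2.0
            )
    return PressureTensorSeries(
        time_step=spec.time_step,
        components=components,
        volume=spec.volume,
        temperature=spec.temperature,
        trajectory_id=trajectory_id,
        set_id=set_id,
    )


def trajectory_rngs(spec: OuSpec, n_trajectories: int) -> list[np.random.Generator]:
    """Independent, reproducible per-trajectory generators from spec.seed."""
    children = np.random.SeedSequence(spec.seed).spawn(n_trajectories)
    return [np.random.default_rng(s) for s in children]


def generate_ensemble(
    spec: OuSpec, n_trajectories: int, sets: int = 1
) -> EnsembleLayout:
    """Generate an ensemble of independent trajectories in labelled sets.

    ``n_trajectories`` must divide evenly into ``sets`` groups (mirroring
    the repeat-set design of the reference workflow). Fully determined by
    ``spec.seed``: the same spec yields a bit-identical ensemble.
    """
    if n_trajectories < 1:
        raise ValidationError("n_trajectories must be >= 1")
    if sets < 1 or n_trajectories % sets != 0:
        raise ValidationError(
            f"n_trajectories ({n_trajectories}) must be divisible by sets ({sets})"
        )
    per_set = n_trajectories // sets
    rngs = trajectory_rngs(spec, n_trajectories)
    trajectories = []
    for i, rng in enumerate(rngs):
        set_label = f"set{i // per_set}"
        trajectories.append(
            generate_series(spec, rng, trajectory_id=f"ou{i:03d}", set_id=set_label)
        )
    return EnsembleLayout(trajectories=trajectories)
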