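"""Pressure channels and their time-origin-averaged autocorrelation functions.

An isotropic fluid offers six statistically exploitable shear channels per
snapshot of the pressure tensor: the three off-diagonal elements P_xy, P_xz,
P_yz (each averaged with its transpose when both were recorded) and the
three diagonal differences (P_xx - P_yy)/2, (P_xx - P_zz)/2, (P_yy - P_zz)/2.
Averaging the autocorrelation functions (ACFs) of all six channels over all
trajectories is what makes the Green-Kubo integral tractable for a noisy
nanoscale system.

ACFs are computed over all time origins with a fast-transform (FFT)
estimator that is numerically identical to the direct O(N^2) sum. No mean
is subtracted by default: every shear channel has zero ensemble mean by
symmetry, and subtracting a noisy sample mean biases the long-lag tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

from .errors import ValidationError
from .pressure_io import DIAGONAL_LABELS, OFF_DIAGONAL_PAIRS, PressureTensorSeries

_ESTIMATORS = ("unbiased", "biased")


@dataclass
class ChannelSet:
    """The exploitable shear channels of one trajectory.

    ``channels`` is an ordered list of ``(label, values [bar])`` pairs: three
    off-diagonal channels always, plus three diagonal-difference channels
    when the diagonal components were recorded. All sequences share one
    length and the trajectory's time step.
    """

    channels: list[tuple[str, np.ndarray]]
    time_step: float
    source: str = "traj"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ChannelSet has no channels")
        lengths = {len(v) for _, v in self.channels}
        if len(lengths) != 1:
            raise ValidationError(f"channel lengths differ: {sorted(lengths)}")
        if self.time_step <= 0:
            raise ValidationError("time_step must be > 0")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class EnsembleAcf:
    """Channel- and trajectory-averaged autocorrelation function.

    ``lags`` is a uniform grid [ps] starting at 0 with spacing equal to the
    time step; ``values`` [bar^2] is the flat (unweighted) mean over every
    channel of every contributing trajectory. ``n_channels`` counts all
    contributing channels, ``n_trajectories`` the distinct sources.
    """

    lags: np.ndarray
    values: np.ndarray
    n_channels: int
    n_trajectories: int
    max_lag: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValidationError("lags and values must have the same shape")
        if self.lags[0] != 0.0:
            raise ValidationError("lag grid must start at 0")

    @property
    def time_step(self) -> float:
        return float(self.lags[1] - self.lags[0])


def combine_components(series: PressureTensorSeries) -> ChannelSet:
    """Form the shear channels of one trajectory.

    Off-diagonal components are averaged elementwise with their transpose
    when both are present (P_xy with P_yx etc.). If all three diagonal
    components are present, the half-differences (P_xx - P_yy)/2,
    (P_xx - P_zz)/2, (P_yy - P_zz)/2 are appended, giving six channels.
    """
    comps = series.components
    channels: list[tuple[str, np.ndarray]] = []
    for a, b in OFF_DIAGONAL_PAIRS:
        if a in comps and b in comps:
            channels.append((a, 0.5 * (comps[a] + comps[b])))
        elif a in comps:
            channels.append((a, comps[a].copy()))
        elif b in comps:
            channels.append((a, comps[b].copy()))
        else:  # unreachable for a validated series; keep the guard anyway
            raise ValidationError(f"missing off-diagonal component {a!r}/{b!r}")
    if series.has_diagonals:
        xx, yy, zz = (comps[l] for l in DIAGONAL_LABELS)
        channels.append(("xx-yy", 0.5 * (xx - yy)))
        channels.append(("xx-zz", 0.5 * (xx - zz)))
        channels.append(("yy-zz", 0.5 * (yy - zz)))
    return ChannelSet(
        channels=channels, time_step=series.time_step, source=series.trajectory_id
    )


def _n_lags(n: int, time_step: float, max_lag: float | None) -> int:
    """Number of lag points including lag 0."""
    if max_lag is None:
        return n
    if max_lag < 0:
        raise ValidationError("max_lag must be >= 0")
    k = int(np.floor(max_lag / time_step + 1e-9)) + 1
    if k > n:
        raise ValidationError(
            f"max_lag {max_lag} ps exceeds series span "
            f"({(n - 1) * time_step} ps at {n} samples)"
        )
    return k


def autocovariance_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Raw lagged sums sum_i x_i x_{i+k} for k = 0..n_lags-1 via FFT.

    Zero-padding to at least 2N makes the circular convolution linear, so
    the result equals the direct sum to floating-point round-off.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    nfft = next_fast_len(2 * n)
    f = rfft(x, nfft)
    acov = irfft(f * np.conj(f), nfft)[:n_lags]
    return acov


def compute_acf(
    channel: Sequence[float] | np.ndarray,
    time_step: float,
    max_lag: float | None = None,
    estimator: str = "unbiased",
    subtract_mean: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-origin-averaged ACF of one channel.

    Parameters
    ----------
    channel:
        Pressure channel [bar], length N >= 2.
    time_step:
        Sampling interval [ps].
    max_lag:
        Largest lag [ps]; default is the full span (N-1 samples).
    estimator:
        ``"unbiased"`` divides the lag-k sum by N-k (default; keeps the
        expectation of the trapezoid integral exact), ``"biased"`` divides
        by N.
    subtract_mean:
        Diagnostic option; off by default because shear channels average to
        zero by symmetry and subtracting a sample mean biases long lags.

    Returns
    -------
    (lags [ps], values [bar^2])
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValidationError("channel must be a 1-D sequence of length >= 2")
    if estimator not in _ESTIMATORS:
        raise ValidationError(f"estimator must be one of {_ESTIMATORS}")
    if subtract_mean:
        x = x - x.mean()
    n = x.shape[0]
    k = _n_lags(n, time_step, max_lag)
    acov = autocovariance_fft(x, k)
    if estimator == "unbiased":
        acov = acov / (n - np.arange(k))
    else:
        acov = acov / n
    lags = time_step * np.arange(k)
    return lags, acov


def average_acfs(
    channel_sets: Iterable[ChannelSet],
    max_lag: float | None = None,
    estimator: str = "unbiased",
    subtract_mean: bool = False,
) -> EnsembleAcf:
    """Flat average of the ACFs of every channel of every trajectory.

    All channel sets must share one time step. Channels are weighted
    equally regardless of whether they arose from transpose-pair averaging.
    """
    sets = list(channel_sets)
    if not sets:
        raise ValidationError("average_acfs needs at least one ChannelSet")
    dt = sets[0].time_step
    for cs in sets:
        if not np.isclose(cs.time_step, dt, rtol=1e-9):
            raise ValidationError(
                f"mixed time steps: {cs.time_step} vs {dt} (source {cs.source})"
            )
    total: np.ndarray | None = None
    n_channels = 0
    lags: np.ndarray | None = None
    for cs in sets:
        for _, values in cs.channels:
            lags_i, acf = compute_acf(
                values, dt, max_lag=max_lag, estimator=estimator,
                subtract_mean=subtract_mean,
            )
            if total is None:
                total, lags = acf, lags_i
            else:
                if acf.shape != total.shape:
                    raise ValidationError(
                        "channel lengths differ between trajectories; "
                        "pass an explicit max_lag"
                    )
                total = total + acf
            n_channels += 1
    assert total is not None and lags is not None
    return EnsembleAcf(
        lags=lags,
        values=total / n_channels,
        n_channels=n_channels,
        n_trajectories=len({cs.source for cs in sets}),
        max_lag=float(lags[-1]),
    )
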