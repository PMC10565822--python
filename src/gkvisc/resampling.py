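"""Bootstrap convergence of the viscosity versus ensemble size.

From N per-trajectory running integrals, subsets of increasing size are
drawn repeatedly *without replacement* (no trajectory appears twice within
one draw), each subset is averaged and pushed through the full
time-decomposition fit, and the mean and standard deviation of the
resulting asymptotic viscosities are recorded per subset size. The decay of
that standard deviation with subset size shows how many trajectories a
stable estimate needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FitError, ValidationError
from .green_kubo import RunningViscosityCurve
from .time_decomposition import MultiExpFit, fit_multiexponential, fit_power_law


@dataclass
class BootstrapResult:
    """Per-size bootstrap statistics of the asymptotic viscosity [mPa.s]."""

    subset_sizes: list[int]
    draws_per_size: int
    mean_eta: np.ndarray
    std_eta: np.ndarray
    seed: int
    n_failures: list[int] = field(default_factory=list)
    etas: dict[int, np.ndarray] = field(default_factory=dict)


def bootstrap_viscosity(
    per_trajectory_curves: Sequence[RunningViscosityCurve] | np.ndarray,
    subset_sizes: Sequence[int] = (10, 20, 30, 40, 50, 60),
    draws_per_size: int = 100,
    b_source: str = "refit",
    fixed_b: float | None = None,
    times: np.ndarray | None = None,
    form: str = "triexponential",
    fit_range: tuple[float, float] | None = None,
    restarts: int = 4,
    max_fit_points: int = 2000,
    warm_start: MultiExpFit | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the viscosity estimate over trajectory subsets.

    Parameters
    ----------
    per_trajectory_curves:
        N running-integral curves sharing one time grid, or an (N, n_lags)
        array (then ``times`` is required).
    subset_sizes:
        Strictly increasing subset sizes, each <= N.
    b_source:
        ``"refit"`` (default) refits the sigma(t) power law on every subset,
        self-consistent with the main pipeline; ``"fixed"`` reuses
        ``fixed_b`` everywhere (faster, needs the full-ensemble exponent).
    restarts, warm_start:
        Each subset fit uses a reduced multi-start budget plus, when given,
        the full-ensemble fit as warm start — subset means differ from the
        full mean only by resampling noise, so the full-set optimum is an
        excellent initialisation.
    seed:
        Fully determines the draw sequence; identical inputs and seed give
        an identical result.

    Draws whose fit fails after all restarts are counted in ``n_failures``
    and skipped; they are never silently imputed.
    """
    if isinstance(per_trajectory_curves, np.ndarray):
        stack = per_trajectory_curves
        if times is None:
            raise ValidationError("times is required with an array of curves")
    else:
        curves = list(per_trajectory_curves)
        times = curves[0].times
        stack = np.vstack([c.eta for c in curves])
    n = stack.shape[0]
    sizes = [int(s) for s in subset_sizes]
    if any(s2 <= s1 for s1, s2 in zip(sizes, sizes[1:])) or len(sizes) == 0:
        raise ValidationError("subset_sizes must be strictly increasing")
    if sizes[-1] > n:
        raise ValidationError(f"subset size {sizes[-1]} exceeds N = {n}")
    if draws_per_size < 2:
        raise ValidationError("draws_per_size must be >= 2")
    if b_source not in ("refit", "fixed"):
        raise ValidationError("b_source must be 'refit' or 'fixed'")
    if b_source == "fixed" and fixed_b is None:
        raise ValidationError("fixed_b is required when b_source='fixed'")

    rng = np.random.default_rng(seed)
    mean_eta, std_eta, n_failures = [], [], []
    etas_by_size: dict[int, np.ndarray] = {}
    for size in sizes:
        etas = []
        failures = 0
        for _ in range(draws_per_size):
            idx = rng.choice(n, size=size, replace=False)
            sub = stack[idx]
            mean_curve = sub.mean(axis=0)
            try:
                if b_source == "refit":
                    sigma = sub.std(axis=0, ddof=1)
                    b = fit_power_law((times, sigma), fit_range=fit_range).b
                else:
                    b = float(fixed_b)  # type: ignore[arg-type]
                fit = fit_multiexponential(
                    (times, mean_curve),
                    b=b,
                    form=form,
                    fit_range=fit_range,
                    restarts=restarts,
                    seed=seed,  # constant: identical subsets refit identically
                    max_fit_points=max_fit_points,
                    x0=warm_start,
                )
            except FitError:
                failures += 1
                continue
            etas.append(fit.eta_infinity)
        if not etas:
            raise FitError(f"every draw failed at subset size {size}")
        arr = np.asarray(etas)
        etas_by_size[size] = arr
        mean_eta.append(arr.mean())
        std_eta.append(arr.std(ddof=1) if arr.size > 1 else 0.0)
        n_failures.append(failures)
    return BootstrapResult(
        subset_sizes=sizes,
        draws_per_size=draws_per_size,
        mean_eta=np.asarray(mean_eta),
        std_eta=np.asarray(std_eta),
        seed=seed,
        n_failures=n_failures,
        etas=etas_by_size,
    )
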