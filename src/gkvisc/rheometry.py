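"""Rotational rheometry of protein solutions.

Three pieces of experimental-side analysis:

* Cone-plate conversion: for a shallow cone of angle alpha and radius R
  rotating at angular velocity omega, the shear rate omega/alpha is nearly
  uniform and the dynamic viscosity follows from the torque M as
  eta = 3 M alpha / (2 pi R^3 omega).

* The Ross-Minton concentration-viscosity law for protein solutions,

      eta(rho) = eta0 * exp( [eta] rho / (1 - (k/v) [eta] rho) ),

  with eta0 the buffer viscosity, [eta] the intrinsic viscosity of the
  solute, k a crowding factor and v a shape parameter (2.5 for spheres).
  Only the ratio k/v is identifiable from viscosity data, so a single
  ``crowding_ratio`` parameter is fitted. Fitting is done on log eta:
  the model is exponential in its argument, and log-space least squares
  equalises relative errors across a ~20-fold viscosity range.

* Inversion (viscosity -> concentration) and a concentration-uncertainty
  band obtained by refitting with all concentrations scaled down/up by a
  relative uncertainty.

A measured (concentration, viscosity) table for a monoclonal antibody at
297 K ships with the package; see :func:`load_mab_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import FitError, ValidationError

_ETA0_BOUNDS = (0.5, 2.0)  # mPa.s; plausible aqueous-buffer range


@dataclass
class RheoDataset:
    """Concentration-viscosity measurements at one temperature.

    ``points`` rows are (concentration rho [mg/mL], viscosity eta [mPa.s],
    filtered flag). Duplicate concentrations are legitimate repeat
    measurements and are never deduplicated.
    """

    points: list[tuple[float, float, bool]]
    temperature: float = 297.0

    def __post_init__(self) -> None:
        for rho, eta, _ in self.points:
            if rho < 0:
                raise ValidationError(f"concentration must be >= 0, got {rho}")
            if eta <= 0:
                raise ValidationError(f"viscosity must be > 0, got {eta}")

    @property
    def rho(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def eta(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    def scaled(self, factor: float) -> "RheoDataset":
        """Copy with all concentrations multiplied by ``factor``."""
        return RheoDataset(
            points=[(rho * factor, eta, f) for rho, eta, f in self.points],
            temperature=self.temperature,
        )


@dataclass
class RossMintonFit:
    """Fitted Ross-Minton parameters.

    The curve is strictly increasing on its domain rho < 1 / (crowding_ratio
    * intrinsic_viscosity) and diverges at that singularity.
    """

    eta0: float  # mPa.s
    intrinsic_viscosity: float  # mL/mg
    crowding_ratio: float  # k/v, dimensionless
    eta0_mode: str  # "fixed" or "fitted"
    residual_norm: float

    @property
    def rho_max(self) -> float:
        """Upper edge of the valid concentration domain [mg/mL]."""
        if self.crowding_ratio <= 0:
            return np.inf
        return 1.0 / (self.crowding_ratio * self.intrinsic_viscosity)


def cone_plate_viscosity(
    torque: float, angular_velocity: float, cone_angle: float, cone_radius: float
) -> float:
    """Dynamic viscosity [mPa.s] from cone-plate torque.

    eta = 3 M alpha / (2 pi R^3 omega) with M in N.m, omega in rad/s,
    alpha in rad (small-angle regime, alpha <= 0.1 rad) and R in m.
    """
    if angular_velocity <= 0:
        raise ValidationError("angular velocity must be > 0")
    if cone_radius <= 0:
        raise ValidationError("cone radius must be > 0")
    if not 0 < cone_angle <= 0.1:
        raise ValidationError(
            "cone angle must be in (0, 0.1] rad: the uniform-shear formula "
            "holds only for shallow cones"
        )
    eta_pa_s = 3.0 * torque * cone_angle / (2.0 * np.pi * cone_radius**3 * angular_velocity)
    return eta_pa_s * 1e3


def ross_minton_eval(fit: RossMintonFit, rho: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted Ross-Minton curve at concentration rho [mg/mL]."""
    rho_arr = np.asarray(rho, dtype=float)
    denom = 1.0 - fit.crowding_ratio * fit.intrinsic_viscosity * rho_arr
    if np.any(denom <= 0):
        raise ValidationError(
            f"concentration at/beyond the model singularity {fit.rho_max:.1f} mg/mL"
        )
    out = fit.eta0 * np.exp(fit.intrinsic_viscosity * rho_arr / denom)
    return float(out) if np.isscalar(rho) else out


def _log_model(rho: np.ndarray, log_eta0: float, iv: float, ratio: float) -> np.ndarray:
    return log_eta0 + iv * rho / (1.0 - ratio * iv * rho)


def ross_minton_fit(
    data: RheoDataset,
    eta0_mode: str = "fitted",
    eta0_value: float | None = None,
) -> RossMintonFit:
    """Least-squares Ross-Minton fit on log viscosity.

    All points — filtered and unfiltered alike — enter the fit. With
    ``eta0_mode="fitted"`` (default) the buffer viscosity is a free
    parameter bounded to [0.5, 2.0] mPa.s; with ``"fixed"`` it is pinned to
    ``eta0_value``. Requires >= 4 points so the 3-parameter model is
    overdetermined.
    """
    if eta0_mode not in ("fitted", "fixed"):
        raise ValidationError("eta0_mode must be 'fitted' or 'fixed'")
    if eta0_mode == "fixed" and (eta0_value is None or eta0_value <= 0):
        raise ValidationError("fixed eta0_mode requires a positive eta0_value")
    rho, eta = data.rho, data.eta
    if rho.size < 4:
        raise ValidationError(f"Ross-Minton fit needs >= 4 points, got {rho.size}")
    log_eta = np.log(eta)
    rho_max = float(rho.max())
    # singularity must lie beyond the largest measured concentration:
    # ratio * iv < 1 / rho_max
    iv0 = max((log_eta.max() - log_eta.min()) / max(rho_max, 1.0), 1e-4)

    if eta0_mode == "fitted":
        def residuals(p: np.ndarray) -> np.ndarray:
            log_eta0, iv, ratio = p
            denom = 1.0 - ratio * iv * rho
            bad = denom <= 1e-9
            denom = np.where(bad, 1e-9, denom)
            r = log_eta0 + iv * rho / denom - log_eta
            return np.where(bad, 1e6, r)

        lb = [np.log(_ETA0_BOUNDS[0]), 1e-6, 0.0]
        ub = [np.log(_ETA0_BOUNDS[1]), 1.0, 50.0]
        x0s = [
            np.array([0.0, iv0, 0.3]),
            np.array([0.0, iv0 * 0.5, 1.0]),
            np.array([np.log(1.0), iv0 * 2.0, 0.1]),
        ]
    else:
        log_eta0_fixed = np.log(eta0_value)

        def residuals(p: np.ndarray) -> np.ndarray:
            iv, ratio = p
            denom = 1.0 - ratio * iv * rho
            bad = denom <= 1e-9
            denom = np.where(bad, 1e-9, denom)
            r = log_eta0_fixed + iv * rho / denom - log_eta
            return np.where(bad, 1e6, r)

        lb = [1e-6, 0.0]
        ub = [1.0, 50.0]
        x0s = [np.array([iv0, 0.3]), np.array([iv0 * 0.5, 1.0])]

    best = None
    for x0 in x0s:
        try:
            sol = least_squares(
                residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("Ross-Minton fit did not converge from any start")
    if eta0_mode == "fitted":
        log_eta0, iv, ratio = best.x
        eta0 = float(np.exp(log_eta0))
    else:
        iv, ratio = best.x
        eta0 = float(eta0_value)
    fit = RossMintonFit(
        eta0=eta0,
        intrinsic_viscosity=float(iv),
        crowding_ratio=float(ratio),
        eta0_mode=eta0_mode,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
    )
    if fit.rho_max <= rho_max:
        raise FitError(
            f"fitted singularity {fit.rho_max:.1f} mg/mL lies inside the data range"
        )
    return fit


def invert_concentration_closed_form(fit: RossMintonFit, eta: float) -> float:
    """Algebraic inversion of the Ross-Minton curve.

    With L = log(eta / eta0): [eta] rho / (1 - r [eta] rho) = L
    => rho = L / ([eta] (1 + r L)).
    """
    if eta <= fit.eta0:
        raise ValidationError(
            f"viscosity {eta} mPa.s must exceed the buffer viscosity {fit.eta0:.3g}"
        )
    L = np.log(eta / fit.eta0)
    return float(L / (fit.intrinsic_viscosity * (1.0 + fit.crowding_ratio * L)))


def invert_concentration(fit: RossMintonFit, eta: float) -> float:
    """Concentration [mg/mL] at which the fitted curve reaches ``eta``.

    Monotone root bracketing on the strictly increasing curve; agrees with
    :func:`invert_concentration_closed_form` to root-finder tolerance.
    """
    if eta <= fit.eta0:
        raise ValidationError(
            f"viscosity {eta} mPa.s must exceed the buffer viscosity {fit.eta0:.3g}"
        )
    # bracket and solve on log eta, which stays finite up to the singularity
    def log_excess(rho: float) -> float:
        denom = 1.0 - fit.crowding_ratio * fit.intrinsic_viscosity * rho
        return (
            np.log(fit.eta0)
            + fit.intrinsic_viscosity * rho / denom
            - np.log(eta)
        )

    hi = fit.rho_max * (1.0 - 1e-9) if np.isfinite(fit.rho_max) else None
    if hi is None:
        # crowding_ratio = 0: pure exponential, expand the bracket upward
        hi = 1.0
        while log_excess(hi) < 0:
            hi *= 2.0
    return float(brentq(log_excess, 0.0, hi, xtol=1e-12, rtol=1e-14))


def concentration_uncertainty_band(
    data: RheoDataset,
    relative_uncertainty: float,
    eta0_mode: str = "fitted",
    eta0_value: float | None = None,
) -> tuple[RossMintonFit, RossMintonFit]:
    """Ross-Minton fits under systematic concentration error.

    Refits with every concentration scaled by (1 - u) and (1 + u); the
    envelope of the two curves is the viscosity band induced by a relative
    concentration uncertainty u. Returns (lower-scaled fit, upper-scaled
    fit); at a given rho the lower-scaled fit is the steeper (upper) curve.
    """
    if not 0 <= relative_uncertainty < 0.5:
        raise ValidationError("relative_uncertainty must be in [0, 0.5)")
    u = relative_uncertainty
    fit_lo = ross_minton_fit(data.scaled(1.0 - u), eta0_mode, eta0_value)
    fit_hi = ross_minton_fit(data.scaled(1.0 + u), eta0_mode, eta0_value)
    return fit_lo, fit_hi


def load_rheo_dataset(path: str | Path, temperature: float = 297.0) -> RheoDataset:
    """Read a delimited text table (concentration, viscosity, filtered)."""
    df = pd.read_csv(path, sep=r"[,\t ]+", comment="#", engine="python")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValidationError(f"{path}: need at least concentration and viscosity columns")
    filt = df[cols[2]].astype(bool) if len(cols) > 2 else pd.Series(True, index=df.index)
    points = [
        (float(r), float(e), bool(f))
        for r, e, f in zip(df[cols[0]], df[cols[1]], filt)
    ]
    return RheoDataset(points=points, temperature=temperature)


def write_rheo_dataset(data: RheoDataset, path: str | Path) -> None:
    """Write a dataset in the same delimited layout the loader reads."""
    df = pd.DataFrame(
        data.points,
        columns=["concentration_mg_per_mL", "viscosity_mPa_s", "filtered"],
    )
    df["filtered"] = df["filtered"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def load_mab_dataset() -> RheoDataset:
    """The bundled mAb rheometry table (297 K, shear rate 1000 1/s)."""
    ref = resources.files("gkvisc.data") / "mab_rheometry_297K.tsv"
    with resources.as_file(ref) as path:
        return load_rheo_dataset(path, temperature=297.0)
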