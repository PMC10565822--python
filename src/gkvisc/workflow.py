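"""End-to-end pipelines tying the analysis stages together.

The canonical flow per trajectory is

    pressure tensor -> shear channels -> channel-averaged ACF
                    -> running Green-Kubo integral

followed ensemble-wide by

    per-trajectory curves -> mean / sigma(t) -> power-law fit of sigma
                          -> t^-b weighted multi-exponential fit of the mean
                          -> per-set fits and aggregated estimate.

:class:`RunConfig` captures every knob with a documented default and
round-trips through YAML; the CLI is a thin wrapper over the functions
here, which are equally usable from Python.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from . import correlation, green_kubo, pressure_io, resampling, rheometry, synthetic
from .errors import FitError, GkviscError, ValidationError
from .green_kubo import RunningViscosityCurve, RunningViscosityEnsemble
from .time_decomposition import (
    MultiExpFit,
    PowerLawFit,
    ViscosityEstimate,
    fit_multiexponential,
    fit_power_law,
    aggregate_sets,
)

logger = logging.getLogger("gkvisc")


@dataclass
class RunConfig:
    """All pipeline options with their defaults.

    Input is either a list of XVG/tabular files (``inputs`` +
    ``volume``/``temperature`` metadata) or a synthetic ensemble
    (``synthetic: true`` with OU modes). Every option is overridable from
    the CLI; the config round-trips losslessly through YAML.
    """

    # --- input ---
    inputs: list[str] = field(default_factory=list)
    volume: float | None = None          # nm^3
    temperature: float | None = None     # K
    column_map: dict[str, int] = field(default_factory=dict)
    n_sets: int = 3
    # --- synthetic input ---
    synthetic: bool = False
    ou_modes: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.5, 1.0), (0.05, 50.0)]
    )
    time_step: float = 0.1               # ps
    n_steps: int = 100_000
    n_trajectories: int = 12
    # --- ACF ---
    max_lag: float | None = None         # ps; None = full span
    estimator: str = "unbiased"
    subtract_mean: bool = False
    # --- fits ---
    form: str = "triexponential"
    fit_range: tuple[float, float] | None = None
    restarts: int = 16
    max_fit_points: int = 4000
    # --- bootstrap ---
    subset_sizes: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50, 60])
    draws_per_size: int = 100
    b_source: str = "refit"
    # --- rheology ---
    rheo_data: str | None = None         # None = bundled mAb table
    eta0_mode: str = "fitted"
    eta0_value: float | None = None
    concentration_uncertainty: float = 0.10
    invert_at: list[float] = field(default_factory=list)  # mPa.s
    # --- misc ---
    seed: int = 0
    output_dir: str = "gkvisc_out"

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ou_modes"] = [list(m) for m in d["ou_modes"]]
        if d["fit_range"] is not None:
            d["fit_range"] = list(d["fit_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "ou_modes" in d:
            d["ou_modes"] = [tuple(m) for m in d["ou_modes"]]
        if d.get("fit_range") is not None:
            d["fit_range"] = tuple(d["fit_range"])
        return cls(**d)


def trajectory_running_curve(
    series: pressure_io.PressureTensorSeries,
    max_lag: float | None = None,
    estimator: str = "unbiased",
    subtract_mean: bool = False,
) -> RunningViscosityCurve:
    """Channel-averaged ACF and running integral of one trajectory."""
    channels = correlation.combine_components(series)
    acf = correlation.average_acfs(
        [channels], max_lag=max_lag, estimator=estimator, subtract_mean=subtract_mean
    )
    return green_kubo.running_integral(
        acf, series.volume, series.temperature, source=series.trajectory_id
    )


def ensemble_running_curves(
    trajectories: Iterable[pressure_io.PressureTensorSeries],
    set_ids: Sequence[str] | None = None,
    max_lag: float | None = None,
    estimator: str = "unbiased",
    subtract_mean: bool = False,
) -> RunningViscosityEnsemble:
    """Per-trajectory running integrals for an ensemble, grouped by set.

    ``trajectories`` may be a lazy iterable: each series is reduced to its
    running-integral curve and released, so arbitrarily long ensembles fit
    in memory as long as one trajectory does.
    """
    curves: list[RunningViscosityCurve] = []
    sets: dict[str, list[int]] = {}
    for i, series in enumerate(trajectories):
        curve = trajectory_running_curve(
            series, max_lag=max_lag, estimator=estimator, subtract_mean=subtract_mean
        )
        label = set_ids[i] if set_ids is not None else series.set_id
        sets.setdefault(label, []).append(i)
        curves.append(curve)
    if len(curves) < 2:
        raise ValidationError("ensemble pipeline needs >= 2 trajectories")
    return green_kubo.build_ensemble(curves, sets=sets)


def synthetic_running_curves(
    spec: synthetic.OuSpec,
    n_trajectories: int,
    sets: int = 3,
    max_lag: float | None = None,
    estimator: str = "unbiased",
) -> RunningViscosityEnsemble:
    """Streamed synthetic-ensemble pipeline (one trajectory in memory at a time)."""
    if sets < 1 or n_trajectories % sets != 0:
        raise ValidationError("n_trajectories must be divisible by sets")
    per_set = n_trajectories // sets
    rngs = synthetic.trajectory_rngs(spec, n_trajectories)

    def gen():
        for i, rng in enumerate(rngs):
            yield synthetic.generate_series(
                spec, rng, trajectory_id=f"ou{i:03d}", set_id=f"set{i // per_set}"
            )

    return ensemble_running_curves(gen(), max_lag=max_lag, estimator=estimator)


def _load_trajectories(config: RunConfig) -> list[pressure_io.PressureTensorSeries]:
    out = []
    n_sets = max(config.n_sets, 1)
    per_set = max(len(config.inputs) // n_sets, 1)
    for i, path in enumerate(config.inputs):
        set_id = f"set{min(i // per_set, n_sets - 1)}"
        if config.column_map:
            if config.volume is None or config.temperature is None:
                raise ValidationError("volume and temperature are required for XVG input")
            series = pressure_io.read_xvg(
                path, config.volume, config.temperature, config.column_map,
                set_id=set_id,
            )
        else:
            series = pressure_io.read_tabular(
                path, volume=config.volume, temperature=config.temperature
            )
            series.set_id = set_id
        out.append(series)
    return out


def _config_ensemble(config: RunConfig) -> RunningViscosityEnsemble:
    if config.synthetic:
        spec = synthetic.OuSpec(
            modes=list(config.ou_modes),
            time_step=config.time_step,
            n_steps=config.n_steps,
            volume=config.volume or 100.0,
            temperature=config.temperature or 298.0,
            seed=config.seed,
        )
        logger.info(
            "synthetic ensemble: %d trajectories x %d steps, analytic eta = %.4g mPa.s",
            config.n_trajectories, config.n_steps, synthetic.analytic_viscosity(spec),
        )
        return synthetic_running_curves(
            spec, config.n_trajectories, sets=config.n_sets,
            max_lag=config.max_lag, estimator=config.estimator,
        )
    trajectories = _load_trajectories(config)
    if len(trajectories) == 1:
        raise ValidationError(
            "a single trajectory yields no sigma(t); supply >= 2 trajectories "
            "or use fit_single_trajectory()"
        )
    return ensemble_running_curves(
        trajectories, max_lag=config.max_lag, estimator=config.estimator,
        subtract_mean=config.subtract_mean,
    )


def fit_single_trajectory(
    curve: RunningViscosityCurve, config: RunConfig
) -> MultiExpFit:
    """Degenerate one-trajectory path: unweighted (b = 0) fit with a warning."""
    logger.warning(
        "only one trajectory: sigma(t) unavailable, skipping the power-law "
        "stage and fitting with uniform weights"
    )
    return fit_multiexponential(
        curve, b=0.0, form=config.form, fit_range=config.fit_range,
        restarts=config.restarts, seed=config.seed,
        max_fit_points=config.max_fit_points,
    )


def _write_curve(path: Path, times: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    header = "time_ps\t" + "\t".join(columns)
    mat = np.column_stack([times] + list(columns.values()))
    np.savetxt(path, mat, header=header, delimiter="\t", comments="")


def run_viscosity(config: RunConfig) -> dict:
    """Full viscosity pipeline; writes curves, fits and a JSON summary.

    Returns the summary dictionary (also written to ``summary.json``):
    power-law (A, b), combined and per-set asymptotic viscosities, and the
    aggregated uncertainty.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble = _config_ensemble(config)
    plaw = fit_power_law(
        (ensemble.times, ensemble.sigma_curve), fit_range=config.fit_range
    )
    logger.info("power law: sigma(t) = %.4g * t^%.3f", plaw.A, plaw.b)
    combined = fit_multiexponential(
        (ensemble.times, ensemble.mean_curve), b=plaw.b, form=config.form,
        fit_range=config.fit_range, restarts=config.restarts, seed=config.seed,
        max_fit_points=config.max_fit_points,
    )
    set_fits: dict[str, MultiExpFit] = {}
    for label, mean in ensemble.set_means.items():
        set_fits[label] = fit_multiexponential(
            (ensemble.times, mean), b=plaw.b, form=config.form,
            fit_range=config.fit_range, restarts=config.restarts,
            seed=config.seed, max_fit_points=config.max_fit_points, x0=combined,
        )
    estimate: ViscosityEstimate | None = None
    if len(set_fits) >= 2:
        estimate = aggregate_sets(list(set_fits.values()), combined)

    _write_curve(
        out / "running_integrals.tsv", ensemble.times,
        {f"eta_{src}" : ensemble.per_trajectory[i]
         for i, src in enumerate(ensemble.sources)},
    )
    _write_curve(
        out / "ensemble_curves.tsv", ensemble.times,
        {"mean_eta_mPa_s": ensemble.mean_curve, "sigma_mPa_s": ensemble.sigma_curve,
         **{f"mean_{lbl}": m for lbl, m in ensemble.set_means.items()}},
    )
    summary = {
        "n_trajectories": ensemble.n,
        "power_law": {"A": plaw.A, "b": plaw.b},
        "combined": {
            "eta_infinity_mPa_s": combined.eta_infinity,
            "form": combined.form,
            "B": combined.B, "alpha": combined.alpha, "beta": combined.beta,
            "taus_ps": list(combined.taus),
            "converged": combined.converged,
        },
        "set_eta_mPa_s": {lbl: f.eta_infinity for lbl, f in set_fits.items()},
    }
    if estimate is not None:
        summary["estimate"] = {
            "eta_mPa_s": estimate.combined_eta,
            "uncertainty_mPa_s": estimate.uncertainty,
            "sample_std_mPa_s": estimate.sample_std,
            "n_sets": estimate.n_sets,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("viscosity: %.4g mPa.s", combined.eta_infinity)
    return summary


def run_bootstrap(config: RunConfig) -> resampling.BootstrapResult:
    """Bootstrap convergence analysis; writes per-size mean/std table."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble = _config_ensemble(config)
    sizes = [s for s in config.subset_sizes if s <= ensemble.n]
    if not sizes:
        raise ValidationError(
            f"no subset size <= N = {ensemble.n}; adjust subset_sizes"
        )
    plaw = fit_power_law((ensemble.times, ensemble.sigma_curve),
                         fit_range=config.fit_range)
    warm = fit_multiexponential(
        (ensemble.times, ensemble.mean_curve), b=plaw.b, form=config.form,
        fit_range=config.fit_range, restarts=config.restarts, seed=config.seed,
        max_fit_points=config.max_fit_points,
    )
    result = resampling.bootstrap_viscosity(
        ensemble.per_trajectory,
        times=ensemble.times,
        subset_sizes=sizes,
        draws_per_size=config.draws_per_size,
        b_source=config.b_source,
        fixed_b=plaw.b,
        form=config.form,
        fit_range=config.fit_range,
        warm_start=warm,
        seed=config.seed,
    )
    table = np.column_stack([result.subset_sizes, result.mean_eta, result.std_eta])
    np.savetxt(
        out / "bootstrap.tsv", table,
        header="subset_size\tmean_eta_mPa_s\tstd_eta_mPa_s",
        delimiter="\t", comments="",
    )
    return result


def run_rheo(config: RunConfig) -> dict:
    """Ross-Minton fit, uncertainty band, and requested inversions."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = (
        rheometry.load_rheo_dataset(config.rheo_data)
        if config.rheo_data
        else rheometry.load_mab_dataset()
    )
    fit = rheometry.ross_minton_fit(data, config.eta0_mode, config.eta0_value)
    band = None
    if config.concentration_uncertainty > 0:
        band = rheometry.concentration_uncertainty_band(
            data, config.concentration_uncertainty,
            config.eta0_mode, config.eta0_value,
        )
    inversions = {}
    for eta in config.invert_at:
        inversions[eta] = rheometry.invert_concentration(fit, eta)
    summary = {
        "eta0_mPa_s": fit.eta0,
        "intrinsic_viscosity_mL_per_mg": fit.intrinsic_viscosity,
        "crowding_ratio": fit.crowding_ratio,
        "residual_norm": fit.residual_norm,
        "inversions_mg_per_mL": inversions,
    }
    if band is not None:
        summary["band"] = {
            "relative_uncertainty": config.concentration_uncertainty,
            "lower_scaled": {
                "eta0": band[0].eta0,
                "intrinsic_viscosity": band[0].intrinsic_viscosity,
                "crowding_ratio": band[0].crowding_ratio,
            },
            "upper_scaled": {
                "eta0": band[1].eta0,
                "intrinsic_viscosity": band[1].intrinsic_viscosity,
                "crowding_ratio": band[1].crowding_ratio,
            },
        }
    (out / "rheometry.json").write_text(json.dumps(summary, indent=2))
    return summary
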