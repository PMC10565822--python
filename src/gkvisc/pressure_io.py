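"""Reading, validating and writing pressure-tensor time series.

Units are fixed at this boundary: time in ps, pressure components in bar,
box volume in nm^3, temperature in K. All unit conversion happens exactly
once, in :mod:`gkvisc.green_kubo`.

Two text dialects are understood:

* XVG-style energy output: ``#`` comment and ``@`` directive lines followed
  by whitespace-delimited numeric rows, first column time [ps].
* Plain tabular: a header row naming the columns (``time`` plus component
  labels), delimiter auto-detected among comma / tab / whitespace, with the
  box volume, temperature and time step carried in ``#``-comment metadata
  lines. :func:`write_series` emits this dialect and :func:`read_tabular`
  reads it back losslessly.

Volume and temperature are caller-supplied metadata for XVG input: energy
files do not reliably carry them, and for constant-volume runs they are
single numbers per trajectory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ColumnMapError, NonUniformTimeGridError, ParseError, ValidationError

#: All recognised tensor-component labels.
COMPONENT_LABELS = ("xx", "yy", "zz", "xy", "xz", "yz", "yx", "zx", "zy")

#: Off-diagonal labels paired with their transposes.
OFF_DIAGONAL_PAIRS = (("xy", "yx"), ("xz", "zx"), ("yz", "zy"))

DIAGONAL_LABELS = ("xx", "yy", "zz")

_TIME_GRID_RTOL = 1e-6


@dataclass
class PressureTensorSeries:
    """One trajectory's pressure-tensor components on a uniform time grid.

    Parameters
    ----------
    time_step:
        Sampling interval [ps], strictly positive.
    components:
        Mapping from component label (subset of ``xx yy zz xy xz yz yx zx
        zy``) to a 1-D array of pressures [bar]. All arrays share one
        length >= 2, and each off-diagonal pair (xy/yx, xz/zx, yz/zy) has at
        least one member present.
    volume:
        Box volume [nm^3] (constant over an NVT trajectory).
    temperature:
        Temperature [K].
    trajectory_id, set_id:
        Opaque provenance labels; ``set_id`` records which repeat set the
        trajectory was spawned from.
    start_time:
        Time of the first sample [ps]; irrelevant for stationary analysis
        but preserved for round-tripping.
    """

    time_step: float
    components: dict[str, np.ndarray]
    volume: float
    temperature: float
    trajectory_id: str = "traj"
    set_id: str = "set0"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValidationError(f"time_step must be > 0, got {self.time_step}")
        if self.volume <= 0:
            raise ValidationError(f"volume must be > 0 nm^3, got {self.volume}")
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.components:
            raise ValidationError("components map is empty")
        clean: dict[str, np.ndarray] = {}
        lengths = set()
        for label, values in self.components.items():
            if label not in COMPONENT_LABELS:
                raise ValidationError(f"unknown component label {label!r}")
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"component {label!r} is not a 1-D sequence")
            lengths.add(arr.shape[0])
            clean[label] = arr
        if len(lengths) != 1:
            raise ValidationError(f"component lengths differ: {sorted(lengths)}")
        (n,) = lengths
        if n < 2:
            raise ValidationError(f"need at least 2 samples per component, got {n}")
        for a, b in OFF_DIAGONAL_PAIRS:
            if a not in clean and b not in clean:
                raise ValidationError(
                    f"off-diagonal component {a!r} (or its transpose {b!r}) is required"
                )
        self.components = clean

    @property
    def n_steps(self) -> int:
        return next(iter(self.components.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times [ps]."""
        return self.start_time + self.time_step * np.arange(self.n_steps)

    @property
    def has_diagonals(self) -> bool:
        return all(lbl in self.components for lbl in DIAGONAL_LABELS)


@dataclass
class EnsembleLayout:
    """A set-partitioned collection of trajectories.

    ``sets`` maps a set label to the indices of its trajectories; the
    partition must be disjoint and cover every trajectory. The design of the
    reference workflow is 3 sets x 21 trajectories, but any disjoint cover
    is accepted.
    """

    trajectories: list[PressureTensorSeries]
    sets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            # default: group by each trajectory's set_id, preserving order
            groups: dict[str, list[int]] = {}
            for i, traj in enumerate(self.trajectories):
                groups.setdefault(traj.set_id, []).append(i)
            self.sets = groups
        seen: list[int] = []
        for indices in self.sets.values():
            seen.extend(indices)
        if sorted(seen) != list(range(len(self.trajectories))):
            raise ValidationError(
                "sets must form a disjoint partition covering all trajectories"
            )

    def __len__(self) -> int:
        return len(self.trajectories)

    def set_trajectories(self, set_label: str) -> list[PressureTensorSeries]:
        return [self.trajectories[i] for i in self.sets[set_label]]


def _numeric_rows(path: Path) -> list[list[str]]:
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#") or stripped.startswith("@"):
            continue
        rows.append(re.split(r"[,\t ]+", stripped))
    return rows


def _parse_cell(cell: str, path: Path) -> float:
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell {cell!r}") from exc


def _infer_time_step(times: np.ndarray, path: Path) -> float:
    dt = times[1] - times[0]
    if dt <= 0:
        raise NonUniformTimeGridError(f"{path}: time column is not increasing")
    diffs = np.diff(times)
    if not np.allclose(diffs, dt, rtol=_TIME_GRID_RTOL, atol=0.0):
        worst = int(np.argmax(np.abs(diffs - dt)))
        raise NonUniformTimeGridError(
            f"{path}: non-uniform time grid (spacing {diffs[worst]:g} ps at row "
            f"{worst + 1} vs {dt:g} ps elsewhere)"
        )
    return float(dt)


def read_xvg(
    path: str | Path,
    volume: float,
    temperature: float,
    column_map: Mapping[str, int],
    trajectory_id: str | None = None,
    set_id: str = "set0",
) -> PressureTensorSeries:
    """Read an XVG-style energy file into a :class:`PressureTensorSeries`.

    Parameters
    ----------
    path:
        File with ``#``/``@`` header lines and whitespace-delimited numeric
        rows; column 0 is time [ps].
    volume, temperature:
        Box volume [nm^3] and temperature [K]; supplied as metadata, never
        parsed from the file.
    column_map:
        Component label -> column index (0 = time column, so data indices
        start at 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pressure file not found: {path}")
    if not column_map:
        raise ColumnMapError(f"{path}: empty column_map")
    rows = _numeric_rows(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, got {len(rows)}")
    width = min(len(r) for r in rows)
    for label, col in column_map.items():
        if not 1 <= col < width:
            raise ColumnMapError(
                f"{path}: column {col} for component {label!r} out of range "
                f"(rows have {width} columns; column 0 is time)"
            )
    data = np.array(
        [[_parse_cell(c, path) for c in row] for row in rows], dtype=float
    )
    times = data[:, 0]
    dt = _infer_time_step(times, path)
    components = {label: data[:, col].copy() for label, col in column_map.items()}
    return PressureTensorSeries(
        time_step=dt,
        components=components,
        volume=volume,
        temperature=temperature,
        trajectory_id=trajectory_id or path.stem,
        set_id=set_id,
        start_time=float(times[0]),
    )


def write_series(series: PressureTensorSeries, path: str | Path) -> None:
    """Write a series as self-describing delimited text.

    The header carries volume, temperature, time step, provenance labels and
    the component order; values are printed at full (round-trippable) float
    precision so ``read_tabular(write_series(s)) == s``.
    """
    path = Path(path)
    if not series.components:
        raise ValidationError("refusing to write a series with no components")
    labels = list(series.components)
    header = [
        f"# gkvisc pressure-tensor series",
        f"# trajectory_id = {series.trajectory_id}",
        f"# set_id = {series.set_id}",
        f"# volume_nm3 = {series.volume!r}",
        f"# temperature_K = {series.temperature!r}",
        f"# time_step_ps = {series.time_step!r}",
        "time\t" + "\t".join(labels),
    ]
    mat = np.column_stack([series.times] + [series.components[l] for l in labels])
    lines = ["\t".join(repr(float(v)) for v in row) for row in mat]
    path.write_text("\n".join(header + lines) + "\n")


def read_tabular(
    path: str | Path,
    volume: float | None = None,
    temperature: float | None = None,
) -> PressureTensorSeries:
    """Read the plain tabular dialect produced by :func:`write_series`.

    Volume and temperature are taken from ``# volume_nm3 = ...`` /
    ``# temperature_K = ...`` metadata comments when present; explicit
    arguments override the metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pressure file not found: {path}")
    meta: dict[str, str] = {}
    header_labels: list[str] | None = None
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#") or stripped.startswith("@"):
            m = re.match(r"[#@]\s*(\w+)\s*=\s*(\S+)", stripped)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        cells = re.split(r"[,\t ]+", stripped)
        if header_labels is None:
            try:
                float(cells[0])
            except ValueError:
                header_labels = cells
                continue
            header_labels = ["time"] + [
                f"c{i}" for i in range(1, len(cells))
            ]  # headerless fallback
        rows.append(cells)
    if header_labels is None or len(rows) < 2:
        raise ParseError(f"{path}: need a header and at least 2 data rows")
    if header_labels[0].lower() not in ("time", "t", "time_ps"):
        raise ParseError(f"{path}: first column must be time, got {header_labels[0]!r}")
    data = np.array([[_parse_cell(c, path) for c in row] for row in rows], dtype=float)
    if data.shape[1] != len(header_labels):
        raise ParseError(f"{path}: row width does not match header")
    times = data[:, 0]
    dt = _infer_time_step(times, path)
    vol = volume if volume is not None else float(meta.get("volume_nm3", "nan"))
    temp = temperature if temperature is not None else float(meta.get("temperature_K", "nan"))
    if not np.isfinite(vol) or not np.isfinite(temp):
        raise ParseError(
            f"{path}: volume/temperature missing from both metadata and arguments"
        )
    components = {
        label: data[:, i].copy() for i, label in enumerate(header_labels) if i > 0
    }
    return PressureTensorSeries(
        time_step=dt,
        components=components,
        volume=vol,
        temperature=temp,
        trajectory_id=meta.get("trajectory_id", path.stem),
        set_id=meta.get("set_id", "set0"),
        start_time=float(times[0]),
    )
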