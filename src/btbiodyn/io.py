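"""Readers and writers for the package's two text formats.

* Kinetics: comma-separated, dot-decimal, UTF-8, with the fixed header
  ``time_h,biomass_g_per_l,phb_g_per_l,dpa_g_per_l,cry_g_per_l``. An optional
  JSON sidecar ``<file>.limits.json`` records the detection limits used when
  the file was generated; when present, exact-zero values of compounds with a
  positive limit are re-flagged as censored on read.
* Parameter sets: flat ``key = value`` config whose keys mirror the standard
  nomenclature (x_max, mu_max, t_c, …, y_cry_phb, plus optional
  glucose_g_per_l / soybean_g_per_l / label). Floats are written with repr so
  a write/read round-trip is bitwise lossless.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .model_core import (
    COMPOUNDS,
    BiodynamicParameters,
    GompertzParams,
    Trajectory,
    YieldCoefficients,
)
from .synthetic_data import KineticsSeries

__all__ = [
    "KINETICS_COLUMNS",
    "PARAMETER_KEYS",
    "KineticsIOError",
    "read_kinetics",
    "write_kinetics",
    "write_trajectory",
    "read_parameters",
    "write_parameters",
]

KINETICS_COLUMNS = ["time_h", "biomass_g_per_l", "phb_g_per_l", "dpa_g_per_l", "cry_g_per_l"]
_COLUMN_TO_COMPOUND = dict(zip(KINETICS_COLUMNS[1:], COMPOUNDS))

#: required numeric keys of a parameter config, in canonical order
PARAMETER_KEYS = [
    "x_max", "mu_max", "t_c",
    "phb_max", "mu_max_p", "t_c_p",
    "dpa_max", "mu_max_d", "t_c_d",
    "cry_max", "mu_max_c", "t_c_c",
    "y_dpa_x", "y_dpa_phb", "y_cry_phb",
]
_OPTIONAL_KEYS = ["glucose_g_per_l", "soybean_g_per_l", "label"]


class KineticsIOError(ValueError):
    """A kinetics or parameter file violated the fixed dialect."""


def _limits_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".limits.json")


def read_kinetics(path, detection_limits: dict[str, float] | None = None) -> KineticsSeries:
    """Parse a kinetics CSV; errors carry 1-based line numbers.

    ``detection_limits`` (or the ``.limits.json`` sidecar, if present) marks
    exact-zero values of compounds with a positive limit as censored.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise KineticsIOError(f"{path}: file is empty") from None
        header = [h.strip() for h in header]
        for col in KINETICS_COLUMNS:
            if col not in header:
                raise KineticsIOError(f"{path}: missing column {col!r}")
        idx = {col: header.index(col) for col in KINETICS_COLUMNS}

        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(header):
                raise KineticsIOError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            parsed = []
            for col in KINETICS_COLUMNS:
                cell = row[idx[col]].strip()
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise KineticsIOError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}"
                    ) from None
            rows.append(parsed)

    if len(rows) == 0:
        raise KineticsIOError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    times = data[:, 0]
    if np.unique(times).size != times.size:
        raise KineticsIOError(f"{path}: duplicate time values")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise KineticsIOError(f"{path}: times must be strictly increasing")

    if detection_limits is None:
        sidecar = _limits_sidecar(path)
        if sidecar.exists():
            detection_limits = json.loads(sidecar.read_text(encoding="utf-8"))

    values = {name: data[:, 1 + i] for i, name in enumerate(COMPOUNDS)}
    censored = {}
    for name in COMPOUNDS:
        limit = (detection_limits or {}).get(name, 0.0)
        censored[name] = (values[name] == 0.0) & (limit > 0.0)
    return KineticsSeries(
        times=times,
        censored=censored,
        detection_limits=dict(detection_limits) if detection_limits else None,
        **values,
    )


def _write_table(path: Path, times, columns: dict[str, np.ndarray]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(KINETICS_COLUMNS)
        arrays = [times] + [columns[name] for name in COMPOUNDS]
        for row in zip(*arrays):
            writer.writerow([repr(float(v)) for v in row])


def write_kinetics(
    series: KineticsSeries, path, detection_limits: dict[str, float] | None = None
) -> None:
    """Write a kinetics series; detection limits (given or carried by the
    series) are recorded in the ``.limits.json`` sidecar."""
    path = Path(path)
    _write_table(path, series.times, {name: series.compound(name) for name in COMPOUNDS})
    if detection_limits is None:
        detection_limits = series.detection_limits
    if detection_limits is not None:
        _limits_sidecar(path).write_text(
            json.dumps(detection_limits, indent=0, sort_keys=True) + "\n", encoding="utf-8"
        )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a simulated trajectory in the standard kinetics layout."""
    _write_table(Path(path), traj.times, {name: traj.compound(name) for name in COMPOUNDS})


def read_parameters(path) -> BiodynamicParameters:
    """Parse a flat key=value parameter config into a validated parameter set."""
    path = Path(path)
    raw: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise KineticsIOError(f"{path}:{lineno}: expected 'key = value', got {stripped!r}")
        key, _, value = stripped.partition("=")
        key = key.strip()
        if key not in PARAMETER_KEYS and key not in _OPTIONAL_KEYS:
            raise KineticsIOError(f"{path}:{lineno}: unknown key {key!r}")
        if key in raw:
            raise KineticsIOError(f"{path}:{lineno}: duplicate key {key!r}")
        raw[key] = value.strip()

    missing = [k for k in PARAMETER_KEYS if k not in raw]
    if missing:
        raise KineticsIOError(f"{path}: missing required key(s): {', '.join(missing)}")

    num: dict[str, float] = {}
    for key in PARAMETER_KEYS + [k for k in ("glucose_g_per_l", "soybean_g_per_l") if k in raw]:
        try:
            num[key] = float(raw[key])
        except ValueError:
            raise KineticsIOError(f"{path}: non-numeric value for {key!r}: {raw[key]!r}") from None

    try:
        return BiodynamicParameters(
            biomass=GompertzParams(num["x_max"], num["mu_max"], num["t_c"]),
            phb=GompertzParams(num["phb_max"], num["mu_max_p"], num["t_c_p"]),
            dpa=GompertzParams(num["dpa_max"], num["mu_max_d"], num["t_c_d"]),
            cry=GompertzParams(num["cry_max"], num["mu_max_c"], num["t_c_c"]),
            yields=YieldCoefficients(num["y_dpa_x"], num["y_dpa_phb"], num["y_cry_phb"]),
            label=raw.get("label", ""),
            initial_glucose=num.get("glucose_g_per_l"),
            initial_soybean=num.get("soybean_g_per_l"),
        )
    except ValueError as err:
        raise KineticsIOError(f"{path}: {err}") from None


def write_parameters(params: BiodynamicParameters, path) -> None:
    """Write a parameter set as a flat config; floats via repr (lossless)."""
    lines = []
    for compound, prefix in (("biomass", ""), ("phb", "_p"), ("dpa", "_d"), ("cry", "_c")):
        g = params.gompertz(compound)
        name_max = {"biomass": "x_max", "phb": "phb_max", "dpa": "dpa_max", "cry": "cry_max"}[compound]
        lines.append(f"{name_max} = {g.asymptote!r}")
        lines.append(f"mu_max{prefix} = {g.rate!r}")
        lines.append(f"t_c{prefix} = {g.critical_time!r}")
    y = params.yields
    lines.append(f"y_dpa_x = {y.dpa_from_biomass!r}")
    lines.append(f"y_dpa_phb = {y.dpa_from_phb!r}")
    lines.append(f"y_cry_phb = {y.cry_from_phb!r}")
    if params.initial_glucose is not None:
        lines.append(f"glucose_g_per_l = {params.initial_glucose!r}")
    if params.initial_soybean is not None:
        lines.append(f"soybean_g_per_l = {params.initial_soybean!r}")
    if params.label:
        lines.append(f"label = {params.label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
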