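"""Readers and writers for the package's delimited-text and JSON formats.

Dispersion CSV dialect (one row per point):
``residue,nucleus,field_T,temp_K,t_cpmg_s,nu_cpmg_hz,r2eff_s1,sigma_s1``.
Rate-series CSV: ``temp_C`` or ``temp_K`` plus
``kex_s1,kex_sigma_s1,pE,pE_sigma`` (pE as a fraction).  State
trajectories are single-column integer CSV, feature trajectories
two-column float CSV; both carry the frame interval in a ``# dt=``
header comment.  JSON output is canonical (sorted keys, fixed float
repr) so identical inputs produce byte-identical files.

Parsing is locale-independent: only the decimal point is accepted.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import KELVIN_OFFSET
from .cpmg import DispersionDataset, DispersionProfile
from .msm import FeatureTraj, StateTraj
from .thermokinetics import RateSeries

__all__ = [
    "read_dispersion_csv",
    "write_dispersion_csv",
    "read_rate_series",
    "experimental_rates",
    "read_state_traj",
    "write_state_traj",
    "read_feature_traj",
    "write_feature_traj",
    "write_json",
    "read_json",
]

_DISPERSION_COLUMNS = [
    "residue", "nucleus", "field_T", "temp_K", "t_cpmg_s",
    "nu_cpmg_hz", "r2eff_s1", "sigma_s1",
]


def _parse_float(token: str, path, line_no: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}:{line_no}: cannot parse {column}={token!r} as a number "
            "(decimal point only)"
        ) from None


def read_dispersion_csv(path) -> DispersionDataset:
    """Read a dispersion dataset, validating every row with line numbers."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header != _DISPERSION_COLUMNS:
        raise ValueError(
            f"{path}:1: bad header {header}; expected {_DISPERSION_COLUMNS}"
        )
    groups: dict[tuple, dict] = {}
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        tokens = [t.strip() for t in line.split(",")]
        if len(tokens) != len(_DISPERSION_COLUMNS):
            raise ValueError(f"{path}:{line_no}: expected {len(_DISPERSION_COLUMNS)} fields")
        residue, nucleus = tokens[0], tokens[1]
        field_t = _parse_float(tokens[2], path, line_no, "field_T")
        temp_k = _parse_float(tokens[3], path, line_no, "temp_K")
        t_cpmg = _parse_float(tokens[4], path, line_no, "t_cpmg_s")
        nu = _parse_float(tokens[5], path, line_no, "nu_cpmg_hz")
        r2 = _parse_float(tokens[6], path, line_no, "r2eff_s1")
        sg = _parse_float(tokens[7], path, line_no, "sigma_s1")
        if nu <= 0:
            raise ValueError(f"{path}:{line_no}: nu_cpmg_hz must be positive")
        if sg < 0:
            raise ValueError(f"{path}:{line_no}: sigma_s1 must be non-negative")
        key = (residue, nucleus, field_t, temp_k, t_cpmg)
        g = groups.setdefault(key, {"nu": [], "r2": [], "sg": []})
        g["nu"].append(nu)
        g["r2"].append(r2)
        g["sg"].append(sg)
    profiles = [
        DispersionProfile(
            residue=k[0], nucleus=k[1], field_t=k[2], temperature_k=k[3],
            t_cpmg=k[4], nu_cpmg=g["nu"], r2eff=g["r2"], sigma=g["sg"],
        )
        for k, g in groups.items()
    ]
    return DispersionDataset(profiles)


def write_dispersion_csv(path, dataset: DispersionDataset) -> None:
    path = Path(path)
    rows = [",".join(_DISPERSION_COLUMNS)]
    for p in dataset.profiles:
        for nu, r2, sg in zip(p.nu_cpmg, p.r2eff, p.sigma):
            rows.append(
                f"{p.residue},{p.nucleus},{float(p.field_t)!r},{float(p.temperature_k)!r},"
                f"{float(p.t_cpmg)!r},{float(nu)!r},{float(r2)!r},{float(sg)!r}"
            )
    path.write_text("\n".join(rows) + "\n")


def read_rate_series(path) -> RateSeries:
    """Read a (temperature, kex, pE) series with uncertainties.

    Temperatures may be given as ``temp_C`` or ``temp_K``; they are
    stored in kelvin (°C + 273.15 exactly)."""
    import pandas as pd

    df = pd.read_csv(path)
    if "temp_K" in df.columns:
        t_k = df["temp_K"].to_numpy(float)
    elif "temp_C" in df.columns:
        t_k = df["temp_C"].to_numpy(float) + KELVIN_OFFSET
    else:
        raise ValueError(f"{path}: need a temp_C or temp_K column")
    for col in ("kex_s1", "pE"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return RateSeries(
        temperature_k=t_k,
        kex=df["kex_s1"].to_numpy(float),
        p_e=df["pE"].to_numpy(float),
        kex_sigma=df["kex_sigma_s1"].to_numpy(float) if "kex_sigma_s1" in df else None,
        pe_sigma=df["pE_sigma"].to_numpy(float) if "pE_sigma" in df else None,
    )


def experimental_rates() -> RateSeries:
    """The packaged experimental (T, kex, pE) series at 1-20.4 °C."""
    with resources.as_file(resources.files("confex.data").joinpath("experimental_rates.csv")) as p:
        return read_rate_series(p)


def _read_traj_lines(path):
    path = Path(path)
    dt = None
    rows = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "dt=" in line:
                dt = float(line.split("dt=")[1].split()[0])
            continue
        rows.append((line_no, line))
    if dt is None:
        raise ValueError(f"{path}: missing '# dt=<seconds>' header comment")
    return dt, rows


def read_state_traj(path) -> StateTraj:
    dt, rows = _read_traj_lines(path)
    states = []
    for line_no, line in rows:
        try:
            states.append(int(line))
        except ValueError:
            raise ValueError(f"{path}:{line_no}: not an integer state id: {line!r}") from None
    return StateTraj(np.asarray(states, dtype=np.int64), dt)


def write_state_traj(path, traj: StateTraj) -> None:
    lines = [f"# dt={float(traj.dt)!r}"] + [str(int(s)) for s in traj.states]
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_traj(path) -> FeatureTraj:
    dt, rows = _read_traj_lines(path)
    xy = []
    for line_no, line in rows:
        parts = line.split(",")
        try:
            xy.append([float(p) for p in parts])
        except ValueError:
            raise ValueError(f"{path}:{line_no}: not a float row: {line!r}") from None
    return FeatureTraj(np.asarray(xy, dtype=float), dt)


def write_feature_traj(path, traj: FeatureTraj) -> None:
    lines = [f"# dt={float(traj.dt)!r}"]
    lines += [",".join(repr(float(v)) for v in row) for row in traj.x]
    Path(path).write_text("\n".join(lines) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(path, payload: dict) -> None:
    """Canonical JSON: sorted keys, repr floats; byte-stable round trips."""
    text = json.dumps(_jsonify(payload), sort_keys=True, indent=1)
    Path(path).write_text(text + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
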