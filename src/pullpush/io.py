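"""Configuration loading, trace/outcome export, and observed-trace input.

Configs are flat YAML (or JSON, a YAML subset) mappings: any
:class:`~pullpush.kinetics.Parameters` field may be overridden, plus the
protocol selectors ``agonist`` and ``induction`` and a few run controls.
Unknown keys are rejected.  Traces and outcome tables are written as tidy
CSV: at most a few hundred rows, human-inspectable, lossless at 12
significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .engine import Protocol, Trajectory
from .kinetics import Parameters
from .observables import OutcomeRecord, weight_trace

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_trace",
    "read_trace",
    "write_outcomes",
    "read_observed_trace",
]

log = logging.getLogger("pullpush")

FLOAT_FORMAT = "%.12g"

_PARAM_KEYS = {f.name for f in dataclasses.fields(Parameters)}
_PROTOCOL_KEYS = {"agonist", "induction"}
_RUN_KEYS = {"out", "grid_dt", "export_dt", "seed", "verbose"}


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass
class RunConfig:
    """Resolved run configuration: parameters, protocol and run controls."""

    params: Parameters
    protocol: Protocol
    out: Optional[str] = None
    grid_dt: float = 0.1     # internal dense grid (min)
    export_dt: float = 1.0   # export grid (min)
    seed: int = 0
    verbose: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file.

    Absent keys fall back to the published defaults; every override is
    re-validated through the :class:`Parameters`/:class:`Protocol`
    constructors, and errors name the offending key.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(raw).__name__}")

    unknown = set(raw) - _PARAM_KEYS - _PROTOCOL_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")

    overrides = {k: raw[k] for k in raw if k in _PARAM_KEYS}
    try:
        params = Parameters(**overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid parameter override: {exc}") from exc

    try:
        protocol = Protocol(
            agonist=raw.get("agonist", "none"),
            induction=raw.get("induction", "none"),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: invalid protocol: {exc}") from exc

    cfg = RunConfig(
        params=params,
        protocol=protocol,
        out=raw.get("out"),
        grid_dt=float(raw.get("grid_dt", 0.1)),
        export_dt=float(raw.get("export_dt", 1.0)),
        seed=int(raw.get("seed", 0)),
        verbose=int(raw.get("verbose", 0)),
    )
    if not cfg.grid_dt > 0 or not cfg.export_dt > 0:
        raise ConfigError(f"{path}: grid spacings must be > 0")
    return cfg


def trace_frame(traj: Trajectory, p: Parameters, dt: float = 1.0) -> pd.DataFrame:
    """Tidy per-time-point table of state, weights and phase labels.

    Rows are subsampled from the trajectory grid at spacing ``dt``
    (endpoints always included).
    """
    wt = weight_trace(traj, p)
    t = traj.times
    keep = np.isclose(np.mod(t - t[0], dt), 0.0, atol=1e-9)
    keep |= np.isclose(np.mod(t - t[0], dt), dt, atol=1e-9)
    keep[0] = keep[-1] = True
    return pd.DataFrame({
        "t_min": t[keep],
        "a_psd": traj.a_psd[keep],
        "a_peri_in": traj.a_peri_in[keep],
        "a_peri_out": traj.a_peri_out[keep],
        "a_ua": traj.a_ua[keep],
        "kin": traj.kin[keep],
        "pp": traj.pp[keep],
        "weight_raw": wt.raw[keep],
        "weight_smoothed": wt.smoothed[keep],
        "weight_normalized_pct": wt.normalized[keep],
        "phase": traj.phase_labels[keep],
    })


def write_trace(traj: Trajectory, p: Parameters, path, dt: float = 1.0) -> Path:
    """Export a simulated trajectory as CSV (see :func:`trace_frame`)."""
    path = Path(path)
    frame = trace_frame(traj, p, dt)
    try:
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise OSError(f"cannot write trace to {path}: {exc}") from exc
    log.info("wrote trace (%d rows) to %s", len(frame), path)
    return path


def read_trace(path) -> pd.DataFrame:
    """Read back a trace CSV written by :func:`write_trace`."""
    return pd.read_csv(path)


def write_outcomes(records, path) -> Path:
    """Export scenario outcome records as a tidy CSV table."""
    path = Path(path)
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    log.info("wrote %d outcome records to %s", len(frame), path)
    return path


def read_observed_trace(path) -> pd.DataFrame:
    """Read a two-column observed-response table (time_min, response_percent).

    Accepts comma-, tab- or whitespace-delimited text with or without a
    header row.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_min, response_percent)")
    first = frame.columns[0]
    try:  # headerless file: the "header" is actually the first data row
        float(first)
        frame = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except ValueError:
        pass
    frame = frame.iloc[:, :2]
    frame.columns = ["time_min", "response_percent"]
    return frame.astype(float)
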