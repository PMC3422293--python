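"""Trace/metrics writers, run manifests and logging helpers.

CSV is the canonical interchange format (one row per recorded sample, named
columns with fixed units: ms, mV, pA, mM); each run writes a YAML sidecar
manifest that suffices to reproduce it bit-for-bit.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import pandas as pd
import yaml

from .engine import SimulationTrace, SlowWaveMetrics
from .parameters import ModelParameters, serialize

log = logging.getLogger("hjsmc")

COLUMN_UNITS = {
    "t": "ms", "V_m": "mV", "I_CaL": "pA", "I_CaT": "pA", "I_Kv": "pA",
    "I_BK": "pA", "I_Na": "pA", "I_NaK": "pA", "I_NCX": "pA",
    "I_NaLeak": "pA", "I_KLeak": "pA", "I_stim": "pA",
    "Po_CaL": "1", "Po_BK": "1", "Po_Na": "1",
    "Na_i": "mM", "K_i": "mM", "Ca_total": "mM", "Ca_free": "mM",
}


def package_version() -> str:
    from importlib.metadata import version
    try:
        return version("hjsmc")
    except Exception:
        return "unknown"


def write_trace(trace: SimulationTrace, out_dir: str | Path,
                stem: str = "trace") -> Path:
    """Write the trace CSV plus its YAML manifest; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    trace.data.to_csv(csv_path, index=False)
    manifest = {
        "tool": "hjsmc",
        "version": package_version(),
        "written": datetime.datetime.now().isoformat(timespec="seconds"),
        "column_units": {c: COLUMN_UNITS.get(c, "?")
                         for c in trace.data.columns},
        **trace.metadata(),
    }
    with open(out_dir / f"{stem}.manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return csv_path


def write_metrics(metrics: SlowWaveMetrics, out_dir: str | Path,
                  stem: str = "metrics") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.csv"
    pd.DataFrame([metrics.as_dict()]).to_csv(path, index=False)
    return path


def write_manifest(out_dir: str | Path, command: str, config: str | None,
                   overrides: dict, outputs: list[str]) -> Path:
    """Run manifest: command, config, overrides and outputs of one CLI run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "hjsmc",
        "version": package_version(),
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "command": command,
        "config": config,
        "overrides": overrides,
        "outputs": outputs,
    }
    path = out_dir / "run_manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def write_effective_params(params: ModelParameters,
                           out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "effective_params.yaml"
    path.write_text(serialize(params))
    return path


def log_parameter_provenance(params: ModelParameters) -> None:
    """INFO-log the headline constants of a run."""
    log.info("C_m=%g pF; G_CaL=%g G_CaT=%g G_Kv=%g G_BK=%g G_Na=%g nS",
             params.C_m, params.G_CaL, params.G_CaT, params.G_Kv,
             params.G_BK, params.G_Na)
    log.info("leak: G_NaLeak=%g G_KLeak=%g nS (G_Kv/leak=%.1f)",
             params.G_NaLeak, params.G_KLeak,
             params.G_Kv / (params.G_NaLeak + params.G_KLeak))
    log.info("P_NaK=%g pA, k_NCX=%g pA, V_c=%g L, T=%g K",
             params.P_NaK, params.k_NCX, params.V_c, params.T)
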