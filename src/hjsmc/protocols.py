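"""In-silico experiments: voltage clamp, Ca2+-free solution, sensitivity sweeps.

The clamp engine forces the membrane potential to a step protocol while the
gates and Markov occupancies evolve; intracellular concentrations are frozen
by default, mimicking a dialyzed (pipette-perfused) cell.  EGTA mode (Ca2+
chelation, used for the L-type fitting protocol) disables the Ca2+-dependent
L-type transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import _kernel as K
from .engine import DEFAULT_DT, SlowWaveMetrics, analyze_trace, run_free
from .markov import all_channel_specs, egta_mode, stationary_distribution
from .parameters import ModelParameters, load_parameters
from .state import StateVector, initial_state
from .stimulus import ICCStimulusParams, default_stimulus

CURRENT_COLUMNS = ("I_CaL", "I_CaT", "I_Kv", "I_BK", "I_Na", "I_NaK",
                   "I_NCX", "I_NaLeak", "I_KLeak")

CA_FREE_CONCENTRATION = 1e-13   # mM  (0.0001 nM, intra- and extracellular)


@dataclass(frozen=True)
class ClampProtocol:
    """A voltage-step protocol."""
    holding: float = -70.0                  # mV
    steps: tuple = tuple(np.arange(-80.0, 20.0 + 1e-9, 5.0))
    hold_duration: float = 5000.0           # ms at holding before each step
    step_duration: float = 2000.0           # ms at the step potential
    channels: tuple | str = "whole_cell"    # current columns to sum
    egta: bool = False                      # chelated-pipette replication
    ca_free: bool = False                   # Ca2+-free bath and cytosol
    evolve_concentrations: bool = False
    record_stride: int = 10

    def __post_init__(self):
        if self.step_duration <= 0:
            raise ValueError("step duration must be positive")
        pots = list(self.steps) + [self.holding]
        if any(p < -120 or p > 60 for p in pots):
            raise ValueError("potentials must lie within [-120, 60] mV")

    def current_of(self, df: pd.DataFrame) -> pd.Series:
        cols = CURRENT_COLUMNS if self.channels == "whole_cell" \
            else tuple(self.channels)
        return df[list(cols)].sum(axis=1)


@dataclass
class ClampResult:
    """Per-step clamp traces with peak and end-of-step summaries."""
    protocol: ClampProtocol
    traces: pd.DataFrame          # tidy: step_V, t, V_m, currents..., I
    summary: pd.DataFrame         # step_V, peak, steady

    def peaks(self) -> np.ndarray:
        return self.summary["peak"].to_numpy()

    def steady(self) -> np.ndarray:
        return self.summary["steady"].to_numpy()


CLAMP_PRESETS = {
    # whole-cell protocol of the human-jejunum patch studies:
    # steps -80..+20 mV in 5 mV increments, 2000 ms
    "farrugia-wholecell": ClampProtocol(),
    # L-type fitting protocol (EGTA pipette)
    "lim-ltype": ClampProtocol(holding=-80.0,
                               steps=tuple(np.arange(-60.0, 30.1, 5.0)),
                               step_duration=300.0, channels=("I_CaL",),
                               egta=True),
    # T-type protocol
    "strege-ttype": ClampProtocol(holding=-80.0,
                                  steps=tuple(np.arange(-80.0, 10.1, 5.0)),
                                  step_duration=300.0, channels=("I_CaT",)),
    # Kv protocol over the physiological range
    "kv": ClampProtocol(holding=-80.0,
                        steps=tuple(np.arange(-60.0, 20.1, 5.0)),
                        channels=("I_Kv",)),
}


def _clamped_state(params: ModelParameters, V: float,
                   egta: bool) -> StateVector:
    state = initial_state(params, V0=float(np.clip(V, -100.0, 20.0)))
    if egta:
        spec = egta_mode(all_channel_specs(params)["CaL"])
        cafree = state.free_calcium(params)
        state.p_CaL = stationary_distribution(spec, state.V_m, cafree)
    return state


def run_voltage_clamp(protocol: ClampProtocol,
                      params: ModelParameters | None = None,
                      dt: float = DEFAULT_DT) -> ClampResult:
    """Simulate the step protocol; returns traces plus per-step summaries.

    The membrane potential follows the protocol exactly (no free dynamics);
    the summary's `peak` is the largest-magnitude current during the step
    (signed) and `steady` the end-of-step value.
    """
    from .engine import _run
    if params is None:
        params = load_parameters()
    if protocol.ca_free:
        params = apply_ca_free(params)
    stim = default_stimulus(params.document)
    n_hold = int(round(protocol.hold_duration / dt))
    n_step = int(round(protocol.step_duration / dt))
    frames, rows = [], []
    for v_step in protocol.steps:
        state = _clamped_state(params, protocol.holding, protocol.egta)
        vprog = np.concatenate([np.full(n_hold, protocol.holding),
                                np.full(n_step, float(v_step))])
        y = state.to_array()
        rec, _ = _run(y, 0.0, n_hold + n_step, dt, protocol.record_stride,
                      params, stim, clamp=True, vprog=vprog,
                      freeze_conc=not protocol.evolve_concentrations,
                      egta=protocol.egta)
        from .engine import TRACE_COLUMNS
        df = pd.DataFrame(rec, columns=list(TRACE_COLUMNS))
        df = df[df["t"] >= protocol.hold_duration].reset_index(drop=True)
        df.insert(0, "step_V", float(v_step))
        cur = protocol.current_of(df)
        df["I"] = cur
        # exclude the first clamped sample (still at holding potential)
        seg = cur.iloc[1:]
        peak = float(seg.iloc[np.argmax(np.abs(seg.to_numpy()))])
        rows.append({"step_V": float(v_step), "peak": peak,
                     "steady": float(cur.iloc[-1])})
        frames.append(df)
    return ClampResult(protocol=protocol,
                       traces=pd.concat(frames, ignore_index=True),
                       summary=pd.DataFrame(rows))


def normalize_iv(peaks: np.ndarray) -> np.ndarray:
    """Normalize per-step peak currents by the largest magnitude."""
    peaks = np.asarray(peaks, dtype=float)
    m = np.abs(peaks).max()
    if m == 0:
        raise ValueError("cannot normalize an all-zero I-V curve")
    return peaks / m


def apply_ca_free(params: ModelParameters) -> ModelParameters:
    """Ca2+-free replication: both Ca2+ pools pinned at 0.0001 nM.

    Intracellular free Ca2+ is held at the same value the bath is set to,
    so E_Ca = 0 mV and all Ca2+-dependent machinery sees the near-zero
    concentration.  Idempotent.
    """
    newp = params.with_overrides({"external": {"Ca_o": CA_FREE_CONCENTRATION}})
    return dc_replace(newp, ca_fixed=CA_FREE_CONCENTRATION)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

# named knobs -> config-document paths
CONDUCTANCE_KNOBS = {
    "G_CaL": ("conductances", "G_CaL"),
    "G_CaT": ("conductances", "G_CaT"),
    "G_Kv": ("conductances", "G_Kv"),
    "G_BK": ("conductances", "G_BK"),
    "G_Na": ("conductances", "G_Na"),
}
# voltage-linked activation / inactivation kinetics (half-activation voltage
# and slope of the HH gates; ladder rate coefficients of the Markov channels)
KINETICS_KNOBS = {
    "CaT_activation": [("gates", "m_CaT", "Vh"), ("gates", "m_CaT", "k")],
    "CaT_inactivation": [("gates", "h_CaT", "Vh"), ("gates", "h_CaT", "k")],
    "Kv_activation": [("gates", "x_Kv", "Vh"), ("gates", "x_Kv", "k")],
    "Kv_inactivation": [("gates", "y_Kv", "Vh"), ("gates", "y_Kv", "k")],
    "CaL_activation": [("markov", "CaL", "a0"), ("markov", "CaL", "b0")],
    "Na_activation": [("markov", "Na", "a0"), ("markov", "Na", "b0")],
    "BK_activation": [("markov", "BK", "theta0"), ("markov", "BK", "delta0")],
}


def _apply_factor(doc: dict, path: tuple, factor: float) -> None:
    node = doc
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = node[path[-1]] * factor


def _variant_params(params: ModelParameters, knob: str,
                    factor: float) -> ModelParameters:
    import copy
    doc = copy.deepcopy(params.document)
    if knob in CONDUCTANCE_KNOBS:
        _apply_factor(doc, CONDUCTANCE_KNOBS[knob], factor)
    elif knob in KINETICS_KNOBS:
        for path in KINETICS_KNOBS[knob]:
            _apply_factor(doc, path, factor)
    else:
        raise ValueError(f"unknown sensitivity knob: {knob}")
    return load_parameters(doc)


def sensitivity_sweep(params: ModelParameters | None = None,
                      stimulus: ICCStimulusParams | None = None,
                      targets: tuple = ("G_CaL", "G_Kv", "G_BK", "G_Na"),
                      fraction: float = 0.5,
                      duration: float = 150000.0,
                      burn_in: float = 60000.0) -> pd.DataFrame:
    """Run baseline plus +/-fraction variants of each knob.

    Returns one row per variant with the slow-wave metrics and their deltas
    relative to baseline.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if params is None:
        params = load_parameters()
    if stimulus is None:
        stimulus = default_stimulus(params.document)
    for knob in targets:
        if knob not in CONDUCTANCE_KNOBS and knob not in KINETICS_KNOBS:
            raise ValueError(f"unknown sensitivity knob: {knob}")

    def metrics_for(p: ModelParameters) -> SlowWaveMetrics:
        trace = run_free(p, stimulus, duration=duration, burn_in=burn_in)
        return analyze_trace(trace)

    base = metrics_for(params)
    rows = [{"knob": "baseline", "factor": 1.0, **base.as_dict()}]
    for knob in targets:
        for factor in (1.0 + fraction, 1.0 - fraction):
            m = metrics_for(_variant_params(params, knob, factor)) \
                if factor != 1.0 else base
            row = {"knob": knob, "factor": factor, **m.as_dict()}
            for key in ("resting_potential", "peak_potential", "amplitude",
                        "frequency", "ca_min", "ca_max"):
                row[f"d_{key}"] = row[key] - getattr(base, key)
            rows.append(row)
    return pd.DataFrame(rows)
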