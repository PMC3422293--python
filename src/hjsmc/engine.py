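"""Time integration of the coupled cell model and slow-wave trace analysis.

The scheme follows the model's published numerics: explicit forward Euler
for the membrane potential, HH gates and ion concentrations, backward Euler
for the Markov occupancy vectors, all at a common 0.1 ms default step.  One
step is Jacobi-split: currents are evaluated once from the beginning-of-step
state and every sub-update uses them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import _kernel as K
from .parameters import ModelParameters, pack_scalars, serialize
from .state import StateVector, initial_state
from .stimulus import ICCStimulusParams, default_stimulus
from .gating import gate_table

DEFAULT_DT = 0.1           # ms; sufficient for convergence and stability
DEFAULT_STRIDE = 10        # record every 1 ms
DEFAULT_BURN_IN = 60000.0  # ms discarded before metric extraction

TRACE_COLUMNS = (
    "t", "V_m", "I_CaL", "I_CaT", "I_Kv", "I_BK", "I_Na", "I_NaK", "I_NCX",
    "I_NaLeak", "I_KLeak", "I_stim", "Po_CaL", "Po_BK", "Po_Na",
    "Na_i", "K_i", "Ca_total", "Ca_free")


class IntegrationError(RuntimeError):
    pass


class MetricError(ValueError):
    pass


@dataclass
class SimulationTrace:
    """Recorded time series of one run plus reproduction metadata."""
    data: pd.DataFrame
    dt: float
    record_stride: int
    protocol: str
    params_hash: str
    burn_in: float = DEFAULT_BURN_IN
    final_state: StateVector | None = field(default=None, repr=False)
    max_occupancy_deviation: float = 0.0
    deterministic: bool = True      # no stochastic terms anywhere

    @property
    def duration(self) -> float:
        return float(self.data["t"].iloc[-1] - self.data["t"].iloc[0])

    def window(self, t0: float, t1: float) -> pd.DataFrame:
        m = (self.data["t"] >= t0) & (self.data["t"] <= t1)
        return self.data.loc[m]

    def metadata(self) -> dict:
        return {
            "protocol": self.protocol,
            "dt_ms": self.dt,
            "record_stride": self.record_stride,
            "burn_in_ms": self.burn_in,
            "params_sha256": self.params_hash,
            "deterministic": self.deterministic,
            "max_occupancy_deviation": float(self.max_occupancy_deviation),
            "n_samples": int(len(self.data)),
        }


@dataclass(frozen=True)
class SlowWaveMetrics:
    """Cycle-averaged slow-wave summary of a trace window."""
    resting_potential: float   # mV, mean per-cycle minimum
    peak_potential: float      # mV, mean per-cycle maximum
    amplitude: float           # mV, peak - resting
    frequency: float           # cycles per minute
    time_to_peak: float        # ms, foot-to-peak time
    ca_min: float              # nM, mean per-cycle free Ca2+ minimum
    ca_max: float              # nM, mean per-cycle free Ca2+ maximum
    n_cycles: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "resting_potential", "peak_potential", "amplitude", "frequency",
            "time_to_peak", "ca_min", "ca_max", "n_cycles")}


def params_hash(params: ModelParameters,
                stimulus: ICCStimulusParams | None = None) -> str:
    h = hashlib.sha256(serialize(params).encode())
    if stimulus is not None:
        h.update(repr(stimulus).encode())
    return h.hexdigest()[:16]


def _kernel_args(params: ModelParameters):
    from .parameters import pack_markov
    cal, bk, nav = pack_markov(params)
    return pack_scalars(params), gate_table(params), cal, bk, nav


def step(state: StateVector, params: ModelParameters,
         stimulus: ICCStimulusParams, t: float,
         dt: float = DEFAULT_DT) -> StateVector:
    """Advance the full model by one operator-split step of size dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    sc, gates, cal, bk, nav = _kernel_args(params)
    st = stimulus.to_array()
    y = state.to_array()
    Q7, A7 = np.zeros((7, 7)), np.zeros((7, 7))
    Q10, A10 = np.zeros((10, 10)), np.zeros((10, 10))
    Q6, A6 = np.zeros((6, 6)), np.zeros((6, 6))
    cur = np.zeros(K.NCUR)
    K.step_once(y, t, dt, sc, gates, cal, bk, nav, st, params.RTF,
                False, 0.0, False, Q7, A7, Q10, A10, Q6, A6, cur)
    if not np.isfinite(y).all():
        bad = int(np.argwhere(~np.isfinite(y))[0])
        raise IntegrationError(f"non-finite state component at index {bad}")
    return StateVector.from_array(y)


def _run(y0: np.ndarray, t0: float, nsteps: int, dt: float, stride: int,
         params: ModelParameters, stimulus: ICCStimulusParams,
         clamp: bool = False, vprog: np.ndarray | None = None,
         freeze_conc: bool = False, egta: bool = False):
    sc, gates, cal, bk, nav = _kernel_args(params)
    if egta:
        cal = cal.copy()
        cal[K.CAL_EGTA] = 1.0
    st = stimulus.to_array()
    nrec = nsteps // stride + 1
    rec = np.zeros((nrec, K.NREC))
    if vprog is None:
        vprog = np.zeros(1)
    dev = K.run_kernel(y0, t0, nsteps, dt, stride, sc, gates, cal, bk, nav,
                       st, params.RTF, clamp, vprog, freeze_conc, rec)
    if not np.isfinite(rec).all():
        r, c = np.argwhere(~np.isfinite(rec))[0]
        raise IntegrationError(
            f"non-finite {TRACE_COLUMNS[c]} at t={rec[r, 0]:.1f} ms")
    return rec, dev


def run_free(params: ModelParameters | None = None,
             stimulus: ICCStimulusParams | None = None,
             duration: float = 180000.0,
             dt: float = DEFAULT_DT,
             record_stride: int = DEFAULT_STRIDE,
             state: StateVector | None = None,
             burn_in: float = DEFAULT_BURN_IN,
             t0: float = 0.0,
             freeze_concentrations: bool = False) -> SimulationTrace:
    """Free-running simulation of `duration` ms under the ICC stimulus.

    Returns the recorded trace; `burn_in` is stored as metadata and used by
    default when extracting metrics.  duration = 0 yields a single-sample
    trace of the initial state.
    """
    if params is None:
        from .parameters import load_parameters
        params = load_parameters()
    if stimulus is None:
        stimulus = default_stimulus(params.document)
    if state is None:
        state = initial_state(params)
    nsteps = int(round(duration / dt))
    y = state.to_array()
    rec, dev = _run(y, t0, nsteps, dt, record_stride, params, stimulus,
                    freeze_conc=freeze_concentrations)
    df = pd.DataFrame(rec, columns=list(TRACE_COLUMNS))
    return SimulationTrace(
        data=df, dt=dt, record_stride=record_stride, protocol="free_run",
        params_hash=params_hash(params, stimulus),
        burn_in=min(burn_in, duration), final_state=StateVector.from_array(y),
        max_occupancy_deviation=dev)


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------

PEAK_PROMINENCE_MV = 2.0   # minimum peak prominence for cycle detection


def _detect_peaks(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    idx, _ = find_peaks(v, prominence=PEAK_PROMINENCE_MV)
    if len(idx) >= 2:
        # second pass with a minimum spacing of half the estimated period
        period = np.median(np.diff(t[idx]))
        dt_samp = t[1] - t[0]
        idx, _ = find_peaks(v, prominence=PEAK_PROMINENCE_MV,
                            distance=max(1, int(0.5 * period / dt_samp)))
    return idx


def analyze_trace(trace: SimulationTrace,
                  window: tuple[float, float] | None = None
                  ) -> SlowWaveMetrics:
    """Slow-wave metrics over a window (defaults to everything after burn-in).

    Cycles are delimited by detected membrane-potential peaks (2 mV
    prominence, half-period minimum spacing); the resting potential is the
    mean per-cycle minimum, the peak potential the mean detected peak value,
    and the frequency comes from the mean inter-peak interval.
    """
    if window is None:
        t_end = float(trace.data["t"].iloc[-1])
        window = (float(trace.data["t"].iloc[0]) + trace.burn_in, t_end)
    df = trace.window(*window)
    if len(df) < 3:
        raise MetricError("window too short for metric extraction")
    t = df["t"].to_numpy()
    v = df["V_m"].to_numpy()
    ca = df["Ca_free"].to_numpy() * 1e6    # mM -> nM
    idx = _detect_peaks(t, v)
    if len(idx) < 2:
        raise MetricError("fewer than two slow-wave peaks in the window; "
                          "frequency undefined")
    intervals = np.diff(t[idx])
    frequency = 60000.0 / float(np.mean(intervals))
    peak_potential = float(np.mean(v[idx]))
    mins, ca_mins, ca_maxs, ttp = [], [], [], []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = slice(a, b + 1)
        mins.append(v[seg].min())
        ca_mins.append(ca[seg].min())
        ca_maxs.append(ca[seg].max())
    resting = float(np.mean(mins))
    amplitude = peak_potential - resting
    # foot-to-peak time: from the 10 %-of-amplitude crossing to the peak
    thresh = resting + 0.1 * amplitude
    for a, b in zip(idx[:-1], idx[1:]):
        tr = a + int(np.argmin(v[a:b + 1]))     # trough of this interval
        rise = v[tr:b + 1] >= thresh
        if rise.any():
            ttp.append(t[b] - t[tr + int(np.argmax(rise))])
    return SlowWaveMetrics(
        resting_potential=resting, peak_potential=peak_potential,
        amplitude=amplitude, frequency=frequency,
        time_to_peak=float(np.mean(ttp)) if ttp else float("nan"),
        ca_min=float(np.mean(ca_mins)), ca_max=float(np.mean(ca_maxs)),
        n_cycles=len(idx) - 1)
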