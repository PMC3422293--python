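"""Hodgkin-Huxley gate kinetics for the T-type Ca2+ (m, h) and Kv (x, y) gates.

Each gate is defined purely by a coefficient row (half-activation voltage,
slope, pedestal, and a Gaussian-bell time-constant table), so corrected
kinetics are a config change, not a code change.  The steady state is a
Boltzmann sigmoid; a positive slope gives an activation gate, a negative
slope an inactivation gate; a nonzero pedestal leaves a non-inactivating
fraction (used for the Kv inactivation gate, which is nearly absent in
jejunal myocytes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .parameters import ModelParameters, pack_gates

GATE_IDS = ("m_CaT", "h_CaT", "x_Kv", "y_Kv")


@dataclass(frozen=True)
class GateSpec:
    """One HH gate: Boltzmann steady state and bell-shaped time constant."""
    id: str
    Vh: float          # half-activation voltage, mV
    k: float           # slope, mV (negative for inactivation gates)
    pedestal: float    # non-inactivating fraction in [0, 1)
    tau0: float        # baseline time constant, ms
    tau_amp: float     # bell amplitude, ms
    tau_mid: float     # bell centre, mV
    tau_width: float   # bell width, mV

    @property
    def is_activation(self) -> bool:
        return self.k > 0

    @classmethod
    def from_params(cls, params: ModelParameters, gate_id: str) -> "GateSpec":
        if gate_id not in GATE_IDS:
            raise ValueError(f"unknown gate id: {gate_id}")
        g = params.gate_kinetics[gate_id]
        return cls(id=gate_id, Vh=g["Vh"], k=g["k"], pedestal=g["pedestal"],
                   tau0=g["tau0"], tau_amp=g["tau_amp"], tau_mid=g["tau_mid"],
                   tau_width=g["tau_width"])


def gate_steady_state(spec: GateSpec, V) -> float | np.ndarray:
    """Equilibrium open fraction of the gate at potential V (mV)."""
    return K.gate_inf_k(np.float64(V), spec.Vh, spec.k, spec.pedestal) \
        if np.isscalar(V) else _vec_inf(spec, np.asarray(V, dtype=float))


def _vec_inf(spec: GateSpec, V: np.ndarray) -> np.ndarray:
    return spec.pedestal + (1.0 - spec.pedestal) / (
        1.0 + np.exp(-(V - spec.Vh) / spec.k))


def gate_time_constant(spec: GateSpec, V) -> float | np.ndarray:
    """Relaxation time constant tau(V) in ms (strictly positive)."""
    z = (np.asarray(V, dtype=float) - spec.tau_mid) / spec.tau_width
    out = spec.tau0 + spec.tau_amp * np.exp(-z * z)
    return float(out) if np.isscalar(V) else out


def advance_gate(g: float, spec: GateSpec, V: float, dt: float) -> float:
    """One forward-Euler step g' = g + dt (g_inf - g)/tau, clipped to [0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    ginf = gate_steady_state(spec, V)
    tau = gate_time_constant(spec, V)
    return float(np.clip(g + dt * (ginf - g) / tau, 0.0, 1.0))


def gate_table(params: ModelParameters) -> np.ndarray:
    """The packed (4, 7) coefficient table used by the compiled kernel."""
    return pack_gates(params)
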