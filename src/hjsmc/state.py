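"""The model state vector and construction of physically consistent states."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .parameters import ModelParameters, pack_scalars


class StateError(ValueError):
    """A state vector violates one of its invariants."""


@dataclass
class StateVector:
    """Membrane potential, gates, Markov occupancies and ion concentrations.

    Invariants: gate values in [0, 1]; each occupancy vector has entries in
    [0, 1] summing to one within 1e-9; concentrations strictly positive.
    """
    V_m: float                       # mV
    m_CaT: float
    h_CaT: float
    x_Kv: float
    y_Kv: float
    p_CaL: np.ndarray                # 7 occupancies
    p_BK: np.ndarray                 # 10 occupancies
    p_Na: np.ndarray                 # 6 occupancies
    Na_i: float                      # mM
    K_i: float                       # mM
    Ca_total_i: float                # mM
    _cafree_cache: float = field(default=-1.0, repr=False)

    def validate(self) -> None:
        for name in ("m_CaT", "h_CaT", "x_Kv", "y_Kv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise StateError(f"gate {name}={v} outside [0, 1]")
        for name, n in (("p_CaL", K.N_CAL), ("p_BK", K.N_BK),
                        ("p_Na", K.N_NAV)):
            p = getattr(self, name)
            if p.shape != (n,):
                raise StateError(f"{name} must have {n} entries")
            if (p < 0).any() or (p > 1).any():
                raise StateError(f"{name} entries outside [0, 1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise StateError(f"{name} does not sum to 1 (sum={p.sum()})")
        for name in ("Na_i", "K_i", "Ca_total_i"):
            if not getattr(self, name) > 0:
                raise StateError(f"{name} must be strictly positive")

    def to_array(self) -> np.ndarray:
        y = np.zeros(K.NY)
        y[K.IV] = self.V_m
        y[K.IMCAT], y[K.IHCAT] = self.m_CaT, self.h_CaT
        y[K.IXKV], y[K.IYKV] = self.x_Kv, self.y_Kv
        y[K.ICAL0:K.ICAL0 + K.N_CAL] = self.p_CaL
        y[K.IBK0:K.IBK0 + K.N_BK] = self.p_BK
        y[K.INA0:K.INA0 + K.N_NAV] = self.p_Na
        y[K.INAI], y[K.IKI], y[K.ICATOT] = self.Na_i, self.K_i, self.Ca_total_i
        y[K.IFCA] = self._cafree_cache
        return y

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(
            V_m=float(y[K.IV]),
            m_CaT=float(y[K.IMCAT]), h_CaT=float(y[K.IHCAT]),
            x_Kv=float(y[K.IXKV]), y_Kv=float(y[K.IYKV]),
            p_CaL=y[K.ICAL0:K.ICAL0 + K.N_CAL].copy(),
            p_BK=y[K.IBK0:K.IBK0 + K.N_BK].copy(),
            p_Na=y[K.INA0:K.INA0 + K.N_NAV].copy(),
            Na_i=float(y[K.INAI]), K_i=float(y[K.IKI]),
            Ca_total_i=float(y[K.ICATOT]),
            _cafree_cache=float(y[K.IFCA]))

    def free_calcium(self, params: ModelParameters) -> float:
        """Free Ca2+ (mM) via the buffering equilibrium."""
        b = params.buffer_params
        return K.free_ca_solve(self.Ca_total_i, b.cam_total, b.cam_kd,
                               b.crt_total, b.crt_kd, self._cafree_cache)

    def pack_scalars_cached(self, params: ModelParameters) -> np.ndarray:
        return pack_scalars(params)


def initial_state(params: ModelParameters,
                  V0: float | None = None) -> StateVector:
    """Physically consistent state at potential V0.

    HH gates start at their steady-state values, Markov occupancies at the
    stationary distribution of their generators at (V0, resting free Ca2+),
    and concentrations at the documented defaults (post-transient values of
    the default free-running model).
    """
    from .gating import GateSpec, gate_steady_state
    from .markov import all_channel_specs, stationary_distribution

    if V0 is None:
        V0 = float(params.initial["V0"])
    if not -100.0 <= V0 <= 20.0:
        raise ValueError(f"V0={V0} outside the supported [-100, 20] mV range")
    init = params.initial
    catot = float(init["Ca_total_i"])
    b = params.buffer_params
    cafree = K.free_ca_solve(catot, b.cam_total, b.cam_kd,
                             b.crt_total, b.crt_kd, -1.0)
    specs = all_channel_specs(params)
    gates = {gid: float(gate_steady_state(GateSpec.from_params(params, gid),
                                          V0))
             for gid in ("m_CaT", "h_CaT", "x_Kv", "y_Kv")}
    st = StateVector(
        V_m=float(V0),
        m_CaT=gates["m_CaT"], h_CaT=gates["h_CaT"],
        x_Kv=gates["x_Kv"], y_Kv=gates["y_Kv"],
        p_CaL=stationary_distribution(specs["CaL"], V0, cafree),
        p_BK=stationary_distribution(specs["BK"], V0, cafree),
        p_Na=stationary_distribution(specs["Na"], V0, cafree),
        Na_i=float(init["Na_i"]), K_i=float(init["K_i"]),
        Ca_total_i=catot, _cafree_cache=cafree)
    st.validate()
    return st
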