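"""Membrane current terms and their sum (sign convention: outward positive).

Channel currents are ohmic, I = G * Po * (V - E), with Nernst reversal
potentials recomputed from the tracked intracellular concentrations at every
evaluation.  The NaK pump and the Na+/Ca2+ exchanger use the ten Tusscher
saturation forms; the nonselective leak has separate Na+ and K+ components,
both reversing at 0 mV and together at least 45-fold smaller than G_Kv.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import _kernel as K
from .parameters import FARADAY, R_GAS, ModelParameters
from .state import StateVector

# species carried by each current and stoichiometric factor per unit of
# membrane charge: the NaK pump extrudes 3 Na+ and imports 2 K+ per net
# charge; NCX imports 3 Na+ and exports 1 Ca2+ per net charge.  Every
# current term appears in exactly one concentration ODE per species.
STOICHIOMETRY = {
    "I_CaL": {"Ca": 1.0},
    "I_CaT": {"Ca": 1.0},
    "I_Kv": {"K": 1.0},
    "I_BK": {"K": 1.0},
    "I_Na": {"Na": 1.0},
    "I_NaK": {"Na": 3.0, "K": -2.0},
    "I_NCX": {"Na": 3.0, "Ca": -2.0},
    "I_NaLeak": {"Na": 1.0},
    "I_KLeak": {"K": 1.0},
}


@dataclass(frozen=True)
class CurrentBreakdown:
    """Every membrane current term of one state snapshot, in pA."""
    I_CaL: float
    I_CaT: float
    I_Kv: float
    I_BK: float
    I_Na: float
    I_NaK: float
    I_NCX: float
    I_NaLeak: float
    I_KLeak: float

    @property
    def I_leak(self) -> float:
        return self.I_NaLeak + self.I_KLeak

    @property
    def I_total(self) -> float:
        return sum(getattr(self, f.name) for f in fields(self))

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["I_total"] = self.I_total
        return d


def nernst(z: int, c_in: float, c_out: float, T: float = 310.0) -> float:
    """Nernst potential (mV) for valence z from the concentration ratio."""
    if c_in <= 0 or c_out <= 0:
        raise ValueError("concentrations must be strictly positive")
    if z == 0:
        raise ValueError("valence must be a nonzero integer")
    return R_GAS * T / (z * FARADAY) * np.log(c_out / c_in)


def channel_current(G: float, Po: float, V: float, E: float) -> float:
    """Ohmic channel current G * Po * (V - E) in pA (nS * mV)."""
    return G * Po * (V - E)


def leak_current(V: float, params: ModelParameters) -> tuple[float, float]:
    """(I_NaLeak, I_KLeak): linear nonselective leak reversing at 0 mV."""
    return params.G_NaLeak * V, params.G_KLeak * V


def nak_current(V: float, Na_i: float, K_o: float,
                params: ModelParameters) -> float:
    """NaK pump current (outward positive), ten Tusscher saturation form."""
    if Na_i <= 0 or K_o <= 0:
        raise ValueError("concentrations must be strictly positive")
    nn = params.nak_ncx
    rtf = params.RTF
    denom = 1.0 + 0.1245 * np.exp(-0.1 * V / rtf) + 0.0353 * np.exp(-V / rtf)
    return params.P_NaK * (K_o / (K_o + nn["K_mK"])) \
        * (Na_i / (Na_i + nn["K_mNa"])) / denom


def ncx_current(V: float, Na_i: float, Ca_free: float,
                params: ModelParameters) -> float:
    """Na+/Ca2+ exchanger current, ten Tusscher form.

    Positive (outward) in Ca2+-entry mode, negative in Ca2+-extrusion mode;
    the sign flips across the reversal condition set by the Na+ and Ca2+
    gradients and the membrane potential.
    """
    if Na_i <= 0 or Ca_free <= 0:
        raise ValueError("concentrations must be strictly positive")
    nn = params.nak_ncx
    rtf = params.RTF
    g = nn["gamma"]
    e1 = np.exp(g * V / rtf)
    e2 = np.exp((g - 1.0) * V / rtf)
    num = e1 * Na_i ** 3 * params.Ca_o \
        - e2 * params.Na_o ** 3 * Ca_free * nn["alpha_NCX"]
    den = (nn["K_mNai"] ** 3 + params.Na_o ** 3) \
        * (nn["K_mCa"] + params.Ca_o) * (1.0 + nn["k_sat"] * e2)
    return params.k_NCX * num / den


def total_ionic_current(state: StateVector,
                        params: ModelParameters) -> CurrentBreakdown:
    """Evaluate all eight current terms consistently from one snapshot."""
    y = state.to_array()
    sc = state.pack_scalars_cached(params)
    cur = np.zeros(K.NCUR)
    cafree = state.free_calcium(params)
    K.eval_currents(y, sc, state.V_m, cafree, params.RTF, cur)
    return CurrentBreakdown(
        I_CaL=cur[K.C_CAL], I_CaT=cur[K.C_CAT], I_Kv=cur[K.C_KV],
        I_BK=cur[K.C_BK], I_Na=cur[K.C_NA], I_NaK=cur[K.C_NAK],
        I_NCX=cur[K.C_NCX], I_NaLeak=cur[K.C_NALEAK], I_KLeak=cur[K.C_KLEAK])
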