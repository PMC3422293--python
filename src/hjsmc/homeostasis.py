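"""Intracellular ion bookkeeping: Ca2+ buffering and concentration ODEs.

Total intracellular Ca2+, Na+ and K+ are tracked as state; free Ca2+ is
obtained each step from the instantaneous buffering equilibrium with
calmodulin and calreticulin (conservation of mass, solved by a safeguarded
scalar root-finder).  Extracellular concentrations are held constant (bath
assumption).  The stimulus (gap-junction) current carries no transmembrane
ion flux and therefore appears in no concentration ODE.
"""

from __future__ import annotations

import numpy as np

from . import _kernel as K
from .currents import STOICHIOMETRY, CurrentBreakdown
from .parameters import BufferSet, ModelParameters


def free_calcium(Ca_total: float, buffers: BufferSet,
                 guess: float = -1.0) -> float:
    """Free Ca2+ (mM): the unique root in [0, Ca_total] of
    Ca_total = f + sum_b B_tot,b * f / (K_d,b + f).

    Strictly monotone increasing in Ca_total.
    """
    if Ca_total < 0:
        raise ValueError("Ca_total must be nonnegative")
    return K.free_ca_solve(float(Ca_total), buffers.cam_total, buffers.cam_kd,
                           buffers.crt_total, buffers.crt_kd, guess)


def buffering_power(Ca_free: float, buffers: BufferSet) -> float:
    """d(Ca_total)/d(Ca_free) at the given free concentration."""
    return 1.0 \
        + buffers.cam_total * buffers.cam_kd / (buffers.cam_kd + Ca_free) ** 2 \
        + buffers.crt_total * buffers.crt_kd / (buffers.crt_kd + Ca_free) ** 2


def concentration_derivatives(currents: CurrentBreakdown,
                              params: ModelParameters,
                              I_stim: float = 0.0
                              ) -> tuple[float, float, float]:
    """(dCa_total, dNa, dK) in mM/ms from a current breakdown.

    Signs follow the outward-positive current convention: inward cation
    current raises the corresponding intracellular concentration.  The
    stoichiometric factors (Ca2+ valence 2; pump 3 Na+ : 2 K+; exchanger
    3 Na+ : 1 Ca2+) are those of the STOICHIOMETRY table.  ``I_stim`` is
    the gap-junction current (inward-positive): a junctional current
    between two cytosols is carried by the dominant cytosolic cation and
    therefore enters the K+ balance.
    """
    conv = 1e-15 / (params.F * params.V_c)     # pA -> mM/ms for valence 1
    dca = -(currents.I_CaL + currents.I_CaT
            - 2.0 * currents.I_NCX) * conv / 2.0
    dna = -(currents.I_Na + currents.I_NaLeak
            + 3.0 * currents.I_NaK + 3.0 * currents.I_NCX) * conv
    dk = -(currents.I_Kv + currents.I_BK + currents.I_KLeak
           - 2.0 * currents.I_NaK - I_stim) * conv
    return dca, dna, dk


def stoichiometry_matrix() -> dict:
    """Species flux factor of every current term (mirrors the ODE code)."""
    return {name: dict(spec) for name, spec in STOICHIOMETRY.items()}
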