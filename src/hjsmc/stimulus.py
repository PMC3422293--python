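"""Phenomenological ICC slow-wave stimulus and gap-junction coupling.

The ICC membrane potential is prescribed (there is no biophysical ICC model
here): a saturating-exponential upstroke of duration t_up to the peak
potential, then a fast settle onto a sustained plateau pedestal and a
smooth terminal repolarization to rest; upstroke plus plateau durations
give the slow-wave period.
The SMC sees the ICC through a constant gap-junction conductance,
I_stim = G_couple * (V_ICC - V_m), so a depolarized ICC depolarizes the SMC.

Two experimentally motivated variants are provided: the 2-APB modification
(reduced frequency and amplitude, slowed upstroke) and a variant matched to
the faster-frequency human recordings of Hwang and colleagues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from . import _kernel as K
from .parameters import default_document


@dataclass(frozen=True)
class ICCStimulusParams:
    """Waveform and coupling parameters of the prescribed ICC slow wave."""
    V_ICCrest: float       # mV, ICC resting potential
    V_ICCamp: float        # mV, slow-wave amplitude (peak = rest + amp)
    t_up: float            # ms, upstroke duration
    t_plat: float          # ms, plateau duration
    k_up: float            # upstroke sharpness (dimensionless)
    p_plat: float          # shape constant: plateau pedestal / amplitude
    c_fast: float          # shape constant: fast-settle tau / t_plat
    c_fall: float          # shape constant: terminal-fall duration / t_plat
    G_couple: float        # nS, gap-junction conductance
    t_start: float = 0.0   # ms, onset time

    def __post_init__(self):
        if self.t_up <= 0 or self.t_plat <= 0:
            raise ValueError("t_up and t_plat must be positive")

    @property
    def period(self) -> float:
        """Slow-wave period T = t_up + t_plat, ms."""
        return self.t_up + self.t_plat

    @property
    def V_peak(self) -> float:
        return self.V_ICCrest + self.V_ICCamp

    @property
    def frequency_cpm(self) -> float:
        return 60000.0 / self.period

    @property
    def shape_constants(self) -> tuple:
        return (self.p_plat, self.c_fast, self.c_fall)

    def to_array(self) -> np.ndarray:
        st = np.zeros(K.N_ST)
        st[K.ST_VREST] = self.V_ICCrest
        st[K.ST_VAMP] = self.V_ICCamp
        st[K.ST_TUP] = self.t_up
        st[K.ST_TPLAT] = self.t_plat
        st[K.ST_KUP] = self.k_up
        st[K.ST_PPLAT] = self.p_plat
        st[K.ST_CFAST] = self.c_fast
        st[K.ST_CFALL] = self.c_fall
        st[K.ST_GCOUPLE] = self.G_couple
        st[K.ST_TSTART] = self.t_start
        return st


def default_stimulus(doc: Mapping | None = None) -> ICCStimulusParams:
    """Stimulus with the published default ICC waveform parameters."""
    s = (doc or default_document())["stimulus"]
    return ICCStimulusParams(
        V_ICCrest=float(s["V_ICCrest"]), V_ICCamp=float(s["V_ICCamp"]),
        t_up=float(s["t_up"]), t_plat=float(s["t_plat"]),
        k_up=float(s["k_up"]), p_plat=float(s["p_plat"]),
        c_fast=float(s["c_fast"]), c_fall=float(s["c_fall"]),
        G_couple=float(s["G_couple"]), t_start=float(s["t_start"]))


def no_stimulus() -> ICCStimulusParams:
    """Uncoupled variant (G_couple = 0): the SMC receives no ICC input."""
    return replace(default_stimulus(), G_couple=0.0)


def icc_voltage(t, sp: ICCStimulusParams):
    """ICC membrane potential (mV) at time t (ms); periodic past onset."""
    st = sp.to_array()
    if np.isscalar(t):
        return float(K.icc_voltage_k(float(t), st))
    return np.array([K.icc_voltage_k(float(ti), st) for ti in np.asarray(t)])


def stimulus_current(V_icc: float, V_m: float, G_couple: float) -> float:
    """Gap-junction current G_couple * (V_icc - V_m), pA, inward-positive."""
    return G_couple * (V_icc - V_m)


# experimental modification factors for 50 uM 2-APB: frequency falls to
# 4.90 cpm, time to peak lengthens by 19.7 %, amplitude falls by 32.9 %
APB_FREQUENCY_CPM = 4.90
APB_TIME_TO_PEAK_FACTOR = 1.197
APB_AMPLITUDE_REDUCTION = 0.329


def variant_2apb(sp: ICCStimulusParams,
                 frequency_cpm: float = APB_FREQUENCY_CPM,
                 time_to_peak_factor: float = APB_TIME_TO_PEAK_FACTOR,
                 amplitude_reduction: float = APB_AMPLITUDE_REDUCTION
                 ) -> ICCStimulusParams:
    """ICC stimulus under 2-APB.

    The period is set from the measured 4.90 cpm, the upstroke is slowed by
    the measured time-to-peak increase and the amplitude scaled down by the
    measured reduction; the dimensionless shape constants are unchanged.
    With neutral factors (the input's own frequency, factor 1, reduction 0)
    the input is reproduced.
    """
    period = 60000.0 / frequency_cpm
    t_up = sp.t_up * time_to_peak_factor
    return replace(sp, t_up=t_up, t_plat=period - t_up,
                   V_ICCamp=sp.V_ICCamp * (1.0 - amplitude_reduction))


HWANG_FREQUENCY_CPM = 7.5
HWANG_V_ICCREST = -61.0      # mV, stimulus-side rest for the -64 mV SMC rest
HWANG_V_ICCAMP = 31.5        # mV, stimulus-side amplitude for 31 mV SMC waves


def variant_hwang(sp: ICCStimulusParams) -> ICCStimulusParams:
    """ICC stimulus matched to the Hwang et al recording conditions.

    Period set from the reported 7.5 cpm; rest and amplitude adjusted toward
    the reported SMC targets (rest -64 mV, amplitude 31 mV); the waveform
    shape constants are preserved.
    """
    period = 60000.0 / HWANG_FREQUENCY_CPM
    return replace(sp, t_up=sp.t_up, t_plat=period - sp.t_up,
                   V_ICCrest=HWANG_V_ICCREST, V_ICCamp=HWANG_V_ICCAMP)
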