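"""Deterministic synthetic fixtures for testing.

Everything here is generated programmatically: a reversible three-state toy
Markov chain with a closed-form stationary distribution, a synthetic
slow-wave trace with prescribed metrics, and random operating points for
current-formula oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ToyChain:
    """Reversible 3-state chain C <-> O <-> I with known stationary law."""
    Q: np.ndarray
    stationary: np.ndarray
    rates: dict


def toy_markov_chain(seed: int) -> ToyChain:
    """A random reversible 3-state chain.

    For the linear chain 0<->1<->2 detailed balance gives the closed form
    pi ~ (1, k01/k10, (k01/k10)(k12/k21)).
    """
    rng = np.random.default_rng(seed)
    k01, k10, k12, k21 = rng.uniform(0.2, 3.0, size=4)
    Q = np.zeros((3, 3))
    for j, i, r in ((0, 1, k01), (1, 0, k10), (1, 2, k12), (2, 1, k21)):
        Q[i, j] += r
        Q[j, j] -= r
    w = np.array([1.0, k01 / k10, (k01 / k10) * (k12 / k21)])
    return ToyChain(Q=Q, stationary=w / w.sum(),
                    rates={"k01": k01, "k10": k10, "k12": k12, "k21": k21})


def synthetic_slow_wave(seed: int, rest: float = -60.0, amplitude: float = 23.0,
                        frequency_cpm: float = 6.0, duration: float = 120000.0,
                        dt: float = 1.0) -> pd.DataFrame:
    """Square-ish slow-wave trace with exactly prescribed metrics.

    Smooth flanks (half-cosine, 300 ms) join a flat plateau at rest+amplitude
    to a flat baseline at rest; free Ca2+ is a scaled copy of the wave
    (94-250 nM).  Deterministic for a given seed (the seed only labels the
    fixture; the waveform has no noise).
    """
    del seed
    period = 60000.0 / frequency_cpm
    t = np.arange(0.0, duration + dt / 2, dt)
    phase = t % period
    edge = 300.0
    plateau = 0.4 * period
    v = np.full_like(t, rest)
    rising = phase < edge
    v[rising] = rest + amplitude * 0.5 * (1 - np.cos(np.pi * phase[rising]
                                                     / edge))
    flat = (phase >= edge) & (phase < edge + plateau)
    v[flat] = rest + amplitude
    falling = (phase >= edge + plateau) & (phase < 2 * edge + plateau)
    s = (phase[falling] - edge - plateau) / edge
    v[falling] = rest + amplitude * 0.5 * (1 + np.cos(np.pi * s))
    frac = (v - rest) / amplitude
    ca_nm = 94.0 + (250.0 - 94.0) * frac
    return pd.DataFrame({"t": t, "V_m": v, "Ca_free": ca_nm * 1e-6})


def random_operating_points(seed: int, n: int = 20) -> pd.DataFrame:
    """Random (V, Na_i, Ca_free, K_i) points for current-formula oracles."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "V": rng.uniform(-90.0, 20.0, n),
        "Na_i": rng.uniform(4.0, 20.0, n),
        "K_i": rng.uniform(110.0, 160.0, n),
        "Ca_free": 10 ** rng.uniform(-5.0, -3.0, n),   # 10 nM .. 1 uM
    })


def generate_fixtures(seed: int) -> dict:
    """The deterministic fixture bundle used across the test suite."""
    return {
        "toy_chain": toy_markov_chain(seed),
        "slow_wave": synthetic_slow_wave(seed),
        "operating_points": random_operating_points(seed),
    }
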