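"""Continuous-time Markov machinery and the three channel topologies.

Channels are deterministic occupancy-vector models: the L-type Ca2+ channel
(Faber-style activation ladder with voltage- and Ca2+-dependent inactivation),
the BK channel (Cox-style allosteric two-tier scheme with sequential Ca2+
binding to the four alpha subunits) and Nav1.5 (six-state chain).  The
generator convention is dp/dt = Q p with column sums zero; occupancies are
advanced with a backward-Euler (implicit) step, which keeps the stiff BK
open/close rates stable at the model's 0.1 ms time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernel as K
from .parameters import ModelParameters, pack_markov


class ModelDefinitionError(ValueError):
    """A rate table produced an invalid generator."""


@dataclass(frozen=True)
class MarkovModelSpec:
    """A channel topology plus its rate-coefficient table."""
    id: str                      # 'CaL' | 'BK' | 'Na'
    n_states: int
    open_states: tuple
    coeffs: np.ndarray           # packed rate coefficients for the kernel
    ca_dependent_edges: tuple    # (from, to) state pairs gated by Ca2+
    egta: bool = False

    def state_labels(self) -> tuple:
        if self.id == "CaL":
            return ("C0", "C1", "C2", "C3", "O", "Iv", "Ica")
        if self.id == "BK":
            return tuple(f"C{i}" for i in range(5)) + \
                tuple(f"O{i}" for i in range(5))
        return ("C3", "C2", "C1", "O", "If", "Is")


def channel_spec(params: ModelParameters, channel_id: str) -> MarkovModelSpec:
    """Build the spec for one of the three channels from a parameter set."""
    cal, bk, nav = pack_markov(params)
    if channel_id == "CaL":
        return MarkovModelSpec("CaL", K.N_CAL, (K.CAL_OPEN,), cal,
                               ca_dependent_edges=((4, 6),))
    if channel_id == "BK":
        edges = tuple((i, i + 1) for i in range(4)) \
            + tuple((5 + i, 6 + i) for i in range(4))
        return MarkovModelSpec("BK", K.N_BK, tuple(range(5, 10)), bk,
                               ca_dependent_edges=edges)
    if channel_id == "Na":
        return MarkovModelSpec("Na", K.N_NAV, (K.NAV_OPEN,), nav,
                               ca_dependent_edges=())
    raise ValueError(f"unknown channel id: {channel_id}")


def all_channel_specs(params: ModelParameters) -> dict:
    return {cid: channel_spec(params, cid) for cid in ("CaL", "BK", "Na")}


def build_generator(spec: MarkovModelSpec, V: float,
                    Ca_free: float) -> np.ndarray:
    """Rate matrix Q (1/ms) at the given potential and free Ca2+.

    Off-diagonal entries are nonnegative transition rates; columns sum to
    zero.  In EGTA mode the Ca2+-dependent edges are disabled, making the
    open probability independent of Ca_free.
    """
    if not (np.isfinite(V) and np.isfinite(Ca_free)) or Ca_free <= 0:
        raise ValueError("V must be finite and Ca_free positive")
    n = spec.n_states
    Q = np.zeros((n, n))
    if spec.id == "CaL":
        coeffs = spec.coeffs.copy()
        coeffs[K.CAL_EGTA] = 1.0 if spec.egta else 0.0
        K.fill_cal(Q, V, Ca_free, coeffs)
    elif spec.id == "BK":
        # EGTA for BK: freeze Ca2+ binding at a fixed reference level
        K.fill_bk(Q, V, 1e-7 if spec.egta else Ca_free,
                  _rtf_from_coeffs(), spec.coeffs)
    else:
        K.fill_nav(Q, V, spec.coeffs)
    off = Q - np.diag(np.diag(Q))
    if (off < 0).any():
        i, j = np.argwhere(off < 0)[0]
        raise ModelDefinitionError(
            f"negative rate on edge {j}->{i} of {spec.id}")
    return Q


_RTF_DEFAULT = 26.712338


def _rtf_from_coeffs() -> float:
    # BK gating-charge rates need the thermal voltage; channel specs do not
    # carry temperature, so the fixed 310 K value is used here.  The engine
    # passes the configured temperature explicitly.
    return _RTF_DEFAULT


def advance_markov(p: np.ndarray, Q: np.ndarray, dt: float) -> np.ndarray:
    """One implicit (backward-Euler) step: solve (I - dt Q) p' = p.

    The result is clamped against negative round-off and renormalized to
    sum exactly one.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("occupancy vector must sum to 1")
    n = p.shape[0]
    A = np.eye(n) - dt * Q
    try:
        out = np.linalg.solve(A, p)
    except np.linalg.LinAlgError as exc:
        raise ModelDefinitionError(
            f"singular implicit system (dt={dt}, |Q|max="
            f"{np.abs(Q).max():.3g})") from exc
    out[out < 0] = 0.0
    return out / out.sum()


def open_probability(p: np.ndarray, spec: MarkovModelSpec) -> float:
    """Sum of occupancies over the spec's open states."""
    p = np.asarray(p, dtype=float)
    return float(p[list(spec.open_states)].sum())


def stationary_distribution(spec: MarkovModelSpec, V: float,
                            Ca_free: float) -> np.ndarray:
    """Stationary occupancy at fixed (V, Ca): solve Q p = 0, sum p = 1."""
    Q = build_generator(spec, V, Ca_free)
    n = spec.n_states
    A = Q.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ModelDefinitionError(
            f"stationary distribution of {spec.id} is not unique at "
            f"V={V}, Ca={Ca_free}") from exc
    if (p < -1e-9).any():
        raise ModelDefinitionError(
            f"stationary solve of {spec.id} produced negative occupancy")
    p[p < 0] = 0.0
    return p / p.sum()


def egta_mode(spec: MarkovModelSpec) -> MarkovModelSpec:
    """Replicate a Ca2+-chelated pipette: disable Ca2+-dependent transitions.

    Idempotent; warns and returns the spec unchanged if it has no
    Ca2+-dependent edges.
    """
    if not spec.ca_dependent_edges:
        warnings.warn(f"channel {spec.id} has no Ca2+-dependent edges; "
                      "EGTA mode is a no-op", stacklevel=2)
        return spec
    if spec.egta:
        return spec
    return replace(spec, egta=True)
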