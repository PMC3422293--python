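"""Parameter data model, configuration loading and initial-state construction.

The canonical constants ship in ``data/default_params.yaml``; user configs are
YAML documents with the same nesting that override any subset of them.
Unknown keys are rejected, overrides merge recursively onto the defaults, and
the effective parameter set can be serialized back to an identical document.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import numpy as np
import yaml

from . import _kernel as K

FARADAY = 96.4853329           # C / mmol
R_GAS = K.R_GAS                # J / (mol K)


class ConfigurationError(ValueError):
    """Malformed or unknown configuration content."""


class ValidationError(ValueError):
    """Configuration parsed but violates a model invariant."""


def _default_document() -> dict:
    with resources.files("hjsmc.data").joinpath("default_params.yaml").open() as fh:
        return yaml.safe_load(fh)


_DEFAULTS: dict | None = None


def default_document() -> dict:
    """Deep copy of the canonical default parameter document."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _default_document()
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigurationError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigurationError(
                    f"{here} must be a mapping, got {type(value).__name__}")
            _merge(base[key], value, here)
        else:
            if isinstance(value, Mapping):
                raise ConfigurationError(f"{here} does not take a mapping")
            base[key] = value
    return base


@dataclass(frozen=True)
class BufferSet:
    """Cytosolic Ca2+ buffers: calmodulin (CaM) and calreticulin (CRT)."""
    cam_total: float     # mM
    cam_kd: float        # mM
    crt_total: float     # mM
    crt_kd: float        # mM


@dataclass(frozen=True)
class ModelParameters:
    """Validated hJSMC parameter set (units: mV, ms, pA, nS, pF, mM, L, K)."""
    C_m: float
    G_CaL: float
    G_CaT: float
    G_Kv: float
    G_BK: float
    G_Na: float
    G_NaLeak: float
    G_KLeak: float
    P_NaK: float
    k_NCX: float
    F: float
    V_c: float
    T: float
    Na_o: float
    K_o: float
    Ca_o: float
    nak_ncx: dict = field(repr=False)
    buffer_params: BufferSet = field(repr=False)
    gate_kinetics: dict = field(repr=False)
    markov_rates: dict = field(repr=False)
    initial: dict = field(repr=False)
    document: dict = field(repr=False)   # the effective config document
    ca_fixed: float = -1.0  # >0: free Ca2+ pinned (Ca2+-free protocol), mM

    @property
    def RTF(self) -> float:
        """Thermal voltage R*T/F in mV."""
        return R_GAS * self.T / FARADAY

    def with_overrides(self, overrides: Mapping) -> "ModelParameters":
        return load_parameters(self.document, overrides=overrides)


_GATE_IDS = ("m_CaT", "h_CaT", "x_Kv", "y_Kv")
_GATE_FIELDS = ("Vh", "k", "pedestal", "tau0", "tau_amp", "tau_mid",
                "tau_width")


def _require_positive(doc: dict, section: str, keys) -> None:
    for key in keys:
        if not doc[section][key] > 0:
            raise ValidationError(f"{section}.{key} must be strictly positive")


def _validate(doc: dict) -> None:
    _require_positive(doc, "membrane", ("C_m",))
    _require_positive(doc, "geometry", ("V_c", "T"))
    _require_positive(doc, "conductances",
                      ("G_CaL", "G_CaT", "G_Kv", "G_BK", "G_Na",
                       "G_NaLeak", "G_KLeak"))
    _require_positive(doc, "external", ("Na_o", "K_o", "Ca_o"))
    for name in ("P_NaK", "k_NCX"):
        if doc["pumps"][name] < 0:
            raise ValidationError(f"pumps.{name} must be nonnegative")
    g = doc["conductances"]
    leak = g["G_NaLeak"] + g["G_KLeak"]
    if g["G_Kv"] / leak < 45.0:
        # the >= 45-fold separation is a property of the default set; a
        # sensitivity variant may cross it, so flag rather than reject
        warnings.warn(
            "total leak conductance is less than 45-fold below G_Kv "
            f"(ratio {g['G_Kv'] / leak:.2f})", stacklevel=2)
    for bname in ("CaM", "CRT"):
        for key in ("total", "Kd"):
            if not doc["buffers"][bname][key] > 0:
                raise ValidationError(f"buffers.{bname}.{key} must be positive")
    for gid in _GATE_IDS:
        gd = doc["gates"][gid]
        if gd["k"] == 0:
            raise ValidationError(f"gates.{gid}.k must be nonzero")
        if not gd["tau0"] > 0 or gd["tau_amp"] < 0 or gd["tau_width"] == 0:
            raise ValidationError(f"gates.{gid} time-constant coefficients "
                                  "must give tau > 0")
        if not 0.0 <= gd["pedestal"] < 1.0:
            raise ValidationError(f"gates.{gid}.pedestal must be in [0, 1)")
    init = doc["initial"]
    for key in ("Na_i", "K_i", "Ca_total_i"):
        if not init[key] > 0:
            raise ValidationError(f"initial.{key} must be strictly positive")


def load_parameters(config: str | Mapping | None = None,
                    overrides: Mapping | None = None) -> ModelParameters:
    """Build a validated parameter set.

    ``config`` may be a path to a YAML document, an already-parsed mapping,
    or None for the package defaults.  ``overrides`` is an additional nested
    mapping merged last (e.g. from ``--set`` flags).
    """
    doc = default_document()
    if config is not None:
        if isinstance(config, (str,)):
            with open(config) as fh:
                loaded = yaml.safe_load(fh)
        else:
            loaded = config
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError("configuration root must be a mapping")
        _merge(doc, loaded)
    if overrides:
        _merge(doc, overrides)
    _validate(doc)
    g = doc["conductances"]
    return ModelParameters(
        C_m=float(doc["membrane"]["C_m"]),
        G_CaL=float(g["G_CaL"]), G_CaT=float(g["G_CaT"]),
        G_Kv=float(g["G_Kv"]), G_BK=float(g["G_BK"]), G_Na=float(g["G_Na"]),
        G_NaLeak=float(g["G_NaLeak"]), G_KLeak=float(g["G_KLeak"]),
        P_NaK=float(doc["pumps"]["P_NaK"]), k_NCX=float(doc["pumps"]["k_NCX"]),
        F=FARADAY,
        V_c=float(doc["geometry"]["V_c"]), T=float(doc["geometry"]["T"]),
        Na_o=float(doc["external"]["Na_o"]), K_o=float(doc["external"]["K_o"]),
        Ca_o=float(doc["external"]["Ca_o"]),
        nak_ncx={k: float(v) for k, v in doc["pumps"].items()
                 if k not in ("P_NaK", "k_NCX")},
        buffer_params=BufferSet(
            cam_total=float(doc["buffers"]["CaM"]["total"]),
            cam_kd=float(doc["buffers"]["CaM"]["Kd"]),
            crt_total=float(doc["buffers"]["CRT"]["total"]),
            crt_kd=float(doc["buffers"]["CRT"]["Kd"])),
        gate_kinetics=copy.deepcopy(doc["gates"]),
        markov_rates=copy.deepcopy(doc["markov"]),
        initial=copy.deepcopy(doc["initial"]),
        document=doc,
    )


def serialize(params: ModelParameters) -> str:
    """YAML document of the effective parameter values (round-trips exactly)."""
    return yaml.safe_dump(params.document, sort_keys=False)


# ---------------------------------------------------------------------------
# packing into kernel arrays
# ---------------------------------------------------------------------------

def pack_scalars(params: ModelParameters) -> np.ndarray:
    sc = np.zeros(K.N_SC)
    sc[K.SC_CM] = params.C_m
    sc[K.SC_GCAL] = params.G_CaL
    sc[K.SC_GCAT] = params.G_CaT
    sc[K.SC_GKV] = params.G_Kv
    sc[K.SC_GBK] = params.G_BK
    sc[K.SC_GNA] = params.G_Na
    sc[K.SC_GNALEAK] = params.G_NaLeak
    sc[K.SC_GKLEAK] = params.G_KLeak
    sc[K.SC_PNAK] = params.P_NaK
    sc[K.SC_KNCX] = params.k_NCX
    sc[K.SC_F] = params.F
    sc[K.SC_VC] = params.V_c
    sc[K.SC_T] = params.T
    sc[K.SC_NAO] = params.Na_o
    sc[K.SC_KO] = params.K_o
    sc[K.SC_CAO] = params.Ca_o
    nn = params.nak_ncx
    sc[K.SC_KMK] = nn["K_mK"]
    sc[K.SC_KMNA] = nn["K_mNa"]
    sc[K.SC_GAMMA] = nn["gamma"]
    sc[K.SC_KMNAI] = nn["K_mNai"]
    sc[K.SC_KMCA] = nn["K_mCa"]
    sc[K.SC_KSAT] = nn["k_sat"]
    sc[K.SC_ALPHA] = nn["alpha_NCX"]
    b = params.buffer_params
    sc[K.SC_B1TOT] = b.cam_total
    sc[K.SC_B1KD] = b.cam_kd
    sc[K.SC_B2TOT] = b.crt_total
    sc[K.SC_B2KD] = b.crt_kd
    sc[K.SC_CAFIXED] = params.ca_fixed
    return sc


def pack_gates(params: ModelParameters) -> np.ndarray:
    table = np.zeros((4, K.N_GATE_COEF))
    for row, gid in enumerate(_GATE_IDS):
        gd = params.gate_kinetics[gid]
        for col, name in enumerate(_GATE_FIELDS):
            table[row, col] = gd[name]
    return table


def pack_markov(params: ModelParameters) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray]:
    m = params.markov_rates
    cal = np.array([m["CaL"][k] for k in
                    ("a0", "sa", "b0", "sb", "kvi", "svi", "rv0", "srv",
                     "kci_max", "Kci", "rci")] + [0.0])
    bk = np.array([m["BK"][k] for k in
                   ("k_on", "Kd_C", "Kd_O", "theta0", "delta0", "q_f", "q_b")])
    nav = np.array([m["Na"][k] for k in
                    ("a0", "sa", "b0", "sb", "h1", "hr0", "shr", "s1",
                     "s20", "ss2")])
    return cal, bk, nav
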