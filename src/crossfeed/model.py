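"""Core chemostat cross-feeding model.

Two *E. coli*-like strains compete for a single limiting sugar (glucose) in a
chemostat.  Catabolism is collapsed into two lumped reactions: glycolysis
(sugar -> intracellular intermediate, low ATP yield) and the TCA cycle
(intermediate -> CO2, high ATP yield).  The intermediate (acetate) can be
excreted and re-imported through a reversible saturating transporter, and the
acetate specialist additionally carries a high-affinity uptake enzyme
(acetyl-CoA synthetase-like).  Intracellular intermediate inhibits growth.

State vector (culture-level concentrations / densities):

    S      glucose in the vessel                [umol/L]
    Xex    extracellular intermediate (acetate) [umol/L]
    N1     glucose-specialist density           [cells/L]
    N2     acetate-specialist density           [cells/L]
    Xin1   strain-1 intracellular intermediate  [umol/L of culture]
    Xin2   strain-2 intracellular intermediate  [umol/L of culture]

Dynamics:

    dS/dt    = D (S0 - S) - vg1(S) N1 - vg2(S) N2
    dXex/dt  = vr1(Xin1-Xex) N1 + (vr2(Xin2-Xex) - vhat(Xex)) N2 - D Xex
               [+ D A_in when acetate is supplied in the inflow]
    dN1/dt   = [G (ng vg1(S) + ntca vt1(Xin1)) c1(Xin1) - D] N1
    dN2/dt   = [G (ng vg2(S) + ntca vt2(Xin2)) c2(Xin2) - D] N2
    dXin1/dt = (2 vg1(S) - vt1(Xin1) - vr1(Xin1-Xex)) N1 - D Xin1
    dXin2/dt = (2 vg2(S) - vt2(Xin2) - vr2(Xin2-Xex) + vhat(Xex)) N2 - D Xin2

The factor 2 in the intermediate equations is stoichiometric: one hexose
yields two trioses.  The intracellular pools are culture-level quantities
(diluted at D, fed by per-cell rates times density), which makes rare-type
physiology density dependent — the mechanism behind the invasion thresholds
this package analyses.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "KineticParams",
    "Environment",
    "State",
    "STATE_FIELDS",
    "STATE_UNITS",
    "DomainError",
    "v_g",
    "v_tca",
    "v_rt",
    "v_hat",
    "cost",
    "growth_rate",
    "rhs",
    "rhs_array",
    "carbon_balance_rhs_residual",
    "percent_wv_to_umolL",
    "umolL_to_percent_wv",
    "load_params",
    "save_params",
    "params_hash",
    "GLUCOSE_MOLAR_MASS",
]

# molar mass of D-glucose [g/mol]
GLUCOSE_MOLAR_MASS = 180.156

STATE_FIELDS = ("S", "Xex", "N1", "N2", "Xin1", "Xin2")
STATE_UNITS = {
    "S": "umol/L",
    "Xex": "umol/L",
    "N1": "cells/L",
    "N2": "cells/L",
    "Xin1": "umol/L",
    "Xin2": "umol/L",
}

# how far below zero a state component may drift before it is treated as a
# genuine domain violation rather than integrator round-off
NEGATIVE_STATE_SLACK = 1e-6


class DomainError(ValueError):
    """Raised when a kinetic function or the RHS receives an invalid input."""


# ---------------------------------------------------------------------------
# saturating-kinetics and cost-function registries
#
# The model fixes only that all reactions follow saturating enzyme
# kinetics; concrete functional forms are configuration, not code.
# Each uptake form maps (x, Vmax, Km) -> rate; each cost form maps
# (Xin, Kc) -> multiplicative growth factor in (0, 1].

def _michaelis_menten(x, vmax, km):
    return vmax * x / (km + x)


def _odd_saturating(delta, vmax, km):
    # odd in delta: positive gradient -> excretion, negative -> uptake
    return vmax * delta / (km + np.abs(delta))


def _cost_hyperbolic(xin, kc):
    return 1.0 / (1.0 + xin / kc)


def _cost_none(xin, kc):
    return np.ones_like(np.asarray(xin, dtype=float)) if np.ndim(xin) else 1.0


UPTAKE_FORMS: dict[str, Callable] = {"michaelis_menten": _michaelis_menten}
TRANSPORT_FORMS: dict[str, Callable] = {"odd_saturating": _odd_saturating}
COST_FORMS: dict[str, Callable] = {"hyperbolic": _cost_hyperbolic, "none": _cost_none}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class KineticParams:
    """Per-strain kinetic constants and shared growth/yield constants.

    Strain index 1 is the glucose specialist (fermenter-like, CV103 analogue),
    strain index 2 the acetate specialist (respirer-like, CV101 analogue).
    All Vmax values are per-cell rates [umol cell^-1 h^-1]; all Km / Kc values
    are concentrations [umol/L].
    """

    # glucose (glycolysis) uptake
    Vmax_g: tuple[float, float]
    Km_g: tuple[float, float]
    # TCA-cycle consumption of the intracellular intermediate
    Vmax_tca: tuple[float, float]
    Km_tca: tuple[float, float]
    # reversible transport of the intermediate across the membrane
    Vrt: tuple[float, float]
    Krt: tuple[float, float]
    # high-affinity acetate uptake, carried only by strain 2
    Vhat: float
    Khat: float
    # ATP yields per reaction and growth-per-ATP proportionality constant
    n_g: float
    n_tca: float
    G: float  # [cells/umol ATP]
    # growth-inhibition scale of the intracellular intermediate
    Kc: tuple[float, float]
    # functional-form selectors (configuration, not code)
    uptake_form: str = "michaelis_menten"
    transport_form: str = "odd_saturating"
    cost_form: str = "hyperbolic"
    provenance: str = "fallback"

    def __post_init__(self):
        for name in ("Vmax_g", "Km_g", "Vmax_tca", "Km_tca", "Vrt", "Krt", "Kc"):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        strictly_positive = {
            "Km_g": self.Km_g, "Km_tca": self.Km_tca, "Krt": self.Krt,
            "Kc": self.Kc, "Vmax_g": self.Vmax_g, "Vmax_tca": self.Vmax_tca,
            "Vrt": self.Vrt,
        }
        for name, pair in strictly_positive.items():
            if len(pair) != 2:
                raise DomainError(f"{name} must have one value per strain")
            if any(not np.isfinite(v) or v <= 0 for v in pair):
                raise DomainError(f"{name} must be strictly positive, got {pair}")
        for name, val in (("n_g", self.n_g), ("n_tca", self.n_tca),
                          ("G", self.G), ("Khat", self.Khat)):
            if not np.isfinite(val) or val <= 0:
                raise DomainError(f"{name} must be strictly positive, got {val}")
        # Vhat may be zero: strain 1 negligibly expresses the enzyme, and the
        # model assigns it to strain 2 only.
        if not np.isfinite(self.Vhat) or self.Vhat < 0:
            raise DomainError(f"Vhat must be nonnegative, got {self.Vhat}")
        # rate-yield trade-off: the glucose specialist has the larger maximum
        # glucose uptake rate
        if not self.Vmax_g[0] > self.Vmax_g[1]:
            raise DomainError(
                "trade-off violated: Vmax_g of the glucose specialist must "
                f"exceed the acetate specialist's ({self.Vmax_g[0]} <= {self.Vmax_g[1]})"
            )
        for sel, registry in ((self.uptake_form, UPTAKE_FORMS),
                              (self.transport_form, TRANSPORT_FORMS),
                              (self.cost_form, COST_FORMS)):
            if sel not in registry:
                raise DomainError(f"unknown functional form {sel!r}; "
                                  f"choose from {sorted(registry)}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)

    def replace(self, **changes) -> "KineticParams":
        d = self.to_dict()
        d.update(changes)
        return KineticParams.from_dict(d)


@dataclass
class Environment:
    """Chemostat settings.

    D     dilution rate [1/h]
    S0    glucose concentration in the inflow [umol/L]
    A_in  acetate concentration in the inflow [umol/L]; 0 unless the
          acetate-supplementation scenario is active
    """

    D: float
    S0: float
    A_in: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.D) or self.D <= 0:
            raise DomainError(f"D must be > 0, got {self.D}")
        if not np.isfinite(self.S0) or self.S0 < 0:
            raise DomainError(f"S0 must be >= 0, got {self.S0}")
        if not np.isfinite(self.A_in) or self.A_in < 0:
            raise DomainError(f"A_in must be >= 0, got {self.A_in}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(**d)

    def replace(self, **changes) -> "Environment":
        d = self.to_dict()
        d.update(changes)
        return Environment.from_dict(d)


@dataclass
class State:
    """A point in the six-dimensional state space (see module docstring)."""

    S: float
    Xex: float
    N1: float
    N2: float
    Xin1: float
    Xin2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.Xex, self.N1, self.N2, self.Xin1, self.Xin2],
                        dtype=float)

    @classmethod
    def from_array(cls, y) -> "State":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise DomainError(f"state must have 6 components, got shape {y.shape}")
        return cls(*y)

    @classmethod
    def washout(cls, env: Environment) -> "State":
        """The washout equilibrium: fresh medium, no cells."""
        return cls(S=env.S0, Xex=0.0, N1=0.0, N2=0.0, Xin1=0.0, Xin2=0.0)

    @classmethod
    def fresh_inoculum(cls, env: Environment, N_total: float, f2: float,
                       Xex0: float = 0.0) -> "State":
        """Cells inoculated into fresh medium.

        Intracellular pools start at zero; ``Xex0`` allows an acetate bolus.
        """
        if not 0.0 <= f2 <= 1.0:
            raise DomainError(f"f2 must lie in [0, 1], got {f2}")
        if N_total < 0 or Xex0 < 0:
            raise DomainError("densities and concentrations must be nonnegative")
        return cls(S=env.S0, Xex=Xex0, N1=N_total * (1.0 - f2),
                   N2=N_total * f2, Xin1=0.0, Xin2=0.0)

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise DomainError(f"non-finite state component: {self}")
        if np.any(y < -NEGATIVE_STATE_SLACK):
            raise DomainError(f"negative state component: {self}")


# ---------------------------------------------------------------------------
# kinetic rate functions


def _strain_index(i: int) -> int:
    if i not in (1, 2):
        raise DomainError(f"strain index must be 1 or 2, got {i}")
    return i - 1


def v_g(params: KineticParams, S: float, i: int) -> float:
    """Glucose (glycolysis) uptake rate of strain ``i`` at sugar level ``S``."""
    if np.any(np.asarray(S) < 0):
        raise DomainError(f"negative substrate concentration: {S}")
    k = _strain_index(i)
    return UPTAKE_FORMS[params.uptake_form](S, params.Vmax_g[k], params.Km_g[k])


def v_tca(params: KineticParams, Xin: float, i: int) -> float:
    """TCA-cycle consumption rate of the intracellular intermediate."""
    if np.any(np.asarray(Xin) < 0):
        raise DomainError(f"negative intermediate concentration: {Xin}")
    k = _strain_index(i)
    return UPTAKE_FORMS[params.uptake_form](Xin, params.Vmax_tca[k], params.Km_tca[k])


def v_rt(params: KineticParams, delta: float, i: int) -> float:
    """Net reversible transport at gradient ``delta`` = Xin_i - Xex.

    Odd and saturating: positive values mean net excretion, negative net
    uptake of the extracellular intermediate.
    """
    k = _strain_index(i)
    return TRANSPORT_FORMS[params.transport_form](delta, params.Vrt[k], params.Krt[k])


def v_hat(params: KineticParams, Xex: float) -> float:
    """High-affinity acetate uptake (strain 2 only; no ATP cofactor)."""
    if np.any(np.asarray(Xex) < 0):
        raise DomainError(f"negative acetate concentration: {Xex}")
    return UPTAKE_FORMS[params.uptake_form](Xex, params.Vhat, params.Khat)


def cost(params: KineticParams, Xin: float, i: int) -> float:
    """Growth-inhibition factor c_i(Xin) in (0, 1]; c_i(0) = 1."""
    if np.any(np.asarray(Xin) < 0):
        raise DomainError(f"negative intermediate concentration: {Xin}")
    k = _strain_index(i)
    return COST_FORMS[params.cost_form](Xin, params.Kc[k])


def growth_rate(params: KineticParams, state: State, i: int) -> float:
    """Per-capita growth rate mu_i = G (ng vg + ntca vtca) c_i."""
    Xin = state.Xin1 if i == 1 else state.Xin2
    return (params.G
            * (params.n_g * v_g(params, state.S, i)
               + params.n_tca * v_tca(params, Xin, i))
            * cost(params, Xin, i))


# ---------------------------------------------------------------------------
# right-hand side


def rhs_array(y: np.ndarray, params: KineticParams, env: Environment) -> np.ndarray:
    """Unvalidated fast path of the RHS, for integrators and root-finders.

    Mildly negative components (integrator probing) are evaluated as-is: all
    saturating forms are well defined there and pull the flow back toward the
    nonnegative orthant.
    """
    S, Xex, N1, N2, Xi1, Xi2 = y
    up = UPTAKE_FORMS[params.uptake_form]
    tr = TRANSPORT_FORMS[params.transport_form]
    co = COST_FORMS[params.cost_form]

    vg1 = up(S, params.Vmax_g[0], params.Km_g[0])
    vg2 = up(S, params.Vmax_g[1], params.Km_g[1])
    vt1 = up(Xi1, params.Vmax_tca[0], params.Km_tca[0])
    vt2 = up(Xi2, params.Vmax_tca[1], params.Km_tca[1])
    vr1 = tr(Xi1 - Xex, params.Vrt[0], params.Krt[0])
    vr2 = tr(Xi2 - Xex, params.Vrt[1], params.Krt[1])
    vh = up(Xex, params.Vhat, params.Khat)
    mu1 = params.G * (params.n_g * vg1 + params.n_tca * vt1) * co(Xi1, params.Kc[0])
    mu2 = params.G * (params.n_g * vg2 + params.n_tca * vt2) * co(Xi2, params.Kc[1])

    D = env.D
    return np.array([
        D * (env.S0 - S) - vg1 * N1 - vg2 * N2,
        vr1 * N1 + (vr2 - vh) * N2 - D * Xex + D * env.A_in,
        (mu1 - D) * N1,
        (mu2 - D) * N2,
        (2.0 * vg1 - vt1 - vr1) * N1 - D * Xi1,
        (2.0 * vg2 - vt2 - vr2 + vh) * N2 - D * Xi2,
    ])


def rhs(state: State, params: KineticParams, env: Environment) -> State:
    """Validated right-hand side; rejects NaN or negative states."""
    state.validate()
    return State.from_array(rhs_array(state.as_array(), params, env))


def carbon_balance_rhs_residual(y: np.ndarray, params: KineticParams,
                                env: Environment) -> float:
    """Residual of the triose-unit balance implied by the model equations.

    Summing the equations with weights (2, 1, 0, 0, 1, 1) all transport terms
    cancel pairwise, leaving

        dC/dt = D (2 S0 + A_in - C) - vtca1 N1 - vtca2 N2,   C = 2S+Xex+Xin1+Xin2.

    Returns the difference between the weighted sum of the implemented RHS and
    that expression — zero up to round-off for a correct implementation.
    """
    S, Xex, N1, N2, Xi1, Xi2 = y
    dy = rhs_array(np.asarray(y, dtype=float), params, env)
    lhs = 2.0 * dy[0] + dy[1] + dy[4] + dy[5]
    C = 2.0 * S + Xex + Xi1 + Xi2
    up = UPTAKE_FORMS[params.uptake_form]
    sink = (up(Xi1, params.Vmax_tca[0], params.Km_tca[0]) * N1
            + up(Xi2, params.Vmax_tca[1], params.Km_tca[1]) * N2)
    return float(lhs - (env.D * (2.0 * env.S0 + env.A_in - C) - sink))


# ---------------------------------------------------------------------------
# units


def percent_wv_to_umolL(p: float) -> float:
    """Convert glucose % weight/volume to umol/L (0.025 % -> ~1.39e3)."""
    if np.any(np.asarray(p) < 0):
        raise DomainError(f"negative concentration: {p}")
    return p * 10.0 / GLUCOSE_MOLAR_MASS * 1e6


def umolL_to_percent_wv(c: float) -> float:
    if np.any(np.asarray(c) < 0):
        raise DomainError(f"negative concentration: {c}")
    return c * GLUCOSE_MOLAR_MASS / 1e6 / 10.0


# ---------------------------------------------------------------------------
# configuration files


def _config_to_objects(cfg: dict) -> tuple[KineticParams, Environment]:
    s1, s2, sh = cfg["strain1"], cfg["strain2"], cfg["shared"]
    params = KineticParams(
        Vmax_g=(s1["Vmax_g"], s2["Vmax_g"]),
        Km_g=(s1["Km_g"], s2["Km_g"]),
        Vmax_tca=(s1["Vmax_tca"], s2["Vmax_tca"]),
        Km_tca=(s1["Km_tca"], s2["Km_tca"]),
        Vrt=(s1["Vrt"], s2["Vrt"]),
        Krt=(s1["Krt"], s2["Krt"]),
        Kc=(s1["Kc"], s2["Kc"]),
        Vhat=s2.get("Vhat", 0.0),
        Khat=s2.get("Khat", 1.0),
        n_g=sh["n_g"], n_tca=sh["n_tca"], G=sh["G"],
        uptake_form=cfg.get("forms", {}).get("uptake", "michaelis_menten"),
        transport_form=cfg.get("forms", {}).get("transport", "odd_saturating"),
        cost_form=cfg.get("forms", {}).get("cost", "hyperbolic"),
        provenance=cfg.get("provenance", "fallback"),
    )
    e = cfg.get("environment", {})
    env = Environment(D=e.get("D", 0.2), S0=e.get("S0", 350.0),
                      A_in=e.get("A_in", 0.0))
    return params, env


def _objects_to_config(params: KineticParams, env: Environment) -> dict:
    def strain(k):
        d = {
            "Vmax_g": params.Vmax_g[k], "Km_g": params.Km_g[k],
            "Vmax_tca": params.Vmax_tca[k], "Km_tca": params.Km_tca[k],
            "Vrt": params.Vrt[k], "Krt": params.Krt[k], "Kc": params.Kc[k],
        }
        if k == 1:
            d["Vhat"] = params.Vhat
            d["Khat"] = params.Khat
        return d

    return {
        "provenance": params.provenance,
        "strain1": strain(0),
        "strain2": strain(1),
        "shared": {"n_g": params.n_g, "n_tca": params.n_tca, "G": params.G},
        "forms": {"uptake": params.uptake_form,
                  "transport": params.transport_form,
                  "cost": params.cost_form},
        "environment": env.to_dict(),
    }


def load_params(path=None) -> tuple[KineticParams, Environment]:
    """Load a parameter/environment config; default is the packaged baseline."""
    if path is None:
        text = resources.files("crossfeed.data").joinpath("baseline.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    return _config_to_objects(cfg)


def save_params(params: KineticParams, env: Environment, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_objects_to_config(params, env), fh, sort_keys=False)


def params_hash(params: KineticParams, env: Environment | None = None) -> str:
    """Stable short hash of a configuration, for output manifests."""
    payload = copy.deepcopy(params.to_dict())
    if env is not None:
        payload["environment"] = env.to_dict()
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
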