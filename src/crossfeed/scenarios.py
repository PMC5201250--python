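"""Canned experiment scenarios and synthetic parameter ensembles.

This module encodes the study conditions the analyses run under: the shipped
baseline parameter set, the figure-style experiment recipes (bifurcation
sweep, outcome map, acetate supplementation, density effect, bistable
invasion pair, invasion-threshold sweeps) and trade-off-preserving
multiplicative parameter perturbations for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .model import (Environment, KineticParams, DomainError, load_params,
                    percent_wv_to_umolL)
from .simulate import run_mixed_culture, acetate_supplement_sweep
from .bifurcation import (continue_branches, classify_regimes, outcome_map,
                          invasion_threshold, monoculture_max_density)

__all__ = [
    "ScenarioSpec",
    "PerturbationEnsemble",
    "baseline_parameters",
    "sample_perturbations",
    "figure_scenarios",
    "run_scenario",
    "regime_sequence",
]

#: perturbable scale parameters (log-uniform multiplicative sampling)
PERTURBABLE = ("Vmax_g", "Km_g", "Vmax_tca", "Km_tca", "Vrt", "Krt", "Kc",
               "Vhat", "Khat", "G")


def baseline_parameters(path=None) -> tuple[KineticParams, Environment]:
    """The shipped baseline parameter set and environment.

    The set is the documented fallback calibration (provenance ``fallback``
    in run manifests): strain 1 is fermenter-like (fast glucose uptake,
    modest TCA capacity, excretes the intermediate), strain 2 respirer-like
    with a high-affinity acetate uptake enzyme.
    """
    return load_params(path)


# ---------------------------------------------------------------------------
# scenario specs


@dataclass
class ScenarioSpec:
    """A named, fully serializable analysis recipe."""

    name: str
    analysis: str                     # simulate | map | continue | threshold | sweep
    environment: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    expected: str | None = None       # optional qualitative assertion

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(text))


S0_FIG4 = percent_wv_to_umolL(0.025)   # ~1387.7 umol/L


def figure_scenarios() -> list[ScenarioSpec]:
    """One canned scenario per headline analysis of the study."""
    return [
        ScenarioSpec(
            name="fig2a_bifurcation", analysis="continue",
            environment={"D": 0.2},
            settings={"S0_min": 2.0, "S0_max": 1500.0, "n_S0": 40,
                      "log_spacing": True},
            expected="regime sequence washout-only -> N1-only -> bistable -> tristable",
        ),
        ScenarioSpec(
            name="fig2b_outcome_map", analysis="map",
            environment={"D": 0.2, "S0": 350.0},
            settings={"n_density": 40, "n_freq": 40,
                      "density_min_rel": 1e-3, "density_max_rel": 1.5},
            expected="all three non-washout outcomes present",
        ),
        ScenarioSpec(
            name="fig3a_acetate_supplement", analysis="sweep",
            environment={"D": 0.2, "S0": S0_FIG4},
            settings={"A_in_values": [0.0, 100.0, 200.0, 400.0, 800.0],
                      "generations": 30, "f2_0": 0.5},
            expected="terminal glucose-specialist frequency non-increasing in A_in",
        ),
        ScenarioSpec(
            name="fig3b_density_effect", analysis="sweep",
            environment={"D": 0.2},
            settings={"S0_percent_wv": [0.00625, 0.0125, 0.025, 0.05, 0.1],
                      "generations": 30, "f2_0": 0.5},
            expected="terminal glucose-specialist frequency non-increasing in S0",
        ),
        ScenarioSpec(
            name="fig4_bistable_invasion", analysis="simulate",
            environment={"D": 0.2, "S0": S0_FIG4},
            settings={"f2_values": [0.0032, 0.0033], "generations": 500,
                      "density": "monoculture_max"},
            expected="opposite outcomes for the two initial frequencies",
        ),
        ScenarioSpec(
            name="fig5a_threshold_vs_density", analysis="threshold",
            environment={"D": 0.2, "S0": S0_FIG4},
            settings={"relative_densities": [0.1, 0.25, 0.5, 0.75, 1.0],
                      "resolution": 1e-4},
            expected="threshold non-increasing in initial density",
        ),
        ScenarioSpec(
            name="fig5b_threshold_vs_S0", analysis="threshold",
            environment={"D": 0.2},
            settings={"S0_percent_wv": [0.0125, 0.01875, 0.025],
                      "resolution": 1e-4},
            expected="threshold non-increasing in S0",
        ),
    ]


def _env_from(spec: ScenarioSpec, base_env: Environment,
              S0: float | None = None) -> Environment:
    d = dict(base_env.to_dict())
    d.update(spec.environment)
    if S0 is not None:
        d["S0"] = S0
    return Environment.from_dict(d)


def regime_sequence(params: KineticParams, D: float = 0.2,
                    S0_min: float = 2.0, S0_max: float = 1500.0,
                    n_S0: int = 40, log_spacing: bool = True,
                    n_starts: int = 48, seed: int = 0):
    """Continuation over S0 plus the derived regime intervals."""
    grid = (np.geomspace(S0_min, S0_max, n_S0) if log_spacing
            else np.linspace(S0_min, S0_max, n_S0))
    branches = continue_branches(params, D, grid, n_starts=n_starts, seed=seed)
    return branches, classify_regimes(branches, grid)


def run_scenario(spec: ScenarioSpec, params: KineticParams | None = None,
                 env: Environment | None = None, seed: int = 0):
    """Execute a scenario and return its result object.

    Results: ``continue`` -> (branches, regimes); ``map`` -> OutcomeMap;
    ``sweep``/``threshold`` -> tidy DataFrame; ``simulate`` -> list of
    (f2_0, Trajectory, Outcome).
    """
    if params is None or env is None:
        p0, e0 = baseline_parameters()
        params = params or p0
        env = env or e0
    s = spec.settings

    if spec.analysis == "continue":
        return regime_sequence(params, D=spec.environment.get("D", env.D),
                               S0_min=s["S0_min"], S0_max=s["S0_max"],
                               n_S0=s["n_S0"],
                               log_spacing=s.get("log_spacing", True),
                               seed=seed)

    if spec.analysis == "map":
        run_env = _env_from(spec, env)
        n_max = monoculture_max_density(params, run_env)
        dens = np.geomspace(s["density_min_rel"], s["density_max_rel"],
                            s["n_density"]) * n_max
        freq = np.linspace(0.0, 1.0, s["n_freq"])
        return outcome_map(params, run_env, dens, freq)

    if spec.analysis == "sweep" and "A_in_values" in s:
        run_env = _env_from(spec, env)
        n_max = monoculture_max_density(params, run_env)
        return acetate_supplement_sweep(params, run_env, s["A_in_values"],
                                        N_total0=n_max, f2_0=s["f2_0"],
                                        g_end=s["generations"])

    if spec.analysis == "sweep" and "S0_percent_wv" in s:
        rows = []
        for p_wv in s["S0_percent_wv"]:
            run_env = _env_from(spec, env, S0=percent_wv_to_umolL(p_wv))
            n_max = monoculture_max_density(params, run_env)
            traj, _ = run_mixed_culture(params, run_env, n_max, s["f2_0"],
                                        g_end=s["generations"],
                                        classify=False)
            f2 = float(traj.f2[-1])
            rows.append({"S0_percent_wv": p_wv,
                         "S0_umol_per_L": run_env.S0,
                         "f1_final": 1.0 - f2, "f2_final": f2})
        return pd.DataFrame(rows)

    if spec.analysis == "simulate":
        run_env = _env_from(spec, env)
        n0 = (monoculture_max_density(params, run_env)
              if s.get("density") == "monoculture_max" else float(s["density"]))
        out = []
        for f2 in s["f2_values"]:
            traj, outcome = run_mixed_culture(params, run_env, n0, f2,
                                              g_end=s["generations"])
            out.append((f2, traj, outcome))
        return out

    if spec.analysis == "threshold":
        rows = []
        if "relative_densities" in s:
            run_env = _env_from(spec, env)
            n_max = monoculture_max_density(params, run_env)
            for rel in s["relative_densities"]:
                thr, (lo, hi) = invasion_threshold(
                    params, run_env, rel * n_max,
                    resolution=s.get("resolution", 1e-4))
                rows.append({"relative_density": rel, "threshold_f2": thr,
                             "bracket_lo": lo, "bracket_hi": hi})
        else:
            for p_wv in s["S0_percent_wv"]:
                run_env = _env_from(spec, env, S0=percent_wv_to_umolL(p_wv))
                n_max = monoculture_max_density(params, run_env)
                thr, (lo, hi) = invasion_threshold(
                    params, run_env, n_max,
                    f_bracket=(1e-5, 0.05),
                    resolution=s.get("resolution", 1e-4))
                rows.append({"S0_percent_wv": p_wv,
                             "S0_umol_per_L": run_env.S0,
                             "threshold_f2": thr,
                             "bracket_lo": lo, "bracket_hi": hi})
        return pd.DataFrame(rows)

    raise DomainError(f"unknown analysis type {spec.analysis!r}")


# ---------------------------------------------------------------------------
# perturbation ensembles


@dataclass
class PerturbationEnsemble:
    """Log-uniform multiplicative perturbations around a base parameter set.

    ``span`` is the one-sided multiplicative range: each perturbable scale
    parameter is multiplied by a factor drawn log-uniformly from
    [1/span, span] (default span 1.2, i.e. roughly +/-20 %).  Samples that
    violate the trade-off structure (strain 1 the faster glucose consumer,
    strain 2 the sole carrier of the high-affinity acetate enzyme) are
    rejected.
    """

    base: KineticParams
    span: float = 1.2
    n_samples: int = 50
    seed: int = 0
    parameters: tuple = PERTURBABLE

    def __post_init__(self):
        if self.span < 1.0:
            raise DomainError(f"span must be >= 1, got {self.span}")


def _perturb_once(base: KineticParams, rng, span: float,
                  names) -> KineticParams:
    d = base.to_dict()
    lo, hi = -np.log(span), np.log(span)
    for name in names:
        v = d[name]
        if isinstance(v, list):
            d[name] = [x * float(np.exp(rng.uniform(lo, hi))) for x in v]
        else:
            if name == "Vhat" and v == 0.0:
                continue
            d[name] = v * float(np.exp(rng.uniform(lo, hi)))
    return KineticParams.from_dict(d)


def sample_perturbations(ensemble: PerturbationEnsemble) -> list[KineticParams]:
    """Draw trade-off-consistent perturbed parameter sets, reproducibly.

    Raises if fewer than 10 % of proposals satisfy the constraints, so a
    mis-specified ensemble can never silently collapse to nothing.
    """
    rng = np.random.default_rng(ensemble.seed)
    out: list[KineticParams] = []
    proposals = 0
    max_proposals = max(10 * ensemble.n_samples, 100)
    while len(out) < ensemble.n_samples:
        if proposals >= max_proposals:
            rate = len(out) / proposals
            raise DomainError(
                f"constraint acceptance rate {rate:.1%} is below 10%; "
                "widen or re-center the ensemble")
        proposals += 1
        try:
            cand = _perturb_once(ensemble.base, rng, ensemble.span,
                                 ensemble.parameters)
        except DomainError:
            continue  # violated an invariant (e.g. trade-off); reject
        out.append(cand)
    return out
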