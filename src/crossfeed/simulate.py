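"""Time-course integration, generation accounting and outcome classification.

The chemostat model is stiff when densities are high (per-cell rates around
1e-9 multiply densities around 1e12), so integration defaults to LSODA with
component-wise absolute tolerances scaled to the problem: concentrations scale
with the inflow concentration S0, densities with the initial total density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (Environment, KineticParams, State, STATE_FIELDS,
                    STATE_UNITS, DomainError, rhs_array,
                    carbon_balance_rhs_residual)

__all__ = [
    "Trajectory",
    "Outcome",
    "IntegrationError",
    "integrate",
    "generations_to_time",
    "time_to_generations",
    "classify_outcome",
    "run_mixed_culture",
    "acetate_supplement_sweep",
]

OUTCOME_LABELS = ("washout", "N1_only", "N2_only", "coexistence", "undecided")

#: relative extinction threshold: a strain below this fraction of the initial
#: total density is considered extinct (well below one cell per realistic
#: culture volume)
EXTINCTION_THRESHOLD = 1e-6

#: default decision horizon for "long-term" outcomes, in generations
DECISION_GENERATIONS = 500.0

#: trailing fraction of a trajectory used for persistence / settling checks
TRAILING_WINDOW = 0.2

#: relative variation below which the trailing window counts as settled
SETTLE_RTOL = 1e-3


class IntegrationError(RuntimeError):
    pass


def generations_to_time(g: float, D: float) -> float:
    """Convert generations to hours via the steady-state chemostat doubling
    time ln(2)/D (growth balances dilution)."""
    if g < 0:
        raise DomainError(f"generations must be >= 0, got {g}")
    if D <= 0:
        raise DomainError(f"D must be > 0, got {D}")
    return g * np.log(2.0) / D


def time_to_generations(t: float, D: float) -> float:
    return t * D / np.log(2.0)


@dataclass(eq=False)
class Trajectory:
    """Integrated time course with derived population series."""

    t: np.ndarray           # [h], strictly increasing
    y: np.ndarray           # 6 x n_t state matrix
    params: KineticParams
    env: Environment
    rtol: float
    atol: np.ndarray

    @property
    def total_density(self) -> np.ndarray:
        return self.y[2] + self.y[3]

    @property
    def f2(self) -> np.ndarray:
        """Frequency of the acetate specialist, N2/(N1+N2)."""
        tot = self.total_density
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.y[3] / tot, np.nan)

    @property
    def generations(self) -> np.ndarray:
        return time_to_generations(self.t, self.env.D)

    @property
    def final_state(self) -> State:
        return State.from_array(np.maximum(self.y[:, -1], 0.0))

    def carbon_balance_residual(self) -> float:
        """Largest residual of the triose balance along the stored points,
        normalised by the dilution flux scale D*(2*S0 + A_in)."""
        res = max(abs(carbon_balance_rhs_residual(self.y[:, k], self.params, self.env))
                  for k in range(self.y.shape[1]))
        scale = self.env.D * (2.0 * self.env.S0 + self.env.A_in) + 1e-300
        return res / scale

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_h": self.t, "generations": self.generations}
        for k, name in enumerate(STATE_FIELDS):
            cols[f"{name}_{STATE_UNITS[name].replace('/', '_per_')}"] = self.y[k]
        cols["f2"] = self.f2
        return pd.DataFrame(cols)


@dataclass
class Outcome:
    label: str
    terminal_state: State
    decision_time: float     # [h]
    f2_final: float

    def __post_init__(self):
        if self.label not in OUTCOME_LABELS:
            raise ValueError(f"unknown outcome label {self.label!r}")


def _default_atol(env: Environment, state0: np.ndarray) -> np.ndarray:
    conc = max(env.S0 + env.A_in, 1.0) * 1e-9
    nref = max(state0[2] + state0[3], 1.0)
    dens = max(nref * 1e-9, 1e-6)
    return np.array([conc, conc, dens, dens, conc, conc])


def integrate(params: KineticParams, env: Environment, state0: State,
              t_end: float, rtol: float = 1e-8, atol=None,
              n_points: int = 200, method: str = "LSODA",
              t_eval=None) -> Trajectory:
    """Integrate the model from ``state0`` for ``t_end`` hours.

    Negative-state policy is rejection, not clamping: if any component of the
    computed trajectory falls below a small tolerance-derived slack the run
    raises :class:`IntegrationError` instead of silently projecting back.
    """
    state0.validate()
    if t_end <= 0:
        raise DomainError(f"t_end must be > 0, got {t_end}")
    y0 = np.maximum(state0.as_array(), 0.0)
    if atol is None:
        atol = _default_atol(env, y0)
    atol = np.asarray(atol, dtype=float)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)

    sol = solve_ivp(lambda t, y: rhs_array(y, params, env), (0.0, t_end), y0,
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    floor = -100.0 * atol[:, None]
    if np.any(sol.y < floor):
        comp = STATE_FIELDS[int(np.argmin((sol.y - floor).min(axis=1)))]
        raise IntegrationError(
            f"state component {comp} fell below the negativity slack; "
            "tighten tolerances")
    return Trajectory(t=sol.t, y=sol.y, params=params, env=env,
                      rtol=rtol, atol=atol)


def classify_outcome(traj: Trajectory,
                     extinction_threshold: float = EXTINCTION_THRESHOLD,
                     settle_rtol: float = SETTLE_RTOL,
                     window: float = TRAILING_WINDOW,
                     min_generations: float = 50.0) -> Outcome:
    """Label the long-term competition outcome of a trajectory.

    A strain is extinct if its density stays below
    ``extinction_threshold * (N1+N2)(0)`` throughout the trailing window.
    ``coexistence`` additionally requires the trailing window to have settled
    (relative variation below ``settle_rtol``); otherwise the legal answer is
    ``undecided`` — never a coerced label.
    """
    gens = time_to_generations(traj.t[-1], traj.env.D)
    if gens < min_generations:
        raise DomainError(
            f"trajectory spans {gens:.1f} generations; at least "
            f"{min_generations} are required for a long-term label")
    n_ref = traj.y[2, 0] + traj.y[3, 0]
    if n_ref <= 0:
        return Outcome("washout", traj.final_state, traj.t[-1], np.nan)
    i0 = int(np.floor((1.0 - window) * (len(traj.t) - 1)))
    tail = traj.y[:, i0:]
    ext1 = np.all(tail[2] < extinction_threshold * n_ref)
    ext2 = np.all(tail[3] < extinction_threshold * n_ref)
    f2_final = float(traj.f2[-1]) if traj.total_density[-1] > 0 else np.nan

    if ext1 and ext2:
        label = "washout"
    elif ext2:
        label = "N1_only"
    elif ext1:
        label = "N2_only"
    else:
        scale = np.maximum(np.abs(tail).max(axis=1),
                           np.array([traj.env.S0, traj.env.S0, n_ref, n_ref,
                                     traj.env.S0, traj.env.S0]) * 1e-9)
        variation = (tail.max(axis=1) - tail.min(axis=1)) / scale
        label = "coexistence" if np.all(variation < settle_rtol) else "undecided"
    return Outcome(label, traj.final_state, float(traj.t[-1]), f2_final)


def run_mixed_culture(params: KineticParams, env: Environment,
                      N_total0: float, f2_0: float,
                      g_end: float = DECISION_GENERATIONS,
                      Xex0: float = 0.0, n_points: int = 200,
                      rtol: float = 1e-8, atol=None,
                      classify: bool = True) -> tuple[Trajectory, Outcome | None]:
    """Inoculate fresh medium with a mixed culture and integrate ``g_end``
    generations.

    Cells enter with empty intracellular pools; ``Xex0`` sets an optional
    one-time acetate bolus (the continuous-supplementation route is
    ``env.A_in``).
    """
    state0 = State.fresh_inoculum(env, N_total0, f2_0, Xex0=Xex0)
    t_end = generations_to_time(g_end, env.D)
    traj = integrate(params, env, state0, t_end, rtol=rtol, atol=atol,
                     n_points=n_points)
    outcome = classify_outcome(traj, min_generations=min(50.0, g_end)) \
        if classify else None
    return traj, outcome


def acetate_supplement_sweep(params: KineticParams, env: Environment,
                             A_in_values, N_total0: float, f2_0: float = 0.5,
                             g_end: float = 30.0) -> pd.DataFrame:
    """Terminal strain frequencies after ``g_end`` generations as a function
    of continuous acetate supplementation of the inflow.

    Returns a tidy frame with the terminal frequency of the glucose
    specialist (f1, the CV103 analogue) and of the acetate specialist (f2).
    """
    rows = []
    for a in np.asarray(A_in_values, dtype=float):
        if a < 0:
            raise DomainError(f"A_in must be >= 0, got {a}")
        env_a = env.replace(A_in=float(a))
        traj, _ = run_mixed_culture(params, env_a, N_total0, f2_0,
                                    g_end=g_end, classify=False)
        f2 = float(traj.f2[-1])
        rows.append({"A_in_umol_per_L": float(a),
                     "f1_final": 1.0 - f2, "f2_final": f2})
    return pd.DataFrame(rows)
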