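"""Bifurcation analysis in the inflow concentration S0, outcome maps over
initial conditions, and invasion / survival thresholds.

Continuation is natural-parameter with multistart re-seeding: the system is
six-dimensional and cheap to solve, and periodic re-seeding by the multistart
equilibrium finder is what guarantees that disconnected branches are found
(pseudo-arclength alone can miss them).  Fold and stability-change locations
are recorded as brackets between consecutive grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Environment, KineticParams, State, DomainError, v_g
from .equilibria import (Equilibrium, find_equilibria, _scales, _solve_from,
                         _make_equilibrium, washout_equilibrium,
                         reference_density)
from .simulate import run_mixed_culture, DECISION_GENERATIONS

__all__ = [
    "BifurcationBranch",
    "OutcomeMap",
    "continue_branches",
    "classify_regimes",
    "outcome_map",
    "invasion_threshold",
    "survival_threshold_S0",
    "washout_invasion_rate",
    "single_strain_washout_threshold",
    "monoculture_max_density",
]


@dataclass(eq=False)
class BifurcationBranch:
    """An equilibrium branch followed over S0."""

    label: str
    S0: list[float] = field(default_factory=list)
    equilibria: list[Equilibrium] = field(default_factory=list)
    events: list[tuple[float, float, str]] = field(default_factory=list)
    # events: (S0_lo, S0_hi, kind) brackets, kind in {fold, stability_change}

    def stability_at(self, s0: float) -> str | None:
        for s, eq in zip(self.S0, self.equilibria):
            if np.isclose(s, s0):
                return eq.stability
        return None

    def to_frame(self) -> pd.DataFrame:
        from .model import STATE_FIELDS
        rows = []
        for s0, eq in zip(self.S0, self.equilibria):
            row = {"S0_umol_per_L": s0, "label": self.label,
                   "max_re_eig_per_h": eq.max_re, "stability": eq.stability}
            row.update({f: eq.state[k] for k, f in enumerate(STATE_FIELDS)})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(eq=False)
class OutcomeMap:
    """Long-term outcome labels over an initial-condition grid at fixed S0."""

    density: np.ndarray       # total initial densities [cells/L]
    frequency: np.ndarray     # initial acetate-specialist frequencies f2
    labels: np.ndarray        # (n_density, n_frequency) array of outcome labels
    S0: float

    def label_set(self) -> set[str]:
        return set(self.labels.ravel().tolist())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.density):
            for j, f in enumerate(self.frequency):
                rows.append({"N_total0_cells_per_L": d, "f2_0": f,
                             "outcome": self.labels[i, j]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# continuation


def _match(prev: Equilibrium, candidates: list[Equilibrium], scales,
           bound: float) -> Equilibrium | None:
    best, best_d = None, np.inf
    for eq in candidates:
        if eq.label != prev.label:
            continue
        d = float(np.linalg.norm((eq.state - prev.state) / scales))
        if d < best_d:
            best, best_d = eq, d
    return best if best_d < bound else None


def continue_branches(params: KineticParams, D: float, S0_values,
                      n_starts: int = 48, seed: int = 0,
                      reseed_every: int = 4,
                      continuity_bound: float = 0.5) -> list[BifurcationBranch]:
    """Follow all equilibrium branches over an ordered grid of S0 values.

    At every grid point the previous branch points serve as warm starts; every
    ``reseed_every``-th point (and the first) additionally runs the full
    multistart search so that disconnected branches are picked up.  A branch
    that loses its root between consecutive grid points records a ``fold``
    bracket; a stability flip records a ``stability_change`` bracket.
    """
    S0_values = np.asarray(S0_values, dtype=float)
    if S0_values.ndim != 1 or len(S0_values) < 2 or np.any(np.diff(S0_values) <= 0):
        raise DomainError("S0_values must be an increasing 1-D grid")
    branches: list[BifurcationBranch] = []
    active: list[BifurcationBranch] = []

    for idx, s0 in enumerate(S0_values):
        env = Environment(D=D, S0=float(s0))
        scales = _scales(params, env)
        warm = [b.equilibria[-1].state for b in active]
        if idx % reseed_every == 0 or not active:
            eqs = find_equilibria(params, env, n_starts=n_starts,
                                  seed=seed + idx, extra_seeds=warm)
        else:
            eqs = find_equilibria(params, env, n_starts=0, seed=seed,
                                  extra_seeds=warm)
        unclaimed = list(eqs)
        still_active = []
        for b in active:
            prev = b.equilibria[-1]
            m = _match(prev, unclaimed, scales, continuity_bound)
            if m is None:
                b.events.append((b.S0[-1], float(s0), "fold"))
                continue
            if m.stability != prev.stability:
                b.events.append((b.S0[-1], float(s0), "stability_change"))
            b.S0.append(float(s0))
            b.equilibria.append(m)
            unclaimed.remove(m)
            still_active.append(b)
        for eq in unclaimed:
            b = BifurcationBranch(label=eq.label, S0=[float(s0)],
                                  equilibria=[eq])
            still_active.append(b)
            branches.append(b)
        active = still_active
    return branches


REGIME_BY_STABLE_SET = {
    frozenset(): "washout-only",
    frozenset({"washout"}): "washout-only",
    frozenset({"N1_monoculture"}): "N1-only",
    frozenset({"N2_monoculture"}): "N2-only",
    frozenset({"N1_monoculture", "N2_monoculture"}): "bistable",
    frozenset({"N1_monoculture", "N2_monoculture", "coexistence"}): "tristable",
}


def _regime_label(stable_labels: set[str]) -> str:
    key = frozenset(stable_labels - {"washout"})
    if key in REGIME_BY_STABLE_SET:
        return REGIME_BY_STABLE_SET[key]
    return "+".join(sorted(key)) or "washout-only"


def classify_regimes(branches: list[BifurcationBranch],
                     S0_values=None) -> list[tuple[float, float, str]]:
    """Partition the scanned S0 range into multistability regimes.

    Returns ordered ``(S0_lo, S0_hi, regime)`` intervals where the regime is
    named from the composition of stable branches: ``washout-only``,
    ``N1-only``, ``bistable`` (both monocultures), ``tristable`` (both
    monocultures plus coexistence), or an explicit ``+``-joined label for any
    other combination.
    """
    if S0_values is None:
        S0_values = sorted({s for b in branches for s in b.S0})
    S0_values = np.asarray(sorted(S0_values), dtype=float)
    regimes = []
    for s0 in S0_values:
        stable = set()
        for b in branches:
            for s, eq in zip(b.S0, b.equilibria):
                if np.isclose(s, s0) and eq.stability == "stable":
                    stable.add(eq.label)
        regimes.append(_regime_label(stable))
    intervals = []
    start = 0
    for i in range(1, len(S0_values) + 1):
        if i == len(S0_values) or regimes[i] != regimes[start]:
            intervals.append((float(S0_values[start]), float(S0_values[i - 1]),
                              regimes[start]))
            start = i
    return intervals


# ---------------------------------------------------------------------------
# outcome map


def outcome_map(params: KineticParams, env: Environment, density_grid,
                freq_grid, g_end: float = DECISION_GENERATIONS) -> OutcomeMap:
    """Classify the long-term outcome for every (density, frequency) cell.

    Cells are independent, so results do not depend on evaluation order.
    """
    density_grid = np.asarray(density_grid, dtype=float)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if density_grid.size == 0 or freq_grid.size == 0:
        raise DomainError("grids must be nonempty")
    labels = np.empty((len(density_grid), len(freq_grid)), dtype=object)
    for i, d in enumerate(density_grid):
        for j, f in enumerate(freq_grid):
            _, out = run_mixed_culture(params, env, d, f, g_end=g_end)
            labels[i, j] = out.label
    return OutcomeMap(density=density_grid, frequency=freq_grid,
                      labels=labels, S0=env.S0)


# ---------------------------------------------------------------------------
# thresholds


def invasion_threshold(params: KineticParams, env: Environment,
                       N_total0: float, f_bracket=(1e-4, 0.05),
                       resolution: float = 1e-4,
                       g_end: float = DECISION_GENERATIONS):
    """Bisect the initial acetate-specialist frequency separating failure
    from establishment, all else fixed.

    Returns ``(threshold, (f_lo, f_hi))`` where the threshold is the midpoint
    of the final bracket.  Raises if the outcomes at the bracket endpoints do
    not differ.
    """
    lo, hi = float(f_bracket[0]), float(f_bracket[1])

    def established(f2):
        _, out = run_mixed_culture(params, env, N_total0, f2, g_end=g_end)
        return out.label in ("N2_only", "coexistence")

    est_lo, est_hi = established(lo), established(hi)
    if est_lo == est_hi:
        _, out_lo = run_mixed_culture(params, env, N_total0, lo, g_end=g_end)
        _, out_hi = run_mixed_culture(params, env, N_total0, hi, g_end=g_end)
        raise DomainError(
            "no invasion threshold in bracket: outcome at "
            f"f2={lo} is {out_lo.label!r} and at f2={hi} is {out_hi.label!r}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if established(mid) == est_hi:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), (lo, hi)


def washout_invasion_rate(params: KineticParams, env: Environment) -> float:
    """max_i mu_i - D evaluated at the washout state (empty pools, S = S0)."""
    return max(growth_rate_at_washout(params, env, 1),
               growth_rate_at_washout(params, env, 2)) - env.D


def growth_rate_at_washout(params: KineticParams, env: Environment,
                           i: int) -> float:
    # at washout the pools are empty, so growth is glycolytic only and
    # the cost factor is exactly 1
    return params.G * params.n_g * v_g(params, env.S0, i)


def single_strain_washout_threshold(params: KineticParams, D: float,
                                    i: int) -> float:
    """Closed-form inflow concentration at which strain ``i`` alone can just
    persist from rarity: G n_g Vmax S/(Km+S) = D.

    Valid when the glycolytic maximum exceeds D; raises otherwise.
    """
    k = i - 1
    mu_max = params.G * params.n_g * params.Vmax_g[k]
    if mu_max <= D:
        raise DomainError(
            f"strain {i} cannot reach D = {D} on glycolysis alone")
    return params.Km_g[k] * D / (mu_max - D)


def survival_threshold_S0(params: KineticParams, D: float,
                          bracket=(1e-2, 100.0),
                          resolution: float = 1e-6) -> float:
    """Bisect the S0 below which no competitor can survive.

    The criterion is washout invadability, max_i mu_i(S0, empty pools) = D;
    the washout equilibrium is stable below the returned value and unstable
    above it.
    """
    lo, hi = float(bracket[0]), float(bracket[1])

    def g(s0):
        return washout_invasion_rate(params, Environment(D=D, S0=s0))

    if not (g(lo) < 0 < g(hi)):
        raise DomainError(
            f"washout invadability does not change sign on [{lo}, {hi}]: "
            f"g(lo)={g(lo):.3g}, g(hi)={g(hi):.3g}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def monoculture_max_density(params: KineticParams, env: Environment,
                            strain: int = 1,
                            g_end: float = DECISION_GENERATIONS) -> float:
    """Maximal population density supported by the environment, operationalized
    as the stable single-strain steady-state density reached from a fresh
    monoculture inoculum."""
    f2 = 1.0 if strain == 2 else 0.0
    seed_density = 0.5 * reference_density(params, env)
    traj, out = run_mixed_culture(params, env, seed_density, f2, g_end=g_end)
    k = 2 + (strain - 1)
    return float(traj.y[k, -1])
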