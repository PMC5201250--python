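"""Steady states of the chemostat model and their linear stability.

Roots of the right-hand side are found by damped multistart root-finding in
plain (not log-transformed) coordinates so that boundary equilibria — washout
and the two monocultures — are reachable.  All quantities are scaled before
solving: concentrations by S0, densities by a reference density derived from
the ATP budget of the inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

from .model import (Environment, KineticParams, State, DomainError,
                    rhs_array, growth_rate, COST_FORMS)

__all__ = [
    "Equilibrium",
    "find_equilibria",
    "monoculture_equilibria",
    "jacobian",
    "jacobian_fd",
    "jacobian_analytic",
    "classify_stability",
    "reference_density",
    "washout_equilibrium",
]

#: eigenvalue real-part margin separating stable/unstable from marginal
EPS_EIG = 1e-8

#: relative merge tolerance for duplicate roots, in the scaled state norm
MERGE_TOL = 1e-6

#: scaled residual norm below which a root is accepted
RESIDUAL_TOL = 1e-9

#: densities below this fraction of the reference density count as zero
#: when labelling branches
ZERO_DENSITY_TOL = 1e-9

BRANCH_LABELS = ("washout", "N1_monoculture", "N2_monoculture", "coexistence")


@dataclass(eq=False)
class Equilibrium:
    state: np.ndarray                 # 6-vector, componentwise >= 0
    label: str
    eigenvalues: np.ndarray           # 6 complex
    stability: str                    # stable | unstable | marginal
    residual: float                   # scaled residual norm

    @property
    def max_re(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def as_state(self) -> State:
        return State.from_array(self.state)


def reference_density(params: KineticParams, env: Environment) -> float:
    """Crude density scale: full conversion of the inflow ATP budget.

    Uses the *respired* yield, which upper-bounds realized monoculture
    densities; used only for scaling and zero-density tolerances.
    """
    atp_per_glucose = params.n_g + 2.0 * params.n_tca
    return max(params.G * atp_per_glucose * max(env.S0, 1.0), 1.0)


def _scales(params: KineticParams, env: Environment) -> np.ndarray:
    c = max(env.S0 + env.A_in, 1.0)
    n = reference_density(params, env)
    return np.array([c, 2.0 * c, n, n, 2.0 * c, 2.0 * c])


def washout_equilibrium(params: KineticParams, env: Environment) -> np.ndarray:
    return np.array([env.S0, env.A_in, 0.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Jacobian


def jacobian_fd(state, params: KineticParams, env: Environment,
                rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with componentwise step scaling."""
    y = np.asarray(state, dtype=float)
    scales = _scales(params, env)
    J = np.empty((6, 6))
    for j in range(6):
        h = rel_step * max(abs(y[j]), 1e-3 * scales[j])
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (rhs_array(yp, params, env) - rhs_array(ym, params, env)) / (2 * h)
    return J


def jacobian_analytic(state, params: KineticParams, env: Environment) -> np.ndarray:
    """Exact Jacobian for the default functional forms.

    Only valid for Michaelis-Menten uptake, the odd saturating transporter
    and the hyperbolic (or absent) cost.
    """
    if params.uptake_form != "michaelis_menten" \
            or params.transport_form != "odd_saturating" \
            or params.cost_form not in ("hyperbolic", "none"):
        raise DomainError("analytic Jacobian implemented only for the "
                          "default functional forms")
    S, E, N1, N2, I1, I2 = np.asarray(state, dtype=float)
    p = params
    D = env.D

    def mm(x, v, k):
        return v * x / (k + x), v * k / (k + x) ** 2

    vg1, dvg1 = mm(S, p.Vmax_g[0], p.Km_g[0])
    vg2, dvg2 = mm(S, p.Vmax_g[1], p.Km_g[1])
    vt1, dvt1 = mm(I1, p.Vmax_tca[0], p.Km_tca[0])
    vt2, dvt2 = mm(I2, p.Vmax_tca[1], p.Km_tca[1])
    vh, dvh = mm(E, p.Vhat, p.Khat)

    def rt(d, v, k):
        return v * d / (k + abs(d)), v * k / (k + abs(d)) ** 2

    vr1, dvr1 = rt(I1 - E, p.Vrt[0], p.Krt[0])
    vr2, dvr2 = rt(I2 - E, p.Vrt[1], p.Krt[1])

    if p.cost_form == "hyperbolic":
        c1 = 1.0 / (1.0 + I1 / p.Kc[0])
        c2 = 1.0 / (1.0 + I2 / p.Kc[1])
        dc1 = -c1 * c1 / p.Kc[0]
        dc2 = -c2 * c2 / p.Kc[1]
    else:
        c1 = c2 = 1.0
        dc1 = dc2 = 0.0

    a1 = p.n_g * vg1 + p.n_tca * vt1
    a2 = p.n_g * vg2 + p.n_tca * vt2
    mu1 = p.G * a1 * c1
    mu2 = p.G * a2 * c2
    dmu1_dS = p.G * p.n_g * dvg1 * c1
    dmu2_dS = p.G * p.n_g * dvg2 * c2
    dmu1_dI = p.G * (p.n_tca * dvt1 * c1 + a1 * dc1)
    dmu2_dI = p.G * (p.n_tca * dvt2 * c2 + a2 * dc2)

    J = np.zeros((6, 6))
    # dS/dt
    J[0, 0] = -D - dvg1 * N1 - dvg2 * N2
    J[0, 2] = -vg1
    J[0, 3] = -vg2
    # dXex/dt
    J[1, 1] = -dvr1 * N1 - (dvr2 + dvh) * N2 - D
    J[1, 2] = vr1
    J[1, 3] = vr2 - vh
    J[1, 4] = dvr1 * N1
    J[1, 5] = dvr2 * N2
    # dN1/dt
    J[2, 0] = dmu1_dS * N1
    J[2, 2] = mu1 - D
    J[2, 4] = dmu1_dI * N1
    # dN2/dt
    J[3, 0] = dmu2_dS * N2
    J[3, 3] = mu2 - D
    J[3, 5] = dmu2_dI * N2
    # dXin1/dt
    J[4, 0] = 2.0 * dvg1 * N1
    J[4, 1] = dvr1 * N1
    J[4, 2] = 2.0 * vg1 - vt1 - vr1
    J[4, 4] = (-dvt1 - dvr1) * N1 - D
    # dXin2/dt
    J[5, 0] = 2.0 * dvg2 * N2
    J[5, 1] = (dvr2 + dvh) * N2
    J[5, 3] = 2.0 * vg2 - vt2 - vr2 + vh
    J[5, 5] = (-dvt2 - dvr2) * N2 - D
    return J


def jacobian(state, params: KineticParams, env: Environment,
             method: str = "auto") -> np.ndarray:
    if method == "fd":
        return jacobian_fd(state, params, env)
    if method == "analytic":
        return jacobian_analytic(state, params, env)
    if method == "auto":
        try:
            return jacobian_analytic(state, params, env)
        except DomainError:
            return jacobian_fd(state, params, env)
    raise ValueError(f"unknown jacobian method {method!r}")


def classify_stability(eigenvalues, eps_eig: float = EPS_EIG) -> str:
    re = np.asarray(eigenvalues).real
    if np.all(re < -eps_eig):
        return "stable"
    if np.any(re > eps_eig):
        return "unstable"
    return "marginal"


# ---------------------------------------------------------------------------
# root finding


def _label(state, params, env) -> str:
    zero = ZERO_DENSITY_TOL * reference_density(params, env)
    n1, n2 = state[2] > zero, state[3] > zero
    if n1 and n2:
        return "coexistence"
    if n1:
        return "N1_monoculture"
    if n2:
        return "N2_monoculture"
    return "washout"


def _make_equilibrium(y, params, env) -> Equilibrium:
    scales = _scales(params, env)
    res = float(np.linalg.norm(rhs_array(y, params, env) / (env.D * scales)))
    eig = np.linalg.eigvals(jacobian(y, params, env))
    return Equilibrium(state=y, label=_label(y, params, env),
                       eigenvalues=eig, stability=classify_stability(eig),
                       residual=res)


def _solve_from(y0, params, env, scales):
    """Damped root solve in scaled coordinates; returns a clean nonnegative
    root or None."""

    def fun(z):
        return rhs_array(z * scales, params, env) / (env.D * scales)

    sol = root(fun, np.asarray(y0) / scales, method="hybr",
               options={"xtol": 1e-12, "maxfev": 4000})
    if not sol.success:
        return None
    z = sol.x
    # snap round-off negatives onto the boundary, reject genuine negatives
    if np.any(z < -1e-7):
        return None
    z = np.maximum(z, 0.0)
    y = z * scales
    if np.linalg.norm(fun(z)) > RESIDUAL_TOL:
        return None
    return y


def monoculture_equilibria(params: KineticParams, env: Environment,
                           strain: int, n_grid: int = 200) -> list[np.ndarray]:
    """Steady states of the single-strain subsystem (other strain absent).

    The reduced system is solved from a grid of substrate seed values so that
    coex‐existing efficient and self-poisoned monoculture branches are both
    found.  Returns full 6-vectors with the absent strain's components at 0.
    """
    if strain not in (1, 2):
        raise DomainError(f"strain must be 1 or 2, got {strain}")
    scales = _scales(params, env)
    k = strain - 1
    found: list[np.ndarray] = []
    # seed S* logarithmically from deep depletion up to S0; seed the pool at
    # a few gradient levels
    s_seeds = np.geomspace(max(env.S0 * 1e-5, 1e-3), env.S0 * 0.98, n_grid // 10)
    for s in s_seeds:
        for xi in (scales[4] * 1e-4, scales[4] * 0.05, scales[4] * 0.5):
            vg = params.Vmax_g[k] * s / (params.Km_g[k] + s)
            n_guess = env.D * max(env.S0 - s, 1e-3 * env.S0) / max(vg, 1e-300)
            y0 = np.zeros(6)
            y0[0] = s
            y0[1] = min(xi, scales[1] * 0.4)
            y0[2 + k] = n_guess
            y0[4 + k] = xi
            y = _solve_from(y0, params, env, scales)
            if y is None:
                continue
            if y[2 + (1 - k)] > ZERO_DENSITY_TOL * reference_density(params, env):
                continue  # wandered off the invariant subspace
            y[2 + (1 - k)] = 0.0
            y[4 + (1 - k)] = 0.0
            if y[2 + k] <= ZERO_DENSITY_TOL * reference_density(params, env):
                continue  # converged to washout
            if not any(np.linalg.norm((y - f) / scales) < 1e-4 for f in found):
                found.append(y)
    return found


def find_equilibria(params: KineticParams, env: Environment,
                    n_starts: int = 64, seed: int = 0,
                    extra_seeds=None) -> list[Equilibrium]:
    """All located steady states at fixed parameters and environment.

    Seeding combines (i) the analytic washout state, (ii) the reduced
    monoculture subsystem solutions, and (iii) a Latin-hypercube cloud in a
    physically bounded box; duplicates are merged in the scaled norm.
    The washout equilibrium is always present (it is exact by construction).
    """
    scales = _scales(params, env)
    roots: list[np.ndarray] = [washout_equilibrium(params, env)]

    def push(y):
        if y is None:
            return
        for r in roots:
            if np.linalg.norm((y - r) / scales) < max(MERGE_TOL, 1e-6):
                return
        roots.append(y)

    mono = {1: monoculture_equilibria(params, env, 1),
            2: monoculture_equilibria(params, env, 2)}
    for strain in (1, 2):
        for y in mono[strain]:
            push(y)

    # interior seeds: mixtures of the two monoculture solutions.  The stable
    # coexistence state sits between them in density space; the near-boundary
    # weights target the rare-invader saddle points that sit close to each
    # monoculture branch.
    for y1 in mono[1]:
        for y2 in mono[2]:
            for w in (0.002, 0.02, 0.3, 0.5, 0.7, 0.98, 0.998):
                y0 = np.array([
                    min(y1[0], y2[0]),
                    w * y1[1] + (1 - w) * y2[1],
                    w * y1[2], (1 - w) * y2[3],
                    w * y1[4], (1 - w) * y2[5],
                ])
                push(_solve_from(y0, params, env, scales))

    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=6, seed=seed)
        u = sampler.random(n_starts)
        # substrate and pool seeds are sampled log-uniformly: chemostat
        # steady states deplete the sugar orders of magnitude below S0
        log_lo = np.log(np.array([1e-5, 1e-4, np.nan, np.nan, 1e-4, 1e-4]))
        log_hi = np.log(np.array([1.05, 3.0, np.nan, np.nan, 3.0, 3.0]))
        for row in u:
            y0 = np.empty(6)
            for j in (0, 1, 4, 5):
                y0[j] = np.exp(log_lo[j] + row[j] * (log_hi[j] - log_lo[j]))
            y0[2] = 1.2 * row[2]
            y0[3] = 1.2 * row[3]
            push(_solve_from(y0 * scales, params, env, scales))

    if extra_seeds is not None:
        for y0 in extra_seeds:
            push(_solve_from(np.asarray(y0, dtype=float), params, env, scales))

    return [_make_equilibrium(y, params, env) for y in roots]
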