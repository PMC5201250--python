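"""Continuation, regime classification, outcome maps and thresholds."""

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.equilibria import _scales
from conftest import same_equilibrium_sets


@pytest.fixture(scope="module")
def branches_and_regimes(params):
    return cf.regime_sequence(params, D=0.2, S0_min=2.0, S0_max=1500.0,
                              n_S0=20, n_starts=32, seed=0)


class TestContinuation:
    def test_washout_branch_spans_range_exactly(self, branches_and_regimes,
                                                params):
        branches, _ = branches_and_regimes
        wash = [b for b in branches if b.label == "washout"]
        assert len(wash) == 1
        b = wash[0]
        assert len(b.S0) == 20
        for s0, eq in zip(b.S0, b.equilibria):
            assert np.allclose(eq.state,
                               [s0, 0, 0, 0, 0, 0])

    def test_checkpoints_agree_with_multistart(self, branches_and_regimes,
                                               params):
        branches, _ = branches_and_regimes
        for s0 in (branches[0].S0[0], branches[0].S0[10], branches[0].S0[-1]):
            env = cf.Environment(D=0.2, S0=s0)
            scales = _scales(params, env)
            multistart = cf.find_equilibria(params, env, n_starts=48, seed=5)
            on_branch = [eq for b in branches
                         for s, eq in zip(b.S0, b.equilibria)
                         if np.isclose(s, s0)]
            assert same_equilibrium_sets(multistart, on_branch, scales)

    def test_stability_changes_only_at_recorded_events(self,
                                                       branches_and_regimes):
        branches, _ = branches_and_regimes
        for b in branches:
            flips = [(lo, hi) for lo, hi, kind in b.events
                     if kind == "stability_change"]
            for (s_lo, e_lo), (s_hi, e_hi) in zip(
                    zip(b.S0[:-1], b.equilibria[:-1]),
                    zip(b.S0[1:], b.equilibria[1:])):
                if e_lo.stability != e_hi.stability:
                    assert any(np.isclose(lo, s_lo) and np.isclose(hi, s_hi)
                               for lo, hi in flips)


class TestRegimes:
    def test_sequence_matches_multistability_narrative(self,
                                                       branches_and_regimes):
        _, regimes = branches_and_regimes
        order = [r for _, _, r in regimes]
        main = [r for r in order
                if r in ("washout-only", "N1-only", "bistable", "tristable")]
        # collapse repeats, keep order
        seq = [r for i, r in enumerate(main) if i == 0 or r != main[i - 1]]
        assert seq == ["washout-only", "N1-only", "bistable", "tristable"]

    def test_low_S0_limit_is_washout_only(self, branches_and_regimes):
        _, regimes = branches_and_regimes
        assert regimes[0][2] == "washout-only"

    def test_boundaries_coincide_with_events(self, branches_and_regimes):
        branches, regimes = branches_and_regimes
        events = [(lo, hi) for b in branches for lo, hi, _ in b.events]
        grid = sorted({s for b in branches for s in b.S0})
        for (_, hi_prev, _), (lo_next, _, _) in zip(regimes[:-1], regimes[1:]):
            # a regime boundary is a grid step; it must contain a recorded
            # fold/stability event or a branch birth (new branch first point)
            births = [b.S0[0] for b in branches]
            covered = (
                any(lo <= hi_prev and lo_next <= hi for lo, hi in events)
                or any(np.isclose(s, lo_next) for s in births)
            )
            assert covered, (hi_prev, lo_next)


@pytest.fixture(scope="module")
def small_map(params, env, nmax_350):
    dens = np.geomspace(1e-3, 1.2, 6) * nmax_350
    freq = np.array([0.0, 0.001, 0.3, 0.7, 0.999, 1.0])
    return cf.outcome_map(params, env, dens, freq, g_end=400)


class TestOutcomeMap:
    def test_pure_strain_columns(self, small_map):
        assert set(small_map.labels[:, 0]) <= {"N1_only", "washout"}
        assert set(small_map.labels[:, -1]) <= {"N2_only", "washout"}

    def test_all_three_outcomes_present_at_350(self, small_map):
        assert {"N1_only", "N2_only", "coexistence"} <= small_map.label_set()

    def test_frame_round_trip(self, small_map):
        df = small_map.to_frame()
        assert len(df) == 36
        assert set(df["outcome"]) == small_map.label_set()


@pytest.fixture(scope="module")
def nmax_350(params, env):
    return cf.monoculture_max_density(params, env)


class TestInvasionThreshold:
    def test_threshold_reproducible_and_bracket_shrinks(self, params,
                                                        env_fig4, nmax_fig4):
        thr1, (lo1, hi1) = cf.invasion_threshold(params, env_fig4, nmax_fig4,
                                                 resolution=2e-4)
        thr2, (lo2, hi2) = cf.invasion_threshold(params, env_fig4, nmax_fig4,
                                                 resolution=2e-4)
        assert thr1 == thr2
        assert hi1 - lo1 <= 2e-4
        assert lo1 <= thr1 <= hi1

    def test_error_when_no_sign_change(self, params, env_fig4, nmax_fig4):
        with pytest.raises(cf.DomainError) as err:
            cf.invasion_threshold(params, env_fig4, nmax_fig4,
                                  f_bracket=(0.2, 0.4))
        assert "coexistence" in str(err.value)

    def test_nonincreasing_in_density(self, params, env_fig4, nmax_fig4):
        thrs = []
        for rel in (0.2, 0.6, 1.0):
            t, _ = cf.invasion_threshold(params, env_fig4, rel * nmax_fig4,
                                         resolution=2e-4)
            thrs.append(t)
        assert thrs[0] >= thrs[1] >= thrs[2]


class TestSurvivalThreshold:
    def test_closed_form_matches_bisection(self, params):
        closed = cf.single_strain_washout_threshold(params, 0.2, 1)
        bisected = cf.survival_threshold_S0(params, 0.2, resolution=1e-8)
        assert bisected == pytest.approx(closed, abs=1e-6)

    def test_increases_with_dilution_rate(self, params):
        t1 = cf.survival_threshold_S0(params, 0.15)
        t2 = cf.survival_threshold_S0(params, 0.25)
        assert t2 > t1

    def test_washout_stability_flips_at_threshold(self, params):
        thr = cf.survival_threshold_S0(params, 0.2)
        for s0, expected in ((0.9 * thr, "stable"), (1.1 * thr, "unstable")):
            env = cf.Environment(D=0.2, S0=s0)
            eqs = cf.find_equilibria(params, env, n_starts=0, seed=0)
            w = next(q for q in eqs if q.label == "washout")
            assert w.stability == expected

    def test_invalid_bracket_rejected(self, params):
        with pytest.raises(cf.DomainError):
            cf.survival_threshold_S0(params, 0.2, bracket=(10.0, 100.0))


class TestSimulationEquilibriumConsistency:
    def test_terminal_states_lie_on_stable_equilibria(self, params, env,
                                                      equilibria_350,
                                                      nmax_350):
        # random initial conditions must settle onto one of the located
        # stable equilibria
        rng = np.random.default_rng(17)
        scales = _scales(params, env)
        stable = [q for q in equilibria_350 if q.stability == "stable"]
        hits = set()
        for _ in range(25):
            n0 = nmax_350 * 10 ** rng.uniform(-2, 0.15)
            f2 = rng.uniform(0, 1)
            traj, out = cf.run_mixed_culture(params, env, n0, f2, g_end=700)
            dists = [np.linalg.norm((traj.y[:, -1] - q.state) / scales)
                     for q in stable]
            assert min(dists) < 1e-3
            nearest = stable[int(np.argmin(dists))]
            hits.add(nearest.label)
            # the simulation label must agree with the nearest equilibrium
            expected = {"N1_monoculture": "N1_only",
                        "N2_monoculture": "N2_only",
                        "coexistence": "coexistence"}[nearest.label]
            assert out.label == expected
        assert len(hits) >= 2  # the draw spans multiple basins
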