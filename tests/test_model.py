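"""Unit and property tests for the kinetic rate functions and the RHS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crossfeed as cf
from crossfeed.model import carbon_balance_rhs_residual
from conftest import random_states


class TestRateFunctions:
    @pytest.mark.parametrize("strain", [1, 2])
    def test_glucose_uptake_identities(self, params, strain):
        k = strain - 1
        assert cf.v_g(params, 0.0, strain) == 0.0
        assert cf.v_g(params, params.Km_g[k], strain) == \
            pytest.approx(params.Vmax_g[k] / 2)
        # direct evaluation of the saturating form at 10x half-saturation
        assert cf.v_g(params, 10 * params.Km_g[k], strain) == \
            pytest.approx(10 / 11 * params.Vmax_g[k])

    @pytest.mark.parametrize("strain", [1, 2])
    def test_tca_identities_and_saturation(self, params, strain):
        k = strain - 1
        assert cf.v_tca(params, 0.0, strain) == 0.0
        assert cf.v_tca(params, params.Km_tca[k], strain) == \
            pytest.approx(params.Vmax_tca[k] / 2)
        assert cf.v_tca(params, 1e12, strain) == \
            pytest.approx(params.Vmax_tca[k], rel=1e-9)

    @pytest.mark.parametrize("strain", [1, 2])
    def test_rates_monotone_and_bounded(self, params, strain):
        x = np.linspace(0, 1e4, 500)
        for fn, vmax in ((cf.v_g, params.Vmax_g[strain - 1]),
                         (cf.v_tca, params.Vmax_tca[strain - 1])):
            vals = np.array([fn(params, xi, strain) for xi in x])
            assert np.all(np.diff(vals) > 0)
            assert np.all(vals < vmax)

    def test_reversible_transport_odd_and_saturating(self, params):
        k = 0
        assert cf.v_rt(params, 0.0, 1) == 0.0
        # half-saturation of the odd form
        assert cf.v_rt(params, params.Krt[k], 1) == \
            pytest.approx(params.Vrt[k] / 2)
        for d in (0.3, 17.0, 420.0):
            assert cf.v_rt(params, -d, 1) == pytest.approx(-cf.v_rt(params, d, 1))
        assert abs(cf.v_rt(params, 1e9, 1)) < params.Vrt[k]

    def test_high_affinity_acetate_uptake(self, params):
        assert cf.v_hat(params, 0.0) == 0.0
        assert cf.v_hat(params, params.Khat) == pytest.approx(params.Vhat / 2)
        x = np.linspace(0, 500, 200)
        vals = np.array([cf.v_hat(params, xi) for xi in x])
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("strain", [1, 2])
    def test_cost_monotone_unit_interval(self, params, strain):
        k = strain - 1
        assert cf.cost(params, 0.0, strain) == 1.0
        assert cf.cost(params, params.Kc[k], strain) == pytest.approx(0.5)
        x = np.linspace(0, 1e4, 300)
        c = np.array([cf.cost(params, xi, strain) for xi in x])
        assert np.all(np.diff(c) <= 0)
        assert np.all((c > 0) & (c <= 1))

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(cf.DomainError):
            cf.v_g(params, -1.0, 1)
        with pytest.raises(cf.DomainError):
            cf.v_tca(params, -0.1, 2)
        with pytest.raises(cf.DomainError):
            cf.v_hat(params, -5.0)
        with pytest.raises(cf.DomainError):
            cf.cost(params, -1.0, 1)


class TestGrowthRate:
    def test_zero_substrate_zero_growth(self, params):
        s = cf.State(S=0, Xex=0, N1=1e9, N2=1e9, Xin1=0, Xin2=0)
        assert cf.growth_rate(params, s, 1) == 0.0
        assert cf.growth_rate(params, s, 2) == 0.0

    def test_cost_free_limit_is_atp_rate(self, params, env):
        nocost = params.replace(cost_form="none")
        s = cf.State(S=37.0, Xex=0, N1=1e9, N2=0, Xin1=140.0, Xin2=0)
        expected = params.G * (params.n_g * cf.v_g(params, 37.0, 1)
                               + params.n_tca * cf.v_tca(params, 140.0, 1))
        assert cf.growth_rate(nocost, s, 1) == pytest.approx(expected)
        assert cf.growth_rate(params, s, 1) < expected

    def test_washout_invadable_by_glucose_specialist(self, params, env):
        # at the outcome-map glucose level the washout state must be
        # invadable by the glucose specialist
        w = cf.State.washout(env)
        assert cf.growth_rate(params, w, 1) > env.D


class TestRHS:
    def test_washout_is_exact_equilibrium(self, params, env):
        dy = cf.rhs(cf.State.washout(env), params, env).as_array()
        assert np.all(dy == 0.0)

    def test_washout_exact_for_perturbed_sets(self, params, env):
        ens = cf.PerturbationEnsemble(base=params, span=1.3, n_samples=5, seed=7)
        for pp in cf.sample_perturbations(ens):
            dy = cf.rhs(cf.State.washout(env), pp, env).as_array()
            assert np.all(dy == 0.0)

    def test_cell_free_acetate_dilutes(self, params, env):
        s = cf.State(S=env.S0, Xex=123.0, N1=0, N2=0, Xin1=0, Xin2=0)
        dy = cf.rhs(s, params, env).as_array()
        assert dy[1] == pytest.approx(-env.D * 123.0)
        env_a = env.replace(A_in=50.0)
        dy = cf.rhs(s, params, env_a).as_array()
        assert dy[1] == pytest.approx(-env.D * 123.0 + env.D * 50.0)

    def test_invalid_states_rejected(self, params, env):
        with pytest.raises(cf.DomainError):
            cf.rhs(cf.State(S=-1.0, Xex=0, N1=0, N2=0, Xin1=0, Xin2=0),
                   params, env)
        with pytest.raises(cf.DomainError):
            cf.rhs(cf.State(S=np.nan, Xex=0, N1=0, N2=0, Xin1=0, Xin2=0),
                   params, env)

    def test_carbon_balance_identity_on_random_states(self, params, env):
        # the triose-weighted sum of the RHS must reduce to the dilution
        # balance minus the TCA sink, exactly (all transport terms cancel)
        for y in random_states(env, 50, seed=5):
            res = carbon_balance_rhs_residual(y, params, env)
            scale = env.D * 2 * env.S0
            assert abs(res) < 1e-9 * scale

    @given(a_in=st.floats(0, 500), s=st.floats(0, 2000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_carbon_balance_identity_with_supplementation(self, params, s, a_in):
        env_a = cf.Environment(D=0.2, S0=700.0, A_in=a_in)
        y = np.array([s, 0.7 * a_in + 1.0, 3e10, 8e10, 40.0, 15.0])
        assert abs(carbon_balance_rhs_residual(y, params, env_a)) \
            < 1e-9 * env_a.D * 2 * env_a.S0


class TestUnits:
    def test_percent_conversion_values(self):
        assert cf.percent_wv_to_umolL(0.0) == 0.0
        # 0.025 % w/v = 0.25 g/L of glucose
        assert cf.percent_wv_to_umolL(0.025) == pytest.approx(1.39e3, rel=1e-2)

    @pytest.mark.parametrize("p", [0.00625, 0.025, 0.1, 1.0])
    def test_percent_round_trip(self, p):
        assert cf.umolL_to_percent_wv(cf.percent_wv_to_umolL(p)) == \
            pytest.approx(p, rel=1e-12)


class TestParamValidation:
    def test_tradeoff_violation_rejected(self, params):
        with pytest.raises(cf.DomainError):
            params.replace(Vmax_g=(params.Vmax_g[1], params.Vmax_g[1]))

    def test_nonpositive_constants_rejected(self, params):
        with pytest.raises(cf.DomainError):
            params.replace(Km_g=(0.0, 60.0))
        with pytest.raises(cf.DomainError):
            params.replace(G=-1.0)

    def test_vhat_zero_is_legal(self, params):
        # strain 1 negligibly expresses the enzyme; a zero-Vhat set is valid
        p0 = params.replace(Vhat=0.0)
        assert p0.Vhat == 0.0

    def test_config_round_trip(self, params, env, tmp_path):
        path = tmp_path / "cfg.yaml"
        cf.save_params(params, env, path)
        p2, e2 = cf.load_params(path)
        assert p2.to_dict() == params.to_dict()
        assert e2.to_dict() == env.to_dict()
        assert cf.params_hash(p2, e2) == cf.params_hash(params, env)
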