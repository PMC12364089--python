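import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frailtyflow.engine import (
    ConfigurationError,
    EntrySpec,
    FlowSpec,
    Model,
    PopulationState,
    annual_proportions,
    build_model,
    simulate,
    step,
    zero_parameters,
    zero_state,
)

from conftest import constant_params


class TestFlowSpec:
    def test_constant(self):
        spec = FlowSpec(kind="constant", p=0.1)
        assert spec.proportion_at(0) == spec.proportion_at(57) == 0.1

    def test_polynomial(self):
        spec = FlowSpec(kind="polynomial", beta=(0.05, 0.01, 0, 0))
        assert spec.proportion_at(2) == pytest.approx(0.07)

    def test_clamp_low_warns(self):
        spec = FlowSpec(kind="polynomial", beta=(-0.02, 0, 0, 0))
        with pytest.warns(UserWarning, match="clamped"):
            assert spec.proportion_at(0) == 0.0

    def test_clamp_high_warns(self):
        spec = FlowSpec(kind="polynomial", beta=(0.5, 1.0))
        with pytest.warns(UserWarning, match="clamped"):
            assert spec.proportion_at(3) == 1.0

    def test_freeze_at_t_max(self):
        spec = FlowSpec(kind="polynomial", beta=(0.0, 0.01, 0.001, 0.0), t_max=11.0)
        frozen = spec.proportion_at(11)
        for t in (12, 20, 1000):
            assert spec.proportion_at(t) == frozen

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_constant_out_of_range(self, p):
        with pytest.raises(ConfigurationError):
            FlowSpec(kind="constant", p=p)

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            FlowSpec(kind="linear", p=0.1)

    def test_entry_negative_clamped(self):
        spec = EntrySpec(kind="polynomial", beta=(-5.0, 0.0))
        with pytest.warns(UserWarning):
            assert spec.rate_at(0) == 0.0


class TestBuildModel:
    def test_default_counts(self):
        model = build_model()
        assert model.n_stocks == 48
        assert model.n_flows == 72

    def test_small_grid_counts(self):
        model = build_model(2, 2, zero_parameters(2, 2))
        assert model.n_stocks == 12
        assert model.n_flows == 16

    @pytest.mark.parametrize("nb,ns", [(1, 1), (2, 3), (3, 2), (5, 4)])
    def test_combinatorial_formula(self, nb, ns):
        model = build_model(nb, ns, zero_parameters(nb, ns))
        assert model.n_stocks == nb * ns * 3
        assert model.n_flows == 3 * nb * ns + nb * (ns - 1) + (nb - 1) * ns
        assert len(model.flow_edges()) == model.n_flows

    def test_missing_spec_named(self):
        params = zero_parameters()
        del params.death[(2, 1)]
        with pytest.raises(ConfigurationError, match=r"death.*band 2, state 1"):
            build_model(4, 4, params)

    def test_irreversibility_structural(self):
        """No flow runs to a younger band or a better frailty state."""
        model = build_model()
        for name, src, dst in model.flow_edges():
            if src is None or dst is None:
                continue
            assert dst[0] >= src[0], f"{name} flows to a younger band"
            assert dst[1] >= src[1], f"{name} flows to a better state"

    def test_no_outflow_from_terminal_compartments(self):
        edges = build_model().flow_edges()
        assert not any(n == "ageing" and s[0] == 3 for n, s, _ in edges)
        assert not any(n == "progression" and s[1] == 3 for n, s, _ in edges)


class TestAnnualProportions:
    def test_constant_passthrough(self):
        props = annual_proportions(constant_params(p_death=0.1), t=7)
        assert np.all(props["death"] == 0.1)

    def test_grid_padding(self):
        props = annual_proportions(constant_params(p_prog=0.05, p_age=0.02), t=0)
        assert np.all(props["progression"][:, :-1] == 0.05)
        assert np.all(props["progression"][:, -1] == 0.0)
        assert np.all(props["ageing"][:-1, :] == 0.02)
        assert np.all(props["ageing"][-1, :] == 0.0)

    def test_negative_time(self):
        with pytest.raises(ValueError):
            annual_proportions(constant_params(), t=-1)


def single_stock_state(n=1000.0, band=0, state=0):
    s = zero_state()
    s.alive[band, state] = n
    return s


class TestStep:
    def test_identity(self):
        state = single_stock_state(1234.0)
        new, rec = step(state, constant_params())
        assert np.array_equal(new.alive, state.alive)
        assert new.t == state.t + 1
        assert rec.deaths.sum() == 0

    def test_death_only(self):
        new, rec = step(single_stock_state(1000.0), constant_params(p_death=0.1))
        assert new.alive[0, 0] == pytest.approx(900.0)
        assert rec.deaths[0, 0] == pytest.approx(100.0)
        assert new.died_cum[0, 0] == pytest.approx(100.0)

    def test_progression_and_ageing(self):
        params = constant_params(p_prog=0.05, p_age=0.02)
        new, rec = step(single_stock_state(1000.0), params)
        assert new.alive[0, 0] == pytest.approx(930.0)
        assert new.alive[0, 1] == pytest.approx(50.0)
        assert new.alive[1, 0] == pytest.approx(20.0)
        assert rec.progression_out[0, 0] == pytest.approx(50.0)
        assert rec.ageing_out[0, 0] == pytest.approx(20.0)

    def test_entries_added_after_outflows(self):
        params = constant_params(p_death=0.5, entry_rate=100.0)
        new, _ = step(single_stock_state(1000.0), params)
        # entrants are not exposed to the same year's death risk
        assert new.alive[0, 0] == pytest.approx(600.0)
        assert new.entered_cum[0, 0] == pytest.approx(100.0)

    def test_overflow_rescaled_with_warning(self):
        params = constant_params(p_death=0.8, p_dereg=0.6)
        with pytest.warns(UserWarning, match="rescaling"):
            new, rec = step(single_stock_state(1000.0), params)
        assert new.alive[0, 0] == pytest.approx(0.0)
        # the two outflows keep their relative sizes
        assert rec.deaths[0, 0] / rec.deregs[0, 0] == pytest.approx(0.8 / 0.6)
        assert rec.deaths[0, 0] + rec.deregs[0, 0] == pytest.approx(1000.0)

    def test_negative_alive_rejected(self):
        state = zero_state()
        state.alive[0, 0] = 10.0
        state.alive[1, 1] = -1.0
        with pytest.raises(ValueError):
            step(state, constant_params())

    def test_substep_equivalence_single_outflow(self):
        """With one outflow, k substeps of 1-(1-p)^(1/k) compose to p exactly."""
        params = constant_params(p_death=0.2)
        annual, _ = step(single_stock_state(1000.0), params, substeps=1)
        sub, _ = step(single_stock_state(1000.0), params, substeps=4)
        assert sub.alive[0, 0] == pytest.approx(annual.alive[0, 0], rel=1e-12)


class TestSimulate:
    def test_geometric_decay_closed_form(self):
        traj = simulate(single_stock_state(1000.0), constant_params(p_death=0.2), 3)
        assert traj.states[-1].alive[0, 0] == pytest.approx(1000 * 0.8**3)
        assert traj.states[-1].alive[0, 0] == pytest.approx(512.0)

    def test_zero_rate_constant_trajectory(self):
        initial = single_stock_state(777.0)
        traj = simulate(initial, constant_params(), 5)
        for state in traj.states:
            assert np.array_equal(state.alive, initial.alive)

    def test_horizon_and_linkage(self):
        traj = simulate(single_stock_state(100.0), constant_params(p_death=0.1), 4)
        assert len(traj.states) == 5
        assert len(traj.flows) == 4
        for k in range(4):
            before = traj.states[k]
            after = traj.states[k + 1]
            rec = traj.flows[k]
            # consecutive states linked exactly by the recorded flows
            outflow = (
                rec.deaths + rec.deregs + rec.ageing_out + rec.progression_out
            )
            inflow = np.zeros_like(outflow)
            inflow[:, 1:] += rec.progression_out[:, :-1]
            inflow[1:, :] += rec.ageing_out[:-1, :]
            inflow += rec.entries
            np.testing.assert_allclose(
                after.alive, before.alive - outflow + inflow, rtol=1e-12
            )

    def test_bad_horizon(self):
        with pytest.raises(ValueError):
            simulate(single_stock_state(), constant_params(), 0)

    def test_deterministic(self):
        a = simulate(single_stock_state(500.0), constant_params(p_death=0.03), 6)
        b = simulate(single_stock_state(500.0), constant_params(p_death=0.03), 6)
        for sa, sb in zip(a.states, b.states):
            assert np.array_equal(sa.alive, sb.alive)


def assert_conserved(traj, initial):
    """Sum(alive + died + left) - entered == initial alive, at every state."""
    baseline = initial.alive.sum()
    for state in traj.states:
        closed = (
            state.alive.sum()
            + state.died_cum.sum()
            + state.left_cum.sum()
            - state.entered_cum.sum()
        )
        assert closed == pytest.approx(baseline, rel=1e-9)


class TestConservation:
    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 2**32 - 1),
        horizon=st.integers(1, 8),
        entry=st.floats(0, 500),
    )
    def test_random_constant_parameters(self, seed, horizon, entry):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0, 0.3, size=(4, 4, 4))
        params = zero_parameters()
        for (b, s) in list(params.death):
            params.death[(b, s)] = FlowSpec(kind="constant", p=raw[0, b, s])
            params.dereg[(b, s)] = FlowSpec(kind="constant", p=raw[1, b, s])
            params.entry[(b, s)] = EntrySpec(kind="constant", rate=entry)
        for key in params.ageing:
            params.ageing[key] = FlowSpec(kind="constant", p=raw[2][key])
        for key in params.progression:
            params.progression[key] = FlowSpec(kind="constant", p=raw[3][key])
        initial = zero_state()
        initial.alive[:] = rng.uniform(0, 10_000, size=(4, 4))
        traj = simulate(initial, params, horizon)
        assert_conserved(traj, initial)

    def test_polynomial_parameters_conserved(self):
        params = constant_params(entry_rate=50.0)
        for key in params.death:
            params.death[key] = FlowSpec(
                kind="polynomial", beta=(0.01, 0.002, 0.0001, 0.0), t_max=11
            )
        initial = zero_state()
        initial.alive[:] = 1000.0
        traj = simulate(initial, params, 15)
        assert_conserved(traj, initial)

    def test_non_negativity(self):
        params = constant_params(p_death=0.3, p_dereg=0.3, p_prog=0.2, p_age=0.2)
        initial = zero_state()
        initial.alive[:] = 100.0
        traj = simulate(initial, params, 10)
        for state in traj.states:
            assert np.all(state.alive >= 0)
            assert np.all(state.died_cum >= 0)
        for rec in traj.flows:
            for arr in (rec.deaths, rec.deregs, rec.entries, rec.ageing_out,
                        rec.progression_out):
                assert np.all(arr >= 0)

    def test_outflows_bounded_by_stock(self):
        params = constant_params(p_death=0.4, p_dereg=0.4, p_prog=0.3, p_age=0.3)
        initial = zero_state()
        initial.alive[:] = 1000.0
        with pytest.warns(UserWarning):
            traj = simulate(initial, params, 3)
        for k, rec in enumerate(traj.flows):
            start = traj.states[k].alive
            out = rec.deaths + rec.deregs + rec.ageing_out + rec.progression_out
            assert np.all(out <= start + 1e-9)
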