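"""Membrane kinetics and the monodomain stepper: equilibria, conservation,
stability, conduction-velocity scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from purkinje3d.ep import (
    MembraneParams,
    StimulusProtocol,
    TissueDomain,
    apply_stimulus_protocol,
    grid_spacing_2d,
    membrane_rates,
    monodomain_step,
    stimulus_vector,
)
from purkinje3d.network_texture import PlacementRect


class TestMembrane:
    def test_rest_state_is_equilibrium(self):
        dv, dh = membrane_rates(0.0, 1.0, MembraneParams())
        assert dv == 0 and dh == 0

    def test_fully_excited_decay_rate(self):
        p = MembraneParams()
        dv, _ = membrane_rates(1.0, 0.0, p)
        assert dv == pytest.approx(-1.0 / p.tau_out)

    def test_action_potential_matches_ode_oracle(self):
        # independent oracle: scipy adaptive ODE integration of the same rates
        p = MembraneParams()

        def rhs(t, y):
            dv, dh = membrane_rates(y[0], y[1], p)
            return [float(dv), float(dh)]

        sol = solve_ivp(rhs, [0, 400], [0.3, 1.0], max_step=0.25)
        dom = TissueDomain(np.ones((1, 1), bool), 0.025, 0.0)
        state = dom.rest_state()
        state.v[:] = 0.3
        peak = 0.0
        for _ in range(40000):
            monodomain_step(state, dom, 0.01)
            peak = max(peak, state.v[0])
        assert peak > 0.9 and sol.y[0].max() > 0.9
        assert peak == pytest.approx(sol.y[0].max(), abs=0.01)
        assert abs(state.v[0]) < 0.05  # repolarized

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MembraneParams(tau_in=-1)
        with pytest.raises(ValueError):
            MembraneParams(v_gate=1.5)

    @given(
        v=st.floats(-0.2, 1.2),
        h=st.floats(0.0, 1.0),
        dt=st.floats(0.001, 5.0),
    )
    def test_gate_stays_in_unit_interval(self, v, h, dt):
        # the exact exponential gate update is unconditionally bounded
        dom = TissueDomain(np.ones((1, 1), bool), 0.025, 0.0)
        state = dom.rest_state()
        state.v[:] = v
        state.h[:] = h
        monodomain_step(state, dom, dt)
        assert 0.0 <= state.h[0] <= 1.0


class TestDiffusion:
    def test_uniform_state_is_fixed_point(self):
        rng = np.random.default_rng(0)
        phase = np.clip(rng.uniform(0.2, 1.0, (12, 12, 12)), 0, 1)
        dom = TissueDomain(phase >= 0.5, 0.025, 0.001, phase=phase)
        state = dom.rest_state()
        state.v[:] = 0.37
        monodomain_step(state, dom, 0.9 * dom.dt_max, reaction=False)
        np.testing.assert_array_equal(state.v, np.full(dom.n_nodes, 0.37))

    def test_phase_weighted_conservation(self):
        rng = np.random.default_rng(1)
        phase = np.clip(rng.uniform(0.2, 1.0, (16, 16, 16)), 0, 1)
        mask = phase >= 0.5
        dom = TissueDomain(mask, 0.025, 0.001, phase=phase)
        state = dom.rest_state()
        state.v[:] = rng.uniform(0, 1, dom.n_nodes)
        phi = phase[mask]
        total0 = float(np.sum(phi * state.v))
        for _ in range(20):
            monodomain_step(state, dom, 0.9 * dom.dt_max, reaction=False)
            total = float(np.sum(phi * state.v))
            assert abs(total - total0) / abs(total0) < 1e-10

    def test_stability_bound_enforced(self):
        dom = TissueDomain(np.ones((8, 8, 8), bool), 0.025, 0.02)
        with pytest.raises(ValueError, match="stability"):
            monodomain_step(dom.rest_state(), dom, 10 * dom.dt_max)

    def test_stability_bound_matches_classical_formula(self):
        h, D, dim = 0.025, 0.001, 3
        dom = TissueDomain(np.ones((10, 10, 10), bool), h, D)
        assert dom.dt_max == pytest.approx(h**2 / (2 * dim * D), rel=1e-9)

    def test_plane_wave_cv_isotropy_2d_vs_1d(self):
        # discretization isotropy: 2D plane wave equals the 1D cable within 3%
        cv = {}
        for ndim in (1, 2):
            shape = (400, 1) if ndim == 1 else (400, 9)
            dom = TissueDomain(np.ones(shape, bool), 0.02, 0.001)
            state = dom.rest_state()
            stim_nodes = np.arange(dom.n_nodes)[dom.node_coords[:, 0] < 5]
            prot = apply_stimulus_protocol(dom, stim_nodes, 2.0, 2.0)
            dt = 0.02
            while state.time < 150:
                stim = stimulus_vector([prot], state.time, dom.n_nodes)
                monodomain_step(state, dom, dt, stim)
                if state.activation[dom.node_of((340, shape[1] // 2))] > 0:
                    break
            i1 = dom.node_of((100, shape[1] // 2))
            i2 = dom.node_of((300, shape[1] // 2))
            cv[ndim] = 200 * 0.02 / (state.activation[i2] - state.activation[i1])
        assert cv[2] == pytest.approx(cv[1], rel=0.03)

    def test_return_to_rest_after_single_stimulus(self):
        dom = TissueDomain(np.ones((100, 1), bool), 0.025, 0.001)
        state = dom.rest_state()
        prot = apply_stimulus_protocol(dom, np.arange(4), 2.0, 2.0)
        dt = 0.05
        while state.time < 1000:
            stim = stimulus_vector([prot], state.time, dom.n_nodes)
            monodomain_step(state, dom, dt, stim)
        assert np.max(np.abs(state.v)) < 1e-3
        assert np.all(state.activation > 0)  # the wave did traverse the cable


class TestConductionVelocity:
    @staticmethod
    def cable_cv(D, h=0.01, length=6.0):
        n = int(length / h)
        dom = TissueDomain(np.ones((n, 1), bool), h, D)
        state = dom.rest_state()
        prot = apply_stimulus_protocol(dom, np.arange(5), 2.0, 2.0)
        dt = min(0.9 * dom.dt_max, 0.005)
        i1, i2 = int(0.3 * n), int(0.8 * n)
        while state.time < 300:
            stim = stimulus_vector([prot], state.time, dom.n_nodes)
            monodomain_step(state, dom, dt, stim)
            if state.activation[i2] > 0:
                break
        return (i2 - i1) * h / (state.activation[i2] - state.activation[i1])

    def test_cv_scales_with_sqrt_of_diffusivity(self):
        cv1 = self.cable_cv(0.001)
        cv20 = self.cable_cv(0.02)
        assert cv20 / cv1 == pytest.approx(np.sqrt(20), rel=0.05)


class TestStimulus:
    def test_zero_amplitude_is_identity(self):
        dom = TissueDomain(np.ones((30, 1), bool), 0.025, 0.001)
        s1, s2 = dom.rest_state(), dom.rest_state()
        prot = apply_stimulus_protocol(dom, [0], 0.0, 2.0)
        for _ in range(100):
            stim = stimulus_vector([prot], s1.time, dom.n_nodes)
            monodomain_step(s1, dom, 0.05, stim)
            monodomain_step(s2, dom, 0.05)
        np.testing.assert_array_equal(s1.v, s2.v)

    def test_protocols_add_linearly(self):
        dom = TissueDomain(np.ones((10, 1), bool), 0.025, 0.001)
        p1 = apply_stimulus_protocol(dom, [2], 1.0, 5.0)
        p2 = apply_stimulus_protocol(dom, [2], 2.0, 5.0)
        v = stimulus_vector([p1, p2], 1.0, dom.n_nodes)
        assert v[2] == pytest.approx(3.0)

    def test_inactive_node_rejected(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        dom = TissueDomain(mask, 0.025, 0.001)
        with pytest.raises(ValueError, match="not an active node"):
            apply_stimulus_protocol(dom, [(3, 3)], 1.0, 1.0)

    def test_cable_end_stimulus_propagates(self):
        dom = TissueDomain(np.ones((120, 1), bool), 0.025, 0.001)
        state = dom.rest_state()
        prot = apply_stimulus_protocol(dom, np.arange(4), 2.0, 2.0)
        while state.time < 150 and state.activation[-1] < 0:
            stim = stimulus_vector([prot], state.time, dom.n_nodes)
            monodomain_step(state, dom, 0.05, stim)
        assert state.activation[-1] > 0


class TestGridSpacing2D:
    def test_worked_example(self):
        # a placement spanning 200 ventricular cells over 400 px halves the spacing
        rect = PlacementRect(a=0.0, b=200 * 0.025, c=0.0, d=1.0)
        dx, _ = grid_spacing_2d(rect, 400, 40, 0.025)
        assert dx == pytest.approx(0.0125)

    def test_square_aspect_gives_equal_spacing(self):
        rect = PlacementRect(a=0.0, b=2.0, c=0.0, d=2.0)
        dx, dy = grid_spacing_2d(rect, 64, 64, 0.025)
        assert dx == pytest.approx(dy)

    def test_doubling_width_halves_spacing(self):
        rect = PlacementRect(a=0.0, b=2.0, c=0.0, d=1.0)
        dx1, _ = grid_spacing_2d(rect, 100, 50, 0.025)
        dx2, _ = grid_spacing_2d(rect, 200, 50, 0.025)
        assert dx2 == pytest.approx(dx1 / 2)

    def test_zero_dimensions_rejected(self):
        rect = PlacementRect(a=0.0, b=1.0, c=0.0, d=1.0)
        with pytest.raises(ValueError):
            grid_spacing_2d(rect, 0, 10, 0.025)
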