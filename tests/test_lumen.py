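"""Lumen transport solver: conservation, junction coupling, equilibria,
boundary conditions, and the mass-balance audit."""

import numpy as np
import pytest

from lungno.cycle import BreathingPattern, Phase
from lungno.lumen import (
    GridSpec,
    TransportModel,
    _PhaseOperator,
    mass_balance_audit,
    simulate_cycle,
    simulate_phase,
)
from lungno.wall import AlveolarParams, WallTransportParams, airway_flux_law, hatta_numbers

TINY = 1e-30


def quiet_walls() -> WallTransportParams:
    """Wall parameters with negligible airway production and consumption."""
    return WallTransportParams(pr=TINY, lambda_t_air=TINY)


def quiet_alveoli() -> AlveolarParams:
    return AlveolarParams(p_alv=TINY, u_alv=1e-12)


@pytest.fixture()
def hold_pattern():
    # long breath-hold for relaxation tests; in/ex phases unused
    return BreathingPattern(q_in=500, q_ex=-50, t_in=2, t_bh=12.0, t_ex=20)


class TestConservation:
    def test_sourceless_breath_hold_conserves_mass_and_uniform_field(
            self, healthy_rest, hold_pattern):
        model = TransportModel(rest=healthy_rest, pattern=hold_pattern,
                               wall_params=quiet_walls(), alveolar=quiet_alveoli())
        op = _PhaseOperator(model, Phase.BREATH_HOLD)
        rng = np.random.default_rng(3)
        c0 = 1e-9 * (1.0 + 0.5 * rng.random(model.grid.n_nodes))
        tr = simulate_phase(model, Phase.BREATH_HOLD, c0)
        w = op.s_of(0.0) * op.w_rest
        m0, m1 = np.sum(w * c0), np.sum(w * tr.final)
        assert m1 == pytest.approx(m0, rel=1e-6)
        # a uniform field is exactly stationary
        cu = np.full(model.grid.n_nodes, 2e-9)
        assert np.abs(op.rhs(0.0, cu)).max() < 1e-18

    def test_uniform_field_stationary_under_inflation(self, healthy_rest):
        # inflation dilutes but inflow replenishes: a uniform field stays
        # uniform away from the NO-free mouth boundary
        pattern = BreathingPattern.classical()
        model = TransportModel(rest=healthy_rest, pattern=pattern,
                               wall_params=quiet_walls(), alveolar=quiet_alveoli(),
                               d_no_air=1e-12)
        c0 = np.full(model.grid.n_nodes, 1e-9)
        tr = simulate_phase(model, Phase.INSPIRATION, c0)
        # the 1000 ml of inspired clean air reaches roughly generation 21;
        # the terminal generation is untouched
        distal = model.grid.node_slice(23).start
        np.testing.assert_allclose(tr.final[distal:], 1e-9, rtol=1e-2)
        # the clean-air front has entered through the mouth
        assert tr.final[1] < 0.5e-9

    def test_production_only_linear_growth(self, healthy_rest, hold_pattern):
        model = TransportModel(
            rest=healthy_rest, pattern=hold_pattern,
            wall_params=WallTransportParams(lambda_t_air=TINY),
            alveolar=quiet_alveoli())
        op = _PhaseOperator(model, Phase.BREATH_HOLD)
        c0 = np.zeros(model.grid.n_nodes)
        tr = simulate_phase(model, Phase.BREATH_HOLD, c0)
        rate, _ = op.source_totals(0.0, c0)
        w = op.s_of(0.0) * op.w_rest
        gained = np.sum(w * tr.final) - 0.0
        assert gained == pytest.approx(rate * tr.times[-1], rel=1e-5)


class TestJunctionCoupling:
    def test_diffusive_flux_weighted_by_flow_cross_section(self, healthy_rest,
                                                           hold_pattern):
        # at the generation 16|17 junction the flow cross-sections differ;
        # a field whose zeta-gradients are inversely proportional to
        # D OmegaPrime / L has continuous total diffusive flow, so the
        # junction node must feel no net diffusion
        model = TransportModel(rest=healthy_rest, pattern=hold_pattern,
                               wall_params=quiet_walls(), alveolar=quiet_alveoli())
        grid = model.grid
        op = _PhaseOperator(model, Phase.BREATH_HOLD)
        g16 = healthy_rest.omega_prime[16] / healthy_rest.length[16]
        g17 = healthy_rest.omega_prime[17] / healthy_rest.length[17]
        c = np.zeros(grid.n_nodes)
        z = grid.zeta()
        s16, s17 = grid.node_slice(16), grid.node_slice(17)
        c[s16] = 1e-9 * (1.0 + z[s16])          # slope 1e-9 in gen 16
        c[s17] = 1e-9 * (2.0 + z[s17] * g16 / g17)  # matched total flow
        j = grid.start_index(17)
        balanced = op.rhs(0.0, c)[j]
        c_bad = c.copy()
        c_bad[s17] = 1e-9 * (2.0 + z[s17])      # same slope: flow jump
        unbalanced = op.rhs(0.0, c_bad)[j]
        assert abs(balanced) < 1e-3 * abs(unbalanced)


class TestEquilibria:
    def test_breath_hold_relaxes_alveolar_zone_to_plateau(self, healthy_rest,
                                                          hold_pattern):
        model = TransportModel(rest=healthy_rest, pattern=hold_pattern,
                               wall_params=quiet_walls())
        tr = simulate_phase(model, Phase.BREATH_HOLD, np.zeros(model.grid.n_nodes))
        c_star = model.alveolar.equilibrium
        sl = model.grid.node_slice(23)
        np.testing.assert_allclose(tr.final[sl], c_star, rtol=0.02)

    def test_airway_equilibrium_is_fixed_point(self, healthy_rest):
        # single-source configuration: negligible alveolar exchange, no flow,
        # negligible inflation so the healthy wall (hence its equilibrium
        # concentration) is identical in every generation.  The uniform field
        # at that equilibrium must be stationary.
        pattern = BreathingPattern(q_in=1e-6, q_ex=-1e-6, t_in=2, t_bh=12, t_ex=2)
        base = WallTransportParams()
        law = airway_flux_law(hatta_numbers(0.0030, 0.0015, 0.0, base), base)
        model = TransportModel(rest=healthy_rest, pattern=pattern,
                               wall_params=base, alveolar=quiet_alveoli())
        op = _PhaseOperator(model, Phase.BREATH_HOLD)
        cu = np.full(model.grid.n_nodes, law.equilibrium)
        scale = np.abs(op.rhs(0.0, np.zeros(model.grid.n_nodes))).max()
        assert np.abs(op.rhs(0.0, cu)).max() < 1e-8 * scale


class TestBoundaryConditions:
    def test_mouth_zero_during_inspiration(self, healthy_cycle):
        insp = healthy_cycle.phases[0]
        assert insp.phase is Phase.INSPIRATION
        assert np.all(insp.fields[:, 0] == 0.0)

    def test_mouth_convective_exit_during_expiration(self, healthy_cycle):
        exp = healthy_cycle.expiration
        # zero diffusive gradient at the mouth: the mouth node tracks its
        # neighbour instead of being pinned
        assert exp.fields[-1, 0] > 0
        assert exp.fields[-1, 0] == pytest.approx(exp.fields[-1, 1], rel=0.05)

    def test_terminal_end_is_closed(self, healthy_rest, hold_pattern):
        # with sources off, nothing leaks through the distal end
        model = TransportModel(rest=healthy_rest, pattern=hold_pattern,
                               wall_params=quiet_walls(), alveolar=quiet_alveoli())
        op = _PhaseOperator(model, Phase.BREATH_HOLD)
        c = np.zeros(model.grid.n_nodes)
        c[-1] = 1e-9
        # mass balance including the terminal node must be conservative
        tr = simulate_phase(model, Phase.BREATH_HOLD, c)
        w = op.s_of(0.0) * op.w_rest
        assert np.sum(w * tr.final) == pytest.approx(np.sum(w * c), rel=1e-6)


class TestSimulateCycle:
    def test_positivity_and_finiteness(self, healthy_cycle):
        for tr in healthy_cycle.phases:
            assert np.isfinite(tr.fields).all()
            assert tr.fields.min() > -1e-15

    def test_mass_balance_audit(self, healthy_cycle):
        assert healthy_cycle.mass_residual < 1e-3

    def test_audit_improves_with_refinement(self, healthy_model_fixture):
        res_few = simulate_cycle(healthy_model_fixture, n_samples=41)
        res_many = simulate_cycle(healthy_model_fixture, n_samples=401)
        assert res_many.mass_residual < res_few.mass_residual

    def test_determinism(self, healthy_model_fixture, healthy_cycle):
        res2 = simulate_cycle(healthy_model_fixture)
        np.testing.assert_array_equal(res2.feno_ppb, healthy_cycle.feno_ppb)
        np.testing.assert_array_equal(res2.expiration.fields,
                                      healthy_cycle.expiration.fields)

    def test_feno_series_shape(self, healthy_cycle):
        assert np.all(healthy_cycle.feno_ppb >= 0)
        assert healthy_cycle.feno_ppb[0] == pytest.approx(0.0, abs=1e-6)
        assert healthy_cycle.feno_end_ppb == pytest.approx(
            healthy_cycle.feno_ppb[-1])

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(3)
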