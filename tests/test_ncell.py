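import copy

import numpy as np
import pytest

from symcell.ncell_dynamics import (
    CellState,
    MediumState,
    PopulationState,
    SimConfig,
    intracellular_derivative,
    medium_derivative,
    run_ncell,
    step_population,
)
from symcell.networks import CatalyticNetwork, Reaction


@pytest.fixture()
def toy_net():
    """Single reaction X0 + 2 X1 -> X3 + 2 X1 on four chemicals."""
    return CatalyticNetwork(
        k=4,
        reactions=(Reaction(0, 3, 1),),
        diffusible=np.array([1.0, 0.0, 0.0, 1.0]),
        alpha=2.0,
    )


class TestIntracellularDerivative:
    def test_single_reaction_hand_value(self, toy_net):
        # rate = eps * x0 * x1**alpha = 1 * 0.5 * 0.25 = 0.125
        cell = CellState(x=np.array([0.5, 0.5, 0.0, 0.0]))
        med = MediumState(x_med=np.zeros(4), V_med=100.0)
        cfg = SimConfig(N=1, C=0.0, V_med=100.0, D=0.0)
        dx, mu = intracellular_derivative(cell, med, toy_net, cfg)
        assert mu == 0.0
        assert dx[3] == pytest.approx(0.125)
        assert dx[0] == pytest.approx(-0.125)
        assert dx[1] == dx[2] == 0.0

    def test_zero_gradient_means_zero_growth(self, net1):
        x = np.full(6, 1 / 6)
        cell = CellState(x=x.copy())
        med = MediumState(x_med=x.copy(), V_med=100.0)
        cfg = SimConfig(N=1, C=0.15, V_med=100.0, D=1.0)
        dx, mu = intracellular_derivative(cell, med, net1, cfg)
        assert mu == pytest.approx(0.0, abs=1e-15)
        # with mu = 0 and no gradient, only the reaction terms remain
        cfg0 = SimConfig(N=1, C=0.15, V_med=100.0, D=0.0)
        dx0, _ = intracellular_derivative(cell, med, net1, cfg0)
        np.testing.assert_allclose(dx, dx0, atol=1e-15)

    def test_no_catalyst_no_reaction(self, net1):
        x = np.zeros(6)
        x[0] = 0.4
        x[5] = 0.6  # X5 catalyses nothing in this network
        cell = CellState(x=x)
        med = MediumState(x_med=x.copy(), V_med=100.0)
        cfg = SimConfig(N=1, C=0.15, V_med=100.0, D=1.0)
        dx, _ = intracellular_derivative(cell, med, net1, cfg)
        np.testing.assert_allclose(dx, 0.0, atol=1e-15)

    def test_length_mismatch_raises(self, net1):
        cell = CellState(x=np.full(5, 0.2))
        med = MediumState(x_med=np.zeros(6), V_med=100.0)
        with pytest.raises(ValueError, match="length mismatch"):
            intracellular_derivative(cell, med, net1, SimConfig())


class TestMediumDerivative:
    def test_equilibrium_with_exterior(self, net1):
        med = MediumState(x_med=np.array([0.15, 0, 0, 0, 0, 0.0]), V_med=100.0)
        cfg = SimConfig(N=1, C=0.15, V_med=100.0, D=1.0)
        np.testing.assert_allclose(medium_derivative([], med, net1, cfg), 0.0)

    def test_supply_only(self, net1):
        med = MediumState(x_med=np.zeros(6), V_med=100.0)
        cfg = SimConfig(N=1, C=0.15, V_med=100.0, D=1.0, D_med=0.7)
        d = medium_derivative([], med, net1, cfg)
        assert d[0] == pytest.approx(0.7 * 0.15)
        np.testing.assert_allclose(d[1:], 0.0)

    def test_zero_gradient_cell_leaves_supply_term(self, net1):
        x = np.full(6, 1 / 6)
        med = MediumState(x_med=x.copy(), V_med=100.0)
        cell = CellState(x=x.copy(), v=2.0)
        cfg = SimConfig(N=1, C=0.15, V_med=100.0, D=1.0)
        d = medium_derivative([cell], med, net1, cfg)
        assert d[0] == pytest.approx(1.0 * (0.15 - 1 / 6))
        np.testing.assert_allclose(d[1:], 0.0, atol=1e-15)


class TestStepPopulation:
    def test_decoupled_cell_never_grows(self, net1):
        cfg = SimConfig(N=4, C=0.15, V_med=100.0, D=0.0, seed=0)
        cell = CellState(x=np.full(6, 1 / 6), v=1.0, v_birth=1.0, id=0)
        state = PopulationState(
            cells=[cell], medium=MediumState(np.zeros(6), 100.0)
        )
        rng = np.random.default_rng(0)
        for _ in range(5):
            state, divs, elims, _ = step_population(state, net1, cfg, 10.0, rng)
            assert divs == [] and elims == []
        assert state.cells[0].v == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_division_gives_identical_daughters(self, net1):
        cfg = SimConfig(N=10, C=0.15, V_med=100.0, D=1.0, division_noise=0.0, seed=0)
        cell = CellState(x=np.full(6, 1 / 6), v=1.05, v_birth=0.5, id=0)
        state = PopulationState(cells=[cell], medium=MediumState(np.zeros(6), 100.0))
        state, divs, _, _ = step_population(state, net1, cfg, 1e-3, np.random.default_rng(0))
        assert len(divs) == 1 and len(state.cells) == 2
        np.testing.assert_array_equal(state.cells[0].x, state.cells[1].x)
        assert state.cells[0].v == pytest.approx(state.cells[1].v)
        assert state.cells[0].divisions == 1

    def test_capacity_enforced_by_random_elimination(self, net1):
        cfg = SimConfig(N=3, C=0.15, V_med=100.0, D=1.0, seed=0)
        cells = [
            CellState(x=np.full(6, 1 / 6), v=1.0, v_birth=1.0, id=i) for i in range(3)
        ]
        cells[0].v_birth = 0.5  # will divide immediately
        cells[0].v = 1.05
        state = PopulationState(cells=cells, medium=MediumState(np.zeros(6), 100.0), next_id=3)
        state, divs, elims, _ = step_population(state, net1, cfg, 1e-3, np.random.default_rng(1))
        assert len(divs) == 1
        assert len(elims) == 1
        assert len(state.cells) == 3


class TestRunNCell:
    def test_seeded_determinism(self, net1):
        cfg = SimConfig(N=4, C=0.15, V_med=10.0, D=1.0, t_max=60.0,
                        record_interval=10.0, seed=42)
        t1 = run_ncell(net1, cfg)
        t2 = run_ncell(net1, cfg)
        assert t1.times == t2.times
        assert t1.division_events == t2.division_events
        assert t1.elimination_events == t2.elimination_events
        for (ca, ma), (cb, mb) in zip(t1.snapshots, t2.snapshots):
            np.testing.assert_array_equal(ma.x_med, mb.x_med)
            for a, b in zip(ca, cb):
                assert a.id == b.id
                np.testing.assert_array_equal(a.x, b.x)
                assert a.v == b.v

    def test_population_capped_and_simplex_conserved(self, net1):
        cfg = SimConfig(N=5, C=0.5, V_med=10.0, D=1.0, t_max=300.0,
                        record_interval=5.0, seed=7)
        traj = run_ncell(net1, cfg)
        assert max(traj.populations) <= 5
        worst = max(
            abs(traj.concentration_array(i).sum(axis=1) - 1.0).max()
            for i in range(len(traj.times))
        )
        assert worst < 1e-7
        assert len(traj.division_events) > 0

    def test_volume_doubling_bounded(self, net1):
        # exact event location keeps volumes at or below the doubling
        # threshold (cells may shrink below birth volume when mu < 0)
        cfg = SimConfig(N=5, C=0.5, V_med=10.0, D=1.0, t_max=300.0,
                        record_interval=5.0, seed=7)
        traj = run_ncell(net1, cfg)
        for cells, _ in traj.snapshots:
            for c in cells:
                assert c.v <= 2.0 * c.v_birth * (1 + 1e-6)
                assert c.v > 0
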