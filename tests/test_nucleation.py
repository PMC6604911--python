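"""Solution boxes and the scaled-down Langevin dynamics."""

import numpy as np
import pytest

from dnapatite.errors import InputError
from dnapatite.nucleation import (PROTOCOL_STAGES_NS, LangevinEngine,
                                  SimulationParams, build_solution_box,
                                  equilibration_protocol, run_langevin,
                                  water_count, WATER_MASS,
                                  DISPLACED_VOLUME)


@pytest.fixture(scope="module")
def water_box():
    return build_solution_box(0, [12.0, 12.0, 12.0], seed=1)


@pytest.fixture(scope="module")
def mini_box():
    return build_solution_box(1, [14.0, 14.0, 14.0], seed=2)


def test_single_formula_unit_composition(mini_box):
    assert (mini_box.n_ca, mini_box.n_po4, mini_box.n_oh) == (10, 6, 2)
    ions = mini_box.structure.select(
        np.isin(mini_box.structure.residue_name, ["CA", "PO4", "OH"]))
    assert ions.net_charge == pytest.approx(0.0)


def test_paper_scale_composition_from_oh_count():
    """n chosen to give 189 hydroxides yields the 945:567:189 composition."""
    n = 189 / 2.0
    assert (int(round(10 * n)), int(round(6 * n)),
            int(round(2 * n))) == (945, 567, 189)
    # the builder applies exactly this rule
    sb = build_solution_box(0.5, [11.0, 11.0, 11.0], seed=4)
    assert (sb.n_ca, sb.n_po4, sb.n_oh) == (5, 3, 1)


def test_water_count_closed_form(water_box):
    v = 12.0 ** 3
    expected = round(1.0 * v * 0.033428)
    assert abs(water_box.n_water - expected) <= 1


def test_water_density_within_one_percent(mini_box):
    v_free = 14.0 ** 3 - DISPLACED_VOLUME * (10 + 5 * 6 + 2)
    rho = mini_box.n_water * WATER_MASS * 1.66054 / v_free
    assert rho == pytest.approx(1.0, abs=0.01)


def test_box_reproducible_under_seed():
    a = build_solution_box(0.5, [11.0, 11.0, 11.0], seed=9)
    b = build_solution_box(0.5, [11.0, 11.0, 11.0], seed=9)
    assert np.array_equal(a.structure.coord, b.structure.coord)


def test_no_intermolecular_clashes(mini_box):
    s = mini_box.structure
    from scipy.spatial import cKDTree

    w = s.coord % mini_box.box
    t = cKDTree(w, boxsize=mini_box.box)
    pairs = t.query_pairs(1.5, output_type="ndarray")
    # any remaining close pair must be an intramolecular bond
    assert all(s.molecule_id[i] == s.molecule_id[j] for i, j in pairs)


def test_simulation_params_invariants():
    with pytest.raises(InputError):
        SimulationParams(timestep=3.0)
    with pytest.raises(InputError):
        SimulationParams(cutoff=8.0, switch_start=9.0)


class TestDynamics:
    @pytest.fixture(scope="class")
    def short_params(self):
        return SimulationParams(n_steps=2000, save_interval=100, seed=3,
                                friction=10.0, cutoff=5.5, switch_start=4.5,
                                relax_steps=50)

    def test_equipartition_temperature(self, water_box, short_params):
        traj = run_langevin(water_box, short_params)
        temps = traj.structure.meta["run"]["temperatures"]
        mean_t = float(np.mean(temps[len(temps) // 2:]))
        assert mean_t == pytest.approx(298.0, abs=15.0)

    def test_same_seed_is_bitwise_identical(self, water_box, short_params):
        t1 = run_langevin(water_box, short_params)
        t2 = run_langevin(water_box, short_params)
        assert np.array_equal(t1.coords, t2.coords)

    def test_frozen_atoms_never_move(self, mini_box):
        s = mini_box.structure
        frozen = s.residue_name == "PO4"
        p = SimulationParams(n_steps=300, save_interval=100, seed=1,
                             cutoff=6.0, switch_start=5.0, relax_steps=20)
        traj = run_langevin(mini_box, p, frozen_mask=frozen)
        assert np.array_equal(traj.coords[-1][frozen], s.coord[frozen])

    def test_nve_energy_drift_below_one_percent(self, water_box):
        p = SimulationParams(n_steps=1000, save_interval=50, seed=3,
                             friction=0.0, cutoff=5.5, switch_start=4.5,
                             relax_steps=100)
        eng = LangevinEngine(water_box.structure, water_box.box, p)
        eng.relax(p.relax_steps)
        eng.init_velocities()
        _, _, _, energies = eng.run()
        drift = abs(energies[-1] - energies[0]) / abs(energies[0])
        assert drift < 0.01

    def test_com_momentum_stays_bounded(self, water_box, short_params):
        eng = LangevinEngine(water_box.structure, water_box.box,
                             short_params)
        eng.relax(50)
        eng.init_velocities()
        eng.run(n_steps=500)
        m = eng.m[:, None]
        p_com = np.abs((m * eng.v).sum(axis=0)).max()
        p_scale = float(np.abs(m * eng.v).sum())
        assert p_com < 0.05 * p_scale


def test_equilibration_protocol_stages(water_box):
    p = SimulationParams(n_steps=100, save_interval=20, seed=2,
                         friction=20.0, cutoff=5.5, switch_start=4.5,
                         relax_steps=50)
    traj, log = equilibration_protocol(water_box, p, scale=2e-4)
    assert len(log) == len(PROTOCOL_STAGES_NS)
    assert log[0]["target_K"] == 500.0
    assert log[-1]["target_K"] == 298.0
    # durations follow the declared stage list x scale
    for entry, ns in zip(log, PROTOCOL_STAGES_NS):
        expected_ps = max(round(ns * 1e6 * 2e-4), p.save_interval) * 1e-3
        assert entry["duration_ps"] == pytest.approx(expected_ps, rel=1e-6)
    # stage boundaries recorded as frame indices
    firsts = [e["first_frame"] for e in log]
    assert firsts == sorted(firsts)
    assert traj.n_frames >= firsts[-1]
    # final stage thermalized near the target
    assert log[-1]["mean_T"] == pytest.approx(298.0, abs=25.0)
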