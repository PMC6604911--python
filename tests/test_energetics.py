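"""Energy terms vs hand values, brute-force oracles and numeric gradients."""

import numpy as np
import pytest

from dnapatite.energy import (COULOMB, bonded_energy, interaction_energy,
                              nonbonded_energy, total_energy)
from dnapatite.errors import InputError, ParameterizationError
from dnapatite.forcefield import build_topology, default_params, load_params
from dnapatite.minimize import minimize_structure
from dnapatite.structure import Structure
from dnapatite.synthetic import (oracle_bonded_energy,
                                 oracle_interaction_energy,
                                 oracle_nonbonded_energy)


def mk(coords, elements, charges=None, mol=None, resname="UNK"):
    n = len(coords)
    return Structure(
        coord=np.asarray(coords, float), element=np.array(elements),
        name=np.array(elements),
        charge=np.array(charges if charges is not None else [0.0] * n),
        molecule_id=np.array(mol if mol is not None else [0] * n, dtype=int),
        residue_id=np.arange(n), residue_name=np.array([resname] * n))


@pytest.fixture(scope="module")
def random_cluster():
    """A bonded 6-atom chain plus charges: bonds, angles, torsions, 1-4."""
    rng = np.random.default_rng(3)
    base = np.array([[0, 0, 0], [1.5, 0, 0], [2.1, 1.3, 0.2],
                     [3.5, 1.4, 0.9], [4.0, 2.6, 0.3], [2.0, -0.9, 1.0]],
                    dtype=float)
    s = mk(base + rng.normal(0, 0.05, base.shape),
           ["C", "C", "C", "C", "O", "N"],
           charges=rng.uniform(-0.3, 0.3, 6))
    return s, build_topology(s)


def test_coulomb_constant_two_unit_charges():
    s = mk([[0, 0, 0], [1, 0, 0]], ["Ca", "Ca"], [1.0, 1.0])
    e = nonbonded_energy(s, build_topology(s), default_params())
    assert e.e_elec == pytest.approx(COULOMB, rel=1e-12)


def test_lj_minimum_is_minus_epsilon(ff_params):
    rmh, eps = ff_params.lj["C"]
    s = mk([[0, 0, 0], [2 * rmh, 0, 0]], ["C", "C"], mol=[0, 1])
    e = nonbonded_energy(s, build_topology(s), ff_params)
    assert e.e_vdw == pytest.approx(-eps, rel=1e-12)


def test_single_bond_hand_value(ff_params):
    k, b0 = ff_params.bond_param("C", "C")
    s = mk([[0, 0, 0], [b0 + 0.1, 0, 0]], ["C", "C"])
    e = bonded_energy(s, build_topology(s), ff_params)
    assert e.e_str == pytest.approx(k * 0.01, rel=1e-12)
    assert e.e_bnd == 0.0 and e.e_tor == 0.0


def test_equilibrium_geometry_has_zero_bonded_energy(ff_params):
    k, b0 = ff_params.bond_param("O", "H")
    s = mk([[0, 0, 0], [b0, 0, 0]], ["O", "H"])
    e = bonded_energy(s, build_topology(s), ff_params)
    assert e.e_str == pytest.approx(0.0, abs=1e-12)


def test_bonded_matches_oracle(random_cluster, ff_params):
    s, t = random_cluster
    e = bonded_energy(s, t, ff_params)
    o_str, o_bnd, o_tor = oracle_bonded_energy(s, t, ff_params)
    assert e.e_str == pytest.approx(o_str, rel=1e-10)
    assert e.e_bnd == pytest.approx(o_bnd, rel=1e-10)
    assert e.e_tor == pytest.approx(o_tor, rel=1e-10)


def test_nonbonded_matches_oracle_exact_mode(rng, ff_params):
    coords = rng.uniform(0, 8, (30, 3))
    elems = list("CONCH" * 6)
    s = mk(coords, elems, charges=rng.uniform(-0.4, 0.4, 30))
    t = build_topology(s)
    e = nonbonded_energy(s, t, ff_params)
    o_vdw, o_elec = oracle_nonbonded_energy(s, t, ff_params)
    assert e.e_vdw == pytest.approx(o_vdw, rel=1e-10)
    assert e.e_elec == pytest.approx(o_elec, rel=1e-10)


def test_energy_invariant_under_rigid_motion(random_cluster, ff_params):
    s, t = random_cluster
    e0 = total_energy(s, t, ff_params).total
    theta = 0.83
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = s.with_coord(s.coord @ R.T + np.array([11.0, -3.0, 7.0]))
    e1 = total_energy(moved, t, ff_params).total
    assert abs(e1 - e0) < 1e-6


def test_forces_match_numeric_gradient(random_cluster, ff_params):
    s, t = random_cluster
    _, f = total_energy(s, t, ff_params, forces=True)
    h = 1e-5
    for i in range(len(s)):
        for d in range(3):
            xp = s.coord.copy()
            xp[i, d] += h
            xm = s.coord.copy()
            xm[i, d] -= h
            num = -(total_energy(s.with_coord(xp), t, ff_params).total
                    - total_energy(s.with_coord(xm), t, ff_params).total) \
                / (2 * h)
            assert abs(f[i, d] - num) < 1e-4


def test_forces_match_numeric_gradient_cutoff_mode(random_cluster, ff_params):
    s, t = random_cluster
    _, f = total_energy(s, t, ff_params, 4.0, 3.0, forces=True)
    h = 1e-5
    num = np.zeros_like(f)
    for i in range(len(s)):
        for d in range(3):
            xp = s.coord.copy()
            xp[i, d] += h
            xm = s.coord.copy()
            xm[i, d] -= h
            num[i, d] = -(total_energy(s.with_coord(xp), t, ff_params,
                                       4.0, 3.0).total
                          - total_energy(s.with_coord(xm), t, ff_params,
                                         4.0, 3.0).total) / (2 * h)
    assert np.abs(f - num).max() < 1e-4


def test_missing_parameter_is_reported():
    lines = ["ATOM C 12.011 1.908 0.1094"]
    p = load_params(lines)
    with pytest.raises(ParameterizationError, match="O"):
        p.lj_param("O")
    with pytest.raises(ParameterizationError, match="C-C"):
        p.bond_param("C", "C")


def test_po4_topology_enumeration(ff_params):
    from dnapatite.nucleation import _tetrahedron

    coords = np.vstack([[0, 0, 0], _tetrahedron(1.56)])
    s = mk(coords, ["P", "O", "O", "O", "O"], resname="PO4")
    t = build_topology(s)
    assert len(t.bonds) == 4
    assert len(t.angles) == 6
    assert len(t.torsions) == 0


def test_water_topology(ff_params):
    from dnapatite.nucleation import _water_template

    s = mk(_water_template(), ["O", "H", "H"], resname="HOH")
    t = build_topology(s)
    assert len(t.bonds) == 2
    assert len(t.angles) == 1


def test_duplex_angle_count_matches_graph_walk(duplex_I, duplex_I_topology):
    """Angle enumeration equals the brute-force walk over the bond graph."""
    t = duplex_I_topology
    n = len(duplex_I.structure)
    neighbors = [[] for _ in range(n)]
    for i, j in t.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    count = sum(len(nb) * (len(nb) - 1) // 2 for nb in neighbors)
    assert len(t.angles) == count


def test_interaction_energy_far_apart_vanishes(ff_params):
    # neutral fragments: only the short-ranged terms remain at 10^3 Å
    s = mk([[0, 0, 0], [0.96, 0, 0], [1000.0, 0, 0], [1000.96, 0, 0]],
           ["O", "H", "O", "H"], [-0.417, 0.417, -0.417, 0.417],
           mol=[0, 0, 1, 1])
    de = interaction_energy(s, np.array([True, True, False, False]),
                            build_topology(s), ff_params)
    assert abs(de) < 1e-3


def test_interaction_energy_matches_oracle(rng, ff_params):
    from dnapatite.nucleation import _tetrahedron

    coords = np.vstack([[3.0, 0, 0],
                        np.vstack([[0, 0, 0], _tetrahedron(1.56)])])
    s = mk(coords, ["Ca", "P", "O", "O", "O", "O"],
           [2.0, 1.3, -1.075, -1.075, -1.075, -1.075], mol=[0, 1, 1, 1, 1, 1])
    t = build_topology(s)
    mask = np.array([True] + [False] * 5)
    de = interaction_energy(s, mask, t, ff_params)
    assert de == pytest.approx(oracle_interaction_energy(s, mask), rel=1e-10)


def test_interaction_energy_rotation_invariant(ff_params):
    s = mk([[0, 0, 0], [2.8, 0.4, 0.1]], ["Ca", "O"], [2.0, -1.0],
           mol=[0, 1])
    t = build_topology(s)
    mask = np.array([True, False])
    de0 = interaction_energy(s, mask, t, ff_params)
    th = 1.2
    R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    de1 = interaction_energy(s.with_coord(s.coord @ R.T), mask, t, ff_params)
    assert de1 == pytest.approx(de0, abs=1e-9)


def test_interaction_energy_rejects_non_bipartition(ff_params):
    s = mk([[0, 0, 0], [3, 0, 0]], ["Ca", "O"], [2.0, -1.0], mol=[0, 1])
    with pytest.raises(InputError):
        interaction_energy(s, np.array([True, True]), build_topology(s),
                           ff_params)


class TestMinimizer:
    def test_harmonic_dimer_reaches_equilibrium(self, ff_params):
        k, b0 = ff_params.bond_param("C", "C")
        s = mk([[0, 0, 0], [b0 + 0.3, 0, 0]], ["C", "C"])
        out, trace = minimize_structure(s, build_topology(s), ff_params,
                                        n_steps=800)
        b = np.linalg.norm(out.coord[1] - out.coord[0])
        assert b == pytest.approx(b0, abs=1e-3)

    def test_already_minimal_structure_is_fixed_point(self, ff_params):
        k, b0 = ff_params.bond_param("C", "C")
        s = mk([[0, 0, 0], [b0, 0, 0]], ["C", "C"])
        out, trace = minimize_structure(s, build_topology(s), ff_params,
                                        n_steps=100)
        assert np.abs(out.coord - s.coord).max() < 1e-6

    def test_trace_is_non_increasing(self, ff_params, rng):
        coords = rng.uniform(0, 5, (8, 3))
        s = mk(coords, ["C"] * 8, charges=rng.uniform(-0.2, 0.2, 8))
        out, trace = minimize_structure(s, build_topology(s), ff_params,
                                        n_steps=300)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_frozen_atoms_never_move(self, ff_params):
        s = mk([[0, 0, 0], [1.8, 0.2, 0]], ["C", "C"])
        frozen = np.array([True, False])
        out, _ = minimize_structure(s, build_topology(s), ff_params,
                                    frozen_mask=frozen, n_steps=200)
        assert np.array_equal(out.coord[0], s.coord[0])
        assert not np.array_equal(out.coord[1], s.coord[1])
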