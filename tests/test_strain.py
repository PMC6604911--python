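"""Distortion metrics: Δτ, all-atom RMSD and inter-chain distance."""

import numpy as np
import pytest

from dnapatite.dna import (SEQUENCE_I, SEQUENCE_II, SEQUENCE_III,
                           build_canonical_duplex)
from dnapatite.errors import InputError
from dnapatite.strain import (StrainReport, delta_tau, interchain_distance,
                              rmsd_all_atom)
from dnapatite.structure import Structure
from dnapatite.synthetic import (make_perturbed_duplex, oracle_bonded_energy,
                                 oracle_rmsd)


def test_delta_tau_of_identical_structures_is_zero(duplex_I,
                                                   duplex_I_topology,
                                                   ff_params):
    s = duplex_I.structure
    rep = delta_tau(s, s, duplex_I_topology, ff_params)
    assert rep.delta_tau == 0.0
    assert (rep.d_e_str, rep.d_e_bnd, rep.d_e_tor) == (0.0, 0.0, 0.0)
    assert rep.rmsd == pytest.approx(0.0, abs=1e-9)


def test_components_always_sum_to_delta_tau(duplex_I, duplex_I_topology,
                                            ff_params):
    pert, canon, _ = make_perturbed_duplex(sigma=0.3, seed=7)
    rep = delta_tau(pert, canon, duplex_I_topology, ff_params)
    assert rep.delta_tau == pytest.approx(
        rep.d_e_str + rep.d_e_bnd + rep.d_e_tor, abs=1e-6)


def test_reported_row_composes_arithmetically():
    """A report with stretching -32, bending -291, torsion +46 composes to
    a total of -277 kcal/mol."""
    rep = StrainReport(-32.0 - 291.0 + 46.0, -32.0, -291.0, 46.0)
    assert rep.delta_tau == pytest.approx(-277.0)
    assert rep.delta_tau == rep.d_e_str + rep.d_e_bnd + rep.d_e_tor


def test_delta_tau_matches_term_oracle(duplex_I, duplex_I_topology,
                                       ff_params):
    pert, canon, _ = make_perturbed_duplex(sigma=0.1, seed=11)
    rep = delta_tau(pert, canon, duplex_I_topology, ff_params)
    o_rel = oracle_bonded_energy(pert, duplex_I_topology, ff_params)
    o_can = oracle_bonded_energy(canon, duplex_I_topology, ff_params)
    assert rep.d_e_str == pytest.approx(o_rel[0] - o_can[0], rel=1e-10)
    assert rep.d_e_bnd == pytest.approx(o_rel[1] - o_can[1], rel=1e-10)
    assert rep.d_e_tor == pytest.approx(o_rel[2] - o_can[2], rel=1e-10)


def test_delta_tau_rejects_mismatched_structures(duplex_I,
                                                 duplex_I_topology,
                                                 ff_params):
    s = duplex_I.structure
    with pytest.raises(InputError):
        delta_tau(s.select(s.molecule_id == 0), s, duplex_I_topology,
                  ff_params)


class TestRMSD:
    def test_identical_is_zero(self, duplex_I):
        s = duplex_I.structure
        assert rmsd_all_atom(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_removed_by_superposition(self, duplex_I):
        s = duplex_I.structure
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = s.with_coord(s.coord @ R.T + 5.0)
        assert rmsd_all_atom(moved, s, superpose=True) < 1e-6
        assert rmsd_all_atom(moved, s, superpose=False) > 1.0

    def test_known_displacement_field_matches_formula(self):
        pert, canon, disp = make_perturbed_duplex(sigma=0.5, seed=3)
        got = rmsd_all_atom(pert, canon, superpose=False)
        # the no-superposition RMSD differs from the raw-displacement value
        # only through the mean shift removed by centering
        centered = disp - disp.mean(axis=0)
        assert got == pytest.approx(oracle_rmsd(centered), rel=1e-9)

    def test_superposed_never_exceeds_raw(self):
        pert, canon, _ = make_perturbed_duplex(sigma=0.8, seed=4)
        assert rmsd_all_atom(pert, canon, True) <= \
            rmsd_all_atom(pert, canon, False) + 1e-12


class TestInterchainDistance:
    def test_canonical_duplexes_in_reported_range(self):
        for seq in (SEQUENCE_I, SEQUENCE_II, SEQUENCE_III):
            s = build_canonical_duplex(seq).structure
            assert 19.0 <= interchain_distance(s) <= 20.3

    def test_translation_invariance(self, duplex_I):
        s = duplex_I.structure
        moved = s.with_coord(s.coord + np.array([100.0, -40.0, 7.0]))
        assert interchain_distance(moved) == pytest.approx(
            interchain_distance(s), abs=1e-9)

    def test_two_point_strands_give_their_separation(self):
        d = 13.7
        s = Structure(
            coord=np.array([[0.0, 0, 0], [d, 0, 0]]),
            element=np.array(["C", "C"]), name=np.array(["C", "C"]),
            charge=np.zeros(2), molecule_id=np.array([0, 1]),
            residue_id=np.array([0, 1]), residue_name=np.array(["X", "X"]))
        assert interchain_distance(s) == pytest.approx(d)

    def test_requires_two_strands(self, duplex_I):
        s = duplex_I.structure
        with pytest.raises(InputError):
            interchain_distance(s.select(s.molecule_id == 0))


def test_perturbation_raises_stretching_energy():
    """Random noise always stretches bonds away from the built geometry."""
    from dnapatite.forcefield import build_topology
    from dnapatite.forcefield import default_params

    pert, canon, _ = make_perturbed_duplex(sigma=0.4, seed=9)
    t = build_topology(canon)
    rep = delta_tau(pert, canon, t, default_params())
    assert rep.d_e_str > 0.0
    assert rep.delta_tau > 0.0
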