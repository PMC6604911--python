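"""Isomorphic phosphate plane, template growth and energy profiles."""

import numpy as np
import pytest

from dnapatite.crystal import build_supercell, build_unit_cell
from dnapatite.errors import InputError, PlaneNotFoundError
from dnapatite.growth import (energy_vs_thickness, find_phosphate_plane,
                              grow_apatite_from_plane, lattice_plane)
from dnapatite.structure import Structure


def planted_parallelogram(u=6.87, v=11.66, gamma=120.0):
    a = np.zeros(3)
    b = np.array([0.0, 0.0, u])
    g = np.deg2rad(gamma)
    c = np.array([v * np.sin(g), 0.0, v * np.cos(g)])
    pts = np.array([a, b, c, b + c])
    return Structure(
        coord=pts, element=np.array(["P"] * 4), name=np.array(["P"] * 4),
        charge=np.zeros(4), molecule_id=np.arange(4),
        residue_id=np.arange(4), residue_name=np.array(["PO4"] * 4))


def test_planted_parallelogram_found_exactly():
    s = planted_parallelogram()
    plane = find_phosphate_plane(s, (6.87, 11.66, 120.0))
    assert plane.u == pytest.approx(6.87, abs=1e-9)
    assert plane.v == pytest.approx(11.66, abs=1e-9)
    assert plane.gamma == pytest.approx(120.0, abs=1e-9)
    assert plane.residual == pytest.approx(0.0, abs=1e-9)


def test_needs_four_phosphorus():
    s = planted_parallelogram().select(np.array([0, 1, 2]))
    with pytest.raises(InputError):
        find_phosphate_plane(s, (6.87, 11.66, 120.0))


def test_not_found_error():
    s = planted_parallelogram(6.0, 9.0, 90.0)
    with pytest.raises(PlaneNotFoundError):
        find_phosphate_plane(s, (6.87, 11.66, 120.0), tolerance=0.1)


def test_hap_lattice_plane_u_is_c(hap_spec):
    plane = lattice_plane(hap_spec)
    assert plane.u == pytest.approx(6.87, abs=1e-3)
    assert plane.v == pytest.approx(11.66, abs=0.05)


def test_fap_lattice_plane_u_is_c(fap_spec):
    plane = lattice_plane(fap_spec)
    assert plane.u == pytest.approx(6.88, abs=1e-3)


def test_duplex_plane_geometry(duplex_I):
    plane = find_phosphate_plane(duplex_I.structure, (6.72, 13.75, 120.0),
                                 pair_tol=2.2)
    assert plane.u == pytest.approx(6.72, abs=0.3)
    assert 108.0 <= plane.gamma <= 141.0


def test_finder_matches_brute_force_oracle(hap_cell):
    """The hashed search returns the same best score as an exhaustive
    pair-of-pairs enumeration."""
    block = build_supercell(hap_cell, 2, 1, 2)
    target, ptol = (6.87, 11.66, 120.0), 0.9
    plane = find_phosphate_plane(block, target, tolerance=10.0,
                                 pair_tol=ptol)

    p_idx = np.where(block.element == "P")[0]
    xyz = block.coord[p_idx]
    diffs = xyz[None] - xyz[:, None]
    dist = np.linalg.norm(diffs, axis=2)
    ii, jj = np.where((dist >= 5.0) & (dist <= 16.0))
    best = None
    for a, b in zip(ii, jj):
        for c, d in zip(ii, jj):
            if len({a, b, c, d}) != 4 or (c, d) <= (a, b):
                continue
            if np.linalg.norm(diffs[c, d] - diffs[a, b]) > ptol:
                continue
            u, v = dist[a, b], dist[a, c]
            if not 5.0 <= v <= 16.0:
                continue
            cosg = np.dot(diffs[a, b], diffs[a, c]) / (u * v)
            g = np.degrees(np.arccos(np.clip(cosg, -1, 1)))
            score = np.sqrt((u - target[0]) ** 2 + (v - target[1]) ** 2
                            + (0.1 * (g - target[2])) ** 2)
            if best is None or score < best:
                best = score
    got = np.sqrt((plane.u - target[0]) ** 2 + (plane.v - target[1]) ** 2
                  + (0.1 * (plane.gamma - target[2])) ** 2)
    assert got == pytest.approx(best, abs=1e-9)


class TestGrowth:
    @pytest.fixture(scope="class")
    def dna_plane(self, duplex_I):
        return find_phosphate_plane(duplex_I.structure,
                                    (6.72, 13.75, 120.0), pair_tol=2.2)

    def test_fit_residual_is_kabsch_rmsd(self, dna_plane, hap_spec):
        grown = grow_apatite_from_plane(dna_plane, hap_spec, 8.0)
        assert grown.meta["fit_residual"] >= 0.0
        assert grown.meta["fit_residual"] < 3.0

    def test_growth_nesting(self, dna_plane, hap_spec):
        small = grow_apatite_from_plane(dna_plane, hap_spec, 8.0)
        large = grow_apatite_from_plane(dna_plane, hap_spec, 14.0)
        assert len(small) < len(large)
        # every small-shell atom appears in the large shell
        d = np.linalg.norm(
            small.coord[:, None, :] - large.coord[None, :, :], axis=2)
        assert d.min(axis=1).max() < 1e-9

    def test_minimal_radius_keeps_only_plane_groups(self, dna_plane,
                                                    hap_spec):
        tiny = grow_apatite_from_plane(dna_plane, hap_spec, 3.0)
        big = grow_apatite_from_plane(dna_plane, hap_spec, 12.0)
        assert 0 < len(tiny) < len(big)

    def test_whole_group_inclusion_keeps_integer_charge(self, dna_plane,
                                                        hap_spec):
        grown = grow_apatite_from_plane(dna_plane, hap_spec, 10.0)
        q = grown.net_charge
        assert q == pytest.approx(round(q), abs=1e-9)

    def test_profile_radii_must_increase(self, dna_plane, hap_spec,
                                         duplex_I):
        with pytest.raises(InputError):
            energy_vs_thickness(None, hap_spec, dna_plane, [8.0, 6.0])

    def test_profile_electrostatic_dominance_and_nesting(self, dna_plane,
                                                         hap_spec,
                                                         duplex_I):
        prof = energy_vs_thickness(duplex_I.structure, hap_spec, dna_plane,
                                   [6.0, 9.0, 12.0])
        assert np.all(np.diff(prof.n_atoms) > 0)
        # total energy dominated by the electrostatic contribution once
        # the crystal shell is present
        assert np.all(np.abs(prof.e_elec[1:]) > np.abs(prof.e_vdw[1:]))
        mineral = energy_vs_thickness(None, hap_spec, dna_plane,
                                      [6.0, 9.0, 12.0])
        assert np.all(np.abs(mineral.e_elec) > np.abs(mineral.e_vdw))

    def test_profile_energy_matches_oracle_on_smallest_shell(self, dna_plane,
                                                             hap_spec,
                                                             ff_params):
        from dnapatite.forcefield import build_topology
        from dnapatite.synthetic import (oracle_bonded_energy,
                                         oracle_nonbonded_energy)

        prof = energy_vs_thickness(None, hap_spec, dna_plane, [5.0])
        grown = grow_apatite_from_plane(dna_plane, hap_spec, 5.0)
        t = build_topology(grown)
        ob = oracle_bonded_energy(grown, t, ff_params)
        on = oracle_nonbonded_energy(grown, t, ff_params)
        assert prof.e_total[0] == pytest.approx(sum(ob) + sum(on),
                                                rel=1e-10)
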