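"""Canonical B-DNA construction, counterions and pore embedding."""

import numpy as np
import pytest

from dnapatite.dna import (SEQUENCE_I, SEQUENCE_II, SEQUENCE_III,
                           HelixParams, NucleotideSequence,
                           build_canonical_duplex, extract_single_strand,
                           phosphorus_indices, place_counterions)
from dnapatite.errors import InputError


def test_sequence_parsing_and_complement():
    seq = NucleotideSequence.from_string("CGCGAATTC*GCG")
    assert len(seq) == 12
    assert seq.residues[8] == "C*"
    assert str(seq.complement()) == "CGCGAATTCGCG"
    with pytest.raises(InputError):
        NucleotideSequence.from_string("CGXG")


def test_helix_params_invariants():
    assert HelixParams().bp_per_turn == pytest.approx(10.0)
    with pytest.raises(InputError):
        HelixParams(rise=-1.0)


def test_duplex_composition(duplex_I):
    s = duplex_I.structure
    assert len(np.unique(s.residue_id)) == 24
    assert len(np.unique(s.molecule_id)) == 2
    assert len(phosphorus_indices(s)) == 22           # 2n-2 free-5'-OH
    assert s.net_charge == pytest.approx(-22.0)


def test_mean_rise_is_034_nm(duplex_I):
    s = duplex_I.structure
    # per-pair z of the C1' midpoints advances by the rise
    z = []
    for pair in range(12):
        rid_a = 12 - pair            # strand A residue at this pair index
        rid_b = duplex_I.pairing[rid_a]
        c1a = s.coord[(s.residue_id == rid_a) & (s.name == "C1'")][0]
        c1b = s.coord[(s.residue_id == rid_b) & (s.name == "C1'")][0]
        z.append(0.5 * (c1a[2] + c1b[2]))
    rises = np.diff(sorted(z))
    assert np.mean(rises) == pytest.approx(3.40, abs=1e-6)


def test_twist_gives_ten_bp_per_turn(duplex_I):
    s = duplex_I.structure
    ang = []
    for rid in range(2, 13):
        a = s.coord[(s.residue_id == rid) & (s.name == "C1'")][0]
        b = s.coord[(s.residue_id == rid - 1) & (s.name == "C1'")][0]
        da = np.degrees(np.arctan2(a[1], a[0]) - np.arctan2(b[1], b[0]))
        ang.append((da + 180.0) % 360.0 - 180.0)
    twist = abs(np.mean(ang))
    assert 360.0 / twist == pytest.approx(10.0, abs=0.01)


def test_methylated_cytosine_has_c5_methyl():
    s = build_canonical_duplex(SEQUENCE_III).structure
    mc = s.select(s.residue_name == "5MC")
    assert len(np.unique(mc.residue_id)) == 1
    assert "C5A" in mc.name


@pytest.mark.parametrize("seq", [SEQUENCE_I, SEQUENCE_II, SEQUENCE_III])
def test_watson_crick_donor_acceptor_distances(seq):
    s = build_canonical_duplex(seq).structure
    pairing = s.meta["pairing"]
    n = len(seq)
    for rid in range(1, n + 1):
        rn = s.residue_name[s.residue_id == rid][0]
        pr = pairing[rid]

        def atom(r, name):
            return s.coord[(s.residue_id == r) & (s.name == name)][0]

        if rn in ("DA", "DG"):
            d = np.linalg.norm(atom(rid, "N1") - atom(pr, "N3"))
        else:
            d = np.linalg.norm(atom(rid, "N3") - atom(pr, "N1"))
        assert 2.7 <= d <= 3.1


def test_rebuild_is_bit_reproducible(duplex_I):
    again = build_canonical_duplex(SEQUENCE_I)
    assert np.array_equal(again.structure.coord, duplex_I.structure.coord)


def test_backbone_connectivity(duplex_I):
    s = duplex_I.structure
    for lo, hi in ((1, 12), (13, 24)):
        for rid in range(lo, hi):
            o3 = s.coord[(s.residue_id == rid) & (s.name == "O3'")][0]
            p = s.coord[(s.residue_id == rid + 1) & (s.name == "P")][0]
            assert 1.55 < np.linalg.norm(o3 - p) < 1.70


def test_extract_single_strand_partition(duplex_I):
    a = extract_single_strand(duplex_I, 0)
    b = extract_single_strand(duplex_I, 1)
    s = duplex_I.structure
    assert len(a) + len(b) == len(s)
    assert len(np.unique(a.residue_id)) == 12
    assert np.allclose(a.coord, s.coord[s.molecule_id == 0])
    with pytest.raises(InputError):
        extract_single_strand(duplex_I, 7)


def test_counterion_counts_and_charge(duplex_I):
    dressed = place_counterions(duplex_I.structure, "minor_groove",
                                seed=0, optimize=False)
    assert int((dressed.element == "Ca").sum()) == 11
    assert dressed.net_charge == pytest.approx(0.0)


def test_single_strand_counterions_report_residual(duplex_I):
    ss = extract_single_strand(duplex_I, 0)
    dressed = place_counterions(ss, "random_backbone", seed=3,
                                optimize=False)
    assert int((dressed.element == "Ca").sum()) == 6   # ceil(11/2)
    assert dressed.net_charge == pytest.approx(1.0)
    assert dressed.meta["ion_log"]["residual_charge"] == pytest.approx(1.0)


def test_counterion_determinism(duplex_I):
    ss = extract_single_strand(duplex_I, 0)
    a = place_counterions(ss, "random_backbone", seed=5, optimize=False)
    b = place_counterions(ss, "random_backbone", seed=5, optimize=False)
    assert np.array_equal(a.coord, b.coord)


def test_duplex_fits_pore_depth(duplex_I):
    s = duplex_I.structure
    extent = s.coord[:, 2].max() - s.coord[:, 2].min()
    assert extent <= 7 * 6.87                 # 12 bp x 3.4 = 40.8 < 48.1
    assert extent == pytest.approx(12 * 3.4, abs=4.0)


def test_embed_orientation_seeds(duplex_I, hap_carved):
    from dnapatite.dna import embed_in_pore

    carved, _ = hap_carved
    s = duplex_I.structure
    systems = [embed_in_pore(carved, s, orientation_seed=k)
               for k in (0, 1)]
    assert len(systems[0]) == len(systems[1])
    assert systems[0].meta["orientation_deg"] != \
        systems[1].meta["orientation_deg"]
    # clash contract: mineral never closer than the threshold to the DNA
    for sys_ in systems:
        dna_mask = np.isin(sys_.residue_name,
                           ["DA", "DC", "DG", "DT", "5MC"])
        from scipy.spatial import cKDTree
        d, _unused = cKDTree(sys_.coord[dna_mask]).query(
            sys_.coord[~dna_mask], k=1)
        assert d.min() >= 2.0
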