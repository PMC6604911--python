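"""Synthetic fixtures with stored ground truths.

Every generator is reproducible bit-for-bit under its seed and returns the
planted ground truth alongside the fixture, so tests never re-derive the
expected value from the code under test.  The oracles in this module are
deliberately written as plain brute-force loops, independent of the
vectorized production implementations they are used to check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Structure, Trajectory, concat

# --------------------------------------------------------------------------
# trajectories with known g(r)


def make_ideal_gas(n: int, box, n_frames: int, seed: int = 0) -> Trajectory:
    """Uniform independent positions each frame; ground truth g(r) = 1."""
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n_frames, n, 3))
    s = Structure(
        coord=coords[0],
        element=np.array(["C"] * n), name=np.array(["C"] * n),
        charge=np.zeros(n), molecule_id=np.arange(n),
        residue_id=np.arange(n), residue_name=np.array(["GAS"] * n))
    return Trajectory(np.arange(1, n_frames + 1, dtype=float), coords, box,
                      structure=s)


def make_lattice_trajectory(n_side: int, spacing: float,
                            n_frames: int = 1) -> Trajectory:
    """Simple-cubic lattice; first neighbor at ``spacing``, next at √2 s."""
    pts = np.array([[i, j, k] for i in range(n_side)
                    for j in range(n_side) for k in range(n_side)],
                   dtype=float) * spacing
    box = np.full(3, n_side * spacing)
    n = len(pts)
    coords = np.repeat(pts[None, :, :], n_frames, axis=0)
    s = Structure(
        coord=pts, element=np.array(["C"] * n), name=np.array(["C"] * n),
        charge=np.zeros(n), molecule_id=np.arange(n),
        residue_id=np.arange(n), residue_name=np.array(["LAT"] * n))
    return Trajectory(np.arange(1, n_frames + 1, dtype=float), coords, box,
                      structure=s)


def make_planted_rdf(centers, heights, widths, r_max=10.0, bin_width=0.05):
    """An RDF-like curve that is a sum of Gaussians on a unit baseline."""
    from .trajectory import RDFCurve

    r = np.arange(bin_width / 2, r_max, bin_width)
    g = np.ones_like(r)
    for c, h, w in zip(centers, heights, widths):
        g += h * np.exp(-0.5 * ((r - c) / w) ** 2)
    return RDFCurve(r, g, "planted", "planted", 1, bin_width)


# --------------------------------------------------------------------------
# perturbed duplexes with stored displacement statistics


def make_perturbed_duplex(seq="CGCGAATTCGCG", sigma: float = 0.5,
                          seed: int = 0):
    """Canonical duplex plus i.i.d. Gaussian coordinate noise.

    Returns ``(perturbed, canonical, displacements)`` with the exact
    per-atom displacement vectors stored as ground truth.
    """
    from .dna import build_canonical_duplex

    canonical = build_canonical_duplex(seq).structure
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma, size=canonical.coord.shape) if sigma > 0 \
        else np.zeros_like(canonical.coord)
    perturbed = canonical.with_coord(canonical.coord + disp)
    return perturbed, canonical, disp


# --------------------------------------------------------------------------
# toy organic-inorganic complexes for the energy oracle


def make_toy_complex(kind: str = "attractive", seed: int = 0):
    """Small apatite fragment posed against a DNA fragment.

    The mineral piece is the whole-group neighborhood of an anchor atom in
    the hydroxyapatite cell; the organic piece is a GC single strand whose
    backbone phosphate faces the anchor.  ``attractive`` anchors on Ca2+
    (negative interaction energy with the phosphate), ``repulsive`` on a
    phosphate oxygen (anion-anion contact, positive).  Returns
    ``(complex, fragment_mask, delta_e_oracle)``; sizes fall in the
    half-to-one-hundred atom range of small model complexes.
    """
    from .crystal import CrystalSpec, build_unit_cell
    from .dna import build_canonical_duplex

    rng = np.random.default_rng(seed)
    cell = build_unit_cell(CrystalSpec.packaged("hap"))
    duplex = build_canonical_duplex("GC").structure
    strand = duplex.select(duplex.molecule_id == 0)
    strand.molecule_id[:] = 0

    if kind == "attractive":
        anchor_mask = cell.element == "Ca"
        gap = 2.5
    elif kind == "repulsive":
        anchor_mask = (cell.element == "O") & (cell.residue_name == "PO4")
        gap = 2.3
    else:
        raise ValueError(f"unknown kind {kind!r}")
    anchor_idx = np.where(anchor_mask)[0][
        int(rng.integers(0, int(anchor_mask.sum())))]
    anchor = cell.coord[anchor_idx]

    # mineral fragment: whole groups near the anchor
    gid = cell.group_id
    masses = cell.masses
    keep_groups = []
    for g in np.unique(gid):
        idx = np.where(gid == g)[0]
        com = (cell.coord[idx] * masses[idx, None]).sum(axis=0) \
            / masses[idx].sum()
        if np.linalg.norm(com - anchor) < 4.6:
            keep_groups.append(g)
    mineral = cell.select(np.isin(gid, keep_groups))
    mineral.molecule_id[:] = 100

    # pose the strand with its phosphate toward the anchor, body outward
    p_mask = np.isin(strand.name, ["P", "OP1", "OP2"])
    pg = strand.coord[p_mask].mean(axis=0)
    body = strand.center_of_mass()
    out_dir = anchor - mineral.center_of_mass()
    out_dir /= np.linalg.norm(out_dir)
    v = body - pg
    v /= np.linalg.norm(v)
    # rotation taking the phosphate->body axis onto the outward direction
    axis = np.cross(v, out_dir)
    sa = np.linalg.norm(axis)
    ca = float(np.dot(v, out_dir))
    if sa > 1e-9:
        axis /= sa
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + sa * K + (1 - ca) * (K @ K)
    else:
        R = np.eye(3) if ca > 0 else -np.eye(3)
    posed = (strand.coord - pg) @ R.T
    # small random spin about the approach axis
    spin = rng.uniform(0, 2 * np.pi)
    c, s_ = np.cos(spin), np.sin(spin)
    K = np.array([[0, -out_dir[2], out_dir[1]], [out_dir[2], 0, -out_dir[0]],
                  [-out_dir[1], out_dir[0], 0]])
    Rs = np.eye(3) + s_ * K + (1 - c) * (K @ K)
    posed = posed @ Rs.T + anchor + out_dir * gap
    # back the strand off until no interpenetration below 2.1 Å
    for _ in range(40):
        d = np.linalg.norm(posed[:, None, :] - mineral.coord[None, :, :],
                           axis=2)
        if d.min() >= 2.1:
            break
        posed = posed + out_dir * 0.15
    frag = strand.with_coord(posed)
    comp = concat([mineral, frag])
    mask = np.zeros(len(comp), dtype=bool)
    mask[:len(mineral)] = True
    de = oracle_interaction_energy(comp, mask)
    return comp, mask, de


# --------------------------------------------------------------------------
# miniature stoichiometric solution boxes


def make_mini_box(n_units: float = 1, seed: int = 0, box=None):
    """Stoichiometric box at ~1.00 g/cm³ water density; truth attached."""
    from .nucleation import build_solution_box

    if box is None:
        # edge sized so the ion concentration matches the full-scale system
        edge = (909114.0 / 94.5 * n_units) ** (1.0 / 3.0)
        box = [edge, edge, edge]
    sb = build_solution_box(n_units, box, seed=seed)
    truth = {"n_ca": int(round(10 * n_units)),
             "n_po4": int(round(6 * n_units)),
             "n_oh": int(round(2 * n_units)),
             "ion_charge": 0.0}
    return sb, truth


# --------------------------------------------------------------------------
# independent brute-force oracles


def oracle_bonded_energy(s: Structure, t, p) -> tuple:
    """Term-by-term bonded energies via plain Python loops."""
    from .forcefield import angle_equilibrium, torsion_class

    x = s.coord
    e_str = 0.0
    for i, j in t.bonds:
        k, b0 = p.bond_param(s.element[i], s.element[j])
        b = math.dist(x[i], x[j])
        e_str += k * (b - b0) ** 2
    e_bnd = 0.0
    th0s = angle_equilibrium(t, s, p)
    for idx in range(len(t.angles)):
        i, j, k = t.angles[idx]
        u = x[i] - x[j]
        v = x[k] - x[j]
        cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        theta = math.acos(max(-1.0, min(1.0, cosv)))
        e_bnd += p.angle_k * (theta - math.radians(th0s[idx])) ** 2
    e_tor = 0.0
    classes = torsion_class(t, s)
    for idx in range(len(t.torsions)):
        i, j, k, m = t.torsions[idx]
        b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[m] - x[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = math.atan2(np.dot(m1, n2), np.dot(n1, n2))
        V, n, gam = p.torsions[classes[idx]]
        e_tor += 0.5 * V * (1.0 + math.cos(n * phi - math.radians(gam)))
    return e_str, e_bnd, e_tor


def oracle_nonbonded_energy(s: Structure, t, p) -> tuple:
    """Exact all-pairs LJ + Coulomb with exclusions and 1-4 scaling."""
    x = s.coord
    n = len(s)
    excl = t.excluded
    p14 = set(map(tuple, t.pairs14)) if len(t.pairs14) else set()
    e_vdw = e_elec = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in excl:
                continue
            se = p.scale14_elec if key in p14 else 1.0
            sl = p.scale14_lj if key in p14 else 1.0
            r = math.dist(x[i], x[j])
            rm = p.lj_param(t.types[i])[0] + p.lj_param(t.types[j])[0]
            ep = math.sqrt(p.lj_param(t.types[i])[1]
                           * p.lj_param(t.types[j])[1])
            s6 = (rm / r) ** 6
            e_vdw += ep * (s6 * s6 - 2.0 * s6) / sl
            e_elec += 332.0636 * s.charge[i] * s.charge[j] / r / se
    return e_vdw, e_elec


def oracle_interaction_energy(comp: Structure, mask) -> float:
    """ΔE via the oracle energies of complex and isolated fragments."""
    from .forcefield import build_topology, default_params

    p = default_params()

    def total(sub):
        t = build_topology(sub)
        eb = oracle_bonded_energy(sub, t, p)
        en = oracle_nonbonded_energy(sub, t, p)
        return sum(eb) + sum(en)

    mask = np.asarray(mask, dtype=bool)
    return total(comp) - total(comp.select(mask)) - total(comp.select(~mask))


def oracle_rmsd(disp: np.ndarray) -> float:
    """Direct formula on stored displacements (no superposition)."""
    return float(np.sqrt(np.mean(np.sum(disp ** 2, axis=1))))


def oracle_rdf_ideal_gas_mean(n: int, box, n_frames: int, seed: int,
                              r_max: float, bin_width: float) -> float:
    """Mean g(r) beyond 2 Å for the seeded ideal-gas fixture, by direct
    pair counting (loops)."""
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n_frames, n, 3))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for f in range(n_frames):
        for i in range(n):
            for j in range(i + 1, n):
                d = coords[f, i] - coords[f, j]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d)
                if r < r_max:
                    hist[int(r / bin_width)] += 2
    vol = np.prod(box)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (n_frames * n * (n / vol) * shell)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return float(np.mean(g[centers > 2.0]))
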