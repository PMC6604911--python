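"""Template-directed apatite growth from the shared phosphate plane.

B-DNA and apatite share a near-isomorphic plane of four phosphate groups:
in the crystal it is spanned by u = c (6.87/6.88 Å for HAp/FAp) and
v = 11.66/11.62 Å with γ = 120°; on the double helix the best-matching
parallelogram of backbone phosphorus atoms averages u ≈ 6.7 Å and
v ≈ 13.8 Å with a broad γ.  The plane finder enumerates near-parallelogram
4-tuples of phosphorus atoms and scores them against a target; the grower
rigid-fits the apatite lattice onto a found plane and emits whole charged
groups within a growing cutoff radius, yielding energy-vs-thickness
profiles for the biomineral (crystal + DNA) and the bare mineral.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .crystal import CrystalSpec, build_supercell, build_unit_cell
from .energy import total_energy
from .errors import FitError, InputError, PlaneNotFoundError
from .forcefield import build_topology, default_params
from .strain import kabsch_rotation
from .structure import Structure, concat

_ANGLE_WEIGHT = 0.1      # Å per degree when scoring (u, v, gamma) deviations


@dataclass
class IsomorphicPlane:
    points: np.ndarray          # (4, 3) phosphorus positions: A, B, C, D
    u: float                    # |B - A| Å
    v: float                    # |C - A| Å
    gamma: float                # angle(B-A, C-A) degrees
    residual: float             # parallelogram closure deviation Å
    atom_indices: tuple = ()

    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class GrowthProfile:
    radii: np.ndarray
    e_total: np.ndarray         # kcal/mol
    e_elec: np.ndarray
    e_vdw: np.ndarray
    n_atoms: np.ndarray
    label: str = "mineral"


def _phosphorus(s: Structure) -> np.ndarray:
    return np.where(s.element == "P")[0]


def _group_com_radius(s: Structure, center: np.ndarray) -> np.ndarray:
    """Per-atom distance of the atom's group center of mass from center."""
    _, inv = np.unique(s.group_id, return_inverse=True)
    m = s.masses
    wsum = np.bincount(inv, weights=m)
    coms = np.column_stack(
        [np.bincount(inv, weights=m * s.coord[:, d]) for d in range(3)]
    ) / wsum[:, None]
    return np.linalg.norm(coms - center, axis=1)[inv]


def find_phosphate_plane(s: Structure, target: tuple = (6.87, 11.66, 120.0),
                         tolerance: float = 3.0,
                         side_range: tuple = (5.0, 16.0),
                         pair_tol: float = 0.9) -> IsomorphicPlane:
    """Best near-parallelogram of four phosphorus atoms matching a target.

    Candidate sides have lengths within ``side_range``; two sides form a
    parallelogram when their displacement vectors agree within
    ``pair_tol`` Å.  Candidates are scored by least-squares deviation of
    (u, v, gamma) from ``target`` (degrees weighted at 0.1 Å/deg); ties
    break lexicographically on atom indices.  The search is exhaustive
    over all 4-tuples whose closure deviation is below ``pair_tol``.
    """
    p_idx = _phosphorus(s)
    if len(p_idx) < 4:
        raise InputError("need at least 4 phosphorus atoms")
    xyz = s.coord[p_idx]
    n = len(xyz)
    lo, hi = side_range
    u_t, v_t, g_t = target

    # ordered pairs with side length in range, hashed by quantized vector
    diffs = xyz[None, :, :] - xyz[:, None, :]
    dist = np.linalg.norm(diffs, axis=2)
    ii, jj = np.where((dist >= lo) & (dist <= hi))
    q = pair_tol
    buckets: dict = {}
    for a, b in zip(ii, jj):
        key = tuple(np.floor(diffs[a, b] / q).astype(int))
        buckets.setdefault(key, []).append((a, b))

    best = None
    neighbor = list(itertools.product((-1, 0, 1), repeat=3))
    for (a, b) in zip(ii, jj):
        vec = diffs[a, b]
        key = tuple(np.floor(vec / q).astype(int))
        for off in neighbor:
            for (c, d) in buckets.get((key[0] + off[0], key[1] + off[1],
                                       key[2] + off[2]), ()):
                if len({a, b, c, d}) != 4 or (c, d) <= (a, b):
                    continue
                closure = np.linalg.norm(diffs[c, d] - vec)
                if closure > pair_tol:
                    continue
                u = dist[a, b]
                v = dist[a, c]
                if not (lo <= v <= hi):
                    continue
                cosg = np.dot(vec, diffs[a, c]) / (u * v)
                gamma = float(np.degrees(np.arccos(np.clip(cosg, -1, 1))))
                score = np.sqrt((u - u_t) ** 2 + (v - v_t) ** 2
                                + (_ANGLE_WEIGHT * (gamma - g_t)) ** 2)
                cand = (score, (int(p_idx[a]), int(p_idx[b]),
                                int(p_idx[c]), int(p_idx[d])),
                        u, v, gamma, closure)
                if best is None or cand[:2] < best[:2]:
                    best = cand
    if best is None or best[0] > tolerance:
        raise PlaneNotFoundError(
            f"no phosphate parallelogram within tolerance {tolerance}")
    score, (a, b, c, d), u, v, gamma, closure = best
    pts = s.coord[[a, b, c, d]]
    return IsomorphicPlane(pts, float(u), float(v), gamma,
                           float(closure / 2.0), (a, b, c, d))


def lattice_plane(spec: CrystalSpec, target: tuple = None) -> IsomorphicPlane:
    """The isomorphic plane of the ideal crystal itself (u = c)."""
    if target is None:
        target = (spec.lattice.c, 11.66, 120.0)
    cell = build_unit_cell(spec)
    # u runs along c and v along the a-c diagonal, so the parallelogram
    # spans three cells in c
    block = build_supercell(cell, 2, 2, 3)
    return find_phosphate_plane(block, target, tolerance=3.0)


def grow_apatite_from_plane(plane: IsomorphicPlane, spec: CrystalSpec,
                            max_radius: float,
                            fit_tolerance: float = 3.0,
                            guest: Structure | None = None,
                            clash_threshold: float = 2.0) -> Structure:
    """Grow the apatite crystal anchored on a phosphate plane.

    Four phosphorus sites of the ideal lattice forming the plane geometry
    are rigid-fit (least squares) onto the plane's phosphorus atoms; the
    whole crystal follows, and every intact charged group whose center of
    mass lies within ``max_radius`` of the plane center is emitted.
    """
    # the rigid fit is solved on a small block; the transform then carries
    # a block large enough to cover the requested sphere
    cell = build_unit_cell(spec)
    ref = find_phosphate_plane(build_supercell(cell, 2, 2, 3),
                               (plane.u, plane.v, plane.gamma),
                               tolerance=10.0)
    src = build_supercell(cell, 2, 2, 3).coord[list(ref.atom_indices)]
    cells = [max(3, int(np.ceil(2 * max_radius / g)) + 2)
             for g in (spec.lattice.a, spec.lattice.b, spec.lattice.c)]
    block = build_supercell(cell, *cells)
    # integer-lattice translation centering the block on the source plane,
    # so the grown sphere never runs off the block edge
    mat = cell.lattice
    f_center = np.linalg.solve(mat.T, src.mean(axis=0))
    offset = np.floor(f_center).astype(int) - np.array(cells) // 2
    block = block.with_coord(block.coord + offset @ mat)
    dst = plane.points
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    R = kabsch_rotation(src - sc, dst - dc)
    fitted = (src - sc) @ R.T + dc
    residual = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    if residual > fit_tolerance:
        raise FitError(f"lattice fit residual {residual:.2f} Å "
                       f"exceeds {fit_tolerance} Å")
    moved = block.with_coord((block.coord - sc) @ R.T + dc)

    center = plane.center()
    keep = _group_com_radius(moved, center) <= max_radius
    if guest is not None and len(guest):
        # the DNA occupies the template region: its own phosphates stand in
        # for the coincident lattice sites, and any crystal group touching
        # the guest is left out as a whole
        from scipy.spatial import cKDTree

        d, _ = cKDTree(guest.coord).query(moved.coord, k=1)
        clash = d < clash_threshold
        bad_groups = np.unique(moved.group_id[clash])
        keep &= ~np.isin(moved.group_id, bad_groups)
    out = moved.select(keep)
    out.meta["fit_residual"] = residual
    out.meta["plane_center"] = center
    out.meta["net_charge"] = out.net_charge
    return out


def energy_vs_thickness(dna: Structure | None, spec: CrystalSpec,
                        plane: IsomorphicPlane, radii,
                        params=None) -> GrowthProfile:
    """Total energy of the (bio)mineral as the crystal thickness grows.

    For each cutoff radius the crystal is grown from the plane and the
    exact (no-cutoff) total energy of crystal + DNA (when present) is
    evaluated, interactions included.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) == 0 or np.any(np.diff(radii) <= 0):
        raise InputError("radii must be strictly increasing")
    p = params or default_params()
    e_tot, e_el, e_vd, n_at = [], [], [], []
    grown_full = grow_apatite_from_plane(plane, spec, float(radii[-1]),
                                         guest=dna)
    atom_r = _group_com_radius(grown_full, plane.center())
    for r in radii:
        crystal = grown_full.select(atom_r <= r)
        system = crystal if dna is None else concat(
            [crystal, dna], renumber_molecules=True)
        t = build_topology(system)
        e = total_energy(system, t, p)
        e_tot.append(e.total)
        e_el.append(e.e_elec)
        e_vd.append(e.e_vdw)
        n_at.append(len(system))
    return GrowthProfile(radii, np.array(e_tot), np.array(e_el),
                         np.array(e_vd), np.array(n_at),
                         label="mineral" if dna is None else "biomineral")
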