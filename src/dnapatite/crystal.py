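"""Apatite crystal building: unit cells, super-cells and DNA-sized nanopores.

Hydroxyapatite (HAp, Ca10(PO4)6(OH)2) and fluoroapatite (FAp, Ca10(PO4)6F2)
are hexagonal P6_3/m minerals.  A :class:`CrystalSpec` holds the lattice
constants, the symmetrically independent sites and the twelve space-group
operations; :func:`build_unit_cell` expands the asymmetric unit, resolves the
disordered hydroxyl column (50% occupancy) deterministically and returns a
charge-neutral 44-atom (HAp) or 42-atom (FAp) cell.  Super-cells are exact
lattice replications; :func:`carve_pore` removes whole unit-cell columns to
open a rhombic channel for a DNA guest, translating clashing charged groups
intact to vacant border sites so that electroneutrality is never broken.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .errors import CarvingError, ConfigurationError, InputError, OccupancyError
from .structure import Structure

_MERGE_TOL = 1e-3       # fractional-coordinate merge tolerance
_H_BOND_MAX = 1.25      # Å, O-H bond perception
_PO_BOND_MAX = 1.75     # Å, P-O bond perception


@dataclass(frozen=True)
class LatticeParams:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 120.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ConfigurationError("lattice constants must be positive")

    def matrix(self) -> np.ndarray:
        """Cell vectors as rows (Å).  Supports the hexagonal setting used here."""
        ga = np.deg2rad(self.gamma)
        return np.array([
            [self.a, 0.0, 0.0],
            [self.b * np.cos(ga), self.b * np.sin(ga), 0.0],
            [0.0, 0.0, self.c],
        ])


@dataclass(frozen=True)
class Site:
    label: str
    element: str
    frac: tuple
    occupancy: float = 1.0
    charge: float = 0.0


@dataclass
class CrystalSpec:
    name: str
    lattice: LatticeParams
    sites: list[Site]
    ops: list[tuple]          # (rot 3x3, trans 3) in fractional space

    @classmethod
    def from_file(cls, path) -> "CrystalSpec":
        with open(path) as fh:
            return cls._from_dict(json.load(fh))

    @classmethod
    def packaged(cls, mineral: str) -> "CrystalSpec":
        """Load the shipped 'hap' or 'fap' specification."""
        name = mineral.lower()
        if name not in ("hap", "fap"):
            raise InputError(f"unknown mineral {mineral!r}; expected 'hap' or 'fap'")
        ref = resources.files("dnapatite.data").joinpath(f"{name}.json")
        return cls._from_dict(json.loads(ref.read_text()))

    @classmethod
    def _from_dict(cls, d: dict) -> "CrystalSpec":
        lat = LatticeParams(**d["lattice"])
        sites = [Site(s["label"], s["element"], tuple(s["frac"]),
                      s.get("occupancy", 1.0), s.get("charge", 0.0))
                 for s in d["sites"]]
        labels = [s.label for s in sites]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("site labels must be unique")
        ops = [(np.array(o["rot"], dtype=float), np.array(o["trans"], dtype=float))
               for o in d["ops"]]
        return cls(d["name"], lat, sites, ops)


@dataclass
class PoreSpec:
    """Hole extent in unit cells plus the record of border translations."""
    extent: tuple = (2, 2, 7)
    center: tuple | None = None    # starting cell indices; None = centered
    clash_threshold: float = 2.0   # Å
    translation_log: list = field(default_factory=list)

    def hole_ranges(self, super_extent: tuple) -> list[range]:
        out = []
        for h, n, c in zip(self.extent, super_extent,
                           self.center or (None, None, None)):
            if h > n:
                raise InputError("hole extent exceeds super-cell extent")
            lo = (n - h) // 2 if c is None else c
            out.append(range(lo, lo + h))
        return out


def _wrap_frac(x: np.ndarray) -> np.ndarray:
    w = x - np.floor(x)
    w[w > 1.0 - 1e-9] = 0.0
    return w


def check_closure(ops) -> None:
    """Verify the op set is closed under composition modulo lattice translations."""
    def key(rot, trans):
        return (tuple(np.round(rot.ravel()).astype(int)),
                tuple(np.round(np.mod(trans, 1.0) * 1e6).astype(int)))

    table = {key(r, t) for r, t in ops}
    for r1, t1 in ops:
        for r2, t2 in ops:
            rc, tc = r1 @ r2, r1 @ t2 + t1
            if key(rc, tc) not in table:
                raise ConfigurationError("symmetry operations do not form a closed group")


def _expand_site(site: Site, ops) -> np.ndarray:
    """Orbit of a site under the ops, wrapped to [0,1), duplicates merged."""
    images = []
    for rot, trans in ops:
        f = _wrap_frac(rot @ np.asarray(site.frac) + trans)
        if not any(np.all(np.abs(_min_image_frac(f - g)) < _MERGE_TOL) for g in images):
            images.append(f)
    return np.array(images)


def _min_image_frac(d: np.ndarray) -> np.ndarray:
    return d - np.round(d)


def _resolve_occupancy(orbit: np.ndarray, occupancy: float) -> np.ndarray:
    """Deterministically keep round(occ * multiplicity) members of an orbit.

    The kept subset is spread over the z-sorted orbit; for the 4e hydroxyl
    column (keep 2 of 4) this selects the lowest and the highest z image,
    i.e. one O-H pointing down and one pointing up, cancelling the cell's
    hydroxyl dipole.
    """
    n = len(orbit)
    k = occupancy * n
    if abs(k - round(k)) > 1e-6:
        raise OccupancyError(
            f"occupancy {occupancy} on a {n}-fold orbit does not give an integer count")
    k = int(round(k))
    order = np.lexsort((orbit[:, 0], orbit[:, 1], orbit[:, 2]))
    if k == n:
        return orbit
    if k == 2 and n == 4:
        keep = [order[0], order[-1]]
    else:
        keep = [order[int(round(j * n / k))] for j in range(k)]
    return orbit[sorted(keep)]


def build_unit_cell(spec: CrystalSpec) -> Structure:
    """Expand the asymmetric unit into one Cartesian unit cell.

    Atoms carry site labels, partial charges and a ``group_id`` tying each
    PO4 tetrahedron, hydroxyl ion or single ion into an intact charged group.
    Group members are unwrapped across the cell boundary so every tetrahedron
    is geometrically contiguous.
    """
    check_closure(spec.ops)
    frac, element, name, charge = [], [], [], []
    deferred_h = []
    for site in spec.sites:
        orbit = _expand_site(site, spec.ops)
        if site.occupancy < 1.0 and site.element == "H":
            deferred_h.append((site, orbit))
            continue
        kept = (_resolve_occupancy(orbit, site.occupancy)
                if site.occupancy < 1.0 else orbit)
        for f in kept:
            frac.append(f)
            element.append(site.element)
            name.append(site.label)
            charge.append(site.charge)
    frac = np.array(frac)
    # Partial-occupancy H sites follow their bonded heavy atom.
    for site, orbit in deferred_h:
        heavy = frac[np.array(element) == "O"]
        mat = spec.lattice.matrix()
        for f in orbit:
            d = _min_image_frac(heavy - f) @ mat
            if len(d) and np.min(np.linalg.norm(d, axis=1)) < _H_BOND_MAX:
                frac = np.vstack([frac, f])
                element.append(site.element)
                name.append(site.label)
                charge.append(site.charge)
    mat = spec.lattice.matrix()
    element = np.array(element)
    n = len(frac)

    # Group perception in fractional space with periodic minimum image.
    group = -np.ones(n, dtype=int)
    next_group = 0
    order_p = np.where(element == "P")[0]
    for p in order_p:
        group[p] = next_group
        d = np.linalg.norm(_min_image_frac(frac - frac[p]) @ mat, axis=1)
        members = np.where((element == "O") & (d < _PO_BOND_MAX))[0]
        group[members] = next_group
        # unwrap O next to its P
        frac[members] = frac[p] + _min_image_frac(frac[members] - frac[p])
        next_group += 1
    for o in np.where((element == "O") & (group < 0))[0]:
        group[o] = next_group
        d = np.linalg.norm(_min_image_frac(frac - frac[o]) @ mat, axis=1)
        members = np.where((element == "H") & (d < _H_BOND_MAX))[0]
        group[members] = next_group
        frac[members] = frac[o] + _min_image_frac(frac[members] - frac[o])
        next_group += 1
    for i in np.where(group < 0)[0]:
        group[i] = next_group
        next_group += 1

    resname = {"Ca": "CA", "P": "PO4", "F": "F"}
    rn = np.array([resname.get(e, "") for e in element], dtype="U6")
    # O/H inherit the residue name of their group
    for g in range(next_group):
        idx = np.where(group == g)[0]
        if "P" in element[idx]:
            rn[idx] = "PO4"
        elif set(element[idx]) <= {"O", "H"}:
            rn[idx] = "OH"

    return Structure(
        coord=frac @ mat,
        element=element,
        name=np.array(name),
        charge=np.array(charge),
        molecule_id=np.zeros(n, dtype=int),
        residue_id=group.copy(),
        residue_name=rn,
        group_id=group,
        cell_index=np.zeros((n, 3), dtype=int),
        lattice=mat,
        meta={"mineral": spec.name, "lattice_params": spec.lattice,
              "super_extent": (1, 1, 1)},
    )


def build_supercell(cell: Structure, na: int, nb: int, nc: int) -> Structure:
    """Replicate a unit cell na x nb x nc times by exact lattice translations."""
    if cell.lattice is None:
        raise InputError("cell carries no lattice metadata")
    if min(na, nb, nc) < 1:
        raise InputError("replication counts must be >= 1")
    mat = cell.lattice
    n = len(cell)
    n_groups = int(cell.group_id.max()) + 1
    coords, cells, groups = [], [], []
    copy = 0
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                shift = i * mat[0] + j * mat[1] + k * mat[2]
                coords.append(cell.coord + shift)
                cells.append(np.tile([i, j, k], (n, 1)))
                groups.append(cell.group_id + copy * n_groups)
                copy += 1
    ncopies = copy
    out = Structure(
        coord=np.concatenate(coords),
        element=np.tile(cell.element, ncopies),
        name=np.tile(cell.name, ncopies),
        charge=np.tile(cell.charge, ncopies),
        molecule_id=np.zeros(n * ncopies, dtype=int),
        residue_id=np.concatenate(groups),
        residue_name=np.tile(cell.residue_name, ncopies),
        group_id=np.concatenate(groups),
        cell_index=np.concatenate(cells),
        lattice=mat,
        meta=dict(cell.meta),
    )
    out.meta["super_extent"] = (na, nb, nc)
    return out


def carve_pore(supercell: Structure, pore: PoreSpec,
               guest: Structure | None = None) -> tuple[Structure, PoreSpec]:
    """Open a rhombic channel of whole unit cells; keep the model neutral.

    Atoms of the hole cells are removed outright (whole cells are neutral).
    If a guest structure is supplied, any remaining mineral group with an
    atom closer than the clash threshold to a guest atom is translated, as
    an intact group, by an integer number of lattice vectors to the nearest
    vacant site on the super-cell border; the move is recorded in the
    returned :class:`PoreSpec` translation log.
    """
    if supercell.cell_index is None or supercell.lattice is None:
        raise InputError("super-cell must carry cell indices and lattice metadata")
    extent = supercell.meta.get("super_extent")
    if extent is None:
        raise InputError("super-cell extent missing from metadata")
    if pore.extent == (0, 0, 0):
        return supercell.copy(), PoreSpec((0, 0, 0), pore.center,
                                          pore.clash_threshold, [])
    ra, rb, rc = pore.hole_ranges(extent)
    ci = supercell.cell_index
    in_hole = (np.isin(ci[:, 0], list(ra)) & np.isin(ci[:, 1], list(rb))
               & np.isin(ci[:, 2], list(rc)))
    carved = supercell.select(~in_hole)
    log: list = []

    if guest is not None and len(guest) > 0:
        mat = supercell.lattice
        na, nb, _ = extent
        tree = cKDTree(guest.coord)
        d, _ = tree.query(carved.coord, k=1)
        clash_groups = np.unique(carved.group_id[d < pore.clash_threshold])
        if len(clash_groups):
            center = _pore_center(supercell, (ra, rb, rc))
            gids = carved.group_id
            for g in clash_groups:
                idx = np.where(gids == g)[0]
                com = carved.coord[idx].mean(axis=0)
                # move outward along a or b, whichever points most away from
                # the pore axis, landing just outside the original boundary
                radial = com - center
                cand = [mat[0] * na, -mat[0] * na, mat[1] * nb, -mat[1] * nb]
                scores = [np.dot(v / np.linalg.norm(v), radial) for v in cand]
                shift = cand[int(np.argmax(scores))]
                new = carved.coord[idx] + shift
                if tree.query(new, k=1)[0].min() < pore.clash_threshold:
                    raise CarvingError(f"group {g} has no vacant border site")
                carved.coord[idx] = new
                log.append({"group_id": int(g),
                            "old_com": com.tolist(),
                            "new_com": (com + shift).tolist()})

    out_pore = PoreSpec(pore.extent, pore.center, pore.clash_threshold, log)
    carved.meta["pore"] = {"extent": pore.extent,
                           "ranges": (list(ra), list(rb), list(rc))}
    return carved, out_pore


def _pore_center(supercell: Structure, ranges) -> np.ndarray:
    mat = supercell.lattice
    ra, rb, rc = ranges
    fa = (ra[0] + ra[-1] + 1) / 2.0
    fb = (rb[0] + rb[-1] + 1) / 2.0
    fc = (rc[0] + rc[-1] + 1) / 2.0
    return fa * mat[0] + fb * mat[1] + fc * mat[2]


@dataclass(frozen=True)
class PoreGeometry:
    side_a: float          # Å, hole extent x lattice constant a
    side_b: float
    angle_gamma: float     # degrees, cross-section angle
    diagonal_long: float   # Å, max atom-atom span along the long diagonal
    diagonal_short: float  # Å, max atom-atom span along the short diagonal


def measure_pore(structure: Structure, pore: PoreSpec,
                 margin: float = 0.8) -> PoreGeometry:
    """Side lengths, cross-section angle and internal atom-atom diagonals.

    The diagonals are the maximum separations, along each diagonal direction
    of the rhombic cross-section, between mineral atoms lining the channel
    (atoms whose ab-projection falls inside the hole rhombus expanded by
    ``margin`` Å — the pore-surface atoms that protrude into the hole).
    """
    if "pore" not in structure.meta:
        raise InputError("structure has no carved pore")
    lat: LatticeParams = structure.meta["lattice_params"]
    ranges = structure.meta["pore"]["ranges"]
    ha, hb, _ = structure.meta["pore"]["extent"]
    mat = structure.lattice
    center = _pore_center(structure, ranges)

    # Fractional a/b coordinates of every atom; pore-lining atoms lie inside
    # the hole ranges expanded by the margin.
    ab = np.linalg.solve(mat[:2, :2].T, structure.coord[:, :2].T).T
    eps_a, eps_b = margin / lat.a, margin / lat.b
    ra, rb = ranges[0], ranges[1]
    lining = ((ab[:, 0] > ra[0] - eps_a) & (ab[:, 0] < ra[-1] + 1 + eps_a)
              & (ab[:, 1] > rb[0] - eps_b) & (ab[:, 1] < rb[-1] + 1 + eps_b))
    if not lining.any():
        raise InputError("no atoms line the pore")
    xy = structure.coord[lining, :2] - center[:2]

    # gamma = 120 deg: long diagonal along a-b, short along a+b.
    lengths = []
    for axis in (mat[0, :2] - mat[1, :2], mat[0, :2] + mat[1, :2]):
        u = axis / np.linalg.norm(axis)
        along = xy @ u
        lengths.append(float(along.max() - along.min()))
    d_long, d_short = max(lengths), min(lengths)
    return PoreGeometry(ha * lat.a, hb * lat.b, lat.gamma, d_long, d_short)
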