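"""Force-field parameter handling and topology perception.

Parameters live in a packaged columnar text file (``data/forcefield.dat``):
per-type Lennard-Jones terms, element-class harmonic bonds, a valence rule
for equilibrium angles and a three-class torsion table.  Partial charges
are carried on the :class:`~dnapatite.structure.Structure` itself (they are
assigned by the builders).  Topology (bonds, angles, torsions, exclusions)
is perceived from geometry with a covalent-radius distance rule, applied
within molecules only — monatomic ions never bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterizationError
from .structure import COVALENT_RADII, Structure

_BOND_SCALE = 1.25    # bond if r < scale * (rcov_i + rcov_j)


@dataclass
class ForceFieldParams:
    lj: dict                      # type -> (rmin_half Å, epsilon kcal/mol)
    masses: dict                  # type -> u
    bonds: dict                   # frozenset({e1,e2}) -> (K, r0)
    angle_k: float
    angle_eq: dict                # (element, degree) -> eq angle deg
    torsions: dict                # 'sp3'|'sp2'|'mixed' -> (V, n, phase deg)
    scale14_elec: float = 1.2
    scale14_lj: float = 2.0

    def bond_param(self, e1: str, e2: str):
        key = frozenset((e1, e2))
        if key not in self.bonds:
            raise ParameterizationError(f"no bond parameters for {e1}-{e2}")
        return self.bonds[key]

    def lj_param(self, t: str):
        if t not in self.lj:
            raise ParameterizationError(f"no Lennard-Jones parameters for type {t!r}")
        return self.lj[t]


def default_params() -> ForceFieldParams:
    ref = resources.files("dnapatite.data").joinpath("forcefield.dat")
    return load_params(ref.read_text().splitlines())


def load_params(lines) -> ForceFieldParams:
    lj, masses, bonds, angle_eq, torsions = {}, {}, {}, {}, {}
    angle_k = 70.0
    s14e, s14l = 1.2, 2.0
    for raw in lines:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "ATOM":
            lj[tok[1]] = (float(tok[3]), float(tok[4]))
            masses[tok[1]] = float(tok[2])
        elif tok[0] == "BOND":
            bonds[frozenset((tok[1], tok[2]))] = (float(tok[3]), float(tok[4]))
        elif tok[0] == "ANGLE_K":
            angle_k = float(tok[1])
        elif tok[0] == "ANGLE_EQ":
            angle_eq[(tok[1], int(tok[2]))] = float(tok[3])
        elif tok[0] == "TORSION":
            torsions[tok[1]] = (float(tok[2]), int(tok[3]), float(tok[4]))
        elif tok[0] == "SCALE14":
            s14e, s14l = float(tok[1]), float(tok[2])
    return ForceFieldParams(lj, masses, bonds, angle_k, angle_eq, torsions,
                            s14e, s14l)


def assign_types(s: Structure) -> np.ndarray:
    """Per-atom force-field types from residue context and element."""
    types = np.empty(len(s), dtype="U2")
    water = np.isin(s.residue_name, ["HOH", "WAT"])
    for i in range(len(s)):
        e = s.element[i]
        if water[i]:
            types[i] = "OW" if e == "O" else "HW"
        elif e == "Ca":
            types[i] = "CA"
        elif e == "F":
            types[i] = "F"
        elif e == "O" and s.residue_name[i] == "OH":
            types[i] = "OX"
        elif e == "H":
            types[i] = "HO" if s.name[i].startswith("HO") else "H"
        else:
            types[i] = e
    return types


@dataclass
class Topology:
    bonds: np.ndarray                  # (Nb, 2) int
    angles: np.ndarray                 # (Na, 3) int, center in the middle
    torsions: np.ndarray               # (Nt, 4) int
    pairs14: np.ndarray                # (N14, 2) int
    excluded: set                      # frozenset pairs (1-2 and 1-3)
    types: np.ndarray                  # (N,) type labels
    degree: np.ndarray = field(default=None)

    @property
    def n_bonds(self):
        return len(self.bonds)


def build_topology(s: Structure) -> Topology:
    """Perceive bonds/angles/torsions from geometry.

    Bonds require both a covalent-radius distance criterion and membership
    in the same molecule; monatomic species (Ca2+, F-) never bond.
    """
    n = len(s)
    types = assign_types(s)
    rcov = np.array([COVALENT_RADII[e] for e in s.element])
    bondable = ~np.isin(s.element, ["Ca", "F"])
    pairs = []
    if n > 1:
        tree = cKDTree(s.coord)
        cand = tree.query_pairs(2.0 * _BOND_SCALE * max(COVALENT_RADII.values()),
                                output_type="ndarray")
        if len(cand):
            i, j = cand[:, 0], cand[:, 1]
            d = np.linalg.norm(s.coord[i] - s.coord[j], axis=1)
            ok = (d < _BOND_SCALE * (rcov[i] + rcov[j]))
            ok &= bondable[i] & bondable[j]
            ok &= s.molecule_id[i] == s.molecule_id[j]
            # no H-H bonds
            ok &= ~((s.element[i] == "H") & (s.element[j] == "H"))
            pairs = cand[ok]
    bonds = np.array(sorted(map(tuple, pairs))) if len(pairs) else \
        np.empty((0, 2), dtype=int)

    neighbors = [[] for _ in range(n)]
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    degree = np.array([len(nb) for nb in neighbors])

    angles = []
    for j in range(n):
        nb = sorted(neighbors[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    angles = np.array(angles) if angles else np.empty((0, 3), dtype=int)

    torsions = []
    for j, k in bonds:
        for i in neighbors[j]:
            if i == k:
                continue
            for m in neighbors[k]:
                if m == j or m == i:
                    continue
                torsions.append((i, j, k, m))
    torsions = np.array(torsions) if torsions else np.empty((0, 4), dtype=int)

    excluded = set()
    for i, j in bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, j, k in angles:
        excluded.add((min(i, k), max(i, k)))
    p14 = set()
    for i, j, k, m in torsions:
        key = (min(i, m), max(i, m))
        if key not in excluded:
            p14.add(key)
    pairs14 = np.array(sorted(p14)) if p14 else np.empty((0, 2), dtype=int)

    return Topology(bonds, angles, torsions, pairs14, excluded, types, degree)


def angle_equilibrium(t: Topology, s: Structure, p: ForceFieldParams) -> np.ndarray:
    """Equilibrium angle (deg) per angle term, by the valence rule."""
    if len(t.angles) == 0:
        return np.empty(0)
    out = np.empty(len(t.angles))
    for idx, (i, j, k) in enumerate(t.angles):
        e = s.element[j]
        key = ("HW", 0) if t.types[j] == "OW" else (e, int(t.degree[j]))
        if key in p.angle_eq:
            out[idx] = p.angle_eq[key]
        elif (e, 4) in p.angle_eq:
            out[idx] = p.angle_eq[(e, 4)]
        else:
            out[idx] = 111.0
    return out


def torsion_class(t: Topology, s: Structure) -> list:
    """'sp3' / 'sp2' / 'mixed' per torsion, by the central-bond degrees."""
    out = []
    for i, j, k, m in t.torsions:
        dj = t.degree[j] if s.element[j] != "H" else 1
        dk = t.degree[k]
        trig_j = (s.element[j] in ("C", "N")) and dj == 3
        trig_k = (s.element[k] in ("C", "N")) and dk == 3
        if trig_j and trig_k:
            out.append("sp2")
        elif trig_j or trig_k:
            out.append("mixed")
        else:
            out.append("sp3")
    return out
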