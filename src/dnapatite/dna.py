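"""Canonical B-form DNA construction from sequence.

The builder produces an idealized fiber-style B-DNA duplex: base pairs are
planar Watson-Crick pairs stacked with a fixed rise (3.4 Å) and twist (36°,
i.e. ~10 bp per turn) about a common axis, and the two strands are related
by the pair dyad, making the duplex exactly helically symmetric.

Residue geometry is derived at import time from the Chemical Component
Dictionary ideal coordinates shipped with biotite: base moieties are taken
rigidly from the CCD components (DA/DT/DG/DC and 5-methyl-dC), posed by a
small deterministic least-squares fit that places each Watson-Crick pair at
its literature hydrogen-bond distances; a common deoxyribose unit is
attached through the glycosidic bond, and the inter-residue phosphate is
solved once under helical symmetry so that every O3'(i-1)-P(i)-O5'(i)
linkage has ideal bond lengths and angles.  Two global degrees of freedom
(the axial displacement of the pair and the sugar spin about the glycosidic
bond) are calibrated once, deterministically, to close the backbone.

5' termini are built without a terminal phosphate (free 5'-OH), so an n-nt
strand carries n-1 phosphates and a formal charge of -(n-1) e.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares, minimize as sp_minimize

from .errors import GeometryError, InputError
from .structure import Structure, concat

# --------------------------------------------------------------------------
# sequences

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "C*": "G"}
_CCD = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "C*": "5CM"}
_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC", "C*": "5MC"}
_PURINES = {"A", "G"}

_BACKBONE_NAMES = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "C1'", "HOP2", "HOP3", "HO5'", "H5'", "H5''", "H4'", "H3'",
    "HO3'", "H2'", "H2''", "H1'",
}

# simplified charge model (e): each internal phosphodiester carries -1,
# sugars and bases are neutral; terminal hydroxyls neutralize their oxygen.
_CHARGES = {"P": 1.2, "OP1": -0.9, "OP2": -0.9, "O5'": -0.2, "O3'": -0.2,
            "HO5'": 0.2, "HO3'": 0.2}


@dataclass(frozen=True)
class NucleotideSequence:
    """5'->3' ordered residues over {A, C, G, T, C*} (C* = 5-methylcytosine)."""

    residues: tuple

    @classmethod
    def from_string(cls, s: str) -> "NucleotideSequence":
        tokens = re.findall(r"[ACGT]\*?", s.upper().replace("5MC", "C*"))
        if "".join(tokens) != s.upper() or not tokens:
            raise InputError(f"cannot parse sequence {s!r}")
        return cls(tuple(tokens))

    def __len__(self) -> int:
        return len(self.residues)

    def complement(self) -> "NucleotideSequence":
        """Watson-Crick complement, returned 5'->3'."""
        return NucleotideSequence(
            tuple(_COMPLEMENT[r] for r in reversed(self.residues)))

    def __str__(self) -> str:
        return "".join(self.residues)


# the three dodecamers studied in the encapsulation models
SEQUENCE_I = NucleotideSequence.from_string("CGCGAATTCGCG")     # Dickerson
SEQUENCE_II = NucleotideSequence.from_string("GCGAGATCTGCG")
SEQUENCE_III = NucleotideSequence.from_string("CGCGAATTC*GCG")  # methylated


@dataclass(frozen=True)
class HelixParams:
    rise: float = 3.4          # Å per base pair
    twist: float = 36.0        # degrees per base pair
    handedness: str = "right"

    def __post_init__(self):
        if self.rise <= 0:
            raise InputError("rise must be positive")
        if self.handedness != "right":
            raise InputError("only right-handed canonical B is supported")

    @property
    def bp_per_turn(self) -> float:
        return 360.0 / self.twist


@dataclass
class DuplexModel:
    """A built duplex: structure, per-residue phosphate atom indices, axis."""

    structure: Structure
    phosphate_index: dict          # residue_id -> atom index of P
    axis_point: np.ndarray
    axis_direction: np.ndarray
    pairing: dict = field(default_factory=dict)  # residue_id -> residue_id


# --------------------------------------------------------------------------
# small geometry helpers

def _rotz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_about(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    return math.degrees(math.atan2(np.dot(np.cross(b1u, v), w), np.dot(v, w)))


def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosv, -1, 1)))


def _sp3_pair(center, n1, n2, bond=1.09, hh_angle=109.5):
    """Two substituent positions completing a tetrahedral center."""
    u1 = (n1 - center) / np.linalg.norm(n1 - center)
    u2 = (n2 - center) / np.linalg.norm(n2 - center)
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    p = np.cross(u1, u2)
    p /= np.linalg.norm(p)
    half = np.deg2rad(hh_angle / 2)
    return (center + bond * (b * np.cos(half) + p * np.sin(half)),
            center + bond * (b * np.cos(half) - p * np.sin(half)))


def _place_by_zmat(a, b, c, bond, angle_deg, torsion_deg):
    """Atom bonded to ``c`` with exact internal coordinates.

    The returned position ``x`` satisfies |x-c| = bond,
    angle(x, c, b) = angle_deg and dihedral(x, c, b, a) = torsion_deg in
    the convention of :func:`_dihedral`.
    """
    e = (b - c) / np.linalg.norm(b - c)
    u = a - b
    u = u - np.dot(u, e) * e
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        u = np.array([1.0, 0.0, 0.0]) - e[0] * e
        nu = np.linalg.norm(u)
    q = u / nu                      # torsion = 0 reference direction
    m = np.cross(e, q)
    ang, tor = np.deg2rad(angle_deg), np.deg2rad(torsion_deg)
    x = c + bond * (np.cos(ang) * e
                    + np.sin(ang) * (np.cos(tor) * q + np.sin(tor) * m))
    # fix the handedness of the torsion reference frame empirically
    if abs(((_dihedral(x, c, b, a) - torsion_deg + 180.0) % 360.0) - 180.0) > 1e-6:
        x = c + bond * (np.cos(ang) * e
                        + np.sin(ang) * (np.cos(tor) * q - np.sin(tor) * m))
    return x


# --------------------------------------------------------------------------
# residue templates (CCD ideal coordinates via biotite)

@lru_cache(maxsize=8)
def _ccd_template(code: str) -> dict:
    import biotite.structure.info as info

    t = info.residue(_CCD[code])
    return {str(n): t.coord[i] for i, n in enumerate(t.atom_name)}


def _glyc_n(code: str) -> str:
    return "N9" if code in _PURINES else "N1"


def _ring_names(code: str) -> list:
    if code in _PURINES:
        return ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
    return ["N1", "C2", "N3", "C4", "C5", "C6"]


_HBOND_TARGETS = {
    # (strand-A code, partner code): [(atom_A, atom_B, distance Å)]
    # the third A:T entry is the minor-groove C2...O2 contact that pins the
    # in-plane orientation (only two hydrogen bonds would leave a spurious
    # overlapping solution)
    ("A", "T"): [("N1", "N3", 2.82), ("N6", "O4", 2.95), ("C2", "O2", 3.65)],
    ("G", "C"): [("O6", "N4", 2.91), ("N1", "N3", 2.95), ("N2", "O2", 2.86)],
}


def _hbond_targets(code_a: str, code_b: str):
    key_a = "C" if code_a == "C*" else code_a
    key_b = "C" if code_b == "C*" else code_b
    if (key_a, key_b) in _HBOND_TARGETS:
        return [(x, y, d) for x, y, d in _HBOND_TARGETS[(key_a, key_b)]]
    if (key_b, key_a) in _HBOND_TARGETS:
        return [(y, x, d) for x, y, d in _HBOND_TARGETS[(key_b, key_a)]]
    raise InputError(f"no Watson-Crick pairing for {code_a}:{code_b}")


_C1C1_HALF = 5.37     # Å, half the C1'-C1' separation in a WC pair
                      # (the value consistent with the CCD base geometries
                      # and the literature hydrogen-bond distances)
_GLYC_BOND = 1.47     # Å, N-C1'
_LAMBDA_REF = 54.5    # deg, reference glycosidic angle for the sugar frame


def _base_atoms(code: str) -> dict:
    tpl = _ccd_template(code)
    names = [n for n in tpl
             if n not in _BACKBONE_NAMES]
    return {n: tpl[n] for n in names}, tpl


def _c1_positions(y1: float = _C1C1_HALF):
    return (np.array([0.0, +y1, 0.0]),
            np.array([0.0, -y1, 0.0]))


def _glyc_n_pos(c1, toward, lam_deg):
    """Glycosidic N at 1.47 Å from C1', rotated lam toward the minor groove."""
    u = toward / np.linalg.norm(toward)
    w = np.array([-1.0, 0.0, 0.0])
    lam = np.deg2rad(lam_deg)
    return c1 + _GLYC_BOND * (np.cos(lam) * u + np.sin(lam) * w)


def _place_base(code: str, n_pos, theta_deg: float, z_sign: int) -> dict:
    """Rigidly pose the CCD base in the z=0 plane.

    The glycosidic N lands on ``n_pos``, the (in-plane projected) N->C1'
    direction points along the in-plane angle ``theta_deg``, and the ring
    normal is ±z.  Non-planar substituent hydrogens ride along rigidly.
    """
    base, tpl = _base_atoms(code)
    nname = _glyc_n(code)
    ring_names = _ring_names(code)
    ring = np.array([tpl[n] for n in ring_names])
    centroid = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    # canonical normal sign: right-handed about the ring walk from the
    # glycosidic N (SVD alone leaves the sign arbitrary per template)
    chem = np.cross(tpl[ring_names[1]] - tpl[nname],
                    tpl[ring_names[-1]] - tpl[nname])
    if np.dot(normal, chem) < 0:
        normal = -normal
    xt = tpl["C1'"] - tpl[nname]
    xt = xt - np.dot(xt, normal) * normal        # in-plane component
    xt /= np.linalg.norm(xt)
    yt = np.cross(normal, xt)
    src = np.column_stack([xt, yt, normal])

    t = np.deg2rad(theta_deg)
    xg = np.array([np.cos(t), np.sin(t), 0.0])
    zg = np.array([0.0, 0.0, float(z_sign)])
    yg = np.cross(zg, xg)
    dst = np.column_stack([xg, yg, zg])
    rot = dst @ src.T
    out = {n: rot @ (p - tpl[nname]) + n_pos for n, p in base.items()}
    # carried along for anchoring; superseded by the sugar at assembly
    out["C1'"] = rot @ (tpl["C1'"] - tpl[nname]) + n_pos
    return out


def _pair_signs(code_a: str, sigma: int) -> tuple:
    """Ring-normal signs for the two bases of a pair.

    Both bases of a Watson-Crick pair share the same canonical-normal sign
    (the right-handed ring walk circulates the same way when the pair is
    viewed down the helix axis).  The purine-as-strand-A orientation defines
    sigma; a pyrimidine leading the pair uses the mirror, which keeps the
    dyad map between the two strand assignments consistent.
    """
    s = sigma if code_a in _PURINES else -sigma
    return (s, s)


def _solve_pair(code_a: str, code_b: str, y1: float = _C1C1_HALF,
                sigma: int = 1):
    """Pose the two bases of a Watson-Crick pair in the z=0 plane.

    Each base has three in-plane rigid degrees of freedom (glycosidic-N
    position and rotation); the fit drives the hydrogen-bond donor-acceptor
    separations to their literature values while anchoring each C1' to its
    position on the C1'-C1' axis.
    """
    c1a, c1b = _c1_positions(y1)
    targets = _hbond_targets(code_a, code_b)
    w_anchor = 3.0
    signs = _pair_signs(code_a, sigma)

    def pose(x):
        A = _place_base(code_a, np.array([x[0], x[1], 0.0]), x[2], signs[0])
        B = _place_base(code_b, np.array([x[3], x[4], 0.0]), x[5], signs[1])
        return A, B

    def residual(x):
        A, B = pose(x)
        r = [np.linalg.norm(A[p] - B[q]) - d for p, q, d in targets]
        r.extend(w_anchor * (A["C1'"] - c1a))
        r.extend(w_anchor * (B["C1'"] - c1b))
        return r

    # multi-start around the classical ~54.5 deg glycosidic geometry; the
    # distance targets alone admit overlapping impostor minima, so solutions
    # with interpenetrating bases are rejected
    na0 = _glyc_n_pos(c1a, c1b - c1a, _LAMBDA_REF)
    nb0 = _glyc_n_pos(c1b, c1a - c1b, _LAMBDA_REF)
    th_a0 = math.degrees(math.atan2(c1a[1] - na0[1], c1a[0] - na0[0]))
    th_b0 = math.degrees(math.atan2(c1b[1] - nb0[1], c1b[0] - nb0[0]))
    best = None
    for da in (0.0, 90.0, 180.0, 270.0):
        for db in (0.0, 90.0, 180.0, 270.0):
            x0 = [na0[0], na0[1], th_a0 + da, nb0[0], nb0[1], th_b0 + db]
            sol = least_squares(residual, x0, xtol=1e-12, ftol=1e-12)
            A, B = pose(sol.x)
            pa = np.array(list(A.values()))
            pb = np.array(list(B.values()))
            dmin = np.min(np.linalg.norm(pa[:, None] - pb[None], axis=2))
            if dmin < 1.4:
                continue
            if best is None or sol.cost < best[0]:
                best = (sol.cost, sol.x)
    if best is None:
        raise InputError(f"no clash-free pose for pair {code_a}:{code_b}")
    A, B = pose(best[1])

    def lam(base_atoms, c1_ref, other_c1):
        n = base_atoms[_glyc_n(code_a if base_atoms is A else code_b)]
        v1 = other_c1 - c1_ref
        v2 = n - c1_ref
        cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(np.clip(cosv, -1, 1)))

    lams = (lam(A, A["C1'"], B["C1'"]), lam(B, B["C1'"], A["C1'"]))
    return A, B, lams


# --------------------------------------------------------------------------
# helically symmetric unit calibration

_SUGAR_NAMES = ["C1'", "C2'", "C3'", "C4'", "O4'", "O3'", "C5'",
                "H1'", "H2'", "H2''", "H3'", "H4'"]

_PUCKER_PHASE = 162.0   # deg, C2'-endo (B-form)
_PUCKER_AMPL = 36.0     # deg, ring torsion amplitude


def _sp3_one(center, n1, n2, n3, bond=1.09):
    u = sum((x - center) / np.linalg.norm(x - center) for x in (n1, n2, n3))
    return center - bond * u / np.linalg.norm(u)


@lru_cache(maxsize=32)
def _sugar_template(phase: float = _PUCKER_PHASE):
    """Idealized C2'-endo deoxyribose built from internal coordinates.

    The furanose ring is solved by least squares against pseudorotation-
    consistent endocyclic torsions (phase 162°, amplitude 36°) and standard
    bond lengths/angles; the exocyclic O3', C5' and glycosidic N are placed
    with the stereochemical offsets measured from the CCD reference, so the
    natural D-deoxyribose chirality is preserved.
    """
    nu = [_PUCKER_AMPL * math.cos(math.radians(phase + 144.0 * (j - 2)))
          for j in range(5)]
    bonds = {"O4'C1'": 1.42, "C1'C2'": 1.53, "C2'C3'": 1.525,
             "C3'C4'": 1.525, "C4'O4'": 1.45}
    angles = {"C4'O4'C1'": 109.9, "O4'C1'C2'": 105.6, "C1'C2'C3'": 102.5,
              "C2'C3'C4'": 102.5, "C3'C4'O4'": 105.6}

    # initial ring guess by sequential construction, then closure refinement
    o4 = np.zeros(3)
    c1 = np.array([bonds["O4'C1'"], 0.0, 0.0])
    a = math.radians(180.0 - angles["O4'C1'C2'"])
    c2 = c1 + bonds["C1'C2'"] * np.array([math.cos(a), math.sin(a), 0.0])
    c3 = _place_by_zmat(o4, c1, c2, bonds["C2'C3'"], angles["C1'C2'C3'"], nu[1])
    c4 = _place_by_zmat(c1, c2, c3, bonds["C3'C4'"], angles["C2'C3'C4'"], nu[2])

    def residual(x):
        C2, C3, C4 = x[0:3], x[3:6], x[6:9]
        r = [
            np.linalg.norm(C2 - c1) - bonds["C1'C2'"],
            np.linalg.norm(C3 - C2) - bonds["C2'C3'"],
            np.linalg.norm(C4 - C3) - bonds["C3'C4'"],
            np.linalg.norm(o4 - C4) - bonds["C4'O4'"],
            np.deg2rad(_angle(o4, c1, C2) - angles["O4'C1'C2'"]),
            np.deg2rad(_angle(c1, C2, C3) - angles["C1'C2'C3'"]),
            np.deg2rad(_angle(C2, C3, C4) - angles["C2'C3'C4'"]),
            np.deg2rad(_angle(C3, C4, o4) - angles["C3'C4'O4'"]),
            np.deg2rad(_angle(C4, o4, c1) - angles["C4'O4'C1'"]),
            0.5 * np.deg2rad(_dihedral(C4, o4, c1, C2) - nu[0]),
            0.5 * np.deg2rad(_dihedral(o4, c1, C2, C3) - nu[1]),
            0.5 * np.deg2rad(_dihedral(c1, C2, C3, C4) - nu[2]),
            0.5 * np.deg2rad(_dihedral(C2, C3, C4, o4) - nu[3]),
            0.5 * np.deg2rad(_dihedral(C3, C4, o4, c1) - nu[4]),
        ]
        return r

    sol = least_squares(residual, np.concatenate([c2, c3, c4]), xtol=1e-12)
    c2, c3, c4 = sol.x[0:3], sol.x[3:6], sol.x[6:9]

    # stereochemical substituent offsets measured on the CCD reference
    tpl = _ccd_template("C")
    def tor(*names):
        return _dihedral(*(tpl[n] for n in names))
    off_c5 = tor("C5'", "C4'", "C3'", "C2'") - tor("O4'", "C4'", "C3'", "C2'")
    off_o3 = tor("O3'", "C3'", "C4'", "O4'") - tor("C2'", "C3'", "C4'", "O4'")
    off_n = tor("N1", "C1'", "C2'", "C3'") - tor("O4'", "C1'", "C2'", "C3'")

    base_c5 = _dihedral(o4, c4, c3, c2)
    c5 = _place_by_zmat(c2, c3, c4, 1.51, 115.0, base_c5 + off_c5)
    base_o3 = _dihedral(c2, c3, c4, o4)
    o3 = _place_by_zmat(o4, c4, c3, 1.43, 110.0, base_o3 + off_o3)
    base_n = _dihedral(o4, c1, c2, c3)
    n1 = _place_by_zmat(c3, c2, c1, 1.47, 114.0, base_n + off_n)

    h1 = _sp3_one(c1, o4, c2, n1)
    h3 = _sp3_one(c3, c2, c4, o3)
    h4 = _sp3_one(c4, c3, o4, c5)
    h2a, h2b = _sp3_pair(c2, c1, c3)
    sugar = {"C1'": c1, "C2'": c2, "C3'": c3, "C4'": c4, "O4'": o4,
             "O3'": o3, "C5'": c5, "H1'": h1, "H2'": h2a, "H2''": h2b,
             "H3'": h3, "H4'": h4}
    ref = dict(sugar)
    ref["N1"] = n1
    return sugar, ref


def _place_sugar(c1_pos, n_ref_pos, spin_deg: float,
                 phase: float = _PUCKER_PHASE) -> dict:
    """Attach the common deoxyribose rigidly through the glycosidic bond."""
    sugar, tpl = _sugar_template(round(phase, 4))
    xt = tpl["N1"] - tpl["C1'"]
    xt /= np.linalg.norm(xt)
    yt = tpl["O4'"] - tpl["C1'"]
    yt = yt - np.dot(yt, xt) * xt
    yt /= np.linalg.norm(yt)
    src = np.column_stack([xt, yt, np.cross(xt, yt)])

    xg = (n_ref_pos - c1_pos)
    xg /= np.linalg.norm(xg)
    p0 = np.array([0.0, 0.0, 1.0]) - np.array([0.0, 0.0, 1.0]).dot(xg) * xg
    p0 /= np.linalg.norm(p0)
    yg = _rot_about(xg, spin_deg) @ p0
    dst = np.column_stack([xg, yg, np.cross(xg, yg)])
    rot = dst @ src.T
    return {n: rot @ (p - tpl["C1'"]) + c1_pos for n, p in sugar.items()}


def _bridge(o3_prev, c5, c3_prev):
    """Least-squares P and O5' bridging O3'(i-1) to C5'(i)."""
    def resid(x):
        P, O5 = x[:3], x[3:]
        return [
            np.linalg.norm(P - o3_prev) - 1.595,
            np.linalg.norm(O5 - P) - 1.593,
            np.linalg.norm(c5 - O5) - 1.440,
            np.deg2rad(_angle(c3_prev, o3_prev, P) - 119.7),
            np.deg2rad(_angle(o3_prev, P, O5) - 104.0),
            np.deg2rad(_angle(P, O5, c5) - 120.9),
        ]

    u = (c5 - o3_prev) / np.linalg.norm(c5 - o3_prev)
    x0 = np.concatenate([o3_prev + 1.6 * u, c5 - 1.44 * u])
    sol = least_squares(resid, x0)
    return sol.x[:3], sol.x[3:], sol.cost


def _phosphate_oxygens(P, o3_prev, o5):
    u1 = (o3_prev - P) / np.linalg.norm(o3_prev - P)
    u2 = (o5 - P) / np.linalg.norm(o5 - P)
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    p = np.cross(u1, u2)
    p /= np.linalg.norm(p)
    half = np.deg2rad(119.6 / 2)
    return (P + 1.485 * (b * np.cos(half) + p * np.sin(half)),
            P + 1.485 * (b * np.cos(half) - p * np.sin(half)))


@lru_cache(maxsize=4)
def _unit_library(rise: float, twist: float):
    """Calibrated residue units in the pair frame of base-pair 0, strand A.

    Returns a dict with per-code atom dictionaries (base + sugar, Å), the
    phosphate unit {P, OP1, OP2, O5'} expressed in the frame of the residue
    owning it, terminal-cap positions and calibration metadata.  Strand B
    units are the dyad images (x, -y, -z) of these.
    """
    R = _rotz(twist)

    def backbone(q):
        """Sugar in the (shifted) pair frame plus the previous residue's
        O3'/C3' expressed in this residue's frame under helical symmetry."""
        dx, spin, lam, phase, y1, zoff, tilt = q
        c1_inplane = np.array([0.0, y1, 0.0])
        n_ref = _glyc_n_pos(c1_inplane, np.array([0.0, -2 * y1, 0.0]), lam)
        # the sugar anchor may sit slightly out of the base-pair plane and
        # its attachment direction may tilt out of plane (the roles played
        # by propeller twist and buckle in real duplexes)
        c1 = np.array([0.0, y1, zoff])
        d_ref = n_ref - c1_inplane
        t = np.deg2rad(tilt)
        d_ref = d_ref * np.cos(t) + np.array([0.0, 0.0, np.linalg.norm(d_ref)]) * np.sin(t)
        shift = np.array([dx, 0.0, 0.0])
        sugar = {n: p + shift for n, p in
                 _place_sugar(c1, c1 + d_ref, spin, phase).items()}
        # the 5'-neighbor of a strand-A residue sits one pair step up:
        # P(pair i) bridges O3'(pair i+1) down to O5'(pair i)
        o3_prev = R @ sugar["O3'"] + np.array([0.0, 0.0, rise])
        c3_prev = R @ sugar["C3'"] + np.array([0.0, 0.0, rise])
        return sugar, o3_prev, c3_prev

    # Joint fit of the model parameters and the bridging phosphate: exact
    # O3'(i-1)-P-O5'(i) linkage geometry plus the canonical-B observables
    # (P radius 9.3 Å; P_y 8.8 Å, the value consistent with the 11.7 /
    # 17.2 Å minor/major groove P-P widths), with the idealized-geometry
    # parameters regularized toward their literature values.
    def joint_residual(x):
        q, P, O5 = x[:7], x[7:10], x[10:13]
        sugar, o3p, c3p = backbone(q)
        c5 = sugar["C5'"]
        return [
            np.linalg.norm(P - o3p) - 1.595,
            np.linalg.norm(O5 - P) - 1.593,
            np.linalg.norm(c5 - O5) - 1.440,
            np.deg2rad(_angle(c3p, o3p, P) - 119.7),
            np.deg2rad(_angle(o3p, P, O5) - 104.0),
            np.deg2rad(_angle(P, O5, c5) - 120.9),
            1.0 * (np.linalg.norm(P[:2]) - 9.7),
            0.5 * (P[1] - 9.1),
            0.05 * (q[2] - _LAMBDA_REF),
            0.02 * (q[3] - _PUCKER_PHASE),
            1.0 * (q[4] - _C1C1_HALF),
            0.3 * q[5],
            0.01 * q[6],
            # keep the pair near the axis (C1' radius ~5.5-5.9 as in fiber B)
            0.2 * (q[0] - 1.0),
        ]

    lb = [-1.0, -1.0, 48.0, 140.0, 5.15, -1.2, -30.0] + [-np.inf] * 6
    ub = [3.0, 361.0, 62.0, 180.0, 5.55, 1.2, 30.0] + [np.inf] * 6
    best = None
    for spin0 in (30.0, 40.0, 50.0, 60.0):
        for dx0 in (0.5, 1.0):
            q0 = [dx0, spin0, _LAMBDA_REF, _PUCKER_PHASE, _C1C1_HALF, 0.0, 0.0]
            sugar0, o3p0, c3p0 = backbone(q0)
            P0, O50, _ = _bridge(o3p0, sugar0["C5'"], c3p0)
            sol = least_squares(joint_residual,
                                np.concatenate([q0, P0, O50]),
                                bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
    q = best.x[:7]
    P, O5 = best.x[7:10], best.x[10:13]
    dx, spin, lam_ref, phase, y1, zoff, tilt = (float(v) for v in q)
    sugar, o3_prev, c3_prev = backbone(q)
    cost = float(np.sum(np.array(joint_residual(best.x)[:6]) ** 2))
    OP1, OP2 = _phosphate_oxygens(P, o3_prev, O5)
    shift = np.array([dx, 0.0, 0.0])

    # Global mirror branch: both candidate sign conventions give valid
    # Watson-Crick pairs; the physical one puts the glycosidic torsion chi
    # in the anti range once the calibrated sugar is attached.
    def chi_for(sigma):
        A, _, _ = _solve_pair("A", "T", y1, sigma)
        return _dihedral(sugar["O4'"], sugar["C1'"],
                         A[_glyc_n("A")] + shift, A["C4"] + shift)

    sigma = 1
    chi1 = chi_for(1)
    if not (-170.0 <= chi1 <= -40.0):
        sigma = -1
    bases = {}
    lam_by_code = {}
    for code, partner in _COMPLEMENT.items():
        A, _, lams = _solve_pair(code, partner, y1, sigma)
        bases[code] = A
        lam_by_code[code] = lams[0]

    units = {}
    for code in _COMPLEMENT:
        atoms = {n: p + shift for n, p in bases[code].items()}
        atoms.update({n: p.copy() for n, p in sugar.items()})
        units[code] = atoms
    p_unit = {"P": P, "OP1": OP1, "OP2": OP2, "O5'": O5}

    # hydrogens rebuilt around the (new) O5': H5', H5'' and terminal caps
    h5, h5p = _sp3_pair(sugar["C5'"], sugar["C4'"], O5)
    ho5 = _place_by_zmat(sugar["C4'"], sugar["C5'"], O5, 0.96, 108.5, 180.0)
    ho3 = _place_by_zmat(sugar["C4'"], sugar["C3'"], sugar["O3'"],
                         0.96, 108.5, 180.0)
    caps = {"H5'": h5, "H5''": h5p, "HO5'": ho5, "HO3'": ho3}
    meta = {"dx": dx, "spin": spin, "lambda_ref": lam_ref, "pucker": phase,
            "c1c1_half": y1, "z_offset": zoff, "tilt": tilt,
            "bridge_cost": cost, "sigma": sigma,
            "lambda": lam_by_code, "P_local": P.copy()}
    return units, p_unit, caps, meta


# --------------------------------------------------------------------------
# public builders

def build_canonical_duplex(seq: NucleotideSequence | str,
                           helix: HelixParams = HelixParams()) -> DuplexModel:
    """Build the canonical B-form duplex of ``seq`` and its complement."""
    if isinstance(seq, str):
        seq = NucleotideSequence.from_string(seq)
    n = len(seq)
    units, p_unit, caps, cal = _unit_library(helix.rise, helix.twist)
    dyad = np.diag([1.0, -1.0, -1.0])

    names, elements, coords, charges = [], [], [], []
    mol, resid, resname = [], [], []
    phosphate_index = {}

    def emit(atom_map, order, molecule, res_id, res_name):
        for name in order:
            p = atom_map[name]
            names.append(name)
            elements.append("H" if name.startswith("H") else name[0])
            coords.append(p)
            charges.append(_CHARGES.get(name, 0.0))
            mol.append(molecule)
            resid.append(res_id)
            resname.append(res_name)
            if name == "P":
                phosphate_index[res_id] = len(names) - 1

    def residue_atoms(code, pair_index, strand):
        """Atom dict for the residue of ``strand`` at ``pair_index``."""
        Rz = _rotz(helix.twist * pair_index)
        tz = np.array([0.0, 0.0, helix.rise * pair_index])
        local = dict(units[code])
        # strand A runs 5'->3' with descending pair index, strand B (the
        # dyad image) with ascending pair index
        is_term5 = (strand == "A" and pair_index == n - 1) or \
                   (strand == "B" and pair_index == 0)
        if not is_term5:
            local.update(p_unit)
        else:
            local["O5'"] = p_unit["O5'"]
            local["HO5'"] = caps["HO5'"]
        is_term3 = (strand == "A" and pair_index == 0) or \
                   (strand == "B" and pair_index == n - 1)
        if is_term3:
            local["HO3'"] = caps["HO3'"]
        local["H5'"] = caps["H5'"]
        local["H5''"] = caps["H5''"]
        if strand == "B":
            local = {k: dyad @ v for k, v in local.items()}
        return {k: Rz @ v + tz for k, v in local.items()}

    order_backbone = ["P", "OP1", "OP2", "O5'", "HO5'", "C5'", "H5'", "H5''",
                      "C4'", "H4'", "O4'", "C3'", "H3'", "O3'", "HO3'",
                      "C2'", "H2'", "H2''", "C1'", "H1'"]

    def emit_residue(code, pair_index, strand, molecule, res_id):
        atoms = residue_atoms(code, pair_index, strand)
        base_order = [nm for nm in atoms if nm not in set(order_backbone)]
        order = [nm for nm in order_backbone if nm in atoms] + base_order
        emit(atoms, order, molecule, res_id, _RESNAME[code])

    pairing = {}
    for j, code in enumerate(seq.residues):           # strand A, 5'->3'
        emit_residue(code, n - 1 - j, "A", 0, j + 1)
    comp = seq.complement()
    for j, code in enumerate(comp.residues):          # strand B, 5'->3'
        emit_residue(code, j, "B", 1, n + j + 1)
        pairing[n - j] = n + j + 1
        pairing[n + j + 1] = n - j

    s = Structure(
        coord=np.array(coords),
        element=np.array(elements),
        name=np.array(names),
        charge=np.array(charges),
        molecule_id=np.array(mol),
        residue_id=np.array(resid),
        residue_name=np.array(resname),
        meta={"kind": "duplex", "sequence": str(seq),
              "helix": helix, "calibration": cal,
              "axis_point": np.zeros(3), "axis_direction": np.array([0., 0., 1.]),
              "pairing": pairing},
    )
    return DuplexModel(s, phosphate_index, np.zeros(3),
                       np.array([0.0, 0.0, 1.0]), pairing)


def extract_single_strand(duplex: DuplexModel, strand_id: int) -> Structure:
    """Keep exactly the atoms of one strand; coordinates unchanged."""
    s = duplex.structure
    if strand_id not in set(s.molecule_id.tolist()):
        raise InputError(f"no strand with molecule_id {strand_id}")
    out = s.select(s.molecule_id == strand_id)
    out.meta["kind"] = "single_strand"
    return out


def phosphorus_indices(s: Structure) -> np.ndarray:
    return np.where((s.element == "P") & (s.name == "P"))[0]


def place_counterions(dna: Structure, mode: str = "minor_groove",
                      seed: int = 0, optimize: bool = True) -> Structure:
    """Add Ca2+ counterions near the DNA phosphates.

    ``minor_groove`` places ions at the minor-groove midline between
    cross-strand phosphate pairs (duplexes); ``random_backbone`` places each
    ion 3-5 Å from a phosphorus picked reproducibly under ``seed``.  The ion
    count is ceil(n_phosphates / 2); any ±1 e residual charge is recorded in
    ``meta['ion_log']`` rather than silently fixed.  With ``optimize`` the
    ion positions are relaxed by steepest descent with the DNA fixed.
    """
    p_idx = phosphorus_indices(dna)
    if len(p_idx) == 0:
        raise InputError("no phosphate groups found")
    n_ca = math.ceil(len(p_idx) / 2)
    rng = np.random.default_rng(seed)
    positions = []
    if mode == "minor_groove":
        axis_p = dna.meta.get("axis_point", np.zeros(3))
        axis_d = dna.meta.get("axis_direction", np.array([0.0, 0.0, 1.0]))
        strands = np.unique(dna.molecule_id[p_idx])
        if len(strands) == 2:
            pa = p_idx[dna.molecule_id[p_idx] == strands[0]]
            pb = p_idx[dna.molecule_id[p_idx] == strands[1]]
            ca = dna.coord[pa]
            cb = dna.coord[pb]
            # cross-strand pairs across the minor groove: nearest P on the
            # other strand, offset along the helix
            mids = []
            for x in ca:
                d = np.linalg.norm(cb - x, axis=1)
                j = int(np.argmin(d))
                mids.append(0.5 * (x + cb[j]))
            mids = np.array(mids)
            sel = np.linspace(0, len(mids) - 1, n_ca).round().astype(int)
            for m in mids[sel]:
                rel = m - axis_p
                radial = rel - np.dot(rel, axis_d) * axis_d
                radial /= max(np.linalg.norm(radial), 1e-9)
                positions.append(m - 1.0 * radial)
        else:
            mode = "random_backbone"
    if mode == "random_backbone":
        positions = []
        order = rng.permutation(np.repeat(p_idx, 2))[:n_ca]
        for i in order:
            for _ in range(200):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                r = rng.uniform(3.0, 5.0)
                cand = dna.coord[i] + r * v
                if np.min(np.linalg.norm(dna.coord - cand, axis=1)) > 2.2:
                    positions.append(cand)
                    break
    positions = np.array(positions[:n_ca])
    next_mol = int(dna.molecule_id.max()) + 1
    next_res = int(dna.residue_id.max()) + 1
    ions = Structure(
        coord=positions,
        element=np.array(["Ca"] * n_ca),
        name=np.array(["CA"] * n_ca),
        charge=np.full(n_ca, 2.0),
        molecule_id=np.full(n_ca, next_mol, dtype=int),
        residue_id=np.arange(next_res, next_res + n_ca),
        residue_name=np.array(["CA"] * n_ca),
    )
    out = concat([dna, ions])
    residual = out.net_charge
    out.meta = dict(dna.meta)
    out.meta["ion_log"] = {"n_ca": n_ca, "mode": mode, "seed": seed,
                           "residual_charge": float(residual)}
    if optimize:
        from .forcefield import build_topology, default_params
        from .minimize import minimize_structure

        frozen = np.ones(len(out), dtype=bool)
        frozen[-n_ca:] = False
        t = build_topology(out)
        p = default_params()
        out, _ = minimize_structure(out, t, p, frozen_mask=~frozen,
                                    n_steps=300, step_size=0.02,
                                    cutoff=12.0, switch_start=10.0)
    return out


def embed_in_pore(mineral: Structure, dna: Structure, orientation_seed: int = 0,
                  supercell: Structure | None = None,
                  pore=None) -> Structure:
    """Center the DNA on the pore c-axis of a carved mineral.

    The DNA helix axis is aligned with the crystallographic c-axis through
    the pore center, the axial rotation is drawn reproducibly from
    ``orientation_seed``, and any mineral group left within the clash
    threshold is translated to the super-cell border (guest-mode carving).
    """
    from .crystal import PoreSpec, _pore_center, carve_pore

    if "pore" not in mineral.meta:
        raise InputError("mineral has no carved pore")
    extent = mineral.meta["pore"]["extent"]
    ranges = mineral.meta["pore"]["ranges"]
    lat = mineral.meta["lattice_params"]
    depth = extent[2] * lat.c
    zspan = dna.coord[:, 2].max() - dna.coord[:, 2].min()
    if zspan > depth:
        raise GeometryError(
            f"DNA axial extent {zspan:.1f} Å exceeds pore depth {depth:.1f} Å")
    rng = np.random.default_rng(orientation_seed)
    angle = rng.uniform(0.0, 360.0)
    Rz = _rotz(angle)
    center = _pore_center(mineral, ranges)
    dna_centered = dna.coord - dna.coord.mean(axis=0)
    guest = dna.with_coord(dna_centered @ Rz.T + center)
    # re-carving the already-carved mineral with the guest is idempotent for
    # the hole cells and performs the guest-driven border translations
    pore_spec = pore or PoreSpec(tuple(extent))
    carved, pore_out = carve_pore(mineral, pore_spec, guest=guest)
    out = concat([carved, guest], renumber_molecules=True)
    out.meta = dict(mineral.meta)
    out.meta["orientation_deg"] = float(angle)
    out.meta["translation_log"] = pore_out.translation_log
    return out
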