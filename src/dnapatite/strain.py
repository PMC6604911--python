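"""Mineral-induced DNA distortion metrics.

Three quantities characterize how an apatite pore deforms an embedded
duplex relative to its canonical B-form starting structure:

* the bonded-energy penalty Δτ = ΔE_str + ΔE_bnd + ΔE_tor — the difference
  in stretching, bending and torsional energies between the relaxed and
  the canonical conformation.  Nonbonded terms are excluded by
  construction, so Δτ measures pure geometric stress;
* the all-atom RMSD between the two conformations (optimal rigid
  superposition by default);
* the inter-chain distance (IC) — the separation of the two
  sugar-phosphate chains across the helix axis, evaluated as twice the
  mean radial distance of the backbone phosphate groups (P, OP1, OP2)
  from the axis fit through the phosphate cloud.  For structures without
  a phosphate backbone the strand mass-center distance is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import bonded_energy
from .errors import InputError
from .forcefield import ForceFieldParams, Topology
from .structure import Structure


@dataclass
class StrainReport:
    delta_tau: float
    d_e_str: float
    d_e_bnd: float
    d_e_tor: float
    rmsd: float | None = None
    interchain_distance: float | None = None
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "delta_tau": self.delta_tau,
            "dE_str": self.d_e_str,
            "dE_bnd": self.d_e_bnd,
            "dE_tor": self.d_e_tor,
            "rmsd": self.rmsd,
            "interchain_distance": self.interchain_distance,
        }


def delta_tau(relaxed: Structure, canonical: Structure,
              t: Topology, p: ForceFieldParams,
              label: str = "") -> StrainReport:
    """Bonded-energy penalty of the relaxed vs the canonical conformation."""
    if len(relaxed) != len(canonical):
        raise InputError("relaxed and canonical structures differ in size")
    if not np.array_equal(relaxed.element, canonical.element):
        raise InputError("atom ordering mismatch between conformations")
    e_rel = bonded_energy(relaxed, t, p)
    e_can = bonded_energy(canonical, t, p)
    ds = e_rel.e_str - e_can.e_str
    db = e_rel.e_bnd - e_can.e_bnd
    dt = e_rel.e_tor - e_can.e_tor
    rep = StrainReport(ds + db + dt, ds, db, dt, label=label)
    rep.rmsd = rmsd_all_atom(relaxed, canonical)
    try:
        rep.interchain_distance = interchain_distance(relaxed)
    except InputError:
        rep.interchain_distance = None
    return rep


def kabsch_rotation(a: np.ndarray, b: np.ndarray,
                    weights: np.ndarray | None = None):
    """Optimal rotation superposing ``a`` onto ``b`` (both centered)."""
    w = np.ones(len(a)) if weights is None else weights
    H = (a * w[:, None]).T @ b
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rmsd_all_atom(a: Structure, b: Structure, superpose: bool = True) -> float:
    """All-atom RMSD; with ``superpose`` the optimal least-squares rigid
    superposition is removed first."""
    if len(a) != len(b):
        raise InputError("atom count mismatch")
    xa = a.coord - a.coord.mean(axis=0)
    xb = b.coord - b.coord.mean(axis=0)
    if superpose:
        R = kabsch_rotation(xa, xb)
        xa = xa @ R.T
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _phosphate_group_centers(duplex: Structure):
    sel = np.isin(duplex.name, ["P", "OP1", "OP2"])
    if not sel.any():
        return None
    rid = duplex.residue_id[sel]
    coords = duplex.coord[sel]
    centers = np.array([coords[rid == r].mean(axis=0) for r in np.unique(rid)])
    return centers


def interchain_distance(duplex: Structure) -> float:
    """Cross-axis separation of the two chains (Å).

    With a phosphate backbone present (≥4 groups), the helix axis is the
    first principal axis of the phosphate-group centers and the IC is
    twice their mean perpendicular distance to it.  Otherwise the distance
    between the two strands' mass centers is returned.
    """
    mols = np.unique(duplex.molecule_id)
    if len(mols) != 2:
        raise InputError("inter-chain distance requires exactly two strands")
    centers = _phosphate_group_centers(duplex)
    if centers is not None and len(centers) >= 4:
        mean = centers.mean(axis=0)
        rel = centers - mean
        _, _, vt = np.linalg.svd(rel)
        axis = vt[0]
        perp = rel - np.outer(rel @ axis, axis)
        return float(2.0 * np.mean(np.linalg.norm(perp, axis=1)))
    a = duplex.select(duplex.molecule_id == mols[0])
    b = duplex.select(duplex.molecule_id == mols[1])
    return float(np.linalg.norm(a.center_of_mass() - b.center_of_mass()))


def format_report_table(reports: list) -> str:
    """Table-style text rendering of strain reports."""
    head = (f"{'system':<16}{'dtau':>10}{'dE_str':>10}{'dE_bnd':>10}"
            f"{'dE_tor':>10}{'IC':>8}{'RMSD':>8}")
    lines = [head, "-" * len(head)]
    for r in reports:
        ic = f"{r.interchain_distance:8.1f}" if r.interchain_distance else f"{'-':>8}"
        rm = f"{r.rmsd:8.1f}" if r.rmsd is not None else f"{'-':>8}"
        lines.append(f"{r.label:<16}{r.delta_tau:10.1f}{r.d_e_str:10.1f}"
                     f"{r.d_e_bnd:10.1f}{r.d_e_tor:10.1f}{ic}{rm}")
    return "\n".join(lines)
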