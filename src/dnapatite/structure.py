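"""Core in-memory containers: :class:`Structure` and :class:`Trajectory`.

A :class:`Structure` is an ordered atom collection carrying, per atom, the
element, an atom name (crystallographic site label or PDB atom name), a
partial charge in elementary-charge units, Cartesian coordinates in Å, and
molecule / residue tags.  Charged groups that must never be split (a PO4
tetrahedron, an OH ion, a single Ca) share a ``group_id``.  Crystal models
additionally carry a 3x3 lattice matrix (rows = cell vectors, Å) and the
cell index each atom was generated in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Atomic masses (u) for the elements this package handles.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "Ca": 40.078,
}

# Single-bond covalent radii (Å), used for distance-based bond perception.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "Ca": 1.76,
}


@dataclass
class Structure:
    """Ordered atom collection in Cartesian Å."""

    coord: np.ndarray                 # (N, 3) float64, Å
    element: np.ndarray               # (N,) str
    name: np.ndarray                  # (N,) str  (site label / PDB atom name)
    charge: np.ndarray                # (N,) float64, e
    molecule_id: np.ndarray           # (N,) int
    residue_id: np.ndarray            # (N,) int
    residue_name: np.ndarray          # (N,) str
    group_id: np.ndarray | None = None    # (N,) int, intact charged groups
    cell_index: np.ndarray | None = None  # (N, 3) int, generating unit cell
    lattice: np.ndarray | None = None     # (3, 3) float64, rows = a, b, c
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=np.float64).reshape(-1, 3)
        n = len(self.coord)
        self.element = np.asarray(self.element, dtype="U4")
        self.name = np.asarray(self.name, dtype="U8")
        self.charge = np.asarray(self.charge, dtype=np.float64)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.residue_id = np.asarray(self.residue_id, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype="U6")
        for arr in (self.element, self.name, self.charge, self.molecule_id,
                    self.residue_id, self.residue_name):
            if len(arr) != n:
                raise ValueError("annotation length mismatch")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coord)

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.element])

    @property
    def net_charge(self) -> float:
        return float(self.charge.sum())

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (self.coord * m[:, None]).sum(axis=0) / m.sum()

    def select(self, mask: np.ndarray) -> "Structure":
        """Sub-structure of the atoms where ``mask`` is True (order kept)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        return Structure(
            coord=self.coord[idx].copy(),
            element=self.element[idx].copy(),
            name=self.name[idx].copy(),
            charge=self.charge[idx].copy(),
            molecule_id=self.molecule_id[idx].copy(),
            residue_id=self.residue_id[idx].copy(),
            residue_name=self.residue_name[idx].copy(),
            group_id=None if self.group_id is None else self.group_id[idx].copy(),
            cell_index=None if self.cell_index is None else self.cell_index[idx].copy(),
            lattice=None if self.lattice is None else self.lattice.copy(),
            meta=dict(self.meta),
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        return replace(self, coord=np.asarray(coord, dtype=np.float64).copy())

    def copy(self) -> "Structure":
        return self.select(np.ones(len(self), dtype=bool))

    def element_counts(self) -> dict:
        vals, counts = np.unique(self.element, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def concat(parts: list[Structure], renumber_molecules: bool = False) -> Structure:
    """Concatenate structures; lattice/meta taken from the first that has one."""
    parts = [p for p in parts if len(p) > 0]
    if not parts:
        raise ValueError("nothing to concatenate")
    mol = []
    offset = 0
    for p in parts:
        m = p.molecule_id.copy()
        if renumber_molecules:
            m = m + offset
            offset = m.max() + 1 if len(m) else offset
        mol.append(m)
    lattice = next((p.lattice for p in parts if p.lattice is not None), None)

    def _cat_optional(attr):
        vals = [getattr(p, attr) for p in parts]
        if any(v is None for v in vals):
            return None
        return np.concatenate(vals)

    return Structure(
        coord=np.concatenate([p.coord for p in parts]),
        element=np.concatenate([p.element for p in parts]),
        name=np.concatenate([p.name for p in parts]),
        charge=np.concatenate([p.charge for p in parts]),
        molecule_id=np.concatenate(mol),
        residue_id=np.concatenate([p.residue_id for p in parts]),
        residue_name=np.concatenate([p.residue_name for p in parts]),
        group_id=_cat_optional("group_id"),
        cell_index=_cat_optional("cell_index"),
        lattice=lattice,
        meta=dict(parts[0].meta),
    )


@dataclass
class Trajectory:
    """Time-ordered coordinate frames with (orthorhombic) box dimensions."""

    times: np.ndarray                  # (F,) ps, strictly increasing
    coords: np.ndarray                 # (F, N, 3) Å
    box: np.ndarray                    # (3,) Å or (F, 3)
    structure: Structure | None = None  # atom metadata reference

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise ValueError("frame count mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def box_at(self, frame: int) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box[frame]
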