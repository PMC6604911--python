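"""Structure and trajectory IO plus the umbrella workflows.

PDB files are read and written through biotite (CRYST1 carried via the
atom-array box); XYZ and multi-frame XYZ are plain text.  Charges are not
part of either format, so :func:`assign_charges` restores the package's
charge model from residue/atom names after reading.  Chain ids follow the
package convention: A/B for the DNA strands, M for mineral, I for ions,
W for water.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError, ParseError
from .structure import Structure, Trajectory

_DNA_RESNAMES = ("DA", "DC", "DG", "DT", "5MC")

# the package charge model by (residue, atom-name) context
_DNA_CHARGES = {"P": 1.2, "OP1": -0.9, "OP2": -0.9, "O5'": -0.2,
                "O3'": -0.2, "HO5'": 0.2, "HO3'": 0.2}
_SPECIES_CHARGES = {
    # keyed on (residue name, element)
    ("CA", "Ca"): 2.0, ("F", "F"): -1.0,
    ("PO4", "P"): 1.3, ("PO4", "O"): -1.075,
    ("OH", "O"): -1.4, ("OH", "H"): 0.4,
    ("HOH", "O"): -0.834, ("HOH", "H"): 0.417,
}


def assign_charges(s: Structure) -> Structure:
    """Restore partial charges from residue/atom-name context."""
    out = s.copy()
    q = np.zeros(len(s))
    for i in range(len(s)):
        rn = s.residue_name[i]
        nm = s.name[i]
        if rn in _DNA_RESNAMES:
            q[i] = _DNA_CHARGES.get(nm, 0.0)
        else:
            q[i] = _SPECIES_CHARGES.get((rn, s.element[i]), 0.0)
    out.charge = q
    return out


def _chain_of(resname: str) -> str:
    if resname in _DNA_RESNAMES:
        return "A"
    if resname == "HOH":
        return "W"
    if resname == "CA":
        return "I"
    return "M"


def to_atom_array(s: Structure):
    import biotite.structure as struc

    arr = struc.AtomArray(len(s))
    arr.coord = s.coord.astype(np.float32)
    arr.atom_name = s.name
    arr.element = np.char.upper(s.element)
    arr.res_name = s.residue_name
    arr.res_id = s.residue_id + 1 - min(0, int(s.residue_id.min()))
    chains = np.array([_chain_of(r) for r in s.residue_name])
    dna = np.isin(s.residue_name, _DNA_RESNAMES)
    if dna.any():
        mols = np.unique(s.molecule_id[dna])
        for label, m in zip("AB", mols):
            chains[dna & (s.molecule_id == m)] = label
    arr.chain_id = chains
    arr.hetero = ~dna
    if s.lattice is not None:
        arr.box = s.lattice.astype(np.float32)
    elif "box" in s.meta:
        arr.box = np.diag(np.asarray(s.meta["box"], dtype=np.float32))
    return arr


def from_atom_array(arr) -> Structure:
    n = arr.array_length()
    element = np.array([e.capitalize() for e in arr.element])
    chain = arr.chain_id
    mol = np.zeros(n, dtype=int)
    for k, c in enumerate(np.unique(chain)):
        mol[chain == c] = k
    lattice = None
    if arr.box is not None:
        lattice = np.asarray(arr.box, dtype=float)
    s = Structure(
        coord=np.asarray(arr.coord, dtype=float),
        element=element,
        name=arr.atom_name,
        charge=np.zeros(n),
        molecule_id=mol,
        residue_id=np.asarray(arr.res_id, dtype=int),
        residue_name=arr.res_name,
        lattice=lattice,
    )
    return assign_charges(s)


def write_pdb(s: Structure, path):
    from biotite.structure.io import pdb

    f = pdb.PDBFile()
    f.set_structure(to_atom_array(s))
    f.write(str(path))


def read_pdb(path) -> Structure:
    from biotite.structure.io import pdb

    try:
        f = pdb.PDBFile.read(str(path))
        arr = f.get_structure(model=1)
    except Exception as exc:
        raise ParseError(f"cannot parse PDB {path}: {exc}") from exc
    return from_atom_array(arr)


def write_xyz(s: Structure, path, comment: str = ""):
    with open(path, "w") as fh:
        fh.write(f"{len(s)}\n{comment}\n")
        for e, (x, y, z) in zip(s.element, s.coord):
            fh.write(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path) -> Structure:
    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: expected atom count")
    elements, coords = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        tok = line.split()
        if len(tok) < 4:
            raise ParseError(f"{path}:{ln}: malformed XYZ record")
        elements.append(tok[0])
        coords.append([float(v) for v in tok[1:4]])
    if len(coords) != n:
        raise ParseError(f"{path}: expected {n} atoms, found {len(coords)}")
    n = len(coords)
    return Structure(
        coord=np.array(coords), element=np.array(elements),
        name=np.array(elements), charge=np.zeros(n),
        molecule_id=np.zeros(n, dtype=int), residue_id=np.arange(n),
        residue_name=np.array(["UNK"] * n))


def write_xyz_trajectory(traj: Trajectory, path):
    elements = (traj.structure.element if traj.structure is not None
                else np.array(["X"] * traj.n_atoms))
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            box = traj.box_at(f)
            fh.write(f"{traj.n_atoms}\n"
                     f"t= {traj.times[f]:.6f} ps box= "
                     f"{box[0]:.4f} {box[1]:.4f} {box[2]:.4f}\n")
            for e, (x, y, z) in zip(elements, traj.coords[f]):
                fh.write(f"{e:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz_trajectory(path) -> Trajectory:
    frames, times, boxes, elements = [], [], [], None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            break
        n = int(lines[i])
        comment = lines[i + 1].split()
        t = float(comment[1]) if len(comment) > 1 else len(times) + 1.0
        box = [float(v) for v in comment[-3:]] if "box=" in lines[i + 1] \
            else [0.0, 0.0, 0.0]
        block = lines[i + 2:i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        if elements is None:
            elements = [ln.split()[0] for ln in block]
        times.append(t)
        boxes.append(box)
        i += 2 + n
    coords = np.array(frames)
    n = coords.shape[1]
    s = Structure(coord=coords[0], element=np.array(elements),
                  name=np.array(elements), charge=np.zeros(n),
                  molecule_id=np.zeros(n, dtype=int),
                  residue_id=np.arange(n),
                  residue_name=np.array(["UNK"] * n))
    return Trajectory(np.array(times), coords, np.array(boxes[0]),
                      structure=s)


# --------------------------------------------------------------------------
# workflows

@dataclass
class RunConfig:
    workflow: str
    seed: int = 0
    outdir: str = "."
    mineral: str = "hap"
    sequence: str = "CGCGAATTCGCG"
    cells: tuple = (6, 6, 7)
    pore: tuple = (2, 2, 7)
    radii: tuple = (5.0, 10.0, 15.0)
    n_units: float = 1.0
    box: tuple = (14.0, 14.0, 14.0)
    n_steps: int = 500
    minimize_steps: int = 500
    overrides: dict = field(default_factory=dict)


def run_workflow(config: RunConfig) -> dict:
    """Execute a named stage chain and write artifacts plus a manifest."""
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"workflow": config.workflow, "seed": config.seed,
                "version": __version__, "stages": [], "artifacts": {}}

    def record(stage, **info):
        manifest["stages"].append({"name": stage, **info})

    try:
        if config.workflow == "encapsulation":
            _workflow_encapsulation(config, out, manifest, record)
        elif config.workflow == "growth":
            _workflow_growth(config, out, manifest, record)
        elif config.workflow == "nucleation":
            _workflow_nucleation(config, out, manifest, record)
        else:
            raise InputError(f"unknown workflow {config.workflow!r}")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _workflow_encapsulation(cfg, out, manifest, record):
    from .crystal import CrystalSpec, PoreSpec, build_supercell, \
        build_unit_cell, carve_pore
    from .dna import build_canonical_duplex, embed_in_pore, place_counterions
    from .forcefield import build_topology, default_params
    from .minimize import minimize_structure
    from .strain import delta_tau
    from .structure import concat

    spec = CrystalSpec.packaged(cfg.mineral)
    cell = build_unit_cell(spec)
    record("build", atoms=len(cell))
    sc = build_supercell(cell, *cfg.cells)
    carved, pore = carve_pore(sc, PoreSpec(tuple(cfg.pore)))
    record("carve", mineral_atoms=len(carved))
    duplex = build_canonical_duplex(cfg.sequence)
    dna = place_counterions(duplex.structure, "minor_groove",
                            seed=cfg.seed, optimize=False)
    system = embed_in_pore(carved, dna, orientation_seed=cfg.seed)
    record("embed", total_atoms=len(system),
           translations=len(system.meta.get("translation_log", [])))
    dna_mask = np.isin(system.residue_name, _DNA_RESNAMES)
    topo = build_topology(system)
    params = default_params()
    relaxed, trace = minimize_structure(
        system, topo, params, frozen_mask=~dna_mask,
        n_steps=cfg.minimize_steps, cutoff=10.0, switch_start=8.0)
    record("minimize", steps=len(trace) - 1, e_final=float(trace[-1]))
    canon_sys = system.select(dna_mask)
    relax_sys = relaxed.select(dna_mask)
    t_dna = build_topology(canon_sys)
    rep = delta_tau(relax_sys, canon_sys, t_dna, params,
                    label=f"{cfg.mineral.upper()}...{cfg.sequence}")
    manifest["strain_report"] = rep.as_dict()
    write_pdb(relaxed, out / "relaxed.pdb")
    manifest["artifacts"]["relaxed"] = "relaxed.pdb"


def _workflow_growth(cfg, out, manifest, record):
    from .crystal import CrystalSpec
    from .dna import build_canonical_duplex
    from .growth import energy_vs_thickness, find_phosphate_plane, \
        grow_apatite_from_plane

    spec = CrystalSpec.packaged(cfg.mineral)
    duplex = build_canonical_duplex(cfg.sequence).structure
    plane = find_phosphate_plane(duplex, (6.72, 13.75, 120.0),
                                 pair_tol=2.2)
    record("plane", u=plane.u, v=plane.v, gamma=plane.gamma)
    grown = grow_apatite_from_plane(plane, spec, max(cfg.radii),
                                    guest=duplex)
    write_pdb(grown, out / "biomineral.pdb")
    record("grow", atoms=len(grown), net_charge=grown.net_charge)
    prof = energy_vs_thickness(duplex, spec, plane, cfg.radii)
    rows = np.column_stack([prof.radii, prof.e_total, prof.e_elec,
                            prof.e_vdw, prof.n_atoms])
    np.savetxt(out / "profile.csv", rows, delimiter=",", fmt="%.4f",
               header="radius,E_T,E_elec,E_vdw,n_atoms")
    manifest["artifacts"]["profile"] = "profile.csv"
    record("profile", radii=list(map(float, prof.radii)))


def _workflow_nucleation(cfg, out, manifest, record):
    from .nucleation import SimulationParams, build_solution_box, run_langevin
    from .trajectory import compute_rdf, locate_peaks, peaks_to_dict, \
        rdf_to_csv

    sb = build_solution_box(cfg.n_units, cfg.box, seed=cfg.seed)
    record("box", **sb.composition)
    params = SimulationParams(n_steps=cfg.n_steps, seed=cfg.seed,
                              cutoff=min(12.0, min(cfg.box) / 2 - 0.5),
                              switch_start=min(10.0, min(cfg.box) / 2 - 2.0))
    traj = run_langevin(sb, params)
    write_xyz_trajectory(traj, out / "traj.xyz")
    manifest["artifacts"]["trajectory"] = "traj.xyz"
    s = sb.structure
    sel_ca = s.element == "Ca"
    sel_p = (s.residue_name == "PO4") & (s.element == "P")
    rmax = min(10.0, float(min(cfg.box)) / 2 - 0.1)
    curve = compute_rdf(traj, sel_p, sel_ca, r_max=rmax,
                        label_a="P", label_b="Ca")
    rdf_to_csv(curve, out / "rdf_p_ca.csv")
    manifest["rdf_peaks"] = peaks_to_dict(locate_peaks(curve))
    record("rdf", n_frames=traj.n_frames)
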