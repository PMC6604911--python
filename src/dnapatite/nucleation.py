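"""Calcium-phosphate nucleation at a B-DNA template, desk scale.

Builds stoichiometric Ca2+ / PO4^3- / OH- aqueous boxes (hydroxyapatite
stoichiometry: 10 : 6 : 2 per formula unit, net charge zero) with an
optional DNA template at the center, and integrates Langevin dynamics in
the NVT ensemble.  The protocol is a declared scaled-down stand-in for
production-scale nucleation MD: flexible 3-site water instead of rigid
water, a shifted-force Coulomb cutoff instead of Ewald summation, and a
Langevin thermostat instead of weak coupling; the template (DNA) is held
fixed throughout.  These choices preserve the contact-pair structure
(first-shell radial distribution peaks) that the analysis targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, IntegrationError, PackingError
from .forcefield import assign_types, build_topology, default_params
from .structure import Structure, Trajectory, concat

KB = 0.0019872041          # kcal/mol/K
ACC = 418.4                # (kcal/mol/Å) / u -> Å/ps²
WATER_MASS = 18.0153       # u
WATER_NUMBER_DENSITY = 0.033428   # molecules/Å^3 at 1.00 g/cm^3
DISPLACED_VOLUME = 9.0     # Å^3 per solute heavy atom, free-volume estimate

# geometry of the small solution species (Å, deg)
_WATER_OH = 0.9572
_WATER_ANG = 104.52
_PO4_BOND = 1.56
_OH_BOND = 0.96


@dataclass
class SolutionBox:
    structure: Structure
    box: np.ndarray              # (3,) Å
    n_ca: int
    n_po4: int
    n_oh: int
    n_water: int
    dna_atoms: int = 0

    @property
    def composition(self) -> dict:
        return {"Ca": self.n_ca, "PO4": self.n_po4, "OH": self.n_oh,
                "water": self.n_water, "dna_atoms": self.dna_atoms}


@dataclass
class SimulationParams:
    temperature: float = 298.0   # K
    friction: float = 5.0        # ps^-1
    timestep: float = 1.0        # fs
    n_steps: int = 1000
    cutoff: float = 12.0         # Å
    switch_start: float = 10.0   # Å
    seed: int = 0
    save_interval: int = 100     # steps
    relax_steps: int = 200       # steepest-descent steps before dynamics

    def __post_init__(self):
        if self.timestep > 2.0:
            raise InputError("timestep must be <= 2 fs")
        if not self.cutoff > self.switch_start:
            raise InputError("cutoff must exceed switch_start")


def _tetrahedron(bond: float) -> np.ndarray:
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                 dtype=float) / math.sqrt(3.0)
    return v * bond


def _water_template() -> np.ndarray:
    ang = math.radians(_WATER_ANG)
    return np.array([
        [0.0, 0.0, 0.0],
        [_WATER_OH, 0.0, 0.0],
        [_WATER_OH * math.cos(ang), _WATER_OH * math.sin(ang), 0.0],
    ])


def _rand_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def water_count(box, n_solute_heavy: int = 0, density: float = 1.0) -> int:
    """Closed-form water count for a box at the given mass density."""
    v_free = float(np.prod(box)) - DISPLACED_VOLUME * n_solute_heavy
    return int(round(WATER_NUMBER_DENSITY * density * v_free))


def build_solution_box(n_formula_units: float, box,
                       dna: Structure | None = None,
                       water_density: float = 1.0,
                       seed: int = 0,
                       min_dist: float = 1.5) -> SolutionBox:
    """Stoichiometric ion/water box, reproducible under ``seed``.

    Ion counts are (10, 6, 2) x n_formula_units (rounded); the DNA, when
    given, is centered in the box; waters fill the remaining free volume
    to ``water_density``.  No two atoms are closer than ``min_dist`` at
    build time.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    n_ca = int(round(10 * n_formula_units))
    n_po4 = int(round(6 * n_formula_units))
    n_oh = int(round(2 * n_formula_units))

    parts = []
    placed = np.empty((0, 3))
    mol0 = 0
    if dna is not None and len(dna):
        d = dna.copy()
        d.coord = d.coord - d.coord.mean(axis=0) + box / 2.0
        parts.append(d)
        placed = d.coord
        mol0 = int(d.molecule_id.max()) + 1

    # periodic clash checking: a wrapped tree over everything placed so
    # far, plus a linear buffer of recent additions
    state = {"tree": cKDTree(placed % box, boxsize=box) if len(placed)
             else None, "buffer": []}

    def clash_free(pos, thresh):
        w = pos % box
        if state["tree"] is not None:
            if np.min(state["tree"].query(w, k=1)[0]) < thresh:
                return False
        for b in state["buffer"]:
            delta = w[:, None, :] - b[None, :, :]
            delta -= box * np.round(delta / box)
            if np.min(np.linalg.norm(delta, axis=2)) < thresh:
                return False
        return True

    def commit(pos):
        nonlocal placed
        placed = np.vstack([placed, pos])
        state["buffer"].append(pos % box)
        if sum(len(b) for b in state["buffer"]) > 600:
            state["tree"] = cKDTree(placed % box, boxsize=box)
            state["buffer"] = []

    def try_place(template):
        for _ in range(4000):
            origin = rng.uniform(0.0, box)
            rot = _rand_rotation(rng)
            pos = np.atleast_2d(template) @ rot.T + origin
            if clash_free(pos, min_dist + 0.7):
                commit(pos)
                return pos
        raise PackingError("cannot place solute at the clash threshold")

    def species(kind, n, template, elements, names, charges, resname):
        nonlocal mol0
        rows = []
        for k in range(n):
            pos = try_place(template)
            na = len(pos)
            rows.append(Structure(
                coord=pos, element=np.array(elements), name=np.array(names),
                charge=np.array(charges),
                molecule_id=np.full(na, mol0, dtype=int),
                residue_id=np.full(na, mol0, dtype=int),
                residue_name=np.array([resname] * na)))
            mol0 += 1
        return rows

    parts += species("ca", n_ca, np.zeros((1, 3)), ["Ca"], ["CA"], [2.0], "CA")
    tet = np.vstack([[0.0, 0.0, 0.0], _tetrahedron(_PO4_BOND)])
    parts += species("po4", n_po4, tet, ["P", "O", "O", "O", "O"],
                     ["P", "O1", "O2", "O3", "O4"],
                     [1.3, -1.075, -1.075, -1.075, -1.075], "PO4")
    oh = np.array([[0.0, 0.0, 0.0], [_OH_BOND, 0.0, 0.0]])
    parts += species("oh", n_oh, oh, ["O", "H"], ["O", "HO"],
                     [-1.4, 0.4], "OH")

    n_heavy = n_ca + 5 * n_po4 + n_oh
    if dna is not None and len(dna):
        n_heavy += int((dna.element != "H").sum())
    n_water = water_count(box, n_heavy, water_density)

    # waters on a jittered grid with orientation retries
    spacing = (np.prod(box) / max(n_water, 1)) ** (1.0 / 3.0)
    counts = np.maximum(np.ceil(box / spacing * 1.35).astype(int), 1)
    grid = np.stack(np.meshgrid(
        *[(np.arange(c) + 0.5) * b / c for c, b in zip(counts, box)],
        indexing="ij"), axis=-1).reshape(-1, 3)
    rng.shuffle(grid)
    wat = _water_template() - _water_template().mean(axis=0)
    water_rows = []
    for site in grid:
        if len(water_rows) >= n_water:
            break
        jitter = site + rng.normal(0.0, 0.08, 3)
        for _ in range(12):
            pos = wat @ _rand_rotation(rng).T + jitter
            if clash_free(pos, min_dist):
                commit(pos)
                water_rows.append(Structure(
                    coord=pos, element=np.array(["O", "H", "H"]),
                    name=np.array(["O", "H1", "H2"]),
                    charge=np.array([-0.834, 0.417, 0.417]),
                    molecule_id=np.full(3, mol0, dtype=int),
                    residue_id=np.full(3, mol0, dtype=int),
                    residue_name=np.array(["HOH"] * 3)))
                mol0 += 1
                break
    if len(water_rows) < n_water:
        raise PackingError(
            f"placed only {len(water_rows)} of {n_water} waters")
    s = concat(parts + water_rows)
    s.meta["box"] = box
    return SolutionBox(s, box, n_ca, n_po4, n_oh, n_water,
                       dna_atoms=0 if dna is None else len(dna))


# --------------------------------------------------------------------------
# Langevin dynamics

def _try_numba():
    try:
        import numba
        return numba
    except Exception:           # pragma: no cover
        return None


_numba = _try_numba()

if _numba is not None:
    @_numba.njit(cache=False, fastmath=False)
    def _nb_kernel(x, q, rmh, eps, pairs, box, cutoff, sw_start, forces):
        e_vdw = 0.0
        e_el = 0.0
        rc2 = cutoff * cutoff
        ron2 = sw_start * sw_start
        denom = (rc2 - ron2) ** 3
        C = 332.0636
        for k in range(pairs.shape[0]):
            i = pairs[k, 0]
            j = pairs[k, 1]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2 or r2 < 1e-12:
                continue
            r = math.sqrt(r2)
            # switched Lennard-Jones
            rm = rmh[i] + rmh[j]
            ep = math.sqrt(eps[i] * eps[j])
            s6 = (rm * rm / r2) ** 3
            ev = ep * (s6 * s6 - 2.0 * s6)
            dev = ep * (-6.0) * (s6 * s6 - s6) / r2   # dE/dr2
            if r2 > ron2:
                a = rc2 - r2
                b = rc2 + 2.0 * r2 - 3.0 * ron2
                sw = a * a * b / denom
                dsw = (-2.0 * a * b + 2.0 * a * a) / denom
                dev = dev * sw + ev * dsw
                ev = ev * sw
            # shifted-force Coulomb
            qq = C * q[i] * q[j]
            ee = qq * (1.0 / r - 1.0 / cutoff + (r - cutoff) / rc2)
            dee = qq * (-1.0 / r2 + 1.0 / rc2) / (2.0 * r)   # dE/dr2 = E'(r)/2r
            e_vdw += ev
            e_el += ee
            g = 2.0 * (dev + dee)
            forces[i, 0] -= g * dx
            forces[i, 1] -= g * dy
            forces[i, 2] -= g * dz
            forces[j, 0] += g * dx
            forces[j, 1] += g * dy
            forces[j, 2] += g * dz
        return e_vdw, e_el
else:                            # pragma: no cover
    _nb_kernel = None


def _nb_numpy(x, q, rmh, eps, pairs, box, cutoff, sw_start, forces):
    """Vectorized fallback identical to the numba kernel."""
    if len(pairs) == 0:
        return 0.0, 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = x[i] - x[j]
    d -= box * np.round(d / box)
    r2 = np.sum(d * d, axis=1)
    keep = (r2 < cutoff ** 2) & (r2 > 1e-12)
    i, j, d, r2 = i[keep], j[keep], d[keep], r2[keep]
    r = np.sqrt(r2)
    rm = rmh[i] + rmh[j]
    ep = np.sqrt(eps[i] * eps[j])
    s6 = (rm * rm / r2) ** 3
    ev = ep * (s6 * s6 - 2.0 * s6)
    dev = ep * (-6.0) * (s6 * s6 - s6) / r2
    ron2, rc2 = sw_start ** 2, cutoff ** 2
    denom = (rc2 - ron2) ** 3
    mid = r2 > ron2
    a = rc2 - r2[mid]
    b = rc2 + 2.0 * r2[mid] - 3.0 * ron2
    sw = a * a * b / denom
    dsw = (-2.0 * a * b + 2.0 * a * a) / denom
    dev[mid] = dev[mid] * sw + ev[mid] * dsw
    ev[mid] = ev[mid] * sw
    qq = 332.0636 * q[i] * q[j]
    ee = qq * (1.0 / r - 1.0 / cutoff + (r - cutoff) / rc2)
    dee = qq * (-1.0 / r2 + 1.0 / rc2) / (2.0 * r)
    g = (2.0 * (dev + dee))[:, None] * d
    np.add.at(forces, i, -g)
    np.add.at(forces, j, g)
    return float(ev.sum()), float(ee.sum())


class LangevinEngine:
    """NVT Langevin dynamics over a :class:`SolutionBox`-style structure.

    Bonded terms are harmonic bonds and angles (the solution species have
    no torsions; the DNA template is frozen).  Nonbonded terms are
    switched Lennard-Jones plus shifted-force Coulomb under the minimum
    image convention.  Integration is BAOAB; with friction -> 0 it reduces
    to velocity Verlet.
    """

    def __init__(self, structure: Structure, box, params: SimulationParams,
                 frozen_mask: np.ndarray | None = None):
        self.s = structure
        self.box = np.asarray(box, dtype=float)
        self.p = params
        n = len(structure)
        self.frozen = (np.zeros(n, dtype=bool) if frozen_mask is None
                       else np.asarray(frozen_mask, dtype=bool))
        ff = default_params()
        topo = build_topology(structure)
        self.types = topo.types
        self.rmh = np.array([ff.lj_param(t)[0] for t in topo.types])
        self.eps = np.array([ff.lj_param(t)[1] for t in topo.types])
        self.q = structure.charge.copy()
        self.m = structure.masses
        self.bonds = topo.bonds
        self.kb = np.empty(len(topo.bonds))
        self.b0 = np.empty(len(topo.bonds))
        for idx, (i, j) in enumerate(topo.bonds):
            self.kb[idx], self.b0[idx] = ff.bond_param(
                structure.element[i], structure.element[j])
        from .forcefield import angle_equilibrium
        self.angles = topo.angles
        self.ka = np.full(len(topo.angles), ff.angle_k)
        self.th0 = np.deg2rad(angle_equilibrium(topo, structure, ff))
        excl = np.array(sorted(topo.excluded)) if topo.excluded else \
            np.empty((0, 2), dtype=int)
        self._excl_keys = (excl[:, 0].astype(np.int64) * n + excl[:, 1]
                           if len(excl) else np.empty(0, dtype=np.int64))
        self.x = structure.coord.copy()
        self.v = np.zeros_like(self.x)
        self.rng = np.random.default_rng(params.seed)
        self._pairs = None
        self._pairs_age = 10 ** 9
        self._skin = 2.0
        # DNA torsional terms are omitted because the template is frozen;
        # refuse to run if mobile atoms carry torsions
        mobile = ~self.frozen
        for i_, j_, k_, m_ in topo.torsions:
            if mobile[[i_, j_, k_, m_]].any():
                tags = set(structure.residue_name[[i_, j_, k_, m_]])
                if not tags <= {"HOH", "PO4", "OH", "CA"}:
                    raise InputError(
                        "mobile atoms with torsional terms; freeze the "
                        "template for scaled-down nucleation runs")

    def relax(self, n_steps: int = 200, step: float = 0.05):
        """Steepest descent with step clipping, removing build-time clashes."""
        mob = ~self.frozen
        for it in range(n_steps):
            f, _ = self.forces()
            fmax = np.abs(f[mob]).max() if mob.any() else 0.0
            if fmax < 5.0:
                break
            self.x[mob] += f[mob] * (step / max(fmax, 1e-9))
            if it % 5 == 4:
                self._pairs_age = 10 ** 9   # force pair-list rebuild
        self._pairs_age = 10 ** 9

    def init_velocities(self):
        kt = KB * self.p.temperature * ACC
        self.v = self.rng.normal(size=self.x.shape) * \
            np.sqrt(kt / self.m)[:, None]
        self.v[self.frozen] = 0.0
        self._remove_com()

    def _remove_com(self):
        mob = ~self.frozen
        if mob.any():
            mv = (self.v[mob] * self.m[mob, None]).sum(axis=0)
            self.v[mob] -= mv / self.m[mob].sum()

    def _pairlist(self):
        n = len(self.x)
        wrapped = self.x % self.box
        tree = cKDTree(wrapped, boxsize=self.box)
        pairs = tree.query_pairs(self.p.cutoff + self._skin,
                                 output_type="ndarray")
        if len(pairs):
            # frozen-frozen interactions are a constant and carry no force
            both_frozen = self.frozen[pairs[:, 0]] & self.frozen[pairs[:, 1]]
            pairs = pairs[~both_frozen]
        if len(pairs) and len(self._excl_keys):
            keys = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
            pairs = pairs[~np.isin(keys, self._excl_keys)]
        self._pairs = np.ascontiguousarray(pairs.astype(np.int64))
        self._pairs_age = 0

    def forces(self):
        # 2 Å skin and ~0.02 Å/step thermal displacement make a 40-step
        # rebuild cadence safe
        if self._pairs is None or self._pairs_age >= 40:
            self._pairlist()
        f = np.zeros_like(self.x)
        kernel = _nb_kernel if _nb_kernel is not None else _nb_numpy
        e_vdw, e_el = kernel(self.x, self.q, self.rmh, self.eps,
                             self._pairs, self.box,
                             self.p.cutoff, self.p.switch_start, f)
        e_bond = 0.0
        if len(self.bonds):
            i, j = self.bonds[:, 0], self.bonds[:, 1]
            d = self.x[j] - self.x[i]
            b = np.linalg.norm(d, axis=1)
            e_bond += float(np.sum(self.kb * (b - self.b0) ** 2))
            g = (2.0 * self.kb * (b - self.b0) / b)[:, None] * d
            np.add.at(f, i, g)
            np.add.at(f, j, -g)
        if len(self.angles):
            i, j, k = self.angles[:, 0], self.angles[:, 1], self.angles[:, 2]
            u = self.x[i] - self.x[j]
            w = self.x[k] - self.x[j]
            nu = np.linalg.norm(u, axis=1)
            nw = np.linalg.norm(w, axis=1)
            cos_t = np.clip(np.sum(u * w, axis=1) / (nu * nw), -1, 1)
            theta = np.arccos(cos_t)
            e_bond += float(np.sum(self.ka * (theta - self.th0) ** 2))
            sin_t = np.sqrt(np.maximum(1 - cos_t ** 2, 1e-12))
            dE = 2.0 * self.ka * (theta - self.th0)
            fi = (u * cos_t[:, None] / nu[:, None] - w / nw[:, None]) \
                / (nu * sin_t)[:, None]
            fk = (w * cos_t[:, None] / nw[:, None] - u / nu[:, None]) \
                / (nw * sin_t)[:, None]
            np.add.at(f, i, -dE[:, None] * fi)
            np.add.at(f, k, -dE[:, None] * fk)
            np.add.at(f, j, dE[:, None] * (fi + fk))
        f[self.frozen] = 0.0
        self._pairs_age += 1
        return f, e_vdw + e_el + e_bond

    def kinetic_temperature(self) -> float:
        mob = ~self.frozen
        ke = 0.5 * np.sum(self.m[mob, None] * self.v[mob] ** 2) / ACC
        ndof = 3 * int(mob.sum()) - 3
        return float(2.0 * ke / (ndof * KB))

    def run(self, n_steps: int | None = None,
            temperature: float | None = None,
            save_interval: int | None = None):
        """Integrate and return ``(times_ps, frames, temps, energies)``."""
        p = self.p
        n_steps = n_steps if n_steps is not None else p.n_steps
        temp = temperature if temperature is not None else p.temperature
        save = save_interval if save_interval is not None else p.save_interval
        dt = p.timestep * 1e-3             # ps
        gamma = p.friction
        c1 = math.exp(-gamma * dt)
        kt = KB * temp * ACC
        sigma = np.sqrt(kt * (1.0 - c1 * c1) / self.m)[:, None]
        mob = ~self.frozen
        f, e = self.forces()
        frames, times, temps, energies = [], [], [], []
        for step in range(1, n_steps + 1):
            self.v[mob] += 0.5 * dt * ACC * f[mob] / self.m[mob, None]
            self.x[mob] += 0.5 * dt * self.v[mob]
            if gamma > 0:
                noise = self.rng.normal(size=self.x.shape)
                self.v[mob] = c1 * self.v[mob] + sigma[mob] * noise[mob]
            self.x[mob] += 0.5 * dt * self.v[mob]
            f, e = self.forces()
            if not np.isfinite(e) or abs(e) > 1e9:
                raise IntegrationError(f"energy blow-up at step {step}")
            self.v[mob] += 0.5 * dt * ACC * f[mob] / self.m[mob, None]
            if step % save == 0:
                self._remove_com()
                frames.append(self.x.copy())
                times.append(step * dt)
                ke = 0.5 * np.sum(self.m[mob, None] * self.v[mob] ** 2) / ACC
                temps.append(self.kinetic_temperature())
                energies.append(e + ke)
        return (np.array(times), np.array(frames), np.array(temps),
                np.array(energies))


def run_langevin(box: SolutionBox, params: SimulationParams,
                 frozen_mask: np.ndarray | None = None) -> Trajectory:
    """Langevin NVT trajectory of a solution box; frozen atoms never move."""
    eng = LangevinEngine(box.structure, box.box, params, frozen_mask)
    if params.relax_steps:
        eng.relax(params.relax_steps)
    eng.init_velocities()
    times, frames, temps, energies = eng.run()
    if len(frames) == 0:
        raise InputError("no frames saved; lower save_interval")
    traj = Trajectory(times, frames, box.box, structure=box.structure)
    traj_meta = {"temperatures": temps, "energies": energies,
                 "params": params}
    traj.structure.meta["run"] = traj_meta
    return traj


# stage durations of the full-scale protocol (ns): solvent scramble at
# 500 K, thermal and density relaxation of the solvent, steady heating of
# the whole system, thermal equilibration, final relaxation
PROTOCOL_STAGES_NS = (0.5, 0.5, 0.5, 0.15, 0.25, 0.5)
PROTOCOL_TEMPS_K = (500.0, 298.0, 298.0, 298.0, 298.0, 298.0)


def equilibration_protocol(box: SolutionBox, params: SimulationParams,
                           scale: float = 1e-3,
                           frozen_mask: np.ndarray | None = None):
    """Staged schedule scaled by ``scale``; returns (Trajectory, stage log)."""
    eng = LangevinEngine(box.structure, box.box, params, frozen_mask)
    if params.relax_steps:
        eng.relax(params.relax_steps)
    eng.init_velocities()
    all_t, all_x, log = [], [], []
    t_offset = 0.0
    frame_index = 0
    for stage, (ns, temp) in enumerate(zip(PROTOCOL_STAGES_NS,
                                           PROTOCOL_TEMPS_K)):
        n_steps = max(int(round(ns * 1e6 * scale / params.timestep)),
                      params.save_interval)
        times, frames, temps, energies = eng.run(
            n_steps=n_steps, temperature=temp)
        all_t.append(times + t_offset)
        all_x.append(frames)
        log.append({"stage": stage, "target_K": temp,
                    "duration_ps": n_steps * params.timestep * 1e-3,
                    "mean_T": float(np.mean(temps)) if len(temps) else None,
                    "first_frame": frame_index})
        frame_index += len(frames)
        t_offset += n_steps * params.timestep * 1e-3
    traj = Trajectory(np.concatenate(all_t), np.concatenate(all_x),
                      box.box, structure=box.structure)
    traj.structure.meta["protocol_log"] = log
    return traj, log
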