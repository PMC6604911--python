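"""Molecular-mechanics energies and analytic forces.

Functional form: harmonic bonds K(b-b0)^2 and angles K(theta-theta0)^2,
cosine torsions (V/2)(1+cos(n*phi-gamma)), 12-6 Lennard-Jones with
Lorentz-Berthelot combining, and Coulomb electrostatics with
C = 332.0636 kcal Å mol^-1 e^-2.  Nonbonded interactions honor 1-2/1-3
exclusions and scaled 1-4 pairs; in cutoff mode a CHARMM-style switching
function is applied to both Lennard-Jones and Coulomb terms between
``switch_start`` and ``cutoff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError
from .forcefield import (ForceFieldParams, Topology, angle_equilibrium,
                         torsion_class)
from .structure import Structure

COULOMB = 332.0636    # kcal Å / (mol e^2)


@dataclass
class EnergyBreakdown:
    e_str: float = 0.0
    e_bnd: float = 0.0
    e_tor: float = 0.0
    e_vdw: float = 0.0
    e_elec: float = 0.0

    @property
    def total(self) -> float:
        return self.e_str + self.e_bnd + self.e_tor + self.e_vdw + self.e_elec

    def __add__(self, other):
        return EnergyBreakdown(self.e_str + other.e_str,
                               self.e_bnd + other.e_bnd,
                               self.e_tor + other.e_tor,
                               self.e_vdw + other.e_vdw,
                               self.e_elec + other.e_elec)


# --------------------------------------------------------------------------
# parameter expansion (cached per topology object)

def _term_params(s: Structure, t: Topology, p: ForceFieldParams):
    key = "_term_cache"
    cached = getattr(t, key, None)
    if cached is not None:
        return cached
    nb = len(t.bonds)
    kb = np.empty(nb)
    b0 = np.empty(nb)
    for idx, (i, j) in enumerate(t.bonds):
        kb[idx], b0[idx] = p.bond_param(s.element[i], s.element[j])
    th0 = np.deg2rad(angle_equilibrium(t, s, p))
    ka = np.full(len(t.angles), p.angle_k)
    cls = torsion_class(t, s)
    vt = np.array([p.torsions[c][0] for c in cls]) if cls else np.empty(0)
    nt = np.array([p.torsions[c][1] for c in cls]) if cls else np.empty(0)
    gt = np.deg2rad([p.torsions[c][2] for c in cls]) if cls else np.empty(0)
    rmin_h = np.array([p.lj_param(x)[0] for x in t.types])
    eps = np.array([p.lj_param(x)[1] for x in t.types])
    cache = (kb, b0, ka, th0, vt, nt, gt, rmin_h, eps)
    setattr(t, key, cache)
    return cache


# --------------------------------------------------------------------------
# bonded terms

def bonded_energy(s: Structure, t: Topology, p: ForceFieldParams,
                  forces: bool = False):
    """Stretching, bending and torsional energies (nonbonded fields zero)."""
    kb, b0, ka, th0, vt, nt, gt, _, _ = _term_params(s, t, p)
    x = s.coord
    e = EnergyBreakdown()
    g = np.zeros_like(x) if forces else None

    if len(t.bonds):
        i, j = t.bonds[:, 0], t.bonds[:, 1]
        rij = x[j] - x[i]
        b = np.linalg.norm(rij, axis=1)
        e.e_str = float(np.sum(kb * (b - b0) ** 2))
        if forces:
            f = (2.0 * kb * (b - b0) / b)[:, None] * rij
            np.add.at(g, i, -f)
            np.add.at(g, j, f)

    if len(t.angles):
        i, j, k = t.angles[:, 0], t.angles[:, 1], t.angles[:, 2]
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        e.e_bnd = float(np.sum(ka * (theta - th0) ** 2))
        if forces:
            sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-12))
            dE = 2.0 * ka * (theta - th0)
            # dtheta/dri and dtheta/drk
            fi = (u * cos_t[:, None] / nu[:, None] - v / nv[:, None]) \
                / (nu * sin_t)[:, None]
            fk = (v * cos_t[:, None] / nv[:, None] - u / nu[:, None]) \
                / (nv * sin_t)[:, None]
            np.add.at(g, i, dE[:, None] * fi)
            np.add.at(g, k, dE[:, None] * fk)
            np.add.at(g, j, -dE[:, None] * (fi + fk))

    if len(t.torsions):
        i, j, k, m = (t.torsions[:, c] for c in range(4))
        b1 = x[j] - x[i]
        b2 = x[k] - x[j]
        b3 = x[m] - x[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        xx = np.sum(n1 * n2, axis=1)
        yy = np.sum(m1 * n2, axis=1)
        phi = np.arctan2(yy, xx)
        e.e_tor = float(np.sum(0.5 * vt * (1.0 + np.cos(nt * phi - gt))))
        if forces:
            dE = -0.5 * vt * nt * np.sin(nt * phi - gt)
            sn1 = np.sum(n1 * n1, axis=1)
            sn2 = np.sum(n2 * n2, axis=1)
            # dphi/dx for the atan2(m1.n2, n1.n2) sign convention
            dpi = (nb2 / sn1)[:, None] * n1
            dpm = -(nb2 / sn2)[:, None] * n2
            d12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
            d32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
            dpj = -(1.0 + d12) * dpi + d32 * dpm
            dpk = d12 * dpi - (1.0 + d32) * dpm
            np.add.at(g, i, dE[:, None] * dpi)
            np.add.at(g, j, dE[:, None] * dpj)
            np.add.at(g, k, dE[:, None] * dpk)
            np.add.at(g, m, dE[:, None] * dpm)

    return (e, -g) if forces else e


# --------------------------------------------------------------------------
# nonbonded terms

def _switch(r2, r_on2, r_off2):
    """CHARMM switching function and its derivative wrt r^2."""
    sw = np.ones_like(r2)
    dsw = np.zeros_like(r2)
    mid = (r2 > r_on2) & (r2 < r_off2)
    denom = (r_off2 - r_on2) ** 3
    a = r_off2 - r2[mid]
    b = r2[mid] - r_on2
    sw[mid] = a * a * (r_off2 + 2.0 * r2[mid] - 3.0 * r_on2) / denom
    dsw[mid] = (-2.0 * a * (r_off2 + 2.0 * r2[mid] - 3.0 * r_on2)
                + 2.0 * a * a) / denom
    sw[r2 >= r_off2] = 0.0
    return sw, dsw


def _pair_energy(x, q, rmin_h, eps, pairs, scale_e=1.0, scale_lj=1.0,
                 cutoff=None, switch_start=None, forces_out=None):
    """LJ + Coulomb over an explicit (n,2) pair list; returns (evdw, eelec)."""
    if len(pairs) == 0:
        return 0.0, 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    rij = x[j] - x[i]
    r2 = np.sum(rij * rij, axis=1)
    if cutoff is not None:
        keep = r2 < cutoff * cutoff
        i, j, rij, r2 = i[keep], j[keep], rij[keep], r2[keep]
        if len(i) == 0:
            return 0.0, 0.0
    r = np.sqrt(r2)
    rm = rmin_h[i] + rmin_h[j]
    ep = np.sqrt(eps[i] * eps[j])
    s6 = (rm * rm / r2) ** 3
    evdw = ep * (s6 * s6 - 2.0 * s6) / scale_lj
    eelec = COULOMB * q[i] * q[j] / r / scale_e
    if cutoff is not None and switch_start is not None:
        sw, dsw = _switch(r2, switch_start ** 2, cutoff ** 2)
    else:
        sw, dsw = 1.0, 0.0
    if forces_out is not None:
        # dE/dr2 terms
        dvdw = ep * (-6.0 * (s6 * s6 - s6) / r2) / scale_lj
        delec = -0.5 * eelec / r2
        if np.isscalar(sw):
            dtot = dvdw + delec
        else:
            dtot = (dvdw + delec) * sw + (evdw + eelec) * dsw
        # gradient convention: dE/dx_i = -2*dtot*rij (rij = x_j - x_i)
        f = (2.0 * dtot)[:, None] * rij
        np.add.at(forces_out, i, -f)
        np.add.at(forces_out, j, f)
    if not np.isscalar(sw):
        evdw = evdw * sw
        eelec = eelec * sw
    return float(np.sum(evdw)), float(np.sum(eelec))


def _excluded_array(t: Topology):
    if not t.excluded:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(t.excluded))


def nonbonded_energy(s: Structure, t: Topology, p: ForceFieldParams,
                     cutoff: float | None = None,
                     switch_start: float | None = None,
                     forces: bool = False):
    """Lennard-Jones + Coulomb energy (and optionally forces).

    ``cutoff=None`` means exact all-pairs; otherwise pairs beyond ``cutoff``
    are dropped and the switching function rolls both terms to zero from
    ``switch_start``.
    """
    if cutoff is not None and switch_start is not None \
            and not cutoff > switch_start > 0:
        raise InputError("require cutoff > switch_start > 0")
    _, _, _, _, _, _, _, rmin_h, eps = _term_params(s, t, p)
    x, q = s.coord, s.charge
    n = len(s)
    g = np.zeros_like(x) if forces else None
    e = EnergyBreakdown()

    excl = _excluded_array(t)
    if cutoff is None:
        # chunked all-pairs, then remove excluded and rescale 1-4
        block = 2000
        ev = ee = 0.0
        for a0 in range(0, n, block):
            a1 = min(a0 + block, n)
            ii = np.arange(a0, a1)
            # pairs (i in block, j > i)
            for b0 in range(a0, n, block):
                b1 = min(b0 + block, n)
                jj = np.arange(b0, b1)
                I, J = np.meshgrid(ii, jj, indexing="ij")
                mask = I < J
                pr = np.column_stack([I[mask], J[mask]])
                dv, de = _pair_energy(x, q, rmin_h, eps, pr,
                                      forces_out=g)
                ev += dv
                ee += de
        # subtract excluded pairs entirely
        if len(excl):
            gneg = np.zeros_like(x) if forces else None
            dv, de = _pair_energy(x, q, rmin_h, eps, excl, forces_out=gneg)
            ev -= dv
            ee -= de
            if forces:
                g -= gneg
        # rescale 1-4 pairs (full already counted -> subtract the excess)
        if len(t.pairs14):
            gneg = np.zeros_like(x) if forces else None
            dv_f, de_f = _pair_energy(x, q, rmin_h, eps, t.pairs14,
                                      forces_out=gneg)
            dv_s = dv_f / p.scale14_lj
            de_s = de_f / p.scale14_elec
            ev += dv_s - dv_f
            ee += de_s - de_f
            if forces:
                gneg2 = np.zeros_like(x)
                _pair_energy(x, q, rmin_h, eps, t.pairs14,
                             scale_e=p.scale14_elec, scale_lj=p.scale14_lj,
                             forces_out=gneg2)
                g += gneg2 - gneg
        e.e_vdw, e.e_elec = ev, ee
    else:
        tree = cKDTree(x)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            keys = pairs[:, 0] * n + pairs[:, 1]
            bad = set()
            if len(excl):
                bad.update((excl[:, 0] * n + excl[:, 1]).tolist())
            if len(t.pairs14):
                bad.update((t.pairs14[:, 0] * n + t.pairs14[:, 1]).tolist())
            if bad:
                keep = ~np.isin(keys, np.fromiter(bad, dtype=np.int64))
                pairs = pairs[keep]
        ev, ee = _pair_energy(x, q, rmin_h, eps, pairs,
                              cutoff=cutoff, switch_start=switch_start,
                              forces_out=g)
        if len(t.pairs14):
            dv, de = _pair_energy(x, q, rmin_h, eps, t.pairs14,
                                  scale_e=p.scale14_elec,
                                  scale_lj=p.scale14_lj,
                                  cutoff=cutoff, switch_start=switch_start,
                                  forces_out=g)
            ev += dv
            ee += de
        e.e_vdw, e.e_elec = ev, ee
    return (e, -g) if forces else e


def total_energy(s: Structure, t: Topology, p: ForceFieldParams,
                 cutoff: float | None = None,
                 switch_start: float | None = None,
                 forces: bool = False):
    if forces:
        eb, gb = bonded_energy(s, t, p, forces=True)
        en, gn = nonbonded_energy(s, t, p, cutoff, switch_start, forces=True)
        return eb + en, gb + gn
    return bonded_energy(s, t, p) + nonbonded_energy(s, t, p, cutoff,
                                                     switch_start)


def interaction_energy(complex_s: Structure, fragment_mask: np.ndarray,
                       t: Topology | None = None,
                       p: ForceFieldParams | None = None) -> float:
    """ΔE = E(complex) − E(fragment A) − E(fragment B), fixed geometry.

    The mask must bipartition the complex; no cutoff is applied.
    """
    from .forcefield import build_topology, default_params

    mask = np.asarray(fragment_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise InputError("fragment mask must split the complex in two")
    if t is not None and any(mask[i] != mask[j] for i, j in t.bonds):
        raise InputError("fragment mask cuts through a bond")
    p = p or default_params()
    t = t or build_topology(complex_s)
    a = complex_s.select(mask)
    b = complex_s.select(~mask)
    e_ab = total_energy(complex_s, t, p).total
    e_a = total_energy(a, build_topology(a), p).total
    e_b = total_energy(b, build_topology(b), p).total
    return e_ab - e_a - e_b
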