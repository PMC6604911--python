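"""Radial distribution functions and peak analysis over trajectories.

g(r) between two atom selections is the histogram of minimum-image pair
distances normalized by shell volume, partner density and frame count, so
a uniform fluid gives g(r) -> 1.  Peaks are local maxima refined by
parabolic interpolation, characterized by position, height and prominence.
First-shell peak positions diagnose ion pairing and embryonic cluster
formation in the nucleation runs (e.g. DNA-phosphate···Ca2+ contact pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .errors import InputError
from .structure import Structure, Trajectory


@dataclass
class RDFCurve:
    r: np.ndarray            # bin centers Å
    g: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    n_frames: int = 0
    bin_width: float = 0.05


@dataclass
class Peak:
    position: float
    height: float
    prominence: float


@dataclass
class PeakSet:
    peaks: list

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])

    def __len__(self):
        return len(self.peaks)


def select_atoms(s: Structure, residue_name: str | None = None,
                 element: str | None = None,
                 name: str | None = None,
                 molecule_range: tuple | None = None) -> np.ndarray:
    """Boolean mask over atoms by simple attribute filters."""
    mask = np.ones(len(s), dtype=bool)
    if residue_name is not None:
        mask &= s.residue_name == residue_name
    if element is not None:
        mask &= s.element == element
    if name is not None:
        mask &= s.name == name
    if molecule_range is not None:
        lo, hi = molecule_range
        mask &= (s.molecule_id >= lo) & (s.molecule_id < hi)
    return mask


def _min_image_distances(xa, xb, box):
    d = xa[:, None, :] - xb[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=2))


def compute_rdf(traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray,
                r_max: float = 10.0, bin_width: float = 0.05,
                label_a: str = "A", label_b: str = "B") -> RDFCurve:
    """g(r) between two selections with minimum-image convention.

    Selections are boolean masks (or index arrays) over the trajectory's
    atoms; they must be non-empty and either disjoint or identical
    (self-RDF).  ``r_max`` may not exceed half the smallest box edge.
    """
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    if sel_a.dtype == bool:
        ia = np.where(sel_a)[0]
    else:
        ia = sel_a
    if sel_b.dtype == bool:
        ib = np.where(sel_b)[0]
    else:
        ib = sel_b
    if len(ia) == 0 or len(ib) == 0:
        raise InputError("empty selection")
    same = np.array_equal(ia, ib)
    if not same and len(np.intersect1d(ia, ib)):
        raise InputError("selections must be disjoint or identical")
    box0 = traj.box_at(0)
    if r_max > box0.min() / 2.0 + 1e-9:
        raise InputError("r_max exceeds half the minimum box edge")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for f in range(traj.n_frames):
        box = traj.box_at(f)
        x = traj.coords[f]
        d = _min_image_distances(x[ia], x[ib], box)
        if same:
            iu = np.triu_indices(len(ia), k=1)
            vals = d[iu]
            hist += 2.0 * np.histogram(vals, bins=edges)[0]
        else:
            hist += np.histogram(d.ravel(), bins=edges)[0]
    volume = float(np.prod(box0))
    rho_b = len(ib) / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * len(ia) * rho_b * shell
    g = hist / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFCurve(centers, g, label_a, label_b, traj.n_frames, bin_width)


def locate_peaks(curve: RDFCurve, min_prominence: float = 0.1) -> PeakSet:
    """Local maxima above a prominence threshold, parabolically refined."""
    if len(curve.g) == 0:
        return PeakSet([])
    idx, _ = find_peaks(curve.g, prominence=min_prominence)
    proms = peak_prominences(curve.g, idx)[0] if len(idx) else []
    peaks = []
    for k, i in enumerate(idx):
        if 0 < i < len(curve.g) - 1:
            y0, y1, y2 = curve.g[i - 1:i + 2]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            pos = curve.r[i] + shift * curve.bin_width
        else:
            pos = curve.r[i]
        peaks.append(Peak(float(pos), float(curve.g[i]), float(proms[k])))
    peaks.sort(key=lambda p: p.position)
    return PeakSet(peaks)


def coordination_count(traj: Trajectory, sel_a, sel_b,
                       r_shell: float) -> float:
    """Mean number of B atoms within ``r_shell`` of each A atom."""
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    ia = np.where(sel_a)[0] if sel_a.dtype == bool else sel_a
    ib = np.where(sel_b)[0] if sel_b.dtype == bool else sel_b
    if len(ia) == 0:
        raise InputError("empty A selection")
    if len(ib) == 0:
        return 0.0
    total = 0.0
    for f in range(traj.n_frames):
        box = traj.box_at(f)
        d = _min_image_distances(traj.coords[f][ia], traj.coords[f][ib], box)
        np.fill_diagonal(d, np.inf) if np.array_equal(ia, ib) else None
        total += float((d <= r_shell).sum())
    return total / (traj.n_frames * len(ia))


def rdf_to_csv(curve: RDFCurve, path):
    header = f"r_angstrom,g_r  # {curve.label_a}...{curve.label_b}, " \
             f"{curve.n_frames} frames"
    np.savetxt(path, np.column_stack([curve.r, curve.g]), fmt="%.6f",
               delimiter=",", header=header)


def peaks_to_dict(ps: PeakSet) -> list:
    return [{"position": p.position, "height": p.height,
             "prominence": p.prominence} for p in ps.peaks]
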