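"""Steepest-descent energy minimization with positional freezing.

The step rule is plain steepest descent along the force direction with
backtracking step halving: a trial step that raises the energy is rejected
and the step size halved; an accepted step grows the step size slightly.
Frozen atoms contribute to the energy and exert forces but never move —
the mode used throughout the encapsulation workflows, where the mineral is
kept at its crystallographic coordinates.
"""

from __future__ import annotations

import numpy as np

from .errors import MinimizationError
from .energy import total_energy
from .forcefield import ForceFieldParams, Topology
from .structure import Structure


def minimize_structure(s: Structure, t: Topology, p: ForceFieldParams,
                       frozen_mask: np.ndarray | None = None,
                       n_steps: int = 5000, step_size: float = 0.01,
                       cutoff: float | None = None,
                       switch_start: float | None = None,
                       f_tol: float = 1e-6):
    """Minimize and return ``(structure, energy_trace)``.

    ``energy_trace`` holds the energy after every accepted step (the first
    entry is the starting energy); it is non-increasing by construction.
    """
    frozen = (np.zeros(len(s), dtype=bool) if frozen_mask is None
              else np.asarray(frozen_mask, dtype=bool))
    x = s.coord.copy()
    work = s.with_coord(x)
    e, f = total_energy(work, t, p, cutoff, switch_start, forces=True)
    if not np.isfinite(e.total):
        raise MinimizationError("starting energy is not finite")
    f[frozen] = 0.0
    trace = [e.total]
    h = step_size
    for _ in range(n_steps):
        fmax = np.abs(f).max()
        if fmax < f_tol:
            break
        direction = f / fmax            # normalized so h is in Å
        x_new = x + h * direction
        work = work.with_coord(x_new)
        e_new, f_new = total_energy(work, t, p, cutoff, switch_start,
                                    forces=True)
        if not np.isfinite(e_new.total):
            raise MinimizationError("energy diverged during minimization")
        if e_new.total <= trace[-1]:
            x = x_new
            f_new[frozen] = 0.0
            f = f_new
            trace.append(e_new.total)
            h = min(h * 1.2, 1.0)
        else:
            h *= 0.5
            if h < 1e-9:
                break
    out = s.with_coord(x)
    return out, np.array(trace)
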