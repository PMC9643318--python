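"""Binding-constant thermodynamics and trajectory statistics.

``ki_from_energy`` converts a docking binding energy (kcal/mol) into the
inhibition constant Ki = exp(dG / RT).  The trajectory utilities compute the
dynamic cross-correlation matrix (dot-product convention, frames equally
weighted), RMSD against a reference frame (inputs assumed pre-aligned; no
optimal superposition), per-particle RMSF, and the mass-weighted radius of
gyration.  Coordinates are in nm.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

#: Gas constant in kcal/(mol*K).
R_KCAL_PER_MOL_K = 1.9872e-3


def ki_from_energy(delta_g: float, temperature: float = 298.15) -> float:
    """Inhibition constant (molar) from binding energy (kcal/mol)."""
    if not math.isfinite(delta_g):
        raise ValueError("binding energy must be finite")
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return math.exp(delta_g / (R_KCAL_PER_MOL_K * temperature))


def ki_nm(delta_g: float, temperature: float = 298.15) -> float:
    """Ki in nanomolar."""
    return ki_from_energy(delta_g, temperature) * 1e9


def _as_trajectory(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 3 or t.shape[2] != 3:
        raise ValueError("trajectory must have shape (frames, particles, 3)")
    return t


def dccm(t: np.ndarray, particle_ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """Dynamic cross-correlation matrix of particle displacements.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the deviation
    from the per-particle time mean, averaged over frames.
    """
    t = _as_trajectory(t)
    n_frames, n_particles, _ = t.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    dev = t - t.mean(axis=0, keepdims=True)
    # cov[i, j] = mean over frames of dot(dev_i, dev_j)
    cov = np.einsum("fik,fjk->ij", dev, dev) / n_frames
    var = np.diag(cov)
    zero = np.flatnonzero(var <= 0)
    if zero.size:
        names = (
            [str(particle_ids[i]) for i in zero]
            if particle_ids is not None
            else [str(i) for i in zero]
        )
        raise ValueError(f"zero displacement variance for particle(s): {', '.join(names)}")
    c = cov / np.sqrt(np.outer(var, var))
    return np.clip(c, -1.0, 1.0)


def rmsd(frame: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square deviation between two frames (no superposition)."""
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("frame and reference must both be (particles, 3)")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsf(t: np.ndarray) -> np.ndarray:
    """Per-particle root-mean-square fluctuation about the time mean."""
    t = _as_trajectory(t)
    if t.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    dev = t - t.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def radius_of_gyration(
    frame: np.ndarray, masses: Optional[Sequence[float]] = None
) -> float:
    """Mass-weighted radius of gyration of one frame (uniform masses default)."""
    x = np.asarray(frame, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("frame must be (particles, 3)")
    if masses is None:
        m = np.ones(x.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (x.shape[0],) or np.any(m <= 0):
            raise ValueError("masses must be positive, one per particle")
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((x - com) ** 2, axis=1)).sum() / m.sum()))
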