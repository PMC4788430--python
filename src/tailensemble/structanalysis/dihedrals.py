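"""Backbone phi/psi dihedrals and a dihedral-window helix assignment.

The helix rule is a documented stand-in for hydrogen-bond-based
secondary-structure assignment: a residue is helical in a frame when its
(phi, psi) falls inside the helical window AND it belongs to a run of at
least ``min_run`` consecutive in-window residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..model_builder import Structure


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def backbone_dihedrals(structure: Structure, chain: str,
                       residue_range: tuple[int, int]) -> dict[int, tuple[float, float]]:
    """Per-residue (phi, psi) in degrees; missing angles are NaN.

    Terminal residues (or residues with missing N/CA/C neighbors) yield
    NaN for the affected angle rather than raising.
    """
    lo, hi = residue_range
    backbone: dict[int, dict[str, np.ndarray]] = {}
    coords = structure.coords
    for i, atom in enumerate(structure.atoms):
        if atom.chain_id == chain and atom.name in ("N", "CA", "C"):
            backbone.setdefault(atom.resseq, {})[atom.name] = coords[i]
    out: dict[int, tuple[float, float]] = {}
    for res in range(lo, hi + 1):
        cur = backbone.get(res, {})
        prev = backbone.get(res - 1, {})
        nxt = backbone.get(res + 1, {})
        phi = math.nan
        psi = math.nan
        if all(k in cur for k in ("N", "CA", "C")):
            if "C" in prev:
                phi = dihedral_angle(prev["C"], cur["N"], cur["CA"], cur["C"])
            if "N" in nxt:
                psi = dihedral_angle(cur["N"], cur["CA"], cur["C"], nxt["N"])
        out[res] = (phi, psi)
    return out


@dataclass(frozen=True)
class HelixWindow:
    phi_min: float = -100.0
    phi_max: float = -30.0
    psi_min: float = -80.0
    psi_max: float = -5.0
    min_run: int = 4


def helix_flags(phi: np.ndarray, psi: np.ndarray,
                window: HelixWindow | None = None) -> np.ndarray:
    """Boolean helix assignment for one frame of per-residue (phi, psi)."""
    window = window or HelixWindow()
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    in_window = (
        (phi >= window.phi_min) & (phi <= window.phi_max)
        & (psi >= window.psi_min) & (psi <= window.psi_max)
    )
    in_window &= np.isfinite(phi) & np.isfinite(psi)
    flags = np.zeros_like(in_window)
    n = len(in_window)
    i = 0
    while i < n:
        if in_window[i]:
            j = i
            while j < n and in_window[j]:
                j += 1
            if j - i >= window.min_run:
                flags[i:j] = True
            i = j
        else:
            i += 1
    return flags


def helix_content(phi_frames: np.ndarray, psi_frames: np.ndarray,
                  weights: np.ndarray | None = None,
                  window: HelixWindow | None = None) -> np.ndarray:
    """Weighted per-residue helix ratio over an ensemble of frames.

    ``phi_frames``/``psi_frames`` have shape (n_frames, n_residues);
    weights default to uniform and are normalized internally.
    """
    phi_frames = np.atleast_2d(np.asarray(phi_frames, dtype=float))
    psi_frames = np.atleast_2d(np.asarray(psi_frames, dtype=float))
    n_frames = len(phi_frames)
    if weights is None:
        weights = np.full(n_frames, 1.0 / n_frames)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    ratio = np.zeros(phi_frames.shape[1])
    for k in range(n_frames):
        ratio += weights[k] * helix_flags(phi_frames[k], psi_frames[k], window)
    return ratio
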