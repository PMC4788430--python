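"""Radius of gyration and least-squares rigid superposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the mass-weighted centroid (A)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise ValueError("need at least one point")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    center = (masses[:, None] * coords).sum(axis=0) / total
    d2 = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * d2) / total))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal rotation + translation mapping ``mobile`` onto ``reference``.

    A proper rotation (det = +1) is enforced.  Degenerate (collinear)
    point sets are rejected because the rotation about the line axis is
    then unconstrained.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape or len(mobile) < 3:
        raise ValueError("point sets must have equal shape with >= 3 points")
    if weights is None:
        weights = np.ones(len(mobile))
    weights = np.asarray(weights, dtype=float)
    w = weights / weights.sum()

    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    a = mobile - mc
    b = reference - rc
    h = (w[:, None] * a).T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set; superposition is ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    moved = (rotation @ mobile.T).T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return (result.rotation @ coords.T).T + result.translation
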