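"""Solvent-accessible surface area (Shrake-Rupley) and contact surface area.

Per-atom SASA is computed by rolling a probe over each atom's expanded
sphere, discretized with a deterministic golden-spiral point set.  CSA
between two groups is the SASA the second group loses when the first is
present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..model_builder import AtomSelection, Structure

#: Default heavy-atom radii (A); phosphorus uses the "phosphate" radius.
DEFAULT_RADII: dict[str, float] = {"C": 1.7, "N": 1.625, "O": 1.48, "P": 1.87}

PROBE_RADIUS = 1.4


@dataclass(frozen=True)
class SASAParams:
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    probe_radius: float = PROBE_RADIUS
    n_sphere_points: int = 960
    exclude_hydrogens: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.probe_radius <= 0:
            raise ValueError("radii and probe radius must be positive")
        if self.n_sphere_points < 8:
            raise ValueError("n_sphere_points must be >= 8")


class UnknownElementError(ValueError):
    """An atom's element has no radius in the parameter map."""

    def __init__(self, atoms: list[str]):
        super().__init__(
            "no radius for atoms: " + ", ".join(atoms[:10])
            + ("..." if len(atoms) > 10 else "")
        )
        self.atoms = atoms


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(coords: np.ndarray, radii: np.ndarray,
         params: SASAParams | None = None,
         compute_indices: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible areas (A^2).

    All atoms act as occluders; areas are evaluated only for
    ``compute_indices`` (default: all), returned in that order.
    """
    params = params or SASAParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = len(coords)
    if compute_indices is None:
        compute_indices = np.arange(n)
    probe = params.probe_radius
    expanded = radii + probe
    pts = sphere_points(params.n_sphere_points)

    tree = cKDTree(coords)
    areas = np.empty(len(compute_indices))
    for out_k, i in enumerate(compute_indices):
        r_i = expanded[i]
        neigh = tree.query_ball_point(coords[i], r_i + expanded.max())
        neigh = [j for j in neigh if j != i]
        if neigh:
            nb = np.asarray(neigh)
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            keep = d < r_i + expanded[nb]
            nb = nb[keep]
        else:
            nb = np.empty(0, dtype=int)
        if len(nb) == 0:
            areas[out_k] = 4.0 * np.pi * r_i * r_i
            continue
        surf = coords[i] + r_i * pts  # (P, 3)
        diff = surf[:, None, :] - coords[nb][None, :, :]
        d2 = np.einsum("pkd,pkd->pk", diff, diff)
        buried = np.any(d2 < (expanded[nb] ** 2)[None, :], axis=1)
        frac = 1.0 - buried.mean()
        areas[out_k] = 4.0 * np.pi * r_i * r_i * frac
    return areas


def _structure_arrays(structure: Structure, selection: AtomSelection | np.ndarray,
                      params: SASAParams) -> tuple[np.ndarray, np.ndarray]:
    idx = selection.indices if isinstance(selection, AtomSelection) else np.asarray(selection)
    elements = structure.elements()
    if params.exclude_hydrogens:
        idx = idx[elements[idx] != "H"]
    unknown = [f"{structure.atoms[i].name}({elements[i]})" for i in idx
               if elements[i] not in params.radii]
    if unknown:
        raise UnknownElementError(unknown)
    radii = np.array([params.radii[elements[i]] for i in idx])
    return idx, radii


def sasa_structure(structure: Structure, selection: AtomSelection | np.ndarray,
                   params: SASAParams | None = None,
                   context: AtomSelection | np.ndarray | None = None) -> float:
    """Total SASA (A^2) of the selected atoms within an occluding context.

    ``context`` defaults to the whole structure; hydrogens are dropped when
    the parameters say so.
    """
    params = params or SASAParams()
    if context is None:
        context = np.arange(structure.n_atoms)
    ctx_idx, ctx_radii = _structure_arrays(structure, context, params)
    sel_idx, _ = _structure_arrays(structure, selection, params)
    pos_in_ctx = {atom: k for k, atom in enumerate(ctx_idx)}
    missing = [i for i in sel_idx if i not in pos_in_ctx]
    if missing:
        raise ValueError("selection atoms missing from the context")
    compute = np.array([pos_in_ctx[i] for i in sel_idx], dtype=int)
    areas = sasa(structure.coords[ctx_idx], ctx_radii, params, compute_indices=compute)
    return float(areas.sum())


def csa(structure: Structure, tail_selection: AtomSelection,
        dna_selection: AtomSelection, params: SASAParams | None = None,
        full_context: bool = True) -> float:
    """Contact surface area: DNA SASA lost due to the tail's presence.

    Both SASA evaluations keep every non-tail atom when ``full_context`` is
    true (the default); otherwise only tail + DNA atoms enter.
    """
    params = params or SASAParams()
    tail = set(tail_selection.indices.tolist())
    dna = set(dna_selection.indices.tolist())
    if not tail or not dna:
        raise ValueError("tail and DNA selections must be non-empty")
    if tail & dna:
        raise ValueError("tail and DNA selections must be disjoint")
    if full_context:
        with_tail = np.arange(structure.n_atoms)
        without_tail = np.array([i for i in range(structure.n_atoms) if i not in tail])
    else:
        with_tail = np.array(sorted(tail | dna))
        without_tail = np.array(sorted(dna))
    a_without = sasa_structure(structure, dna_selection.indices, params, context=without_tail)
    a_with = sasa_structure(structure, dna_selection.indices, params, context=with_tail)
    return a_without - a_with


def csa_coords(coords: np.ndarray, radii: np.ndarray, tail_idx: np.ndarray,
               dna_idx: np.ndarray, params: SASAParams | None = None,
               context_idx: np.ndarray | None = None) -> float:
    """CSA on raw coordinate/radius arrays (coarse-grained path).

    ``context_idx`` lists additional occluding atoms present in both
    evaluations (default: everything outside the tail).
    """
    params = params or SASAParams()
    tail_idx = np.asarray(tail_idx, dtype=int)
    dna_idx = np.asarray(dna_idx, dtype=int)
    if len(tail_idx) == 0 or len(dna_idx) == 0:
        raise ValueError("tail and DNA index sets must be non-empty")
    if np.intersect1d(tail_idx, dna_idx).size:
        raise ValueError("tail and DNA index sets must be disjoint")
    n = len(coords)
    if context_idx is None:
        context_idx = np.setdiff1d(np.arange(n), tail_idx)
    without = np.asarray(sorted(set(context_idx.tolist()) | set(dna_idx.tolist())), dtype=int)
    with_tail = np.asarray(sorted(set(without.tolist()) | set(tail_idx.tolist())), dtype=int)

    def total(ctx: np.ndarray) -> float:
        pos = {a: k for k, a in enumerate(ctx)}
        compute = np.array([pos[a] for a in dna_idx], dtype=int)
        return float(sasa(coords[ctx], radii[ctx], params, compute_indices=compute).sum())

    return total(without) - total(with_tail)
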