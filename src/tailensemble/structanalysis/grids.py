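"""Weighted 3D occupancy grids and difference maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch_superpose, apply_superposition


@dataclass
class DensityGrid:
    """Regular voxel grid of weighted occupancy counts.

    Out-of-bounds hits accumulate in ``overflow`` (a warning is emitted).
    Difference grids may hold negative values.
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray  # 3D
    overflow: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3D array")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> "DensityGrid":
        total = self.total
        if total == 0:
            raise ValueError("cannot normalize an empty grid")
        return DensityGrid(self.origin, self.spacing, self.counts / total, self.overflow)

    # -- text serialization (documented voxel-map format) --------------------

    def to_text(self) -> str:
        nx, ny, nz = self.counts.shape
        lines = [
            "# tailensemble voxel map format 1",
            f"origin {self.origin[0]:.6g} {self.origin[1]:.6g} {self.origin[2]:.6g}",
            f"spacing {self.spacing:.6g}",
            f"shape {nx} {ny} {nz}",
            f"overflow {self.overflow:.10g}",
        ]
        flat = self.counts.ravel()
        nz_idx = np.flatnonzero(flat)
        for i in nz_idx:
            lines.append(f"{i} {flat[i]:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DensityGrid":
        origin = spacing = shape = None
        overflow = 0.0
        entries = []
        for ln in text.splitlines():
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if parts[0] == "origin":
                origin = [float(x) for x in parts[1:4]]
            elif parts[0] == "spacing":
                spacing = float(parts[1])
            elif parts[0] == "shape":
                shape = tuple(int(x) for x in parts[1:4])
            elif parts[0] == "overflow":
                overflow = float(parts[1])
            else:
                entries.append((int(parts[0]), float(parts[1])))
        counts = np.zeros(int(np.prod(shape)))
        for i, v in entries:
            counts[i] = v
        return cls(np.asarray(origin), spacing, counts.reshape(shape), overflow)

    def export_dx(self, path) -> None:
        """OpenDX volumetric export for visualization tools."""
        nx, ny, nz = self.counts.shape
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {self.origin[0]:.6f} {self.origin[1]:.6f} {self.origin[2]:.6f}\n")
            fh.write(f"delta {self.spacing:.6f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.6f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
            flat = self.counts.ravel()
            for k in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[k:k + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')


def density_grid(frames: np.ndarray, weights: np.ndarray, sel_idx: np.ndarray,
                 origin, spacing: float, shape: tuple[int, int, int],
                 alignment: tuple[np.ndarray, np.ndarray] | None = None) -> DensityGrid:
    """Weighted voxel occupancy of selected atoms over an ensemble.

    ``alignment`` is an optional (reference_coords, core_indices) pair:
    each frame is rigidly superposed onto the reference using the core
    atoms before counting.  The grid total plus overflow equals
    sum(frame weight * selected atom count).
    """
    frames = np.asarray(frames, dtype=float)
    weights = np.asarray(weights, dtype=float)
    sel_idx = np.asarray(sel_idx, dtype=int)
    origin = np.asarray(origin, dtype=float).reshape(3)
    counts = np.zeros(shape)
    overflow = 0.0
    for f in range(len(frames)):
        coords = frames[f]
        if alignment is not None:
            ref, core = alignment
            sup = kabsch_superpose(coords[core], ref[np.asarray(core, dtype=int)]
                                   if len(ref) == frames.shape[1] else ref)
            coords = apply_superposition(coords, sup)
        voxels = np.floor((coords[sel_idx] - origin) / spacing).astype(int)
        inside = np.all((voxels >= 0) & (voxels < np.array(shape)), axis=1)
        n_out = int(np.sum(~inside))
        if n_out:
            overflow += weights[f] * n_out
        v = voxels[inside]
        np.add.at(counts, (v[:, 0], v[:, 1], v[:, 2]), weights[f])
    if overflow > 0:
        warnings.warn(f"{overflow:.4g} weighted counts fell outside the grid",
                      stacklevel=2)
    return DensityGrid(origin=origin, spacing=spacing, counts=counts, overflow=overflow)


def density_difference(grid_a: DensityGrid, grid_b: DensityGrid) -> DensityGrid:
    """Voxelwise difference of unit-normalized grids (positive = preferred in a)."""
    if grid_a.counts.shape != grid_b.counts.shape:
        raise ValueError("grids must have identical shapes")
    if not np.allclose(grid_a.origin, grid_b.origin) or grid_a.spacing != grid_b.spacing:
        raise ValueError("grids must share origin and spacing")
    a = grid_a.normalized()
    b = grid_b.normalized()
    return DensityGrid(grid_a.origin, grid_a.spacing, a.counts - b.counts)
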