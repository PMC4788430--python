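"""Per-frame observables on coarse-grained trajectories and their TTP summaries."""

from __future__ import annotations

import numpy as np

from .alsd import Trajectory
from .ensemble import SummaryStat, WeightedEnsemble, ttp_summary
from .model_builder import CGSystem
from .structanalysis import SASAParams, csa_coords, radius_of_gyration


def frame_csa(system: CGSystem, frames: np.ndarray,
              params: SASAParams | None = None) -> np.ndarray:
    """CSA (scaffold area buried by the tail) for every frame."""
    params = params or SASAParams()
    tail = system.tail_indices
    rest = system.rest_indices
    out = np.empty(len(frames))
    for f in range(len(frames)):
        out[f] = csa_coords(frames[f], system.radii, tail, rest, params)
    return out


def frame_rg(frames: np.ndarray, indices: np.ndarray,
             masses: np.ndarray | None = None) -> np.ndarray:
    """Radius of gyration of the indexed beads for every frame."""
    indices = np.asarray(indices, dtype=int)
    out = np.empty(len(frames))
    for f in range(len(frames)):
        out[f] = radius_of_gyration(frames[f, indices], masses)
    return out


def reweighted_mean(ensemble: WeightedEnsemble, per_frame_values: np.ndarray) -> float:
    return ensemble.mean(per_frame_values)


def ttp_observable(system: CGSystem, ensembles: list[WeightedEnsemble],
                   observable: str, params: SASAParams | None = None,
                   stride: int = 1) -> tuple[SummaryStat, list[float]]:
    """Reweighted per-run means and their TTP summary for a named observable.

    ``observable`` is "csa" or "rg".  ``stride`` thins frames (with weight
    renormalization) to bound the SASA cost of the CSA path.
    """
    per_run: list[float] = []
    for ens in ensembles:
        frames = ens.trajectory.positions[::stride]
        weights = ens.weights[::stride]
        weights = weights / weights.sum()
        if observable == "csa":
            vals = frame_csa(system, frames, params)
        elif observable == "rg":
            vals = frame_rg(frames, system.tail_indices)
        else:
            raise ValueError(f"unknown observable {observable!r}")
        per_run.append(float(np.sum(weights * vals)))
    return ttp_summary(per_run), per_run


def run_ensembles(trajectories: list[Trajectory], bias, config) -> list[WeightedEnsemble]:
    from .ensemble import reweight

    return [reweight(t, bias, config) for t in trajectories]
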