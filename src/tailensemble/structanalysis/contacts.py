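"""Contact statistics: per-position contact, burial-based contact ratio,
solvent-exposure ratio and site-site distances.

All functions operate on one run (a frame stack plus normalized frame
weights) and return run-level scalars or arrays; cross-run means and
standard errors are taken with :func:`tailensemble.ensemble.ttp_summary`.
"""

from __future__ import annotations

import numpy as np

from .sasa import SASAParams, sasa

#: Extra pair-distance allowance (one water diameter, A) in contact checks.
CONTACT_PAD = 2.8

#: Buried-area threshold (A^2) above discretization noise for contact_ratio.
BURIAL_THRESHOLD = 0.1


def weighted_contact_fraction(contact_flags: np.ndarray, weights: np.ndarray) -> float:
    """Weighted fraction of frames flagged as in contact."""
    flags = np.asarray(contact_flags, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * flags) / weights.sum())


def per_position_contact(frames: np.ndarray, weights: np.ndarray,
                         tail_idx: np.ndarray, position_groups: list[np.ndarray],
                         radii: np.ndarray, pad: float = CONTACT_PAD) -> np.ndarray:
    """Weighted probability that any tail bead touches each position group.

    Contact: center distance <= r_i + r_j + pad for any (tail, group) pair.
    Returns one probability per position group.
    """
    frames = np.asarray(frames, dtype=float)
    weights = np.asarray(weights, dtype=float)
    tail_idx = np.asarray(tail_idx, dtype=int)
    radii = np.asarray(radii, dtype=float)
    out = np.empty(len(position_groups))
    for g, group in enumerate(position_groups):
        group = np.asarray(group, dtype=int)
        if len(group) == 0:
            raise ValueError(f"position group {g} is empty")
        cut = radii[tail_idx][:, None] + radii[group][None, :] + pad
        flags = np.empty(len(frames), dtype=bool)
        for f in range(len(frames)):
            d = np.linalg.norm(frames[f, tail_idx][:, None, :]
                               - frames[f, group][None, :, :], axis=2)
            flags[f] = bool(np.any(d <= cut))
        out[g] = weighted_contact_fraction(flags, weights)
    return out


def contact_ratio(frames: np.ndarray, weights: np.ndarray,
                  terminal_idx: int, dna_idx: np.ndarray, radii: np.ndarray,
                  params: SASAParams | None = None,
                  context_idx: np.ndarray | None = None,
                  threshold: float = BURIAL_THRESHOLD) -> float:
    """Weighted fraction of frames where the terminal atom is buried by DNA.

    Burial against DNA = (terminal SASA without the DNA group present)
    minus (with it present), both within the remaining context; a frame
    counts as contact when the burial exceeds ``threshold``.
    """
    params = params or SASAParams()
    frames = np.asarray(frames, dtype=float)
    weights = np.asarray(weights, dtype=float)
    dna_idx = np.asarray(dna_idx, dtype=int)
    n = frames.shape[1]
    if context_idx is None:
        context_idx = np.setdiff1d(np.arange(n), dna_idx)
    context_idx = np.asarray(context_idx, dtype=int)
    if terminal_idx not in context_idx:
        raise ValueError("terminal atom must be part of the non-DNA context")
    with_dna = np.concatenate([context_idx, dna_idx])

    def term_area(f: int, ctx: np.ndarray) -> float:
        where = int(np.flatnonzero(ctx == terminal_idx)[0])
        return float(sasa(frames[f, ctx], radii[ctx], params,
                          compute_indices=np.array([where]))[0])

    flags = np.empty(len(frames), dtype=bool)
    for f in range(len(frames)):
        burial = term_area(f, context_idx) - term_area(f, with_dna)
        flags[f] = burial > threshold
    return weighted_contact_fraction(flags, weights)


def exposure_ratio(frames: np.ndarray, weights: np.ndarray,
                   terminal_idx: int, radii: np.ndarray,
                   reference_area: float,
                   params: SASAParams | None = None,
                   context_idx: np.ndarray | None = None) -> tuple[float, bool]:
    """Weighted mean of terminal-atom SASA relative to an extended reference.

    ``reference_area`` is the terminal atom's SASA in the fully extended
    reference conformation.  Returns (ratio, exceeded_unity_flag); ratios
    above 1 are reported as-is but flagged.
    """
    params = params or SASAParams()
    if reference_area <= 0:
        raise ValueError("reference SASA must be positive")
    frames = np.asarray(frames, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = frames.shape[1]
    if context_idx is None:
        context_idx = np.arange(n)
    context_idx = np.asarray(context_idx, dtype=int)
    where = int(np.flatnonzero(context_idx == terminal_idx)[0])
    vals = np.empty(len(frames))
    for f in range(len(frames)):
        vals[f] = sasa(frames[f, context_idx], radii[context_idx], params,
                       compute_indices=np.array([where]))[0]
    ratios = vals / reference_area
    mean = float(np.sum(weights * ratios) / weights.sum())
    return mean, bool(np.any(ratios > 1.0 + 1e-9))


def pair_distance_distribution(frames: np.ndarray, weights: np.ndarray,
                               site_pairs: list[tuple[int, int]],
                               bins: int | np.ndarray = 30):
    """Weighted distance histograms and means for the listed site pairs.

    Returns (means, histograms, edges_list): one weighted mean and one
    normalized histogram per pair.  Standard errors across runs come from
    combining per-run means with :func:`tailensemble.ensemble.ttp_summary`.
    """
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    d = pair_distances(frames, site_pairs)
    means = (weights[:, None] * d).sum(axis=0)
    histograms = []
    edges_list = []
    for k in range(d.shape[1]):
        h, edges = np.histogram(d[:, k], bins=bins, weights=weights)
        total = h.sum()
        histograms.append(h / total if total > 0 else h)
        edges_list.append(edges)
    return means, histograms, edges_list


def pair_distances(frames: np.ndarray, site_pairs: list[tuple[int, int]]) -> np.ndarray:
    """Per-frame distances (n_frames, n_pairs) between site index pairs."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty((len(frames), len(site_pairs)))
    for k, (i, j) in enumerate(site_pairs):
        if not (0 <= i < frames.shape[1] and 0 <= j < frames.shape[1]):
            raise ValueError(f"site pair ({i}, {j}) out of range")
        out[:, k] = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
    return out
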