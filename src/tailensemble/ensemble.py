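"""Canonical-ensemble reconstruction by importance reweighting.

Frames sampled across the lambda range are weighted back to the
canonical ensemble at lambda = 1:

    log w  =  -beta * [(1 - lambda^2) E_tail + (1 - lambda) E_tail_rest]
              + ln_p(lambda)

normalized within each run via log-sum-exp.  Cross-run statistics are
always combined at the run level (mean of per-run means, standard error
from the between-run spread), never by pooling frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alsd import ALSDConfig, BiasEstimate, Trajectory


class BiasMismatchError(ValueError):
    """The bias passed for reweighting is not the one used in production."""


@dataclass
class WeightedEnsemble:
    """Frame weights targeting the canonical ensemble at lambda = 1."""

    trajectory: Trajectory
    weights: np.ndarray
    target_lambda: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    @property
    def n_frames(self) -> int:
        return len(self.weights)

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights ** 2))

    def mean(self, values: np.ndarray) -> float:
        """Weighted mean of a per-frame observable."""
        values = np.asarray(values, dtype=float)
        return float(np.sum(self.weights * values))


@dataclass(frozen=True)
class SummaryStat:
    """TTP summary: mean of per-run means with a between-run standard error."""

    mean: float
    se: float
    n_runs: int


def reweight(trajectory: Trajectory, bias: BiasEstimate, config: ALSDConfig,
             lambda_window: tuple[float, float] | None = None,
             check_hash: bool = True) -> WeightedEnsemble:
    """Importance weights recovering the canonical ensemble at lambda = 1.

    ``lambda_window`` optionally restricts contributing frames to a lambda
    interval (sensitivity analysis); by default all frames contribute.
    Raises :class:`BiasMismatchError` when the bias hash does not match the
    trajectory metadata (guard against silent misweighting).
    """
    if check_hash:
        recorded = trajectory.metadata.get("bias_hash")
        if recorded is not None and recorded != bias.content_hash():
            raise BiasMismatchError(
                f"bias hash {bias.content_hash()} does not match the one used in "
                f"production ({recorded})"
            )
    beta = 1.0 / config.rt
    lam = trajectory.lambdas
    ln_p = np.array([bias.value(l) for l in lam])
    log_w = -beta * ((1.0 - lam ** 2) * trajectory.e_tail
                     + (1.0 - lam) * trajectory.e_tail_rest) + ln_p
    if lambda_window is not None:
        lo, hi = lambda_window
        log_w = np.where((lam >= lo) & (lam <= hi), log_w, -np.inf)
    if np.all(np.isneginf(log_w)):
        raise ValueError("no frames contribute within the lambda window")
    log_w = log_w - logsumexp(log_w)
    return WeightedEnsemble(trajectory=trajectory, weights=np.exp(log_w))


def ttp_summary(per_run_values) -> SummaryStat:
    """Mean and standard error across independent runs."""
    values = np.asarray(per_run_values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("TTP summary needs at least 2 per-run values")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(len(values)))
    return SummaryStat(mean=mean, se=se, n_runs=len(values))


def weighted_histogram(values, weights, bins) -> tuple[np.ndarray, np.ndarray]:
    """Normalized weighted histogram (masses sum to 1 over in-range values).

    Returns (masses, edges).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must align")
    if np.all(weights == 0):
        raise ValueError("all weights are zero")
    hist, edges = np.histogram(values, bins=bins, weights=weights)
    total = hist.sum()
    if total <= 0:
        raise ValueError("no weight falls inside the histogram range")
    return hist / total, edges


def histogram_by_lambda(values, lambdas, weights, lambda_edges, value_bins):
    """Per-lambda-slice weighted distributions of an observable.

    Returns (masses, value_edges, lambda_edges) where ``masses[k]`` is the
    normalized distribution of the observable conditioned on lambda falling
    in slice k (rows of all-zero weight stay zero).
    """
    values = np.asarray(values, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    lambda_edges = np.asarray(lambda_edges, dtype=float)
    _, value_edges = np.histogram(values, bins=value_bins)
    out = np.zeros((len(lambda_edges) - 1, len(value_edges) - 1))
    for k in range(len(lambda_edges) - 1):
        lo, hi = lambda_edges[k], lambda_edges[k + 1]
        sel = (lambdas >= lo) & (lambdas < hi if k < len(lambda_edges) - 2 else lambdas <= hi)
        if not np.any(sel) or weights[sel].sum() == 0:
            continue
        h, _ = np.histogram(values[sel], bins=value_edges, weights=weights[sel])
        if h.sum() > 0:
            out[k] = h / h.sum()
    return out, value_edges, lambda_edges
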