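"""Target-domain generation from multi-trial EEG.

A domain-adaptive autoencoder reconstructs a *target* signal that differs
from its source trial. Two target constructions are provided:

uniform
    One shared target per trial set: the equal-weight trial average
    ``S_UR(t) = (1/K) sum_i S_i(t)``.

softmin
    One target per trial: the trial is re-weighted sample-by-sample by its
    similarity to the cross-trial median reference ``R(t)``,

    ``W_i(c,t) = exp(-beta |S_i(c,t) - R(c,t)|) / sum_j exp(-beta |S_j(c,t) - R(c,t)|)``
    ``T_i(c,t) = W_i(c,t) * S_i(c,t)``.

    Samples deviating from the consensus are suppressed while common
    (evoked) segments are kept; ``beta`` is the sensitivity of the
    exponential similarity kernel (study default 0.1). Weights form a
    simplex over trials at every (channel, time) point.

Weighting operates on band-filtered trial sets (after preprocessing), and
the exponent uses the absolute deviation |S - R|: the weights measure
similarity, so undershooting and overshooting the reference are penalized
alike. The even-K median is the midpoint of the two central order
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BETA",
    "TrialSet",
    "ReferenceSignal",
    "WeightField",
    "TargetTrialSet",
    "uniform_reference",
    "median_reference",
    "softmin_weights",
    "softmin_targets",
    "uniform_targets",
    "make_targets",
]

DEFAULT_BETA = 0.1


@dataclass(frozen=True)
class TrialSet:
    """Aligned K x C x T block of trials for one subject/session/stimulus/band."""

    trials: np.ndarray = field(repr=False)  # (K, C, T) uV
    subject_id: str = ""
    session: int = 0
    stimulus: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.trials)
        if arr.ndim != 3:
            raise ValueError(f"trials must be (K, C, T), got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError(f"need K >= 2 trials, got K={arr.shape[0]}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trials contain non-finite samples")

    @property
    def K(self) -> int:
        return self.trials.shape[0]

    @classmethod
    def from_trials(cls, trials, subject_id="", session=0, stimulus="", band="") -> "TrialSet":
        """Stack a list of RawTrial (or arrays) into a TrialSet."""
        data = np.stack([t.data if hasattr(t, "channel_names") else np.asarray(t)
                         for t in trials])
        return cls(data, subject_id, session, stimulus, band)


@dataclass(frozen=True)
class ReferenceSignal:
    values: np.ndarray = field(repr=False)  # (C, T)
    kind: str = "uniform-mean"  # or "median"


@dataclass(frozen=True)
class WeightField:
    """Per-trial, per-channel, per-time weights; simplex over trials."""

    weights: np.ndarray = field(repr=False)  # (K, C, T)
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        w = self.weights
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        sums = w.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1 over trials at every (c, t)")


@dataclass(frozen=True)
class TargetTrialSet:
    """Decoder targets: K per-trial targets (softmin) or one shared (uniform)."""

    targets: np.ndarray = field(repr=False)  # (K, C, T) or (1, C, T)
    scheme: str = "uniform"  # or "softmin"


def uniform_reference(ts: TrialSet) -> ReferenceSignal:
    """Equal-weight trial average: each trial carries weight 1/K."""
    return ReferenceSignal(ts.trials.mean(axis=0), kind="uniform-mean")


def median_reference(ts: TrialSet) -> ReferenceSignal:
    """Cross-trial median at every (channel, time) point."""
    return ReferenceSignal(np.median(ts.trials, axis=0), kind="median")


def softmin_weights(ts: TrialSet, ref: ReferenceSignal, beta: float = DEFAULT_BETA) -> WeightField:
    """Exponential similarity weights against the reference (simplex per (c, t))."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if ref.values.shape != ts.trials.shape[1:]:
        raise ValueError(
            f"reference shape {ref.values.shape} does not match trials {ts.trials.shape[1:]}"
        )
    dev = np.abs(ts.trials - ref.values[None])  # (K, C, T)
    # subtract the per-(c,t) min before exponentiating for numerical stability
    logw = -beta * dev
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=0, keepdims=True)
    return WeightField(w, beta=beta)


def softmin_targets(ts: TrialSet, w: WeightField) -> TargetTrialSet:
    """Per-trial targets: elementwise weighted trials ``W_i * S_i``."""
    if w.weights.shape != ts.trials.shape:
        raise ValueError(
            f"weight shape {w.weights.shape} does not match trials {ts.trials.shape}"
        )
    return TargetTrialSet(w.weights * ts.trials, scheme="softmin")


def uniform_targets(ts: TrialSet) -> TargetTrialSet:
    """Single shared target: the uniform reference, for every source trial."""
    return TargetTrialSet(uniform_reference(ts).values[None], scheme="uniform")


def make_targets(ts: TrialSet, scheme: str, beta: float = DEFAULT_BETA) -> TargetTrialSet:
    """Dispatch on scheme: 'uniform' or 'softmin'."""
    if scheme == "uniform":
        return uniform_targets(ts)
    if scheme == "softmin":
        return softmin_targets(ts, softmin_weights(ts, median_reference(ts), beta))
    raise ValueError(f"unknown scheme {scheme!r}; expected 'uniform' or 'softmin'")
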