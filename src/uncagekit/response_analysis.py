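"""Rule-based classification of per-cell post-uncaging response patterns.

Features are computed from a cell's trace and its labelled events around
the photoactivation time: event rates before/after, mean
baseline-subtracted intensity, mean event amplitude and duration, the
longest post-uncaging event-free gap and whether activity recovers after
it.  A fixed decision list then assigns one of five response classes,
evaluated in an order that prevents pathological overlaps (a cell with no
pre-activity can never be called potentiated):

1. *initiated* — essentially silent before, oscillating after;
2. *terminated* — activity collapses with no recovery;
3. *transient suppression* — an event-free gap of 4–10 min followed by
   recovery to at least half the pre rate;
4. *potentiated* — rate, amplitude or baseline criterion exceeded;
5. *no change* otherwise.

The classifier is a pure function of (features, thresholds) and, with the
default ratio-based criteria, invariant to rescaling all intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calcium_events import BinnedCounts, Event, compare_event_distributions
from .synth_calcium import CalciumTrace, ResponseClass

__all__ = [
    "ResponseFeatures",
    "ClassifierThresholds",
    "UnclassifiableError",
    "extract_features",
    "classify_response",
    "population_summary",
]


class UnclassifiableError(ValueError):
    """Raised when the post-uncaging observation window is too short."""


@dataclass(frozen=True)
class ResponseFeatures:
    """Per-cell descriptors of calcium activity before vs after uncaging.

    Rates are events/min; intensities are baseline-subtracted trace means;
    the suppression gap is the longest event-free interval (min) in the
    post window, with ``recovery`` true when events occur after it.
    """

    pre_rate_per_min: float
    post_rate_per_min: float
    pre_rate_high_per_min: float
    post_rate_high_per_min: float
    pre_mean_intensity: float
    post_mean_intensity: float
    pre_mean_amplitude: float
    post_mean_amplitude: float
    pre_mean_fwhm_s: float
    post_mean_fwhm_s: float
    suppression_gap_min: float
    recovery: bool
    post_gap_rate_per_min: float
    pre_window_min: float
    post_window_min: float

    def __post_init__(self) -> None:
        for name in (
            "pre_rate_per_min",
            "post_rate_per_min",
            "pre_rate_high_per_min",
            "post_rate_high_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.suppression_gap_min > self.post_window_min + 1e-9:
            raise ValueError("suppression gap cannot exceed the post window")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the rule-based classifier.

    All criteria are ratios or rates so the default configuration is
    invariant to intensity rescaling.  The transient-suppression gap
    bounds default to the typical 4–10 min interruption.
    """

    potentiation_rate_ratio: float = 2.0
    potentiation_amplitude_ratio: float = 1.5
    potentiation_baseline_step: float = math.inf
    initiation_pre_rate_ceiling_per_min: float = 0.1
    termination_rate_floor: float = 0.2
    suppression_gap_bounds_min: tuple[float, float] = (4.0, 10.0)
    suppression_recovery_fraction: float = 0.5
    min_post_observation_min: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.suppression_gap_bounds_min
        if not 0 < lo < hi:
            raise ValueError("suppression gap bounds must satisfy 0 < lower < upper")
        for name in (
            "potentiation_rate_ratio",
            "potentiation_amplitude_ratio",
            "initiation_pre_rate_ceiling_per_min",
            "termination_rate_floor",
            "suppression_recovery_fraction",
            "min_post_observation_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else 0.0


def extract_features(
    trace: CalciumTrace,
    events: list[Event],
    t0_s: float | None = None,
    min_post_observation_min: float = 5.0,
) -> ResponseFeatures:
    """Compute per-cell response features from a trace and its labelled events."""
    t0 = trace.uncaging_time_s if t0_s is None else t0_s
    t_start = float(trace.time_s[0])
    t_end = float(trace.time_s[-1])
    pre_min = (t0 - t_start) / 60.0
    post_min = (t_end - t0) / 60.0
    if post_min < min_post_observation_min:
        raise UnclassifiableError(
            f"post window {post_min:.1f} min shorter than required {min_post_observation_min} min"
        )

    pre_events = [e for e in events if e.peak_time_s < t0]
    post_events = [e for e in events if e.peak_time_s >= t0]
    pre_high = [e for e in pre_events if e.label == "high"]
    post_high = [e for e in post_events if e.label == "high"]

    # longest event-free gap within the post window and recovery afterwards
    post_times = sorted(e.peak_time_s for e in post_events)
    boundaries = [t0] + post_times + [t_end]
    gaps = np.diff(boundaries)
    gap_idx = int(np.argmax(gaps))
    gap_min = float(gaps[gap_idx]) / 60.0
    gap_end = boundaries[gap_idx + 1]
    after_gap = [t for t in post_times if t >= gap_end]
    recovery = len(after_gap) > 0
    remaining_min = (t_end - gap_end) / 60.0
    post_gap_rate = len(after_gap) / remaining_min if remaining_min > 0 else 0.0

    # baseline-subtracted intensity: subtract the pre-window 10th percentile
    pre_mask = trace.time_s < t0
    post_mask = ~pre_mask
    baseline_level = float(np.percentile(trace.values[pre_mask], 10)) if pre_mask.any() else 0.0

    return ResponseFeatures(
        pre_rate_per_min=len(pre_events) / pre_min if pre_min > 0 else 0.0,
        post_rate_per_min=len(post_events) / post_min,
        pre_rate_high_per_min=len(pre_high) / pre_min if pre_min > 0 else 0.0,
        post_rate_high_per_min=len(post_high) / post_min,
        pre_mean_intensity=float(trace.values[pre_mask].mean() - baseline_level)
        if pre_mask.any()
        else 0.0,
        post_mean_intensity=float(trace.values[post_mask].mean() - baseline_level),
        pre_mean_amplitude=_mean([e.height for e in pre_events]),
        post_mean_amplitude=_mean([e.height for e in post_events]),
        pre_mean_fwhm_s=_mean([e.width_fwhm_s for e in pre_events]),
        post_mean_fwhm_s=_mean([e.width_fwhm_s for e in post_events]),
        suppression_gap_min=gap_min,
        recovery=recovery,
        post_gap_rate_per_min=post_gap_rate,
        pre_window_min=pre_min,
        post_window_min=post_min,
    )


def classify_response(
    features: ResponseFeatures, thresholds: ClassifierThresholds | None = None
) -> ResponseClass:
    """Assign a response class by the ordered decision rules (first match wins)."""
    th = thresholds or ClassifierThresholds()
    if features.post_window_min < th.min_post_observation_min:
        raise UnclassifiableError("post observation window too short to classify")

    pre = features.pre_rate_per_min
    post = features.post_rate_per_min
    ceiling = th.initiation_pre_rate_ceiling_per_min

    # 1. initiated: silent before, active after
    if pre <= ceiling and post > ceiling:
        return ResponseClass.INITIATED
    # 2. terminated: activity collapses, no recovery
    if post <= th.termination_rate_floor * pre and not features.recovery:
        return ResponseClass.TERMINATED
    # 3. transient suppression: bounded event-free gap, then recovery
    lo, hi = th.suppression_gap_bounds_min
    if (
        lo <= features.suppression_gap_min <= hi
        and features.recovery
        and features.post_gap_rate_per_min >= th.suppression_recovery_fraction * pre
    ):
        return ResponseClass.TRANSIENT_SUPPRESSION
    # 4. potentiated: rate, amplitude or baseline criterion
    rate_ratio = post / pre if pre > 0 else math.inf
    amp_ratio = (
        features.post_mean_amplitude / features.pre_mean_amplitude
        if features.pre_mean_amplitude > 0
        else math.inf
    )
    baseline_step = features.post_mean_intensity - features.pre_mean_intensity
    if (
        rate_ratio >= th.potentiation_rate_ratio
        or amp_ratio >= th.potentiation_amplitude_ratio
        or baseline_step >= th.potentiation_baseline_step
    ):
        return ResponseClass.POTENTIATED
    return ResponseClass.NO_CHANGE


def population_summary(
    classifications: list[ResponseClass],
    binned: BinnedCounts | None = None,
    t0_s: float | None = None,
) -> dict:
    """Population-level report: class fractions with binomial 95 % CIs plus
    pre/post binned-count statistics and their Welch comparison.

    When ``binned`` and ``t0_s`` are given, the Welch test compares per-cell
    total high-event counts in the pre-uncaging bins against the post bins.
    """
    if not classifications:
        raise ValueError("need at least one classified cell")
    n = len(classifications)
    fractions = {}
    for cls in ResponseClass:
        k = sum(1 for c in classifications if c is cls)
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
        fractions[cls.value] = {
            "count": k,
            "fraction": k / n,
            "ci95": (float(ci.low), float(ci.high)),
        }
    report = {"n_cells": n, "class_fractions": fractions}

    if binned is not None:
        if t0_s is None:
            raise ValueError("t0_s is required when binned counts are supplied")
        pre_bins = binned.bin_starts_s < t0_s
        pre_counts = binned.counts[:, pre_bins].sum(axis=1)
        post_counts = binned.counts[:, ~pre_bins].sum(axis=1)
        welch = compare_event_distributions(pre_counts, post_counts)
        report["binned"] = {
            "bin_starts_s": binned.bin_starts_s.tolist(),
            "mean": binned.mean.tolist(),
            "sem": binned.sem.tolist(),
            "welch_t": welch.t,
            "welch_df": welch.df,
            "welch_p": welch.p,
        }
    return report
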