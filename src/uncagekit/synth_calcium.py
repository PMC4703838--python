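"""Synthetic single-cell calcium traces with ground-truth transients.

Emulates glucose-stimulated beta-cell calcium oscillations reported by a
red genetically encoded indicator: a baseline with stochastic transients
(difference-of-exponentials kernels, log-normal amplitudes, Poisson event
times) and a single perturbation at ``uncaging_time_s`` that switches the
generative parameters according to one of five response classes:

* ``initiated`` — silent before, oscillating after;
* ``potentiated`` — higher event rate and/or amplitude (and optionally a
  baseline step) after;
* ``transient_suppression`` — events pause for 4–10 min, then resume;
* ``terminated`` — no events after;
* ``no_change`` — identical statistics throughout.

Every trace is reproducible from a seed and ships with an
:class:`EventGroundTruth` so detectors and classifiers can be scored
against the generating process.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ResponseClass",
    "TransientShape",
    "CalciumTrace",
    "EventGroundTruth",
    "TraceParams",
    "PopulationParams",
    "generate_trace",
    "generate_population",
]


class ResponseClass(str, enum.Enum):
    """Closed enumeration of post-uncaging response patterns."""

    INITIATED = "initiated"
    POTENTIATED = "potentiated"
    TRANSIENT_SUPPRESSION = "transient_suppression"
    TERMINATED = "terminated"
    NO_CHANGE = "no_change"


@dataclass(frozen=True)
class TransientShape:
    """Difference-of-exponentials calcium transient kernel.

    ``amplitude`` is the peak height in ΔF/F-like units above baseline;
    rise must be faster than decay for a well-formed transient.
    """

    amplitude: float = 1.0
    rise_s: float = 2.0
    decay_s: float = 15.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("amplitude and time constants must be positive")
        if self.rise_s >= self.decay_s:
            raise ValueError("rise time constant must be smaller than decay")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel values at times ``t`` (s) after event onset, peak = amplitude."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, None)
        shape = np.where(t >= 0, np.exp(-tc / self.decay_s) - np.exp(-tc / self.rise_s), 0.0)
        # normalize so the analytic maximum equals `amplitude`
        t_peak = (
            np.log(self.decay_s / self.rise_s)
            * self.rise_s
            * self.decay_s
            / (self.decay_s - self.rise_s)
        )
        peak = np.exp(-t_peak / self.decay_s) - np.exp(-t_peak / self.rise_s)
        return self.amplitude * shape / peak

    @property
    def fwhm_s(self) -> float:
        """Approximate full width at half maximum of the kernel (s)."""
        t = np.arange(0.0, 12.0 * self.decay_s, self.rise_s / 10.0)
        y = self.evaluate(t)
        above = np.nonzero(y >= self.amplitude / 2.0)[0]
        return float(t[above[-1]] - t[above[0]]) if above.size else 0.0


@dataclass(frozen=True)
class CalciumTrace:
    """Uniformly sampled single-cell fluorescence time series."""

    time_s: np.ndarray
    values: np.ndarray
    uncaging_time_s: float
    cell_id: int = 0

    def __post_init__(self) -> None:
        if self.time_s.shape != self.values.shape:
            raise ValueError("time and values must have equal length")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("sampling must be uniform")
        if not (self.time_s[0] <= self.uncaging_time_s <= self.time_s[-1]):
            raise ValueError("uncaging time outside the record")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass(frozen=True)
class EventGroundTruth:
    """Generator-side truth for one trace."""

    event_times_s: np.ndarray
    amplitudes: np.ndarray
    durations_s: np.ndarray
    response_class: ResponseClass
    rate_pre_per_min: float
    rate_post_per_min: float
    amplitude_scale_post: float
    baseline_step: float
    suppression_duration_s: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times_s) < 0):
            raise ValueError("event times must be sorted")
        needs_tau = self.response_class is ResponseClass.TRANSIENT_SUPPRESSION
        if needs_tau != (self.suppression_duration_s is not None):
            raise ValueError("suppression duration present iff class is transient_suppression")


@dataclass(frozen=True)
class TraceParams:
    """Generator settings for one cell.

    Defaults emulate a 30-min confocal time-lapse sampled every 2 s with
    photoactivation at 10 min and ~2 oscillations/min at stimulatory
    glucose.  Rates are events/min; amplitudes are drawn log-normally
    around ``shape.amplitude`` with spread ``amplitude_sigma_log``.
    """

    duration_s: float = 1800.0
    dt_s: float = 2.0
    uncaging_time_s: float = 600.0
    baseline: float = 100.0
    rate_pre_per_min: float = 2.0
    shape: TransientShape = field(default_factory=TransientShape)
    amplitude_sigma_log: float = 0.3
    noise_sd: float = 0.0
    # class-effect knobs
    potentiation_rate_factor: float = 3.0
    potentiation_amplitude_factor: float = 2.0
    potentiation_baseline_step: float = 0.0
    initiated_rate_post_per_min: float = 2.0
    suppression_range_min: tuple[float, float] = (4.0, 10.0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.dt_s <= 0:
            raise ValueError("duration and sampling interval must be positive")
        if not 0 < self.uncaging_time_s < self.duration_s:
            raise ValueError("uncaging time must fall inside the record")
        if self.rate_pre_per_min < 0 or self.initiated_rate_post_per_min < 0:
            raise ValueError("rates must be >= 0")
        lo, hi = self.suppression_range_min
        if not 0 < lo < hi:
            raise ValueError("suppression range must be ordered and positive")


def _poisson_times(rng: np.random.Generator, rate_per_min: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson event times in [t0, t1)."""
    if rate_per_min <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_per_min * (t1 - t0) / 60.0)
    return np.sort(rng.uniform(t0, t1, n))


def generate_trace(
    response_class: ResponseClass | str,
    params: TraceParams | None = None,
    seed: int = 0,
    cell_id: int = 0,
) -> tuple[CalciumTrace, EventGroundTruth]:
    """Simulate one cell with the given response class.

    Event times follow a Poisson renewal process with rate λ_pre before
    and λ_post after uncaging; the class sets λ_post, the post amplitude
    scale and (for transient suppression) an event-free interval of 4–10
    min immediately after uncaging.  The same seed yields an identical
    trace.
    """
    response_class = ResponseClass(response_class)
    params = params or TraceParams()
    rng = np.random.default_rng(seed)
    t0 = params.uncaging_time_s
    t_end = params.duration_s

    rate_pre = params.rate_pre_per_min
    rate_post = rate_pre
    amp_scale_post = 1.0
    baseline_step = 0.0
    suppression: float | None = None

    if response_class is ResponseClass.INITIATED:
        rate_pre = 0.0
        rate_post = params.initiated_rate_post_per_min
    elif response_class is ResponseClass.POTENTIATED:
        rate_post = rate_pre * params.potentiation_rate_factor
        amp_scale_post = params.potentiation_amplitude_factor
        baseline_step = params.potentiation_baseline_step
    elif response_class is ResponseClass.TERMINATED:
        rate_post = 0.0
    elif response_class is ResponseClass.TRANSIENT_SUPPRESSION:
        lo, hi = params.suppression_range_min
        suppression = float(rng.uniform(lo, hi) * 60.0)

    pre_times = _poisson_times(rng, rate_pre, 0.0, t0)
    if response_class is ResponseClass.TRANSIENT_SUPPRESSION:
        post_times = _poisson_times(rng, rate_post, t0 + suppression, t_end)
    else:
        post_times = _poisson_times(rng, rate_post, t0, t_end)
    event_times = np.concatenate([pre_times, post_times])

    n_events = event_times.size
    amplitudes = params.shape.amplitude * rng.lognormal(
        mean=0.0, sigma=params.amplitude_sigma_log, size=n_events
    )
    amplitudes[event_times >= t0] *= amp_scale_post

    time = np.arange(0.0, params.duration_s, params.dt_s)
    values = np.full(time.shape, float(params.baseline))
    if baseline_step:
        values += baseline_step * (time >= t0)
    durations = np.empty(n_events)
    for i, (t_event, amp) in enumerate(zip(event_times, amplitudes)):
        kernel_shape = replace(params.shape, amplitude=float(amp))
        values += kernel_shape.evaluate(time - t_event)
        durations[i] = kernel_shape.fwhm_s
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, time.shape)

    trace = CalciumTrace(
        time_s=time, values=values, uncaging_time_s=t0, cell_id=cell_id
    )
    truth = EventGroundTruth(
        event_times_s=event_times,
        amplitudes=amplitudes,
        durations_s=durations,
        response_class=response_class,
        rate_pre_per_min=rate_pre,
        rate_post_per_min=rate_post,
        amplitude_scale_post=amp_scale_post,
        baseline_step=baseline_step,
        suppression_duration_s=suppression,
    )
    return trace, truth


@dataclass(frozen=True)
class PopulationParams:
    """Population-level heterogeneity ranges.

    Each cell draws its own pre-uncaging event rate, amplitude scale and
    noise level uniformly from these ranges, reproducing the wide
    cell-to-cell diversity of oscillation frequency and amplitude that
    makes per-trace internal normalization necessary.
    """

    base: TraceParams = field(default_factory=TraceParams)
    rate_pre_range_per_min: tuple[float, float] = (0.5, 2.5)
    amplitude_range: tuple[float, float] = (5.0, 20.0)
    noise_sd_range: tuple[float, float] = (0.3, 0.8)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.rate_pre_range_per_min,
            self.amplitude_range,
            self.noise_sd_range,
        ):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be ordered and non-negative")


def generate_population(
    class_mix: dict[ResponseClass | str, float],
    n_cells: int,
    params: PopulationParams | None = None,
    seed: int = 0,
) -> tuple[list[CalciumTrace], list[EventGroundTruth]]:
    """Simulate a heterogeneous cell population with known response classes.

    ``class_mix`` maps response classes to proportions summing to 1; each
    cell's class is sampled from the mix and its rate/amplitude/noise
    hyper-parameters drawn from the configured ranges.  The master seed
    spawns one independent stream per cell, so the dataset is reproducible
    and insensitive to generation order.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    params = params or PopulationParams()
    classes = [ResponseClass(c) for c in class_mix]
    probs = np.array([class_mix[c] for c in class_mix], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")

    master = np.random.SeedSequence(seed)
    mix_rng = np.random.default_rng(master.spawn(1)[0])
    assignments = mix_rng.choice(len(classes), size=n_cells, p=probs)
    cell_seeds = master.spawn(n_cells)

    traces: list[CalciumTrace] = []
    truths: list[EventGroundTruth] = []
    for cell_id, (class_idx, child) in enumerate(zip(assignments, cell_seeds)):
        cell_rng = np.random.default_rng(child)
        rate = cell_rng.uniform(*params.rate_pre_range_per_min)
        amplitude = cell_rng.uniform(*params.amplitude_range)
        noise_sd = cell_rng.uniform(*params.noise_sd_range)
        cell_params = replace(
            params.base,
            rate_pre_per_min=float(rate),
            initiated_rate_post_per_min=max(
                params.base.initiated_rate_post_per_min, float(rate)
            ),
            shape=replace(params.base.shape, amplitude=float(amplitude)),
            noise_sd=float(noise_sd),
        )
        trace_seed = int(cell_rng.integers(0, 2**31 - 1))
        trace, truth = generate_trace(
            classes[class_idx], cell_params, seed=trace_seed, cell_id=cell_id
        )
        traces.append(trace)
        truths.append(truth)
    return traces, truths
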