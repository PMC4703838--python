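"""Quantify completeness and efficiency of photo-uncaging from a stack.

The analysis chain mirrors the live-cell assay: segment the plasma-membrane
(PM) ring, intracellular vesicles and cell-free background on a
pre-activation reference image; extract background-subtracted,
baseline-normalized intensity traces per compartment; compute the
fractional fluorescence decreases ΔF = (F_pre - F_post)/F_pre; and form
the PM/vesicle ΔF ratio.  Because vesicular loss can only come from
photobleaching while PM loss combines uncaging and bleaching, the ratio
measures photoreaction efficiency and the residual normalized PM intensity
measures completeness.  A titration over laser intensities locates the
dose window that is complete yet maximally efficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .synth_imaging import CompartmentMasks, ImageStack

__all__ = [
    "SegmentationParams",
    "RoiTrace",
    "DeltaF",
    "UncagingResult",
    "TitrationReport",
    "NoCellFoundError",
    "segment_compartments",
    "extract_traces",
    "compute_dF",
    "aggregate_dF",
    "efficiency_ratio",
    "assess_completeness",
    "analyze_titration",
    "quantify_stack",
]


class NoCellFoundError(ValueError):
    """Raised when no foreground component is found in the reference image."""


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the semi-automated compartment segmentation.

    ``ring_width_px`` is the PM band width along the detected cell
    boundary; ``tophat_radius_px`` the white top-hat structuring radius for
    vesicle spots; ``vesicle_k`` the MAD multiplier above the interior
    median for the spot threshold; ``pm_exclusion_px`` how far from the PM
    band vesicle pixels are discarded (mixed-mechanism pixels);
    ``background_margin_px`` the halo around the cell excluded from the
    background mask.
    """

    ring_width_px: int = 3
    tophat_radius_px: int = 5
    vesicle_k: float = 5.0
    pm_exclusion_px: int = 2
    background_margin_px: int = 6
    #: each spot is trimmed to pixels above this fraction of its top-hat peak
    #: (the half-maximum contour of a blurred disc approximates the disc)
    spot_halfmax_fraction: float = 0.5
    min_spot_px: int = 4


@dataclass(frozen=True)
class RoiTrace:
    """Background-subtracted compartment intensity trace and its normalization.

    ``values`` holds the per-frame ROI mean minus the background-mask mean;
    ``normalized`` divides by the mean of the baseline window, so the
    pre-activation level is 1 by construction.
    """

    roi_label: str
    values: np.ndarray
    normalized: np.ndarray
    baseline_frames: tuple[int, int]

    def __post_init__(self) -> None:
        if self.values.shape != self.normalized.shape:
            raise ValueError("values and normalized must have equal length")
        lo, hi = self.baseline_frames
        baseline_mean = float(np.mean(self.normalized[lo:hi]))
        if abs(baseline_mean - 1.0) > 1e-9:
            raise ValueError(f"normalized baseline mean must be 1, got {baseline_mean!r}")


@dataclass(frozen=True)
class DeltaF:
    """Fractional fluorescence decrease ΔF = (F_pre − F_post)/F_pre, with s.e.m.

    The s.e.m. is computed across replicate experiments when aggregating;
    a single trace carries sem = 0.
    """

    value: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.value > 1 + 1e-12:
            raise ValueError("ΔF cannot exceed 1")


@dataclass(frozen=True)
class UncagingResult:
    """Per-experiment quantification of the photoreaction.

    ``efficiency_ratio`` = ΔF_PM / ΔF_ves with ``ratio_err`` from standard
    error propagation; ``remaining_pm`` is the mean normalized PM intensity
    after activation (completeness readout); ``bleaching_estimate`` equals
    ΔF_ves because vesicular loss is photobleaching only.
    """

    dF_pm: DeltaF
    dF_ves: DeltaF
    efficiency_ratio: float
    ratio_err: float
    remaining_pm: float
    complete: bool
    laser_level: float = 0.0

    @property
    def bleaching_estimate(self) -> float:
        return self.dF_ves.value


@dataclass(frozen=True)
class TitrationReport:
    """Summary of a laser-intensity titration series."""

    results: tuple[UncagingResult, ...]
    complete_levels: tuple[float, ...]
    optimal_level: float

    def __post_init__(self) -> None:
        levels = {r.laser_level for r in self.results}
        if self.optimal_level not in levels:
            raise ValueError("optimal_level must be a tested level")
        if not set(self.complete_levels) <= levels:
            raise ValueError("complete_levels must be tested levels")


def segment_compartments(
    reference_image: np.ndarray,
    params: SegmentationParams | None = None,
    user_masks: CompartmentMasks | None = None,
) -> CompartmentMasks:
    """Segment PM ring, vesicles and background from a pre-activation average.

    Pipeline: global (Otsu) threshold → largest connected component, holes
    filled → PM band = component minus its erosion by the ring width →
    vesicles = white top-hat spots in the interior above a robust
    (median + k·1.4826·MAD) threshold, excluding pixels near the PM band →
    background = sub-threshold pixels away from the cell.  A user-supplied
    label mask short-circuits the pipeline and is passed through unchanged.
    """
    if user_masks is not None:
        return user_masks
    params = params or SegmentationParams()

    reference_image = np.asarray(reference_image, dtype=float)
    if reference_image.ndim != 2:
        raise ValueError("reference image must be 2-D")
    if np.ptp(reference_image) == 0:
        raise NoCellFoundError("reference image is constant; no cell found")

    threshold = filters.threshold_otsu(reference_image)
    binary = reference_image > threshold
    if not binary.any():
        raise NoCellFoundError("no pixels above threshold; no cell found")

    labels = measure.label(binary)
    component_sizes = np.bincount(labels.ravel())
    component_sizes[0] = 0
    cell = ndimage.binary_fill_holes(labels == component_sizes.argmax())

    ring = morphology.disk(params.ring_width_px)
    interior = ndimage.binary_erosion(cell, structure=ring)
    pm = cell & ~interior

    # vesicle spots: top-hat enhances bright blobs on the smoother interior
    tophat = morphology.white_tophat(reference_image, morphology.disk(params.tophat_radius_px))
    interior_vals = tophat[interior]
    if interior.any():
        med = np.median(interior_vals)
        mad = np.median(np.abs(interior_vals - med))
        spot_threshold = med + params.vesicle_k * 1.4826 * mad
        near_pm = ndimage.binary_dilation(pm, morphology.disk(params.pm_exclusion_px))
        candidates = (tophat > spot_threshold) & interior & ~near_pm
        # trim every blob to its half-maximum contour and drop specks
        vesicles = np.zeros_like(cell)
        blob_labels = measure.label(candidates)
        for blob in measure.regionprops(blob_labels):
            blob_mask = blob_labels == blob.label
            peak = tophat[blob_mask].max()
            core = blob_mask & (tophat >= params.spot_halfmax_fraction * peak)
            if core.sum() >= params.min_spot_px:
                vesicles |= core
    else:
        vesicles = np.zeros_like(cell)
    if not vesicles.any():
        warnings.warn(
            "empty vesicle mask: quantification restricted to the PM compartment",
            stacklevel=2,
        )

    away = ~ndimage.binary_dilation(cell, morphology.disk(params.background_margin_px))
    background = away & (reference_image <= threshold)
    return CompartmentMasks(pm=pm, vesicles=vesicles, background=background)


def extract_traces(
    stack: ImageStack, masks: CompartmentMasks, n_baseline: int | None = None
) -> dict[str, RoiTrace]:
    """Extract background-subtracted, baseline-normalized compartment traces.

    Per frame the ROI mean minus the background-mask mean is computed for
    the PM and (if present) vesicle masks; each trace is then normalized by
    the mean of the last ``n_baseline`` pre-activation frames (default: all
    pre-frames).
    """
    n_pre = stack.uncaging_frame
    if n_baseline is None:
        n_baseline = n_pre
    if not 1 <= n_baseline <= n_pre:
        raise ValueError("n_baseline must be between 1 and the number of pre-frames")
    if not masks.background.any():
        raise ValueError("background mask is empty")

    pixels = stack.pixels
    background = pixels[:, masks.background].mean(axis=1)
    baseline_window = (n_pre - n_baseline, n_pre)

    traces: dict[str, RoiTrace] = {}
    rois = {"pm": masks.pm}
    if masks.vesicles.any():
        rois["vesicle"] = masks.vesicles
    for label, mask in rois.items():
        if not mask.any():
            raise ValueError(f"{label} mask is empty")
        values = pixels[:, mask].mean(axis=1) - background
        baseline = float(values[baseline_window[0] : baseline_window[1]].mean())
        if baseline <= 0:
            raise ValueError(f"{label} baseline mean <= 0 after background subtraction")
        traces[label] = RoiTrace(
            roi_label=label,
            values=values,
            normalized=values / baseline,
            baseline_frames=baseline_window,
        )
    return traces


def compute_dF(
    trace: RoiTrace, uncaging_frame: int, n_pre: int = 3, n_post: int = 3
) -> DeltaF:
    """ΔF of one trace: 1 − mean(normalized over the first ``n_post`` post-frames).

    ``n_pre`` asserts that the baseline window used for normalization has at
    least that many frames; the post window starts at ``uncaging_frame`` and
    must not cross the end of the trace.  Early post-frames are used because
    slow vesicle motion degrades later ones.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("n_pre and n_post must be >= 1")
    n = len(trace.normalized)
    if uncaging_frame + n_post > n:
        raise ValueError("post window extends beyond the trace")
    if uncaging_frame - n_pre < 0:
        raise ValueError("pre window extends before the trace start")
    lo, hi = trace.baseline_frames
    if hi > uncaging_frame:
        raise ValueError("baseline window overlaps the post-activation frames")
    post = float(trace.normalized[uncaging_frame : uncaging_frame + n_post].mean())
    return DeltaF(value=1.0 - post, sem=0.0)


def aggregate_dF(replicates: list[DeltaF]) -> DeltaF:
    """Mean ΔF across replicate experiments with the s.e.m. across them."""
    if not replicates:
        raise ValueError("need at least one replicate")
    values = np.array([r.value for r in replicates])
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return DeltaF(value=float(values.mean()), sem=sem)


def efficiency_ratio(
    dF_pm: DeltaF, dF_ves: DeltaF, epsilon: float = 1e-3
) -> tuple[float, float]:
    """ΔF_PM / ΔF_ves with the error propagated from the two s.e.m. values.

    ratio_err = ratio · sqrt((sem_pm/ΔF_pm)² + (sem_ves/ΔF_ves)²).  A
    vesicular ΔF below ``epsilon`` means the bleach-free regime where the
    ratio is undefined.
    """
    if dF_ves.value <= epsilon:
        raise ValueError(
            "vesicular ΔF indistinguishable from zero; ratio undefined (bleach-free regime)"
        )
    ratio = dF_pm.value / dF_ves.value
    rel_pm = dF_pm.sem / dF_pm.value if dF_pm.value != 0 else 0.0
    rel_ves = dF_ves.sem / dF_ves.value
    return ratio, abs(ratio) * math.sqrt(rel_pm**2 + rel_ves**2)


def assess_completeness(
    pm_trace: RoiTrace,
    uncaging_frame: int,
    n_post: int = 3,
    threshold: float = 0.05,
    background_trace: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> tuple[bool, float]:
    """Judge photoreaction completeness from the residual normalized PM signal.

    ``complete`` when the mean post-window normalized PM intensity is at or
    below ``threshold``, or within 2·noise_sd of a supplied background
    trace level.
    """
    if uncaging_frame + n_post > len(pm_trace.normalized):
        raise ValueError("post window extends beyond the trace")
    remaining = float(pm_trace.normalized[uncaging_frame : uncaging_frame + n_post].mean())
    complete = remaining <= threshold
    if not complete and background_trace is not None and noise_sd is not None:
        bg_level = float(np.mean(background_trace[uncaging_frame : uncaging_frame + n_post]))
        complete = remaining <= bg_level + 2.0 * noise_sd
    return complete, remaining


def quantify_stack(
    stack: ImageStack,
    masks: CompartmentMasks,
    n_baseline: int | None = None,
    n_post: int = 3,
    completeness_threshold: float = 0.05,
) -> UncagingResult:
    """Full single-stack quantification: traces → ΔF values → ratio → verdict."""
    traces = extract_traces(stack, masks, n_baseline=n_baseline)
    k = stack.uncaging_frame
    dF_pm = compute_dF(traces["pm"], k, n_pre=1, n_post=n_post)
    if "vesicle" not in traces:
        raise ValueError("vesicle trace unavailable; cannot form the efficiency ratio")
    dF_ves = compute_dF(traces["vesicle"], k, n_pre=1, n_post=n_post)
    ratio, ratio_err = efficiency_ratio(dF_pm, dF_ves)
    complete, remaining = assess_completeness(
        traces["pm"], k, n_post=n_post, threshold=completeness_threshold
    )
    return UncagingResult(
        dF_pm=dF_pm,
        dF_ves=dF_ves,
        efficiency_ratio=ratio,
        ratio_err=ratio_err,
        remaining_pm=remaining,
        complete=complete,
        laser_level=stack.laser_level,
    )


def analyze_titration(results: list[UncagingResult]) -> TitrationReport:
    """Pick the optimal laser level from a titration series.

    The optimal level maximizes the efficiency ratio (ties broken toward
    the lowest level, i.e. least photodamage); ``complete_levels`` are all
    levels whose residual PM intensity met the completeness criterion.
    """
    if len(results) < 2:
        raise ValueError("titration needs at least two levels")
    finite = [r for r in results if math.isfinite(r.efficiency_ratio)]
    if not finite:
        raise ValueError("all efficiency ratios undefined")
    best = max(finite, key=lambda r: (r.efficiency_ratio, -r.laser_level))
    complete_levels = tuple(r.laser_level for r in results if r.complete)
    return TitrationReport(
        results=tuple(results),
        complete_levels=complete_levels,
        optimal_level=best.laser_level,
    )
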