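"""Compartment segmentation, ΔF quantification and titration analysis."""

import numpy as np
import pytest

from uncagekit import (
    DeltaF,
    SceneParams,
    UncagingResult,
    aggregate_dF,
    analyze_titration,
    assess_completeness,
    compute_dF,
    efficiency_ratio,
    extract_traces,
    quantify_stack,
    render_stack,
    segment_compartments,
)
from uncagekit.photochemistry import PhotoreactionParams
from uncagekit.synth_imaging import ImageStack
from uncagekit.uncaging_quant import NoCellFoundError, RoiTrace


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


def _make_trace(normalized, baseline_frames=(0, 3)):
    normalized = np.asarray(normalized, float)
    lo, hi = baseline_frames
    normalized = normalized / normalized[lo:hi].mean()
    return RoiTrace(
        roi_label="pm",
        values=normalized * 100.0,
        normalized=normalized,
        baseline_frames=baseline_frames,
    )


class TestSegmentation:
    def test_low_noise_segmentation_overlaps_generative_masks(self, ref_reaction):
        scene = SceneParams(shot_noise=False, read_noise_sigma=2.0, seed=11)
        stack, masks, _ = render_stack(scene, ref_reaction, n_pre=5, n_post=5)
        reference = stack.pixels[:5].mean(axis=0)
        seg = segment_compartments(reference)
        assert _iou(seg.pm, masks.pm) >= 0.7
        assert _iou(seg.vesicles, masks.vesicles) >= 0.7
        assert _iou(seg.background, masks.background) >= 0.7

    def test_user_supplied_masks_pass_through_unchanged(self, noisefree_scene, ref_reaction):
        _, masks, _ = render_stack(noisefree_scene, ref_reaction)
        out = segment_compartments(np.zeros((8, 8)), user_masks=masks)
        assert out is masks

    def test_constant_image_raises_no_cell_found(self):
        with pytest.raises(NoCellFoundError):
            segment_compartments(np.zeros((64, 64)))


class TestTraces:
    def test_constant_stack_normalizes_to_one(self, noisefree_scene):
        reaction = PhotoreactionParams(1.0, 0.1, 0.05, 0.0)
        stack, masks, _ = render_stack(noisefree_scene, reaction, n_pre=3, n_post=4)
        traces = extract_traces(stack, masks)
        np.testing.assert_allclose(traces["pm"].normalized, 1.0, rtol=1e-9)
        np.testing.assert_allclose(traces["vesicle"].normalized, 1.0, rtol=1e-9)

    def test_noisefree_post_levels_match_closed_form(self, noisefree_scene, ref_reaction):
        stack, masks, _ = render_stack(noisefree_scene, ref_reaction, n_pre=4, n_post=4)
        traces = extract_traces(stack, masks)
        assert traces["pm"].normalized[4:].mean() == pytest.approx(0.33287108, rel=0.01)
        assert traces["vesicle"].normalized[4:].mean() == pytest.approx(0.92178379, rel=0.01)

    def test_every_baseline_mean_is_exactly_one(self, noisefree_scene, ref_reaction):
        stack, masks, _ = render_stack(noisefree_scene, ref_reaction, n_pre=5, n_post=5)
        for trace in extract_traces(stack, masks, n_baseline=3).values():
            lo, hi = trace.baseline_frames
            assert abs(trace.normalized[lo:hi].mean() - 1.0) <= 1e-9

    def test_zero_signal_stack_raises_on_nonpositive_baseline(self):
        pixels = np.zeros((4, 16, 16))
        stack = ImageStack(pixels=pixels, uncaging_frame=2)
        masks_shape = np.zeros((16, 16), dtype=bool)
        pm = masks_shape.copy()
        pm[4:6, 4:6] = True
        bg = masks_shape.copy()
        bg[12:, 12:] = True
        from uncagekit.synth_imaging import CompartmentMasks

        masks = CompartmentMasks(pm=pm, vesicles=masks_shape, background=bg)
        with pytest.raises(ValueError, match="baseline"):
            extract_traces(stack, masks)


class TestDeltaF:
    def test_step_trace_delta_f(self):
        trace = _make_trace([1.0, 1.0, 1.0, 0.4, 0.4, 0.4])
        dF = compute_dF(trace, uncaging_frame=3, n_pre=3, n_post=3)
        assert dF.value == pytest.approx(0.6, abs=1e-12)
        assert dF.sem == 0.0

    def test_flat_trace_delta_f_is_zero(self):
        trace = _make_trace([1.0] * 6)
        assert compute_dF(trace, 3, 3, 3).value == pytest.approx(0.0, abs=1e-12)

    def test_window_crossing_trace_end_rejected(self):
        trace = _make_trace([1.0, 1.0, 1.0, 0.4, 0.4])
        with pytest.raises(ValueError):
            compute_dF(trace, uncaging_frame=3, n_pre=3, n_post=5)

    def test_replicate_aggregation_recovers_truth_within_two_sem(self, rng):
        """20 noisy replicates of a 0.6 step: mean ΔF near 0.6, sem ~ sd/sqrt(20)."""
        n_rep, noise_sd = 20, 0.05
        reps = []
        for _ in range(n_rep):
            post = 0.4 + rng.normal(0.0, noise_sd)
            trace = _make_trace([1.0, 1.0, 1.0, post, post, post])
            reps.append(compute_dF(trace, 3, 3, 3))
        agg = aggregate_dF(reps)
        # normalization by a noise-free baseline leaves post noise sd intact
        assert agg.value == pytest.approx(0.6, abs=2 * noise_sd / np.sqrt(n_rep) + 0.02)
        assert agg.sem == pytest.approx(noise_sd / np.sqrt(n_rep), rel=0.5)


class TestEfficiencyRatio:
    def test_reference_parameter_ratio(self):
        ratio, err = efficiency_ratio(DeltaF(0.6671289163), DeltaF(0.0782162108))
        assert ratio == pytest.approx(8.529, abs=0.005)
        assert err == 0.0

    def test_pure_bleaching_gives_unity_ratio(self):
        ratio, _ = efficiency_ratio(DeltaF(0.3), DeltaF(0.3))
        assert ratio == pytest.approx(1.0)

    def test_error_propagation_formula(self):
        ratio, err = efficiency_ratio(DeltaF(0.6, 0.06), DeltaF(0.2, 0.02))
        assert ratio == pytest.approx(3.0)
        assert err == pytest.approx(3.0 * np.sqrt(0.01 + 0.01), rel=1e-9)

    def test_vanishing_vesicular_delta_f_is_flagged(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            efficiency_ratio(DeltaF(0.5), DeltaF(0.0005))


class TestCompletenessAndTitration:
    def test_completeness_threshold(self):
        below = _make_trace([1.0, 1.0, 1.0, 0.02, 0.02, 0.02])
        above = _make_trace([1.0, 1.0, 1.0, 0.30, 0.30, 0.30])
        assert assess_completeness(below, 3, n_post=3)[0] is True
        assert assess_completeness(above, 3, n_post=3)[0] is False
        assert assess_completeness(above, 3, n_post=3)[1] == pytest.approx(0.30, abs=1e-9)

    def test_background_proximity_criterion(self):
        trace = _make_trace([1.0, 1.0, 1.0, 0.08, 0.08, 0.08])
        background = np.full(6, 0.06)
        complete, _ = assess_completeness(
            trace, 3, n_post=3, background_trace=background, noise_sd=0.02
        )
        assert complete is True

    def _result(self, level, ratio, complete):
        return UncagingResult(
            dF_pm=DeltaF(0.5),
            dF_ves=DeltaF(0.1),
            efficiency_ratio=ratio,
            ratio_err=0.0,
            remaining_pm=0.5,
            complete=complete,
            laser_level=level,
        )

    def test_optimal_level_is_argmax_with_low_tie_break(self):
        results = [
            self._result(5.0, 8.0, False),
            self._result(10.0, 8.0, False),
            self._result(25.0, 4.0, True),
        ]
        report = analyze_titration(results)
        assert report.optimal_level == 5.0
        assert report.complete_levels == (25.0,)

    def test_no_complete_levels_yields_empty_tuple(self):
        results = [self._result(5.0, 8.0, False), self._result(10.0, 6.0, False)]
        assert analyze_titration(results).complete_levels == ()

    def test_noisefree_titration_end_to_end(self, noisefree_scene):
        """Measured optimum at the lowest level; completeness matches truth."""
        from uncagekit import simulate_titration

        base = PhotoreactionParams(1.0, 0.1, 0.05, 0.0)
        series = simulate_titration(
            noisefree_scene, base, [5.0, 10.0, 25.0, 50.0], dose_per_percent=0.12
        )
        results = [quantify_stack(stack, masks) for stack, masks, _ in series]
        report = analyze_titration(results)
        assert report.optimal_level == 5.0
        expected_complete = tuple(
            stack.laser_level
            for stack, _, truth in series
            if truth["pm"].fluorescent <= 0.05
        )
        assert report.complete_levels == expected_complete
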