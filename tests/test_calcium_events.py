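"""Transient detection, 60 % labelling, 60-s binning and the Welch test."""

import numpy as np
import pytest

from uncagekit import (
    CalciumTrace,
    DetectionConfig,
    Event,
    TraceParams,
    TransientShape,
    bin_high_events,
    compare_event_distributions,
    detect_events,
    estimate_baseline_noise,
    generate_trace,
    label_events,
)

from .oracles import welch_from_formulas


def _trace(values, dt=2.0, t0=600.0):
    values = np.asarray(values, float)
    return CalciumTrace(
        time_s=np.arange(len(values)) * dt, values=values, uncaging_time_s=min(t0, (len(values) - 1) * dt)
    )


def _events(times, heights):
    return [Event(peak_time_s=t, height=h, width_fwhm_s=10.0) for t, h in zip(times, heights)]


class TestBaselineNoise:
    def test_flat_trace_baseline_and_zero_sigma(self):
        with pytest.warns(UserWarning, match="constant"):
            baseline, sigma = estimate_baseline_noise(_trace(np.full(600, 100.0)))
        assert sigma == 0.0
        np.testing.assert_allclose(baseline, 100.0)

    def test_sigma_consistent_for_gaussian_noise(self, rng):
        values = 100.0 + rng.normal(0.0, 1.0, 10000)
        _, sigma = estimate_baseline_noise(_trace(values))
        assert sigma == pytest.approx(1.0, abs=0.05)

    def test_baseline_tracks_linear_drift(self, rng):
        n = 3000
        drift = np.linspace(100.0, 140.0, n)
        values = drift + rng.normal(0.0, 1.0, n)
        baseline, sigma = estimate_baseline_noise(_trace(values))
        # residual noise scale unaffected by the drift within 10%
        assert sigma == pytest.approx(1.0, rel=0.10)
        inner = slice(200, -200)
        assert np.max(np.abs(baseline[inner] - drift[inner])) < 5.0


class TestDetection:
    def test_all_separated_transients_found_at_true_times(self):
        params = TraceParams(
            rate_pre_per_min=0.0, noise_sd=0.4, shape=TransientShape(amplitude=8.0)
        )
        trace, _ = generate_trace("no_change", params, seed=0)
        # inject 5 well-separated transients manually
        shape = TransientShape(amplitude=8.0)
        truth_times = np.array([200.0, 400.0, 700.0, 1000.0, 1400.0])
        values = trace.values.copy()
        for t in truth_times:
            values += shape.evaluate(trace.time_s - t)
        trace = CalciumTrace(trace.time_s, values, trace.uncaging_time_s)
        events = detect_events(trace)
        assert len(events) == 5
        t_peak = np.log(15.0 / 2.0) * 2.0 * 15.0 / 13.0
        for e, t in zip(events, truth_times):
            assert abs(e.peak_time_s - (t + t_peak)) <= 2 * trace.dt_s

    def test_conflicting_peaks_keep_the_higher_one(self, rng):
        config = DetectionConfig(min_separation_s=30.0)
        time = np.arange(600) * 2.0
        values = 100.0 + rng.normal(0.0, 0.2, 600)
        shape_small = TransientShape(amplitude=5.0)
        shape_big = TransientShape(amplitude=10.0)
        values += shape_big.evaluate(time - 500.0) + shape_small.evaluate(time - 520.0)
        trace = CalciumTrace(time, values, 600.0)
        events = [e for e in detect_events(trace, config) if 480.0 <= e.peak_time_s <= 560.0]
        assert len(events) == 1
        assert events[0].height > 7.0  # the larger transient survives

    def test_null_false_positive_rate_low(self, rng):
        """<= 0.1 spurious events/trace on pure-noise traces at k=3."""
        n_traces = 300
        total = 0
        for _ in range(n_traces):
            values = 100.0 + rng.normal(0.0, 1.0, 900)
            total += len(detect_events(_trace(values)))
        assert total / n_traces <= 0.1

    def test_detection_sensitivity_precision_on_ground_truth(self):
        """Sensitivity and precision >= 0.95 for ample, well-separated transients."""
        params = TraceParams(
            rate_pre_per_min=1.0,
            noise_sd=0.5,
            shape=TransientShape(amplitude=10.0),
            amplitude_sigma_log=0.2,
        )
        t_peak = np.log(15.0 / 2.0) * 2.0 * 15.0 / 13.0
        hits = misses = false = 0
        for seed in range(100):
            trace, truth = generate_trace("no_change", params, seed=seed)
            # score only truths separated by >= 2x min separation
            events = detect_events(trace)
            det_times = np.array([e.peak_time_s for e in events])
            kept = []
            for t in truth.event_times_s:
                others = truth.event_times_s[truth.event_times_s != t]
                if others.size == 0 or np.min(np.abs(others - t)) >= 20.0:
                    kept.append(t + t_peak)
            matched = set()
            for t in kept:
                if det_times.size and np.min(np.abs(det_times - t)) <= 8.0:
                    hits += 1
                    matched.add(int(np.argmin(np.abs(det_times - t))))
                else:
                    misses += 1
            near_any_truth = [
                np.min(np.abs(truth.event_times_s + t_peak - dt)) <= 12.0
                for dt in det_times
            ] if truth.event_times_s.size else [False] * det_times.size
            false += sum(1 for ok in near_any_truth if not ok)
        sensitivity = hits / (hits + misses)
        precision = hits / (hits + false) if hits + false else 1.0
        assert sensitivity >= 0.95
        assert precision >= 0.95


class TestLabelling:
    def test_sixty_percent_boundary_is_inclusive(self):
        events = label_events(_events([10.0, 30.0, 50.0], [10.0, 6.0, 5.9]))
        assert [e.label for e in events] == ["high", "high", "low"]
        assert events[1].relative_height == pytest.approx(0.60)

    def test_single_event_is_high_with_unit_relative_height(self):
        (event,) = label_events(_events([10.0], [3.3]))
        assert event.relative_height == 1.0
        assert event.label == "high"

    def test_equal_heights_all_high(self):
        events = label_events(_events([10.0, 20.0, 30.0], [4.0, 4.0, 4.0]))
        assert all(e.label == "high" for e in events)

    def test_empty_event_list_passes_through(self):
        assert label_events([]) == []

    def test_exactly_one_event_reaches_relative_height_one(self):
        events = label_events(_events([1.0, 2.0, 3.0], [2.0, 5.0, 4.0]))
        assert sum(e.relative_height == 1.0 for e in events) == 1

    def test_scale_invariance_of_labels_and_counts(self):
        """Multiplying a trace by c > 0 leaves relative heights and bins unchanged."""
        params = TraceParams(noise_sd=0.5, shape=TransientShape(amplitude=10.0))
        trace, _ = generate_trace("no_change", params, seed=21)
        for c in (0.25, 4.0):
            scaled = CalciumTrace(trace.time_s, trace.values * c, trace.uncaging_time_s)
            base_events = label_events(detect_events(trace))
            scaled_events = label_events(detect_events(scaled))
            assert [e.label for e in base_events] == [e.label for e in scaled_events]
            np.testing.assert_allclose(
                [e.relative_height for e in base_events],
                [e.relative_height for e in scaled_events],
                rtol=1e-9,
            )
            b1 = bin_high_events([base_events], 600.0, pre_s=600.0, post_s=1200.0)
            b2 = bin_high_events([scaled_events], 600.0, pre_s=600.0, post_s=1200.0)
            np.testing.assert_array_equal(b1.counts, b2.counts)

    def test_high_plus_low_equals_total(self):
        params = TraceParams(noise_sd=0.5, shape=TransientShape(amplitude=10.0))
        trace, _ = generate_trace("no_change", params, seed=33)
        events = label_events(detect_events(trace))
        n_high = sum(e.label == "high" for e in events)
        n_low = sum(e.label == "low" for e in events)
        assert n_high + n_low == len(events)


class TestBinning:
    def test_events_fall_into_expected_post_bins(self):
        events = label_events(_events([605.0, 665.0], [5.0, 5.0]))
        binned = bin_high_events([events], 600.0, pre_s=60.0, post_s=120.0)
        np.testing.assert_array_equal(binned.counts[0], [0, 1, 1])

    def test_bin_edge_event_goes_to_later_bin(self):
        events = label_events(_events([660.0], [5.0]))
        binned = bin_high_events([events], 600.0, pre_s=60.0, post_s=120.0)
        np.testing.assert_array_equal(binned.counts[0], [0, 0, 1])

    def test_bin_sums_equal_high_event_totals_per_cell(self):
        params = TraceParams(noise_sd=0.5, shape=TransientShape(amplitude=10.0))
        cells = []
        for seed in range(10):
            trace, _ = generate_trace("no_change", params, seed=seed)
            cells.append(label_events(detect_events(trace)))
        binned = bin_high_events(cells, 600.0, pre_s=600.0, post_s=1200.0)
        for row, events in zip(binned.counts, cells):
            inside = [
                e
                for e in events
                if e.label == "high" and 0.0 <= e.peak_time_s < 1800.0
            ]
            assert row.sum() == len(inside)

    def test_potentiated_population_rate_ratio_recovered(self, rng):
        """λ_post = 4·λ_pre in high events: binned post/pre ratio = 4 within 2 s.e."""
        lam_pre, factor, n_cells = 1.0, 4.0, 120
        cells = []
        for _ in range(n_cells):
            n_pre = rng.poisson(lam_pre * 10)
            n_post = rng.poisson(lam_pre * factor * 20)
            times = np.concatenate(
                [rng.uniform(0.0, 600.0, n_pre), rng.uniform(600.0, 1800.0, n_post)]
            )
            cells.append(label_events(_events(np.sort(times), np.full(times.size, 5.0))))
        binned = bin_high_events(cells, 600.0, pre_s=600.0, post_s=1200.0)
        pre_tot = binned.counts[:, binned.bin_starts_s < 600.0].sum(axis=1)
        post_tot = binned.counts[:, binned.bin_starts_s >= 600.0].sum(axis=1)
        ratio = (post_tot.mean() / 20.0) / (pre_tot.mean() / 10.0)
        se = ratio * np.sqrt(
            (post_tot.std(ddof=1) / np.sqrt(n_cells) / post_tot.mean()) ** 2
            + (pre_tot.std(ddof=1) / np.sqrt(n_cells) / pre_tot.mean()) ** 2
        )
        assert abs(ratio - factor) <= 2.0 * se


class TestWelch:
    def test_identical_samples_give_t_zero_p_one(self):
        res = compare_event_distributions([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_frozen_example_against_formula_oracle(self):
        res = compare_event_distributions([1, 2, 3], [2, 3, 4])
        t, df, p = welch_from_formulas([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.224744871391589, abs=1e-9)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.2878641347266905, abs=1e-9)
        assert (res.t, res.df, res.p) == pytest.approx((t, df, p))

    def test_zero_variance_equal_means_p_one(self):
        res = compare_event_distributions([2, 2, 2], [2, 2, 2])
        assert res.p == 1.0 and res.t == 0.0

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at α=0.05 within [0.04, 0.06] over 10000 pairs."""
        from scipy import stats as sps

        n_rep, n = 10000, 20
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        res = sps.ttest_ind(x, y, axis=1, equal_var=False)
        rate = float((res.pvalue < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_event_distributions([1.0], [1.0, 2.0])
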