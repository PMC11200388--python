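"""Ground-truth signal pipeline and the experiment runner."""

import numpy as np
import pandas as pd
import pytest

from stepbench import (
    ConvergenceError,
    LabelSequence,
    NoiseSpec,
    OpticalTrace,
    SensorSettings,
    compute_error,
    converged_count,
    count_peaks,
    enforce_alternation,
    quantize,
    run_experiment,
    sample_low_high_cadences,
    smooth,
)


def labelled(values):
    return LabelSequence(labels=np.asarray(values, dtype=np.int64), sample_rate_hz=100.0)


class TestQuantize:
    def test_all_zero_trace(self):
        trace = OpticalTrace(100.0, np.zeros(50), ())
        assert np.all(quantize(trace).labels == 0)

    def test_clean_trace_yields_alternating_blocks(self, clean_trace_30):
        labels = quantize(clean_trace_30).labels
        n, sides = count_peaks(LabelSequence(labels, 100.0))
        assert n == clean_trace_30.true_count
        assert np.all(sides[::2] == 1) and np.all(sides[1::2] == 2)

    def test_single_high_spike_labels_two(self):
        v = np.zeros(20)
        v[7] = 3.0
        labels = quantize(OpticalTrace(100.0, v, ())).labels
        assert labels[7] == 2 and labels.sum() == 2

    def test_dead_band_maps_to_zero(self):
        v = np.array([0.0, 0.7, 0.99, 1.0, 2.0])
        assert list(quantize(OpticalTrace(100.0, v, ())).labels) == [0, 0, 0, 1, 2]

    def test_invalid_cuts_rejected(self):
        trace = OpticalTrace(100.0, np.zeros(5), ())
        with pytest.raises(ValueError):
            quantize(trace, low_cut=1.5, class_cut=1.0)


class TestSmooth:
    def test_single_sample_spike_removed(self):
        assert list(smooth(labelled([0, 1, 0]), 3).labels) == [0, 0, 0]

    def test_plateau_interior_preserved(self):
        out = smooth(labelled([1, 1, 1]), 3).labels
        assert out[1] == 1  # edges are zero-padded and may be suppressed

    def test_matches_direct_moving_mean_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 200)
        w = 3
        out = smooth(labelled(x), w).labels
        # oracle: per-side zero-padded centered mean, non-integers -> 0
        expect = np.zeros(len(x), dtype=int)
        for side in (1, 2):
            ind = (x == side).astype(float)
            padded = np.concatenate([np.zeros(w), ind, np.zeros(w)])
            for i in range(len(x)):
                j = i + w  # padded index of sample i
                mean = padded[j - (w - 1) // 2: j - (w - 1) // 2 + w].mean()
                if mean == 1.0:
                    expect[i] = side
        assert np.array_equal(out, expect)

    def test_peak_shrinks_by_window_minus_one(self):
        x = [0, 0, 2, 2, 2, 2, 2, 0, 0]
        for w in (3, 4, 5):
            out = smooth(labelled(x), w).labels
            assert int(np.sum(out == 2)) == 5 - w + 1

    def test_window_longer_than_run_deletes_it(self):
        assert smooth(labelled([0, 2, 2, 2, 0]), 4).labels.sum() == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(labelled([0, 1]), 0)


class TestCountPeaks:
    def test_two_separated_runs(self):
        n, sides = count_peaks(labelled([0, 1, 1, 0, 2, 2, 0]))
        assert n == 2 and list(sides) == [1, 2]

    def test_all_zeros(self):
        n, sides = count_peaks(labelled([0, 0, 0]))
        assert n == 0 and len(sides) == 0

    def test_adjacent_different_values_split(self):
        n, sides = count_peaks(labelled([1, 1, 2, 2]))
        assert n == 2 and list(sides) == [1, 2]

    def test_noise_free_trace_counts_generator_truth(self):
        from stepbench import generate_optical_trace
        trace = generate_optical_trace(30, 2700.0)
        q = quantize(trace)
        n, _ = count_peaks(smooth(q, 3))
        assert n == trace.true_count == 1350


class TestEnforceAlternation:
    @pytest.mark.parametrize(
        "sides, kept, removed",
        [((1, 2, 1, 2), 4, 0), ((1, 1, 2), 2, 1), ((), 0, 0),
         ((2, 2, 2, 2), 1, 3), ((1, 2, 2, 1, 1, 2), 4, 2)],
    )
    def test_duplicate_sides_dropped(self, sides, kept, removed):
        assert enforce_alternation(sides) == (kept, removed)


class TestConvergedCount:
    def test_clean_trace_converges_immediately(self, clean_trace_30):
        gt = converged_count(clean_trace_30)
        assert gt.steps == clean_trace_30.true_count == 30
        assert gt.window_used == 3
        assert gt.iterations == 1
        assert gt.repeats_removed == 0

    def test_spiked_trace_recovers_generator_truth(self):
        from stepbench import generate_optical_trace
        for seed in range(10):
            noise = NoiseSpec(spike_rate_per_min=10.0, spike_amplitude_v=3.0, seed=seed)
            trace = generate_optical_trace(40 + 7 * seed, 60.0, noise=noise)
            assert converged_count(trace).steps == trace.true_count

    def test_nonconvergent_trace_raises_at_cap(self):
        # alternating-side runs with strictly decreasing lengths: each window
        # increment deletes exactly one run, so successive counts never agree
        chunks = []
        for i, length in enumerate(range(26, 2, -1)):
            chunks.append(np.full(length, 1.5 if i % 2 == 0 else 2.5))
            chunks.append(np.zeros(60))
        v = np.concatenate(chunks)
        trace = OpticalTrace(100.0, v, ())
        with pytest.raises(ConvergenceError, match="converge"):
            converged_count(trace, trial="pathological")

    def test_stability_once_converged_on_clean_trace(self, clean_trace_30):
        from stepbench.ground_truth import _corrected_count
        q = quantize(clean_trace_30)
        counts = [_corrected_count(q, w)[0] for w in range(3, 8)]
        assert len(set(counts)) == 1


class TestComputeError:
    @pytest.mark.parametrize(
        "sensor, truth, expected",
        [(1000, 1000, 0.0), (900, 1000, -0.10), (1100, 1000, +0.10)],
    )
    def test_signed_fraction(self, sensor, truth, expected):
        assert compute_error(sensor, truth) == pytest.approx(expected)

    def test_antisymmetric_about_truth(self):
        for d in (1, 17, 250):
            assert compute_error(1000 + d, 1000) == pytest.approx(
                -compute_error(1000 - d, 1000))

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_error(5, 0)


class TestRunExperiment:
    def test_cartesian_design_row_count_and_columns(self):
        settings = [SensorSettings(480.0, 2, 2480.0), SensorSettings(480.0, 6, 80.0)]
        table = run_experiment(settings, [40, 80], duration_s=30.0, seed=1)
        assert len(table) == 4
        assert list(table.columns) == [
            "threshold_mg", "debounce_steps", "debounce_time_ms", "cadence_spm",
            "true_steps", "sensor_steps", "error_frac", "seed",
        ]

    def test_perfect_sensor_on_clean_input_has_zero_error(self):
        table = run_experiment([SensorSettings(480.0, 2, 2480.0)], [60],
                               duration_s=60.0, seed=0)
        assert table.error_frac.iloc[0] == 0.0
        assert table.true_steps.iloc[0] == 60

    def test_rerun_with_same_seed_is_identical(self):
        settings = [SensorSettings(480.0, 2, 2480.0)]
        noise = NoiseSpec(spike_rate_per_min=5.0, timing_jitter_sd_s=0.05,
                          amplitude_jitter_sd_g=0.1)
        a = run_experiment(settings, [45, 90], duration_s=30.0, noise=noise, seed=9)
        b = run_experiment(settings, [45, 90], duration_s=30.0, noise=noise, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_low_high_mode_draws_one_low_one_high_per_setting(self):
        settings = [SensorSettings(480.0, 2, 2480.0)] * 5
        table = run_experiment(settings, "low-high", duration_s=30.0, seed=3)
        assert len(table) == 10
        lows = table.cadence_spm.iloc[::2]
        highs = table.cadence_spm.iloc[1::2]
        assert ((lows >= 30) & (lows < 70)).all()
        assert ((highs >= 70) & (highs <= 110)).all()

    def test_low_high_sampling_is_seeded(self):
        assert sample_low_high_cadences(8, 4) == sample_low_high_cadences(8, 4)
        assert sample_low_high_cadences(8, 4) != sample_low_high_cadences(8, 5)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_experiment([], [60])
        with pytest.raises(ValueError):
            run_experiment([SensorSettings(480.0, 2, 2480.0)], [])
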