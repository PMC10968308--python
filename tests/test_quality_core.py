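"""Window statistics, template search, rejection rules and aggregation."""

import math

import numpy as np
import pytest

from ecgqc import (
    AnnotationInterval,
    ClassifierConfig,
    ECGSignal,
    NoiseEpisode,
    NoStableReferenceError,
    ReferenceTemplate,
    StreamingClassifier,
    SynthRecipe,
    WindowStats,
    WindowVerdict,
    aggregate_windows_to_samples,
    classify_signal,
    classify_window,
    compute_window_stats,
    find_reference_template,
    generate_clean_ecg,
    intervals_to_sample_labels,
    simulate,
)


def make_stats(max_w, min_w, sd_w, mean_w=None, index=0, start_s=0.0):
    if mean_w is None:
        mean_w = 0.5 * (max_w + min_w)
    return WindowStats(
        index=index, start_s=start_s, mean_w=mean_w,
        max_w=max_w, min_w=min_w, sd_w=sd_w,
    )


TEMPLATE = ReferenceTemplate(max_t=1.0, min_t=-0.2, sd_t=0.15)


class TestComputeWindowStats:
    def test_constant_segment(self):
        st = compute_window_stats([0.3] * 10, start_s=0.0, index=0)
        assert st.mean_w == pytest.approx(0.3)
        assert (st.max_w, st.min_w) == (0.3, 0.3)
        assert st.sd_w == pytest.approx(0.0, abs=1e-12)

    def test_alternating_closed_form(self):
        a = 0.7
        st = compute_window_stats([a, -a] * 8, start_s=2.0, index=1)
        assert st.mean_w == pytest.approx(0.0)
        assert st.max_w == a and st.min_w == -a
        assert st.sd_w == pytest.approx(a)

    def test_matches_two_pass_recomputation(self, rng):
        seg = rng.normal(scale=0.4, size=500)
        st = compute_window_stats(seg, start_s=0.0, index=0)
        # independent two-pass oracle in plain Python
        mean = sum(seg) / len(seg)
        var = sum((x - mean) ** 2 for x in seg) / len(seg)
        assert st.mean_w == pytest.approx(mean, abs=1e-12)
        assert st.sd_w == pytest.approx(math.sqrt(var), rel=1e-12)
        assert st.max_w == max(seg) and st.min_w == min(seg)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            compute_window_stats([0.1], start_s=0.0, index=0)

    def test_sd_bounded_by_half_range(self, rng):
        seg = rng.uniform(-1, 1, size=200)
        st = compute_window_stats(seg, start_s=0.0, index=0)
        assert st.min_w <= st.mean_w <= st.max_w
        assert st.sd_w <= (st.max_w - st.min_w) / 2 + 1e-12


class TestFindReferenceTemplate:
    def test_clean_signal_stable_from_start(self, clean_signal, clean_template):
        assert clean_template.start_s == 0.0
        assert clean_template.sd_t > 0
        assert clean_template.max_t > clean_template.min_t

    def test_saturated_head_pushes_start_past_it(self):
        recipe = SynthRecipe(
            duration_s=60.0, seed=3,
            episodes=(NoiseEpisode("saturation", 0.0, 30.0),),
        )
        res = simulate(recipe)
        tpl = find_reference_template(res.signal)
        assert tpl.start_s >= 30.0

    def test_matches_exhaustive_scan_oracle(self):
        recipe = SynthRecipe(
            duration_s=80.0, seed=7,
            episodes=(
                NoiseEpisode("saturation", 4.0, 6.0),
                NoiseEpisode("saturation", 17.0, 5.0),
                NoiseEpisode("muscle", 28.0, 4.0),
            ),
        )
        res = simulate(recipe)
        cfg = ClassifierConfig()
        sig = res.signal
        fs = int(sig.fs)
        n_tpl = int(cfg.template_min_duration_s * fs)

        def span_qualifies(i0):
            seg = sig.values[i0:i0 + n_tpl]
            ptp = seg.max() - seg.min()
            if ptp <= 0 or ptp >= cfg.template_variability_fraction * 1000.0:
                return False
            means = [
                seg[j:j + fs].mean() for j in range(0, n_tpl, fs)
                if j + fs <= n_tpl
            ]
            return max(means) - min(means) <= cfg.baseline_drift_fraction * ptp

        oracle_start = next(
            i0 / fs
            for i0 in range(0, len(sig) - n_tpl + 1, fs)
            if span_qualifies(i0)
        )
        tpl = find_reference_template(sig, cfg)
        assert tpl.start_s == pytest.approx(oracle_start)

    def test_no_stable_period_raises(self):
        recipe = SynthRecipe(
            duration_s=30.0, seed=5,
            episodes=(NoiseEpisode("saturation", 0.0, 30.0),),
        )
        res = simulate(recipe)
        with pytest.raises(NoStableReferenceError):
            find_reference_template(res.signal)

    def test_dead_flat_recording_raises(self):
        sig = ECGSignal(values=np.zeros(250 * 30), fs=250.0)
        with pytest.raises(NoStableReferenceError):
            find_reference_template(sig)


class TestClassifyWindow:
    def test_saturation_rule(self, device):
        v = classify_window(make_stats(480.0, -480.0, 100.0), TEMPLATE, device)
        assert v.label == "unacceptable" and v.reason == "saturation"

    def test_low_amplitude_rule(self, device):
        v = classify_window(make_stats(0.025, -0.025, 0.01), TEMPLATE, device)
        assert v.label == "unacceptable" and v.reason == "low_amplitude"

    def test_excess_sd_rule(self, device):
        v = classify_window(make_stats(0.9, -0.2, 0.31), TEMPLATE, device)
        assert v.label == "unacceptable" and v.reason == "excess_sd"

    def test_sd_exactly_twice_template_is_acceptable(self, device):
        # strict '>' comparison: 0.30 is NOT above 2 x 0.15
        v = classify_window(make_stats(0.9, -0.2, 0.30), TEMPLATE, device)
        assert v.label == "acceptable" and v.reason == "ok"

    def test_range_exactly_at_thresholds_is_acceptable(self, device):
        # 0.95 * 1000 and 0.05 * 1.2 exactly: strict inequalities do not fire
        at_sat = make_stats(475.0, -475.0, 0.1)
        assert classify_window(at_sat, TEMPLATE, device).reason != "saturation"
        at_floor = make_stats(0.05 * (TEMPLATE.max_t - TEMPLATE.min_t), 0.0, 0.01)
        assert classify_window(at_floor, TEMPLATE, device).reason != "low_amplitude"

    def test_rule_order_saturation_first(self, device):
        # a rail-to-rail window also has huge SD; saturation must be reported
        v = classify_window(make_stats(500.0, -500.0, 300.0), TEMPLATE, device)
        assert v.reason == "saturation"

    def test_verdict_label_reason_consistency(self):
        with pytest.raises(ValueError):
            WindowVerdict(make_stats(1.0, 0.0, 0.1), "acceptable", "excess_sd")


class TestClassifySignal:
    def test_window_counts(self, clean_template):
        recipe = SynthRecipe(duration_s=20.0, seed=4)
        sig = generate_clean_ecg(recipe)
        assert len(classify_signal(sig, template=clean_template)) == 10

    def test_trailing_partial_window_discarded(self):
        recipe = SynthRecipe(duration_s=21.0, seed=4)
        sig = generate_clean_ecg(recipe)
        verdicts = classify_signal(sig)
        assert len(verdicts) == 10  # 21 s -> 10 windows, 1 s dropped

    def test_matches_per_window_oracle(self, mixed_result, cfg, device):
        sig = mixed_result.signal
        tpl = find_reference_template(sig, cfg)
        verdicts = classify_signal(sig, cfg, tpl)
        n_win = int(cfg.window_len_s * sig.fs)
        for w, v in enumerate(verdicts):
            seg = sig.values[w * n_win:(w + 1) * n_win]
            rng_w = seg.max() - seg.min()
            sd_w = seg.std()
            if rng_w > 0.95 * device.full_span_mv:
                expected = "saturation"
            elif rng_w < 0.05 * (tpl.max_t - tpl.min_t):
                expected = "low_amplitude"
            elif sd_w > 2 * tpl.sd_t:
                expected = "excess_sd"
            else:
                expected = "ok"
            assert v.reason == expected, f"window {w}"

    def test_template_found_automatically_when_absent(self, mixed_result):
        auto = classify_signal(mixed_result.signal)
        tpl = find_reference_template(mixed_result.signal)
        explicit = classify_signal(mixed_result.signal, template=tpl)
        assert auto == explicit


class TestAggregation:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (("u", "u", "u", "a", "a"), "unacceptable"),
            (("a", "a", "a", "a", "a"), "acceptable"),
            (("a", "a", "a", "u", "u"), "acceptable"),
        ],
    )
    def test_majority_of_five(self, labels, expected, device):
        long = {"u": "unacceptable", "a": "acceptable"}
        verdicts = [
            WindowVerdict(
                make_stats(0.5, -0.1, 0.1, index=i, start_s=2.0 * i),
                long[lbl],
                "ok" if lbl == "a" else "excess_sd",
            )
            for i, lbl in enumerate(labels)
        ]
        out = aggregate_windows_to_samples(verdicts)
        assert tuple(out) == (expected,)

    def test_even_k_tie_is_unacceptable(self):
        cfg = ClassifierConfig(window_len_s=2.0, sample_len_s=8.0)
        verdicts = [
            WindowVerdict(
                make_stats(0.5, -0.1, 0.1, index=i, start_s=2.0 * i),
                lbl,
                "ok" if lbl == "acceptable" else "excess_sd",
            )
            for i, lbl in enumerate(
                ("acceptable", "acceptable", "unacceptable", "unacceptable")
            )
        ]
        assert tuple(aggregate_windows_to_samples(verdicts, cfg)) == ("unacceptable",)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aggregate_windows_to_samples([])

    def test_trailing_incomplete_group_dropped(self, mixed_result):
        verdicts = classify_signal(mixed_result.signal)
        out = aggregate_windows_to_samples(verdicts[:12])
        assert len(out) == 2


class TestIntervalsToSampleLabels:
    def test_full_cover_single_interval(self):
        track = [AnnotationInterval(0.0, 10.0, "unacceptable")]
        assert tuple(intervals_to_sample_labels(track, 10.0)) == ("unacceptable",)

    def test_prevalence_six_seconds_acceptable(self):
        track = [
            AnnotationInterval(0.0, 4.0, "unacceptable"),
            AnnotationInterval(4.0, 10.0, "acceptable"),
        ]
        assert tuple(intervals_to_sample_labels(track, 10.0)) == ("acceptable",)

    def test_exact_tie_is_unacceptable(self):
        track = [
            AnnotationInterval(0.0, 5.0, "acceptable"),
            AnnotationInterval(5.0, 10.0, "unacceptable"),
        ]
        assert tuple(intervals_to_sample_labels(track, 10.0)) == ("unacceptable",)

    def test_uncovered_time_counts_as_unacceptable(self):
        track = [AnnotationInterval(0.0, 4.0, "acceptable")]
        assert tuple(intervals_to_sample_labels(track, 10.0)) == ("unacceptable",)

    def test_trailing_remainder_dropped(self):
        track = [AnnotationInterval(0.0, 25.0, "acceptable")]
        out = intervals_to_sample_labels(track, 25.0)
        assert len(out) == 2


class TestStreamingClassifier:
    def test_emission_delay_contract(self, clean_signal, clean_template):
        sc = StreamingClassifier(fs=250.0, template=clean_template)
        for i in range(499):
            assert sc.push(clean_signal.values[i]) is None
        assert sc.push(clean_signal.values[499]) is not None

    def test_stream_equals_batch_exactly(self, mixed_result):
        sig = mixed_result.signal
        tpl = find_reference_template(sig)
        batch = classify_signal(sig, template=tpl)
        sc = StreamingClassifier(fs=sig.fs, template=tpl)
        stream = sc.push_many(sig.values)
        assert stream == batch

    def test_push_after_close_rejected(self, clean_template):
        sc = StreamingClassifier(fs=250.0, template=clean_template)
        sc.push(0.1)
        assert sc.close() == 1
        with pytest.raises(RuntimeError):
            sc.push(0.2)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"saturation_factor": 1.5},
            {"sd_multiplier": 0.9},
            {"window_len_s": 3.0},  # does not divide 10 s
            {"floor_fraction": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierConfig(**kwargs)

    def test_windows_per_sample(self, cfg):
        assert cfg.windows_per_sample == 5
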