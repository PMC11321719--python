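import numpy as np
import pytest

import endodoc as e
from endodoc.errors import EmptyStream, NoBodyDetected, NoCecumDetected
from endodoc.segmentation import merge_runs, runs_from_mask
from endodoc.taxonomy import LABEL_INDEX

from conftest import make_random_stream
from oracles import (
    brute_filter,
    brute_interventions,
    brute_merge,
    brute_runs,
    brute_smooth,
)


def _step_stream(fps=10.0, t_in=10.0, t_out=600.0, total=610.0,
                 landmark=None):
    """outside=1 before t_in and from t_out on; optional landmark window."""
    n = int(total * fps)
    ts = np.arange(n) / fps
    conf = np.full((n, 10), 0.0)
    outside = (ts < t_in) | (ts >= t_out)
    conf[:, LABEL_INDEX["outside"]] = np.where(outside, 1.0, 0.0)
    if landmark:
        label, lo, hi = landmark
        conf[(ts >= lo) & (ts < hi), LABEL_INDEX[label]] = 1.0
    return e.PredictionStream(np.arange(n), ts, conf, fps=fps)


# --- smoothing --------------------------------------------------------------

def test_smooth_zero_window_is_identity():
    rng = np.random.default_rng(0)
    stream = make_random_stream(rng, 50)
    out = e.smooth(stream, 0.0)
    np.testing.assert_array_equal(out.confidences, stream.confidences)


def test_smooth_constant_stream_is_fixed_point():
    n = 60
    conf = np.full((n, 10), 0.37)
    stream = e.PredictionStream(np.arange(n), np.arange(n) / 10.0, conf,
                                fps=10.0)
    out = e.smooth(stream, 2.5)
    np.testing.assert_allclose(out.confidences, 0.37, atol=1e-12)


def test_smooth_matches_brute_force_windowed_mean():
    rng = np.random.default_rng(1)
    stream = make_random_stream(rng, 100)
    out = e.smooth(stream, 1.0)
    np.testing.assert_allclose(out.confidences, brute_smooth(stream, 1.0),
                               atol=1e-12, rtol=0)
    assert len(out) == len(stream)
    np.testing.assert_array_equal(out.timestamps, stream.timestamps)


def test_smooth_empty_stream_raises():
    empty = e.PredictionStream.from_frames([], fps=10.0)
    with pytest.raises(EmptyStream):
        e.smooth(empty, 1.0)


# --- body interval ----------------------------------------------------------

def test_all_outside_raises_no_body(config):
    n = 100
    conf = np.zeros((n, 10))
    conf[:, LABEL_INDEX["outside"]] = 1.0
    stream = e.PredictionStream(np.arange(n), np.arange(n) / 10.0, conf,
                                fps=10.0)
    with pytest.raises(NoBodyDetected):
        e.detect_body_interval(stream, config)


def test_step_function_body_interval(config):
    stream = _step_stream()
    assert e.detect_body_interval(stream, config) == (10.0, 600.0)


def test_zero_noise_body_recovery(config):
    spec = e.SyntheticExamSpec(durations=(8.0, 60.0, 30.0, 90.0, 8.0),
                               noise=None)
    truth, stream = e.simulate_exam(spec)
    sm = e.smooth(stream, config.window_s)
    t_enter, t_exit = e.detect_body_interval(sm, config)
    assert abs(t_enter - truth.t_enter_body) <= 1 / spec.fps + 1e-9
    assert abs(t_exit - truth.t_exit_body) <= 1 / spec.fps + 1e-9


# --- cecum anchors ----------------------------------------------------------

def test_no_landmark_evidence_raises_no_cecum(config):
    stream = _step_stream()  # in body but landmark confidences all zero
    body = e.detect_body_interval(stream, config)
    with pytest.raises(NoCecumDetected):
        e.detect_cecum_anchors(stream, body, config)


def test_single_sustained_run_gives_both_anchors(config):
    stream = _step_stream(landmark=("ileocecal_valve", 300.0, 360.0))
    body = e.detect_body_interval(stream, config)
    assert e.detect_cecum_anchors(stream, body, config) == (300.0, 360.0)


def test_multi_run_anchors_match_exhaustive_run_scan(config):
    rng = np.random.default_rng(2)
    stream = _step_stream(total=120.0, t_in=5.0, t_out=115.0)
    conf = stream.confidences.copy()
    # random sustained and non-sustained landmark bursts
    for _ in range(8):
        start = rng.uniform(5, 110)
        dur = rng.uniform(0.3, 8.0)
        label = rng.choice(list(e.LANDMARK_LABELS))
        sel = (stream.timestamps >= start) & (stream.timestamps < start + dur)
        conf[sel, LABEL_INDEX[label]] = 0.9
    stream = stream.with_confidences(conf)
    body = e.detect_body_interval(stream, config)

    mask = np.zeros(len(stream), dtype=bool)
    for label in e.LANDMARK_LABELS:
        mask |= stream.label(label) >= 0.5
    runs = brute_runs(stream.timestamps, mask, stream.end_s)
    clipped = [(max(s, body[0]), min(en, body[1])) for s, en in runs
               if max(s, body[0]) < min(en, body[1])]
    sustained = brute_filter(clipped, config.min_sustain_s)
    if not sustained:
        with pytest.raises(NoCecumDetected):
            e.detect_cecum_anchors(stream, body, config)
    else:
        expected = (sustained[0][0], sustained[-1][1])
        assert e.detect_cecum_anchors(stream, body, config) == expected


def test_raising_landmark_threshold_never_moves_first_cecum_earlier():
    for seed in range(8):
        spec = e.random_exam_spec(seed)
        _, stream = e.simulate_exam(spec)
        sm = e.smooth(stream, 1.0)
        firsts = []
        for thr in (0.35, 0.5, 0.65, 0.8):
            cfg = e.validate_config(e.PipelineConfig(
                thresholds={l: thr for l in e.LANDMARK_LABELS}))
            body = e.detect_body_interval(sm, cfg)
            try:
                first, _ = e.detect_cecum_anchors(sm, body, cfg)
            except NoCecumDetected:
                first = float("inf")
            firsts.append(first)
        assert firsts == sorted(firsts)


# --- interventions ----------------------------------------------------------

def test_no_evidence_gives_empty_interventions(config):
    stream = _step_stream()
    body = e.detect_body_interval(stream, config)
    assert e.detect_interventions(stream, body, config) == []


def test_nearby_runs_merge_across_small_gap(config):
    stream = _step_stream()
    conf = stream.confidences.copy()
    for lo, hi in [(100.0, 110.0), (112.0, 120.0)]:
        sel = (stream.timestamps >= lo) & (stream.timestamps < hi)
        conf[sel, LABEL_INDEX["polyp"]] = 1.0
    stream = stream.with_confidences(conf)
    body = e.detect_body_interval(stream, config)
    assert e.detect_interventions(stream, body, config) == [(100.0, 120.0)]


def test_interventions_match_brute_force_interval_algebra(config):
    rng = np.random.default_rng(3)
    for _ in range(10):
        stream = make_random_stream(rng, int(rng.integers(50, 400)))
        body = (float(stream.timestamps[2]),
                float(stream.timestamps[-3]))
        assert e.detect_interventions(stream, body, config) == \
            brute_interventions(stream, body, config)


def test_merge_runs_examples():
    assert merge_runs([(0, 1), (2, 3)], 5.0) == [(0, 3)]
    assert merge_runs([(0, 1), (7, 8)], 5.0) == [(0, 1), (7, 8)]
    assert merge_runs([(0, 1), (6, 8)], 5.0) == [(0, 1), (6, 8)]  # gap == 5


# --- full segmentation ------------------------------------------------------

def test_zero_noise_segments_match_ground_truth(config):
    spec = e.default_exam_spec(noise=None)
    truth, stream = e.simulate_exam(spec)
    timeline = e.segment_exam(stream, config)
    tol = 1 / spec.fps + 1e-9
    truth_by_phase = [(s.phase, s.start_s, s.end_s)
                      for s in truth.base_segments]
    got_by_phase = [(s.phase, s.start_s, s.end_s)
                    for s in timeline.base_segments]
    assert [p for p, *_ in got_by_phase] == [p for p, *_ in truth_by_phase]
    for (_, s0, e0), (_, s1, e1) in zip(truth_by_phase, got_by_phase):
        assert abs(s0 - s1) <= tol and abs(e0 - e1) <= tol


def test_no_interventions_means_corrections_are_no_ops(config):
    stream = _step_stream(landmark=("appendix", 300.0, 360.0))
    timeline = e.segment_exam(stream, config)
    assert timeline.interventions == ()
    timing = e.compute_times(timeline)
    assert timing.t_withdrawal_corrected == timing.t_withdrawal
    assert timing.t_cecum_inspection_corrected == timing.t_cecum_inspection


def test_base_segments_tile_the_stream(config):
    for seed in range(6):
        _, stream = e.simulate_exam(e.random_exam_spec(seed))
        timeline = e.segment_exam(stream, config)
        assert timeline.base_segments[0].start_s == 0.0
        total = sum(s.duration_s for s in timeline.base_segments)
        assert total == pytest.approx(stream.end_s, abs=1 / stream.fps)


def test_segmentation_is_frame_index_independent(config):
    _, stream = e.simulate_exam(e.random_exam_spec(4))
    reindexed = e.PredictionStream(stream.frame_index + 1000,
                                   stream.timestamps, stream.confidences,
                                   fps=stream.fps)
    a = e.segment_exam(stream, config)
    b = e.segment_exam(reindexed, config)
    assert a.to_json_dict() == b.to_json_dict()


def test_runs_from_mask_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(1, 60))
        ts = np.arange(n) / 10.0
        mask = rng.random(n) < 0.4
        end_s = n / 10.0
        assert runs_from_mask(ts, mask, end_s) == \
            brute_runs(ts, mask, end_s)
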