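import json

import numpy as np
import pytest

import endodoc as e
from endodoc.errors import FrameSourceMismatch, NoCecumDetected
from endodoc.taxonomy import LABEL_INDEX

from conftest import make_random_stream
from oracles import brute_landmark_selection, brute_polyp_selection


def _stream_from_rows(rows, fps=10.0):
    n = len(rows)
    return e.PredictionStream(np.arange(n), np.arange(n) / fps,
                              np.asarray(rows, dtype=float), fps=fps)


def _row(**conf):
    row = np.full(10, 0.1)
    for label, c in conf.items():
        row[LABEL_INDEX[label]] = c
    return row


# --- landmark selection -----------------------------------------------------

def test_single_eligible_frame_selected(config):
    stream = _stream_from_rows([_row(), _row(ileocecal_valve=0.99), _row()])
    image = e.select_landmark_image(stream, "ileocecal_valve", config)
    assert image.frame_index == 1
    assert image.confidence == pytest.approx(0.99)


def test_uninformative_frame_skipped_for_next_best(config):
    stream = _stream_from_rows([
        _row(ileocecal_valve=0.99, low_quality=0.9),  # global max, ineligible
        _row(ileocecal_valve=0.80),
    ])
    image = e.select_landmark_image(stream, "ileocecal_valve", config)
    assert image.frame_index == 1
    assert image.confidence == pytest.approx(0.80)


def test_no_frame_above_threshold_gives_absent(config):
    stream = _stream_from_rows([_row(appendix=0.4), _row(appendix=0.3)])
    assert e.select_landmark_image(stream, "appendix", config) is None


def test_landmark_selection_matches_exhaustive_scan(config):
    rng = np.random.default_rng(21)
    for _ in range(10):
        stream = make_random_stream(rng, 500, quantize=0.1)
        for label in e.LANDMARK_LABELS:
            got = e.select_landmark_image(stream, label, config)
            expected = brute_landmark_selection(stream, label, config)
            if expected is None:
                assert got is None
            else:
                assert got.frame_index == int(stream.frame_index[expected])


# --- polyp role selection ---------------------------------------------------

def test_plain_polyp_sequence_fills_white_light_only(config):
    stream = _stream_from_rows([_row(polyp=0.9), _row(polyp=0.95)])
    images = e.select_polyp_images(stream, (0.0, 0.2), config)
    assert [im.role for im in images] == ["polyp_white_light"]
    assert images[0].frame_index == 1


def test_snared_sequence_fills_instrument_role(config):
    stream = _stream_from_rows([
        _row(polyp=0.9),
        _row(polyp=0.8, snare=0.9),
    ])
    images = e.select_polyp_images(stream, (0.0, 0.2), config)
    roles = {im.role: im for im in images}
    assert set(roles) == {"polyp_white_light", "polyp_with_instrument"}
    instr = roles["polyp_with_instrument"]
    assert instr.frame_index == 1
    assert stream.frame(1).confidences["snare"] >= config.threshold("snare")


def test_polyp_roles_match_exhaustive_scan(config):
    rng = np.random.default_rng(22)
    for _ in range(10):
        stream = make_random_stream(rng, 300, quantize=0.1)
        interval = (2.0, 25.0)
        got = {im.role: im.frame_index
               for im in e.select_polyp_images(stream, interval, config)}
        expected = {role: int(stream.frame_index[i]) for role, i in
                    brute_polyp_selection(stream, interval, config).items()}
        assert got == expected


def test_selected_images_never_carry_uninformative_labels(config):
    rng = np.random.default_rng(23)
    for _ in range(5):
        stream = make_random_stream(rng, 400)
        images = [e.select_landmark_image(stream, l, config)
                  for l in e.LANDMARK_LABELS]
        images += e.select_polyp_images(stream, (0.0, stream.end_s), config)
        for im in filter(None, images):
            pos = int(np.flatnonzero(stream.frame_index ==
                                     im.frame_index)[0])
            for label in e.UNINFORMATIVE_LABELS:
                assert stream.confidences[pos, LABEL_INDEX[label]] \
                    < config.threshold(label)


def test_selection_depends_on_timestamps_not_frame_indices(config):
    rng = np.random.default_rng(24)
    stream = make_random_stream(rng, 200, quantize=0.1)
    relabeled = e.PredictionStream(
        rng.permutation(10_000)[:200], stream.timestamps,
        stream.confidences, fps=stream.fps)
    for label in e.LANDMARK_LABELS:
        a = e.select_landmark_image(stream, label, config)
        b = e.select_landmark_image(relabeled, label, config)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.timestamp_s == b.timestamp_s


# --- report assembly --------------------------------------------------------

def test_report_without_polyps_has_landmarks_only(config):
    spec = e.SyntheticExamSpec(durations=(5.0, 60.0, 30.0, 120.0, 5.0),
                               noise=None)
    _, stream = e.simulate_exam(spec)
    result = e.run_pipeline(stream, config)
    assert result.report.polyp_reports == ()
    assert result.report.cecum_documented
    assert len(result.report.landmark_images) == 3


def test_zero_noise_two_polyp_report(config):
    spec = e.default_exam_spec(noise=None)
    _, stream = e.simulate_exam(spec)
    result = e.run_pipeline(stream, config)
    assert len(result.report.polyp_reports) == 2
    roles_per_polyp = [{im.role for im in p.images}
                       for p in result.report.polyp_reports]
    # first polyp: snare resection under chromoendoscopy -> all three roles
    assert roles_per_polyp[0] == {"polyp_white_light", "polyp_chromo",
                                  "polyp_with_instrument"}
    # second polyp: plain inspection only
    assert roles_per_polyp[1] == {"polyp_white_light"}


def test_missing_cecum_propagates_before_report(config):
    spec = e.SyntheticExamSpec(durations=(5.0, 60.0, 30.0, 120.0, 5.0),
                               landmark_windows={}, noise=None)
    _, stream = e.simulate_exam(spec)
    with pytest.raises(NoCecumDetected):
        e.run_pipeline(stream, config)


def test_report_json_round_trips(config):
    _, stream = e.simulate_exam(e.default_exam_spec(seed=3))
    report = e.run_pipeline(stream, config).report
    d = report.to_json_dict()
    assert json.loads(json.dumps(d)) == d
    assert list(d) == ["source_id", "timing", "anchors", "landmarks",
                       "polyps", "cecum_documented"]


def test_cecum_documented_on_zero_noise_exams(config):
    for seed in range(3):
        spec = e.random_exam_spec(seed, noise=None)
        _, stream = e.simulate_exam(spec)
        assert e.run_pipeline(stream, config).report.cecum_documented


# --- rendering and export ---------------------------------------------------

def test_render_timeline_no_interventions(config, tmp_path):
    timeline = e.ExamTimeline.from_anchors(10.0, 300.0, 360.0, 960.0,
                                           end_s=970.0)
    path = e.render_timeline(timeline, tmp_path / "t.png")
    assert path.exists() and path.stat().st_size > 0


def test_render_timeline_is_deterministic(config, tmp_path):
    timeline = e.ExamTimeline.from_anchors(
        10.0, 300.0, 360.0, 960.0, end_s=970.0,
        interventions=[(400.0, 460.0)],
        polyp_sequences=[(400.0, 440.0), (500.0, 520.0)])
    a = e.render_timeline(timeline, tmp_path / "a.png")
    b = e.render_timeline(timeline, tmp_path / "b.png")
    assert a.read_bytes() == b.read_bytes()


def test_image_export_and_source_mismatch(config, tmp_path):
    spec = e.SyntheticExamSpec(durations=(3.0, 20.0, 10.0, 30.0, 3.0),
                               noise=None)
    from endodoc.simulate import render_toy_frames

    _, stream = e.simulate_exam(spec)
    frames_dir = render_toy_frames(spec, tmp_path / "frames")
    result = e.run_pipeline(stream, config, frames_dir=frames_dir,
                            images_out=tmp_path / "out")
    exported = sorted(p.name for p in (tmp_path / "out").glob("*.png"))
    assert exported  # at least the landmark images
    for im in result.report.landmark_images:
        assert f"{im.role}_{im.frame_index}.png" in exported
    # a frame index outside the rendered range must be detected
    from endodoc.report import export_report_images
    bad = e.SelectedImage("ileum", 999_999, 0.0, 0.9)
    broken = e.ImageReport(
        source_id="x", timing=result.timing, timeline=result.timeline,
        landmark_images=(bad,), polyp_reports=())
    with pytest.raises(FrameSourceMismatch):
        export_report_images(broken, frames_dir, tmp_path / "out2")
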