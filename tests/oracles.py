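"""Brute-force reference implementations used to cross-check the pipeline.

These deliberately use naive O(n*w) loops and direct interval algebra,
independent of the vectorized/incremental code paths they validate.
"""

import numpy as np

import endodoc as e
from endodoc.taxonomy import (
    IMAGE_LABELS,
    INSTRUMENT_LABELS,
    LABEL_INDEX,
    UNINFORMATIVE_LABELS,
)


def brute_smooth(stream, window_s):
    """Per-frame windowed mean by explicit scan."""
    ts = stream.timestamps
    conf = stream.confidences
    half = window_s / 2.0
    out = np.empty_like(conf)
    for i in range(len(ts)):
        sel = [j for j in range(len(ts))
               if ts[i] - half <= ts[j] <= ts[i] + half]
        out[i] = conf[sel].mean(axis=0)
    return out


def brute_runs(ts, mask, end_s):
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = float(ts[i])
        elif not m and start is not None:
            runs.append((start, float(ts[i])))
            start = None
    if start is not None:
        runs.append((start, float(end_s)))
    return runs


def brute_merge(runs, max_gap):
    merged = []
    for s, ee in runs:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], ee))
        else:
            merged.append((s, ee))
    return merged


def brute_filter(runs, min_dur):
    return [(s, ee) for s, ee in runs if ee - s >= min_dur]


def brute_clip(runs, lo, hi):
    out = []
    for s, ee in runs:
        s2, e2 = max(s, lo), min(ee, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def brute_interventions(stream, body, cfg):
    mask = []
    for i in range(len(stream)):
        mask.append(any(
            stream.confidences[i, LABEL_INDEX[l]] >= cfg.threshold(l)
            for l in ("polyp", "biopsy_forceps", "snare", "wound")))
    runs = brute_runs(stream.timestamps, mask, stream.end_s)
    merged = brute_merge(runs, cfg.merge_gap_s)
    kept = brute_filter(merged, cfg.min_duration_s)
    return brute_clip(kept, body[0], body[1])


def brute_eligible(stream, cfg, i):
    return all(stream.confidences[i, LABEL_INDEX[l]] < cfg.threshold(l)
               for l in UNINFORMATIVE_LABELS)


def brute_landmark_selection(stream, label, cfg):
    """Earliest eligible argmax; None below threshold."""
    best_i, best = None, -1.0
    col = LABEL_INDEX[label]
    for i in range(len(stream)):
        if not brute_eligible(stream, cfg, i):
            continue
        c = stream.confidences[i, col]
        if c > best:
            best, best_i = c, i
    if best_i is None or best < cfg.threshold(label):
        return None
    return best_i


def brute_polyp_selection(stream, interval, cfg):
    """Role -> frame position, by exhaustive scan."""
    polyp = LABEL_INDEX["polyp"]
    chromo = LABEL_INDEX["chromoendoscopy"]
    instr = [LABEL_INDEX[l] for l in INSTRUMENT_LABELS]
    out = {}
    for i in range(len(stream)):
        t = stream.timestamps[i]
        if not (interval[0] <= t < interval[1]):
            continue
        if not brute_eligible(stream, cfg, i):
            continue
        row = stream.confidences[i]
        chromo_above = row[chromo] >= cfg.threshold("chromoendoscopy")
        instr_above = any(row[j] >= cfg.threshold(IMAGE_LABELS[j])
                          for j in instr)
        if not chromo_above and not instr_above:
            if out.get("polyp_white_light", (None, -1.0))[1] < row[polyp]:
                out["polyp_white_light"] = (i, row[polyp])
        if chromo_above:
            if out.get("polyp_chromo", (None, -1.0))[1] < row[polyp]:
                out["polyp_chromo"] = (i, row[polyp])
        if instr_above:
            score = min(row[polyp], max(row[j] for j in instr))
            if out.get("polyp_with_instrument", (None, -1.0))[1] < score:
                out["polyp_with_instrument"] = (i, score)
    return {role: i for role, (i, _) in out.items()}


def brute_corrected_times(timeline, dt):
    """Corrected durations by discretized overlap accumulation."""
    cecum = withdrawal = 0.0
    grid = np.arange(timeline.t_enter_body, timeline.t_exit_body, dt)
    for t in grid:
        in_intervention = any(s <= t < ee for s, ee in timeline.interventions)
        if not in_intervention:
            continue
        if timeline.t_first_cecum <= t < timeline.t_last_cecum:
            cecum += dt
        elif timeline.t_last_cecum <= t < timeline.t_exit_body:
            withdrawal += dt
    return ((timeline.t_last_cecum - timeline.t_first_cecum) - cecum,
            (timeline.t_exit_body - timeline.t_last_cecum) - withdrawal)


def random_timeline(rng):
    """A random valid timeline with up to three disjoint interventions."""
    anchors = np.sort(rng.uniform(0.0, 1000.0, size=4))
    t_enter, t_first, t_last, t_exit = (float(a) for a in anchors)
    k = int(rng.integers(0, 4))
    interventions = []
    if k and t_exit - t_enter > 1.0:
        points = np.sort(rng.uniform(t_enter, t_exit, size=2 * k))
        interventions = [(float(points[2 * i]), float(points[2 * i + 1]))
                         for i in range(k)
                         if points[2 * i] < points[2 * i + 1]]
    return e.ExamTimeline.from_anchors(
        t_enter, t_first, t_last, t_exit, end_s=1000.0,
        interventions=interventions)
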