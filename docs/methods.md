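# Methods

## Problem setting

Withdrawal time — the time spent inspecting the mucosa while withdrawing
the colonoscope from the cecum — is an established colonoscopy quality
metric, but its measurement in practice is unstandardized (report
timestamps, stopwatches) and does not account for time spent on
interventions. endodoc computes it, and the accompanying
photodocumentation, deterministically from a frame classifier's output.
The classifier itself is out of scope: any callable producing per-frame
confidences for the ten image labels can feed the pipeline, and the
package ships a glyph-based toy classifier only to close the loop in
end-to-end tests.

## Data model and conventions

Timestamps are seconds from recording start; for video-derived streams
`timestamp_s = frame_index / fps`. All intervals are half-open
`[start, end)`, which makes duration arithmetic exact and lets phases tile
the recording without double counting. A run of evidence frames ends at
the timestamp of the first frame after it (or at the last timestamp plus
one frame period at the end of the stream). Confidences are serialized
with six decimals and compared at 1e-6 — far below any clinically
meaningful resolution. The label name `appendix` canonically denotes the
appendiceal orifice.

## Segmentation

The post-processor is a threshold → sustained-run → merge/filter design:

* **Smoothing**: centered moving average over frames within ±`window_s`/2
  (default 1 s), truncating at the recording boundaries. Defined on
  timestamps, so the pipeline is rate-agnostic; 10 fps is the reference
  ingest rate of the real-time application, not an assumption.
* **Body interval**: frames with smoothed `outside` confidence strictly
  below threshold are in-body; runs sustained ≥ `min_sustain_s` (default
  2 s, rejecting single-frame false positives at 10 fps) are kept, and the
  body spans the first sustained run's start to the last one's end.
* **Cecum anchors**: a frame is cecal evidence when *any* landmark label
  reaches its threshold (a cecal image is credited if any of the three
  landmarks is identifiable). Evidence runs are computed globally, clipped
  to the body interval, sustain-filtered; `t_first_cecum` / `t_last_cecum`
  are the first run's start and last run's end. No sustained run ⇒
  `NoCecumDetected`, and the exam yields no timing summary.
* **Interventions**: evidence is any of polyp / biopsy forceps / snare /
  wound at threshold. Chromoendoscopy deliberately does *not* trigger
  intervention — digital image enhancement also occurs during plain
  inspection. Runs merge when gaps are strictly below `merge_gap_s`
  (default 5 s, bridging brief occlusions during one polypectomy), then
  runs shorter than `min_duration_s` (default 2 s) drop, then intervals
  are clipped — never extended — at the body boundaries. Polyp sequences
  use the same run/merge/filter parameters on the polyp label alone.
* Ties at exactly the threshold resolve consistently: evidence uses `>=`,
  in-body uses `<`; run boundaries fall on the earliest frame.

Computing evidence runs globally and clipping afterwards (rather than
scanning only in-body frames) is an equivalent formulation chosen so the
streaming engine can track runs before the body interval is known.

The true post-processing used with the clinical system is not public;
this design is the simplest mechanism that reproduces the described
outputs (a re-design, not a reconstruction). Whether it used hysteresis or
state-machine smoothing is unknown; the sustained-run design with separate
merge/filter stages was chosen for transparency and testability. How a
resection instrument visible during insertion should be handled is equally
unstated (such exams were excluded from the clinical test set); here such
evidence contributes to `t_intervention_total` but never corrects
insertion.

## Timing

The six durations follow directly from the anchors (see README). The two
corrected durations subtract, per phase, only the intervention time
overlapping that phase, so an intervention straddling the
cecum/withdrawal boundary splits between the two corrections; interventions
during insertion correct neither. Consequences that hold by construction
and are asserted as properties: the three uncorrected durations sum to the
in-body duration; corrected values never exceed uncorrected ones; the sum
of both corrections never exceeds the total intervention time; all
durations are shift-invariant.

The divergence flag for comparing a predicted against a measured
withdrawal time is strict (`> threshold`, default 0.20): a prediction
diverging by exactly 20 % is not flagged. Percentage summaries
(specificity of selected images, polypectomy representation rate) round
half-up to one decimal, matching how such figures are conventionally
printed. A `reported_withdrawal_time` helper subtracts two user-supplied
photo timestamps (the common clinical fallback) but is not used by the
pipeline.

## Image selection

Eligibility: no uninformative label at/above its threshold (this also
excludes out-of-body frames). Landmark images are chosen over the whole
stream, not only the cecum segment — landmarks are often best seen on
withdrawal re-inspection — and require the winning confidence to reach the
label's threshold. Polyp roles within a sequence:

* *white light*: argmax polyp confidence with chromoendoscopy and both
  instruments below threshold (white light is defined operationally, since
  it is not itself a label; instruments are excluded to keep roles
  distinct);
* *chromo*: argmax polyp confidence with chromoendoscopy above threshold;
* *with instrument*: argmax of `min(polyp, max(instrument))` with an
  instrument above threshold — the min-score demands both objects be
  confidently visible, since no scoring rule is prescribed for this role.

Roles are omitted when no qualifying frame exists; ties go to the earliest
eligible frame, making selection independent of frame storage order.
Selection operates on the smoothed stream, consistent with segmentation.
This design allows up to 3 landmark and 3 per-polyp images and does not
impose a per-exam image cap.

## Streaming engine

The engine ingests frames one at a time and maintains the smoothing buffer,
run trackers and provisional landmark trackers incrementally; a frame is
smoothed once a frame more than half a window ahead has arrived, so
real-time smoothing is centered, at the cost of `window_s`/2 of latency —
equality with the offline pipeline was prioritized over latency, and
mid-exam provisional outputs are advisory only. The smoothing kernel is
shared verbatim with the offline path and applied to identically shaped
buffers, so the smoothed values — and hence every downstream quantity —
are bit-identical, which the tests assert on serialized JSON. Per-push
work is bounded by the window length (an operation counter exposes this);
`finalize()` does a single linear pass for image selection over the
accumulated smoothed frames, never re-scanning on push.

## Synthetic exams

The simulator is the package's study-condition generator, not a fixture.
An exam is phase durations (defaults: 10 s outside, 5 min insertion, 60 s
cecum inspection, 8 min withdrawal, 10 s outside — an unremarkable
screening exam meeting the ≥6 min withdrawal recommendation), polyp events
(start, duration, resected?, instrument, chromoendoscopy?), and landmark
visibility windows inside the cecum phase. By default the ileocecal valve
is visible for the whole cecum inspection — the phase is, by annotation
convention, delimited by landmark visibility — with the appendiceal
orifice and terminal ileum in sub-windows. During a polyp event the polyp
label is active throughout, chromoendoscopy in the middle third (if used),
the instrument in the final third (if resected), and the wound label for a
fixed 10 s tail afterwards — post-polypectomy wound care belongs to the
intervention, with no published duration, so a single representative value
is used. Low-quality frames are injected as independent 2 % Bernoulli
events to exercise the eligibility filter.

Confidence noise: active labels draw from Beta(8, 2) (mean 0.8), inactive
from Beta(2, 8) (mean 0.2) — separable at the 0.5 threshold yet
overlapping enough that raw thresholding is unreliable and smoothing/run
filtering do real work. `noise=None` yields the exact 0/1 activity
pattern. Draws are i.i.d. across frames; real CNN confidences are
temporally autocorrelated, which the default does not emulate (an AR(1)
blend knob exists, default off). Everything is a pure function of the spec
including its seed.

What passing recovery tests show, and what they do not: they validate the
post-processing machinery — that the run/merge/anchor logic inverts the
generative structure under calibrated, temporally clean noise. They say
nothing about a real classifier's error modes (correlated failures during
retroflexion, specularities, instrument occlusion), which is precisely why
the clinical headline numbers are not re-derivable here.

`random_exam_spec` draws realistic structures (insertion 2–5 min, cecum
30–90 s, withdrawal 4–9 min, 0–3 polyp events of 15–60 s spaced ≥ 20 s)
deterministically per seed; the recovery experiments use 50 such exams
(≈ 4000–10 000 frames each at 10 fps), a problem size that exercises every
stage while keeping the full suite fast.

## Numerical and degenerate-input choices

* Smoothing with `window_s = 0` is the identity; empty streams raise
  `EmptyStream`.
* A smoothed value exactly at threshold follows the comparison rules above;
  a step boundary can therefore shift by at most one frame, which is why
  zero-noise recovery is asserted to within `1/fps`.
* Zero-length phases (e.g. an exam starting in-body) are omitted from the
  segment list; anchors may coincide.
* Exams with no in-body frames raise `NoBodyDetected`; with no sustained
  landmark evidence, `NoCecumDetected` (observed clinically in a small
  fraction of exams). Neither produces a timing summary.
* Timeline JSON rounds times to 3 decimals (1 ms); timing JSON reports
  seconds (3 decimals) and minutes (1 decimal, half-up).

## Known limitations

* No polyp re-identification: two evidence sequences separated by more
  than the merge gap count as two polyps even if anatomically one.
* The per-exam image count is uncapped (up to 3 + 3·polyps), so busy exams
  produce more images than a typical clinical report stores.
* The simulator's noise model is uncalibrated against any real classifier;
  recovery rates under it are an upper bound on real-world behaviour.
* The prediction rate for offline analysis is unconstrained; all windows
  are defined in seconds, so heterogeneous frame rates are handled but
  have not been profiled for very low rates (< 2 fps), where sustain
  filters interact coarsely with frame spacing.
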