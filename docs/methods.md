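# Methods

## Coordinate frame and angle conventions

All geometry lives in the raster frame: origin top-left, x rightward,
y **downward**. A line's angle is `atan2(dy, dx)` of its left-to-right
direction, so a positive endplate or bilateral tilt means the right end
sits inferior on the image. "Left"/"right" in keypoint names are image
x-order, not anatomical side; any anatomical laterality mapping belongs
to the presentation layer.

Angles are normalized to the **half-open** interval [−90°, 90°). The
closed interval would represent a vertical line twice (as −90° and
+90°); mapping the +90° boundary to −90° removes the ambiguity without
changing any measured magnitude.

## Endplate angles, tilt, Cobb

Superior/inferior endplate angles are the normalized `atan2` angles of
the top and bottom corner segments; the vertebral tilt is their
arithmetic mean. The Cobb magnitude of a candidate end-vertebra pair
(i superior, j inferior) is |α_i − β_j| with the difference first
wrapped to (−90°, 90°]. The wrap matters only when near-vertical
endplates normalize to opposite signs: two lines always meet at an
acute angle, and clinical Cobb values are reported acute, so a raw
difference of 170° is measured as 10°. Consequently every reported
Cobb lies in [0°, 90°].

Segments shorter than 1e−9 px are treated as degenerate and the
vertebra is skipped; a corner keypoint flagged absent (visibility 0)
likewise skips the vertebra. Skipped vertebrae are removed from the
candidate pair set but do **not** split the search interval — one
low-confidence vertebra should not truncate a curve — and their indices
are listed in the report's audit trail.

## End-vertebra search and multi-curve decomposition

The search over an interval [s, e] is a plain exhaustive scan of all
pairs with j − i ≥ `min_span` (default 3 vertebrae, guarding against
short-range spurious pairs). The argmax pair is reported when its
magnitude reaches `min_angle` (default 5°); exact ties resolve to the
lexicographically smallest (i, j), which deterministically favors the
more cranial curve. At ≤17 vertebrae the O(n²) scan is at most 136
pairs, so nothing cleverer is warranted.

Decomposition runs the search once over the whole sequence, then once
over each flanking interval [0, i] and [j, N−1]. The primary end
vertebrae stay in the flanking intervals as candidates, so adjacent
curves may share a transitional vertebra, matching clinical convention.
Recursion stops after that single level: at most three curves, which is
also the clinical expectation for a whole-spine radiograph. When
`max_curves` < 3 forces a choice between two flanking curves, the
larger Cobb magnitude is kept (tie: more cranial) — the cap exists to
limit output, and dropping the smaller curve loses the least
information.

## Level numbering

With a pelvis, the PSIS line is the mean y of the two PSIS points, and
the most caudal vertebra whose **box center** lies above it is L5.
The box center was chosen over the inferior corner as the reference
point because it is robust to corner jitter; nothing else in the
anchoring depends on corner positions. Labels then run superiorly
L4 … T1; more than 17 visible vertebrae, or any vertebra below the L5
anchor, is an error rather than a silent guess. Without a pelvis, the
most superior visible vertebra is assumed to be T1 and a standing
warning records that assumption.

The aspect-ratio verification (mean thoracic h/w > mean lumbar h/w)
is advisory: a failure warns but never re-labels, because silent
re-labeling would break auditability and no threshold or corrective
rule is defined for it.

## Synthetic spines and ground truth

The simulator emulates keypoint annotations of a standing PA
radiograph; it never synthesizes pixels. The centerline deviates
laterally by a sum of Gaussian bumps x(s) = Σ A_k exp(−(s−μ_k)²/2w_k²)
over arc parameter s ∈ [0, 1]; vertebra n sits at equally spaced s_n as
a W×H rectangle whose endplates are perpendicular to the centerline
tangent, giving the closed-form inclination φ_n = atan2(−x′(s_n), L).
Both endplates of a vertebra are therefore parallel (α_n = β_n = φ_n
exactly): this makes the ground truth analytic and isolates
search-logic errors from wedge-shape effects, which are out of scope.
The true curves are the same admissible-pair search applied to φ
directly, an input path that never touches keypoints.

Default dimensions, chosen once for realism at a typical downsampled
whole-spine radiograph scale: column length 1530 px for 17 vertebrae
(≈90 px per level), thoracic vertebrae 80×72 px and lumbar 100×70 px —
height/width 0.9 and 0.7 respectively, preserving the thoracic > lumbar
aspect-ratio ordering the level verification relies on. The PSIS pair
sits one vertebra-height plus disc gap caudal to the lowest vertebra,
separated by twice the lumbar width and inclined at the requested
pelvic tilt; only its y-relation to L5 matters for anchoring.
Single-bump cohorts sample the bump center from U(0.35, 0.65) and width
from U(0.12, 0.20) of the column and solve the amplitude by Brent
root-finding so the true primary Cobb hits a requested target exactly;
cohort targets are drawn U(5°, 58°), the range a screening population
with confirmed scoliosis spans.

Keypoint noise is i.i.d. isotropic Gaussian jitter applied to every
keypoint, with the jitter field drawn once per seed and scaled by σ, so
error curves across σ are comparable under common random numbers. Two
guards reject degenerate geometry: a separating-axis overlap test on
consecutive vertebra rectangles, and a 60° cap on |φ| (beyond which the
"top edge superior" reading of a rectangle breaks down).

What passing tests on this generator do **not** show: robustness to
wedged or rotated vertebrae, endplate curvature, detector-style
correlated localization errors, occlusion, or image-quality effects.
The generator validates the geometry and search logic, not a detector.

## Agreement statistics

* Consensus: with exactly three readers, a case whose max pairwise
  spread is ≤3° gets the arithmetic mean as reference; a larger spread
  flags `NEEDS_ADJUDICATION` and the case carries no automatic value —
  joint re-reading cannot be automated, so it is not guessed.
  The boundary (spread exactly 3°) takes the mean.
* Error metrics: MAE, median absolute error, RMSE; MAE ≤ RMSE by
  Jensen's inequality, checked as an invariant.
* ICC is fixed to **ICC(2,1)** — two-way random effects, absolute
  agreement, single measurement — computed from the ANOVA mean squares
  (MSR, MSC, MSE). Absolute agreement is the right form for
  method-vs-reference comparison because a constant offset between
  methods must be penalized. The form is echoed in output metadata.
* Bland–Altman uses the sample (n−1) SD and the conventional 1.96
  multiplier (no small-sample t correction); LoA = bias ± 1.96·SD holds
  exactly as stored.
* Stratified tables split by the severity of the **reference** value
  (mild <20°, moderate 20–35°, severe >35°, sub-threshold ≤10°); empty
  strata are omitted.

## Numerical and scale choices

Tolerances: noiseless round-trip agreement between pipeline and
analytic truth is asserted at 1e−6° (observed ≈1e−13°); geometric
invariances at 1e−9°; ICC vs the mean-squares oracle at 1e−9. The
oracle-equivalence check runs 1,000 random sequences; recovery and
noise studies use 200 spines per condition and the invariance suite
100 — sizes at which every statistic assessed here is stable across
seeds while the whole suite stays fast.

## Known limitations

* No vertebral rotation (Nash–Moe) grading, sagittal parameters, Lenke
  classification, or curve-convexity labeling (the signed Cobb
  difference is retained in the audit trail only).
* Shoulder tilt is computed only from a caller-supplied bilateral pair;
  the annotation scheme contains no shoulder landmarks to infer it from.
* The pose-label dialect is an interoperability choice; no DICOM or
  COCO ingestion.
* Severity near stratum boundaries is as noise-sensitive as any hard
  threshold; the report carries the raw angles so downstream users can
  apply their own margins.
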