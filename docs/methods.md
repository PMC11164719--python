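# Methods

This note documents the models and procedures `faceiq` implements, the
conventions chosen where the underlying methodology leaves room, and what
the synthetic fixtures do and do not establish about real casework images.

## Face resolution (FIPP)

The face/head/neck region of a questioned image is located by a manually
supplied rectangular crop box (the workflow this mirrors used a paint tool
to crop to the last visible face pixel; no automatic detection is offered,
deliberately). The face-to-image pixel proportion is the box area over the
original frame area, on bounding-box pixels — a segmentation-mask variant
was considered and rejected because the manual-cropping procedure being
formalised is rectangular.

Conventions: 0-based pixel coordinates, origin top-left, half-open boxes.
FIPP is exact rational arithmetic on integer areas, so it is scale-invariant
and reproducible to the last bit.

## Exposure metrics

All exposure statistics are computed from the 256-bin histogram of the
*cropped* face, after collapsing RGB to grey. Two conversions are offered:
the unweighted channel mean (default, matching the default behaviour of the
histogram tooling the pipeline reproduces) and Rec. 601 luma. Fractional
grey values round half-up. Bit depths above 8 per channel are rejected
rather than rescaled, because silently changing depth would alter every
downstream statistic.

* UFR/OFR use grey values 0–9 and 246–255 ("first/last 10 bins" pinned to
  explicit value ranges). For any image UFR, OFR ∈ [0, 1] and
  UFR + OFR ≤ 1, with equality exactly when no pixel lies between 10
  and 245.
* Moments are **population** moments (skewness = m₃/m₂^{3/2}); the sample
  (bias-corrected) alternative is isolated inside `summarize` and would be
  a one-line swap. On a constant image the skewness is reported as 0 with a
  `degenerate` flag instead of 0/0.
* Median: smallest grey value whose cumulative count reaches ⌈N/2⌉.
  Mode: smallest grey value attaining the maximum count. Both tie-breaks
  are towards the darker value, chosen once and frozen by tests.

Batch extraction walks a folder in lexicographic filename order and writes
two CSVs (`file,total,c0..c255` and
`file,total,mean,median,mode,sd,skewness,min,max,ufr,ofr`); unreadable files
are logged and skipped, and the result object records them so callers can
signal partial failure.

## Quality rubric

The six verbal quality levels are made operational as four independent
criteria, each producing a candidate score; the final score is the maximum
(worst). The quantified bands are:

| score | unusable FISWG components | overlay/artefact % |
|------:|---------------------------|--------------------|
| 1     | 0                         | 0                  |
| 2     | 1                         | (0, 5]             |
| 3     | 2–4                       | (5, 30)            |
| 4     | 5–9                       | [30, 65)           |
| 5     | 10–12                     | [65, 80)           |
| 6     | ≥ 13                      | ≥ 80               |

The percentage boundaries at 5/30/65/80 are formally unassigned in the
verbal definitions ("greater than 5% but smaller than 30%" vs "greater than
30%"); the half-open convention above keeps every value in exactly one band
and keeps the percentage bands aligned with the component counts. Detail
visibility maps detailed → 1, somewhat unclear → 2, limited → 4, absent
→ 5 when only large-scale features remain describable, otherwise 6.
Colour depth below 8 bits per channel is sufficient on its own for score 6.

The free-text resolution/sharpness/illumination "deficiency" wording has no
precedence rule relative to the quantified criteria, so it is carried as an
advisory grade only and never determines the score. Counting rules for the
caller: bilateral features count once if either side is usable; the three
optional components (scars, marks, alterations) are excluded from the
15-component denominator.

The rubric is a pure function; monotonicity in components and overlay is
property-tested over the full discrete lattice against a band-table oracle.

## Triage policy

Decisions are ordered proceed < caution < exclude:

* score 6 → exclude;
* FIPP < `fipp_threshold` (default 0.06) → exclude, even at scores 1–2 —
  the conservative reading, since the face simply carries too few pixels;
  within [0.01, 0.06) a further-research warning marks the band where no
  validated threshold exists;
* otherwise scores 1–2 proceed, scores 3–5 get caution (with an explicit
  `intermediate_quality_score` reason so decisions are reconstructible from
  reasons alone).

Exposure warnings annotate but never change the decision:
UFR > `ufr_warn` (default 0.20) flags false-positive risk, OFR > `ofr_warn`
(default 0.10) notes the false-negative tendency of overexposure. No
validated exposure thresholds exist; the defaults sit between the observed
regimes of heavily underexposed ceiling-CCTV material (mean dark-bin ratio
≈ 32 %) and everything else (≤ 8 %), and are configurable precisely because
they are extrapolations.

## Correctness model

Match correctness collapses comparison outcomes (TP/TN → correct, FP/FN →
incorrect, inconclusive → excluded). The model is a binomial logistic
regression of *incorrectness* on one-hot indicators of the quality score,
reference level = lowest score present, so the intercept is the log-odds of
an incorrect match at score 1 and positive coefficients mean worse scores.

* Penalty: L2 with objective −ℓ(β) + λ‖β‖²/2, implemented via
  scikit-learn's lbfgs solver with C = 1/λ, gradient tolerance 1e-10.
* λ is selected from a log-spaced grid (default 10⁻¹⁰ … 10²) by mean
  accuracy over deterministic unshuffled stratified CV folds; ties resolve
  to the smallest λ. With one-hot predictors the model is saturated, so at
  λ → 0 fitted per-level probabilities equal empirical rates — the
  parameter-recovery tests exploit this closed form.
* The train/test split is an unstratified uniform permutation under an
  explicit seed (the original analysis's split is random and unrepeatable;
  the seed is a logged parameter, and split sizes are
  ⌊0.8 n⌋ / remainder — 309/78 at n = 387). Inconclusive records are
  dropped before splitting.
* Classification threshold 0.5; test-set levels unseen in training fall
  back to the reference level with a warning.
* Metrics with zero denominators are reported as undefined (`None`), not 0.

Exact coefficient values from the original restricted data are not a
reproduction target (unknown split seed, inaccessible images); the model's
sign structure and log-odds recovery on synthetic data are.

## Rank tests and agreement

* Kruskal–Wallis: tie-corrected H on mid-ranks, chi-square reference with
  k − 1 df (delegated to scipy, which implements exactly this statistic;
  an all-tied sample raises a degenerate-data error since the correction
  denominator vanishes).
* Pairwise Wilcoxon rank-sum: exact enumeration when both groups have ≤ 25
  observations and the pooled data are tie-free, otherwise the normal
  approximation with 0.5 continuity correction; two-sided throughout;
  Bonferroni adjustment multiplies by the number of tested pairs and caps
  at 1. The exact/approximate switch point is configurable.
* Weighted kappa: quadratic agreement weights
  w_ij = 1 − ((i−j)/(k−1))² over category positions; the p-value is the
  large-sample normal test of κ = 0 with the Fleiss–Cohen–Everitt null
  variance. Categories default to the sorted union of observed ratings;
  pass the full 1–6 scale explicitly when levels are unobserved, since
  position-based weights otherwise compress the ordinal distances.
* ICC(3,1): two-way mixed, single measures, **consistency** form,
  (BMS − EMS)/(BMS + (k−1)·EMS) from the ANOVA decomposition with F, df and
  p reported. "Two-way, mixed, single-measures" most commonly denotes this
  consistency form; it is invariant to per-rater offsets, which is the
  wanted behaviour for crop pixel totals. Identical columns give ICC = 1
  with F = ∞.

Both agreement statistics are hand-implemented (the H0 p-values are not
available from scikit-learn) and cross-checked in the test suite against
scikit-learn's `cohen_kappa_score` and pingouin's `intraclass_corr`.

## Synthetic fixtures

`make_image` paints a uniform background, fills an elliptical face inside
the crop box with truncated-normal noise, and injects exact pixel counts of
dark (0–9) and bright (246–255) values uniformly over the box. Face noise
is confined to grey values [10, 245] so the injected pixels alone determine
UFR/OFR; realized ratios therefore equal ⌊targets·area⌉/area exactly, and
FIPP follows from geometry. The generator is deterministic per seed
(byte-identical rasters).

`make_study_table` reproduces the four-cohort study structure (75 wildtype
photographs, 100 standard CCTV, 95 eye-level CCTV, 130 analogue CCTV; 400
pools, 13 inconclusive) with exact per-cohort quality-score and outcome
marginals. The joint coupling of score and outcome within a cohort is *not*
part of the published record: deterministic mode pairs ascending scores
with outcomes ordered correct-first — a synthetic, intentionally strong
coupling — while sampled mode randomizes the pairing under a seed.
`make_coupled_records` instead draws outcomes from caller-specified
P(incorrect | score), which is what the model-recovery tests use so their
ground truth is explicit.

What passing tests show: the metric implementations are exact against
brute-force oracles, the rubric and triage rules implement their tables
faithfully, and the model recovers known generating probabilities. What
they do not show: anything about real CCTV optics — compression artefacts,
perspective distortion, motion blur, uneven lighting across the face — none
of which the flat-noise fixtures emulate; conclusions about real-image
performance require the original protected database.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes — images up to
~80×80 pixels, 200 random images for the oracle sweeps, n = 10 000 records
for model recovery (per-level Monte-Carlo error ≈ 0.01 on a probability,
comfortably inside the 0.05 assertion) — sizes at which every check is
exact or oracle-backed while the whole suite stays fast. Floating-point
tolerances: 1e-9 for oracle agreement (exact integer inputs), 1e-3 for
optimizer-limited coefficient comparisons.

## Known limitations

* FIPP is bounding-box based; tight hair/garment crops inflate it slightly
  relative to a face-only mask.
* The rubric formalises examiner judgements; it does not estimate unusable
  components from pixels.
* Exposure warning thresholds are extrapolated defaults, not validated
  cut-offs.
* The exact-Wilcoxon switch point and the CV tuning criterion (accuracy)
  are conventions; both are isolated behind parameters.
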