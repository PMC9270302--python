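# Methods

## The measurement and the two readings of it

A QFR virtual pullback is a sampled curve of index QFR versus position
along a coronary vessel, from the proximal landmark (position 0, the
ostium of the analyzed segment) to the distal landmark (position = total
vessel length, TVL). The distal value of the pre-PCI trace is the vessel's
pre-PCI QFR; likewise for the post-PCI trace. Physiologically the curve is
non-increasing — distal pressure cannot recover along a vessel — so any
upward wiggle is acquisition noise.

**Pre-processing.** Every downstream computation operates on the trace
after (1) linear resampling onto a uniform 0.5-mm grid (the vendor's
sampling density is not published; 0.5 mm is a package choice, fine enough
that window and segment boundaries are not grid-limited, and exposed as
`step_mm`) and (2) projection onto the non-increasing cone by isotonic
regression (pool-adjacent-violators, least squares). The projection is
parameter-free, idempotent and order-preserving, and it is the *only*
smoothing applied: "drop" and "decline" are then well defined under noise
without committing to a bandwidth.

**Quantitative method (QVP index).**

    QVP = [ MaxQFR_20mm / ΔQFR_vessel + (1 − LFD / TVL) ] / 2

* `ΔQFR_vessel` — ostial minus distal index QFR.
* `MaxQFR_20mm` — maximal drop over a 20-mm window. Windows must lie fully
  inside `[0, TVL]`; for vessels no longer than the window the whole-vessel
  drop is used (a short vessel is focal-dominant by construction). Ties go
  to the most proximal window start, for determinism.
* `LFD` — length with functional disease: total length of grid cells whose
  decline exceeds `slope_eps` = 0.002 QFR/mm, after merging segments closer
  than `merge_gap_mm` = 2 mm. The source analysis does not state a numeric
  criterion for "a decline"; both parameters are package choices exposed in
  configuration. 0.002 QFR/mm is an order of magnitude below the shallowest
  clinically meaningful diffuse gradient modelled here, and 2 mm bridges
  single-cell gaps without fusing distinct lesions.

On a monotone trace `MaxQFR_20mm ≤ ΔQFR_vessel` and `LFD ≤ TVL`, so
QVP ∈ [0, 1]: ≈1 means all pressure loss concentrated in one short segment
(focal), ≈0 means loss spread along the vessel (diffuse). Vessels with
`ΔQFR_vessel ≤ min_delta` (default 0.02) raise a no-functional-disease
error rather than returning a sentinel: the index is undefined without
disease, and the study population consisted of vessels undergoing PCI.

Decision thresholds (all configuration defaults, never hard-coded at call
sites, boundary semantics exactly as printed): QVP > 0.71 predicts a focal
pattern, ≤ 0.51 a diffuse pattern; QVP ≤ 0.57 predicts a suboptimal PCI
result; tertile bounds ≤ 0.54 / (0.54, 0.71] / > 0.71; a suboptimal PCI
result is post-PCI QFR ≤ 0.89.

**Qualitative method.** The clinical definitions are: focal = a single
drop ≥ 0.05 within 10 mm; serial = two or more separated focal drops;
diffuse = progressive decline without clear evidence of a focal drop;
combination = any mixture. Mechanisation requires three quantities the
clinical text leaves to the reader's eye, all exposed in configuration:

* *"separated"* → at least `separation_mm` = 5 mm of near-plateau (drop
  < 0.01) between focal events;
* a *diffuse* component → a declining region ≥ 15 mm long with cumulative
  drop ≥ 0.05 after excluding focal events. These bounds keep a 30–60 mm
  gentle gradient detectable while the shoulders of a focal step (steep
  core ≤ 10 mm) are not;
* focal events are chosen greedily by descending magnitude (ties: shorter
  span, then more proximal) among all grid windows with span ≤ 10 mm and
  drop ≥ 0.05, subject to disjointness and plateau separation — the
  deterministic analogue of a reader marking the steepest step-ups first.

One numerical wrinkle: the isotonic projection of a noisy gentle ramp is a
staircase whose flat treads can span 2–4 mm, so the cell-level diseased
segments of a ramp are fragmented. When assembling *diffuse events* (not
when measuring LFD) segments are therefore bridged across gaps up to
`diffuse_merge_gap_mm` = 6 mm. Plateau noise cannot masquerade as diffuse
disease through this bridging because a plateau's cumulative drop under
σ = 0.005 noise stays far below the 0.05 event threshold.

Classification: 1 focal event → focal; ≥2 focal → serial; diffuse only →
diffuse; both kinds → combination (also when ≥2 focal drops coexist with a
gradient, since "combination" covers any mixture). No events → the same
no-functional-disease error as the quantitative method.

The study's two human reviewers (plus consensus) cannot be reproduced;
inter-rater agreement is instead exercised by running the classifier under
a strict (default) and a slightly more lenient preset on the same traces
and reporting Cohen's kappa. This measures the rules' sensitivity to
threshold choice, not human agreement.

## Synthetic cohorts

Because the per-vessel traces are not deposited, the generator emulates the
published cohort structure: TVL uniform on 55–80 mm (median ≈ 65), ostial
QFR uniform on 0.97–1.0, distal pre-PCI QFR targeted at 0.70–0.77, pattern
mix 43/17/12/28 % (focal / serial / diffuse / combination), additive
i.i.d. Gaussian noise σ = 0.005 QFR units, and about 8 % of patients
contributing a second vessel. Defaults are calibrated once to the printed
medians and interquartile ranges; they are generating conditions, not free
parameters.

Lesion shapes are the simplest ones satisfying the qualitative
definitions: focal lesions are logistic step-downs with a 1.5–3 mm
transition (their steep core sits well inside a 10-mm window), diffuse
disease is a linear ramp. Ramp slopes are drawn from 0.0028–0.0038 QFR/mm
(hard cap 0.0040): steeper ramps would lose ≥ 0.05 over some 10-mm window
— under noise even ≈ 0.0045 occasionally does — and would stop being
diffuse under the rules they are meant to instantiate. Consequences of
this constraint, accepted deliberately: generated diffuse ramps are
45–70 mm long (the upper half of the published diffuse LFD range
45 [30–55] mm), diffuse vessels draw TVL from 65–80 mm, and their distal
QFR can sit slightly above the 0.77 target ceiling. Serial vessels place
2–3 steps (each drop ≥ 0.07) with centres ≥ 20 mm apart so the plateau
between detected events survives noise; combination vessels place one
focal step and one ramp separated by ≥ 8 mm, in random order, shifting any
drop the ramp cannot absorb onto the focal component so the distal target
is still met.

**PCI simulation** is pure bookkeeping, not hemodynamics. The default
strategy stents every focal component (stent length = core + 10–14 mm,
largest drops first) while total stented length fits a 40-mm cap — a
lesion beyond the cap is left untreated — and spends the remaining cap on
the most diseased diffuse area from its proximal end, covering 65–100 % of
what remains. A focal component vanishes iff its core is covered; a
diffuse component keeps drop proportional to its uncovered length; each
stent adds a small in-stent gradient (uniform on [0, 0.012]). The post-PCI
trace is rebuilt from the residual components with fresh noise. An
alternative single-stent strategy (`stent-max-drop-segment`) centres one
stent on the maximal 20-mm drop. This mechanism reproduces the direction
of the clinical findings — stenting part of a diffuse area raises the
residual QFR but often not enough — without fitting anything: the
published correlation (r = 0.62) and C-statistic (0.80) belong to clinical
data this package cannot see, and the synthetic analogues (r ≈ 0.8,
AUC ≈ 0.9) are systematically cleaner because the generator contains none
of the biological variability (tandem intermediate lesions, ostial
effects, measurement-angle artefacts) of real angiograms. Passing the
directional checks therefore shows the pipeline's internal consistency and
the mechanism's plausibility, not clinical validity.

## Cohort statistics

* ROC: empirical curve over all midpoints between adjacent distinct
  scores (± sentinels); AUC by trapezoid; the reported cutoff maximizes
  sensitivity + specificity with ties broken toward the smaller threshold,
  and is printed to 2 decimals. For the suboptimal-PCI analysis the low
  score predicts the event, so "score ≤ cutoff" is the positive call.
* Pearson r with a Fisher-z 95 % interval.
* Cohen's kappa on the cross-tabulation, large-sample variance interval.
* Group comparisons: one-way ANOVA (continuous), Fisher exact
  (categorical; exact for 2×2, seeded Monte-Carlo estimate of the exact p
  with ≥ 10⁵ fixed-margin permutations for larger tables, add-one
  corrected), Bonferroni adjustment across the reported family.
* Standardized β: outcome and predictors z-scored, OLS with
  cluster-robust covariance grouped by patient. This replaces a
  patient-level random-intercept model; with ~8 % multi-vessel patients
  the two are near-identical, and only the sign and ordering of
  coefficients (focal positive, diffuse negative) are treated as
  contractual on synthetic data.

## Degenerate inputs and numerical choices

* Traces must have ≥ 2 samples, strictly increasing positions starting at
  0, and QFR in (0, 1.05] (the small allowance above 1 is for ostial
  noise).
* A negative ΔQFR (possible only on raw, non-projected input) is returned
  with a warning rather than silently clipped.
* A cohort with a single outcome class skips the ROC stage with a warning;
  single-pattern cohorts skip group tests and pattern regression the same
  way; everything else is still reported.
* All randomness flows from explicit integer seeds (numpy `default_rng`);
  identical config + seed gives byte-identical output files. The
  Monte-Carlo Fisher seed is recorded in the analysis report.

## Problem sizes

Default cohorts are 120 vessels (the published cohort size); property and
directional checks in the test suite use 500-vessel cohorts and 200-seed
oracle sweeps, sizes at which the binomial noise on a rate is ≈ 2 % and a
full pipeline run takes seconds on one CPU.

## Known limitations

* No QFR computation from angiograms: traces are the input.
* The generator's lesion geometry is calibrated only to printed medians
  and IQRs; the joint distribution of pattern, vessel and lesion geometry
  in real cohorts is unknown.
* Diffuse archetypes are constrained to slopes the qualitative rules can
  classify as diffuse, which skews generated diffuse LFD long (see above).
* The in-stent residual gradient and untreated-lesion mechanisms are
  stylised; no instent restenosis, recoil or operator error model.
* The strict/lenient kappa is a sensitivity analysis of the rule
  thresholds, not a reproduction of human inter-observer agreement.
* QVP has not been compared head-to-head against the motorized-pullback
  pressure-gradient index it adapts; that comparison needs wire data.
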