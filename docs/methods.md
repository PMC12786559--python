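# Methods

## Model structure and assumptions

`crcscreen` implements a one-round, two-arm decision tree for
stool-based CRC screening in a fixed cohort of 1,000,000 average-risk
adults. The event sequence per arm is: disease-state partition →
stool-test completion (screening adherence) → test result
(state-specific sensitivity; 1 − specificity in the no-neoplasia
state) → diagnostic-colonoscopy attendance (follow-up adherence) →
lesion detection (colonoscopy sensitivity). The cohort engine
propagates continuous expected person-counts; nothing is rounded until
report formatting, because several published outcome rows are only
reachable without intermediate rounding.

Key structural assumptions:

- **Single round, prevalent disease only.** No incidence, aging, stage
  progression before symptomatic presentation, or repeat screening.
- **Symptomatic presentation within 10 years.** Every prevalent cancer
  not screen-detected (unscreened persons, false negatives, positive
  non-attendees, colonoscopy misses) presents clinically within the
  horizon and incurs treatment cost at a late-stage-weighted per-case
  cost.
- **APL removal prevents cancer.** A detected advanced precancerous
  lesion is removed; 8% of APLs would otherwise become CRC within
  10 years, so prevention = detected APL × 0.08. Prevented cases enter
  the ledger as a *credit* at the symptomatic per-case cost. Cancers
  arising from *undetected* APLs are computed (exposed as
  `undetected_apl`) but deliberately excluded from treatment costs:
  that exclusion is the unique ledger consistent with all four
  published cost rows, as the calibration cross-check shows.
- **No discounting, no QALYs, no colonoscopy-complication costs, no
  age/sex/race stratification.** The model is a budget-impact
  estimator, not a cost-effectiveness analysis.

## Parameters

All defaults live in `crcscreen.params` and are stored as fractions at
full published precision (71.3% → 0.713). The arm-specific inputs:
screening adherence 0.713 (ng mt-sDNA) vs 0.321 (FIT); follow-up
adherence 0.771 vs 0.451; CRC sensitivity by stage (0.88, 0.929, 1.0,
1.0) vs (0.56, 0.786, 0.733, 0.833); APL sensitivity 0.433 vs 0.233;
NAA 0.125 vs 0.067; specificity 0.927 vs 0.957; kit cost USD 591.92
(billed per returned kit) vs USD 18.05 (billed for all 1,000,000
offered — the published billing footnotes differ by arm, and this
asymmetry is load-bearing for the cost rows). Shared inputs: prevalence
CRC 0.45%, APL 10.4%, NAA 34.4%; APL→CRC 10-year transition 8%;
colonoscopy sensitivity 0.95 for CRC and 0.940 for APL (the
lesion-size-weighted mean of 75/85/95% over a 1.3/7.4/91.3% size mix);
colonoscopy USD 1602 without and USD 2223 with polypectomy; treatment
USD 174,362 / 375,526 / 495,464 per localized/regional/distant case.

Stages map to SEER summary groups as I, II → localized, III → regional,
IV → distant; this standard convention is also the only stage map that
reproduces both arms' published treatment totals.

## Calibrated inputs

Two required inputs are not published and are recovered in
`crcscreen.calibration` by inverting printed outputs; printed outcome
values are confined to that module so the engines never read their own
targets.

**Prevalent-CRC stage distribution.** Detections at stage *s* are
proportional to g_s × Se_s × f × c_CRC, so g is recovered from the ng
arm's published stage detections (639, 377, 871, 348) as
g ∝ detected/Se, normalized: (0.3089, 0.1726, 0.3705, 0.1480), frozen
as the default. Because only ng inputs enter, predicting the FIT arm's
stage counts is genuine cross-validation; the prediction (107.05,
83.97, 168.07, 76.31) matches the published (107, 84, 168, 76) within
0.32 cases.

**Symptomatic per-case cost.** Solving the treatment ledger
(printed total − screen-detected stage cost)/undetected count gives
USD 329,502 (ng) and USD 329,619 (FIT); the printed prevention credit
divided by prevented cases gives USD 329,741 — three independent
estimates agreeing within 0.07%. The default is represented as a
stage-group distribution (0.37, 0.39, 0.24) over
localized/regional/distant, implying USD 329,880 per case; a
distributional form was chosen over a bare unit cost so the ±10%
stage-cost scenarios propagate into symptomatic costing coherently
(`SymptomaticCosting` also supports a direct unit cost).

## Economic ledger choices

- Polypectomy pricing applies to every colonoscopy at which a lesion
  (CRC, APL, or NAA) is present in the attendee; no-lesion (false
  positive) colonoscopies are priced without polypectomy. The published
  footnote also mentions non-neoplastic findings requiring biopsy
  without giving a rate, so `fp_biopsy_fraction` (default 0) lets a
  fraction of no-lesion colonoscopies carry the polypectomy price; the
  residual ~USD 1M gap on the colonoscopy cost row (148.0 vs 149
  published) sits inside this under-specification.
- Costs accumulate in exact USD; reports render money totals in
  millions and per-patient values in whole USD, with percentage deltas
  using the FIT arm as denominator.

## Scenario analyses

`crcscreen.sensitivity` implements three deterministic families: a
one-way ±10% sweep (each input separately — per arm for test cost and
the two adherences, once for the shared prevalences, transition,
colonoscopy costs, and each stage-group treatment cost), FIT adherence
uplift ×1.2/1.4/1.6 (multiplicative on the real-world values, per knob
and jointly — "increased by 20%" is read multiplicatively, consistent
with "compared with current adherence values"), and FIT per-offered
program costs of USD 20–100. A bisection search (tolerance 1e-4,
checked against a 0.001-step grid) finds the smallest FIT adherence
multiplier at which FIT's overall total falls to the ng arm's,
reported separately for the screening, follow-up, and joint knobs.

With the rounded published inputs the base overall delta is USD 48M in
favour of ng mt-sDNA (the published tables, computed from unrounded
regulatory values, print 44M; the gap traces mostly to the APL
detection row, 23,270 recomputed vs 23,206 printed). Because the
prevention credit differs between arms by ~USD 525M, any −10% scenario
on the APL channel (APL prevalence, APL→CRC transition, ng follow-up
adherence) swings ~USD 50M and flips the sign of the delta — an
arithmetic consequence of the published numbers themselves, reported
as-is by `analysis/03_sensitivity.py`. The single-knob break-even FIT
adherence multipliers compute to ≈1.64.

## Microsimulation oracle

`crcscreen.microsim` simulates individual persons through the identical
event tree (multinomial disease state, Bernoulli events in fixed order,
per-person cost items, a Bernoulli 10-year progression draw for each
APL, and a drawn symptomatic stage group for each missed cancer) from a
single explicitly seeded `numpy.random.Generator`, so every
expected-value output is testable against an independent stochastic
computation. `compare_to_cohort` z-scores each shared outcome using
binomial SEs for counts and CLT SEs for cost totals, flagging |z| > 4.

What the oracle does and does not show: agreement at n = 10⁶ (max |z|
≈ 1.8 at the defaults) verifies that the deterministic engine computes
the expectations of the stated stochastic process — it says nothing
about whether that process matches real screening behaviour
(correlated adherence, within-person repeat testing, secular trends are
all absent by design). At small n the empirical-SE z-scores for
heavy-tailed cost totals are anticonservative (a cohort of 1,000 FIT
persons carries ~4.5 expected CRC cases), so the comparator reports
z = NaN when zero events were observed, and the validation contract is
intended at n ≥ 10⁵. Convergence of relative errors follows n^(−1/2)
(log-log slope ≈ −0.5 over n = 10⁴…10⁶, estimated from 32 seeds × 4
count outcomes, a replication level chosen so the slope estimator's
spread is well inside the ±0.1 acceptance band).

## Numerical notes and limitations

- Probability distributions are accepted when within 1e-6 of 1 and then
  normalized exactly; probabilities outside [0,1] are rejected at
  validation, and scenario transforms that push a probability above 1
  saturate at 1 with a warning.
- Zero denominators (no detections, nobody screened) yield infinite NNS
  and NaN ratios rather than exceptions.
- Expected counts are fractional by design; published integer rows are
  matched after rounding only.
- The model shares its single-round, prevalence-only scope with the
  published analysis; none of its outputs should be read as lifetime
  cost-effectiveness.
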