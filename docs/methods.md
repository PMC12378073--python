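# Methods

## Scope and model

`bmrisk` assesses non-carcinogenic risk to breastfed infants from two
milk contaminants, melamine (MEL) and cyanuric acid (CYA). The exposure
model is the standard screening-level dose equation: per infant,
EDI = C × FIR, where C (ng/mL) is the contaminant concentration in the
mother's milk and FIR (mL per kg body weight per day) the milk intake
rate; the dose is therefore already normalised per kg body weight, and a
group's EDI is the arithmetic mean of its infants' EDIs (summing across
infants would not be dimensionally meaningful). Risk is screened as
HQ = EDI/TDI per analyte and HI = HQ_MEL + HQ_CYA for the mixture, with
the conventional strict threshold: HI > 1 flags potential concern.

Reference constants are fixed package-wide: TDI 3150 (MEL) and 2500
(CYA) ng/kg bw/day — the most conservative published values — and method
limits LOD 90/100, LOQ 270/310 ng/mL. They enter as given constants; no
analytical-chemistry computation is in scope.

## Left-censored statistics

Concentrations below the LOD are non-detects. Following common practice
for this study type, the package implements substitution rules only
(`exclude`, `zero`, `half_lod`, `lod`) rather than maximum-likelihood
censored estimators; `exclude` is the default for descriptive tables
because published survey minima typically exceed the LOD, implying
non-detects were omitted from means and ranges. For any dataset with at
least one non-detect the rule means are ordered
mean(exclude) ≥ mean(lod) ≥ mean(half_lod) ≥ mean(zero), which the test
suite checks as a property.

Detection frequencies carry exact equal-tailed 95% CIs (Clopper–Pearson,
via `scipy.stats.binomtest`). Group differences use rank tests —
Mann–Whitney U for two groups, Kruskal–Wallis for three or more — with
tie-corrected statistics and two-sided p-values. The Mann–Whitney normal
approximation is used *without* continuity correction so that identical
samples yield p ≈ 1 under the tie-corrected variance; for small untied
samples scipy's exact method applies automatically. TDI exceedance is
reported as a count, with a chi-square goodness-of-fit test against a
reference proportion when that reference is non-degenerate (a 0%
reference has a degenerate expectation, so only counts are reported).

## Display convention for risk tables

Published risk tables round HQ to two decimals and print an HI equal to
the sum of the *rounded* HQs (e.g. raw HQs 0.01284 and 0.02305 print as
0.01 and 0.02 with HI 0.03, not round(0.03589) = 0.04). The package
carries raw unrounded values everywhere and derives display values by
half-up rounding at two decimals, summing displayed HQs into the
displayed HI. The `at_risk` flag always uses the raw HI.

## Age strata and cohort conventions

Infants are stratified as 0–2 months (≤ 60 days), 2–4 months (61–120)
and 4–6 months (121–180); generated cohorts default to sizes 20/15/15
with ages uniform in 15–60 / 61–120 / 121–150 days (the survey enrolled
infants of 15–150 days). Body weight is lognormal around WHO-typical
stratum medians 4.5/6.0/7.0 kg with 12% CV; the intake-rate default for
exclusively breastfed infants is 150 mL/kg bw/day (lognormal, 25% CV).
These cohort defaults are generic infant-physiology values, not survey
measurements. Each infant can be linked to their mother's sample by
`sample_id`; unlinked infants draw from the empirical concentration
distribution under a declared resampling seed.

## Monte Carlo engine

Concentrations are modelled as normal (symmetric scatter around the
mean), truncated at zero by redraw since negative concentrations are
unphysical; body weight and intake rate are lognormal, the standard
choice for positively skewed exposure factors. Inputs are drawn
independently (no correlation structure is asserted). Intake can be
parameterised directly as FIR (mL/kg/day) or as intake (mL/day) divided
by body weight per draw. Each of the default 10,000 iterations forms HQ
per analyte and HI; the 95th percentile of the HQ distribution is the
probabilistic risk readout, and the verdict is "below threshold" only
when every P95 HQ and the P95 HI are strictly below 1.

Sensitivity follows the spreadsheet-risk-tool convention: Spearman rank
correlation of each input with the output, squared and normalised to a
contribution-to-variance; inputs are ranked by absolute contribution. A
constant output reports zero correlations with a degeneracy flag.

Randomness is a single master seed expanded into per-variable substreams
(spawned in sorted-variable-name order), so a simulation is
bit-reproducible from its config. Tolerances in stochastic tests use the
bootstrap standard error of the percentile (200 resamples).

Distribution fitting is deliberately method-of-moments: sample mean/SD
for normal, mean/SD of log-values for lognormal. A zero fitted scale
degenerates to a point mass, and an all-point simulation collapses
exactly to the deterministic HQ — both are tested invariants.

## Synthetic-data generator and calibration

No raw survey data are published, so the generator emulates the
published summary structure: 100 censored samples per analyte and a
50-infant cohort. The pinned emulation fixture is produced by
`calibrate_to_targets` in three steps:

1. **Detection geometry.** The concentration location is solved (by CDF
   inversion of the zero-truncated normal, keeping the published
   spread parameters 26/38 as the scale) so the analytic censored
   fraction equals the published 23%/16%. This yields locations near
   109 (MEL) and 138 (CYA) ng/mL.
2. **Non-detect placement.** The exact non-detect counts are
   apportioned across strata by largest-remainder shares and placed
   within strata at random, with a deterministic retry so every stratum
   keeps at least one single-analyte non-detect; values are then drawn
   from the same truncated normal *conditioned* on the observed pattern
   (stratified rejection sampling), so the fixture hits 23/16 exactly
   while the generic generator remains unconditional (binomial counts).
3. **Intake-rate solve.** Per-infant FIRs are solved as the minimal
   relative deviation from a lognormal baseline subject to the equality
   constraints that each group's mean per-infant EDI equal the published
   group EDI, with positivity enforced by active-set clamping. The
   published EDIs therefore reproduce to solver precision (~1e-9).

**A deliberate tension.** The published summary is internally
inconsistent: a concentration scale of several hundred ng/mL cannot be
reconciled with group EDIs of tens of ng/kg/day under any physiological
intake rate (150 mL/kg/day would give EDIs three orders of magnitude
larger), nor can a zero-truncated normal simultaneously carry 23% of its
mass below 90 ng/mL and a detected-value mean of 730 ng/mL (its
log-concave tail bounds the conditional mean well below that). The
fixture prioritises the risk surface — detection counts and the EDI/HQ/HI
table, which are the quantities the analysis consumes — and consequently
its concentration means (~114/147 ng/mL) and effective intake rates
(~0.5 mL/kg/day) are *emulation artifacts*, not estimates of the survey's
raw data. The solved per-infant FIRs are likewise calibration artifacts
(bimodal, with some infants at the positivity bound); fitting a
population distribution to them is not meaningful, which is why the
shipped run config declares the simulation distributions explicitly —
normal concentrations at the fixture's detected moments and a lognormal
FIR at the fixture's effective scale (log-mean −0.7, log-SD 0.5). When a
config declares no distributions, the pipeline fits them from the data,
which is the intended behaviour for real datasets.

What passing tests on this fixture therefore show: the statistical
machinery (censoring, exact CIs, risk arithmetic, simulation,
sensitivity) is correct and reproducible under a data-generating process
with the survey's censoring geometry and risk surface. What they do not
show: recovery of the survey's unpublished raw concentrations or intake
rates, or of its probabilistic results — the published 95th-percentile
HQs and probabilistic EDIs rest on unprinted input parameters and
internally inconsistent units, and are out of scope by design. The
engine's correctness is instead established by property-based checks
(point-mass equivalence, closed-form lognormal quantile recovery,
bit-identical reruns, sensitivity ordering under a 4:1 CV ratio).

## Numerical choices

- Half-up decimal rounding via `decimal.Decimal` (string construction to
  avoid binary-float surprises).
- Truncation by redraw, with a guard against pathological truncation
  windows; conditional draws in the calibrator use rejection sampling in
  the target window.
- The censored-fraction function uses survival-function ratios, stable
  far into the tails.
- Percentiles use numpy's default linear interpolation; percentile
  tables are non-decreasing by construction and tested.
- Active-set projection for the FIR solve iterates at most n+2 times and
  verifies the equality residual before accepting.
- Degenerate cases: n = 1 summaries report SD 0; all-censored series
  under `exclude` yield NaN moments; constant simulation outputs are
  flagged rather than given spurious correlations.

## Problem sizes

Default problem sizes mirror the emulated survey: 100 samples per
analyte, 50 infants, 10,000 Monte Carlo iterations; the full test suite
and the acceptance script regenerate everything from seeds at these
sizes in seconds.

## Known limitations

- Substitution rules only for non-detects; no Kaplan–Meier or regression
  on order statistics (out of scope by design).
- Input independence in the simulation; real concentration–intake
  correlations, if any, are not modelled.
- The fixture's concentration scale is an emulation artifact (see
  above); Table-1-style means from the fixture are not the published
  730/400 ng/mL, which no single truncated-normal model can reconcile
  with the published censoring counts.
- Maternal covariates are generated independently of concentration (the
  emulated survey found no covariate associations), so covariate
  comparisons exercise the pipeline rather than encode structure.
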