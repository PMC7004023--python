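# Methods

## Acuity scale and comparisons

All acuities are compared on the logMAR scale: a Snellen fraction *n/d*
maps to log10(*d*/*n*), so 6/6 is 0.0, 6/12 is ≈0.301 and 6/60 is 1.0;
20-foot fractions convert by ratio equivalence (20/40 ≡ 6/12). Threshold
predicates use an absolute tolerance of 1e-6 logMAR, chosen so that
recorded chart lines compare exactly (the closest distinct standard lines
are ≈0.08 logMAR apart) while floating-point noise in log10 cannot flip
an equality. Survey charts are categorical, so this treats "6/12 or
better" as inclusive of the 6/12 line and "worse than 6/12" as its exact
negation. For data recorded as *continuous* logMAR the same inclusive
rule applies at the numeric threshold; values such as 0.32 count as worse
than 6/12, which is the natural reading but worth knowing when comparing
against analyses that bin continuous logMAR to lines.

Low-vision categories are mapped to fixed ordinal sentinels — CF 2.0,
HM 2.3, PL 2.6, NPL 3.0 logMAR — strictly worse than every measurable
line and strictly increasing in severity. Any such mapping gives
identical classifications because the pipeline only ever compares
acuities to thresholds at 6/6–6/60; the magnitudes are never used.

The better eye is the minimum logMAR over the measured eyes; one missing
eye falls back to the other, and two missing eyes propagate as missing
rather than as worst, so missingness surfaces as an INDETERMINATE
classification instead of inflating unmet need.

## Classification

The flowchart is evaluated per person at a *need* threshold and an
*outcome* threshold, both defaulting to 6/12 in the better eye:

1. better-eye UCVA missing → INDETERMINATE; UCVA meets the need
   threshold → NO_NEED (including correction owners who see the line
   without it);
2. non-wearers: pinhole (or best-corrected) acuity meets the need
   threshold → UNMET; fails it → OTHER_VI; missing → INDETERMINATE;
3. wearers: CVA meets the *outcome* threshold → MET; otherwise
   pinhole-over-correction / new refraction meets the *need* threshold →
   UNDER_MET, fails → OTHER_VI, missing → INDETERMINATE.

Design choices made where the rules leave room:

- **BCVA precedence.** When both a fresh refraction (BCVA) and a pinhole
  result exist, BCVA decides the improvement test: refraction is the more
  definitive measure of whether the impairment is refractive.
- **Which threshold where.** MET requires the outcome threshold; the
  UNDER_MET/OTHER_VI split uses the need threshold, because that split
  asks whether refractive error is the *cause* of the impairment, not
  whether a service-quality target is reached. With a stricter outcome
  than need (say outcome 6/6, need 6/12), a wearer whose CVA sits between
  the two still goes through the improvement test; without one they are
  INDETERMINATE rather than assumed under-met.
- **Contradictions.** Batteries that are internally odd (CVA worse than
  UCVA) classify strictly by the thresholds and raise a data-quality
  warning; nothing is corrected or dropped. A person not wearing their
  owned correction on the day is simply whatever their measurements
  imply — non-compliance is undetectable in a survey battery.
- **INDETERMINATE is first-class.** It is counted and reported next to
  OTHER_VI in every table; silent exclusion of people with incomplete
  batteries would bias coverage in either direction.

## Estimation

eREC, REC and the quality gap are ratios over the need population
a+b+c. In weighted mode both numerator and denominator are survey-weight
sums (a standard ratio estimator for a domain proportion); estimates are
therefore invariant to rescaling all weights. All arithmetic uses
unrounded proportions; one-decimal display rounding happens only at
serialisation. A zero denominator yields a flagged undefined estimate
carrying its counts, never a silent NaN.

Confidence intervals: the default is the Wilson score interval on the
unweighted proportion (statsmodels implementation); with weights or a
cluster design, a seeded percentile bootstrap resamples clusters — or
persons when unclustered — with 1,000 replicates by default. The quality
gap is reported without an interval; it is a derived ratio of two
correlated estimates and a defensible interval for it needs the
bootstrap, which can be run on request.

Stratified output gives every indicator per stratum-level combination
plus the overall estimate; zero-denominator strata are flagged, not
dropped. Direct standardisation computes Σ share_s · estimate_s over a
reference population share table that must cover all strata and sum to
one; a zero-denominator stratum is an error instructing coarser strata
rather than a guess. Reports always include the 6/12-need, 6/12-outcome
pair for international comparability, appending it when not requested.

## Synthetic cohorts

The generator emulates the population structure the indicators assume:
independent per person, vision-impairing refractive error (prevalence
0.3 by default, optionally per age band), non-refractive impairment
(prevalence 0.05, independent of refractive status, capping pinhole
acuity below the need threshold), correction possession among those with
refractive error (uptake 0.5) and a good visual outcome among owners
(quality 0.8). Acuities are drawn from the standard chart lines
{6/6 … 3/60, CF, HM} consistently with the latent state, the impaired
severity mix skewed towards mild impairment as in most surveys; an
optional one-line jitter stays on its side of the threshold. Under this
independence model the population eREC among those in need is
uptake × quality and REC is uptake — the closed forms the
parameter-recovery tests check against. Because quality is already
conditional on possession, conditioning is the dependence knob; no
separate correlation parameter exists.

Missing data is injected only into pinhole fields
(`missing_pinhole_rate`, default 0), mirroring the measurement surveys
most often skip. The default is zero because pinhole missingness is
category-dependent — only non-wearers and wearers failing the outcome
threshold ever need it — so it biases naive coverage estimates upward;
tests exercise it explicitly instead of baking it into the recovery
conditions.

What the generator does *not* emulate: sphere/cylinder refraction,
acuity test–retest error, correlation between refractive and other
impairment (e.g. both rising with age), non-compliance, informative
missingness beyond pinhole, and realistic cluster effects (clusters are
assigned at random, carrying no intra-class correlation). Passing tests
therefore demonstrate correctness of the classification and estimation
machinery under the stated model, not robustness to the messiness of
real survey data.

## Numerical and reproducibility choices

- logMAR comparison tolerance 1e-6 (absolute); ties in the better-eye
  minimum keep the left eye, which is order-irrelevant since only the
  logMAR value flows on.
- Bootstrap and generator randomness use numpy's integer-state PCG64
  generator seeded explicitly; repeated runs with the same seed produce
  byte-identical cohort files and reports. Derived per-run seeds are
  drawn below 2^31.
- Recovery experiments in the test suite use cohorts of n = 10,000 with
  50 seeds (the headline check) and smaller cohorts elsewhere; at
  n = 10,000 and need prevalence 0.3 the binomial standard error of eREC
  is ≈0.009, so the mean over 50 seeds is expected within 0.01 of truth.
- Report serialisation sorts keys and fixes decimal formatting (four
  places internally, one place for display fields), making outputs
  byte-comparable across runs.

## Known limitations

Presbyopic/near-vision correction need is out of scope and should be
analysed separately. Eye-level (as opposed to person-level) coverage is
not computed. There is no small-area estimation, no time-trend modelling
and no imputation of missing acuities: the package reports
indeterminacy; it does not model it.
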