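# Methods

## The scientific problem

Late-onset Alzheimer disease (AD) is preceded by decades of accumulating
pathology, but the age at which cognition first begins to respond — and the
cognitive domains in which it responds first — cannot be observed directly
without prohibitively long follow-up. A practical alternative uses a genetic
risk score (GRS) for AD, fixed at conception, in a large cross-sectional
midlife cohort: if the association between the GRS and a cognitive measure
strengthens with age, the measure is registering an age-dependent disease
process rather than stable differences in cognitive reserve.

`divage` implements that design as a two-stage procedure plus the
supporting machinery (risk-score construction, a synthetic cohort
generator, and a detectability scan).

## Stage 1 — interaction screen

For each cognitive measure Y (recoded so larger is always better; times and
error counts are negated) the model

    Y ~ link( b_age·Age + b_grs·GRSz + b_int·GRSz×Age + Σ b_i·W_i )

is fit on complete cases, with the identity link (least squares) for
continuous and ordinal measures and the logit link (maximum likelihood) for
binary ones. Covariates W are sex, genotyping assay, assessment center
(when applicable), a practice-effect indicator for online retests, and 10
genetic ancestry principal components. Age enters in decades centered at
40; slopes are reported per decade with Wald 95% CIs (estimate ± 1.96 SE).
Ordinal counts are deliberately modeled with the identity link, accepting
heteroscedasticity in exchange for the interpretable slope scale.

The screen's effect-size metric is the percent ratio 100·b_int/b_age: the
percentage by which a 1-SD-higher score steepens the age-related change.
Measures with p(b_int) below the Bonferroni threshold α/m (m = number of
measures attempted; m = 32 gives 0.05/32 = 1.5625×10⁻³) proceed to stage 2.
Fit failures still count toward m by default (the conservative choice; a
flag reverses it).

Coefficients are named by role (`age_main`, `grs_main`, `interaction`),
never by index, to keep the reporting unambiguous.

## Stage 2 — divergence-age (threshold) model

For a selected measure, and for each candidate threshold age t_thr on a
grid (default integer ages 40–70), the model

    Y ~ link( b0 + b1·t + b2·t² + b_div·GRSz·max(0, t − t_thr)^3 + Σ b_i·W_i )

is fit with t = (age − 40)/10 in decades. Two structural constraints define
the model:

- **no GRS main effect**: below the threshold the score's association with
  the outcome is constrained to exactly zero, so a single age curve
  describes everyone;
- **smooth divergence**: above the threshold the mean diverges by score
  level through a truncated power term of order one above the base
  polynomial. The default quadratic base with a cubic divergence term
  gives a mean function with continuous value, slope and curvature (C²) at
  the knot. The sensitivity forms are a rigid linear base with quadratic
  divergence (C¹) and a flexible cubic base with quartic divergence (C³).

Candidates are compared by mean squared prediction error in a 10-fold
cross-validation. One fold partition, drawn deterministically from
`fold_seed`, is reused for every candidate so that partition noise cancels
out of the comparison rather than being re-drawn per threshold. The
selected threshold is the MSPE argmin; exact ties break toward the
**largest** threshold, the most conservative claim about early divergence
(configurable). The boundary semantics matter: a selection at the grid
minimum says score-specific curves fit best at all observed ages (the true
divergence age is at or below the youngest testable age), while a
selection at the maximum says one curve suffices (no detectable divergence
in range).

A threshold at or above the oldest observed age makes the divergence
column identically zero; the column is dropped, the coefficient recorded
as not estimable, and the fit proceeds as the pure base model. Coefficients
at the selected threshold are refit on all complete cases. A diagnostic
refit that adds a GRS main effect is available to inspect the
zero-association constraint, but never participates in selection.

Age is expressed in decades internally so cubed and quartic terms stay
well-conditioned; all reporting converts back to years.

For the logit link the held-out squared error is taken on predicted
probabilities; this path is functional but flagged experimental, since the
procedure is designed around the continuous measures that survive stage 1.

## Detectability scan

The divergence age is a statement about population means; a separate
question is when the high-score vs low-score gap becomes statistically
detectable. For each age a on the grid, the modeled mean difference between
the 95th-percentile and 5th-percentile z-scores (at reference covariates,
which cancel from the difference) is combined with the fitted model's
residual SD and the observed tail-group counts in the age bin
[a − ½step, a + ½step) to form a one-sided two-sample t statistic
(direction: high score performs worse). The earliest age with p ≤ α
(default .05) is reported, or "not detectable in range". Because the
modeled difference is exactly zero below the threshold, detection can never
precede divergence — asserted on every run. How group variance and sizes
enter this test is not uniquely determined by the design; the implemented
definition (model residual SD, empirical tail counts per bin) is isolated
in one operation so alternatives are pluggable.

## Risk-score construction

The AD-GRS is a weighted sum of effect-allele dosages, standardized by
centering at the scored sample's mean and dividing by its sample SD
(ddof = 1; mean 0, SD 1 to 1e−12). Dosages arrive as VCF (DS field or GT
hard calls, via cyvcf2) or a delimited matrix, and are aligned so each
variant counts its weight's effect allele (d → 2 − d when the matrix
counts the other allele; a counted allele matching neither listed allele
is an error). Strand-ambiguous A/T and C/G variants are scored as-is with
a warning; strict mode drops them. Missing dosages are imputed to the
variant's sample mean dosage (2 × effect-allele frequency), matching common
scoring-tool behavior, with an option to fail instead; participants missing
every dosage get a missing score.

The APOE-region-excluded score drops variants in a configurable chr19
interval (default 44.4–46.5 Mb, GRCh37, spanning TOMM40/APOE/APOC1 with a
margin). APOE ε4 alleles are counted from the unphased rs429358/rs7412
diplotype, with rs429358 counted on C (the ε4/ε1 base) and rs7412 on T
(the ε2/ε1 base): the double heterozygote is ambiguous between ε2/ε4 and
ε1/ε3 and is resolved to one ε4 allele by the most-common-haplotype rule
(ε1 is vanishingly rare) and flagged. The shipped 23-variant weight panel
is synthetic — fabricated identifiers, positions and weights for examples
and tests — because real weights are an input the user supplies.

## Synthetic cohort generator

The generator draws ages uniform on [40, 70] (the enrollment window of the
target study design), sex/assay/practice indicators, assessment centers,
10 standard-normal PCs, and a Normal(grs_mean, grs_sd) raw score z-scored
against the sample. Each phenotype's mean is exactly the stage-2 model:
quadratic in age (decades since 40) plus an optional score-dependent
truncated-power divergence term activating above a true threshold age,
plus covariate effects. Binary phenotypes pass the linear predictor
through the logistic function; count phenotypes are rounded, zero-floored
continuous draws (a full count GLM is unnecessary since the analysis
treats ordinal measures with the identity link). Missingness is completely
at random per phenotype, with an optional age-dependent slope to emulate
healthy-volunteer attrition. The GRS is simulated directly as a normal
score for pipeline work, since the analysis consumes only the standardized
score; genotype-level Hardy-Weinberg simulation exists solely to exercise
the scoring path.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium and population
stratification (PCs are independent noise), genotyping error, informative
missingness beyond the age-slope knob, measurement-error structure in the
cognitive tests, cohort effects embedded in cross-sectional age contrasts,
and selective survival.

## Simulation study conditions

The Monte-Carlo harnesses in `divage.experiments` characterize the
procedure under fixed conditions: cohorts of n = 100 000, ages uniform
40–70, residual SD 1, a quadratic age trend (−0.25/decade, −0.05/decade²),
sex + assay + 10 PCs as covariates, and a cubic divergence coefficient of
−0.02 per decade³ per SD of the score — a magnitude inside the published
range of interaction slopes for the screened cognitive measures. Threshold
experiments use 20 replicates; the family-wise error experiment uses 200
replicates of 32 independent null phenotypes. These sizes give stable
rates while keeping a full run of the reproduction script in minutes on
one CPU. Under these conditions the search recovers a true threshold of 50
within ±3 years in ≥80% of replicates, piles up at the old end of the grid
under the null, selects the grid minimum when divergence is active
everywhere, and the Bonferroni screen holds the family-wise error rate
near α.

The demonstration battery in `analysis/study_config.py` uses a 20 000-person
cohort with 12 measures, per-test missingness from 5% to 85% (analytic n
≈ 3000–19 000, mirroring the order-of-magnitude spread of real test
batteries) and divergence effects sized so that most — not all — truly
divergent measures survive the screen at this n; one heavily-missing
measure is deliberately underpowered, as happens in practice.

## Numerical choices

- Identity-link fits go through the QR factorization (LAPACK, on a
  Fortran-ordered design); cross-validation inside the threshold search
  uses per-fold Gram-matrix subtraction, numerically equivalent for these
  well-conditioned decade-scaled designs and much cheaper than refitting
  from raw rows. Both paths are checked against a brute-force
  (XᵀX)⁻¹Xᵀy oracle to 1e−10 in the test suite.
- `screen_all` factors a design once and reuses it across phenotypes that
  share covariates, age coding and the identical complete-case rows; the
  batched path is bit-identical to the single-fit path.
- Rank-deficient designs raise an error naming the collinear columns
  (identified from the near-null eigenvectors of XᵀX).
- A constant outcome yields zero slopes with p = 1 (no evidence), not a
  0/0 failure.
- Folds smaller than the parameter count raise with a suggestion to use
  fewer folds.
- All randomness flows from explicit seeds (simulation seed, fold seed);
  identical configurations reproduce byte-identical artifacts.

## Known limitations

- The threshold's sampling uncertainty is not quantified (no CI on the
  selected divergence age), matching the design this package implements.
- The logit-link CV path is experimental; the detection scan assumes the
  identity link's residual-SD interpretation.
- Complete-case analysis throughout; no imputation of missing phenotypes.
- The percent-ratio metric is undefined when the age slope is zero and
  unstable when it is near zero.
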