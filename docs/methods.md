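# Methods

## Model and estimators

Two-sample MR works from per-variant summary associations: for variant
*j*, an exposure effect β̂X_j with standard error seX_j from one GWAS and
an outcome effect β̂Y_j with seY_j from another.  Under the
instrumental-variable assumptions every valid instrument satisfies
E[β̂Y_j] = b·β̂X_j for a single causal slope b (log-odds scale for binary
outcomes), so the per-variant Wald ratio r_j = β̂Y_j/β̂X_j estimates b
with first-order SE seY_j/|β̂X_j|.

**IVW.**  The inverse-variance-weighted estimate is the weighted mean of
the ratios with weights w_j = β̂X_j²/seY_j², algebraically identical to
weighted through-origin least squares of β̂Y on β̂X (a numerically
verified identity in the tests).  Fixed-effects SE is (Σw_j)^(−1/2);
heterogeneity is Cochran's Q = Σw_j(r_j − b)² on nsnp−1 degrees of
freedom.  The random-effects variant multiplies the fixed SE by
max(1, √(Q/(nsnp−1))) — a multiplicative overdispersion model with the
floor at 1, the standard choice for summary-data MR.  Mode ``auto``
(the pipeline default) uses random effects when Q's p-value is below
0.05.

**MR-Egger.**  Weighted regression of β̂Y on β̂X *with* an intercept,
after orienting each variant so β̂X_j ≥ 0 (both betas negated together;
without a fixed orientation the intercept has no meaning).  A nonzero
intercept estimates the average directional pleiotropy; intercept
p < 0.05 flags it.  Slope and intercept SEs carry the same
overdispersion floor.  The regression itself is delegated to
statsmodels WLS; the floor is applied to its unit-scale covariance.

**Weighted median.**  Ratios are sorted and the estimate interpolates
them at the midpoint of the normalized inverse-variance weight
distribution; it is consistent when at least half the weight comes from
valid instruments.  Its SE is the standard deviation of the estimate
over a seeded parametric bootstrap (default 1000 draws of β̂X_j, β̂Y_j
from normals centred on the observed values); the seed is an explicit
required argument in the API and is derived from the run seed in the
pipeline.

**MR-PRESSO.**  For each variant the leave-one-out IVW slope b_{−j}
gives a predicted outcome effect; the observed residual sum of squares
RSS = Σ_j (β̂Y_j − b_{−j}β̂X_j)²/seY_j² is compared with RSS values from
replicate datasets simulated under no pleiotropy
(β̂Y*_j ~ N(b_{−j}β̂X_j, seY_j), β̂X*_j ~ N(β̂X_j, seX_j)).  Empirical
p-values use the +1 correction, so 1/(n_sim+1) is the attainable floor;
n_sim defaults to 1000.  Per-variant outlier p-values are the simulated
exceedance fractions of each residual, Bonferroni-multiplied by nsnp
and flagged below 0.05.  The distortion test compares the
outlier-corrected IVW slope with slopes after random same-sized
removals.  A minimum of four instruments is required.

**Multivariable MR.**  Outcome effects are regressed on K aligned
exposure-effect columns without an intercept, weights 1/seY_j²;
coefficient covariance is the inverse weighted normal matrix scaled by
max(1, RSS_w/(nsnp−K)).  Joint instruments are the union of variants
genome-wide significant for any exposure, present in every table,
clumped on the minimum p-value across exposures; the remaining filters
match the univariable chain.  With K = 1 the fit reduces exactly to
fixed-effects IVW.

**Two-step mediation.**  α is the univariable IVW effect of exposure on
mediator; β1 is the mediator's coefficient in the exposure-adjusted
multivariable fit; the indirect effect is αβ1 with first-order
delta-method SE √(α²se²_β1 + β1²se²_α) (no cross term) and a symmetric
normal 95% CI.  The proportion mediated is 100·αβ1/β with β the
univariable total effect.  Its CI comes from 1000 seeded draws of the
three estimates from independent normals; the default interval is
point ± 1.96·(bootstrap SD), matching the symmetric intervals such
analyses report (a percentile interval is available by flag).
Independence of the three draws is an approximation — α and β share
exposure instruments.  Draws with |β*| < 10⁻⁶ are rejected and redrawn
(the ratio of normals has no finite moments); more than 50% rejections
aborts with an instability error.  A mediator is *admitted* when both
α's and β1's p-values are below 0.05; failure flags the result rather
than raising.

All p-values are two-sided normal (not t), consistent with the
large-sample character of GWAS summary statistics, and significance is
p < 0.05 with no multiple-testing correction across exposures — a
convention of this analysis style worth keeping in mind when screening
many exposures.

## Harmonization and instrument selection

Tables are matched on rsID only (the data sources in scope are
rsID-keyed); indels and multi-allelic records are rejected at read time
with per-row reasons.  Allele alignment keeps identical pairs, negates
swapped pairs (eaf ↦ 1−eaf), and resolves strand-complement pairs by
complementing first.  Palindromic pairs (A/T, C/G) carry no strand
information in their labels: when either study's effect-allele
frequency lies in (0.42, 0.58) they are dropped; otherwise orientation
is inferred from whether the two frequencies fall on the same side of
0.5.  The symmetric band — checked in *both* studies — is the
conservative reading of a one-sided "MAF > 0.42" rule.

Filters run in a fixed order: significance, MAF, LD clumping, outcome
association, instrument strength.  Clumping is greedy by p-value (ties
broken lexicographically by rsID, making the output independent of row
order), removing neighbours within the window whose r² exceeds the
threshold; variants without coordinates are compared by LD alone, and
without any LD input clumping degrades to a warned no-op (the synthetic
generator declares its own LD).  R² = 2·maf(1−maf)β² assumes a
standardized phenotype and is an approximation.  The per-SNP F uses
k = 1; an aggregate F over the retained set (k = nSNP, summed R²) is
recorded alongside.

Two deliberate judgment calls:

1. **The outcome-association exclusion (p < 0.001) applies to the
   disease outcome only.**  In the two-step analysis the mediator
   occupies the outcome slot of the exposure→mediator leg; screening
   instruments against the mediator at p < 0.001 would delete exactly
   the variants that carry a real exposure→mediator effect, and the
   strongly significant step-1 estimates this analysis style reports
   could not arise under such a filter.  ``two_step_mediation``
   therefore disables the exclusion for that leg (``outcome_p_exclude``
   set to 0); every analysis whose screened trait is the disease
   outcome applies it exactly as configured.
2. **The p < 0.001 threshold itself is unusually permissive** relative
   to pipelines that only exclude genome-wide-significant outcome hits,
   and under a strong true causal effect it removes and truncates valid
   instruments (see *Known limitations*).  It is the default because it
   is the documented analysis choice of the design this package
   implements, and it is fully configurable.

## Synthetic-data generator

The generator emulates the summary statistics such a study consumes,
at the summary level (no individual genotypes — sufficient for every
estimator in scope and orders of magnitude faster).  Defaults describe
the study conditions the recovery experiments use: 100 exposure
instruments and 100 mediator instruments, 100,000 samples per GWAS,
per-SNP instrument effects N(0, 0.05) on a standardized trait (giving
per-SNP F between ~30 and ~900, the realistic range for strong
instruments), MAF uniform on (0.05, 0.5), mediation structure
α = −0.2, β1 = 0.5, τ = −0.7 (true proportion mediated 12.5%), and a
binary outcome whose SEs carry a case-fraction factor
(2·n·maf(1−maf)·φ(1−φ))^(−1/2) with φ = 0.0326, the case fraction of a
large nephropathy case-control meta-analysis.  Treating binary-outcome
effects directly on the log-odds scale with this SE is itself a
simplification (no per-study liability modelling).

Mediator-specific instruments are essential, not decorative: if every
variant affected the mediator only through the exposure, the
multivariable design matrix would be collinear in truth
(βmed = α·βX exactly) and the direct effect β1 unidentifiable.
Outcome-specific instruments (off by default) give the reverse
direction of a bidirectional analysis disease loci to draw on.
Pleiotropy acts in the exposure-increasing allele frame — a directional
mean shift defined against arbitrary allele coding would cancel across
variants.  Reported effect alleles are flipped at random per study and
per variant, so harmonization is exercised end to end.  LD blocks are
declarative: the emitted LD table drives clumping, but effect estimates
remain independent across variants — generated LD *structure* without
generated estimate *correlation*, a deliberate simplification adequate
for testing the clumping logic but not LD-aware estimators.

What passing tests on these synthetics do **not** show: robustness to
realistic allele-frequency spectra, population stratification, sample
overlap between GWAS, correlated pleiotropy beyond the single InSIDE
knob, or misspecified binary-trait scales.

## Numerical choices and problem sizes

- Estimator SEs use exact closed forms; the only iteration anywhere is
  seeded Monte Carlo (weighted-median bootstrap, MR-PRESSO null,
  proportion bootstrap).  Every stage seed in the pipeline is derived
  deterministically from the run seed and a stage tag, so a rerun with
  the same configuration is byte-identical.
- The weighted-median interpolation clamps to the extreme ratios when
  the midpoint falls outside the cumulative-weight grid.
- Degenerate inputs raise typed errors rather than returning NaNs:
  zero exposure betas (undefined Wald ratio), eaf ∈ {0,1}, n ≤ k+1,
  collinear MVMR columns, empty instrument sets (which carry the
  per-filter removal counts).
- Report tables round only at serialization (``%.10g``); internal state
  is full precision.  Odds ratios are exponentiated from unrounded
  slopes, so a third-decimal disagreement with values printed from
  rounded slopes is expected (e.g. exp(0.506) = 1.659).
- Recovery and calibration experiments in the test suite use 200
  simulated studies / seeds, 50–100 instruments, and 200–300 MR-PRESSO
  replicates — sizes chosen so the whole suite completes in well under
  a minute while keeping Monte-Carlo error small relative to the
  asserted bands.

## Known limitations

- **The outcome-association exclusion biases strong-effect recovery.**
  Under the default generating conditions the per-variant outcome
  z-statistics of truly causal instruments reach ~6, so the p < 0.001
  exclusion removes the strongest instruments and — more importantly —
  truncates the observed outcome effects of retained near-threshold
  variants.  Measured over 200 simulated studies this attenuates the
  total effect to a mean of −0.71 (truth −0.8) and inflates the mean
  recovered proportion mediated to 13.2% against a true 12.5%;
  disabling the single filter restores 12.4%.  The package keeps the
  filter because it is the documented design choice being implemented;
  analysts studying exposures with large effects on well-powered
  outcomes should treat it with suspicion or tighten it to genome-wide
  significance.
- No Steiger directionality filtering, mode-based or robust/penalized
  estimators, MVMR-Egger, or conditional-F diagnostics.
- No reference-panel LD computation, proxy-SNP search, liftover, or
  VCF ingestion; LD enters only as a declared pairwise r² table.
- Mediators are analyzed one at a time; there is no joint
  multiple-mediator decomposition.
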