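# Methods

## Model and procedure

The package analyses a fixed panel of biallelic SNPs in asthma drug-pathway
genes for a case/control sample.  Dosages count copies of the panel's
*counted allele* (the rare/alternate allele); all file dialects are
re-oriented onto this frame at read time, and an allele set matching the
panel in neither orientation is a hard error.  No strand-flip inference is
attempted, even for A/T and C/G SNPs: silent strand guessing corrupts
weights, and a literal mismatch is something the user must resolve in the
input.

**Association.** Each SNP is fit marginally with the log-additive logistic
model logit P(y=1|g) = α + β·g by Newton/IRLS.  Convergence requires a
log-likelihood change below 1e-10 *and* a parameter step below 1e-8
(within 50 iterations, with step-halving); the tight tolerance keeps the
fit within 1e-6 of closed-form MLEs on saturated 2×2 tables.  SEs come
from the observed information at the MLE; p-values are two-sided Wald.
Separation or non-convergence yields `converged=False` with NaN p — a
flagged result, never a silently wrong number.  Missing dosages are
dropped per SNP (complete-case); imputation is a scoring-stage concern
only.  No covariates are fit by default (the emulated study design matches
groups rather than adjusting), but a covariate hook exists.

**QC.** MAF per stratum; the exact conditional Hardy–Weinberg test
(enumeration over heterozygote counts compatible with the observed minor-
allele count, probability ∝ multinomial × 2^het, p = Σ of configurations
no more likely than the observed one), computed on controls by default
with an option for the combined sample; greedy LD pruning that visits SNPs
by ascending association p and keeps a SNP iff r² ≤ 0.2 against everything
already kept.  SNPs failing HWE at α = 0.05 are excluded from scoring and
listed in the manifest.

**Weights.** Two designs.  `local`: w = |β̂| with the risk allele set by
sign(β̂); a β of exactly 0 keeps the counted allele with weight 0
(documented tie rule).  `gwas_corrected`: external summary-statistic βs,
sign-oriented onto the counted-allele frame by literal allele match; when
an overlapping cohort's per-SNP (β, SE) is supplied, its contribution is
removed by inverting the fixed-effect inverse-variance pooling formula —
valid only when the removed precision is strictly below the pooled
precision, otherwise a hard error.  Panel SNPs absent from the external
stats may borrow a proxy SNP's corrected β, unmodified (no r²-attenuation
scaling), provided the user-supplied proxy r² is at least the threshold.
The default threshold is 0.8: a proxy is only a faithful stand-in under
strong LD, and the permissive 0.08 remains reachable by flag.  Risk-allele
orientation defaults to the local regression's sign in both designs (one
orientation shared across analyses); `orient_by="external"` switches to
the corrected external sign.  Accounting always holds: every panel SNP is
either weighted or listed as dropped.

**Scoring.** PGS_i = Σ_j w_j·r_ij over risk-allele dosages.  Missing
genotypes are mean-imputed with twice the control-sample risk-allele
frequency (deterministic, the standard scoring behaviour); `skip_rescale`
instead omits missing SNPs and rescales by total/used weight.  A
weight-set SNP absent from the dataset is a hard error, because scores
over silently shrunken panels are not comparable.

**Evaluation.** The odds ratio is reported per SD of the PGS — the input
convention is not dictated by the score's raw scale, per-SD is the field
convention, and the output flags it (`scale` column).  Standardization
uses the analysed sample (stratum cases plus all controls), so the
moderate-to-severe analysis is self-contained.  AUC is the Mann–Whitney
probability with ties counted ½, computed from midranks (identical to the
pairwise count).  The default CI is DeLong's from placement-value
variances — no installed Python package provides one, so it is implemented
here and cross-checked against a seeded stratified bootstrap in the tests.
The operating point maximizes Youden's J with ties broken toward the lower
threshold (higher sensitivity); the rule name is echoed in the output
because a reported sensitivity/specificity pair is meaningless without it.

## Simulator

The generator emulates a retrospective case/control study on the default
panel: genotypes in exact HWE at the panel's control-group frequencies
(two Bernoulli haplotypes per individual), disease via the same logistic
model the association stage fits, and rejection sampling until the
configured group sizes are reached — by default 378 cases (174 labelled
moderate-to-severe) and 504 controls, the emulated study's sizes.  (The
source tables report the control group inconsistently as 504 and 542; the
generator parameterizes the count and defaults to 504.)  The default
intercept −0.29 ≈ logit(378/882) makes both strata cheap to fill under the
null; under retrospective sampling the intercept does not affect the slope
β, so its value only matters for sampling efficiency.  A stratum whose
expected yield falls below 10⁻⁶ per draw raises a diagnostic error rather
than looping forever.  LD proxy pairs are generated at the haplotype
level: the proxy haplotype copies the source with probability
c = r·√(q_p(1−q_p)/q_s(1−q_s)), making r² a population parameter rather
than a dosage-level artifact.

What the simulator does *not* model: genome-wide LD structure, population
stratification, relatedness, covariates (age/sex/ethnicity are matched,
not adjusted, in the emulated design), and gene–environment interaction.
Passing tests therefore demonstrate the correctness and calibration of the
*statistics* under the stated model, not robustness of the science to
confounding in real cohorts.

## Numerical and design choices

- Coordinates are 1-based; panel positions are treated as build-agnostic
  labels and SNPs match by rsID first, chrom:pos second (no liftover).
- Missing genotypes: `./.` in VCF, `NA` in `.raw`, NaN internally.
- p-values are floored at the smallest positive float so the (0, 1]
  invariant survives extreme z-scores.
- Greedy pruning keeps the smaller-p member of a correlated pair by
  construction; a duplicated column always loses to its better copy.
- The pipeline's in-sample (`local`) design intentionally reuses the same
  individuals for weight estimation and evaluation; the manifest carries
  an explicit optimistic-bias notice, and the `replicate` design (an
  independent draw of the same scenario, seed offset by a fixed constant)
  provides the unbiased counterpart.  This contrast is itself a tested
  property: under a global null at the default scale, in-sample weights
  give mean AUC well above 0.5 while replicate weights sit at chance.
- Result bundles are deterministic: fixed column orders, 8-significant-
  digit formatting, a sorted-key JSON manifest without timestamps or
  output paths, so identical config + seed reproduce byte-identical files.

## Test scales

The calibration tests use 500 replicates for coverage/bias at the
378/504 design, 2,000 single-SNP null replicates at n = 500 for type-I
error, 200 panel-scale replicates for the overfitting contrast, and
n = 20,000 for the binormal AUC limit — sizes at which the binomial/Monte
Carlo error of each checked quantity is several times smaller than its
acceptance band.  The HWE generator check accepts rejection rates in
[0.03, 99%-upper-envelope of 0.05]: the upper side is the scientifically
load-bearing one (excess rejection would mean the generator violates
HWE), while the exact test's discreteness makes it conservative, which
the looser lower bound absorbs.

## Known limitations

- `gwas_corrected` weighting takes the overlapping cohort's per-SNP
  (β, SE) as input; it cannot reconstruct an unknown overlap from the
  pooled numbers alone.
- Proxy LD values are user-supplied (e.g. from a reference-panel lookup);
  the package does not compute LD from external reference panels.
- Only VCF 4.x GT fields and PLINK-style `.raw` additive text are read;
  BGEN/PGEN, imputation dosages and genotype imputation are out of scope.
- The exact HWE test and the DeLong interval assume independent
  individuals; related samples would invalidate both.
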