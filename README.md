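# drugpgs

Polygenic-score (PGS) analysis of a curated panel of asthma drug-pathway
gene variants, built for case/control studies of childhood-onset asthma.
The package covers the whole analysis path — per-SNP quality control and
association, PGS weight construction (including correction of external GWAS
effect sizes for an overlapping cohort), per-individual scoring, odds-ratio
estimation and ROC evaluation — together with a synthetic genotype
simulator so every stage can be exercised and calibrated without access to
individual-level study data.

## The analysis

The packaged default panel holds 26 biallelic SNPs in genes involved in the
metabolism of the major asthma drug classes (glucocorticosteroids,
beta-2-agonists, antihistamines, antileukotrienes), each with its rare
(counted) allele and its control-group minor-allele frequency.

For each SNP the association stage fits a log-additive logistic model

    logit P(y = 1 | g) = α + β·g,      g ∈ {0, 1, 2} counted-allele copies

by IRLS maximum likelihood, with SE from the observed information and a
two-sided Wald p-value.  QC covers minor-allele frequency, the exact
conditional Hardy–Weinberg test (on controls), and greedy LD pruning at
r² > 0.2.

PGS weights come from either design:

* **local** — w_j = |β̂_j| from the study sample itself, with the risk
  allele chosen by the sign of β̂_j;
* **gwas_corrected** — external GWAS summary statistics, corrected when the
  external meta-analysis contains a cohort overlapping the study sample by
  inverting the fixed-effect inverse-variance pooling
  (β_meta = Σ β_k/SE_k² / Σ 1/SE_k², so the overlapping cohort's
  precision-weighted contribution can be subtracted back out), with
  high-LD proxy SNPs standing in for panel SNPs the external study lacks.

The score is PGS_i = Σ_j w_j · r_ij with r_ij the risk-allele dosage.  Its
disease association is reported as an odds ratio per standard deviation of
the score (logistic regression on the standardized PGS), overall and in a
moderate-to-severe case stratum; discrimination is summarized as AUC with a
DeLong 95% CI and a Youden-index operating point.

The simulator draws genotypes in Hardy–Weinberg equilibrium at the panel
frequencies, applies the same logistic disease model, and accumulates
individuals by rejection until the configured group sizes (default 378
cases / 504 controls, 174 moderate-to-severe cases) are reached — so
in-sample and independent-replicate weighting can be contrasted under a
known truth.

## Worked example

```python
from drugpgs import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(
    seed=7, out_dir="results/demo",
    sim=SimConfig(seed=7, effects={"rs295137": 0.47, "rs2395672": 0.44}),
)
bundle = run_pipeline(cfg)
print(bundle["score_association"][["weight_mode", "stratum", "or_per_sd", "p"]])
print(bundle["roc_summary"][["weight_mode", "stratum", "auc"]])
```

prints (two truly associated SNPs, all other effects null):

```
  weight_mode          stratum  or_per_sd             p
0       local        all_cases   1.673053  1.824486e-12
1       local  moderate_severe   1.586945  2.176176e-07
2   replicate        all_cases   1.458755  9.413622e-08
3   replicate  moderate_severe   1.342817  7.564499e-04
  weight_mode          stratum       auc
0       local        all_cases  0.638031
1       local  moderate_severe  0.624367
2   replicate        all_cases  0.603156
3   replicate  moderate_severe  0.578926
```

The `local` rows weight the score with the same sample's β̂s — the manifest
flags these as optimistically biased — while the `replicate` rows use
weights from an independent draw of the same scenario and are accordingly
more modest.  The same run is available from the shell:

```sh
drugpgs run --config analysis.yaml
```

with `simulate`, `assoc`, `weights`, `score`, `associate` and `evaluate`
subcommands for the individual stages.

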