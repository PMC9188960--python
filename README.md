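# epiprs

Polygenic-risk analysis for presumed monogenic (severe) epilepsy cohorts.

Severe early-onset epilepsies such as the developmental and epileptic
encephalopathies (DEEs) are classically treated as monogenic: a rare de
novo variant of large effect explains the phenotype in up to half of
patients. `epiprs` implements, as a tested and fully simulatable
pipeline, the analysis design used to ask whether *common* genetic
variation also contributes in these patients: polygenic risk scores
(PRS) built from epilepsy GWAS summary statistics are compared between
cases and controls, between case strata with and without an identifiable
damaging rare variant ("screen-positive" / "screen-negative"), pooled
across cohorts by inverse-variance meta-analysis, and tested
within-family by the polygenic transmission disequilibrium test (pTDT)
in parent-offspring trios.

## What is in the box

| module | role |
|---|---|
| `epiprs.synthetic_data` | liability-threshold cohort/trio simulator with ground-truth labels |
| `epiprs.io_formats` | VCF / summary-stats / pedigree / manifest readers and writers |
| `epiprs.genotype_qc` | call-rate, MAF, exact-HWE and INFO filters; LD pruning; GRM PCA; outlier flagging |
| `epiprs.prs_scoring` | allele harmonisation, p ≤ 0.5 thresholding, weighted-dosage scoring, z-normalisation |
| `epiprs.association` | `PRSLogit` / `PRSLogitResults`: covariate-adjusted logistic PRS association, Nagelkerke R², three-group screen-stratified contrasts |
| `epiprs.meta_analysis` | `MetaAnalysis` / `MetaAnalysisResults`: fixed-effects pooling with Q and I², DerSimonian–Laird random effects, forest tables |
| `epiprs.ptdt` | `PTDT` / `PTDTResult`: child-minus-mid-parent deviation t-test, overall and by screen stratum |
| `epiprs.variant_screen` | rule-based qualifying rare-variant screen (panel gene, LoF / missense MPC > 2, population-database absence, recurrence ≤ 3; CNV > 2 Mb / hotspot / pLI > 0.9) |
| `epiprs.pipeline`, `epiprs.cli` | end-to-end orchestration and the `epiprs` console command |

## The core statistics

For sample *i* with harmonised per-allele log-odds weights
*w<sub>j</sub>* and dosages *d<sub>ij</sub>*, the score is
PRS<sub>i</sub> = Σ<sub>j</sub> w<sub>j</sub> d<sub>ij</sub>, z-standardised
to mean 0, SD 1. Case status is modelled as

&nbsp;&nbsp;logit P(case) = β₀ + β·PRS_z + γ₁·sex + Σ<sub>k=1..4</sub> δ<sub>k</sub>·PC<sub>k</sub>

with β the log-odds per SD of PRS and Nagelkerke's pseudo-R² as the
variance-explained summary. Per-cohort β̂ are pooled with inverse-variance
weights w<sub>i</sub> = 1/se<sub>i</sub>²; heterogeneity is Cochran's
Q with I² = max(0, (Q − df)/Q)·100. In trios, each child's deviation
from the mid-parent score, standardised by the SD of mid-parent scores,
is tested against 0 by a one-sample t-test (the pTDT) — a design immune
to population stratification.

The simulator draws unlinked SNPs in Hardy-Weinberg equilibrium and a
latent liability L = Σ a<sub>j</sub>(g<sub>ij</sub> − 2p<sub>j</sub>) +
γC<sub>i</sub> + ε with polygenic variance h², a rare dominant
major-effect carrier flag C (frequency f, effect γ), and ε ~ N(0, 1 − h²);
an individual is a case iff L > Φ⁻¹(1 − K) for prevalence K.

## Worked example

```python
import numpy as np
from epiprs import SimulationConfig, PRSLogit, MetaAnalysis
from epiprs.synthetic_data import (simulate_true_effects, simulate_summary_stats,
                                   simulate_cohort, simulate_trios)
from epiprs.prs_scoring import compute_prs
from epiprs.genotype_qc import compute_pcs
from epiprs.ptdt import PTDT

cfg = SimulationConfig(m_snps=300, n_cases=500, n_controls=500, n_trios=100, seed=1)
effects = simulate_true_effects(cfg)                    # h2 = 0.3 of liability
gwas = simulate_summary_stats(effects, cfg.n_discovery, seed=1)
genotypes, samples = simulate_cohort(effects, cfg)

prs = compute_prs(genotypes, gwas)                      # harmonise, p<=0.5, score, z
pcs = compute_pcs(genotypes, 4)
model = PRSLogit.from_samples(samples.merge(pcs.reset_index(), on="id"), prs)
print(model.fit().summary())
```

```
PRS logistic regression
  observations: 1000 (500 cases, 500 controls)
  log-likelihood: -538.8936 (covariates-only: -678.8550)
  Nagelkerke R2 (PRS term): 32.8721%

  term            coef        se        z           p
  const         0.0953    0.2357    0.404       0.686
  prs           1.4310    0.1042   13.735    6.25e-43
  sex          -0.0716    0.1489   -0.481       0.631
  pc1          -0.1278    0.8522   -0.150       0.881
  pc2          -0.9044    0.8610   -1.050       0.294
  pc3          -1.1573    0.8634   -1.340        0.18
  pc4           0.6959    0.8884    0.783       0.433
```

The PRS coefficient (1.43 log-odds per SD) is large because cases are
ascertained from the 1% tail of a liability that is 30% polygenic and the
simulated discovery GWAS is nearly noise-free at these settings; real
epilepsy cohorts sit at a fraction of this (R² well under 5%).
Trios and meta-analysis follow the same pattern:

```python
trio_g, trio_samples, trios = simulate_trios(effects, cfg, seed=1)
trio_prs = compute_prs(trio_g, gwas)
print(PTDT(trios, trio_prs, trio_samples).fit("all").summary())
meta = MetaAnalysis([0.55, 0.70, 0.62], [0.09, 0.11, 0.10],
                    labels=["cohort1", "cohort2", "cohort3"]).fit("fixed")
print(meta.summary())
```

```
pTDT [all]: n = 100, mean deviation = 0.8071 (sd 0.8461), t(99) = 9.539, p = 1.11e-15
fixed-effects meta-analysis of 3 studies
  pooled log-odds per SD: 0.6134 (se 0.0572, z 10.731, p 7.26e-27)
  heterogeneity: Q = 1.120 on 2 df, I2 = 0.0%, tau2 = 0.0000
```

Affected children carry, on average, 0.81 mid-parent SDs more polygenic
risk than their parents transmit under the null — the over-transmission
signature expected when probands are ascertained on a partly polygenic
liability.

The same steps are available from a shell:

```sh
epiprs simulate --seed 1 --out-dir sim/
epiprs qc sim/cohort.vcf --out-vcf qc.vcf --report qc_report.tsv
epiprs score qc.vcf sim/summary_stats.tsv --out prs.tsv
epiprs assoc prs.tsv sim/samples.tsv --out assoc.tsv
epiprs run-all --seed 1 --out-dir run/      # the whole pipeline
```

## What the synthetic data does and does not show

Simulated cohorts have no linkage disequilibrium, no population
stratification (beyond dedicated two-population PCA fixtures in the
tests), a single dominant major-effect variant, and exactly known screen
labels. Passing tests therefore validate the statistical machinery and
its calibration, not effect sizes in real cohorts — the study-scale
cohorts behind the published analysis are access-controlled. See
`docs/methods.md` for the model, parameter defaults, and limitations.
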