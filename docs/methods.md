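# Methods

## The analysis design

`epiprs` implements the case-control + trio design used to measure a
polygenic contribution in cohorts ascertained for presumed monogenic
severe epilepsy. The chain is: genotype QC → PRS construction from
discovery-GWAS summary statistics → covariate-adjusted logistic
association per cohort → inverse-variance meta-analysis across cohorts →
screen-stratified three-group comparison → within-family pTDT in trios →
rule-based rare-variant screen that defines the strata. Because the
real cohorts are access-controlled, the package ships a generative model
of the same statistical structure so that every stage can be tested
against ground truth.

## The liability-threshold generative model

Individual *i* has liability

    L_i = sum_j a_j (g_ij - 2 p_j) + gamma * C_i + eps_i

* `g_ij ~ Binomial(2, p_j)` — unlinked biallelic SNPs in HWE, allele
  frequencies `p_j ~ Uniform(maf_range)`.
* `a_j` — per-allele liability effects, normal draws rescaled so that
  `sum_j 2 p_j (1-p_j) a_j^2 = h2` exactly. The polygenic term is
  mean-centred so E[L] = 0; this is what makes the unascertained case
  fraction equal the nominal prevalence K and keeps the per-carrier
  shift `gamma` interpretable on the liability-SD scale.
* `C_i ~ Bernoulli(f)` — carrier flag for a single rare dominant variant
  of major effect `gamma` (liability SD per carrier). Among cases,
  carrier status is the ground-truth "screen-positive" label.
* `eps_i ~ Normal(0, 1 - h2)` — residual, so the non-carrier liability
  has variance exactly 1 and Var(L) = 1 + gamma^2 f (1-f).
* Case iff `L_i > Phi^-1(1 - K)`. Cohorts are rejection-sampled to the
  requested numbers of cases and controls; trios draw two parents from
  the population model, transmit one uniformly chosen allele per parent
  per SNP, and (by default) retain only trios whose child is a case —
  affected-proband ascertainment.

Discovery-GWAS summary statistics are simulated per SNP as
`se_j = 1/sqrt(2 p_j (1-p_j) n_discovery)`,
`beta_j = a_j + Normal(0, se_j^2)`, p from the two-sided Wald statistic.
This treats the discovery study as a quantitative-liability GWAS; the
noise scaling is what matters for every property tested downstream.

### Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| `prevalence_k` | 0.01 | approximate lifetime epilepsy prevalence; makes affected ascertainment meaningful without being intractable |
| `h2_liability` | 0.3 | middle of the test grid {0, 0.1, 0.3}; the phenotype's true value in these cohorts is unknown |
| `gamma_major` | 3.0 (liability SD) | a genuinely major effect: carrier penetrance ≈ Phi(3 − 2.33) ≈ 0.75 at K = 0.01 |
| `carrier_freq` | 0.002 | with gamma = 3 this yields ~15% of ascertained cases carrying the major variant — the order of the published screen-positive fraction (460/2,759 ≈ 17%) |
| `n_discovery` | 20,000 | a discovery study large enough that PRS weights are informative but noisy |
| `maf_range` | (0.05, 0.5) | common variants, the PRS regime |

## Quality control

Variant filters run in a fixed order (call rate < 98%, then MAF < 1%,
then exact-HWE p < 1e-5, then INFO < 0.9 where INFO is present), so QC
reports are deterministic and each removal is attributed to the first
rule it fails. Sample filters: call rate < 98%, then heterozygosity
outside mean ± 3 SD (skipped below 3 samples or at zero SD). Dosages
are hard-called by rounding for HWE and heterozygosity; no ambiguity
zone is applied, since array/imputation pipelines hard-call upstream
and simulated data is integer-valued anyway.

The HWE test is the exact conditional test: given the allele counts, the
probability of every heterozygote count of compatible parity is
enumerated and the p-value is the total probability of configurations no
more likely than the observed one. Probabilities are computed in log
space (gammaln) with a 1e-9 relative tolerance in the "no more likely"
comparison to make exact ties robust to rounding; agreement with an
exact-rational enumeration oracle is < 2e-14 over all 23,425 genotype
tables with n ≤ 50. Monomorphic sites return p = 1. HWE is computed on
all samples; restricting to controls is a caller-side subset.

LD pruning follows the PLINK `--indep-pairwise`-style SNP-count window
(1000 SNPs, step 100, r² 0.1): within each window the highest-r² pair
above threshold is resolved by dropping its lower-MAF member (ties: the
later position), until no pair exceeds the threshold. On the simulator's
unlinked SNPs this is the identity, which keeps the PRS oracle exact.

PCs come from the variance-standardised genetic relationship matrix
X Xᵀ/m (columns standardised to unit variance, zero-variance columns
dropped, missing dosages mean-imputed); PCs are eigenvectors scaled by
sqrt(eigenvalue), with the largest-magnitude loading made positive for
sign stability. Ancestry outliers are automated as |PC − median| >
6 × 1.4826 × MAD on PC1/PC2, replacing the visual-inspection step that a
manual workflow would use; zero MAD disables an axis.

## PRS construction

Variants are matched to summary statistics by id; the weight is +beta
when the genotype's counted allele is the GWAS effect allele, −beta when
it is the other allele, with strand complements resolved the same way.
Palindromic (A/T, C/G) variants are excluded outright — without allele
frequencies strand cannot be resolved, and frequency-matching is out of
scope. SNPs with discovery p ≤ 0.5 (boundary inclusive) enter the
score. Missing dosages score at the variant's mean observed dosage, the
standard scoring-tool default. Scores are z-standardised over all scored
samples (cases + controls jointly, per analysis cohort); the
normalisation set is a parameter. Optional greedy p-value clumping
against a reference panel is provided but off by default — on unlinked
synthetic data it is the identity, and for real scores the choice
belongs to the weight-providing GWAS workflow.

## Association and the three-group comparison

`PRSLogit.fit()` is a maximum-likelihood binomial GLM (statsmodels IRLS,
tolerance 1e-10, 100 iterations) with intercept, PRS, and covariates
(sex coded 1/2; unknown sex mean-coded with a warning; top four PCs by
convention). Rank deficiency is reported with the collinear columns;
quasi-complete separation (fitted probabilities pinned at 0/1 with
diverging coefficients) raises rather than returning garbage. Wald
standard errors and two-sided p-values match standard GLM summaries.

Nagelkerke's R² is Cox–Snell rescaled:
`R2_N = [1 − exp(2(ll_null − ll_full)/n)] / [1 − exp(2 ll_null / n)]`,
clipped to [0, 1]. The results object uses the covariates-only model as
the null, so the reported R² is the variance explained by the PRS term
itself, not by the whole model; the free function accepts any pair of
log-likelihoods.

The three-group comparison (controls / screen-positive / screen-negative)
is run as three pairwise covariate-adjusted logistic fits with Bonferroni
adjustment across the three contrasts. A single multinomial model with a
simultaneous max-t adjustment is the tighter alternative; the pairwise
form was chosen because its contrast matrix is fully explicit and each
contrast is independently testable. Orientation is fixed: positive beta
means higher PRS in cases than controls, and in screen-positive than
screen-negative. One failing contrast (e.g. an empty group) is reported
with its error and does not abort the others.

Note a behaviour of the generative model worth knowing when reading
three-group results: with a large-effect carrier variant (`gamma` big),
conditioning on case status makes carriers need *less* polygenic
liability, so screen-positive cases genuinely have lower PRS — a
collider effect, not a bug. The "shared polygenic background" scenario
(both strata drawn from the same polygenic distribution) corresponds to
`gamma = 0` with `carrier_freq > 0`, where the screen label is
independent of liability.

## Meta-analysis

Fixed effects: weights 1/se², pooled se = sqrt(1/Σw), Q = Σw(β−pooled)²,
I² = max(0,(Q−df)/Q)·100 with df = k−1 (0 when k = 1 or Q = 0). Random
effects use the DerSimonian–Laird τ² = max(0, (Q−df)/(Σw − Σw²/Σw)) and
re-weight with 1/(se²+τ²). DL was chosen over REML for its closed form —
every number is hand-checkable — accepting a documented divergence from
REML-defaulting tools; the fixed-effects model is the primary one in
this design. Forest tables carry per-study 95% CIs (β ± 1.96 se) and
percentage weights.

## pTDT

Per trio, deviation = (child PRS − mid-parent PRS) / SD(mid-parent),
with SD (n−1 denominator) taken over the analysed trio set — per
stratum when stratifying, matching the construction of the test as
cited; a global-SD switch is available. The test is a one-sample
two-sided t-test of the mean deviation against 0. Location and scale
changes of the PRS cancel, so raw vs z scores do not affect t or p
(z is the default). Strata with fewer than 2 trios are reported as
skipped rather than failing the run.

## Rare-variant screen

SNV/indel qualifying rule: panel gene AND (LoF, or missense with
MPC > 2) AND absent from population databases AND seen ≤ 3 times in the
dataset; missense without an MPC score does not qualify. CNV rule
(OR semantics, as published): length > 2 Mb, or overlap with an epilepsy
gene/hotspot, or overlap with a pLI > 0.9 gene; a CNV qualifying by
length alone is flagged `qualifies_by_length_only` in the audit log
because that clause alone is permissive. All thresholds are strict
inequalities. Population-database presence and panel membership are
boolean input columns — no live database queries, which would not be
reproducible. Cases absent from both variant tables are `unknown`,
mirroring cohorts whose cases lacked rare-variant data.

## Numerical and design choices

* Variants are keyed by id (rsID-style), coordinates 1-based as in VCF;
  multi-allelic records are rejected, not split.
* DS takes priority over GT when both are present (imputed-data
  convention); VCF FORMAT/Float is single precision, and the writer
  rounds to that resolution so VCF round trips are exact.
* An odds-ratio column in summary statistics is never log-transformed
  implicitly; the caller must supply beta = log(OR).
* Determinism: every stochastic routine takes a seed; identical seed and
  configuration give byte-identical outputs, including pipeline TSVs.
* Rejection sampling batches are sized adaptively (~1.3× the expected
  draw needed) and capped; an infeasible ascertainment request fails
  with the cap stated.

## Problem sizes used in the test suite

Type-I calibration runs 2,000 null replicates each for the association
test (n = 200+200 per replicate at K = 0.2, h² = 0 — the rejection rate
is invariant to these sizes) and the pTDT (50 unascertained trios per
replicate). Heritability-ordering recovery uses n = 2,000+2,000 at
K = 0.01 over h² ∈ {0, 0.1, 0.3}, 20 seeded runs; pTDT power uses the
171-trio cohort scale at h² = 0.3 with affected ascertainment.

## Limitations

* No LD: clumping/pruning are identity operations on synthetic data, so
  their behaviour on correlated real SNPs is exercised only by dedicated
  correlated-column fixtures.
* No population stratification in the main generator; PCs in simulated
  fits are noise covariates. The pTDT's robustness to stratification is
  by design of the statistic, not demonstrated on stratified data.
* Single dominant major-effect variant; recessive and X-linked
  architectures are out of scope.
* The simulated discovery GWAS is a quantitative-liability study;
  case-control discovery designs differ by a scale factor in beta that
  is irrelevant to rank-based SNP selection and to every calibration
  property tested.
* Imputation, phasing, relatedness pruning and cross-array batch
  handling are upstream of this package; INFO scores are consumed as
  input.
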