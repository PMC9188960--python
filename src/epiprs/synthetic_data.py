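"""Liability-threshold cohort simulator with ground-truth labels.

Emulates the statistical structure of severe-epilepsy case-control and
trio studies: unlinked biallelic SNPs in Hardy-Weinberg equilibrium, a
polygenic liability component with SNP-heritability h2, a rare dominant
major-effect variant carried by a subset of cases ("screen-positive"
ground truth), disease prevalence K, noisy discovery-GWAS effect
estimates, and affected-proband-ascertained trios.  Every generated
object carries the labels downstream tests need (true effects, carrier
flags, qualifying-variant ground truth, injected QC artifacts).

The model: per-individual liability
L = sum_j a_j (g_j - 2 p_j) + gamma * C + eps
(the polygenic term is mean-centred so E[L] = 0 and prevalence matches K),
with g_j ~ Binomial(2, p_j) independently across unlinked SNPs,
C ~ Bernoulli(f) a dominant rare-variant carrier flag, and
eps ~ Normal(0, 1 - h2) so the non-major polygenic + environmental
variance totals 1.  An individual is a case iff L exceeds the threshold
Phi^-1(1 - K) implied by prevalence K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

__all__ = [
    "SimulationConfig", "TrueEffects", "simulate_true_effects",
    "simulate_summary_stats", "simulate_cohort", "simulate_trios",
    "simulate_annotations", "inject_qc_artifacts", "ArtifactSpec",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults reflect a severe-epilepsy study design: ~1% lifetime disease
    prevalence, a polygenic liability share of 0.3, and a rare dominant
    variant of large effect (3 liability SD per carrier) carried by 0.2%
    of the population, which makes carriers a minority of ascertained
    cases as observed in sequenced severe-epilepsy cohorts.
    """

    m_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_liability: float = 0.3
    prevalence_k: float = 0.01
    gamma_major: float = 3.0
    carrier_freq: float = 0.002
    n_discovery: int = 20_000
    n_cases: int = 1000
    n_controls: int = 1000
    n_trios: int = 100
    ascertain_trios: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not (0 <= self.h2_liability < 1):
            raise ValueError("h2_liability must be in [0, 1)")
        if not (0 < self.prevalence_k < 1):
            raise ValueError("prevalence_k must be in (0, 1)")
        if self.gamma_major < 0:
            raise ValueError("gamma_major must be >= 0")
        if not (0 <= self.carrier_freq < 1):
            raise ValueError("carrier_freq must be in [0, 1)")


@dataclass
class TrueEffects:
    """Generator ground truth: per-SNP MAF and true liability effect."""

    variants: pd.DataFrame  # id, chrom, pos, a1, a2
    p: np.ndarray  # allele frequency of a1
    a: np.ndarray  # per-allele liability effect
    h2: float

    def polygenic_liability(self, dosages: np.ndarray) -> np.ndarray:
        return dosages @ self.a


def _variant_frame(m: int) -> pd.DataFrame:
    # one synthetic chromosome, evenly spaced, non-palindromic alleles
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 10_000,
            "a1": "A",
            "a2": "G",
            "info": 1.0,
        }
    )


def simulate_true_effects(config: SimulationConfig) -> TrueEffects:
    """Draw per-SNP frequencies and effects carrying exactly h2 of liability.

    Frequencies are Uniform over ``maf_range``; raw effects are standard
    normal and rescaled so sum_j 2 p_j (1 - p_j) a_j^2 = h2 exactly.
    """
    if config.m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.m_snps)
    a = rng.standard_normal(config.m_snps)
    if config.h2_liability == 0:
        a = np.zeros(config.m_snps)
    else:
        var_raw = np.sum(2 * p * (1 - p) * a**2)
        a = a * np.sqrt(config.h2_liability / var_raw)
    return TrueEffects(variants=_variant_frame(config.m_snps), p=p, a=a,
                       h2=config.h2_liability)


def simulate_summary_stats(effects: TrueEffects, n_discovery: int,
                           seed: int = 0) -> pd.DataFrame:
    """Noisy discovery-GWAS estimates of the true effects.

    se_j = 1 / sqrt(2 p_j (1 - p_j) n); beta_j = a_j + N(0, se_j^2);
    p from the two-sided Wald statistic beta/se.
    """
    if n_discovery <= 0:
        raise ValueError("n_discovery must be > 0")
    rng = np.random.default_rng(seed + 1)
    se = 1.0 / np.sqrt(2 * effects.p * (1 - effects.p) * n_discovery)
    beta = effects.a + rng.normal(0.0, se)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "id": effects.variants["id"],
            "chrom": effects.variants["chrom"],
            "pos": effects.variants["pos"],
            "effect_allele": effects.variants["a1"],
            "other_allele": effects.variants["a2"],
            "beta": beta,
            "se": se,
            "p": pvals,
        }
    )


def _liability_threshold(k: float) -> float:
    return stats.norm.isf(k)


def _draw_population(rng: np.random.Generator, effects: TrueEffects,
                     config: SimulationConfig, n: int):
    """One unascertained batch: genotypes, carrier flags, liabilities, case flags."""
    g = rng.binomial(2, effects.p, size=(n, len(effects.p))).astype(float)
    carrier = rng.random(n) < config.carrier_freq
    eps = rng.normal(0.0, np.sqrt(1.0 - config.h2_liability), size=n)
    liability = (g - 2 * effects.p) @ effects.a + config.gamma_major * carrier + eps
    case = liability > _liability_threshold(config.prevalence_k)
    return g, carrier, liability, case


_MAX_BATCHES = 2000
_BATCH = 20_000


def simulate_cohort(effects: TrueEffects, config: SimulationConfig,
                    seed: int | None = None):
    """Ascertain a case-control cohort under the liability-threshold model.

    Rejection-samples unascertained individuals in batches until
    ``n_cases`` cases and ``n_controls`` controls are collected.  Screen
    status ground truth equals major-variant carrier status among cases;
    controls are not screened and carry status 'unknown'.

    Returns (GenotypeMatrix, sample DataFrame).  The sample table also
    carries the ground-truth columns ``carrier`` and ``liability``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    need_cases, need_controls = config.n_cases, config.n_controls
    if need_cases <= 0 and need_controls <= 0:
        raise ValueError("nothing to simulate: n_cases and n_controls are 0")
    # batch sized to fill the request in ~1 draw without gross overdraw
    expected = max(need_cases / config.prevalence_k,
                   need_controls / (1.0 - config.prevalence_k))
    batch = int(min(_BATCH, max(512, 1.3 * expected)))
    got_g, got_meta = [], []
    n_cases = n_controls = 0
    for _ in range(_MAX_BATCHES):
        if n_cases >= need_cases and n_controls >= need_controls:
            break
        g, carrier, liability, case = _draw_population(rng, effects, config, batch)
        take_case = case & (n_cases + np.cumsum(case) <= need_cases)
        take_ctrl = (~case) & (n_controls + np.cumsum(~case) <= need_controls)
        keep = take_case | take_ctrl
        if keep.any():
            got_g.append(g[keep])
            got_meta.append(
                pd.DataFrame({"case": case[keep], "carrier": carrier[keep],
                              "liability": liability[keep]})
            )
            n_cases += int(take_case.sum())
            n_controls += int(take_ctrl.sum())
    else:
        raise RuntimeError(
            f"could not ascertain {need_cases} cases / {need_controls} controls "
            f"within {_MAX_BATCHES} batches of {_BATCH} "
            f"(prevalence K={config.prevalence_k} too small for the request)"
        )
    dosages = np.vstack(got_g)
    meta = pd.concat(got_meta, ignore_index=True)
    # stable order: cases first, controls after, in draw order
    order = np.argsort(~meta["case"].values, kind="stable")
    dosages = dosages[order]
    meta = meta.iloc[order].reset_index(drop=True)
    n = len(meta)
    ids = [f"S{i + 1}" for i in range(n)]
    screen = np.where(
        meta["case"], np.where(meta["carrier"], "positive", "negative"), "unknown"
    )
    samples = pd.DataFrame(
        {
            "id": ids,
            "phenotype": np.where(meta["case"], "case", "control"),
            "sex": rng.integers(1, 3, size=n),
            "cohort": "sim",
            "screen_status": screen,
            "carrier": meta["carrier"].values,
            "liability": meta["liability"].values,
        }
    )
    gmat = GenotypeMatrix(sample_ids=ids, variants=effects.variants.copy(),
                          dosages=dosages)
    return gmat, samples


def _transmit(rng: np.random.Generator, parent_g: np.ndarray) -> np.ndarray:
    """One transmitted allele per SNP: 0/2 are obligate, hets transmit a coin flip."""
    coin = rng.random(parent_g.shape) < 0.5
    return np.where(parent_g == 1, coin.astype(float), parent_g / 2.0)


def simulate_trios(effects: TrueEffects, config: SimulationConfig,
                   seed: int | None = None):
    """Simulate parent-offspring trios with Mendelian transmission.

    Parents are unascertained population draws; each child allele comes
    from the corresponding parent's own two alleles with equal
    probability.  With ``ascertain_trios`` only trios whose child is a
    case (liability rule, including a possible de novo major-effect
    carrier event) are retained, mirroring affected-proband recruitment.

    Returns (GenotypeMatrix over all members, sample DataFrame, trio
    DataFrame with father_id/mother_id/child_id).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7)
    m = len(effects.p)
    need = config.n_trios
    if need <= 0:
        raise ValueError("n_trios must be > 0")
    fa_l, mo_l, ch_l, meta_l = [], [], [], []
    got = 0
    batch = max(256, min(_BATCH // 4, int(need / max(config.prevalence_k, 1e-6) / 2) + 256)) \
        if config.ascertain_trios else need
    for _ in range(_MAX_BATCHES):
        if got >= need:
            break
        fa = rng.binomial(2, effects.p, size=(batch, m)).astype(float)
        mo = rng.binomial(2, effects.p, size=(batch, m)).astype(float)
        ch = _transmit(rng, fa) + _transmit(rng, mo)
        carrier = rng.random(batch) < config.carrier_freq  # de novo dominant event
        eps = rng.normal(0.0, np.sqrt(1.0 - config.h2_liability), size=batch)
        liability = (ch - 2 * effects.p) @ effects.a + config.gamma_major * carrier + eps
        case = liability > _liability_threshold(config.prevalence_k)
        keep = case.copy() if config.ascertain_trios else np.ones(batch, dtype=bool)
        keep &= np.cumsum(keep) + got <= need
        if keep.any():
            fa_l.append(fa[keep]); mo_l.append(mo[keep]); ch_l.append(ch[keep])
            meta_l.append(pd.DataFrame({"carrier": carrier[keep],
                                        "liability": liability[keep],
                                        "case": case[keep]}))
            got += int(keep.sum())
    else:
        raise RuntimeError(
            f"could not ascertain {need} affected trios within "
            f"{_MAX_BATCHES} batches of {batch} (K={config.prevalence_k})"
        )
    fa = np.vstack(fa_l); mo = np.vstack(mo_l); ch = np.vstack(ch_l)
    meta = pd.concat(meta_l, ignore_index=True)
    n = got
    fids = [f"T{i + 1}_F" for i in range(n)]
    mids = [f"T{i + 1}_M" for i in range(n)]
    cids = [f"T{i + 1}_C" for i in range(n)]
    sample_ids = fids + mids + cids
    dosages = np.vstack([fa, mo, ch])
    screen = np.where(
        meta["case"], np.where(meta["carrier"], "positive", "negative"), "unknown"
    )
    samples = pd.DataFrame(
        {
            "id": sample_ids,
            "phenotype": ["control"] * (2 * n)
            + list(np.where(meta["case"], "case", "control")),
            "sex": [1] * n + [2] * n + list(rng.integers(1, 3, size=n)),
            "cohort": "sim_trios",
            "screen_status": ["unknown"] * (2 * n) + list(screen),
            "carrier": [False] * (2 * n) + list(meta["carrier"].values),
            "liability": [np.nan] * (2 * n) + list(meta["liability"].values),
        }
    )
    trios = pd.DataFrame({"father_id": fids, "mother_id": mids, "child_id": cids})
    gmat = GenotypeMatrix(sample_ids=sample_ids, variants=effects.variants.copy(),
                          dosages=dosages)
    return gmat, samples, trios


# ---------------------------------------------------------------------------
# Rare-variant annotation tables

_DECOY_SNV_RULES = ("mpc_low", "in_population_db", "dataset_count_high",
                    "not_in_panel", "synonymous")
_DECOY_CNV_RULES = ("cnv_short_no_overlap",)


def simulate_annotations(samples: pd.DataFrame, config: SimulationConfig,
                         seed: int | None = None):
    """Annotated SNV/CNV tables exercising every qualifying rule.

    Each ground-truth carrier case receives exactly one qualifying record
    (SNV or CNV).  Non-carrier cases receive decoy records, each violating
    exactly one rule, so rule-level audits can attribute every rejection.

    Returns (snv DataFrame, cnv DataFrame, truth DataFrame with the
    expected screen status per case).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 13)
    cases = samples[samples["phenotype"] == "case"]
    snv_rows, cnv_rows, truth_rows = [], [], []
    k = 0
    for _, row in cases.iterrows():
        cid = row["id"]
        carrier = bool(row.get("carrier", row.get("screen_status") == "positive"))
        if carrier:
            if rng.random() < 0.5:
                lof = rng.random() < 0.5
                snv_rows.append(
                    {"case_id": cid, "variant_key": f"qual_snv_{k}",
                     "gene": "PANEL_GENE1",
                     "consequence": "lof" if lof else "missense",
                     "mpc": np.nan if lof else float(rng.uniform(2.1, 4.0)),
                     "in_population_db": False,
                     "dataset_count": int(rng.integers(1, 4)),
                     "gene_in_dominant_panel": True}
                )
            else:
                mode = rng.integers(3)
                cnv_rows.append(
                    {"case_id": cid, "variant_key": f"qual_cnv_{k}",
                     "length_bp": int(rng.integers(2_000_001, 5_000_000))
                     if mode == 0 else int(rng.integers(50_000, 2_000_000)),
                     "overlaps_epilepsy_gene_or_hotspot": bool(mode == 1),
                     "overlaps_pli_gt_0_9_gene": bool(mode == 2)}
                )
            truth_rows.append({"case_id": cid, "status": "positive"})
        else:
            rule = _DECOY_SNV_RULES[int(rng.integers(len(_DECOY_SNV_RULES)))] \
                if rng.random() < 0.8 else _DECOY_CNV_RULES[0]
            rec = {"case_id": cid, "variant_key": f"decoy_{rule}_{k}",
                   "gene": "PANEL_GENE1", "consequence": "missense",
                   "mpc": float(rng.uniform(2.1, 4.0)),
                   "in_population_db": False, "dataset_count": 1,
                   "gene_in_dominant_panel": True}
            if rule == "mpc_low":
                rec["mpc"] = 1.9
                snv_rows.append(rec)
            elif rule == "in_population_db":
                rec["in_population_db"] = True
                snv_rows.append(rec)
            elif rule == "dataset_count_high":
                rec["dataset_count"] = 4
                snv_rows.append(rec)
            elif rule == "not_in_panel":
                rec["gene"] = "OFF_PANEL_GENE"
                rec["gene_in_dominant_panel"] = False
                snv_rows.append(rec)
            elif rule == "synonymous":
                rec["consequence"] = "synonymous"
                rec["mpc"] = np.nan
                snv_rows.append(rec)
            else:  # cnv_short_no_overlap
                cnv_rows.append(
                    {"case_id": cid, "variant_key": f"decoy_{rule}_{k}",
                     "length_bp": int(rng.integers(50_000, 2_000_000)),
                     "overlaps_epilepsy_gene_or_hotspot": False,
                     "overlaps_pli_gt_0_9_gene": False}
                )
            truth_rows.append({"case_id": cid, "status": "negative",
                               "decoy_rule": rule})
        k += 1
    snv_cols = ["case_id", "variant_key", "gene", "consequence", "mpc",
                "in_population_db", "dataset_count", "gene_in_dominant_panel"]
    cnv_cols = ["case_id", "variant_key", "length_bp",
                "overlaps_epilepsy_gene_or_hotspot", "overlaps_pli_gt_0_9_gene"]
    snvs = pd.DataFrame(snv_rows, columns=snv_cols)
    cnvs = pd.DataFrame(cnv_rows, columns=cnv_cols)
    truth = pd.DataFrame(truth_rows, columns=["case_id", "status", "decoy_rule"])
    return snvs, cnvs, truth


# ---------------------------------------------------------------------------
# QC artifact injection

@dataclass(frozen=True)
class ArtifactSpec:
    """Rates of deliberately degraded variants/samples for QC testing."""

    frac_missing_variants: float = 0.0
    missing_rate: float = 0.05  # per-genotype missingness on targeted variants
    frac_low_maf_variants: float = 0.0
    frac_hwe_violating_variants: float = 0.0
    frac_missing_samples: float = 0.0
    frac_het_outlier_samples: float = 0.0
    seed: int = 0


def inject_qc_artifacts(g: GenotypeMatrix, spec: ArtifactSpec):
    """Return a degraded copy of ``g`` plus ground-truth artifact flags.

    Each targeted variant/sample violates exactly one filter: call rate
    (random missingness), MAF (near-monomorphic rewrite), HWE (all
    heterozygous rewrite), sample call rate, or heterozygosity excess.
    """
    rng = np.random.default_rng(spec.seed)
    dos = g.dosages.copy()
    n, m = dos.shape
    counts = {
        "missing_variants": int(round(spec.frac_missing_variants * m)),
        "low_maf_variants": int(round(spec.frac_low_maf_variants * m)),
        "hwe_variants": int(round(spec.frac_hwe_violating_variants * m)),
        "missing_samples": int(round(spec.frac_missing_samples * n)),
        "het_outlier_samples": int(round(spec.frac_het_outlier_samples * n)),
    }
    total_v = counts["missing_variants"] + counts["low_maf_variants"] + counts["hwe_variants"]
    if total_v > m:
        raise ValueError("variant artifact fractions exceed available variants")
    vperm = rng.permutation(m)
    v_missing = vperm[: counts["missing_variants"]]
    v_lowmaf = vperm[counts["missing_variants"]: counts["missing_variants"] + counts["low_maf_variants"]]
    v_hwe = vperm[counts["missing_variants"] + counts["low_maf_variants"]: total_v]
    for j in v_missing:
        mask = rng.random(n) < spec.missing_rate
        if not mask.any():
            mask[rng.integers(n)] = True
        dos[mask, j] = np.nan
    for j in v_lowmaf:
        dos[:, j] = 0.0
        dos[rng.integers(n), j] = 1.0  # one het keeps the site polymorphic
    for j in v_hwe:
        dos[:, j] = 1.0  # every sample heterozygous: extreme HWE violation
    total_s = counts["missing_samples"] + counts["het_outlier_samples"]
    if total_s > n:
        raise ValueError("sample artifact fractions exceed available samples")
    sperm = rng.permutation(n)
    s_missing = sperm[: counts["missing_samples"]]
    s_het = sperm[counts["missing_samples"]: total_s]
    clean_cols = np.setdiff1d(np.arange(m), np.concatenate([v_missing, v_lowmaf, v_hwe]))
    for i in s_missing:
        k = max(1, int(round(0.05 * m)))
        cols = rng.choice(clean_cols, size=min(k, len(clean_cols)), replace=False)
        dos[i, cols] = np.nan
    for i in s_het:
        dos[i, clean_cols] = 1.0
    flags = {
        "variants_missing": [g.variants["id"].iloc[j] for j in sorted(v_missing)],
        "variants_low_maf": [g.variants["id"].iloc[j] for j in sorted(v_lowmaf)],
        "variants_hwe": [g.variants["id"].iloc[j] for j in sorted(v_hwe)],
        "samples_missing": [g.sample_ids[i] for i in sorted(s_missing)],
        "samples_het_outlier": [g.sample_ids[i] for i in sorted(s_het)],
    }
    degraded = GenotypeMatrix(sample_ids=list(g.sample_ids),
                              variants=g.variants.copy(), dosages=dos)
    return degraded, flags
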