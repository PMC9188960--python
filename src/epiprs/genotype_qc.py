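"""Genotype quality control: exact HWE test, variant/sample filters,
LD pruning, relationship-matrix PCA and ancestry-outlier flagging.

The filter cascade mirrors standard array-QC practice: SNP call rate
>= 98%, MAF >= 1%, Hardy-Weinberg exact-test p >= 1e-5, imputation INFO
>= 0.9; sample call rate >= 98% and heterozygosity within +-3 SD.
LD thinning follows the PLINK ``--indep-pairwise 1000,100,0.1``
convention (SNP-count windows), and principal components come from the
variance-standardised genetic relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import GenotypeMatrix

__all__ = [
    "QCThresholds", "QCReport", "hwe_exact_test", "hwe_pvalues",
    "filter_variants", "filter_samples", "ld_prune", "compute_pcs",
    "flag_pc_outliers",
]


@dataclass(frozen=True)
class QCThresholds:
    snp_call_rate_min: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    sample_call_rate_min: float = 0.98
    het_sd_limit: float = 3.0
    info_min: float = 0.9
    prune_window_snps: int = 1000
    prune_step: int = 100
    prune_r2: float = 0.1
    n_pcs: int = 4

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "sample_call_rate_min", "info_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.prune_window_snps >= self.prune_step >= 1:
            raise ValueError("require prune_window_snps >= prune_step >= 1")


@dataclass
class QCReport:
    """Per-rule removal counts, in application order, plus retained ids."""

    dimension: str  # 'variants' or 'samples'
    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"dimension": self.dimension, "rule": rule, "n_removed": len(ids)}
                for rule, ids in self.removed.items()]
        rows.append({"dimension": self.dimension, "rule": "retained",
                     "n_removed": len(self.retained)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed
    allele counts (same parity as the minor-allele count) and sums the
    probabilities of all configurations no more probable than the observed
    one, under the exact sampling distribution of genotype counts given
    allele counts.  Monomorphic sites return p = 1 by convention.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("no genotyped samples")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(h) = log n! - log n_AA! - log h! - log n_BB! + h log 2
    #          + log n_a! + log n_b! - log (2n)!
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= obs * (1.0 + 1e-9)].sum()
    return float(min(p, 1.0))


def _hard_call_counts(dosages_col: np.ndarray) -> tuple[int, int, int]:
    d = dosages_col[~np.isnan(dosages_col)]
    hard = np.rint(d).astype(int)
    return int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per variant, from hard-called (rounded) dosages."""
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        c0, c1, c2 = _hard_call_counts(g.dosages[:, j])
        if c0 + c1 + c2 == 0:
            out[j] = np.nan
        else:
            out[j] = hwe_exact_test(c0, c1, c2)
    return out


# ---------------------------------------------------------------------------
# Filters

def filter_variants(g: GenotypeMatrix, t: QCThresholds | None = None
                    ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant filter cascade in fixed order.

    Order: call rate, then MAF, then HWE exact test, then INFO (when an
    INFO column is present).  MAF uses non-missing dosages; HWE uses
    hard-called genotypes.  Removing everything yields an empty matrix
    with a warning, not an error.
    """
    t = t or QCThresholds()
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(dimension="variants", n_input=g.n_variants)
    ids = g.variants["id"].to_numpy()
    alive = np.ones(g.n_variants, dtype=bool)

    cr = g.call_rate()
    drop = alive & (cr < t.snp_call_rate_min)
    report.removed["call_rate"] = list(ids[drop])
    alive &= ~drop

    maf = g.maf()
    with np.errstate(invalid="ignore"):
        drop = alive & ((maf < t.maf_min) | np.isnan(maf))
    report.removed["maf"] = list(ids[drop])
    alive &= ~drop

    hwe_p = np.ones(g.n_variants)
    for j in np.where(alive)[0]:
        c0, c1, c2 = _hard_call_counts(g.dosages[:, j])
        hwe_p[j] = hwe_exact_test(c0, c1, c2) if (c0 + c1 + c2) else 0.0
    drop = alive & (hwe_p < t.hwe_p_min)
    report.removed["hwe"] = list(ids[drop])
    alive &= ~drop

    if "info" in g.variants.columns:
        info = g.variants["info"].to_numpy(dtype=float)
        drop = alive & np.isfinite(info) & (info < t.info_min)
        report.removed["info"] = list(ids[drop])
        alive &= ~drop

    report.retained = list(ids[alive])
    if not alive.any():
        warnings.warn("all variants removed by QC filters")
    out = g.subset(variant_ids=ids[alive])
    return out, report


def filter_samples(g: GenotypeMatrix, t: QCThresholds | None = None
                   ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate samples, then heterozygosity outliers.

    Heterozygosity rate = fraction of hard-called genotypes equal to 1;
    outliers lie beyond mean +- het_sd_limit * SD among surviving samples.
    With fewer than 3 survivors, or zero SD, the heterozygosity step is
    skipped.
    """
    t = t or QCThresholds()
    if g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(dimension="samples", n_input=g.n_samples)
    ids = np.array(g.sample_ids)
    alive = np.ones(g.n_samples, dtype=bool)

    cr = g.sample_call_rate()
    drop = cr < t.sample_call_rate_min
    report.removed["call_rate"] = list(ids[drop])
    alive &= ~drop

    report.removed["heterozygosity"] = []
    idx = np.where(alive)[0]
    if len(idx) < 3:
        warnings.warn("fewer than 3 samples: heterozygosity filter skipped")
    else:
        hard = np.rint(g.dosages[idx])
        het_rate = np.nanmean(hard == 1, axis=1)
        sd = het_rate.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            pass  # degenerate: identical samples, nothing to flag
        else:
            mean = het_rate.mean()
            out = np.abs(het_rate - mean) > t.het_sd_limit * sd
            report.removed["heterozygosity"] = list(ids[idx[out]])
            alive[idx[out]] = False

    report.retained = list(ids[alive])
    return g.subset(samples=ids[alive]), report


# ---------------------------------------------------------------------------
# LD pruning

def _pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    xi = x.copy()
    col_mean = np.nanmean(xi, axis=0)
    nan_mask = np.isnan(xi)
    xi[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    xi -= xi.mean(axis=0)
    sd = xi.std(axis=0)
    sd[sd == 0] = np.nan
    xi /= sd
    with np.errstate(invalid="ignore"):
        r = (xi.T @ xi) / xi.shape[0]
    return r**2


def ld_prune(g: GenotypeMatrix, window_snps: int = 1000, step: int = 100,
             r2_max: float = 0.1) -> list[str]:
    """Greedy windowed LD pruning; returns retained variant ids.

    Within each sliding window of ``window_snps`` variants (advanced by
    ``step``, per chromosome in position order), while any surviving pair
    exceeds ``r2_max`` the pair with the highest r2 is resolved by
    removing its lower-MAF member (ties: later position).  Deterministic.
    """
    mafs = g.maf()
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
    removed = set()
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms[order]):
        cidx = order[chroms[order] == chrom]
        start = 0
        while start < len(cidx):
            widx = cidx[start: start + window_snps]
            live = [j for j in widx if j not in removed]
            if len(live) > 1:
                r2 = _pairwise_r2(g.dosages[:, live])
                np.fill_diagonal(r2, 0.0)
                r2 = np.nan_to_num(r2)
                while True:
                    i, k = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, k] <= r2_max:
                        break
                    ji, jk = live[i], live[k]
                    if mafs[ji] < mafs[jk]:
                        victim = i
                    elif mafs[jk] < mafs[ji]:
                        victim = k
                    else:  # tie: later position goes
                        victim = i if g.variants["pos"].iloc[ji] > g.variants["pos"].iloc[jk] else k
                    removed.add(live[victim])
                    r2[victim, :] = 0.0
                    r2[:, victim] = 0.0
            if start + window_snps >= len(cidx):
                break
            start += step
    keep_mask = [j for j in range(g.n_variants) if j not in removed]
    return [g.variants["id"].iloc[j] for j in keep_mask]


# ---------------------------------------------------------------------------
# PCA on the variance-standardised relationship matrix

def compute_pcs(g: GenotypeMatrix, n_pcs: int = 4) -> pd.DataFrame:
    """Principal components of the variance-standardised GRM.

    Each variant column is standardised to mean 0, variance 1 (zero
    variance columns dropped; missing dosages mean-imputed), the genetic
    relationship matrix is X X^T / m, and PCs are its leading
    eigenvectors scaled by sqrt(eigenvalue).  Sign convention: the
    largest-magnitude loading of each PC is positive.
    """
    if g.n_samples < 2 or g.n_variants < 2:
        raise ValueError("need at least 2 samples and 2 variants for PCA")
    x = g.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    m = x.shape[1]
    if m == 0:
        warnings.warn("no polymorphic variants: returning zero PCs")
        return pd.DataFrame(index=pd.Index(g.sample_ids, name="id"))
    grm = (x @ x.T) / m
    evals, evecs = np.linalg.eigh(grm)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = max(g.n_samples, m) * np.finfo(float).eps * max(evals.max(), 0.0)
    rank = int((evals > tol).sum())
    if n_pcs > rank:
        warnings.warn(f"requested {n_pcs} PCs but rank is {rank}; truncating")
    k = min(n_pcs, rank)
    pcs = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))
    for j in range(k):
        i_max = np.argmax(np.abs(pcs[:, j]))
        if pcs[i_max, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pd.DataFrame(pcs, index=pd.Index(g.sample_ids, name="id"),
                        columns=[f"pc{j + 1}" for j in range(k)])


def flag_pc_outliers(pcs: pd.DataFrame, sd_limit: float = 6.0) -> list[str]:
    """Samples beyond median +- sd_limit robust SDs (1.4826 * MAD) on PC1/PC2.

    Automates the usual visual inspection of ancestry PCA plots.  Zero
    MAD on an axis disables that axis (no outliers flagged by it).
    """
    if len(pcs) < 3:
        raise ValueError("need at least 3 samples to flag outliers")
    flagged: set[str] = set()
    for col in [c for c in ("pc1", "pc2") if c in pcs.columns]:
        v = pcs[col].to_numpy(dtype=float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            continue
        out = np.abs(v - med) > sd_limit * robust_sd
        flagged.update(np.asarray(pcs.index)[out])
    return sorted(flagged)
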