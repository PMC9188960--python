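"""Polygenic risk scoring: allele harmonisation, p-value thresholding,
optional clumping, weighted-dosage scoring and normalisation.

The score for sample i is raw_i = sum_j w_j d_ij over the harmonised,
p-thresholded SNP set (default threshold p <= 0.5), with w_j the
discovery-GWAS log-odds on the genotype's counted allele and d_ij the
additive dosage.  Scores are normalised to mean 0, SD 1 over a
normalisation set (default: all scored samples jointly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

__all__ = ["WeightTable", "PRSVector", "harmonize_alleles", "select_snps",
           "clump", "score", "normalize_prs", "compute_prs"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_allele(a: str) -> str:
    return a.translate(_COMPLEMENT)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class WeightTable:
    """Per-variant scoring weights after harmonisation.

    ``weight`` is log-odds per copy of the genotype's counted allele;
    ``sign_flipped`` marks variants whose GWAS effect allele was the
    genotype's other allele.
    """

    table: pd.DataFrame  # columns: id, counted_allele, weight, sign_flipped, p
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"]))

    def __len__(self) -> int:
        return len(self.table)

    def exclusion_counts(self) -> dict[str, int]:
        return self.exclusions["reason"].value_counts().to_dict()


@dataclass
class PRSVector:
    """Per-sample raw and (optionally) normalised polygenic scores."""

    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"id": self.sample_ids, "raw": self.raw}
        if self.z is not None:
            d["z"] = self.z
        return pd.DataFrame(d)

    def z_series(self) -> pd.Series:
        if self.z is None:
            raise ValueError("scores not normalised yet")
        return pd.Series(self.z, index=self.sample_ids, name="prs_z")


def harmonize_alleles(variants: pd.DataFrame, stats: pd.DataFrame) -> WeightTable:
    """Match genotype variants to summary statistics by id and align alleles.

    If the genotype's counted allele equals the GWAS effect allele the
    weight is beta; if it equals the other allele the weight is -beta
    (sign flip); a strand-complement match is resolved the same way after
    complementing.  Palindromic (A/T, C/G) variants are excluded as
    strand-ambiguous, as are ids missing from either input and allele
    mismatches.
    """
    srows = stats.set_index("id", drop=False)
    rows, excl = [], []
    for v in variants.itertuples(index=False):
        vid = v.id
        a1, a2 = v.a1.upper(), v.a2.upper()
        if vid not in srows.index:
            excl.append({"id": vid, "reason": "not_in_stats"})
            continue
        if _is_palindromic(a1, a2):
            excl.append({"id": vid, "reason": "palindromic"})
            continue
        s = srows.loc[vid]
        ea, oa = s["effect_allele"], s["other_allele"]
        beta, p = float(s["beta"]), float(s["p"])
        if (a1, a2) == (ea, oa):
            w, flip = beta, False
        elif (a1, a2) == (oa, ea):
            w, flip = -beta, True
        elif (a1, a2) == (_revcomp_allele(ea), _revcomp_allele(oa)):
            w, flip = beta, False
        elif (a1, a2) == (_revcomp_allele(oa), _revcomp_allele(ea)):
            w, flip = -beta, True
        else:
            excl.append({"id": vid, "reason": "allele_mismatch"})
            continue
        if not np.isfinite(w):
            excl.append({"id": vid, "reason": "non_finite_weight"})
            continue
        rows.append({"id": vid, "counted_allele": a1, "weight": w,
                     "sign_flipped": flip, "p": p})
    if not rows:
        raise ValueError("no variants matched between genotypes and summary statistics")
    return WeightTable(
        table=pd.DataFrame(rows, columns=["id", "counted_allele", "weight",
                                          "sign_flipped", "p"]),
        exclusions=pd.DataFrame(excl, columns=["id", "reason"]),
    )


def select_snps(weights: WeightTable, p_max: float = 0.5) -> WeightTable:
    """Retain variants with discovery p <= p_max (boundary inclusive)."""
    kept = weights.table[weights.table["p"] <= p_max].reset_index(drop=True)
    return WeightTable(table=kept, exclusions=weights.exclusions)


def clump(stats: pd.DataFrame, reference: GenotypeMatrix, r2_max: float = 0.1,
          window_kb: float = 250.0) -> list[str]:
    """Greedy p-value clumping against a reference panel.

    Variants are visited by ascending p; one is accepted if no
    already-accepted variant within ``window_kb`` on the same chromosome
    has dosage r-squared above ``r2_max`` with it.  Returns accepted
    (index-variant) ids.
    """
    if len(stats) == 0:
        return []
    ref_idx = {v: j for j, v in enumerate(reference.variants["id"])}
    missing = [v for v in stats["id"] if v not in ref_idx]
    if missing:
        raise ValueError(f"variants absent from reference panel: {missing[:5]}")
    meta = reference.variants.set_index("id")
    x = reference.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    mask = np.isnan(x)
    x[mask] = np.take(col_mean, np.where(mask)[1])
    order = stats.sort_values(["p", "id"], kind="stable")
    accepted: list[str] = []
    for vid in order["id"]:
        chrom, pos = meta.loc[vid, "chrom"], meta.loc[vid, "pos"]
        ok = True
        for aid in accepted:
            if meta.loc[aid, "chrom"] != chrom:
                continue
            if abs(meta.loc[aid, "pos"] - pos) > window_kb * 1000:
                continue
            xa, xb = x[:, ref_idx[aid]], x[:, ref_idx[vid]]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            accepted.append(vid)
    return accepted


def score(g: GenotypeMatrix, weights: WeightTable,
          missing_policy: str = "mean_dosage") -> PRSVector:
    """Raw PRS: weighted dosage sum with mean-dosage imputation of missing calls."""
    if missing_policy != "mean_dosage":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    geno_ids = set(g.variants["id"])
    absent = [v for v in weights.table["id"] if v not in geno_ids]
    if absent:
        raise ValueError(
            f"weights reference variants absent from genotypes: {absent[:5]} "
            "(harmonize against these genotypes first)")
    sub = g.subset(variant_ids=list(weights.table["id"]))
    x = sub.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing variant contributes 0
    mask = np.isnan(x)
    x[mask] = np.take(col_mean, np.where(mask)[1])
    raw = x @ weights.table["weight"].to_numpy(dtype=float)
    return PRSVector(sample_ids=list(g.sample_ids), raw=raw)


def normalize_prs(prs: PRSVector, normalisation_set: list[str] | None = None
                  ) -> PRSVector:
    """Z-standardise raw scores over ``normalisation_set`` (default: all samples).

    The mean/SD come from the normalisation set; the affine map is applied
    to every sample.  SD uses the n-1 denominator.
    """
    if normalisation_set is None:
        idx = np.arange(len(prs.sample_ids))
    else:
        pos = {s: i for i, s in enumerate(prs.sample_ids)}
        idx = np.array([pos[s] for s in normalisation_set], dtype=int)
    if len(idx) < 2:
        raise ValueError("need at least 2 samples to normalise")
    mu = prs.raw[idx].mean()
    sd = prs.raw[idx].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate score: zero standard deviation")
    return PRSVector(sample_ids=prs.sample_ids, raw=prs.raw,
                     z=(prs.raw - mu) / sd)


def compute_prs(g: GenotypeMatrix, stats: pd.DataFrame, p_max: float = 0.5,
                normalisation_set: list[str] | None = None) -> PRSVector:
    """Harmonise, threshold, score and normalise in one call."""
    weights = select_snps(harmonize_alleles(g.variants, stats), p_max=p_max)
    if len(weights) == 0:
        raise ValueError(f"no variants pass the p <= {p_max} threshold")
    return normalize_prs(score(g, weights), normalisation_set)
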