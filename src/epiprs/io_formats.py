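"""Readers, writers and containers for the external formats the pipeline touches.

Genotypes travel as :class:`GenotypeMatrix` (samples x variants additive
dosages of a counted allele, missing allowed), GWAS summary statistics,
sample phenotype tables, cohort manifests and pedigrees as pandas
DataFrames with validated schemas.  Coordinates are 1-based as in VCF and
variants are keyed by id (rsID-style), which is how GWAS summary statistics
are distributed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: default column-name synonyms accepted by :func:`read_summary_stats`
SUMMARY_STAT_SYNONYMS = {
    "id": ["id", "snp", "rsid", "markername", "variant_id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "bp", "position", "base_pair_location"],
    "effect_allele": ["effect_allele", "a1", "ea", "allele1"],
    "other_allele": ["other_allele", "a2", "oa", "nea", "allele2"],
    "beta": ["beta", "b", "effect", "log_odds"],
    "se": ["se", "stderr", "standard_error"],
    "p": ["p", "pval", "pvalue", "p_value"],
}


@dataclass
class VariantRecord:
    """One biallelic variant with the per-variant QC quantities attached."""

    id: str
    chrom: str
    pos: int
    allele_a1: str  # counted / effect allele
    allele_a2: str
    maf: float | None = None
    call_rate: float | None = None
    hwe_p: float | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        if not self.allele_a1 or not self.allele_a2:
            raise ValueError(f"variant {self.id}: empty allele")
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1")
        if self.maf is not None and not (0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix with per-variant metadata.

    ``dosages`` is ``n_samples x n_variants`` float64 in [0, 2]; missing
    genotypes are NaN.  ``variants`` carries columns ``id, chrom, pos, a1,
    a2`` and optionally ``info``; ``a1`` is the counted allele.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids not unique")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing dosages."""
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Per-variant counted-allele frequency from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset(
        self,
        samples: Sequence[str] | np.ndarray | None = None,
        variant_ids: Sequence[str] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset preserving order of the requested ids."""
        if samples is None:
            row_idx = np.arange(self.n_samples)
            new_samples = list(self.sample_ids)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            row_idx = np.array([pos[s] for s in samples], dtype=int)
            new_samples = list(samples)
        if variant_ids is None:
            col_idx = np.arange(self.n_variants)
        else:
            vpos = {v: i for i, v in enumerate(self.variants["id"])}
            col_idx = np.array([vpos[v] for v in variant_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=new_samples,
            variants=self.variants.iloc[col_idx].reset_index(drop=True),
            dosages=self.dosages[np.ix_(row_idx, col_idx)].copy(),
        )

    def variant_records(self) -> list[VariantRecord]:
        mafs = self.maf()
        crs = self.call_rate()
        recs = []
        for j, row in enumerate(self.variants.itertuples(index=False)):
            recs.append(
                VariantRecord(
                    id=row.id,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    allele_a1=row.a1,
                    allele_a2=row.a2,
                    maf=float(mafs[j]) if np.isfinite(mafs[j]) else None,
                    call_rate=float(crs[j]),
                    info=float(row.info) if "info" in self.variants.columns and np.isfinite(row.info) else None,
                )
            )
        return recs


# ---------------------------------------------------------------------------
# VCF

def read_genotypes_vcf(path: str, counted_allele: str = "alt") -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Dosage is taken from the DS FORMAT field when present (imputed-data
    convention), otherwise from counting ``counted_allele`` copies in GT.
    Missing GT (./.) becomes a missing dosage.  Variants are preserved in
    file order.  Multi-allelic records and duplicate variant ids are
    rejected.
    """
    from cyvcf2 import VCF

    if counted_allele not in ("alt", "ref"):
        raise ValueError("counted_allele must be 'alt' or 'ref'")
    vcf = VCF(path)
    samples = list(vcf.samples)
    meta_rows = []
    cols = []
    seen = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multi-allelic record {v.ID or f'{v.CHROM}:{v.POS}'} "
                f"(ALT={','.join(v.ALT) or '.'}) is not supported"
            )
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        if vid in seen:
            raise ValueError(f"duplicate variant id {vid!r}")
        seen.add(vid)
        ds = v.format("DS")
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            gts = v.genotype.array()  # n x (ploidy+1), -1 = missing
            if gts is None:
                raise ValueError(f"variant {vid}: neither GT nor DS present")
            alleles = gts[:, :2].astype(float)
            miss = (alleles < 0).any(axis=1)
            alt_count = np.where(miss, np.nan, (gts[:, :2] == 1).sum(axis=1))
            dos = alt_count if counted_allele == "alt" else 2.0 - alt_count
        if counted_allele == "alt":
            a1, a2 = v.ALT[0], v.REF
        else:
            a1, a2 = v.REF, v.ALT[0]
        info_score = v.INFO.get("INFO")
        if ds is not None and counted_allele == "ref":
            dos = 2.0 - dos
        meta_rows.append(
            {"id": vid, "chrom": v.CHROM, "pos": v.POS, "a1": a1, "a2": a2,
             "info": float(info_score) if info_score is not None else np.nan}
        )
        cols.append(dos)
    vcf.close()
    variants = pd.DataFrame(meta_rows, columns=["id", "chrom", "pos", "a1", "a2", "info"])
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


def write_genotypes_vcf(g: GenotypeMatrix, path: str, counted_allele: str = "alt") -> None:
    """Write a minimal VCF 4.2 with GT (hard call) and DS per genotype.

    DS is rounded to single precision (the VCF FORMAT/Float resolution)
    and written with shortest-round-trip formatting, so writing and
    re-reading is the identity for any dosage matrix that itself came
    from a VCF (and exact for hard calls always).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        has_info = "info" in g.variants.columns
        for j, row in enumerate(g.variants.itertuples(index=False)):
            if counted_allele == "alt":
                ref, alt = row.a2, row.a1
                dos = g.dosages[:, j]
            else:
                ref, alt = row.a1, row.a2
                dos = 2.0 - g.dosages[:, j]
            info = "."
            if has_info and np.isfinite(row.info):
                info = f"INFO={row.info:g}"
            fields = [str(row.chrom), str(int(row.pos)), str(row.id), ref, alt,
                      ".", ".", info, "GT:DS"]
            cells = []
            for d in dos:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = ["0/0", "0/1", "1/1"][hard]
                    cells.append(f"{gt}:{float(np.float32(d))!r}")
            fh.write("\t".join(fields + cells) + "\n")


# ---------------------------------------------------------------------------
# Summary statistics

def read_summary_stats(
    path: str,
    synonyms: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV.

    Requires (possibly via synonyms) columns id, effect_allele,
    other_allele, beta (log-odds per effect-allele copy), se, p.  Rows with
    unparseable numerics or p outside (0, 1] are dropped with a logged
    count.  An OR column is never converted implicitly: odds-ratio input
    must be logged by the caller.
    """
    syn = {**SUMMARY_STAT_SYNONYMS, **(synonyms or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    mandatory = ["id", "effect_allele", "other_allele", "beta", "se", "p"]
    rename = {}
    for canon in syn:
        for alias in syn[canon]:
            if alias in raw.columns and canon not in rename.values():
                rename[alias] = canon
                break
    raw = raw.rename(columns=rename)
    missing = [c for c in mandatory if c not in raw.columns]
    if missing:
        hint = ""
        if "or" in raw.columns and "beta" in missing:
            hint = (" (found 'OR' column: odds ratios are not log-transformed "
                    "automatically; provide beta = log(OR) explicitly)")
        raise ValueError(
            f"summary statistics missing mandatory column(s) {missing}; "
            f"expected header with {mandatory} or synonyms{hint}"
        )
    out = raw.copy()
    for col in ("beta", "se", "p"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if "pos" in out.columns:
        out["pos"] = pd.to_numeric(out["pos"], errors="coerce")
    n0 = len(out)
    keep = (
        out["beta"].notna()
        & out["se"].notna()
        & (out["se"] > 0)
        & out["p"].notna()
        & (out["p"] > 0)
        & (out["p"] <= 1)
    )
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.warning("read_summary_stats: dropped %d malformed row(s)", dropped)
    out = out[keep].reset_index(drop=True)
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].str.upper()
    out.attrs["n_dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# Samples, trios, pedigree

PHENOTYPES = ("case", "control")
SCREEN_STATUSES = ("positive", "negative", "unknown")


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-table schema (id, phenotype, sex, cohort, screen_status)."""
    required = {"id", "phenotype"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    if samples["id"].duplicated().any():
        raise ValueError("duplicate sample id in sample table")
    bad = set(samples["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise ValueError(f"unknown phenotype value(s) {sorted(bad)}")
    if "screen_status" in samples.columns:
        bad = set(samples["screen_status"].dropna()) - set(SCREEN_STATUSES)
        if bad:
            raise ValueError(f"unknown screen_status value(s) {sorted(bad)}")
    return samples


def read_samples_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return validate_samples(df)


def read_trios_fam(path: str) -> pd.DataFrame:
    """Read a 6-column FAM pedigree and extract complete trios.

    Returns a DataFrame with columns father_id, mother_id, child_id; a
    child appears in at most one trio.
    """
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    trios = fam[(fam["father"] != "0") & (fam["mother"] != "0")]
    out = pd.DataFrame(
        {"father_id": trios["father"].values,
         "mother_id": trios["mother"].values,
         "child_id": trios["iid"].values}
    )
    return validate_trios(out)


def validate_trios(trios: pd.DataFrame) -> pd.DataFrame:
    for _, r in trios.iterrows():
        ids = {r["father_id"], r["mother_id"], r["child_id"]}
        if len(ids) != 3:
            raise ValueError(f"trio with non-distinct members: {sorted(ids)}")
    if trios["child_id"].duplicated().any():
        raise ValueError("a child appears in more than one trio")
    return trios


def write_trios_fam(trios: pd.DataFrame, samples: pd.DataFrame, path: str) -> None:
    """Write trio members (and any singletons) as a FAM pedigree."""
    sex = dict(zip(samples["id"], samples.get("sex", pd.Series(dtype=int))))
    phen = dict(zip(samples["id"], samples["phenotype"]))
    in_trio_child = set(trios["child_id"])
    with open(path, "w") as fh:
        for i, r in trios.iterrows():
            fam_id = f"FAM{i}"
            for member, fa, mo in (
                (r["father_id"], "0", "0"),
                (r["mother_id"], "0", "0"),
                (r["child_id"], r["father_id"], r["mother_id"]),
            ):
                code = {"case": 2, "control": 1}.get(phen.get(member), 0)
                fh.write(f"{fam_id} {member} {fa} {mo} {sex.get(member, 0)} {code}\n")
        for sid in samples["id"]:
            if sid not in in_trio_child and sid not in set(trios["father_id"]) \
                    and sid not in set(trios["mother_id"]):
                code = {"case": 2, "control": 1}.get(phen.get(sid), 0)
                fh.write(f"U_{sid} {sid} 0 0 {sex.get(sid, 0)} {code}\n")


# ---------------------------------------------------------------------------
# Cohort manifest

MANIFEST_COLUMNS = ["cohort", "n_cases", "n_screen_positive", "n_screen_negative",
                    "n_controls", "phenotype"]


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return df


def bundled_manifest() -> pd.DataFrame:
    """The study's published per-cohort case/control breakdown."""
    from importlib.resources import files

    path = files("epiprs.data").joinpath("cohort_manifest.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def validate_manifest(manifest: pd.DataFrame, printed_control_total: int | None = None) -> dict:
    """Aggregate a cohort manifest into study-level totals.

    Returns total cases, screen-positive, screen-negative, unassigned
    (cases minus both screen strata) and controls.  When a separately
    printed control total is supplied it is echoed next to the recomputed
    column sum rather than reconciled.
    """
    if len(manifest) == 0:
        totals = {"n_cases": 0, "n_screen_positive": 0, "n_screen_negative": 0,
                  "n_unassigned": 0, "n_controls": 0}
    else:
        for col in ("n_cases", "n_screen_positive", "n_screen_negative", "n_controls"):
            if (manifest[col] < 0).any():
                raise ValueError(f"negative count in column {col}")
        over = manifest["n_screen_positive"] + manifest["n_screen_negative"] > manifest["n_cases"]
        if over.any():
            bad = manifest.loc[over, "cohort"].tolist()
            raise ValueError(
                f"inconsistent manifest: screen strata exceed cases in {bad}"
            )
        totals = {
            "n_cases": int(manifest["n_cases"].sum()),
            "n_screen_positive": int(manifest["n_screen_positive"].sum()),
            "n_screen_negative": int(manifest["n_screen_negative"].sum()),
            "n_controls": int(manifest["n_controls"].sum()),
        }
        totals["n_unassigned"] = (
            totals["n_cases"] - totals["n_screen_positive"] - totals["n_screen_negative"]
        )
        if totals["n_unassigned"] < 0:
            raise ValueError("inconsistent manifest: negative implied unassigned count")
    if printed_control_total is not None:
        totals["n_controls_printed"] = int(printed_control_total)
        totals["n_controls_recomputed"] = totals.pop("n_controls")
    return totals


# ---------------------------------------------------------------------------
# Result tables

def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            rows.append(r)
        else:
            raise TypeError(f"cannot tabulate record of type {type(r).__name__}")
    return pd.DataFrame(rows)


def write_results_tsv(records, path: str) -> None:
    """Write any homogeneous result table as TSV, floats at 6 significant digits."""
    df = _records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
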