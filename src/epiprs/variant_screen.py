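"""Rule-based qualifying rare-variant screen.

Classifies each case as screen-positive (carries at least one qualifying
SNV/indel or CNV), screen-negative (variant data present but nothing
qualifies) or unknown (no variant data).  The qualifying rules mirror
the bioinformatic screen used for exome+array severe-epilepsy cohorts:

SNV/indel: in a known dominant epilepsy/ID panel gene, AND
loss-of-function or missense with MPC > 2, AND absent from population
databases, AND seen at most 3 times in the dataset.

CNV: longer than 2 Mb, OR overlapping a known epilepsy gene/hotspot, OR
overlapping a gene with pLI > 0.9 (OR semantics as published; the
audit log flags length-only qualifiers for review).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["classify_snv", "classify_cnv", "assign_screen_status",
           "snv_failed_rules", "cnv_failed_rules", "ScreenAssignment"]

MPC_MIN = 2.0
CNV_LENGTH_MIN_BP = 2_000_000
DATASET_COUNT_MAX = 3


@dataclass
class ScreenAssignment:
    case_id: str
    status: str  # positive | negative | unknown
    qualifying: list[str] = field(default_factory=list)  # variant keys


def _get(v, key, default=None):
    if isinstance(v, dict):
        return v.get(key, default)
    return getattr(v, key, default)


def snv_failed_rules(v) -> list[str]:
    """Names of the qualifying clauses this SNV/indel record violates."""
    failed = []
    if not bool(_get(v, "gene_in_dominant_panel")):
        failed.append("not_in_dominant_panel")
    consequence = _get(v, "consequence")
    if consequence == "lof":
        pass
    elif consequence == "missense":
        mpc = _get(v, "mpc")
        if mpc is None or (isinstance(mpc, float) and np.isnan(mpc)) or mpc <= MPC_MIN:
            failed.append("missense_mpc_le_2")
    else:
        failed.append("consequence_not_damaging")
    if bool(_get(v, "in_population_db")):
        failed.append("present_in_population_db")
    if int(_get(v, "dataset_count", 1)) > DATASET_COUNT_MAX:
        failed.append("dataset_count_gt_3")
    return failed


def classify_snv(v) -> bool:
    """Qualifying iff panel gene AND (LoF OR missense with MPC > 2)
    AND absent from population databases AND dataset count <= 3."""
    return not snv_failed_rules(v)


def cnv_failed_rules(c) -> list[str]:
    """Names of the (OR-combined) CNV clauses this record does NOT satisfy."""
    failed = []
    if int(_get(c, "length_bp")) <= CNV_LENGTH_MIN_BP:
        failed.append("length_le_2mb")
    if not bool(_get(c, "overlaps_epilepsy_gene_or_hotspot")):
        failed.append("no_epilepsy_gene_or_hotspot_overlap")
    if not bool(_get(c, "overlaps_pli_gt_0_9_gene")):
        failed.append("no_pli_gt_0_9_overlap")
    return failed


def classify_cnv(c) -> bool:
    """Qualifying iff > 2 Mb long OR overlapping an epilepsy gene/hotspot
    OR overlapping a pLI > 0.9 gene (any one clause suffices)."""
    return len(cnv_failed_rules(c)) < 3


def assign_screen_status(case_ids, snvs: pd.DataFrame | None = None,
                         cnvs: pd.DataFrame | None = None
                         ) -> tuple[list[ScreenAssignment], pd.DataFrame]:
    """Screen every case; returns assignments plus a per-record audit log.

    positive: at least one qualifying SNV or CNV; negative: variant data
    present but no qualifying record; unknown: absent from both tables.
    Variant rows referencing a case id outside ``case_ids`` are an error.
    The audit log itemises, per record, whether it qualified and which
    clauses failed (SNV) or which clauses carried it (CNV), so each decoy
    can be attributed to exactly the rule it violates.
    """
    case_ids = list(case_ids)
    known = set(case_ids)
    snvs = snvs if snvs is not None else pd.DataFrame(columns=["case_id"])
    cnvs = cnvs if cnvs is not None else pd.DataFrame(columns=["case_id"])
    for name, tab in (("snv", snvs), ("cnv", cnvs)):
        stray = set(tab["case_id"]) - known
        if stray:
            raise ValueError(f"{name} table references unknown case id(s): "
                             f"{sorted(stray)[:5]}")
    qualifying: dict[str, list[str]] = {cid: [] for cid in case_ids}
    has_data: set[str] = set()
    audit_rows = []
    for rec in snvs.itertuples(index=False):
        has_data.add(rec.case_id)
        failed = snv_failed_rules(rec)
        key = _get(rec, "variant_key", f"snv:{rec.case_id}")
        if not failed:
            qualifying[rec.case_id].append(key)
        audit_rows.append({"case_id": rec.case_id, "variant_key": key,
                           "kind": "snv", "qualifying": not failed,
                           "failed_rules": ";".join(failed),
                           "note": ""})
    for rec in cnvs.itertuples(index=False):
        has_data.add(rec.case_id)
        failed = cnv_failed_rules(rec)
        ok = len(failed) < 3
        key = _get(rec, "variant_key", f"cnv:{rec.case_id}")
        note = ""
        if ok and "no_epilepsy_gene_or_hotspot_overlap" in failed \
                and "no_pli_gt_0_9_overlap" in failed:
            note = "qualifies_by_length_only"
        if ok:
            qualifying[rec.case_id].append(key)
        audit_rows.append({"case_id": rec.case_id, "variant_key": key,
                           "kind": "cnv", "qualifying": ok,
                           "failed_rules": ";".join(failed), "note": note})
    assignments = []
    for cid in case_ids:
        if qualifying[cid]:
            status = "positive"
        elif cid in has_data:
            status = "negative"
        else:
            status = "unknown"
        assignments.append(ScreenAssignment(case_id=cid, status=status,
                                            qualifying=qualifying[cid]))
    audit = pd.DataFrame(audit_rows, columns=["case_id", "variant_key", "kind",
                                              "qualifying", "failed_rules", "note"])
    return assignments, audit
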