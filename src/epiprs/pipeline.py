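"""End-to-end orchestration: simulate -> QC -> score -> associate ->
compare groups -> meta-analyse -> pTDT -> screen.

Each stage persists its outputs as TSV under the run directory so any
stage can be re-run from intermediates; a provenance YAML records the
configuration, seed, package version and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import PRSLogit, pairwise_group_comparison
from .genotype_qc import QCThresholds, compute_pcs, filter_samples, filter_variants
from .io_formats import (GenotypeMatrix, write_genotypes_vcf, write_results_tsv,
                         write_trios_fam)
from .meta_analysis import MetaAnalysis
from .prs_scoring import compute_prs
from .ptdt import PTDT
from .synthetic_data import (SimulationConfig, simulate_annotations,
                             simulate_cohort, simulate_summary_stats,
                             simulate_trios, simulate_true_effects)
from .variant_screen import assign_screen_status

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "score", "assoc", "compare_groups", "meta",
          "ptdt", "screen")


@dataclass
class PipelineConfig:
    out_dir: str = "epiprs_run"
    seed: int = 0
    n_cohorts: int = 3
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    p_max: float = 0.5
    meta_model: str = "both"  # fixed | random | both
    write_vcf: bool = False  # full VCFs are large; TSV dosages by default

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        qc = QCThresholds(**raw.pop("qc", {}))
        return cls(sim=sim, qc=qc, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _covariate_frame(samples: pd.DataFrame, pcs: pd.DataFrame) -> pd.DataFrame:
    cov = samples.set_index("id")[["sex"]].astype(float)
    cov = cov.join(pcs)
    return cov.reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in fixed order; returns a result summary dict.

    A stage failure aborts the remaining stages with a diagnostic naming
    the stage.  Outputs land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"package_version": __version__, "seed": config.seed,
                        "config": config.to_dict(), "stages": {}}
    summary: dict = {}
    rng_seed = config.seed

    def run_stage(name, fn):
        try:
            rows = fn()
            provenance["stages"][name] = rows
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, e) from e

    cohorts: dict[str, dict] = {}
    effects = None
    trio_bundle: dict = {}

    def stage_simulate():
        nonlocal effects
        cfg = dataclasses.replace(config.sim, seed=rng_seed)
        effects = simulate_true_effects(cfg)
        stats = simulate_summary_stats(effects, cfg.n_discovery, seed=rng_seed)
        stats.to_csv(out / "summary_stats.tsv", sep="\t", index=False)
        counts = {"snps": len(stats)}
        for c in range(config.n_cohorts):
            g, samples = simulate_cohort(effects, cfg, seed=rng_seed + 1000 * (c + 1))
            samples = samples.assign(cohort=f"cohort{c + 1}")
            snvs, cnvs, truth = simulate_annotations(samples, cfg,
                                                     seed=rng_seed + 1000 * (c + 1))
            cohorts[f"cohort{c + 1}"] = {"g": g, "samples": samples,
                                         "samples_all": samples,
                                         "snvs": snvs, "cnvs": cnvs,
                                         "truth": truth}
            samples.to_csv(out / f"cohort{c + 1}.samples.tsv", sep="\t", index=False)
            snvs.to_csv(out / f"cohort{c + 1}.snvs.tsv", sep="\t", index=False)
            cnvs.to_csv(out / f"cohort{c + 1}.cnvs.tsv", sep="\t", index=False)
            if config.write_vcf:
                write_genotypes_vcf(g, str(out / f"cohort{c + 1}.vcf"))
            counts[f"cohort{c + 1}_samples"] = len(samples)
        gt, st, trios = simulate_trios(effects, cfg, seed=rng_seed + 99)
        trio_bundle.update({"g": gt, "samples": st, "trios": trios})
        st.to_csv(out / "trios.samples.tsv", sep="\t", index=False)
        write_trios_fam(trios, st, str(out / "trios.fam"))
        counts["trios"] = len(trios)
        return counts

    def stage_qc():
        counts = {}
        for name, c in cohorts.items():
            g, vrep = filter_variants(c["g"], config.qc)
            g, srep = filter_samples(g, config.qc)
            c["g_qc"] = g
            c["samples"] = c["samples"][c["samples"]["id"].isin(g.sample_ids)]
            pd.concat([vrep.to_frame(), srep.to_frame()]).to_csv(
                out / f"{name}.qc_report.tsv", sep="\t", index=False)
            pcs = compute_pcs(g, config.qc.n_pcs)
            c["pcs"] = pcs
            counts[name] = {"variants": g.n_variants, "samples": g.n_samples}
        return counts

    def stage_score():
        stats = pd.read_csv(out / "summary_stats.tsv", sep="\t")
        counts = {}
        for name, c in cohorts.items():
            prs = compute_prs(c["g_qc"], stats, p_max=config.p_max)
            c["prs"] = prs
            prs.to_frame().to_csv(out / f"{name}.prs.tsv", sep="\t", index=False)
            counts[name] = len(prs.sample_ids)
        tstats = pd.read_csv(out / "summary_stats.tsv", sep="\t")
        trio_bundle["prs"] = compute_prs(trio_bundle["g"], tstats, p_max=config.p_max)
        trio_bundle["prs"].to_frame().to_csv(out / "trios.prs.tsv", sep="\t",
                                             index=False)
        return counts

    def stage_assoc():
        results = []
        for name, c in cohorts.items():
            samples = c["samples"].merge(c["pcs"].reset_index(), on="id")
            model = PRSLogit.from_samples(samples, c["prs"])
            res = model.fit().to_assoc_result()
            res.cohort = name
            c["assoc"] = res
            results.append(res)
        write_results_tsv(results, str(out / "assoc_results.tsv"))
        return {r.cohort: {"beta": round(r.beta, 4), "p": float(f"{r.p:.3g}")}
                for r in results}

    def stage_compare_groups():
        rows = []
        for name, c in cohorts.items():
            samples = c["samples"].merge(c["pcs"].reset_index(), on="id")
            grp = np.where(samples["phenotype"] == "control", "control",
                           np.where(samples["screen_status"] == "positive",
                                    "screen_pos", "screen_neg"))
            z = c["prs"].z_series().loc[samples["id"]].to_numpy()
            cov = samples[["sex"] + [col for col in samples.columns
                                     if col.startswith("pc")]].astype(float)
            comps = pairwise_group_comparison(z, grp, covariates=cov)
            c["comparisons"] = comps
            for comp in comps:
                row = {"cohort": name, "contrast": comp.contrast,
                       "error": comp.error or ""}
                if comp.result is not None:
                    row.update(beta=comp.result.beta, se=comp.result.se,
                               p=comp.result.p, p_adjusted=comp.p_adjusted)
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "group_comparisons.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        return {"contrasts": len(rows)}

    def stage_meta():
        results = [c["assoc"] for c in cohorts.values()]
        ma = MetaAnalysis.from_results(results)
        fitted = {}
        models = ("fixed", "random") if config.meta_model == "both" \
            else (config.meta_model,)
        rows = []
        for m in models:
            r = ma.fit(m)
            fitted[m] = r
            rows.append(dataclasses.asdict(r.result))
            r.forest_table().to_csv(out / f"forest_{m}.tsv", sep="\t",
                                    index=False, float_format="%.6g")
        write_results_tsv(rows, str(out / "meta_results.tsv"))
        summary["meta"] = {m: {"pooled_beta": fitted[m].pooled_beta,
                               "p": fitted[m].p, "i2": fitted[m].i2}
                           for m in fitted}
        return {m: round(fitted[m].pooled_beta, 4) for m in fitted}

    def stage_ptdt():
        model = PTDT(trio_bundle["trios"], trio_bundle["prs"],
                     trio_bundle["samples"])
        results = model.fit_stratified()
        write_results_tsv([dataclasses.asdict(r) for r in results],
                          str(out / "ptdt_results.tsv"))
        summary["ptdt"] = {r.stratum: {"mean_deviation": r.mean_deviation,
                                       "p": r.p} for r in results}
        return {r.stratum: r.n_trios for r in results}

    def stage_screen():
        counts = {}
        for name, c in cohorts.items():
            all_samples = c["samples_all"]
            case_ids = all_samples.loc[all_samples["phenotype"] == "case", "id"]
            assignments, audit = assign_screen_status(case_ids, c["snvs"], c["cnvs"])
            audit.to_csv(out / f"{name}.screen_audit.tsv", sep="\t", index=False)
            assigned = pd.DataFrame(
                [{"case_id": a.case_id, "status": a.status,
                  "n_qualifying": len(a.qualifying)} for a in assignments])
            assigned.to_csv(out / f"{name}.screen.tsv", sep="\t", index=False)
            truth = c["truth"].set_index("case_id")["status"]
            got = assigned.set_index("case_id")["status"]
            common = truth.index.intersection(got.index)
            agree = float((truth.loc[common] == got.loc[common]).mean()) \
                if len(common) else float("nan")
            counts[name] = {"n_assigned": len(assigned),
                            "truth_agreement": agree}
        summary["screen"] = counts
        return counts

    for stage_name, fn in (
        ("simulate", stage_simulate), ("qc", stage_qc), ("score", stage_score),
        ("assoc", stage_assoc), ("compare_groups", stage_compare_groups),
        ("meta", stage_meta), ("ptdt", stage_ptdt), ("screen", stage_screen),
    ):
        logger.info("running stage %s", stage_name)
        run_stage(stage_name, fn)

    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=False)
    summary["provenance"] = provenance
    return summary


def replicate_study_pattern(config: PipelineConfig) -> pd.DataFrame:
    """Per-cohort and pooled case-control and three-group contrasts.

    Mirrors the layout of a multi-cohort forest figure: one case-control
    row per cohort plus the pooled fixed-effects row, and the pooled
    screen-stratified contrasts (both strata vs controls, and strata vs
    each other).
    """
    if config.n_cohorts < 2:
        raise ValueError("study-pattern replication needs >= 2 cohorts")
    res = run_pipeline(config)
    out = Path(config.out_dir)
    assoc = pd.read_csv(out / "assoc_results.tsv", sep="\t")
    rows = [
        {"analysis": "case_control", "cohort": r["cohort"], "beta": r["beta"],
         "se": r["se"], "p": r["p"]}
        for _, r in assoc.iterrows()
    ]
    meta = pd.read_csv(out / "meta_results.tsv", sep="\t")
    for _, r in meta.iterrows():
        rows.append({"analysis": "case_control", "cohort": f"pooled_{r['model']}",
                     "beta": r["pooled_beta"], "se": r["pooled_se"], "p": r["p"]})
    comps = pd.read_csv(out / "group_comparisons.tsv", sep="\t")
    ok = comps[comps.get("beta").notna()] if "beta" in comps.columns else comps.iloc[0:0]
    for contrast, sub in ok.groupby("contrast"):
        ma = MetaAnalysis(sub["beta"].to_numpy(), sub["se"].to_numpy(),
                          labels=list(sub["cohort"]))
        r = ma.fit("fixed")
        rows.append({"analysis": contrast, "cohort": "pooled_fixed",
                     "beta": r.pooled_beta, "se": r.pooled_se, "p": r.p})
    table = pd.DataFrame(rows)
    table.to_csv(out / "study_pattern.tsv", sep="\t", index=False,
                 float_format="%.6g")
    return table
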