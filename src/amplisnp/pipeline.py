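"""End-to-end orchestration: simulate -> genotype -> popgen -> association -> report.

The pipeline consumes either a directory of per-sample FASTQ files plus a
cohort table, a cohort table that already carries genotypes, or nothing at
all (fully synthetic run).  Each stage writes machine-readable TSVs under
the output directory; the six study-style tables are rendered last, and a
run manifest records versions, the config hash and per-stage record counts.
Per-sample genotyping failures are quarantined and reported, not fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association as assoc, popgen, report
from .design import DEFAULT_DESIGN, AmpliconDesign, design_from_dict, design_to_dict
from .genotyper import CallParams, calls_to_frame, genotype_sample, write_vcf
from .simulate import (
    CohortConfig,
    ReadSimConfig,
    read_cohort,
    simulate_amplicon_reads,
    simulate_cohort,
    write_cohort,
    write_fastq,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_pipeline_config"]


class ConfigError(ValueError):
    """Validation failure; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(errors))


@dataclass
class PipelineConfig:
    out_dir: str | Path = "amplisnp_run"
    fastq_dir: str | Path | None = None
    cohort_path: str | Path | None = None
    design: AmpliconDesign = DEFAULT_DESIGN
    call_params: CallParams = field(default_factory=CallParams)
    covariates: tuple[str, ...] = ("age", "bmi")
    alpha: float = 0.05
    bonferroni_k: int = 2
    simulate: bool = False
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)
    simulate_reads: bool = True
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        errors: list[str] = []
        if not self.simulate:
            if self.cohort_path is None:
                errors.append("cohort_path is required unless simulate=true")
            elif check_paths and not Path(self.cohort_path).exists():
                errors.append(f"cohort_path does not exist: {self.cohort_path}")
            if self.fastq_dir is not None and check_paths and not Path(self.fastq_dir).is_dir():
                errors.append(f"fastq_dir is not a directory: {self.fastq_dir}")
        if not 0 < self.alpha < 1:
            errors.append(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.bonferroni_k < 1:
            errors.append(f"bonferroni_k must be >= 1, got {self.bonferroni_k}")
        for name in self.covariates:
            if not isinstance(name, str) or not name:
                errors.append(f"bad covariate name: {name!r}")
        if errors:
            raise ConfigError(errors)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, np.generic)):
            return str(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_pipeline_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (see docs for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    kwargs: dict = {}
    simple = {
        "out_dir", "fastq_dir", "cohort_path", "alpha", "bonferroni_k",
        "simulate", "simulate_reads", "seed",
    }
    for key, value in raw.items():
        if key in simple:
            kwargs[key] = value
        elif key == "covariates":
            kwargs[key] = tuple(value)
        elif key == "design":
            try:
                kwargs[key] = design_from_dict(value)
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"design: {exc}")
        elif key == "call_params":
            try:
                kwargs[key] = CallParams(**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"call_params: {exc}")
        elif key == "cohort_config":
            try:
                kwargs[key] = CohortConfig(**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"cohort_config: {exc}")
        elif key == "read_sim":
            try:
                kwargs[key] = ReadSimConfig(**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"read_sim: {exc}")
        else:
            errors.append(f"unknown config key: {key}")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(**kwargs)


def _geno_code_columns(cohort: pd.DataFrame, design: AmpliconDesign) -> dict[str, np.ndarray]:
    return {
        snp.snp_id: popgen.geno_codes(cohort[f"genotype_{snp.snp_id}"], snp)
        for snp in design.snps
    }


def run_pipeline(config: PipelineConfig, log=print) -> Path:
    """Execute every stage and return the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    manifest: dict = {
        "tool": "amplisnp",
        "version": __version__,
        "config_hash": _config_hash(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    # --- stage 1: cohort ----------------------------------------------------
    if config.simulate:
        log(f"[simulate] cohort n_case={config.cohort_config.n_case} "
            f"n_control={config.cohort_config.n_control}")
        cohort = simulate_cohort(config.cohort_config, seed=int(rng.integers(2**31)), design=design)
        write_cohort(cohort, out / "cohort.tsv")
    else:
        cohort = read_cohort(config.cohort_path)
    manifest["stages"]["cohort"] = {"n_records": len(cohort)}

    # --- stage 2: reads + genotyping ---------------------------------------
    fastq_dir = Path(config.fastq_dir) if config.fastq_dir else None
    if config.simulate and config.simulate_reads:
        fastq_dir = out / "fastq"
        fastq_dir.mkdir(exist_ok=True)
        log(f"[simulate] reads depth={config.read_sim.depth} -> {fastq_dir}")
        for _, row in cohort.iterrows():
            genotype = tuple(
                tuple(str(row[f"genotype_{snp.snp_id}"]).split("/"))
                for snp in design.snps
            )
            reads = simulate_amplicon_reads(
                genotype, design, config.read_sim,
                seed=int(rng.integers(2**31)), sample_id=row["sample_id"],
            )
            write_fastq(reads, fastq_dir / f"{row['sample_id']}.fastq")

    quarantined: dict[str, str] = {}
    if fastq_dir is not None:
        log(f"[genotype] {fastq_dir}")
        calls_per_sample = {}
        qc_rows = []
        fastqs = sorted(
            p for p in fastq_dir.iterdir()
            if p.name.endswith((".fastq", ".fastq.gz", ".fq", ".fq.gz"))
        )
        for path in fastqs:
            sample_id = path.name.split(".")[0]
            try:
                calls, qc = genotype_sample(path, design, config.call_params)
            except (ValueError, OSError) as exc:
                quarantined[sample_id] = str(exc)
                continue
            calls_per_sample[sample_id] = calls
            qc_rows.append(
                {"sample_id": sample_id, "reads_in": qc.reads_in,
                 "reads_kept": qc.reads_kept, "reads_dropped": qc.reads_dropped,
                 **{f"assigned_{k}": v for k, v in qc.assigned.items()}}
            )
        geno_table = calls_to_frame(calls_per_sample, design)
        geno_table.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        pd.DataFrame(qc_rows).to_csv(out / "genotype_qc.tsv", sep="\t", index=False)
        write_vcf(calls_per_sample, design, out / "genotypes.vcf")
        manifest["stages"]["genotype"] = {
            "n_fastq": len(fastqs),
            "n_called": len(calls_per_sample),
            "n_quarantined": len(quarantined),
        }
        if quarantined:
            with open(out / "quarantine.tsv", "w") as fh:
                fh.write("sample_id\terror\n")
                for sid, msg in quarantined.items():
                    fh.write(f"{sid}\t{msg}\n")
        # merge called genotypes into the cohort (drop samples with no cohort row)
        geno_cols = ["sample_id"] + [f"genotype_{s.snp_id}" for s in design.snps]
        cohort = cohort.drop(
            columns=[c for c in cohort.columns if c.startswith("genotype_")],
            errors="ignore",
        ).merge(geno_table[geno_cols], on="sample_id", how="inner")
    missing_cols = [
        f"genotype_{s.snp_id}" for s in design.snps
        if f"genotype_{s.snp_id}" not in cohort.columns
    ]
    if missing_cols:
        raise ConfigError(
            [f"cohort lacks genotype column {c} and no FASTQ input was given"
             for c in missing_cols]
        )
    cohort.to_csv(out / "analysis_cohort.tsv", sep="\t", index=False)

    if len(cohort) == 0:
        log("[warn] empty cohort: writing headers only")
        for name in ("table1_cohort", "table2_frequencies"):
            (out / f"{name}.tsv").write_text("")
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out

    # --- stage 3: population genetics ---------------------------------------
    log("[popgen] frequencies, HWE, EM haplotypes, LD")
    codes = _geno_code_columns(cohort, design)
    is_case = (cohort["status"] == "case").to_numpy()
    groups = np.where(is_case, "case", "control")
    freq_frames = []
    hwe_rows = []
    for snp in design.snps:
        tab = popgen.genotype_counts(codes[snp.snp_id], groups)
        tab.insert(0, "snp", snp.snp_id)
        freq_frames.append(tab)
        for _, row in tab.iterrows():
            if row["n"] == 0:
                continue
            hwe = popgen.hwe_chisq(row["n_hom_ref"], row["n_het"], row["n_hom_alt"])
            hwe_rows.append(
                {"snp": snp.snp_id, "group": row["group"], "chi2": round(hwe.chi2, 4),
                 "p": round(hwe.p, 4), "monomorphic": hwe.monomorphic}
            )
    pd.concat(freq_frames).to_csv(out / "genotype_counts.tsv", sep="\t", index=False)
    pd.DataFrame(hwe_rows).to_csv(out / "hwe.tsv", sep="\t", index=False)

    g1 = codes[design.snps[0].snp_id]
    g2 = codes[design.snps[1].snp_id]
    labels = popgen.haplotype_labels(design.snps[0], design.snps[1])
    est_total = popgen.em_haplotype_freqs(g1, g2)
    est_case = popgen.em_haplotype_freqs(g1[is_case], g2[is_case])
    est_control = popgen.em_haplotype_freqs(g1[~is_case], g2[~is_case])
    ld = popgen.ld_stats(est_total)
    with open(out / "ld.tsv", "w") as fh:
        fh.write("D\tDmax\tDprime\tdefined\n")
        fh.write(f"{ld.D:.6f}\t{ld.Dmax:.6f}\t{ld.Dprime:.6f}\t{ld.defined}\n")
    manifest["stages"]["popgen"] = {
        "n_complete_pairs": est_total.n_used,
        "em_converged": est_total.converged,
        "dprime": round(ld.Dprime, 4) if ld.defined else None,
    }

    # --- stage 4: association ----------------------------------------------
    log("[assoc] five genetic models, haplotype association, traits")
    cov = cohort[list(config.covariates)].astype(float)
    y = is_case.astype(float)
    results_per_snp = {}
    assoc_rows = []
    for snp in design.snps:
        res = assoc.assoc_genetic_models(codes[snp.snp_id], y, cov)
        results_per_snp[snp.snp_id] = res
        for model, r in res.items():
            for term, or_, lo, hi in r.levels:
                assoc_rows.append(
                    {"snp": snp.snp_id, "model": model, "term": term,
                     "OR": round(or_, 4), "ci_low": round(lo, 4),
                     "ci_high": round(hi, 4), "lrt_p": round(r.lrt_p, 6),
                     "df": r.df, "n": r.n}
                )
    pd.DataFrame(assoc_rows).to_csv(out / "association.tsv", sep="\t", index=False)

    dosages = pd.DataFrame(
        popgen.haplotype_dosages(g1, g2, est_total.freqs), columns=list(labels)
    )
    # rare haplotypes can perfectly separate small cohorts; escalate the
    # pooling floor before giving up on the haplotype model
    hap_res = None
    for floor in (0.01, 0.05, 0.10):
        try:
            hap_res = assoc.haplotype_assoc(dosages, y, cov, freq_floor=floor)
            break
        except (assoc.SeparationError, ValueError) as exc:
            log(f"[assoc] haplotype model at floor {floor} not estimable: {exc}")

    trait_cols = [
        c for c in ("SBP", "DBP", "FBS", "HbA1c", "TC", "TG", "HDL", "LDL")
        if c in cohort.columns
    ]
    anova_rows = []
    case_df = cohort[is_case]
    for snp in design.snps:
        sub_codes = popgen.geno_codes(case_df[f"genotype_{snp.snp_id}"], snp)
        for name in trait_cols:
            norm = assoc.orq_normalize(case_df[name].to_numpy(float))
            try:
                f_stat, p = assoc.anova_by_genotype(norm, sub_codes)
            except ValueError:
                f_stat, p = np.nan, np.nan
            anova_rows.append(
                {"snp": snp.snp_id, "trait": name, "F": round(f_stat, 4),
                 "p": round(p, 4)}
            )
    pd.DataFrame(anova_rows).to_csv(out / "trait_anova.tsv", sep="\t", index=False)
    manifest["stages"]["association"] = {
        "n_models": len(assoc_rows),
        "haplotype_global_p": round(hap_res.global_p, 4) if hap_res else None,
        "bonferroni_threshold": assoc.bonferroni_threshold(config.alpha, config.bonferroni_k),
    }

    # --- stage 5: report -----------------------------------------------------
    log("[report] rendering tables")
    tables = {
        "table1_cohort": report.cohort_table(cohort),
        "table2_frequencies": report.frequency_table(cohort, design),
        "table3_genetic_models": report.genetic_model_table(results_per_snp, design),
        "table4_traits_by_genotype": report.trait_by_genotype_table(cohort, design),
        "table5_haplotypes": report.haplotype_table(
            est_case, est_control, est_total, hap_res, labels
        ),
    }
    if "CVD" in cohort.columns and cohort.loc[is_case, "CVD"].astype(bool).sum() >= 3:
        tables["table6_cvd"] = report.complication_table(
            cohort, design, "CVD", config.covariates
        )
    text_parts = []
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        text_parts.append(report.render_text(table, name))
    (out / "report.txt").write_text("\n".join(text_parts))
    manifest["stages"]["report"] = {"n_tables": len(tables)}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log(f"[done] {out}")
    return out
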