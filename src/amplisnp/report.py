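"""Presentation layer: render analysis results as the six study-style tables.

Every number in a rendered table is re-derivable from the machine-readable
results it is built from; this module only formats ("n (%)", "OR [lo-hi]",
mean (SE)) and never computes new statistics beyond calling back into the
analysis modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association as assoc
from . import popgen
from .design import AmpliconDesign

__all__ = [
    "cohort_table",
    "frequency_table",
    "genetic_model_table",
    "trait_by_genotype_table",
    "haplotype_table",
    "complication_table",
    "render_text",
]

TRAIT_ROWS = ("age", "bmi", "SBP", "DBP", "FBS", "HbA1c", "TC", "TG", "HDL", "LDL")


def _mean_se(x: np.ndarray) -> str:
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return "NA"
    se = np.std(x, ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
    return f"{np.mean(x):.1f} ({se:.2f})"


def _fmt_p(p: float) -> str:
    if np.isnan(p):
        return "NA"
    return f"{p:.4f}" if p >= 0.0001 else "<0.0001"


def _fmt_or(or_, lo, hi) -> str:
    return f"{or_:.2f} [{lo:.2f}-{hi:.2f}]"


def cohort_table(cohort: pd.DataFrame, traits=TRAIT_ROWS) -> pd.DataFrame:
    """Demographic/biochemical characteristics by arm with Welch t P-values."""
    is_case = (cohort["status"] == "case").to_numpy()
    rows = []
    for name in traits:
        if name not in cohort.columns:
            continue
        x = cohort[name].to_numpy(float)
        a, b = x[~is_case], x[is_case]
        try:
            _, p = assoc.welch_t(a, b)
        except ValueError:
            p = np.nan
        rows.append(
            {
                "parameter": name,
                f"control (n={int((~is_case).sum())})": _mean_se(a),
                f"T2DM (n={int(is_case.sum())})": _mean_se(b),
                "P": _fmt_p(p),
            }
        )
    return pd.DataFrame(rows)


def frequency_table(
    cohort: pd.DataFrame, design: AmpliconDesign
) -> pd.DataFrame:
    """Allele and genotype counts (%) per arm with per-row 2x2 chi-square P.

    Allele rows compare case vs control allele counts; genotype rows compare
    the genotype against all others, case vs control.  Allele totals are
    derived from genotype counts.
    """
    is_case = (cohort["status"] == "case").to_numpy()
    groups = np.where(is_case, "case", "control")
    rows = []
    for snp in design.snps:
        codes = popgen.geno_codes(cohort[f"genotype_{snp.snp_id}"], snp)
        tab = popgen.genotype_counts(codes, groups).set_index("group")
        al, co, ca = tab.loc["all"], tab.loc["control"], tab.loc["case"]

        def pct(x, tot):
            return f"{int(x)} ({100 * x / tot:.0f})" if tot else "0"

        # allele rows
        for allele, col in ((snp.allele_ref, "count_ref"), (snp.allele_alt, "count_alt")):
            other = "count_alt" if col == "count_ref" else "count_ref"
            chi = assoc.pearson_chi2_2x2(ca[col], ca[other], co[col], co[other])
            rows.append(
                {
                    "snp": snp.snp_id,
                    "row": allele,
                    "all": pct(al[col], al[col] + al[other]),
                    "control": pct(co[col], co[col] + co[other]),
                    "case": pct(ca[col], ca[col] + ca[other]),
                    "P": _fmt_p(chi.p),
                }
            )
        # genotype rows
        geno_labels = (
            (f"{snp.allele_ref}{snp.allele_ref}", "n_hom_ref"),
            (f"{snp.allele_ref}{snp.allele_alt}", "n_het"),
            (f"{snp.allele_alt}{snp.allele_alt}", "n_hom_alt"),
        )
        for label, col in geno_labels:
            chi = assoc.pearson_chi2_2x2(
                ca[col], ca["n"] - ca[col], co[col], co["n"] - co[col]
            )
            rows.append(
                {
                    "snp": snp.snp_id,
                    "row": label,
                    "all": pct(al[col], al["n"]),
                    "control": pct(co[col], co["n"]),
                    "case": pct(ca[col], ca["n"]),
                    "P": _fmt_p(chi.p),
                }
            )
    return pd.DataFrame(rows)


_LEVEL_LABELS = {
    "codominant": {"het": "{r}/{a}", "hom_alt": "{a}/{a}"},
    "dominant": {"carrier": "{r}/{a}-{a}/{a}"},
    "recessive": {"hom_alt": "{a}/{a}"},
    "overdominant": {"het": "{r}/{a}"},
    "log-additive": {"alt_count": "-"},
}

_REF_LABELS = {
    "codominant": "{r}/{r}",
    "dominant": "{r}/{r}",
    "recessive": "{r}/{r}-{r}/{a}",
    "overdominant": "{r}/{r}-{a}/{a}",
    "log-additive": "",
}


def genetic_model_table(
    results_per_snp: dict[str, dict[str, assoc.AssocModelResult]],
    design: AmpliconDesign,
) -> pd.DataFrame:
    """Five-genetic-model OR table (one block per SNP, reference rows OR=1)."""
    rows = []
    snps = {s.snp_id: s for s in design.snps}
    for snp_id, per_model in results_per_snp.items():
        snp = snps[snp_id]
        fmt = {"r": snp.allele_ref, "a": snp.allele_alt}
        for model, res in per_model.items():
            ref_label = _REF_LABELS[model].format(**fmt)
            if ref_label:
                rows.append(
                    {
                        "snp": snp_id,
                        "model": model,
                        "genotype": ref_label,
                        "OR (95% CI)": "1",
                        "P": _fmt_p(res.lrt_p),
                    }
                )
            for term, or_, lo, hi in res.levels:
                rows.append(
                    {
                        "snp": snp_id,
                        "model": model,
                        "genotype": _LEVEL_LABELS[model][term].format(**fmt),
                        "OR (95% CI)": _fmt_or(or_, lo, hi),
                        "P": _fmt_p(res.lrt_p) if not ref_label else "",
                    }
                )
    return pd.DataFrame(rows)


def trait_by_genotype_table(
    cohort: pd.DataFrame,
    design: AmpliconDesign,
    traits=("bmi", "SBP", "DBP", "FBS", "HbA1c", "TC", "TG", "LDL", "HDL"),
    status: str = "case",
) -> pd.DataFrame:
    """Trait mean (SE) per genotype with one-way ANOVA P, per SNP.

    Restricted to one arm (cases by default, as in the study's stratified
    analysis).
    """
    sub = cohort[cohort["status"] == status] if status else cohort
    rows = []
    for name in traits:
        if name not in sub.columns:
            continue
        row: dict[str, str] = {"parameter": name}
        for snp in design.snps:
            codes = popgen.geno_codes(sub[f"genotype_{snp.snp_id}"], snp)
            x = sub[name].to_numpy(float)
            for code, glabel in (
                (2, f"{snp.allele_alt}{snp.allele_alt}"),
                (1, f"{snp.allele_ref}{snp.allele_alt}"),
                (0, f"{snp.allele_ref}{snp.allele_ref}"),
            ):
                row[f"{snp.snp_id}:{glabel}"] = _mean_se(x[codes == code])
            try:
                _, p = assoc.anova_by_genotype(x, codes)
            except ValueError:
                p = np.nan
            row[f"{snp.snp_id}:P"] = _fmt_p(p)
        rows.append(row)
    return pd.DataFrame(rows)


def haplotype_table(
    est_case: popgen.HaplotypeEstimate,
    est_control: popgen.HaplotypeEstimate,
    est_total: popgen.HaplotypeEstimate,
    hap_result: assoc.HapAssocResult | None,
    labels: tuple[str, ...],
) -> pd.DataFrame:
    """Haplotype frequency/association table (most frequent = reference).

    ``hap_result`` may be None when the haplotype model was not estimable
    (e.g. separation in a tiny cohort); frequencies are still reported.
    """
    per_level = (
        {lab: (or_, lo, hi) for lab, or_, lo, hi in hap_result.levels}
        if hap_result
        else {}
    )
    rows = []
    order = np.argsort(-est_total.freqs.as_array())
    for k in order:
        lab = labels[k]
        if hap_result is None:
            or_str = "NA"
        elif lab == hap_result.reference:
            or_str = "1"
        elif lab in per_level:
            or_str = _fmt_or(*per_level[lab])
        else:
            or_str = "pooled (rare)" if lab in hap_result.pooled_rare else "NA"
        rows.append(
            {
                "haplotype": lab,
                "freq_case": round(est_case.freqs.as_array()[k], 4),
                "freq_control": round(est_control.freqs.as_array()[k], 4),
                "freq_total": round(est_total.freqs.as_array()[k], 4),
                "OR (95% CI)": or_str,
                "global_P": (
                    _fmt_p(hap_result.global_p)
                    if hap_result and lab == hap_result.reference
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def complication_table(
    cohort: pd.DataFrame,
    design: AmpliconDesign,
    complication: str = "CVD",
    covariates=("age", "bmi"),
    models=("dominant", "recessive", "overdominant"),
) -> pd.DataFrame:
    """Genotype association with a complication among cases (adjusted ORs)."""
    cases = cohort[cohort["status"] == "case"].reset_index(drop=True)
    y = cases[complication].astype(float).to_numpy()
    cov = cases[list(covariates)]
    rows = []
    for snp in design.snps:
        codes = popgen.geno_codes(cases[f"genotype_{snp.snp_id}"], snp)
        try:
            results = assoc.assoc_genetic_models(codes, y, cov, models=models)
        except (assoc.SeparationError, ValueError) as exc:
            rows.append(
                {"snp": snp.snp_id, "model": "-", "genotype": "-",
                 "OR (95% CI)": "NA", "P": f"not estimable: {exc}"}
            )
            continue
        table = genetic_model_table({snp.snp_id: results}, design)
        rows.extend(table.to_dict("records"))
    return pd.DataFrame(rows)


def render_text(table: pd.DataFrame, title: str = "") -> str:
    body = table.to_string(index=False)
    if title:
        rule = "=" * max(len(title), 8)
        return f"{title}\n{rule}\n{body}\n"
    return body + "\n"
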