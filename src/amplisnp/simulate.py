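"""Synthetic cohorts and amplicon reads.

The generator emulates the statistical structure the downstream analysis
assumes: two biallelic SNPs in strong LD with a four-haplotype structure,
Hardy-Weinberg genotypes (random union of two independent haplotype draws),
a logistic disease model with age/BMI covariates and a genotype effect, and
Gaussian genotype/status-conditional quantitative traits with LDL derived
from the Friedewald formula rather than drawn independently.

Defaults correspond to a case-control study of 102 diabetic and 112 control
women typed at the ESR1 PvuII (rs2234693, T/C) and XbaI (rs9340799, A/G)
variants: haplotype frequencies (TA, TG, CA, CG) = (0.5485, 0.0216, 0.0286,
0.4013), an overdominant heterozygote effect of log(2.32) at PvuII, and
trait means/SDs taken from the study cohort's published summary statistics.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import DEFAULT_DESIGN, AmpliconDesign

__all__ = [
    "HaplotypeFreqs",
    "TraitSpec",
    "CohortConfig",
    "ReadSimConfig",
    "DEFAULT_HAP_FREQS",
    "DEFAULT_TRAITS",
    "friedewald_ldl",
    "simulate_genotypes",
    "assign_case_status",
    "simulate_traits",
    "simulate_cohort",
    "simulate_amplicon_reads",
    "write_cohort",
    "read_cohort",
    "write_fastq",
    "read_fastq",
]

GENO_CODINGS = ("dominant", "recessive", "overdominant", "additive")

COMPLICATIONS = ("CVD", "nephropathy", "retinopathy", "diabetic_foot")


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Population frequencies of the four two-locus haplotypes.

    ``f_11`` is the haplotype carrying the reference allele at both SNPs
    (TA in the ESR1 labelling), ``f_12`` ref/alt (TG), ``f_21`` alt/ref
    (CA), ``f_22`` alt/alt (CG).
    """

    f_11: float
    f_12: float
    f_21: float
    f_22: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("haplotype frequencies must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"haplotype frequencies sum to {arr.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_11, self.f_12, self.f_21, self.f_22], float)

    @property
    def p_ref_snp1(self) -> float:
        return self.f_11 + self.f_12

    @property
    def p_ref_snp2(self) -> float:
        return self.f_11 + self.f_21


# Study-scale haplotype structure: (TA, TG, CA, CG), D' about 0.91.
DEFAULT_HAP_FREQS = HaplotypeFreqs(0.5485, 0.0216, 0.0286, 0.4013)


@dataclass(frozen=True)
class TraitSpec:
    """Gaussian trait model: status-conditional mean/sd plus optional
    additive per-genotype shifts (keyed by alt-allele count at the effect
    SNP)."""

    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    geno_delta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.control_sd < 0 or self.case_sd < 0:
            raise ValueError("trait sd must be >= 0")


def _study_traits() -> dict[str, TraitSpec]:
    # Means from the study's cohort table (control, case); SD = SE * sqrt(n)
    # with n=112 controls / n=102 cases.  Control TG/HDL are not published;
    # values chosen as typical for an adult female clinic population.
    return {
        "SBP": TraitSpec(122.0, 9.8, 136.2, 16.2),
        "DBP": TraitSpec(77.9, 9.0, 78.9, 10.3),
        "FBS": TraitSpec(90.1, 10.3, 161.8, 49.5),
        "HbA1c": TraitSpec(5.3, 0.4, 7.9, 2.6),
        "TC": TraitSpec(182.0, 36.0, 192.0, 40.6),
        "TG": TraitSpec(150.0, 55.0, 190.0, 80.0),
        "HDL": TraitSpec(45.0, 10.0, 41.6, 12.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic case-control cohort."""

    n_case: int = 102
    n_control: int = 112
    hap_freqs: HaplotypeFreqs = DEFAULT_HAP_FREQS
    # Disease model: logit P(case) = beta0 + beta_geno*g + beta_age*age + beta_bmi*bmi
    beta0: float = -7.0
    beta_geno: float = float(np.log(2.32))
    beta_age: float = 0.10
    beta_bmi: float = 0.05
    geno_coding: str = "overdominant"
    effect_snp: int = 0
    # Population age/BMI distribution the screening samples from.
    age_mean: float = 53.0
    age_sd: float = 8.0
    bmi_mean: float = 33.0
    bmi_sd: float = 5.0
    traits: dict[str, TraitSpec] = field(default_factory=_study_traits)
    complication_rates: dict[str, float] = field(
        default_factory=lambda: {
            "CVD": 0.108,
            "nephropathy": 0.088,
            "retinopathy": 0.059,
            "diabetic_foot": 0.078,
        }
    )
    # Control-group screening: fasting glucose below the diabetic cutoff;
    # the BMI floor is off by default.
    control_max_fbs: float = 126.0
    control_min_bmi: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.geno_coding not in GENO_CODINGS:
            raise ValueError(f"unknown genotype coding {self.geno_coding!r}")
        if self.age_sd <= 0 or self.bmi_sd <= 0:
            raise ValueError("age/BMI sd must be > 0")


@dataclass(frozen=True)
class ReadSimConfig:
    """Amplicon read simulator settings (single-end, substitution errors)."""

    depth: int = 20_000
    read_length: int = 150
    per_base_error: float = 0.005
    q_mean: float = 30.0
    q_sd: float = 5.0
    adapter_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_error < 0.5:
            raise ValueError("per_base_error must lie in [0, 0.5)")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.adapter_rate <= 1:
            raise ValueError("adapter_rate must lie in [0, 1]")


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL cholesterol (mg/dl) from total cholesterol, HDL and triglycerides.

    Valid only for TG < 400 mg/dl; higher values raise ``ValueError``.
    """
    if tg >= 400:
        raise ValueError(f"Friedewald formula invalid for TG >= 400 (got {tg})")
    return tc - hdl - tg / 5.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# Haplotype index -> (alt count at SNP1, alt count at SNP2)
_HAP_ALT = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])


def simulate_genotypes(
    hap_freqs: HaplotypeFreqs, n: int, seed=0
) -> np.ndarray:
    """Draw ``n`` unphased two-locus genotypes under random haplotype union.

    Each individual is the union of two independent haplotype draws (HWE at
    the haplotype level); phase is discarded.  Returns an ``(n, 2)`` integer
    array of alt-allele counts (0/1/2) per SNP.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    haps = rng.choice(4, size=(n, 2), p=hap_freqs.as_array())
    return _HAP_ALT[haps[:, 0]] + _HAP_ALT[haps[:, 1]]


def encode_geno_effect(g: np.ndarray, coding: str) -> np.ndarray:
    """Scalar risk coding of an alt-allele count vector."""
    g = np.asarray(g)
    if coding == "dominant":
        return (g >= 1).astype(float)
    if coding == "recessive":
        return (g == 2).astype(float)
    if coding == "overdominant":
        return (g == 1).astype(float)
    if coding == "additive":
        return g.astype(float)
    raise ValueError(f"unknown genotype coding {coding!r}")


def assign_case_status(
    genotypes: np.ndarray,
    age: np.ndarray,
    bmi: np.ndarray,
    config: CohortConfig,
    seed=0,
) -> np.ndarray:
    """Bernoulli case status from the logistic disease model.

    ``genotypes`` is the (n, 2) alt-count array; the effect enters through
    ``config.geno_coding`` applied to ``config.effect_snp``.
    Returns a boolean array (True = case).
    """
    rng = _as_rng(seed)
    g = encode_geno_effect(np.asarray(genotypes)[:, config.effect_snp], config.geno_coding)
    logit = (
        config.beta0
        + config.beta_geno * g
        + config.beta_age * np.asarray(age)
        + config.beta_bmi * np.asarray(bmi)
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    return rng.random(len(p)) < p


def simulate_traits(
    status: np.ndarray,
    genotypes: np.ndarray,
    config: CohortConfig,
    seed=0,
) -> pd.DataFrame:
    """Gaussian traits conditional on status and genotype; LDL by Friedewald.

    TG draws are clipped below 400 mg/dl so the Friedewald formula stays in
    its validity range.
    """
    rng = _as_rng(seed)
    status = np.asarray(status, bool)
    g_eff = np.asarray(genotypes)[:, config.effect_snp]
    n = len(status)
    cols = {}
    for name, spec in config.traits.items():
        mean = np.where(status, spec.case_mean, spec.control_mean)
        sd = np.where(status, spec.case_sd, spec.control_sd)
        delta = np.asarray(spec.geno_delta, float)[g_eff]
        cols[name] = mean + delta + sd * rng.standard_normal(n)
    for required in ("TC", "HDL", "TG"):
        if required not in cols:
            raise ValueError(f"trait parameters for {required} are required for LDL")
    cols["TG"] = np.clip(cols["TG"], 10.0, 399.0)
    cols["LDL"] = cols["TC"] - cols["HDL"] - cols["TG"] / 5.0
    return pd.DataFrame(cols)


def _geno_string(snp, alt_count: int) -> str:
    a = [snp.allele_ref, snp.allele_alt]
    pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(alt_count)]
    return f"{a[pair[0]]}/{a[pair[1]]}"


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    design: AmpliconDesign = DEFAULT_DESIGN,
) -> pd.DataFrame:
    """Simulate a full case-control cohort table.

    Individuals are drawn from the population model (haplotype genotypes,
    Gaussian age/BMI, logistic case status) and accrued until the configured
    case and control quotas are filled; controls additionally pass the
    fasting-glucose screen (and optional BMI floor).  Returns one row per
    subject with genotypes as allele-pair strings, traits in their stated
    units, and boolean complication flags (cases only).
    """
    config = config or CohortConfig()
    rng = _as_rng(config.seed if seed is None else seed)
    cases: list[pd.DataFrame] = []
    controls: list[pd.DataFrame] = []
    n_case_have = n_ctrl_have = 0
    batch = max(4 * (config.n_case + config.n_control), 256)
    rounds = 0
    while n_case_have < config.n_case or n_ctrl_have < config.n_control:
        rounds += 1
        if rounds > 1000:
            raise RuntimeError(
                "case/control accrual did not fill quotas; disease model "
                "prevalence is too extreme for the requested arm sizes"
            )
        geno = simulate_genotypes(config.hap_freqs, batch, rng)
        age = config.age_mean + config.age_sd * rng.standard_normal(batch)
        age = np.clip(age, 40.0, None)  # study enrolled women aged > 40
        bmi = config.bmi_mean + config.bmi_sd * rng.standard_normal(batch)
        bmi = np.clip(bmi, 15.0, None)
        status = assign_case_status(geno, age, bmi, config, rng)
        traits = simulate_traits(status, geno, config, rng)
        df = pd.DataFrame(
            {
                "status": np.where(status, "case", "control"),
                "age": np.round(age, 1),
                "bmi": np.round(bmi, 1),
            }
        )
        for j, snp in enumerate(design.snps):
            df[f"genotype_{snp.snp_id}"] = [
                _geno_string(snp, g) for g in geno[:, j]
            ]
        traits = traits.round(1)
        # keep the Friedewald identity exact on the stored (rounded) columns
        traits["LDL"] = traits["TC"] - traits["HDL"] - traits["TG"] / 5.0
        df = pd.concat([df, traits], axis=1)
        for comp in COMPLICATIONS:
            rate = config.complication_rates.get(comp, 0.0)
            df[comp] = status & (rng.random(batch) < rate)
        keep_ctrl = ~status & (traits["FBS"].to_numpy() < config.control_max_fbs)
        if config.control_min_bmi is not None:
            keep_ctrl &= bmi > config.control_min_bmi
        cases.append(df[status])
        controls.append(df[keep_ctrl])
        n_case_have += int(status.sum())
        n_ctrl_have += int(keep_ctrl.sum())
    out = pd.concat(
        [
            pd.concat(cases, ignore_index=True).head(config.n_case),
            pd.concat(controls, ignore_index=True).head(config.n_control),
        ],
        ignore_index=True,
    )
    out.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(len(out))])
    return out


_BASE_TO_CODE = np.full(256, -1, np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", np.uint8)


def _mutate_and_render(
    template: str, n: int, cfg: ReadSimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Render n reads from one template with substitution errors + qualities."""
    tpl = np.frombuffer(template.encode(), np.uint8)
    L = len(tpl)
    mat = np.tile(tpl, (n, 1))
    codes = _BASE_TO_CODE[mat]
    err = (rng.random((n, L)) < cfg.per_base_error) & (codes >= 0)
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()))
        codes_err = (codes[err] + shift) % 4
        mat[err] = _CODE_TO_BASE[codes_err]
    quals = np.clip(
        np.rint(cfg.q_mean + cfg.q_sd * rng.standard_normal((n, L))), 2, 40
    ).astype(np.uint8) + 33
    seqs = [row.tobytes().decode() for row in mat]
    qstrs = [row.tobytes().decode() for row in quals]
    return seqs, qstrs


def simulate_amplicon_reads(
    genotype,
    design: AmpliconDesign = DEFAULT_DESIGN,
    cfg: ReadSimConfig | None = None,
    seed=None,
    sample_id: str = "sample",
) -> list[tuple[str, str, str]]:
    """Simulate single-end amplicon reads for one diploid sample.

    ``genotype`` is either the (alt1, alt2) count pair or a per-SNP tuple of
    allele pairs, e.g. ``(("T","C"), ("A","A"))``.  Heterozygous sites are
    arranged onto two template haplotypes (cis arbitrary; per-SNP allele
    ratios are unaffected by phase) and each read picks a template with a
    fair coin flip.  A configurable fraction of reads runs through into the
    3' adapter.  Returns ``(read_id, seq, qual_string)`` tuples, Phred+33.
    """
    cfg = cfg or ReadSimConfig()
    rng = _as_rng(cfg.seed if seed is None else seed)
    pairs = []
    for j, snp in enumerate(design.snps):
        g = genotype[j]
        if isinstance(g, (int, np.integer)):
            pair = {
                0: (snp.allele_ref, snp.allele_ref),
                1: (snp.allele_ref, snp.allele_alt),
                2: (snp.allele_alt, snp.allele_alt),
            }[int(g)]
        else:
            pair = tuple(g)
        pairs.append(pair)
    hap_a = design.haplotype_seq(tuple(p[0] for p in pairs))
    hap_b = design.haplotype_seq(tuple(p[1] for p in pairs))
    max_probe_end = max(
        snp.offset + len(snp.probe_ref) for snp in design.snps
    )
    if cfg.read_length < max_probe_end:
        raise ValueError(
            f"read_length {cfg.read_length} shorter than probe span "
            f"{max_probe_end}"
        )
    if cfg.depth == 0:
        return []
    which_hap = rng.random(cfg.depth) < 0.5
    with_adapter = rng.random(cfg.depth) < cfg.adapter_rate
    reads: list[tuple[str, str, str] | None] = [None] * cfg.depth
    idx = np.arange(cfg.depth)
    for hap_flag, hap in ((False, hap_a), (True, hap_b)):
        for ad_flag in (False, True):
            sel = idx[(which_hap == hap_flag) & (with_adapter == ad_flag)]
            if len(sel) == 0:
                continue
            template = (hap + design.adapter) if ad_flag else hap
            template = template[: cfg.read_length]
            seqs, quals = _mutate_and_render(template, len(sel), cfg, rng)
            for k, i in enumerate(sel):
                reads[i] = (f"{sample_id}_read{i + 1}", seqs[k], quals[k])
    return reads  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# I/O

COHORT_DTYPES = {"age": float, "bmi": float}


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort table as TSV (lossless round trip via read_cohort)."""
    records.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for comp in COMPLICATIONS:
        if comp in df.columns:
            df[comp] = df[comp].astype(bool)
    return df


def _open_maybe_gzip(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads, path) -> None:
    """Write (read_id, seq, qual_string) records as FASTQ (gzip by suffix)."""
    with _open_maybe_gzip(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    with _open_maybe_gzip(path, "r") as fh:
        return [(rid.split()[0], seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]
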