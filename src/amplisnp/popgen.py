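"""Population-genetic statistics on called genotypes.

Genotypes are coded as alt-allele counts (0/1/2), with -1 for missing.
The two-locus haplotype frequencies are estimated by the classic EM for
unphased diploid data: only double heterozygotes are phase-ambiguous, the
E-step splits them between the cis and trans configurations in proportion
to the current frequency products, and the M-step renormalises expected
haplotype counts over the 2n chromosomes.  Linkage disequilibrium is
summarised by Lewontin's D' = |D| / Dmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SnpDef
from .simulate import HaplotypeFreqs

__all__ = [
    "HweResult",
    "HaplotypeEstimate",
    "LDResult",
    "HAPLOTYPE_ORDER",
    "geno_codes",
    "genotype_counts",
    "hwe_chisq",
    "em_haplotype_freqs",
    "ld_stats",
    "haplotype_dosages",
    "haplotype_labels",
]

MISSING = -1

# (alt count at SNP1, alt count at SNP2) per haplotype index; index order
# matches HaplotypeFreqs fields (ref-ref, ref-alt, alt-ref, alt-alt).
HAPLOTYPE_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


def haplotype_labels(snp1: SnpDef, snp2: SnpDef) -> tuple[str, ...]:
    """Allele-pair labels for the four haplotypes, e.g. ('TA','TG','CA','CG')."""
    a1 = (snp1.allele_ref, snp1.allele_alt)
    a2 = (snp2.allele_ref, snp2.allele_alt)
    return tuple(a1[i] + a2[j] for i, j in HAPLOTYPE_ORDER)


def geno_codes(values, snp: SnpDef) -> np.ndarray:
    """Convert allele-pair strings ('T/C', './.') to alt-count codes."""
    lut = {
        f"{snp.allele_ref}/{snp.allele_ref}": 0,
        f"{snp.allele_ref}/{snp.allele_alt}": 1,
        f"{snp.allele_alt}/{snp.allele_ref}": 1,
        f"{snp.allele_alt}/{snp.allele_alt}": 2,
        "./.": MISSING,
    }
    out = np.empty(len(values), int)
    for i, v in enumerate(values):
        if isinstance(v, (int, np.integer)):
            out[i] = int(v)
            continue
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = MISSING
            continue
        try:
            out[i] = lut[str(v)]
        except KeyError:
            raise ValueError(
                f"sample index {i}: genotype {v!r} uses alleles outside the "
                f"design for {snp.snp_id}"
            ) from None
    return out


def genotype_counts(codes, groups=None) -> pd.DataFrame:
    """Genotype and allele counts/frequencies, overall and per group.

    ``codes`` is an alt-count vector for one SNP (-1 = missing); ``groups``
    an optional label vector (e.g. case/control).  Allele counts are derived
    from genotypes (ref = 2*hom_ref + het); missing genotypes are excluded
    and reported per group.
    """
    codes = np.asarray(codes)
    groups = np.asarray(["all"] * len(codes)) if groups is None else np.asarray(groups)
    rows = []
    group_names = ["all"] + [g for g in pd.unique(groups) if g != "all"]
    for name in group_names:
        sel = codes if name == "all" else codes[groups == name]
        n_missing = int((sel == MISSING).sum())
        sel = sel[sel != MISSING]
        n = len(sel)
        n_hom_ref = int((sel == 0).sum())
        n_het = int((sel == 1).sum())
        n_hom_alt = int((sel == 2).sum())
        count_ref = 2 * n_hom_ref + n_het
        count_alt = 2 * n_hom_alt + n_het
        total = count_ref + count_alt
        rows.append(
            {
                "group": name,
                "n": n,
                "n_missing": n_missing,
                "n_hom_ref": n_hom_ref,
                "n_het": n_het,
                "n_hom_alt": n_hom_alt,
                "count_ref": count_ref,
                "count_alt": count_alt,
                "freq_ref": count_ref / total if total else np.nan,
                "freq_alt": count_alt / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p: float
    expected: tuple[float, float, float]
    monomorphic: bool = False


def hwe_chisq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    The allele frequency is estimated from the sample, expected counts are
    (n*p^2, 2*n*p*q, n*q^2), and the statistic compares observed genotype
    counts to them.  A monomorphic sample returns chi2=0, p=1 with a
    warning.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic SNP: HWE test degenerate", stacklevel=2)
        return HweResult(0.0, 1, 1.0, expected, monomorphic=True)
    observed = (n_hom_ref, n_het, n_hom_alt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(float(chi2), 1, float(stats.chi2.sf(chi2, 1)), expected)


@dataclass(frozen=True)
class HaplotypeEstimate:
    freqs: HaplotypeFreqs
    loglik: float
    n_iter: int
    converged: bool
    n_used: int
    loglik_trace: tuple[float, ...] = ()


def _cell_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype-cell probabilities given haplotype freqs (f00,f01,f10,f11)."""
    f00, f01, f10, f11 = f
    p = np.empty((3, 3))
    p[0, 0] = f00 * f00
    p[0, 1] = 2 * f00 * f01
    p[0, 2] = f01 * f01
    p[1, 0] = 2 * f00 * f10
    p[1, 1] = 2 * f00 * f11 + 2 * f01 * f10
    p[1, 2] = 2 * f01 * f11
    p[2, 0] = f10 * f10
    p[2, 1] = 2 * f10 * f11
    p[2, 2] = f11 * f11
    return p


def _genotype_table(g1, g2) -> tuple[np.ndarray, int]:
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok], g2[ok]
    table = np.zeros((3, 3))
    np.add.at(table, (g1, g2), 1)
    return table, int(ok.sum())


def two_locus_loglik(f, table: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3x3 genotype table."""
    p = _cell_probs(np.asarray(f, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(p), 0.0)
    return float(terms.sum())


def em_haplotype_freqs(
    g1,
    g2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: np.ndarray | None = None,
) -> HaplotypeEstimate:
    """EM estimate of the four two-locus haplotype frequencies.

    Individuals missing either genotype are excluded (complete-case).
    Initialisation is uniform by default; convergence is declared when the
    log-likelihood improves by less than ``tol``.  Non-convergence within
    ``max_iter`` is flagged, not fatal.
    """
    table, n = _genotype_table(g1, g2)
    if n == 0:
        raise ValueError("no individuals with both genotypes called")
    f = np.full(4, 0.25) if init is None else np.asarray(init, float)
    f = f / f.sum()
    trace = [two_locus_loglik(f, table)]
    n00, n01, n02 = table[0]
    n10, n11, n12 = table[1]
    n20, n21, n22 = table[2]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        p_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
        c = np.array(
            [
                2 * n00 + n01 + n10 + n11 * p_cis,
                2 * n02 + n01 + n12 + n11 * (1 - p_cis),
                2 * n20 + n10 + n21 + n11 * (1 - p_cis),
                2 * n22 + n12 + n21 + n11 * p_cis,
            ]
        )
        f = c / (2 * n)
        trace.append(two_locus_loglik(f, table))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    freqs = HaplotypeFreqs(*np.clip(f, 0.0, 1.0) / np.clip(f, 0.0, 1.0).sum())
    return HaplotypeEstimate(
        freqs, trace[-1], it, converged, n, tuple(trace)
    )


@dataclass(frozen=True)
class LDResult:
    D: float
    Dmax: float
    Dprime: float
    defined: bool = True


def ld_stats(hap: HaplotypeEstimate | HaplotypeFreqs) -> LDResult:
    """Lewontin's D' from estimated haplotype frequencies.

    D = f(ref-ref) - p_ref(SNP1) * p_ref(SNP2); Dmax is the tightest bound
    given the allele frequencies (sign-dependent); D' = |D| / Dmax.
    Monomorphic loci make D' undefined and are flagged rather than coerced
    to zero.
    """
    freqs = hap.freqs if isinstance(hap, HaplotypeEstimate) else hap
    p1 = freqs.p_ref_snp1
    p2 = freqs.p_ref_snp2
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return LDResult(np.nan, np.nan, np.nan, defined=False)
    D = freqs.f_11 - p1 * p2
    q1, q2 = 1 - p1, 1 - p2
    if D >= 0:
        Dmax = min(p1 * q2, q1 * p2)
    else:
        Dmax = min(p1 * p2, q1 * q2)
    return LDResult(float(D), float(Dmax), float(abs(D) / Dmax))


def haplotype_dosages(g1, g2, freqs: HaplotypeFreqs) -> np.ndarray:
    """Expected per-individual haplotype counts (each row sums to 2).

    All genotype configurations are phase-unambiguous except the double
    heterozygote, which is split between cis (ref-ref + alt-alt) and trans
    haplotype pairs by the posterior cis probability
    f11*f22 / (f11*f22 + f12*f21).  Individuals with a missing genotype get
    NaN dosages.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    n = len(g1)
    out = np.zeros((n, 4))
    f = freqs.as_array()
    cis = f[0] * f[3]
    trans = f[1] * f[2]
    p_cis = cis / (cis + trans) if cis + trans > 0 else 0.5
    # haplotype contribution of each (g1, g2) cell
    cell_dosage = {
        (0, 0): (2, 0, 0, 0),
        (0, 1): (1, 1, 0, 0),
        (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0),
        (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0),
        (2, 1): (0, 0, 1, 1),
        (2, 2): (0, 0, 0, 2),
        (1, 1): (p_cis, 1 - p_cis, 1 - p_cis, p_cis),
    }
    for i in range(n):
        if g1[i] == MISSING or g2[i] == MISSING:
            out[i] = np.nan
        else:
            out[i] = cell_dosage[(int(g1[i]), int(g2[i]))]
    return out
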