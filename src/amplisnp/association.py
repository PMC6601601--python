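"""Case-control association testing.

Covers the statistical layer of the study design: uncorrected 2x2 Pearson
chi-square tests on genotype/allele contingency tables, covariate-adjusted
logistic regression under the five standard genetic models (codominant,
dominant, recessive, overdominant, log-additive) with likelihood-ratio
P-values, haplotype-dosage association, rank-based quantile normalisation
of quantitative traits, one-way ANOVA across genotypes, Welch's t test and
Bonferroni multiplicity control.

Logistic fits are maximum-likelihood via statsmodels; separation and rank
deficiency are detected and reported rather than silently returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "Chi2Result",
    "OddsRatio",
    "LogisticFit",
    "AssocModelResult",
    "HapAssocResult",
    "SeparationError",
    "GENETIC_MODELS",
    "pearson_chi2_2x2",
    "odds_ratio_2x2",
    "logistic_fit",
    "encode_genetic_model",
    "assoc_genetic_models",
    "haplotype_assoc",
    "bonferroni_threshold",
    "orq_normalize",
    "anova_by_genotype",
    "welch_t",
]

GENETIC_MODELS = (
    "codominant",
    "dominant",
    "recessive",
    "overdominant",
    "log-additive",
)

Z_95 = float(stats.norm.ppf(0.975))


class SeparationError(RuntimeError):
    """Raised when a logistic fit is perfectly (quasi-)separated."""


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    observed: tuple[tuple[float, float], tuple[float, float]]
    expected: tuple[tuple[float, float], tuple[float, float]]
    defined: bool = True


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> Chi2Result:
    """Uncorrected Pearson chi-square on a 2x2 table [[a, b], [c, d]].

    Statistic: n*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.  A zero
    margin makes the test undefined; the result is flagged instead of
    raising.
    """
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    observed = ((a, b), (c, d))
    if any(m == 0 for m in margins):
        warnings.warn("zero margin: chi-square undefined", stacklevel=2)
        return Chi2Result(np.nan, 1, np.nan, observed, observed, defined=False)
    expected = tuple(
        tuple(margins[i] * margins[2 + j] / n for j in (0, 1)) for i in (0, 1)
    )
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return Chi2Result(
        float(chi2), 1, float(stats.chi2.sf(chi2, 1)), observed, expected
    )


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool = False


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> OddsRatio:
    """Cross-product odds ratio with a Wald 95% CI on the log scale.

    Zero cells trigger the Haldane-Anscombe 0.5 correction (flagged).
    """
    cells = [a, b, c, d]
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return OddsRatio(
        float(np.exp(log_or)),
        float(np.exp(log_or - Z_95 * se)),
        float(np.exp(log_or + Z_95 * se)),
        corrected,
    )


@dataclass(frozen=True)
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int


_SEPARATION_BETA = 25.0  # |log-odds| beyond this on standardized-ish designs


def logistic_fit(y, X: pd.DataFrame, add_const: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``X`` columns are the predictors; an intercept is prepended unless
    ``add_const`` is False.  Rank-deficient designs raise ``ValueError``;
    (quasi-)separated data raise ``SeparationError``.
    """
    y = np.asarray(y, float)
    X = pd.DataFrame(X).astype(float)
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]} columns (collinear)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"perfect separation detected: {exc}") from exc
    if np.max(np.abs(res.params.to_numpy())) > _SEPARATION_BETA:
        raise SeparationError(
            "diverging coefficients: data are (quasi-)separated"
        )
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(
            res.cov_params(), index=X.columns, columns=X.columns
        ),
        loglik=float(res.llf),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_obs=len(y),
    )


def encode_genetic_model(genotypes, model: str) -> pd.DataFrame:
    """Regression encoding of alt-allele counts under a genetic model.

    codominant: two indicators (het, hom_alt) vs hom_ref; dominant: carrier
    indicator; recessive: hom_alt indicator; overdominant: het indicator;
    log-additive: the allele count itself.
    """
    g = np.asarray(genotypes)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotypes must be called (0/1/2) for encoding")
    if model == "codominant":
        return pd.DataFrame({"het": (g == 1).astype(float), "hom_alt": (g == 2).astype(float)})
    if model == "dominant":
        return pd.DataFrame({"carrier": (g >= 1).astype(float)})
    if model == "recessive":
        return pd.DataFrame({"hom_alt": (g == 2).astype(float)})
    if model == "overdominant":
        return pd.DataFrame({"het": (g == 1).astype(float)})
    if model == "log-additive":
        return pd.DataFrame({"alt_count": g.astype(float)})
    raise ValueError(f"unknown genetic model {model!r}")


@dataclass(frozen=True)
class AssocModelResult:
    model: str
    levels: tuple[tuple[str, float, float, float], ...]  # (label, OR, lo, hi)
    lrt_p: float
    df: int
    n: int


def _wald_or(fit: LogisticFit, term: str) -> tuple[float, float, float]:
    beta = fit.params[term]
    se = fit.bse[term]
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
    )


def assoc_genetic_models(
    genotypes,
    y,
    covariates: pd.DataFrame | None = None,
    models=GENETIC_MODELS,
) -> dict[str, AssocModelResult]:
    """Adjusted logistic association under each requested genetic model.

    For each model the full fit (genotype encoding + covariates) is compared
    to the covariate-only null by a likelihood-ratio test with df equal to
    the number of encoding columns; per-level ORs carry Wald 95% CIs.
    Rows with missing genotype, outcome or covariates are dropped
    (complete-case).
    """
    g = np.asarray(genotypes)
    y = np.asarray(y, float)
    cov = (
        pd.DataFrame(index=range(len(y)))
        if covariates is None
        else pd.DataFrame(covariates).reset_index(drop=True)
    )
    ok = (g >= 0) & ~np.isnan(y)
    if len(cov.columns):
        ok &= ~cov.isna().any(axis=1).to_numpy()
    g, y, cov = g[ok], y[ok], cov.loc[ok].reset_index(drop=True)
    null_fit = logistic_fit(y, cov)
    out = {}
    for model in models:
        enc = encode_genetic_model(g, model).reset_index(drop=True)
        X = pd.concat([enc, cov], axis=1)
        fit = logistic_fit(y, X)
        df = enc.shape[1]
        lrt = 2.0 * (fit.loglik - null_fit.loglik)
        lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df))
        levels = tuple((col, *_wald_or(fit, col)) for col in enc.columns)
        out[model] = AssocModelResult(model, levels, lrt_p, df, int(ok.sum()))
    return out


@dataclass(frozen=True)
class HapAssocResult:
    reference: str
    levels: tuple[tuple[str, float, float, float], ...]
    global_p: float
    df: int
    n: int
    pooled_rare: tuple[str, ...] = ()


def haplotype_assoc(
    dosages: pd.DataFrame,
    y,
    covariates: pd.DataFrame | None = None,
    freq_floor: float = 0.01,
) -> HapAssocResult:
    """Haplotype association via expected-dosage logistic regression.

    ``dosages`` has one column per haplotype (rows summing to 2).  The most
    frequent haplotype is the reference and is omitted from the design;
    haplotypes with estimated frequency below ``freq_floor`` are pooled into
    a 'rare' column (flagged).  The global P is a likelihood-ratio test of
    all non-reference dosage terms against the covariate-only null.
    """
    dos = pd.DataFrame(dosages).reset_index(drop=True)
    y = np.asarray(y, float)
    cov = (
        pd.DataFrame(index=range(len(y)))
        if covariates is None
        else pd.DataFrame(covariates).reset_index(drop=True)
    )
    ok = ~dos.isna().any(axis=1).to_numpy() & ~np.isnan(y)
    if len(cov.columns):
        ok &= ~cov.isna().any(axis=1).to_numpy()
    dos, y, cov = dos.loc[ok].reset_index(drop=True), y[ok], cov.loc[ok].reset_index(drop=True)
    freqs = dos.mean(axis=0) / 2.0
    if (freqs > 0).sum() < 2:
        raise ValueError("fewer than two haplotypes present; nothing to test")
    reference = str(freqs.idxmax())
    rare = tuple(str(c) for c in freqs.index if freqs[c] < freq_floor and c != reference)
    keep = [c for c in dos.columns if c != reference and c not in rare]
    X = dos[keep].copy()
    if rare:
        X["rare"] = dos[list(rare)].sum(axis=1)
    # drop zero-variance columns (haplotypes absent from the sample)
    X = X.loc[:, X.std(axis=0) > 0]
    if X.shape[1] == 0:
        raise ValueError("no estimable non-reference haplotype effects")
    null_fit = logistic_fit(y, cov)
    fit = logistic_fit(y, pd.concat([X, cov], axis=1))
    df = X.shape[1]
    lrt = 2.0 * (fit.loglik - null_fit.loglik)
    global_p = float(stats.chi2.sf(max(lrt, 0.0), df))
    levels = tuple((str(col), *_wald_or(fit, col)) for col in X.columns)
    return HapAssocResult(reference, levels, global_p, df, int(ok.sum()), rare)


def bonferroni_threshold(alpha: float = 0.05, k: int = 2) -> float:
    """Per-test significance threshold alpha / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def orq_normalize(values) -> np.ndarray:
    """Rank-based ordered-quantile (inverse-normal) transform.

    Maps value of rank r (average ranks for ties) to the standard-normal
    quantile at (r - 0.5) / n; strictly monotone in the input ranks.
    Missing values propagate; a constant vector maps to zeros with a
    warning.
    """
    x = np.asarray(values, float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanstd(x) == 0:
        warnings.warn("constant input: normalized values set to 0", stacklevel=2)
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def anova_by_genotype(trait, genotypes) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a trait across genotype groups."""
    trait = np.asarray(trait, float)
    g = np.asarray(genotypes)
    ok = ~np.isnan(trait) & (g >= 0)
    groups = [trait[ok & (g == k)] for k in np.unique(g[ok])]
    groups = [grp for grp in groups if len(grp) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype groups with >= 2 observations")
    if all(np.ptp(grp) == 0 for grp in groups) and len({grp[0] for grp in groups}) == 1:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch unequal-variance t test."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
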