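"""Two-group differential expression.

Count features (mRNA, lncRNA) are tested with a negative-binomial Wald test
on median-of-ratios-normalized counts; miRNA abundances (TPM) with a
Wilcoxon rank-sum test.  Both apply the same call rule: a feature is
differentially expressed when its Benjamini-Hochberg adjusted p-value is
below ``alpha`` AND |log2 fold change| is at least ``lfc_min`` (defaults
.05 and 2).

The NB test is a self-contained stand-in for a full GLM framework, not a
clone of one: per-feature dispersions come from the method of moments,
shrunk halfway toward a fitted mean-dispersion trend, and the Wald statistic
for the log fold change of normalized group means (pseudocount 0.5) is
referred to a t distribution with n1 + n2 - 2 degrees of freedom — the
standard small-sample adjustment that keeps the type-I error near nominal
with moment dispersion estimates.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DE_COLUMNS = ["feature_id", "base_mean", "log2fc", "pvalue", "padj", "is_de"]

_DISP_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1).

    Raises ``ValueError`` for values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Ratios are taken against the per-feature geometric mean over samples;
    only features positive in every sample contribute.  Raises if no such
    feature exists (advice: filter first).
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples for size factors")
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "filter low-expression features before normalization"
        )
    logx = np.log(x[allpos])
    logg = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - logg, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def filter_low_expression(matrix: pd.DataFrame, min_mean: float) -> pd.DataFrame:
    """Keep features whose mean abundance is >= ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = matrix.mean(axis=1) >= min_mean
    out = matrix.loc[keep]
    log.info("low-expression filter: kept %d / %d features (min_mean=%g)",
             out.shape[0], matrix.shape[0], min_mean)
    return out


def de_call(padj, log2fc, alpha: float = 0.05, lfc_min: float = 2.0):
    """The differential-expression call rule: padj < alpha AND |log2fc| >= lfc_min."""
    return (np.asarray(padj) < alpha) & (np.abs(log2fc) >= lfc_min)


def _two_group_index(groups: pd.Series, columns) -> tuple:
    g = pd.Series(groups).reindex(columns)
    if g.isna().any():
        missing = list(g.index[g.isna()])[:5]
        raise ValueError(f"no group label for samples: {missing}")
    levels = sorted(set(g))  # lexicographic: results don't depend on sample order
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    i1 = np.flatnonzero((g == levels[0]).to_numpy())
    i2 = np.flatnonzero((g == levels[1]).to_numpy())
    return levels, i1, i2


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Least-squares fit of disp ~ a + b/mu, clipped at the floor."""
    ok = mu > 0
    if ok.sum() < 3:
        return np.maximum(disp, _DISP_FLOOR)
    b, a = np.polyfit(1.0 / mu[ok], disp[ok], 1)
    trend = a + b / np.where(ok, mu, 1.0)
    return np.maximum(trend, _DISP_FLOOR)


def de_test_counts(counts: pd.DataFrame, groups, alpha: float = 0.05,
                   lfc_min: float = 2.0) -> pd.DataFrame:
    """NB Wald differential-expression test for a two-group count matrix.

    Returns a DataFrame with columns ``feature_id, base_mean, log2fc,
    pvalue, padj, is_de``; ``log2fc`` is group2 vs group1 where group1 is
    the lexicographically first group label (e.g. healthy < psoriasis).
    """
    levels, i1, i2 = _two_group_index(groups, counts.columns)
    n1, n2 = len(i1), len(i2)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >=2 samples for a dispersion estimate "
            f"(got {levels[0]}:{n1}, {levels[1]}:{n2})"
        )
    sf = size_factors(counts)
    y = counts.to_numpy(dtype=float) / sf.to_numpy()

    m1 = y[:, i1].mean(axis=1)
    m2 = y[:, i2].mean(axis=1)
    v1 = y[:, i1].var(axis=1, ddof=1)
    v2 = y[:, i2].var(axis=1, ddof=1)
    base_mean = y.mean(axis=1)

    # moment dispersion from pooled within-group variance, var = mu + disp*mu^2
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(mu > 0, (pooled_var - mu) / np.square(mu), 0.0)
    disp_mom = np.maximum(disp_mom, _DISP_FLOOR)
    trend = _dispersion_trend(mu, disp_mom)
    disp = np.maximum(0.5 * disp_mom + 0.5 * trend, _DISP_FLOOR)

    log2fc = np.log2((m2 + _PSEUDOCOUNT) / (m1 + _PSEUDOCOUNT))
    var_m1 = (m1 + disp * np.square(m1)) / n1
    var_m2 = (m2 + disp * np.square(m2)) / n2
    # delta method on log(mean + pseudocount)
    se_ln = np.sqrt(var_m1 / np.square(m1 + _PSEUDOCOUNT)
                    + var_m2 / np.square(m2 + _PSEUDOCOUNT))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se_ln > 0, np.log(2.0) * log2fc / se_ln, 0.0)
    pvalue = np.where(se_ln > 0,
                      2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2), 1.0)
    pvalue = np.clip(pvalue, 0.0, 1.0)

    padj = bh_adjust(pvalue)
    return pd.DataFrame({
        "feature_id": counts.index,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "is_de": de_call(padj, log2fc, alpha, lfc_min),
    }).set_index("feature_id", drop=False)


def de_test_tpm(tpm: pd.DataFrame, groups, alpha: float = 0.05,
                lfc_min: float = 2.0) -> pd.DataFrame:
    """Rank-sum differential-expression test for a TPM matrix (miRNA).

    Per feature, a two-sided Wilcoxon rank-sum (Mann-Whitney) test with tie
    correction; log2 fold change from group mean TPM with pseudocount 1.
    A feature constant across all samples gets p = 1 and is never called.
    """
    levels, i1, i2 = _two_group_index(groups, tpm.columns)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("each group needs >=2 samples")
    x = tpm.to_numpy(dtype=float)
    m1 = x[:, i1].mean(axis=1)
    m2 = x[:, i2].mean(axis=1)
    log2fc = np.log2((m2 + 1.0) / (m1 + 1.0))

    pvalue = np.ones(x.shape[0])
    for k in range(x.shape[0]):
        row = x[k]
        if np.ptp(row) == 0:  # constant feature
            continue
        pvalue[k] = stats.mannwhitneyu(row[i2], row[i1],
                                       alternative="two-sided",
                                       method="auto").pvalue
    pvalue = np.clip(pvalue, 0.0, 1.0)
    padj = bh_adjust(pvalue)
    return pd.DataFrame({
        "feature_id": tpm.index,
        "base_mean": x.mean(axis=1),
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "is_de": de_call(padj, log2fc, alpha, lfc_min),
    }).set_index("feature_id", drop=False)
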