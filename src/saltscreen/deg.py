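"""Count-based differential expression with the screening study's filters.

The test is a deliberately simple negative-binomial Wald test:

1. size factors by the median-of-ratios method (per-sample median of
   count / geometric-mean-across-samples, over genes expressed everywhere);
2. normalized condition means with a pseudocount of 1, so fold changes of
   zero-count genes stay finite: log2FC = log2((m_B + 1) / (m_A + 1));
3. a single method-of-moments dispersion alpha shared across genes, fitted
   by regressing the within-condition excess variance s^2 - m on m^2;
4. a two-sided Wald statistic on the log scale via the delta method,
   referred to the standard normal (with the dispersion pooled over
   thousands of genes it is effectively known, and the statistic is very
   close to N(0,1) under the null across the expression range); p-values
   are floored at 1e-15 and BH-adjusted.

A gene is called differentially expressed when |log2FC| > 1 and p < 0.01,
both strict, applied to the raw p-value by default (the adjusted value is
reported and can be used instead).  FPKM (fragments per kilobase of
transcript per million mapped reads) is provided for expression-level
reporting: count * 1e9 / (length * library_size).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "fpkm",
    "size_factors",
    "estimate_dispersion",
    "de_test",
    "call_degs",
    "common_degs",
    "P_FLOOR",
]

P_FLOOR = 1e-15


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length * library size), per gene and sample.

    ``library_sizes`` defaults to per-sample total counts (the proxy for
    "million mapped reads" when only the count matrix is available).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples; genes with
    any zero count drop out of the reference (their log geometric mean is
    -inf).  Falls back to total-count scaling if no gene is expressed in
    every sample.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
        logmean = logc.mean(axis=1)
    usable = np.isfinite(logmean)
    if not usable.any():
        logger.warning("no gene expressed in all samples; "
                       "falling back to total-count size factors")
        ls = counts.sum(axis=0).astype(float)
        return ls / np.exp(np.log(ls).mean())
    ratios = logc[usable] - logmean[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(norm: pd.DataFrame, groups: pd.Series) -> float:
    """Pooled method-of-moments common dispersion alpha (Var = mu + alpha*mu^2).

    Within each condition, per-gene sample mean m and unbiased variance s^2
    satisfy E[s^2] = mu + alpha*mu^2, so the excess s^2 - m is regressed
    through the origin on m^2 across all genes and conditions.  Clipped to
    a small positive floor (Poisson-like data can give a negative estimate).
    """
    num = 0.0
    den = 0.0
    for cond in groups.unique():
        sub = norm.loc[:, groups[groups == cond].index].to_numpy(dtype=float)
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        keep = m > 0
        num += float(np.sum((s2[keep] - m[keep]) * m[keep] ** 2))
        den += float(np.sum(m[keep] ** 4))
    alpha = num / den if den > 0 else 0.0
    return max(alpha, 1e-8)


def de_test(counts: pd.DataFrame, conditions: pd.Series,
            contrast: tuple[str, str], *, pseudocount: float = 1.0,
            dispersion: float | None = None) -> pd.DataFrame:
    """NB Wald differential-expression test for ``contrast = (treated, reference)``.

    Positive log2FC means higher expression in the treated condition.
    Returns per-gene baseMean per condition, log2fc, pvalue, padj.
    """
    treated, reference = contrast
    conditions = conditions.reindex(counts.columns)
    for cond in contrast:
        if (conditions == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} needs at least 2 replicates")
    cols = conditions[conditions.isin(contrast)].index
    sub = counts[cols]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    groups = conditions[cols]
    if dispersion is None:
        dispersion = estimate_dispersion(norm, groups)
        logger.info("common dispersion alpha = %.4g", dispersion)

    a_cols = groups[groups == reference].index
    b_cols = groups[groups == treated].index
    m_a = norm[a_cols].mean(axis=1).to_numpy()
    m_b = norm[b_cols].mean(axis=1).to_numpy()
    n_a, n_b = len(a_cols), len(b_cols)

    log2fc = np.log2((m_b + pseudocount) / (m_a + pseudocount))
    # delta method on log(mean + pseudocount); Var(mean) = (mu + alpha mu^2)/n
    var_log = ((m_a + dispersion * m_a ** 2) / (n_a * (m_a + pseudocount) ** 2)
               + (m_b + dispersion * m_b ** 2) / (n_b * (m_b + pseudocount) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(m_b + pseudocount) - np.log(m_a + pseudocount)) / np.sqrt(var_log)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    allzero = (m_a == 0) & (m_b == 0)
    pvalue[allzero] = 1.0
    pvalue = np.clip(np.nan_to_num(pvalue, nan=1.0), P_FLOOR, 1.0)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    return pd.DataFrame({
        f"baseMean_{reference}": m_a,
        f"baseMean_{treated}": m_b,
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
    }, index=counts.index.rename("gene"))


def call_degs(deg_table: pd.DataFrame, lfc_cut: float = 1.0,
              p_cut: float = 0.01, *, use_adjusted: bool = False) -> pd.DataFrame:
    """Label genes up/down/ns: |log2FC| > lfc_cut and p < p_cut, both strict."""
    p = deg_table["padj" if use_adjusted else "pvalue"]
    sig = (p < p_cut) & (deg_table["log2fc"].abs() > lfc_cut)
    call = np.where(~sig, "ns", np.where(deg_table["log2fc"] > 0, "up", "down"))
    out = deg_table.copy()
    out["call"] = call
    return out


def deg_summary(calls: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping: n_up + n_down = n_deg by construction."""
    n_up = int((calls["call"] == "up").sum())
    n_down = int((calls["call"] == "down").sum())
    return {"n_up": n_up, "n_down": n_down, "n_deg": n_up + n_down,
            "n_ns": int((calls["call"] == "ns").sum())}


def common_degs(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> set:
    """Genes called differentially expressed (up or down) in both contrasts."""
    deg_a = set(calls_a.index[calls_a["call"] != "ns"])
    deg_b = set(calls_b.index[calls_b["call"] != "ns"])
    return deg_a & deg_b


__all__.append("deg_summary")
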