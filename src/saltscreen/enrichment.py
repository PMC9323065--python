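"""Term over-representation and transcription-factor family profiling.

Enrichment of a DEG set in annotation terms (GO namespaces or pathways)
uses the upper-tail hypergeometric test: with N database-annotated genes in
the universe, K of them in the term, and n database-annotated DEGs of which
k fall in the term, p = P(X >= k).  Each row also carries the "cluster
frequency" k / n — the share of annotated DEGs that belong to the term —
the quantity plotted in enrichment bar charts.  p-values are BH-adjusted
within each namespace and rows with adjusted p below the cutoff (default
0.01) are flagged significant.

The TF profile tallies up- and down-regulated DEGs per transcription-factor
family and reports the families shared between two contrasts.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["enrich", "tf_tally", "shared_tf", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=big_n, K=big_k, n draws)."""
    if not 0 <= k <= min(big_k, n):
        raise ValueError("require 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def enrich(deg_genes, term_map: pd.DataFrame, universe,
           *, sig_cut: float = 0.01) -> pd.DataFrame:
    """Hypergeometric over-representation of ``deg_genes`` per term.

    Parameters
    ----------
    deg_genes : iterable of gene ids (must be a subset of ``universe``)
    term_map : DataFrame with columns ``term``, ``namespace``, ``genes``
        (each ``genes`` entry an iterable of gene ids)
    universe : iterable of all testable gene ids

    The effective universe per namespace is the set of universe genes
    annotated to at least one term of that namespace, matching the
    cluster-frequency denominator (annotated DEGs).
    """
    universe = set(universe)
    deg = set(deg_genes)
    if not deg <= universe:
        raise ValueError("deg_genes must be a subset of the universe")
    if not deg:
        logger.warning("empty DEG set; returning empty enrichment table")
        return pd.DataFrame(columns=["term", "namespace", "k", "K", "n", "N",
                                     "cluster_frequency", "pvalue", "padj",
                                     "significant"])
    frames = []
    for ns, sub in term_map.groupby("namespace", sort=True):
        annotated = set()
        gene_sets = {}
        for _, row in sub.iterrows():
            gs = set(row["genes"]) & universe
            if not gs:
                continue
            gene_sets[row["term"]] = gs
            annotated |= gs
        big_n = len(annotated)
        n = len(deg & annotated)
        rows = []
        for term, gs in sorted(gene_sets.items()):
            k = len(deg & gs)
            big_k = len(gs)
            p = hypergeom_upper_tail(k, big_n, big_k, n) if n else 1.0
            rows.append({"term": term, "namespace": ns, "k": k, "K": big_k,
                         "n": n, "N": big_n,
                         "cluster_frequency": k / n if n else 0.0,
                         "pvalue": p})
        if not rows:
            continue
        ns_df = pd.DataFrame(rows)
        ns_df["padj"] = multipletests(ns_df["pvalue"], method="fdr_bh")[1]
        frames.append(ns_df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["term", "namespace", "k", "K", "n", "N",
                 "cluster_frequency", "pvalue", "padj"])
    out["significant"] = out["padj"] < sig_cut
    return out.sort_values(["pvalue", "term"], ignore_index=True)


def tf_tally(calls: pd.DataFrame, tf_annotation: pd.DataFrame) -> pd.DataFrame:
    """Up/down DEG counts per transcription-factor family.

    ``calls`` is a DEG table indexed by gene with a ``call`` column;
    ``tf_annotation`` has columns ``gene`` and ``family`` (one family per
    gene).  DEGs without a TF annotation are ignored; families with no DEG
    are omitted.
    """
    fam = tf_annotation.set_index("gene")["family"]
    deg = calls[calls["call"] != "ns"]
    tagged = deg.join(fam, how="inner")
    if tagged.empty:
        return pd.DataFrame(columns=["family", "n_up", "n_down"])
    tally = (tagged.groupby("family")["call"]
             .value_counts().unstack(fill_value=0)
             .reindex(columns=["up", "down"], fill_value=0)
             .rename(columns={"up": "n_up", "down": "n_down"}))
    tally = tally[(tally["n_up"] + tally["n_down"]) > 0]
    return tally.reset_index().sort_values("family", ignore_index=True)


def shared_tf(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
              tf_annotation: pd.DataFrame) -> dict:
    """TF genes and families differentially expressed in both contrasts."""
    fam = tf_annotation.set_index("gene")["family"]
    tf_a = set(calls_a.index[calls_a["call"] != "ns"]) & set(fam.index)
    tf_b = set(calls_b.index[calls_b["call"] != "ns"]) & set(fam.index)
    genes = tf_a & tf_b
    return {"genes": sorted(genes),
            "families": sorted({fam[g] for g in genes})}
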