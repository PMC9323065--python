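"""Fuzzy-mathematics comprehensive evaluation of stress tolerance.

The membership-function method rescales each trait (index) linearly across
genotypes to [0, 1],

    u_ij = (x_ij - min_j) / (max_j - min_j),

so the worst-performing accession for an index gets membership 0 and the
best gets 1.  Memberships are summed over indices within an evaluation
group (here: one NaCl concentration) to give a per-group comprehensive
score, and per-group scores are summed over groups for the total score.
Higher score = more salt tolerant.  Ranks are descending competition ranks
("1224": tied scores share the smallest rank and the next rank is skipped).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "membership",
    "membership_matrix",
    "comprehensive_score",
    "total_score",
    "rank_scores",
    "select_extremes",
    "evaluate",
]


def membership(values) -> np.ndarray:
    """Min–max membership values for one group x index.

    Parameters
    ----------
    values : array-like of float
        Raw trait values across accessions within a single evaluation
        stratum.  NaN entries propagate as NaN.

    Returns
    -------
    ndarray
        ``(x - min) / (max - min)``.  When all non-missing values are equal
        the index is uninformative and every membership is set to 0.5 (with
        a logged warning) rather than forcing an arbitrary extreme.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("membership needs at least 2 non-missing values")
    lo = v[finite].min()
    hi = v[finite].max()
    out = np.full_like(v, np.nan)
    if hi == lo:
        logger.warning("degenerate index (max == min == %g); memberships set to 0.5", hi)
        out[finite] = 0.5
        return out
    out[finite] = (v[finite] - lo) / (hi - lo)
    return out


def membership_matrix(df: pd.DataFrame, *, group: str = "group",
                      index: str = "trait", value: str = "value") -> pd.DataFrame:
    """Attach a ``membership`` column, computed within each group x index.

    `df` is long-form with one row per (group, accession, index).
    """
    out = df.copy()
    out["membership"] = (
        out.groupby([group, index], sort=False)[value]
        .transform(lambda s: membership(s.to_numpy()))
    )
    return out


def comprehensive_score(mem: pd.DataFrame, *, group: str = "group",
                        accession: str = "accession") -> pd.DataFrame:
    """Per-accession, per-group score: sum of memberships over indices.

    Missing memberships are excluded from the sum and the accession flagged
    in the ``complete`` column; an accession with every index missing in a
    group is dropped from that group.
    """
    g = mem.groupby([group, accession], sort=False)["membership"]
    scores = g.sum(min_count=1).rename("score")
    n_missing = g.apply(lambda s: int(s.isna().sum())).rename("n_missing")
    out = pd.concat([scores, n_missing], axis=1).reset_index()
    out["complete"] = out["n_missing"] == 0
    dropped = out["score"].isna()
    if dropped.any():
        for _, row in out[dropped].iterrows():
            logger.warning("accession %s has no usable index in group %s; excluded",
                           row[accession], row[group])
        out = out[~dropped]
    return out.reset_index(drop=True)


def total_score(per_group: pd.DataFrame, *, group: str = "group",
                accession: str = "accession", score: str = "score") -> pd.Series:
    """Sum per-group scores over groups, indexed by accession.

    Accessions missing any group are excluded with a logged warning, so the
    total stays comparable across accessions.
    """
    n_groups = per_group[group].nunique()
    counts = per_group.groupby(accession)[score].count()
    incomplete = counts[counts < n_groups].index
    for acc in incomplete:
        logger.warning("accession %s missing %d group(s); excluded from totals",
                       acc, n_groups - counts[acc])
    keep = per_group[~per_group[accession].isin(incomplete)]
    return keep.groupby(accession)[score].sum().rename("total_score")


def rank_scores(scores) -> np.ndarray:
    """Descending competition ranks: best score -> 1, ties share the min rank."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot rank an empty score vector")
    return rankdata(-s, method="min").astype(int)


def select_extremes(total: pd.Series, k_top: int, k_bottom: int) -> tuple[list, list]:
    """Top-``k_top`` (tolerant) and bottom-``k_bottom`` (sensitive) accessions.

    Ties are broken lexicographically by accession id so the selection is
    deterministic.  The two sets must not overlap.
    """
    if k_top + k_bottom > len(total):
        raise ValueError(
            f"k_top + k_bottom = {k_top + k_bottom} exceeds {len(total)} accessions")
    df = total.rename("score").rename_axis("accession").reset_index()
    desc = df.sort_values(["score", "accession"],
                          ascending=[False, True])["accession"].tolist()
    asc = df.sort_values(["score", "accession"],
                         ascending=[True, True])["accession"].tolist()
    tolerant = desc[:k_top]
    sensitive = asc[:k_bottom]
    if set(tolerant) & set(sensitive):
        raise ValueError("tolerant and sensitive selections overlap")
    return tolerant, sensitive


def evaluate(relative: pd.DataFrame, *, group: str = "group",
             accession: str = "accession", index: str = "trait",
             value: str = "value") -> pd.DataFrame:
    """Full comprehensive evaluation: memberships -> scores -> ranks.

    Returns a wide score table with one row per accession: per-group
    ``score_<g>`` / ``rank_<g>`` columns plus ``total_score`` and
    ``total_rank`` (the published score-table shape).
    """
    mem = membership_matrix(relative, group=group, index=index, value=value)
    per_group = comprehensive_score(mem, group=group, accession=accession)
    total = total_score(per_group, group=group, accession=accession)

    wide = per_group.pivot(index=accession, columns=group, values="score")
    wide = wide.loc[total.index]
    out = pd.DataFrame(index=wide.index)
    for g in wide.columns:
        out[f"score_{g}"] = wide[g]
        out[f"rank_{g}"] = rank_scores(wide[g].to_numpy())
    out["total_score"] = total
    out["total_rank"] = rank_scores(total.to_numpy())
    return out.reset_index()
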