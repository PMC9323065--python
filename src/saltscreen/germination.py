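"""Germination-stage salt-tolerance traits.

From per-dish cumulative germination censuses (counts recorded every two
days over an eight-day test) and final plumule/radicle lengths, this module
derives the five standard seed-vigour indices:

* GR — germination rate, fraction germinated at the final census;
* GP — germination potential, fraction germinated by day 4;
* GI — germination index, sum over census days of GR_t / D_t, where GR_t is
  the germination rate at day t and D_t the days elapsed (earlier
  germination weighs more);
* PL, RL — plumule and radicle length at the final census (mm).

Relative forms (RGR, RGP, RGI, RPL, RRL) divide the replicate-mean under
salt by the replicate-mean under control for each accession; values below 1
indicate salt inhibition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "germination_rate",
    "germination_potential",
    "germination_index",
    "germination_traits",
    "relative_traits",
    "GERMINATION_TRAITS",
    "RELATIVE_NAMES",
]

GERMINATION_TRAITS = ["GR", "GP", "GI", "PL", "RL"]
RELATIVE_NAMES = {"GR": "RGR", "GP": "RGP", "GI": "RGI", "PL": "RPL", "RL": "RRL"}

#: census day that defines germination potential
GP_DAY = 4


def _check_dish(days: np.ndarray, germinated: np.ndarray, sown: int) -> None:
    if sown <= 0:
        raise ValueError("sown must be positive")
    if np.any(np.diff(days) <= 0):
        raise ValueError("census days must be strictly increasing")
    if np.any(days <= 0):
        raise ValueError("census days must be positive (day 0 divides by zero in GI)")
    if np.any(germinated < 0) or np.any(germinated > sown):
        raise ValueError("germinated counts must lie in [0, sown]")
    if np.any(np.diff(germinated) < 0):
        raise ValueError("cumulative germinated counts must be non-decreasing")


def germination_rate(days, germinated, sown: int) -> float:
    """GR: fraction of sown seeds germinated at the final census."""
    days = np.asarray(days)
    germinated = np.asarray(germinated)
    _check_dish(days, germinated, sown)
    return germinated[-1] / sown


def germination_potential(days, germinated, sown: int, gp_day: int = GP_DAY) -> float:
    """GP: fraction of sown seeds germinated by ``gp_day`` (default day 4)."""
    days = np.asarray(days)
    germinated = np.asarray(germinated)
    _check_dish(days, germinated, sown)
    at = np.nonzero(days == gp_day)[0]
    if at.size == 0:
        raise ValueError(f"no census at day {gp_day}; cannot compute GP")
    return germinated[at[0]] / sown


def germination_index(days, germinated, sown: int, *,
                      convention: str = "cumulative") -> float:
    """GI = sum over census days of GR_t / D_t.

    ``convention="cumulative"`` (default) takes GR_t as the cumulative
    germination rate at day t.  ``convention="interval"`` takes GR_t as the
    fraction newly germinated since the previous census — both conventions
    circulate in the seed-science literature.
    """
    days = np.asarray(days, dtype=float)
    germinated = np.asarray(germinated, dtype=float)
    _check_dish(days, germinated, sown)
    if convention == "cumulative":
        rates = germinated / sown
    elif convention == "interval":
        rates = np.diff(germinated, prepend=0.0) / sown
    else:
        raise ValueError(f"unknown GI convention {convention!r}")
    return float(np.sum(rates / days))


def germination_traits(census: pd.DataFrame, *,
                       gi_convention: str = "cumulative") -> pd.DataFrame:
    """Per-dish germination traits from a long census table.

    ``census`` columns: accession, condition, replicate, day, germinated,
    sown, plumule_length, radicle_length (lengths recorded at the final
    census; earlier rows may repeat or leave them NaN — the final-census
    value is used).

    Returns one row per (accession, condition, replicate) with columns
    GR, GP, GI, PL, RL.
    """
    rows = []
    for (acc, cond, rep), dish in census.groupby(
            ["accession", "condition", "replicate"], sort=True):
        dish = dish.sort_values("day")
        days = dish["day"].to_numpy()
        germ = dish["germinated"].to_numpy()
        sown = int(dish["sown"].iloc[0])
        rows.append({
            "accession": acc,
            "condition": cond,
            "replicate": rep,
            "GR": germination_rate(days, germ, sown),
            "GP": germination_potential(days, germ, sown),
            "GI": germination_index(days, germ, sown, convention=gi_convention),
            "PL": float(dish["plumule_length"].iloc[-1]),
            "RL": float(dish["radicle_length"].iloc[-1]),
        })
    return pd.DataFrame(rows)


def relative_traits(traits: pd.DataFrame, *, control: str = "control",
                    salt: str = "salt") -> pd.DataFrame:
    """Relative traits: replicate-mean(salt) / replicate-mean(control).

    Dishes are unpaired, so the ratio is taken on replicate means rather
    than per-replicate pairs.  A zero control mean makes the ratio
    undefined; the trait is emitted as NaN with a logged warning so the
    membership scoring can exclude it.

    Returns long form: accession, trait (RGR, RGP, ...), value.
    """
    means = (traits.groupby(["accession", "condition"])[GERMINATION_TRAITS]
             .mean())
    rows = []
    for acc in means.index.get_level_values("accession").unique():
        if (acc, control) not in means.index or (acc, salt) not in means.index:
            logger.warning("accession %s lacks a %s/%s pair; skipped",
                           acc, control, salt)
            continue
        c = means.loc[(acc, control)]
        s = means.loc[(acc, salt)]
        for t in GERMINATION_TRAITS:
            if c[t] == 0:
                logger.warning("accession %s: control mean of %s is 0; "
                               "relative %s flagged missing", acc, t, t)
                val = np.nan
            else:
                val = s[t] / c[t]
            rows.append({"accession": acc, "trait": RELATIVE_NAMES[t], "value": val})
    return pd.DataFrame(rows)
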