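"""Seedling-stage salt-tolerance traits.

The secondary screen grows the shortlisted accessions to the seedling stage
and stresses them at several NaCl concentrations.  Four indices are derived
per accession x concentration, each expressed relative to the unsalted
control:

* relative biomass — fresh weight of the sampled seedlings;
* relative growth rate — mean height gain per day over the stress window;
* relative chlorophyll — total chlorophyll from DMSO-extract absorbances at
  663 and 645 nm (Arnon relation, 8.02*A663 + 20.21*A645 mg/L);
* relative K+/Na+ — leaf potassium-to-sodium content ratio; maintaining it
  under salt marks tolerance.

Only relative values feed the downstream fuzzy evaluation, so constant
factors (extract volume, sample mass, the chlorophyll coefficients) cancel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "growth_rate",
    "chlorophyll_total",
    "k_na_ratio",
    "seedling_traits",
    "relative_seedling_traits",
    "SEEDLING_TRAITS",
    "CHL_A663_COEF",
    "CHL_A645_COEF",
]

SEEDLING_TRAITS = ["biomass", "growth_rate", "chlorophyll", "k_na"]

# Arnon total-chlorophyll coefficients for A663/A645 pairs (mg per litre)
CHL_A663_COEF = 8.02
CHL_A645_COEF = 20.21


def growth_rate(height_initial, height_final, duration) -> float | np.ndarray:
    """Average height gain per day, (final - initial) / duration (cm/day)."""
    duration = np.asarray(duration, dtype=float)
    if np.any(duration <= 0):
        raise ValueError("duration must be positive")
    rate = (np.asarray(height_final, dtype=float)
            - np.asarray(height_initial, dtype=float)) / duration
    if np.any(np.asarray(rate) < 0):
        logger.warning("negative growth rate encountered (final height < initial)")
    return rate if np.ndim(rate) else float(rate)


def chlorophyll_total(a663, a645) -> float | np.ndarray:
    """Total chlorophyll (mg/L) from absorbances at 663 and 645 nm."""
    a663 = np.asarray(a663, dtype=float)
    a645 = np.asarray(a645, dtype=float)
    if np.any(a663 < 0) or np.any(a645 < 0):
        raise ValueError("absorbances must be non-negative")
    out = CHL_A663_COEF * a663 + CHL_A645_COEF * a645
    return out if np.ndim(out) else float(out)


def k_na_ratio(k, na) -> float | np.ndarray:
    """K+/Na+ content ratio; Na = 0 yields NaN with a logged warning."""
    k = np.asarray(k, dtype=float)
    na = np.asarray(na, dtype=float)
    zero = na == 0
    if np.any(zero):
        logger.warning("Na content of 0 encountered; K/Na flagged missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, k / na)
    return out if np.ndim(out) else float(out)


def seedling_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the four seedling indices per replicate row.

    ``table`` columns: accession, concentration (mol/L NaCl, 0 = control),
    replicate, biomass, height_initial, height_final, duration, A663, A645,
    Na, K.
    """
    out = table[["accession", "concentration", "replicate"]].copy()
    out["biomass"] = table["biomass"].astype(float)
    out["growth_rate"] = growth_rate(table["height_initial"],
                                     table["height_final"], table["duration"])
    out["chlorophyll"] = chlorophyll_total(table["A663"], table["A645"])
    out["k_na"] = k_na_ratio(table["K"], table["Na"])
    return out


def relative_seedling_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Relative traits per accession x salt concentration.

    Each trait's replicate mean under a salt concentration is divided by the
    same accession's replicate mean at concentration 0.  Accessions with no
    control rows are excluded with a logged warning.

    Returns long form: accession, group (the concentration), trait, value —
    ready for the fuzzy evaluation.
    """
    derived = seedling_traits(table)
    means = derived.groupby(["accession", "concentration"])[SEEDLING_TRAITS].mean()
    rows = []
    for acc in means.index.get_level_values("accession").unique():
        sub = means.loc[acc]
        if 0 not in sub.index:
            logger.warning("accession %s has no control (0 NaCl) rows; excluded", acc)
            continue
        ctrl = sub.loc[0]
        for conc in sub.index:
            if conc == 0:
                continue
            for t in SEEDLING_TRAITS:
                val = sub.loc[conc, t] / ctrl[t] if ctrl[t] != 0 else np.nan
                rows.append({"accession": acc, "group": conc,
                             "trait": f"relative_{t}", "value": val})
    return pd.DataFrame(rows)
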