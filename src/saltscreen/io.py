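"""Readers and writers for the pipeline's delimited-text formats.

All tabular files are TSV: UTF-8, header row, '.' decimal separator,
missing values written as "NA".  Term maps use the GMT convention (term,
description, then member genes, tab-separated); the namespace rides in the
description field.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_counts",
    "read_gmt",
    "write_gmt",
    "load_reference_scores",
    "load_config",
]

NA = "NA"


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=True, **kw)


def write_tsv(df: pd.DataFrame, path, *, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=NA, lineterminator="\n")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column holds gene ids."""
    df = read_tsv(path)
    return df.set_index(df.columns[0]).astype(int)


def read_gmt(path) -> pd.DataFrame:
    """GMT term map -> DataFrame(term, namespace, genes)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            rows.append({"term": parts[0], "namespace": parts[1] or "NA",
                         "genes": parts[2:]})
    return pd.DataFrame(rows, columns=["term", "namespace", "genes"])


def write_gmt(term_map: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in term_map.iterrows():
            fh.write("\t".join([str(row["term"]), str(row["namespace"]),
                                *map(str, row["genes"])]) + "\n")


def load_reference_scores() -> pd.DataFrame:
    """Published comprehensive-evaluation score table for the 18-accession
    seedling screen (per-concentration scores/ranks, totals and ranks)."""
    with resources.files("saltscreen.data").joinpath(
            "reference_scores.tsv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def load_config(path) -> dict:
    """YAML key/value configuration file -> nested dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
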