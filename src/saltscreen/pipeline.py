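"""End-to-end driver: simulate -> screen -> evaluate -> DEGs -> profiles -> hubs.

The pipeline mirrors the two-stage screening study design: a large
germination panel is scored by fuzzy comprehensive evaluation to shortlist
tolerant and sensitive accessions; the shortlist is re-screened at the
seedling stage; the extreme accessions define two RNA-seq contrasts
(sensitive salt/control = SS/SC, tolerant salt/control = TS/TC); DEGs are
profiled by term enrichment and TF-family tallies; and the DEG interaction
network yields MCC hub genes.  Every stage writes a TSV and the run ends
with a provenance manifest (seed, thresholds, per-stage row counts), so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import deg as deg_mod
from . import enrichment, fuzzy, germination, network, seedling, simulate
from .io import write_gmt, write_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and selection sizes for a full pipeline run."""

    seed: int = 0
    k_top: int = 5
    k_bottom: int = 13
    lfc_cut: float = 1.0
    p_cut: float = 0.01
    enrich_cut: float = 0.01
    ppi_threshold: float = 0.9
    k_hubs: int = 10
    # the tolerant contrast plants fewer DEGs than the sensitive one
    # (tolerant accessions are less perturbed), a fraction of them shared
    shared_deg_fraction: float = 0.3
    tolerant_deg_ratio: float = 0.4
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.p_cut <= 1 or not 0 < self.enrich_cut <= 1:
            raise ValueError("p-value cutoffs must be in (0, 1]")
        if not 0 <= self.ppi_threshold <= 1:
            raise ValueError("ppi_threshold must be in [0, 1]")
        if self.lfc_cut < 0 or self.k_hubs < 1:
            raise ValueError("invalid lfc_cut or k_hubs")

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(seed=self.seed, **self.sim)


def _stage(manifest: list, name: str, **info) -> None:
    logger.info("[%s] %s", name, info)
    manifest.append({"stage": name, **info})


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic inputs and write results under ``outdir``.

    Returns a results bundle (in-memory tables keyed by stage).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim_config()
    manifest: list[dict] = []
    bundle: dict = {}

    # --- simulate + germination screen -----------------------------------
    census, classes = simulate.generate_germination(sim)
    write_tsv(census, out / "census.tsv")
    write_tsv(classes.reset_index(), out / "latent_classes.tsv")
    _stage(manifest, "simulate", rows=len(census), accessions=sim.n_accessions)

    traits = germination.germination_traits(census)
    rel_germ = germination.relative_traits(traits)
    rel_germ["group"] = "salt"
    write_tsv(traits, out / "germination_traits.tsv")
    write_tsv(rel_germ, out / "germination_relative.tsv")
    _stage(manifest, "germscreen", rows=len(rel_germ))

    germ_scores = fuzzy.evaluate(rel_germ)
    write_tsv(germ_scores, out / "germination_scores.tsv")
    tolerant, sensitive = fuzzy.select_extremes(
        germ_scores.set_index("accession")["total_score"],
        config.k_top, config.k_bottom)
    shortlist = classes.loc[tolerant + sensitive]
    bundle["germination_scores"] = germ_scores
    bundle["shortlist"] = shortlist

    # --- seedling screen + fuzzy evaluation ------------------------------
    seed_table = simulate.generate_seedling(sim, shortlist)
    write_tsv(seed_table, out / "seedling.tsv")
    rel_seed = seedling.relative_seedling_traits(seed_table)
    write_tsv(rel_seed, out / "seedling_relative.tsv")
    _stage(manifest, "seedscreen", rows=len(rel_seed))

    score_table = fuzzy.evaluate(rel_seed)
    write_tsv(score_table, out / "score_table.tsv")
    _stage(manifest, "evaluate", rows=len(score_table))
    bundle["score_table"] = score_table
    ranked = score_table.set_index("accession")
    most_tolerant = ranked["total_rank"].idxmin()
    most_sensitive = ranked["total_rank"].idxmax()
    bundle["most_tolerant"] = most_tolerant
    bundle["most_sensitive"] = most_sensitive

    # --- DEG pipeline: SS/SC and TS/TC contrasts --------------------------
    counts_s, lengths, truth_s = simulate.generate_counts(
        sim, conditions=("SC", "SS"), stream="counts")
    planted_s = truth_s.loc[truth_s["direction"] != "none", "direction"]
    n_shared = int(round(config.shared_deg_fraction * len(planted_s)))
    n_tol = max(int(round(config.tolerant_deg_ratio * len(planted_s))), n_shared)
    shared = planted_s.iloc[:n_shared]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(1000,)))
    pool = truth_s.index[truth_s["direction"] == "none"].to_numpy()
    extra = rng.choice(pool, size=n_tol - n_shared, replace=False)
    extra_dir = np.where(rng.random(len(extra)) < 0.5, "up", "down")
    planted_t = pd.concat([shared, pd.Series(extra_dir, index=extra)])
    counts_t, _, truth_t = simulate.generate_counts(
        sim, conditions=("TC", "TS"), planted=planted_t, stream="counts_b")
    write_tsv(counts_s.reset_index(), out / "counts_SS_SC.tsv")
    write_tsv(counts_t.reset_index(), out / "counts_TS_TC.tsv")
    write_tsv(lengths.reset_index(), out / "gene_lengths.tsv")

    calls = {}
    for label, counts, (ref, trt) in (("SS_SC", counts_s, ("SC", "SS")),
                                      ("TS_TC", counts_t, ("TC", "TS"))):
        conditions = pd.Series({c: c.split("_")[0] for c in counts.columns})
        table = deg_mod.de_test(counts, conditions, (trt, ref))
        called = deg_mod.call_degs(table, config.lfc_cut, config.p_cut)
        calls[label] = called
        write_tsv(called.reset_index(), out / f"deg_{label}.tsv")
        summary = deg_mod.deg_summary(called)
        _stage(manifest, f"deg_{label}", **summary)
        bundle[f"deg_{label}"] = called
    common = deg_mod.common_degs(calls["SS_SC"], calls["TS_TC"])
    bundle["common_degs"] = common
    write_tsv(pd.DataFrame({"gene": sorted(common)}), out / "common_degs.tsv")
    _stage(manifest, "deg_common", n_common=len(common))

    # --- functional profile ------------------------------------------------
    genes = counts_s.index
    term_map, tf_table = simulate.generate_annotations(sim, genes)
    write_gmt(term_map, out / "terms.gmt")
    write_tsv(tf_table, out / "tf_annotation.tsv")
    deg_set = set(calls["SS_SC"].index[calls["SS_SC"]["call"] != "ns"])
    enr = enrichment.enrich(deg_set, term_map, genes, sig_cut=config.enrich_cut)
    write_tsv(enr, out / "enrichment_SS_SC.tsv")
    tallies = enrichment.tf_tally(calls["SS_SC"], tf_table)
    write_tsv(tallies, out / "tf_tally_SS_SC.tsv")
    _stage(manifest, "enrich", n_terms=len(enr),
           n_significant=int(enr["significant"].sum()) if len(enr) else 0,
           n_tf_families=len(tallies))
    bundle["enrichment"] = enr
    bundle["tf_tally"] = tallies

    # --- PPI network + hubs ------------------------------------------------
    ppi_genes = sorted(deg_set) if len(deg_set) >= sim.ppi_nodes else list(genes)
    edges = simulate.generate_ppi(sim, ppi_genes)
    write_tsv(edges, out / "ppi_edges.tsv")
    graph = network.build_graph(edges, config.ppi_threshold)
    scores = network.mcc_scores(graph)
    hubs, sub = network.top_hubs(scores, graph, config.k_hubs)
    write_tsv(scores, out / "hub_scores.tsv")
    write_tsv(pd.DataFrame({"gene": hubs}), out / "hub_genes.tsv")
    _stage(manifest, "hub", n_edges=graph.number_of_edges(),
           n_nodes=graph.number_of_nodes(), n_hubs=len(hubs))
    bundle["hub_scores"] = scores
    bundle["hubs"] = hubs

    manifest_obj = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items() if k != "sim"},
        "stages": manifest,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest_obj, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest_obj
    return bundle
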