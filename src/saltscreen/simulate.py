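"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the screening/transcriptome pipeline can be exercised
without any download: this module emulates

* a germination screen — accession panel x {control, salt} x replicate
  dishes of 20 seeds censused on days 2/4/6/8, with latent tolerant /
  sensitive accession classes.  Each dish draws its final germinated count
  binomially from a class- and condition-dependent asymptote, then spreads
  germination times along a logistic-in-time curve, so cumulative censuses
  are monotone and bounded by construction;
* a seedling screen — a shortlist of accessions under control plus three
  NaCl concentrations, emitting the raw quantities the trait module
  consumes (fresh biomass, initial/final height, A663/A645 absorbances,
  Na+ and K+ contents), with salt depressing traits more for the sensitive
  class;
* RNA-seq count matrices — negative-binomial counts (Var = mu + alpha*mu^2,
  one alpha shared across genes) with log-uniform baseline means and a
  planted fraction of genes shifted by +/- a log2 effect, plus gene
  lengths;
* term and TF annotations — random gene sets per term across namespaces,
  and a 15-family transcription-factor assignment;
* protein-interaction graphs — planted cliques at confidence >= 0.9 over an
  Erdős–Rényi background below 0.9.

All randomness flows from one root seed through named substreams, so
adding or re-running one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "generate_germination",
    "generate_seedling",
    "generate_counts",
    "generate_annotations",
    "generate_ppi",
    "TF_FAMILIES",
]

TF_FAMILIES = [
    "bHLH", "WRKY", "AP2/ERF", "MYB-MYC", "HSF", "NAC", "GATA", "NF-Y",
    "bZIP", "C2H2", "MADS", "TCP", "Trihelix", "ARF", "DOF",
]

# fixed spawn keys: one independent substream per generator
_STREAMS = {
    "classes": 0,
    "germination": 1,
    "seedling": 2,
    "counts": 3,
    "counts_b": 4,
    "annotations": 5,
    "ppi": 6,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults follow the screening design this generator emulates: a
    104-accession germination panel in triplicate dishes of 20 seeds
    censused on days 2/4/6/8, a seedling stage at 0.13/0.17/0.22 mol/L
    NaCl, and two-condition RNA-seq with 3 replicates per group.
    """

    seed: int = 0
    # germination screen
    n_accessions: int = 104
    tolerant_fraction: float = 0.2
    n_seeds_per_dish: int = 20
    census_days: tuple[int, ...] = (2, 4, 6, 8)
    n_replicates: int = 3
    # seedling screen
    salt_levels: tuple[float, ...] = (0.13, 0.17, 0.22)
    # RNA-seq
    n_genes: int = 20000
    n_samples_per_group: int = 3
    deg_fraction: float = 0.05
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.05
    # annotations
    n_terms: int = 200
    genes_per_term: tuple[int, int] = (10, 100)
    tf_fraction: float = 0.03
    # PPI
    ppi_nodes: int = 300
    planted_clique_sizes: tuple[int, ...] = (14, 5, 3)
    background_edge_prob: float = 0.01
    # germination model shape
    germ_control_asymptote: float = 0.9
    germ_t50: float = 3.5
    germ_time_scale: float = 1.2
    germ_salt_delay: float = 1.0
    tolerant_salt_retention: float = 0.85
    sensitive_salt_retention: float = 0.35
    retention_sd: float = 0.06
    # seedling model shape: peak severity (fraction of trait lost at the
    # highest NaCl level) per latent class
    seedling_effect_tolerant: float = 0.2
    seedling_effect_sensitive: float = 0.6
    seedling_noise_sd: float = 0.05
    stress_duration: float = 6.0

    def __post_init__(self):
        for name in ("tolerant_fraction", "deg_fraction", "tf_fraction",
                     "background_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(s <= 0 for s in self.salt_levels):
            raise ValueError("salt_levels must be positive")
        if self.n_seeds_per_dish < 1:
            raise ValueError("n_seeds_per_dish must be >= 1")
        days = self.census_days
        if any(b <= a for a, b in zip(days, days[1:])) or any(d <= 0 for d in days):
            raise ValueError("census_days must be positive and strictly increasing")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],)))


def accession_ids(config: SimConfig) -> list[str]:
    return [f"FM{i + 1}" for i in range(config.n_accessions)]


def latent_classes(config: SimConfig) -> pd.Series:
    """Latent tolerant/sensitive label per accession (a fixed tolerant count
    rounded from ``tolerant_fraction``, positions shuffled)."""
    rng = _rng(config, "classes")
    ids = accession_ids(config)
    n_tol = int(round(config.tolerant_fraction * len(ids)))
    labels = np.array(["sensitive"] * len(ids), dtype=object)
    labels[rng.choice(len(ids), size=n_tol, replace=False)] = "tolerant"
    return pd.Series(labels, index=pd.Index(ids, name="accession"), name="class")


def _nb_draw(rng, mu, alpha, size=None):
    if alpha < 1e-8:
        return rng.poisson(mu, size=size)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


def generate_germination(config: SimConfig):
    """Germination censuses plus latent class labels.

    Returns ``(census, classes)``: a long table (accession, condition,
    replicate, day, germinated, sown, plumule_length, radicle_length —
    lengths on the final-census rows, repeated on earlier rows) and the
    tolerant/sensitive labels.  Cumulative counts are monotone and bounded
    by seeds sown by construction.
    """
    classes = latent_classes(config)
    rng = _rng(config, "germination")
    days = np.asarray(config.census_days, dtype=float)
    rows = []
    for acc in classes.index:
        tolerant = classes[acc] == "tolerant"
        retention_mean = (config.tolerant_salt_retention if tolerant
                          else config.sensitive_salt_retention)
        p_ctrl = float(np.clip(rng.normal(config.germ_control_asymptote, 0.04),
                               0.05, 1.0))
        retention = float(np.clip(rng.normal(retention_mean, config.retention_sd),
                                  0.0, 1.0))
        p_salt = p_ctrl * retention
        # length scale shrinks under salt roughly with the same retention
        pl_ctrl = max(rng.normal(12.0, 1.5), 0.5)
        rl_ctrl = max(rng.normal(15.0, 2.0), 0.5)
        for cond, p_asym, delay in (("control", p_ctrl, 0.0),
                                    ("salt", p_salt, config.germ_salt_delay)):
            shrink = 1.0 if cond == "control" else max(retention, 0.0)
            for rep in range(1, config.n_replicates + 1):
                n_germ = rng.binomial(config.n_seeds_per_dish, p_asym)
                times = rng.logistic(config.germ_t50 + delay,
                                     config.germ_time_scale, size=n_germ)
                cum = (times[:, None] <= days).sum(axis=0) if n_germ else \
                    np.zeros(len(days), dtype=int)
                pl = max(rng.normal(pl_ctrl * shrink, 0.8), 0.0)
                rl = max(rng.normal(rl_ctrl * shrink, 1.0), 0.0)
                for d, g in zip(config.census_days, cum):
                    rows.append({"accession": acc, "condition": cond,
                                 "replicate": rep, "day": int(d),
                                 "germinated": int(g),
                                 "sown": config.n_seeds_per_dish,
                                 "plumule_length": round(pl, 3),
                                 "radicle_length": round(rl, 3)})
    return pd.DataFrame(rows), classes


def generate_seedling(config: SimConfig, accession_classes: pd.Series) -> pd.DataFrame:
    """Raw seedling measurements per accession x concentration x replicate.

    Salt severity grows linearly with concentration up to the class's peak
    effect at the highest level; Na+ rises and the other traits fall with
    severity, multiplicative lognormal-ish noise throughout.
    """
    if accession_classes.empty:
        raise ValueError("accession_classes must be non-empty")
    rng = _rng(config, "seedling")
    top = max(config.salt_levels)
    concentrations = (0.0,) + tuple(config.salt_levels)
    sd = config.seedling_noise_sd
    rows = []
    for acc, cls in accession_classes.items():
        peak = (config.seedling_effect_tolerant if cls == "tolerant"
                else config.seedling_effect_sensitive)
        biomass0 = max(rng.normal(1.5, 0.15), 0.05)
        h0_mean = max(rng.normal(10.0, 1.0), 1.0)
        grow0 = max(rng.normal(1.0, 0.1), 0.05)
        a663_0 = max(rng.normal(0.60, 0.05), 0.01)
        a645_0 = max(rng.normal(0.25, 0.02), 0.01)
        na0 = max(rng.normal(2.0, 0.2), 0.1)
        k0 = max(rng.normal(30.0, 2.0), 1.0)
        for conc in concentrations:
            sev = peak * conc / top
            keep = 1.0 - sev
            for rep in range(1, config.n_replicates + 1):
                noise = lambda: float(np.exp(rng.normal(0.0, sd)))
                h_init = h0_mean * noise()
                grow = grow0 * keep * noise()
                rows.append({
                    "accession": acc, "concentration": conc, "replicate": rep,
                    "biomass": round(biomass0 * keep * noise(), 5),
                    "height_initial": round(h_init, 4),
                    "height_final": round(h_init + grow * config.stress_duration, 4),
                    "duration": config.stress_duration,
                    "A663": round(a663_0 * keep * noise(), 5),
                    "A645": round(a645_0 * keep * noise(), 5),
                    "Na": round(na0 * (1.0 + 4.0 * sev) * noise(), 4),
                    "K": round(k0 * keep * noise(), 4),
                })
    return pd.DataFrame(rows)


def generate_counts(config: SimConfig, *, conditions: tuple[str, str] = ("C", "S"),
                    planted: pd.Series | None = None, stream: str = "counts",
                    baseline_mean: float | None = None):
    """NB count matrix for a two-condition contrast with planted DEGs.

    Returns ``(counts, lengths, truth)``: a gene x sample integer
    DataFrame (columns ``{cond}_{i}``), gene lengths (nt), and the planted
    truth (``direction`` in {up, down, none} and ``true_lfc``).  Pass
    ``planted`` (a gene -> direction Series) to plant a chosen DEG set,
    e.g. to share DEGs between contrasts; otherwise a ``deg_fraction``
    subset is drawn.  ``stream`` names the substream so two contrasts get
    independent noise; ``baseline_mean`` fixes all baselines to one value
    (for moment checks) instead of the log-uniform draw.
    """
    if config.n_genes < 100:
        raise ValueError("n_genes must be >= 100 for stable downstream tests")
    rng = _rng(config, stream)
    genes = pd.Index([f"g{i + 1:05d}" for i in range(config.n_genes)], name="gene")
    if baseline_mean is None:
        mu0 = 10.0 ** rng.uniform(0.5, 3.5, size=config.n_genes)
    else:
        mu0 = np.full(config.n_genes, float(baseline_mean))
    lengths = pd.Series(rng.integers(200, 10001, size=config.n_genes),
                        index=genes, name="length")

    direction = pd.Series("none", index=genes, dtype=object)
    if planted is not None:
        direction.loc[planted.index] = planted.to_numpy()
    else:
        n_deg = int(round(config.deg_fraction * config.n_genes))
        chosen = rng.choice(config.n_genes, size=n_deg, replace=False)
        signs = rng.random(n_deg) < 0.5
        direction.iloc[chosen] = np.where(signs, "up", "down")
    true_lfc = np.where(direction == "up", config.lfc_effect,
                        np.where(direction == "down", -config.lfc_effect, 0.0))

    ref, treat = conditions
    mu_treat = mu0 * 2.0 ** true_lfc
    data = {}
    for i in range(1, config.n_samples_per_group + 1):
        data[f"{ref}_{i}"] = _nb_draw(rng, mu0, config.nb_dispersion)
    for i in range(1, config.n_samples_per_group + 1):
        data[f"{treat}_{i}"] = _nb_draw(rng, mu_treat, config.nb_dispersion)
    counts = pd.DataFrame(data, index=genes)
    truth = pd.DataFrame({"direction": direction, "true_lfc": true_lfc,
                          "base_mean": mu0}, index=genes)
    return counts, lengths, truth


def generate_annotations(config: SimConfig, gene_ids):
    """Random term -> gene-set map and TF-family table.

    Terms cycle through the BP / CC / MF / pathway namespaces with sizes
    uniform in ``genes_per_term``; a ``tf_fraction`` subset of genes gets
    one of the 15 TF family labels.
    """
    gene_ids = pd.Index(gene_ids)
    if gene_ids.empty:
        raise ValueError("gene_ids must be non-empty")
    rng = _rng(config, "annotations")
    lo, hi = config.genes_per_term
    namespaces = ["BP", "CC", "MF", "pathway"]
    terms = []
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(gene_ids))
        members = sorted(rng.choice(gene_ids.to_numpy(), size=size, replace=False))
        terms.append({"term": f"T{i + 1:04d}",
                      "namespace": namespaces[i % len(namespaces)],
                      "genes": members})
    term_map = pd.DataFrame(terms)

    n_tf = int(round(config.tf_fraction * len(gene_ids)))
    tf_genes = sorted(rng.choice(gene_ids.to_numpy(), size=n_tf, replace=False))
    fams = rng.choice(TF_FAMILIES, size=n_tf)
    tf = pd.DataFrame({"gene": tf_genes, "family": fams})
    return term_map, tf


def generate_ppi(config: SimConfig, gene_ids) -> pd.DataFrame:
    """Confidence-weighted edge list with planted high-confidence cliques.

    Disjoint cliques of the configured sizes get confidences in [0.9, 1];
    background pairs appear with probability ``background_edge_prob`` at
    confidences in [0.4, 0.9).  Returns columns geneA, geneB, confidence.
    """
    gene_ids = list(gene_ids)
    if config.ppi_nodes > len(gene_ids):
        raise ValueError("ppi_nodes exceeds the number of gene ids")
    rng = _rng(config, "ppi")
    nodes = sorted(rng.choice(np.asarray(gene_ids, dtype=object),
                              size=config.ppi_nodes, replace=False))
    if sum(config.planted_clique_sizes) > len(nodes):
        raise ValueError("planted cliques need more nodes than ppi_nodes provides")
    perm = rng.permutation(len(nodes))
    edges = {}
    pos = 0
    for size in config.planted_clique_sizes:
        members = [nodes[j] for j in perm[pos:pos + size]]
        pos += size
        for i in range(size):
            for j in range(i + 1, size):
                u, v = sorted((members[i], members[j]))
                edges[(u, v)] = float(rng.uniform(0.9, 1.0))
    if config.background_edge_prob > 0:
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                pair = (nodes[i], nodes[j])
                if pair in edges:
                    continue
                if rng.random() < config.background_edge_prob:
                    edges[pair] = float(rng.uniform(0.4, 0.8999))
    rows = [{"geneA": u, "geneB": v, "confidence": round(c, 4)}
            for (u, v), c in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["geneA", "geneB", "confidence"])
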