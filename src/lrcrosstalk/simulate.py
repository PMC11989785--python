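"""Seeded generators for the four-group co-culture study design.

The real study profiled intramuscular preadipocytes (IMAdC) and skeletal
muscle satellite cells (SMSC), each in monoculture and in transwell
co-culture, with three biological replicates per group.  No expression data
were released, so everything downstream is exercised on negative-binomial
counts with planted truth: known log2 fold changes, known ligand-receptor
pairs, and a planted block-model network.

All randomness flows from one integer seed via numpy SeedSequence spawning,
so a whole simulated study is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (
    CELL_TYPES,
    CULTURES,
    CountsMatrix,
    GeneSetCollection,
    LRDatabase,
    SampleSheet,
)

# canonical contrast names of the study design (first-listed group = log2FC numerator)
IMADC_CONTRAST = "IMAdC_mono_vs_co"
SMSC_CONTRAST = "SMSC_mono_vs_co"
CO_CONTRAST = "CO_IMAdC_vs_CO_SMSC"

#: contrast name -> ((cell, culture) numerator, (cell, culture) denominator)
STUDY_CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    IMADC_CONTRAST: (("IMAdC", "mono"), ("IMAdC", "co")),
    CO_CONTRAST: (("IMAdC", "co"), ("SMSC", "co")),
    SMSC_CONTRAST: (("SMSC", "mono"), ("SMSC", "co")),
}


class ConfigError(ValueError):
    """Raised for contradictory or impossible simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic four-group count experiment.

    Defaults mirror the study scale: 4 groups x 3 replicates and a
    desk-scale 2,000-gene transcriptome.  Baseline abundance is log2-normal;
    dispersion is the NB alpha in var = mu + alpha * mu^2, either constant
    or gamma-distributed per gene.
    """

    n_genes: int = 2000
    n_reps_per_group: int = 3
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    dispersion_gamma_shape: float | None = None  # if set, alpha_g ~ Gamma(shape, dispersion/shape)
    planted_de: tuple[tuple[str, str, float], ...] = ()  # (gene, contrast, true_log2fc)
    library_size_factors: tuple[float, ...] | None = None  # per sample, else all 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps_per_group < 1:
            raise ConfigError("n_genes and n_reps_per_group must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        seen: set[tuple[str, str]] = set()
        for gene, contrast, _ in self.planted_de:
            if contrast not in STUDY_CONTRASTS:
                raise ConfigError(f"unknown contrast {contrast!r} in planted_de")
            if (gene, contrast) in seen:
                raise ConfigError(f"gene {gene!r} planted twice in contrast {contrast!r}")
            seen.add((gene, contrast))
        if self.library_size_factors is not None:
            n_samples = 4 * self.n_reps_per_group
            if len(self.library_size_factors) != n_samples:
                raise ConfigError(f"library_size_factors must have length {n_samples}")
            if any(s <= 0 for s in self.library_size_factors):
                raise ConfigError("library size factors must be positive")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth returned alongside every generated object."""

    true_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    true_lr_pairs: list[dict] = field(default_factory=list)  # CrosstalkPair skeletons
    true_modules: dict[str, int] = field(default_factory=dict)


def _study_sheet(n_reps: int) -> SampleSheet:
    rows = []
    for cell in CELL_TYPES:
        for culture in CULTURES:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{cell}_{culture}_{rep}",
                        "cell_type": cell,
                        "culture": culture,
                        "replicate": rep,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def generate_counts(config: SimulationConfig) -> tuple[CountsMatrix, SyntheticTruth]:
    """Draw NB counts for the 2x2 study design with planted fold changes.

    Gene means are ``s_j * 2**(baseline_g + sum of planted group offsets)``;
    a planted (gene, contrast, lfc) raises the contrast's numerator group by
    lfc on the log2 scale relative to the denominator group.  Counts are
    NB(mean mu, var mu + alpha*mu^2); a dispersion below 1e-8 falls back to
    the Poisson limit.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_disp, rng_counts = [np.random.default_rng(s) for s in ss.spawn(3)]

    genes = config.gene_names()
    sheet = _study_sheet(config.n_reps_per_group)
    samples = sheet.sample_ids
    n_samples = len(samples)

    baseline = rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    if config.dispersion_gamma_shape is not None:
        shape = config.dispersion_gamma_shape
        alpha = rng_disp.gamma(shape, config.dispersion / shape, config.n_genes)
    else:
        alpha = np.full(config.n_genes, config.dispersion)

    # per-gene, per-group log2 offsets from planted effects
    gene_index = {g: i for i, g in enumerate(genes)}
    group_keys = [(c, u) for c in CELL_TYPES for u in CULTURES]
    group_index = {k: i for i, k in enumerate(group_keys)}
    offsets = np.zeros((config.n_genes, len(group_keys)))
    truth = SyntheticTruth()
    for gene, contrast, lfc in config.planted_de:
        if gene not in gene_index:
            raise ConfigError(f"planted gene {gene!r} not in the generated matrix")
        first, _second = STUDY_CONTRASTS[contrast]
        offsets[gene_index[gene], group_index[first]] += lfc
        truth.true_log2fc[(gene, contrast)] = lfc

    sf = (
        np.asarray(config.library_size_factors, dtype=float)
        if config.library_size_factors is not None
        else np.ones(n_samples)
    )
    group_of_sample = [
        group_index[(ct, cu)] for ct, cu in zip(sheet.table["cell_type"], sheet.table["culture"])
    ]

    mu = np.empty((config.n_genes, n_samples))
    for j in range(n_samples):
        mu[:, j] = sf[j] * 2.0 ** (baseline + offsets[:, group_of_sample[j]])

    counts = np.empty_like(mu, dtype="int64")
    alpha_col = alpha[:, None] * np.ones_like(mu)
    poisson_like = alpha_col < 1e-8
    if poisson_like.any():
        counts[poisson_like] = rng_counts.poisson(mu[poisson_like])
    nb_mask = ~poisson_like
    if nb_mask.any():
        n_param = 1.0 / alpha_col[nb_mask]
        p_param = n_param / (n_param + mu[nb_mask])
        counts[nb_mask] = rng_counts.negative_binomial(n_param, p_param)

    matrix = CountsMatrix(pd.DataFrame(counts, index=genes, columns=samples), sheet)
    return matrix, truth


# ---------------------------------------------------------------------------
# ligand-receptor scenario


def _default_paracrine_rule() -> dict:
    # method-1 paracrine SMSC -> IMAdC: ligand up in SMSC mono-vs-co,
    # receptor down in IMAdC mono-vs-co
    return {
        "mode": "paracrine",
        "method": 1,
        "ligand_contrast": SMSC_CONTRAST,
        "ligand_status_required": "UP",
        "receptor_contrast": IMADC_CONTRAST,
        "receptor_status_required": "DOWN",
        "source_cell": "SMSC",
        "target_cell": "IMAdC",
    }


def generate_lr_scenario(
    config: SimulationConfig,
    n_true_pairs: int,
    n_decoys: int,
    rule: dict | None = None,
) -> tuple[LRDatabase, SyntheticTruth]:
    """Build an LR database whose true pairs ride on planted DE genes.

    True-pair ligands/receptors are drawn from genes already planted in the
    rule's contrasts with the required direction; decoy pairs use genes with
    no planted effect anywhere, so a correct crosstalk inference recovers
    exactly the true pairs.
    """
    rule = rule or _default_paracrine_rule()
    planted = {(g, c): lfc for g, c, lfc in config.planted_de}
    planted_genes = {g for g, _, _ in config.planted_de}

    def hosts(contrast: str, required: str) -> list[str]:
        out = []
        for (g, c), lfc in planted.items():
            if c != contrast:
                continue
            if required == "UP" and lfc <= 0:
                continue
            if required == "DOWN" and lfc >= 0:
                continue
            out.append(g)
        return sorted(out)

    ligand_hosts = hosts(rule["ligand_contrast"], rule["ligand_status_required"])
    receptor_hosts = [
        g
        for g in hosts(rule["receptor_contrast"], rule["receptor_status_required"])
        if g not in ligand_hosts
    ]
    if n_true_pairs > min(len(ligand_hosts), len(receptor_hosts)):
        raise ConfigError(
            f"requested {n_true_pairs} true pairs but only "
            f"{len(ligand_hosts)} ligand / {len(receptor_hosts)} receptor hosts are planted"
        )

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    ligands = list(rng.choice(ligand_hosts, size=n_true_pairs, replace=False))
    receptors = list(rng.choice(receptor_hosts, size=n_true_pairs, replace=False))

    null_genes = sorted(set(config.gene_names()) - planted_genes)
    if 2 * n_decoys > len(null_genes):
        raise ConfigError("not enough non-DE genes for the requested decoy pairs")
    decoy_genes = list(rng.choice(null_genes, size=2 * n_decoys, replace=False))

    pairs = set(zip(ligands, receptors))
    pairs |= set(zip(decoy_genes[:n_decoys], decoy_genes[n_decoys:]))

    truth = SyntheticTruth()
    for lig, rec in zip(ligands, receptors):
        truth.true_lr_pairs.append(
            {
                "ligand": lig,
                "receptor": rec,
                "mode": rule["mode"],
                "method": rule["method"],
                "source_cell": rule["source_cell"],
                "target_cell": rule["target_cell"],
            }
        )
    db = LRDatabase(frozenset(pairs), provenance="synthetic")
    return db, truth


# ---------------------------------------------------------------------------
# planted module network


def generate_block_network(
    module_sizes: list[int],
    p_within: float,
    p_between: float,
    seed: int,
    gene_names: list[str] | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Stochastic block model over named genes with module labels as truth."""
    if not 0 <= p_within <= 1 or not 0 <= p_between <= 1:
        raise ConfigError("block-model probabilities must lie in [0, 1]")
    if p_within <= p_between:
        raise ConfigError("p_within must exceed p_between for planted modules")
    n_total = sum(module_sizes)
    if gene_names is None:
        width = len(str(n_total))
        gene_names = [f"N{i:0{width}d}" for i in range(1, n_total + 1)]
    if len(gene_names) != n_total:
        raise ConfigError("gene_names length must equal the total module size")

    rng = np.random.default_rng(seed)
    labels: list[int] = []
    for m, size in enumerate(module_sizes, start=1):
        labels.extend([m] * size)

    graph = nx.Graph()
    graph.add_nodes_from(gene_names)
    for i in range(n_total):
        for j in range(i + 1, n_total):
            p = p_within if labels[i] == labels[j] else p_between
            if rng.random() < p:
                graph.add_edge(gene_names[i], gene_names[j])

    truth = SyntheticTruth(true_modules=dict(zip(gene_names, labels)))
    return graph, truth


# ---------------------------------------------------------------------------
# gene sets with planted enrichment


def generate_gene_sets(
    universe: list[str],
    enriched_members: list[str],
    n_null_sets: int,
    set_size: int,
    seed: int,
) -> GeneSetCollection:
    """One set holding the planted genes plus seeded random null sets."""
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    if enriched_members:
        sets["SET_TRUE"] = ("planted-effect gene set", frozenset(enriched_members))
    for i in range(1, n_null_sets + 1):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets[f"SET_NULL{i:03d}"] = (f"random set {i}", frozenset(members))
    return GeneSetCollection(sets)


def with_planted_de(config: SimulationConfig, planted: list[tuple[str, str, float]]) -> SimulationConfig:
    """Convenience: return a copy of config with planted effects attached."""
    return replace(config, planted_de=tuple(planted))
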