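"""End-to-end orchestration of the co-culture analysis.

One config drives the whole run: QC -> differential expression (all
contrasts) -> overlap partition -> enrichment (UP and DOWN lists per
contrast) -> network hubs/modules -> ligand-receptor crosstalk.  Every
stage writes plain TSVs under a fixed directory layout plus a JSON manifest
(config echo, seed, per-stage row counts), and identical config + seed
yields byte-identical output trees.

In synthetic mode the inputs are generated by the simulate module with
planted truth, which is also written out for recovery checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosstalk import default_rules, run_crosstalk
from .diffexpr import (
    ContrastResult,
    ContrastSpec,
    estimate_dispersion,
    filter_low_counts,
    nb_wald_contrast,
    partition_overlap,
    size_factors,
    study_contrasts,
)
from .enrichment import enrichment_report, ora
from .io_formats import (
    CountsMatrix,
    GeneSetCollection,
    LRDatabase,
    read_counts,
    read_edge_list,
    read_gene_lengths,
    read_gmt,
    read_lr_database,
    write_counts,
    write_edge_list,
    write_gene_lengths,
    write_gmt,
    write_lr_database,
    write_table,
)
from .network import hub_ranking, induced_subgraph, kmeans_modules, pathway_gene_network
from .qc import fpkm, log_transform, qc_summary
from .simulate import (
    CO_CONTRAST,
    IMADC_CONTRAST,
    SMSC_CONTRAST,
    SimulationConfig,
    SyntheticTruth,
    generate_block_network,
    generate_counts,
    generate_gene_sets,
    generate_lr_scenario,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs or a simulation recipe, thresholds, seed."""

    mode: str = "synthetic"  # synthetic | real
    seed: int = 0
    alpha: float = 0.05
    lfc_min: float = 1.0
    k_modules: int = 3
    top_n_hubs: int = 10
    top_m_terms: int = 10
    min_total_counts: int = 10
    contrasts: list[ContrastSpec] = field(default_factory=study_contrasts)
    synthetic: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        contrasts = [
            ContrastSpec(c["name"], tuple(c["group_first"]), tuple(c["group_second"]))
            for c in raw.pop("contrasts", [])
        ] or study_contrasts()
        return cls(contrasts=contrasts, **raw)

    def echo(self) -> dict[str, Any]:
        """Config as plain JSON-able data (for the manifest)."""
        d = asdict(self)
        d["contrasts"] = [
            {"name": c.name, "group_first": list(c.group_first), "group_second": list(c.group_second)}
            for c in self.contrasts
        ]
        return d


REQUIRED_INPUT_KEYS = ("counts", "sample_sheet", "lengths", "lr_db", "gmt", "edge_list")


def validate(config: PipelineConfig) -> list[str]:
    """Dry-run structural checks; returns all failures at once."""
    failures: list[str] = []
    if config.mode == "real":
        for key in REQUIRED_INPUT_KEYS:
            path = config.inputs.get(key)
            if not path:
                failures.append(f"real mode requires inputs.{key}")
            elif not Path(path).exists():
                failures.append(f"inputs.{key} does not exist: {path}")
        if not failures:
            try:
                counts = read_counts(config.inputs["counts"], config.inputs["sample_sheet"])
                for spec in config.contrasts:
                    for grp in (spec.group_first, spec.group_second):
                        n = len(counts.sheet.group(*grp))
                        if n < 2:
                            failures.append(
                                f"group {grp} has {n} replicate(s); contrasts need >= 2"
                            )
            except Exception as exc:  # surface parse errors as validation failures
                failures.append(str(exc))
    else:
        try:
            _simulation_config(config)
        except Exception as exc:
            failures.append(str(exc))
    if config.alpha <= 0 or config.alpha >= 1:
        failures.append("alpha must lie in (0, 1)")
    if config.lfc_min < 0:
        failures.append("lfc_min must be non-negative")
    return failures


# ---------------------------------------------------------------------------
# synthetic study assembly


def default_planted_effects(n_genes: int) -> list[tuple[str, str, float]]:
    """Planted DE genes for the three study contrasts on disjoint gene blocks.

    Effect magnitudes alternate between 2 and 3 on the log2 scale; the IMAdC
    mono-vs-co contrast carries the most effects, the SMSC contrast the
    fewest, echoing the asymmetry the co-culture design expects.
    """
    width = len(str(n_genes))

    def gene(i: int) -> str:
        return f"G{i:0{width}d}"

    planted: list[tuple[str, str, float]] = []
    blocks = [
        (IMADC_CONTRAST, 60, 40),
        (CO_CONTRAST, 40, 20),
        (SMSC_CONTRAST, 10, 5),
    ]
    i = 1
    for contrast, n_up, n_down in blocks:
        for j in range(n_up):
            planted.append((gene(i), contrast, 2.0 + (j % 2)))
            i += 1
        for j in range(n_down):
            planted.append((gene(i), contrast, -(2.0 + (j % 2))))
            i += 1
    if i - 1 > n_genes:
        raise ValueError(f"n_genes={n_genes} too small for the default planted design")
    return planted


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    syn = dict(config.synthetic)
    syn.pop("n_true_lr_pairs", None)
    syn.pop("n_decoy_lr_pairs", None)
    syn.pop("module_sizes", None)
    syn.pop("p_within", None)
    syn.pop("p_between", None)
    syn.pop("n_null_sets", None)
    syn.pop("set_size", None)
    syn.setdefault("n_genes", 2000)
    syn.setdefault("baseline_log2_mean", 6.0)
    syn.setdefault("baseline_log2_sd", 1.5)
    if "planted_de" not in syn:
        syn["planted_de"] = tuple(default_planted_effects(syn["n_genes"]))
    else:
        syn["planted_de"] = tuple(tuple(p) for p in syn["planted_de"])
    syn["seed"] = config.seed
    return SimulationConfig(**syn)


@dataclass
class StudyInputs:
    counts: CountsMatrix
    lengths: pd.Series
    lr_db: LRDatabase
    gene_sets: GeneSetCollection
    network: "Any"
    truth: SyntheticTruth | None = None


def simulate_study(config: PipelineConfig) -> StudyInputs:
    """Generate the full synthetic input bundle with planted truth."""
    sim = _simulation_config(config)
    syn = config.synthetic
    counts, truth = generate_counts(sim)

    ss = np.random.SeedSequence(config.seed)
    aux = ss.spawn(8)
    rng_len = np.random.default_rng(aux[5])
    lengths = pd.Series(
        rng_len.integers(200, 10001, sim.n_genes), index=counts.gene_ids, name="length_bp"
    )

    lr_db, lr_truth = generate_lr_scenario(
        sim,
        n_true_pairs=syn.get("n_true_lr_pairs", 4),
        n_decoys=syn.get("n_decoy_lr_pairs", 10),
    )
    truth.true_lr_pairs = lr_truth.true_lr_pairs

    # planted modules over the IMAdC-contrast DE genes
    imadc_genes = sorted(g for g, c, _ in sim.planted_de if c == IMADC_CONTRAST)
    module_sizes = syn.get("module_sizes", [15, 15, 15])
    n_net = sum(module_sizes)
    net_genes = imadc_genes[:n_net]
    if len(net_genes) < n_net:
        raise ValueError("not enough IMAdC-contrast planted genes to host the network modules")
    network, net_truth = generate_block_network(
        module_sizes,
        syn.get("p_within", 0.45),
        syn.get("p_between", 0.02),
        seed=int(aux[6].generate_state(1)[0] % 2**31),
        gene_names=net_genes,
    )
    truth.true_modules = net_truth.true_modules

    up_imadc = sorted(g for g, c, lfc in sim.planted_de if c == IMADC_CONTRAST and lfc > 0)
    gene_sets = generate_gene_sets(
        counts.gene_ids,
        enriched_members=up_imadc,
        n_null_sets=syn.get("n_null_sets", 20),
        set_size=syn.get("set_size", 25),
        seed=int(aux[7].generate_state(1)[0] % 2**31),
    )
    return StudyInputs(counts, lengths, lr_db, gene_sets, network, truth)


def load_study(config: PipelineConfig) -> StudyInputs:
    inp = config.inputs
    counts = read_counts(inp["counts"], inp["sample_sheet"])
    return StudyInputs(
        counts=counts,
        lengths=read_gene_lengths(inp["lengths"]),
        lr_db=read_lr_database(inp["lr_db"]),
        gene_sets=read_gmt(inp["gmt"]),
        network=read_edge_list(inp["edge_list"]),
        truth=None,
    )


def write_inputs(study: StudyInputs, out: Path) -> None:
    d = out / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    write_counts(study.counts, d / "counts.tsv", d / "samples.tsv")
    write_gene_lengths(study.lengths, d / "lengths.tsv")
    write_lr_database(study.lr_db, d / "lr_db.tsv")
    write_gmt(study.gene_sets, d / "gene_sets.gmt")
    write_edge_list(study.network, d / "network_edges.tsv")
    if study.truth is not None:
        rows = [
            {"gene": g, "contrast": c, "true_log2fc": lfc}
            for (g, c), lfc in sorted(study.truth.true_log2fc.items())
        ]
        write_table(pd.DataFrame(rows, columns=["gene", "contrast", "true_log2fc"]), d / "truth_de.tsv")
        write_table(
            pd.DataFrame(study.truth.true_lr_pairs).sort_values(["ligand", "receptor"]).reset_index(drop=True)
            if study.truth.true_lr_pairs
            else pd.DataFrame(columns=["ligand", "receptor", "mode", "method", "source_cell", "target_cell"]),
            d / "truth_lr_pairs.tsv",
        )
        mod_rows = [{"gene": g, "module": m} for g, m in sorted(study.truth.true_modules.items())]
        write_table(pd.DataFrame(mod_rows, columns=["gene", "module"]), d / "truth_modules.tsv")


# ---------------------------------------------------------------------------
# the run itself


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("qc")
def _run_qc(study: StudyInputs, out: Path, manifest: dict) -> None:
    expr = log_transform(fpkm(study.counts, study.lengths))
    summary = qc_summary(expr)
    d = out / "qc"
    write_table(expr.values.round(6), d / "log10_fpkm_plus1.tsv", index=True)
    write_table(summary.correlation.round(6), d / "correlation.tsv", index=True)
    write_table(summary.pca_scores.round(6), d / "pca_scores.tsv", index=True)
    write_table(
        pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(summary.pca_var_explained))],
                "var_explained": np.round(summary.pca_var_explained, 6),
            }
        ),
        d / "pca_var_explained.tsv",
    )
    with open(d / "hclust.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "method": summary.linkage_method,
                "distance": summary.distance,
                "leaf_order": summary.hclust_order,
                "linkage": np.round(summary.hclust_linkage, 8).tolist(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    manifest["stages"]["qc"] = {"n_samples": int(expr.values.shape[1]), "n_genes": int(expr.values.shape[0])}


@_stage("diffexpr")
def _run_de(
    study: StudyInputs, config: PipelineConfig, out: Path, manifest: dict
) -> dict[str, ContrastResult]:
    filtered = filter_low_counts(study.counts, config.min_total_counts)
    factors = size_factors(filtered)
    dispersions = estimate_dispersion(filtered, factors)
    results: dict[str, ContrastResult] = {}
    for spec in config.contrasts:
        res = nb_wald_contrast(
            filtered,
            spec,
            dispersions,
            factors,
            alpha=config.alpha,
            lfc_min=config.lfc_min,
        )
        results[spec.name] = res
        d = out / "de" / spec.name
        table = res.table.sort_values(["padj", "gene"], kind="stable").round(6)
        write_table(table, d / "results.tsv", index=True)
        manifest["stages"].setdefault("diffexpr", {})[spec.name] = {
            "n_genes": len(res.table),
            "n_up": res.n_up,
            "n_down": res.n_down,
        }
    partition = partition_overlap(list(results.values()))
    d = out / "de"
    part_table = pd.DataFrame(
        {"category": partition.categories, **{c: partition.membership[c] for c in partition.membership}}
    )
    part_table = part_table[part_table["category"] != "NS"].sort_index()
    write_table(part_table, d / "partition.tsv", index=True)
    write_table(partition.region_counts, d / "venn_regions.tsv")
    manifest["stages"]["partition"] = {
        cat: int((partition.categories == cat).sum()) for cat in ("UP", "DOWN", "CONFLICT")
    }
    return results


@_stage("enrichment")
def _run_enrichment(
    study: StudyInputs,
    config: PipelineConfig,
    results: dict[str, ContrastResult],
    out: Path,
    manifest: dict,
) -> dict[tuple[str, str], pd.DataFrame]:
    universe = set(next(iter(results.values())).table.index)
    all_rows: dict[tuple[str, str], pd.DataFrame] = {}
    for name, res in results.items():
        for direction in ("UP", "DOWN"):
            degs = res.deg_genes(direction)
            rows = ora(degs, universe, study.gene_sets, alpha=config.alpha)
            d = out / "enrichment" / name / direction.lower()
            write_table(rows.round({"p": 10, "padj": 10}), d / "ora.tsv")
            top, incidence = enrichment_report(rows, config.top_m_terms)
            write_table(top.round({"p": 10, "padj": 10}), d / "top_terms.tsv")
            write_table(incidence, d / "incidence.tsv")
            all_rows[(name, direction)] = rows
            manifest["stages"].setdefault("enrichment", {})[f"{name}/{direction}"] = {
                "n_terms_tested": len(rows),
                "n_significant": int(rows["significant"].sum()) if len(rows) else 0,
            }
    return all_rows


@_stage("network")
def _run_network(
    study: StudyInputs,
    config: PipelineConfig,
    results: dict[str, ContrastResult],
    enrich: dict[tuple[str, str], pd.DataFrame],
    out: Path,
    manifest: dict,
) -> None:
    focal = config.contrasts[0].name
    res = results[focal]
    d = out / "network"
    d.mkdir(parents=True, exist_ok=True)
    sub = induced_subgraph(study.network, res.deg_genes())
    write_edge_list(sub, d / "deg_subnetwork.tsv")
    hubs = hub_ranking(sub, config.top_n_hubs)
    write_table(hubs, d / "hubs.tsv")
    info: dict[str, Any] = {
        "focal_contrast": focal,
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
        "embedding": "normalized-laplacian spectral + kmeans",
    }
    non_isolated = sum(1 for n in sub.nodes if sub.degree(n) > 0)
    if non_isolated >= config.k_modules:
        assignment = kmeans_modules(sub, k=config.k_modules, seed=config.seed)
        write_table(assignment.as_table(), d / "modules.tsv")
        write_table(
            pd.DataFrame({"gene": sorted(assignment.isolated)}), d / "isolated_nodes.tsv"
        )
        info["k"] = config.k_modules
        info["n_isolated"] = len(assignment.isolated)
    else:
        info["modules"] = "skipped: fewer non-isolated nodes than k"
    incidence, co_edges = pathway_gene_network(
        enrich[(focal, "UP")], res.table, top_pathways=config.top_m_terms
    )
    write_table(incidence.round(6), d / "pathway_incidence.tsv")
    write_table(co_edges, d / "pathway_comembership.tsv")
    manifest["stages"]["network"] = info


@_stage("crosstalk")
def _run_crosstalk_stage(
    study: StudyInputs,
    config: PipelineConfig,
    results: dict[str, ContrastResult],
    out: Path,
    manifest: dict,
) -> pd.DataFrame:
    table = run_crosstalk(results, study.lr_db)
    d = out / "crosstalk"
    d.mkdir(parents=True, exist_ok=True)
    write_table(table.round(6), d / "pairs.tsv")
    for (mode, method, src, tgt), chunk in table.groupby(
        ["mode", "method", "source_cell", "target_cell"], sort=True
    ):
        links = chunk.sort_values("rank")[["ligand", "receptor"]]
        write_table(links, d / f"links_{mode}_m{method}_{src}_to_{tgt}.tsv")
    manifest["stages"]["crosstalk"] = {"n_pairs": len(table)}
    return table


def run(config: PipelineConfig, output_dir: str | Path) -> Path:
    """Execute every stage; returns the output directory.

    The manifest (``manifest.json``) echoes the config (minus any output
    paths), the seed, the package version, and per-stage row counts; it
    contains no timestamps, so reruns are byte-identical.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures = validate(config)
    if failures:
        raise PipelineError("config validation failed: " + "; ".join(failures))

    manifest: dict[str, Any] = {
        "package": "lrcrosstalk",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "stages": {},
    }

    if config.mode == "synthetic":
        study = simulate_study(config)
        write_inputs(study, out)
    else:
        study = load_study(config)

    _run_qc(study, out, manifest)
    results = _run_de(study, config, out, manifest)
    enrich = _run_enrichment(study, config, results, out, manifest)
    _run_network(study, config, results, enrich, out, manifest)
    _run_crosstalk_stage(study, config, results, out, manifest)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out
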