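"""Negative-binomial Wald differential expression between sample groups.

The model is the standard bulk RNA-seq one: counts K_gj ~ NB(mean s_j * q_g,
variance mu + alpha_g * mu^2), with median-of-ratios size factors s_j,
method-of-moments dispersion alpha_g shrunk toward a fitted mean-dispersion
trend, and a Wald test on the log2 ratio of normalized group means.  DEG
status uses the strict thresholds |log2FC| > lfc_min with BH-adjusted
p < alpha.

The log2FC orientation puts the first-listed group of a contrast in the
numerator, so in "IMAdC_mono_vs_co" a positive log2FC means higher
expression in monoculture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_formats import CountsMatrix
from .simulate import STUDY_CONTRASTS

ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
LOW_COUNT_MIN_TOTAL = 10


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison; the first group is the log2FC numerator."""

    name: str
    group_first: tuple[str, str]  # (cell_type, culture)
    group_second: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group_first == self.group_second:
            raise ValueError("contrast groups must be disjoint")


def study_contrasts() -> list[ContrastSpec]:
    """The three contrasts of the co-culture design."""
    return [ContrastSpec(name, first, second) for name, (first, second) in STUDY_CONTRASTS.items()]


@dataclass
class ContrastResult:
    """Per-gene Wald statistics for one contrast.

    ``table`` columns: mean_first, mean_second, log2fc, se, wald_z, p, padj,
    status (UP/DOWN/NS).
    """

    name: str
    table: pd.DataFrame
    alpha: float | None = None
    lfc_min: float | None = None

    @property
    def n_up(self) -> int:
        return int((self.table["status"] == "UP").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["status"] == "DOWN").sum())

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down

    def deg_genes(self, direction: str | None = None) -> set[str]:
        if direction is None:
            mask = self.table["status"].isin(["UP", "DOWN"])
        else:
            mask = self.table["status"] == direction
        return set(self.table.index[mask])


def filter_low_counts(counts: CountsMatrix, min_total: int = LOW_COUNT_MIN_TOTAL) -> CountsMatrix:
    """Drop genes with fewer than ``min_total`` summed counts.

    Very low-count genes destabilize moment dispersion estimates and cannot
    be called differential anyway.
    """
    keep = counts.counts.sum(axis=1) >= min_total
    return CountsMatrix(counts.counts.loc[keep], counts.sheet)


def size_factors(counts: CountsMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean rescaled to 1.

    For each sample, the factor is the median over genes (positive in every
    sample) of count / geometric-mean reference; the vector is then divided
    by its own geometric mean.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter low-count genes first"
        )
    pos = mat[all_positive]
    log_ref = np.log(pos).mean(axis=1)
    ratios = np.log(pos) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def estimate_dispersion(
    counts: CountsMatrix,
    factors: pd.Series | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion: method of moments + trend shrinkage.

    On normalized counts, alpha_raw = max(floor, (pooled within-group
    variance - mean) / mean^2); a lowess mean-dispersion trend is fitted on
    log10 mean and each estimate is shrunk halfway toward it.  Degenerate
    genes (zero mean or zero variance) receive the floor.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    sheet = counts.sheet.table
    groups = list(sheet.groupby(["cell_type", "culture"], sort=True).groups.values())
    col_of = {s: i for i, s in enumerate(counts.sample_ids)}

    n_total = norm.shape[1]
    n_groups = 0
    ss_within = np.zeros(norm.shape[0])
    for idx in groups:
        cols = [col_of[s] for s in sheet.loc[idx, "sample_id"]]
        if len(cols) < 2:
            continue
        sub = norm[:, cols]
        ss_within += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_groups += 1
    df = n_total - n_groups
    if df < 1:
        raise ValueError("need at least 2 replicates per group to estimate dispersion")
    var_within = ss_within / df
    mean = norm.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var_within - mean) / mean**2
    raw = np.where(np.isfinite(raw), raw, alpha_floor)
    raw = np.maximum(raw, alpha_floor)

    ok = mean > 0
    if ok.sum() >= 10:
        trend = np.full_like(raw, alpha_floor)
        fitted = lowess(raw[ok], np.log10(mean[ok]), frac=0.5, return_sorted=False)
        trend[ok] = np.maximum(fitted, alpha_floor)
        shrunk = np.maximum(0.5 * raw + 0.5 * trend, alpha_floor)
    else:
        shrunk = raw
    shrunk[~ok] = alpha_floor
    return pd.Series(shrunk, index=counts.gene_ids, name="dispersion")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_contrast(
    counts: CountsMatrix,
    spec: ContrastSpec,
    dispersions: pd.Series,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    use_adjusted: bool = True,
) -> ContrastResult:
    """Wald test on the log2 ratio of normalized group means.

    A pseudocount of 0.5 enters both means only when either mean falls below
    it, keeping the fold change finite near zero without biasing expressed
    genes.  The SE comes from the delta method on the NB variance of each
    group mean; p-values are two-sided normal and BH-adjusted across genes.
    """
    if factors is None:
        factors = size_factors(counts)
    sheet = counts.sheet
    first = sheet.group(*spec.group_first)
    second = sheet.group(*spec.group_second)
    if not first or not second:
        raise ValueError(f"contrast {spec.name!r}: empty group")
    if len(first) < 2 or len(second) < 2:
        raise ValueError(f"contrast {spec.name!r}: each group needs >= 2 replicates")

    norm = counts.counts / factors
    alpha_g = dispersions.loc[counts.gene_ids].to_numpy()

    def group_stats(samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = norm[samples]
        m = sub.mean(axis=1).to_numpy()
        s = factors.loc[samples].to_numpy()
        return m, s

    m1, s1 = group_stats(first)
    m2, s2 = group_stats(second)

    needs_pc = (m1 < PSEUDOCOUNT) | (m2 < PSEUDOCOUNT)
    m1p = np.where(needs_pc, m1 + PSEUDOCOUNT, m1)
    m2p = np.where(needs_pc, m2 + PSEUDOCOUNT, m2)
    log2fc = np.log2(m1p / m2p)

    # Var(mean of K_gj/s_j) = (1/n^2) * sum_j (mu/s_j + alpha*mu^2)
    def mean_var(mu: np.ndarray, s: np.ndarray) -> np.ndarray:
        n = len(s)
        return (mu[:, None] / s[None, :] + alpha_g[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2

    ln2sq = np.log(2.0) ** 2
    var_lfc = mean_var(m1p, s1) / (m1p**2 * ln2sq) + mean_var(m2p, s2) / (m2p**2 * ln2sq)
    se = np.sqrt(var_lfc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(p)

    table = pd.DataFrame(
        {
            "mean_first": m1,
            "mean_second": m2,
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p": p,
            "padj": padj,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    result = ContrastResult(spec.name, table)
    return classify_degs(result, lfc_min=lfc_min, alpha=alpha, use_adjusted=use_adjusted)


def classify_degs(
    result: ContrastResult,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> ContrastResult:
    """Stamp UP/DOWN/NS statuses at strict thresholds.

    UP means padj < alpha and log2fc > lfc_min (strictly); DOWN mirrors it.
    A gene at exactly |log2fc| = lfc_min is NS.  ``use_adjusted=False``
    thresholds the raw p instead.
    """
    t = result.table
    pcol = t["padj"] if use_adjusted else t["p"]
    sig = pcol < alpha
    status = np.where(
        sig & (t["log2fc"] > lfc_min),
        "UP",
        np.where(sig & (t["log2fc"] < -lfc_min), "DOWN", "NS"),
    )
    table = t.assign(status=status)
    return ContrastResult(result.name, table, alpha=alpha, lfc_min=lfc_min)


@dataclass
class DEGPartition:
    """UP/DOWN/CONFLICT/NS category per gene across a set of contrasts."""

    categories: pd.Series  # gene -> category
    membership: pd.DataFrame  # gene x contrast, values UP/DOWN/NS
    region_counts: pd.DataFrame = field(default=None)  # Venn region x category counts

    def venn_counts(self) -> pd.DataFrame:
        return self.region_counts


def partition_overlap(results: list[ContrastResult]) -> DEGPartition:
    """Overlap/specificity partition of DEGs across >= 2 contrasts.

    A gene is CONFLICT when it is UP in at least one contrast and DOWN in
    another; otherwise UP or DOWN if called in any contrast; NS genes join
    no Venn region.  Region counts are tallied per Venn region (the subset
    of contrasts in which the gene is a DEG).
    """
    if len(results) < 2:
        raise ValueError("partition_overlap needs at least 2 contrasts")
    universe = list(results[0].table.index)
    for r in results[1:]:
        if set(r.table.index) != set(universe):
            raise ValueError("contrasts have mismatched gene universes")

    membership = pd.DataFrame(
        {r.name: r.table["status"].reindex(universe) for r in results},
        index=pd.Index(universe, name="gene"),
    )
    any_up = (membership == "UP").any(axis=1)
    any_down = (membership == "DOWN").any(axis=1)
    categories = pd.Series(
        np.where(
            any_up & any_down, "CONFLICT", np.where(any_up, "UP", np.where(any_down, "DOWN", "NS"))
        ),
        index=membership.index,
        name="category",
    )

    de_mask = membership.isin(["UP", "DOWN"])
    regions: dict[tuple[str, ...], dict[str, int]] = {}
    for gene in membership.index[de_mask.any(axis=1)]:
        region = tuple(c for c in membership.columns if de_mask.at[gene, c])
        cat = categories.at[gene]
        regions.setdefault(region, {"UP": 0, "DOWN": 0, "CONFLICT": 0})
        regions[region][cat] += 1
    rows = [
        {"region": "&".join(region), **counts}
        for region, counts in sorted(regions.items())
    ]
    region_counts = pd.DataFrame(rows, columns=["region", "UP", "DOWN", "CONFLICT"])
    return DEGPartition(categories, membership, region_counts)
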