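"""Expression normalization and sample-level QC.

FPKM normalization, the log10(FPKM+1) transform, sample Pearson correlation,
PCA, and average-linkage hierarchical clustering on correlation distance —
the standard battery for checking replicate consistency in a bulk RNA-seq
design — plus two closed-form lab utilities (Phred quality, 2^-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .io_formats import CountsMatrix


class ExpressionUnit(str, Enum):
    FPKM = "FPKM"
    LOG10_FPKM_PLUS1 = "log10_fpkm_plus1"


@dataclass(frozen=True)
class ExpressionMatrix:
    values: pd.DataFrame  # genes x samples, float
    unit: ExpressionUnit

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class QCSummary:
    correlation: pd.DataFrame  # sample x sample Pearson
    pca_scores: pd.DataFrame  # sample x component
    pca_var_explained: np.ndarray  # fractions, non-increasing
    hclust_linkage: np.ndarray  # scipy linkage matrix (average linkage)
    hclust_order: list[str]  # leaf order
    linkage_method: str = "average"
    distance: str = "1 - pearson"


def fpkm(counts: CountsMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_gj = counts_gj / ((length_g / 1e3) * (libsize_j / 1e6)) where
    libsize_j is the column sum of the count matrix.
    """
    missing = set(counts.gene_ids) - set(lengths.index)
    if missing:
        raise ValueError(f"gene lengths missing for: {sorted(missing)[:10]}")
    libsize = counts.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    kb = lengths.loc[counts.gene_ids].to_numpy() / 1e3
    per_million = libsize.to_numpy() / 1e6
    vals = counts.counts.to_numpy() / (kb[:, None] * per_million[None, :])
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        ExpressionUnit.FPKM,
    )


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(x + 1); input must be FPKM."""
    if expr.unit is not ExpressionUnit.FPKM:
        raise ValueError(f"log_transform expects FPKM input, got {expr.unit.value}")
    return ExpressionMatrix(np.log10(expr.values + 1.0), ExpressionUnit.LOG10_FPKM_PLUS1)


def phred_quality(error_rate: float) -> float:
    """Phred base-call quality Q = -10 * log10(error probability)."""
    if not 0.0 < error_rate <= 1.0:
        raise ValueError("error_rate must lie in (0, 1]")
    return -10.0 * np.log10(error_rate)


def ddct_relative_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated) - (Ct_target,control - Ct_ref,control).
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def qc_summary(expr: ExpressionMatrix) -> QCSummary:
    """Replicate-consistency summary on log-transformed expression.

    Pearson correlation across genes, PCA with samples as observations
    (gene-centered, unscaled), and average-linkage hierarchical clustering
    on 1 - correlation.
    """
    if expr.unit is not ExpressionUnit.LOG10_FPKM_PLUS1:
        raise ValueError("qc_summary expects log10(FPKM+1) input")
    samples = list(expr.values.columns)
    if len(samples) < 2:
        raise ValueError("qc_summary needs at least 2 samples")
    X = expr.values.to_numpy()
    sds = X.std(axis=0)
    flat = [s for s, sd in zip(samples, sds) if sd == 0]
    if flat:
        raise ValueError(f"zero-variance sample(s), correlation undefined: {flat}")

    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=samples, columns=samples)

    n_comp = min(len(samples) - 1, X.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X.T)  # sklearn centers features (= genes)
    pca_scores = pd.DataFrame(
        scores, index=samples, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )

    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [samples[i] for i in hierarchy.leaves_list(linkage)]

    return QCSummary(
        correlation=corr,
        pca_scores=pca_scores,
        pca_var_explained=pca.explained_variance_ratio_,
        hclust_linkage=linkage,
        hclust_order=order,
    )
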