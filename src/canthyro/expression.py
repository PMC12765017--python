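"""Bulk expression processing: normalization, filtering, variable-gene
selection, embedding/clustering and differential-gene thresholding.

The container is a gene-by-sample count matrix.  Normalization follows the
median-of-ratios scheme: a pseudo-reference sample is built as the per-gene
geometric mean over samples (genes with any zero count are excluded from
the reference), each sample's size factor is the median ratio of its counts
to that reference, and normalized counts are raw counts divided by the size
factor.  Clustering embeds samples into 2-D with a neighbor-graph embedding
over a high-variance gene subset and partitions the embedding with k-means,
making the visual cluster assignment reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "NormalizationError",
    "normalize_median_of_ratios",
    "compute_tpm",
    "filter_low_expression",
    "log2_layer",
    "select_variable_genes",
    "cluster_samples",
    "select_differential_genes",
]


class NormalizationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene-by-sample nonnegative count matrix with derived layers."""

    counts: np.ndarray  # genes x samples, nonnegative
    gene_ids: list
    sample_ids: list
    gene_lengths: np.ndarray = None  # bases, optional
    layers: dict = field(default_factory=dict)
    size_factors: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
            if len(self.gene_lengths) != len(self.gene_ids) or np.any(self.gene_lengths <= 0):
                raise ValueError("gene_lengths must be positive and match gene_ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self, layer: str = None) -> pd.DataFrame:
        mat = self.counts if layer is None else self.layers[layer]
        return pd.DataFrame(mat, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ExpressionMatrix(
            counts=self.counts[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths[idx],
            layers={k: v[idx] for k, v in self.layers.items()},
            size_factors=self.size_factors,
        )


@dataclass
class ClusterResult:
    embedding: np.ndarray  # samples x 2
    labels: np.ndarray  # cluster id per sample
    sample_ids: list
    selected_genes: list
    params: dict


def normalize_median_of_ratios(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size factors and a ``normalized`` layer.

    Genes with a zero count in any sample are excluded from the pseudo-
    reference; the size factor of sample j is the median over reference
    genes of count(g, j) / geometric-mean_g.
    """
    if mat.n_samples < 2:
        raise NormalizationError("need >= 2 samples to normalize")
    counts = mat.counts.astype(float)
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        raise NormalizationError("no gene has nonzero counts in every sample")
    ref = counts[all_positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geomean[:, None]
    size_factors = np.median(ratios, axis=0)
    out = replace(mat)
    out.size_factors = size_factors
    out.layers = dict(mat.layers)
    out.layers["normalized"] = counts / size_factors[None, :]
    return out


def compute_tpm(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million layer: per-kilobase rates rescaled so each
    sample column sums to 1e6."""
    if mat.gene_lengths is None:
        raise ValueError("gene_lengths required to compute TPM")
    rate = mat.counts.astype(float) / (mat.gene_lengths[:, None] / 1000.0)
    col = rate.sum(axis=0)
    col[col == 0] = np.nan
    out = replace(mat)
    out.layers = dict(mat.layers)
    out.layers["tpm"] = 1e6 * rate / col[None, :]
    return out


def filter_low_expression(mat: ExpressionMatrix, min_reads: int = 10, min_samples: int = 5) -> ExpressionMatrix:
    """Retain genes with >= min_reads counts in >= min_samples samples
    (both thresholds inclusive)."""
    keep = (mat.counts >= min_reads).sum(axis=1) >= min_samples
    return mat.subset_genes(keep)


def log2_layer(mat: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized + pseudocount) as a genes x samples frame;
    normalizes first if no normalized layer is present."""
    if "normalized" not in mat.layers:
        mat = normalize_median_of_ratios(mat)
    return pd.DataFrame(
        np.log2(mat.layers["normalized"] + pseudocount), index=mat.gene_ids, columns=mat.sample_ids
    )


def select_variable_genes(log_expr: pd.DataFrame, mean_threshold: float = 2.0, var_threshold: float = 6.0) -> list:
    """High-variance gene subset: per-gene mean of log2 values strictly
    above ``mean_threshold`` and unbiased sample variance strictly above
    ``var_threshold``."""
    means = log_expr.mean(axis=1)
    variances = log_expr.var(axis=1, ddof=1)
    mask = (means > mean_threshold) & (variances > var_threshold)
    return list(log_expr.index[mask])


def cluster_samples(
    log_expr: pd.DataFrame,
    selected_genes: Sequence,
    n_clusters: int,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    exclude_samples: Iterable = (),
) -> ClusterResult:
    """Embed samples (2-D neighbor embedding on standardized selected
    genes) and partition the embedding with seeded k-means."""
    from sklearn.cluster import KMeans

    missing = [g for g in selected_genes if g not in log_expr.index]
    if missing:
        raise KeyError(f"selected genes absent from matrix: {missing[:5]}")
    if len(selected_genes) < 2:
        raise ValueError("need >= 2 selected genes")
    cols = [s for s in log_expr.columns if s not in set(exclude_samples)]
    if len(cols) < n_clusters:
        raise ValueError(f"{len(cols)} samples < {n_clusters} clusters")
    sub = log_expr.loc[list(selected_genes), cols].to_numpy().T  # samples x genes
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd

    import umap

    nn = min(n_neighbors, len(cols) - 1)
    emb = umap.UMAP(
        n_components=2, n_neighbors=nn, min_dist=min_dist, random_state=seed, n_jobs=1
    ).fit_transform(z)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    return ClusterResult(
        embedding=emb,
        labels=labels,
        sample_ids=cols,
        selected_genes=list(selected_genes),
        params={"n_neighbors": nn, "min_dist": min_dist, "n_clusters": n_clusters, "seed": seed},
    )


def select_differential_genes(
    stats: pd.DataFrame, lfc_threshold: float = 2.0, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag differential genes by strict thresholds: |log2FC| > lfc_threshold
    and adjusted p < p_threshold.  ``stats`` needs columns ``log2fc`` and
    ``padj``; returns a copy with ``passes`` and ``direction`` columns
    (``up_group1`` for positive fold changes)."""
    if not {"log2fc", "padj"}.issubset(stats.columns):
        raise KeyError("stats must have 'log2fc' and 'padj' columns")
    padj = stats["padj"].to_numpy(dtype=float)
    if np.any((padj < 0) | (padj > 1)):
        raise ValueError("adjusted p-values must lie in [0, 1]")
    out = stats.copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    out["passes"] = (np.abs(lfc) > lfc_threshold) & (padj < p_threshold)
    out["direction"] = np.where(lfc >= 0, "up_group1", "up_group2")
    return out
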