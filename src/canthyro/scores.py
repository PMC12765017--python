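"""Per-sample transcriptomic signature scores and correlation screens.

Three scores summarize thyroid tumor biology from log2 normalized counts:

* **MPAS** (MAPK pathway activation score): the sum of per-gene z-scores
  over 10 canonical MAPK transcriptional targets, divided by the square
  root of the number of genes used.
* **ERK score** (ERK output signature): the mean z-score over a set of up
  to 52 RAF-MEK-ERK target genes; genes unresolvable in the annotation are
  masked and the number actually used is recorded.
* **TDS** (thyroid differentiation score): for each of 16 thyroid
  metabolism/function genes, log2 expression is centered on the gene's
  cohort median; the TDS of a sample is the sum of its 16 centered values.
  High TDS marks well-differentiated, thyrocyte-like tumors.

The module also provides a transcriptome-wide correlation screen of any
per-sample score against all genes (Spearman or Pearson with BH FDR) and a
weighted Kolmogorov-Smirnov pre-ranked enrichment statistic with a
gene-label permutation p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "ScoreGeneSets",
    "ScoreError",
    "MPAS_GENES",
    "zscore_by_gene",
    "mpas",
    "erk_score",
    "tds",
    "score_table",
    "correlate_with_vector",
    "preranked_enrichment",
]

#: The 10 MAPK transcriptional targets used by the pathway activation score.
MPAS_GENES = (
    "CCND1", "DUSP4", "DUSP6", "EPHA2", "EPHA4",
    "ETV4", "ETV5", "PHLDA1", "SPRY2", "SPRY4",
)


class ScoreError(ValueError):
    pass


@dataclass
class ScoreGeneSets:
    """Gene sets backing the three scores.

    ``erk_available`` optionally masks ERK genes that cannot be resolved in
    the annotation in use; when None, every gene present in the expression
    matrix is used.
    """

    tds_genes: tuple
    mpas_genes: tuple = MPAS_GENES
    erk_genes: tuple = ()
    erk_available: tuple = None

    def __post_init__(self):
        for name in ("tds_genes", "mpas_genes", "erk_genes"):
            vals = getattr(self, name)
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate ids in {name}")
        if len(self.mpas_genes) != 10:
            raise ValueError("mpas_genes must have exactly 10 entries")
        if len(self.erk_genes) > 52:
            raise ValueError("erk_genes may have at most 52 entries")
        if self.erk_available is not None:
            unknown = set(self.erk_available) - set(self.erk_genes)
            if unknown:
                raise ValueError(f"erk_available not a subset of erk_genes: {sorted(unknown)[:5]}")

    def erk_usable(self) -> tuple:
        return tuple(self.erk_available) if self.erk_available is not None else tuple(self.erk_genes)


def zscore_by_gene(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across the cohort (n-1 sd); constant genes get
    all-zero rows rather than NaN."""
    if log_expr.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    mu = log_expr.mean(axis=1)
    sd = log_expr.std(axis=1, ddof=1)
    z = log_expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def mpas(z: pd.DataFrame, sets: ScoreGeneSets) -> pd.Series:
    """Sum of z-scores over present MPAS genes divided by sqrt(n present)."""
    present = [g for g in sets.mpas_genes if g in z.index]
    if not present:
        raise ScoreError("no MPAS genes present in the matrix")
    s = z.loc[present].sum(axis=0) / math.sqrt(len(present))
    s.name = "MPAS"
    s.attrs["n_genes_used"] = len(present)
    return s


def erk_score(z: pd.DataFrame, sets: ScoreGeneSets) -> pd.Series:
    """Mean z-score over available ERK signature genes present in the matrix."""
    present = [g for g in sets.erk_usable() if g in z.index]
    if not present:
        raise ScoreError("no ERK genes present in the matrix")
    s = z.loc[present].mean(axis=0)
    s.name = "ERK"
    s.attrs["n_genes_used"] = len(present)
    return s


def tds(log_expr: pd.DataFrame, sets: ScoreGeneSets) -> pd.Series:
    """Sum over the 16 TDS genes of (log2 value - gene's cohort median).

    All TDS genes must be present; missing ids raise with the full list
    rather than being silently dropped.
    """
    missing = [g for g in sets.tds_genes if g not in log_expr.index]
    if missing:
        raise ScoreError(f"TDS genes missing from matrix: {missing}")
    sub = log_expr.loc[list(sets.tds_genes)]
    centered = sub.sub(sub.median(axis=1), axis=0)
    s = centered.sum(axis=0)
    s.name = "TDS"
    s.attrs["n_genes_used"] = len(sets.tds_genes)
    return s


def score_table(log_expr: pd.DataFrame, sets: ScoreGeneSets) -> pd.DataFrame:
    """TDS/MPAS/ERK per sample in one frame, with genes-used counts in
    ``DataFrame.attrs['n_genes_used']``."""
    z = zscore_by_gene(log_expr)
    cols = {"TDS": tds(log_expr, sets), "MPAS": mpas(z, sets), "ERK": erk_score(z, sets)}
    out = pd.DataFrame(cols)
    out.attrs["n_genes_used"] = {k: v.attrs["n_genes_used"] for k, v in cols.items()}
    return out


def _spearman_exact_p(score_ranks: np.ndarray, gene_ranks: np.ndarray, rho_obs: float) -> float:
    # exact permutation null of |rho| for tiny cohorts
    gr = gene_ranks - gene_ranks.mean()
    denom_g = math.sqrt(np.sum(gr**2))
    if denom_g == 0:
        return 1.0
    count = total = 0
    for perm in itertools.permutations(score_ranks):
        p = np.asarray(perm, dtype=float)
        p -= p.mean()
        denom_p = math.sqrt(np.sum(p**2))
        r = float(np.dot(p, gr)) / (denom_p * denom_g) if denom_p > 0 else 0.0
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def correlate_with_vector(score: pd.Series, log_expr: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Correlate a per-sample score with every gene's expression.

    Returns a frame indexed by gene with ``coefficient``, ``p`` and ``fdr``
    (BH across all tested genes).  Spearman p-values use the t
    approximation for larger cohorts and an exact permutation null for
    tiny ones (n <= 8); Pearson uses the t approximation throughout.
    """
    common = [s for s in log_expr.columns if s in score.index]
    if len(common) < 4:
        raise ValueError("need >= 4 samples shared between score and matrix")
    v = score.loc[common].to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("score contains non-finite values")
    if np.all(v == v[0]):
        raise ValueError("score vector is constant")
    X = log_expr[common].to_numpy(dtype=float)
    n = len(common)

    if method == "spearman":
        v_use = sps.rankdata(v)
        X_use = sps.rankdata(X, axis=1)
    elif method == "pearson":
        v_use, X_use = v, X
    else:
        raise ValueError(f"unknown method {method!r}")

    vc = v_use - v_use.mean()
    Xc = X_use - X_use.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(vc**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ vc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0 - 1e-12, 0.0, p)

    if method == "spearman" and n <= 8:
        p = np.array([_spearman_exact_p(v_use, X_use[i], r[i]) for i in range(X_use.shape[0])])

    return pd.DataFrame(
        {"coefficient": r, "p": p, "fdr": bh_fdr(np.clip(p, 0, 1)), "method": method},
        index=log_expr.index,
    )


def _running_sum_es(abs_scores: np.ndarray, in_set: np.ndarray) -> float:
    hit_total = abs_scores[in_set].sum()
    n_miss = len(abs_scores) - int(in_set.sum())
    if hit_total == 0:
        # all in-set ranking scores are zero: fall back to unweighted hits
        steps_hit = in_set / max(1, int(in_set.sum()))
    else:
        steps_hit = np.where(in_set, abs_scores / hit_total, 0.0)
    steps_miss = np.where(~in_set, 1.0 / max(1, n_miss), 0.0)
    running = np.cumsum(steps_hit - steps_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_enrichment(ranked: pd.Series, gene_set, n_permutations: int = 1000, seed: int = 0):
    """Weighted running-sum enrichment of a gene set in a ranked list.

    ``ranked`` maps gene -> ranking score, ordered from most up- to most
    down-regulated.  Hits advance the running sum by |score| (exponent 1,
    normalized over in-set scores), misses retreat by 1/(N-k); the
    enrichment score ES is the extreme deviation of the running sum.
    Significance comes from a two-sided permutation null on |ES| obtained
    by redrawing the set's gene labels, deterministic given ``seed``.

    Returns ``(es, p)``.
    """
    genes = list(ranked.index)
    if len(set(genes)) != len(genes):
        raise ValueError("ranking has duplicate gene ids")
    member = set(gene_set)
    in_set = np.array([g in member for g in genes])
    k = int(in_set.sum())
    if k == 0:
        raise ScoreError("gene set does not intersect the ranking")
    scores = np.abs(ranked.to_numpy(dtype=float))
    es = _running_sum_es(scores, in_set)

    rng = np.random.default_rng(seed)
    n = len(genes)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        null[i] = _running_sum_es(scores, mask)
    p = (1 + np.sum(np.abs(null) >= abs(es) - 1e-12)) / (n_permutations + 1)
    return float(es), float(p)
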