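"""Cross-batch and cross-platform agreement analytics.

Two questions decide whether a transcriptome-derived reference-gene panel
can be trusted: do per-gene expression means and stabilities (CVs) agree
between independent biological replicate sets (batches grown in different
greenhouses), and do they agree between RNA-seq and qPCR? Both are
answered with Pearson correlations on paired per-gene statistics, with the
two-sided p-value from the t transform of r at n − 2 degrees of freedom.

Means span orders of magnitude, so they are correlated on the log10 scale
by default (a small offset guards zeros); CVs are correlated raw.
Lowly expressed genes (mean below a floor in either batch) are excluded
from replicate comparisons — their CVs are dominated by counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix

__all__ = [
    "METRIC_MEAN",
    "METRIC_CV",
    "ConcordanceReport",
    "replicate_concordance",
    "platform_concordance",
]

METRIC_MEAN = "mean"
METRIC_CV = "cv"

#: offset added before log10 of means, to guard zeros
LOG_OFFSET = 1e-3


@dataclass(frozen=True)
class ConcordanceReport:
    """Pearson agreement between two per-gene statistics vectors."""

    metric: str
    source_a: str
    source_b: str
    n_genes: int
    pearson_r: float
    p_value: float
    exclusion_rule: str = ""

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("correlation needs at least 3 genes")
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")


def _per_gene_stats(m: ExpressionMatrix, metric: str) -> pd.Series:
    vals = m.values
    if metric == METRIC_MEAN:
        return vals.mean(axis=1)
    if metric == METRIC_CV:
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        return (sd / mean).where(mean > 0)
    raise ValueError(f"unknown metric {metric!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def replicate_concordance(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    metric: str = METRIC_CV,
    min_mean_fpkm: float = 1.0,
    log_means: bool = True,
    labels: tuple[str, str] = ("batch_a", "batch_b"),
) -> ConcordanceReport:
    """Agreement of per-gene means or CVs between two replicate batches.

    Each matrix spans one batch's samples (e.g. the four tissues of T1 and
    of T2). Genes with mean expression below ``min_mean_fpkm`` in either
    batch are excluded. Means are log10-transformed before correlating
    unless ``log_means=False``; CVs are always correlated raw.
    """
    shared = a.values.index.intersection(b.values.index)
    if len(shared) == 0:
        raise ValueError("matrices share no genes")
    mean_a = a.values.loc[shared].mean(axis=1)
    mean_b = b.values.loc[shared].mean(axis=1)
    keep = (mean_a >= min_mean_fpkm) & (mean_b >= min_mean_fpkm)
    stat_a = _per_gene_stats(a.subset_genes(shared[keep]), metric)
    stat_b = _per_gene_stats(b.subset_genes(shared[keep]), metric)
    ok = stat_a.notna() & stat_b.notna()
    x, y = stat_a[ok].to_numpy(), stat_b[ok].to_numpy()
    if len(x) < 3:
        raise ValueError(f"only {len(x)} shared genes after exclusion; need >= 3")
    if metric == METRIC_MEAN and log_means:
        x, y = np.log10(x + LOG_OFFSET), np.log10(y + LOG_OFFSET)
    r, p = _pearson(x, y)
    return ConcordanceReport(
        metric=metric,
        source_a=labels[0],
        source_b=labels[1],
        n_genes=int(len(x)),
        pearson_r=r,
        p_value=p,
        exclusion_rule=f"mean < {min_mean_fpkm} FPKM in either batch excluded",
    )


def platform_concordance(
    rnaseq: pd.Series,
    qpcr: pd.Series,
    metric: str = METRIC_MEAN,
    log_means: bool = True,
    labels: tuple[str, str] = ("rnaseq", "qpcr"),
) -> ConcordanceReport:
    """Agreement of per-gene statistics between RNA-seq and qPCR.

    Inputs are per-gene Series (means or CVs) indexed by gene id; the gene
    sets must match exactly. Means are log10-transformed by default — the
    two platforms report on different absolute scales (FPKM vs E^ΔCq), and
    a log correlation is insensitive to that overall scale.
    """
    unmatched = set(rnaseq.index).symmetric_difference(qpcr.index)
    if unmatched:
        raise ValueError(f"unmatched gene ids: {sorted(unmatched)}")
    if len(rnaseq) < 3:
        raise ValueError("need at least 3 genes")
    qpcr = qpcr.reindex(rnaseq.index)
    x, y = rnaseq.to_numpy(dtype=float), qpcr.to_numpy(dtype=float)
    if metric == METRIC_MEAN and log_means:
        x, y = np.log10(x + LOG_OFFSET), np.log10(y + LOG_OFFSET)
    r, p = _pearson(x, y)
    return ConcordanceReport(
        metric=metric,
        source_a=labels[0],
        source_b=labels[1],
        n_genes=int(len(x)),
        pearson_r=r,
        p_value=p,
        exclusion_rule="pre-matched gene panel",
    )
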