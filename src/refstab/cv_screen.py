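"""Coefficient-of-variation stability screen.

A candidate qPCR reference gene must be (a) expressed robustly enough to
quantify and (b) stable across tissues and growing conditions. The CV
method operationalizes this as: drop every gene whose expression falls
below a minimum FPKM in *any* sample, then rank the survivors by the
coefficient of variation CV = SD/mean computed over all samples (four
tissue types × two biological replicate sets in the motivating design).

Conventions (all deliberate):

* SD uses the sample (n−1) denominator.
* The minimum-expression filter keeps genes exactly at the threshold
  ("lower than" excludes).
* CV-threshold counts use strict less-than.
* Rank ties are broken by gene id, lexicographically, for determinism.
* Genes with mean 0 (possible only on unfiltered input) get no rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, HomeologMap, UNIT_FPKM

__all__ = [
    "FilterPolicy",
    "filter_min_expression",
    "stability_cv",
    "cv_screen",
    "top_n",
    "cv_threshold_summary",
    "average_homeolog_cvs",
]

#: columns of a stability table
STABILITY_COLUMNS = ["mean", "sd", "cv", "rank", "passed_filter"]


@dataclass(frozen=True)
class FilterPolicy:
    """Minimum-expression filter: exclude a gene if it is below
    ``min_expression`` FPKM in ANY sample."""

    min_expression: float = 5.0

    def __post_init__(self) -> None:
        if self.min_expression < 0:
            raise ValueError("min_expression must be >= 0")


def filter_min_expression(
    m: ExpressionMatrix, policy: FilterPolicy = FilterPolicy()
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Apply the any-sample minimum-expression filter.

    Returns the retained matrix and a table of excluded genes with the
    first offending sample and its value.

    Genes with expression exactly at the threshold are retained.
    """
    if m.unit != UNIT_FPKM:
        raise ValueError("minimum-expression filter expects FPKM values")
    if m.n_genes == 0:
        raise ValueError("empty expression matrix")
    vals = m.values.to_numpy()
    below = vals < policy.min_expression
    excluded_mask = below.any(axis=1)
    records = []
    for gi in np.nonzero(excluded_mask)[0]:
        si = int(np.argmax(below[gi]))
        records.append(
            {
                "gene_id": m.values.index[gi],
                "offending_sample": m.values.columns[si],
                "value": vals[gi, si],
            }
        )
    excluded = pd.DataFrame(records, columns=["gene_id", "offending_sample", "value"])
    kept = m.values.loc[~excluded_mask]
    return ExpressionMatrix(kept, list(m.samples), m.unit), excluded


def stability_cv(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean, sample SD, CV = SD/mean, and ascending CV rank.

    Returns a DataFrame indexed by gene id with columns ``mean``, ``sd``,
    ``cv``, ``rank``. Genes whose mean is 0 have CV = NaN and no rank.
    """
    if m.n_samples < 2:
        raise ValueError("CV needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    out = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv}, index=m.values.index)
    rankable = out[out["cv"].notna()]
    # deterministic tie-break: lexicographic gene id within equal CV
    order = sorted(rankable.index, key=lambda g: (rankable.at[g, "cv"], str(g)))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order, dtype="float")
    out["rank"] = ranks.reindex(out.index)
    return out


def cv_screen(
    m: ExpressionMatrix, policy: FilterPolicy = FilterPolicy()
) -> pd.DataFrame:
    """Full CV screen: filter, then rank survivors by CV.

    Returns a stability table over ALL input genes, with ``passed_filter``
    flags; mean/sd/cv are reported for every gene but only filter-passing
    genes are ranked.
    """
    kept, _excluded = filter_min_expression(m, policy)
    all_stats = stability_cv(m)
    ranked = stability_cv(kept)
    table = all_stats.drop(columns="rank")
    table["rank"] = ranked["rank"].reindex(table.index)
    table["passed_filter"] = table.index.isin(kept.gene_ids)
    return table[STABILITY_COLUMNS]


def top_n(table: pd.DataFrame, n: int) -> tuple[list[str], float]:
    """The n lowest-CV ranked genes and the maximum CV within that list."""
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = table[table["rank"].notna()].sort_values("rank")
    if n > len(ranked):
        warnings.warn(
            f"requested top {n} but only {len(ranked)} ranked genes; returning all",
            stacklevel=2,
        )
        n = len(ranked)
    head = ranked.head(n)
    return list(head.index), float(head["cv"].max())


def cv_threshold_summary(table: pd.DataFrame, threshold: float) -> dict[str, int]:
    """Count ranked genes with CV strictly below ``threshold``."""
    ranked = table[table["rank"].notna()]
    return {
        "below": int((ranked["cv"] < threshold).sum()),
        "total": int(len(ranked)),
    }


def average_homeolog_cvs(table: pd.DataFrame, hmap: HomeologMap) -> pd.Series:
    """Average the two homeologs' CVs for each pair.

    This reports per-pair stability for a polyploid as the arithmetic mean
    of the two copies' CVs (not the CV of averaged expression, which is a
    different statistic). Returns a Series indexed ``"A|B"``.
    """
    absent = sorted(hmap.gene_ids() - set(table.index))
    if absent:
        raise ValueError(f"homeolog map ids absent from stability table: {absent}")
    data = {
        f"{a}|{b}": (table.at[a, "cv"] + table.at[b, "cv"]) / 2.0
        for a, b in hmap.pairs
    }
    return pd.Series(data, name="cv")
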