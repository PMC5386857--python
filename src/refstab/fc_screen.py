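"""Pairwise fold-change exclusion screen.

The second route to stable genes: after library-size normalization, a gene
is eliminated if its absolute log2 fold change exceeds a cutoff in ANY
pairwise comparison between samples. What survives is, by construction, a
short list of genes that never move much between any two libraries — a
stricter, set-valued counterpart to the CV ranking.

Normalization here is plain counts-per-million: the motivation for using a
count-based DE package in this role is only its library-size scaling, and
any fold-change recipe may be substituted (``NormalizationPolicy.method =
"none"`` accepts pre-normalized input, e.g. FPKM). A pseudocount (default
0.5, the usual prior-count convention) guards zeros; it is immaterial after
a ≥5 FPKM pre-filter.

Cutoff semantics: "high fold change (>c) eliminated", so retention is
``max |log2 FC| <= c`` — a gene exactly at the cutoff survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, UNIT_COUNTS

__all__ = [
    "NormalizationPolicy",
    "normalize_library_size",
    "pairwise_logfc",
    "foldchange_screen",
    "method_concordance",
]


@dataclass(frozen=True)
class NormalizationPolicy:
    """How to normalize before fold changes: ``"cpm"`` (library-size
    counts-per-million) or ``"none"`` (input already normalized)."""

    method: str = "cpm"
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in ("cpm", "none"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def normalize_library_size(
    m: ExpressionMatrix, policy: NormalizationPolicy = NormalizationPolicy()
) -> ExpressionMatrix:
    """Scale each sample to counts-per-million of its column sum."""
    if policy.method == "none":
        return ExpressionMatrix(m.values.copy(), list(m.samples), m.unit)
    if m.unit != UNIT_COUNTS:
        raise ValueError("CPM normalization expects a COUNTS matrix")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero library size in samples: {list(zero.index)}")
    cpm = m.values / colsums * 1e6
    return ExpressionMatrix(cpm, list(m.samples), m.unit)


def pairwise_logfc(m: ExpressionMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 fold change for every unordered sample pair.

    Returns a DataFrame indexed by gene id whose columns are a MultiIndex of
    (sample_i, sample_j) for i < j in matrix order, holding
    log2((v_i + p) / (v_j + p)). The reverse comparison is the negation.
    """
    if m.n_samples < 2:
        raise ValueError("pairwise fold changes need at least 2 samples")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    v = m.values.to_numpy(dtype=float) + pseudocount
    if pseudocount == 0 and (v <= 0).any():
        raise ValueError("zero values require a positive pseudocount")
    cols = list(m.values.columns)
    pairs = list(combinations(range(len(cols)), 2))
    with np.errstate(divide="ignore"):
        data = {
            (cols[i], cols[j]): np.log2(v[:, i] / v[:, j]) for i, j in pairs
        }
    out = pd.DataFrame(data, index=m.values.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample_a", "sample_b"])
    return out


def foldchange_screen(
    m: ExpressionMatrix,
    cutoff: float,
    policy: NormalizationPolicy = NormalizationPolicy(),
) -> pd.DataFrame:
    """Screen genes by their worst pairwise |log2 FC|.

    Returns a table (sorted ascending by ``max_abs_logfc``) with columns
    ``max_abs_logfc``, ``worst_pair_a``, ``worst_pair_b``, ``retained``.
    A gene is retained iff its maximum absolute pairwise log2 fold change
    is <= cutoff. The input should already be filtered for minimum
    expression; pass ``policy.method="none"`` for FPKM input.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    norm = normalize_library_size(m, policy)
    lfc = pairwise_logfc(norm, policy.pseudocount)
    abs_lfc = lfc.abs()
    worst_idx = abs_lfc.to_numpy().argmax(axis=1)
    pairs = list(lfc.columns)
    worst_pairs = [pairs[i] for i in worst_idx]
    out = pd.DataFrame(
        {
            "max_abs_logfc": abs_lfc.to_numpy().max(axis=1),
            "worst_pair_a": [p[0] for p in worst_pairs],
            "worst_pair_b": [p[1] for p in worst_pairs],
        },
        index=lfc.index,
    )
    out["retained"] = out["max_abs_logfc"] <= cutoff
    out = out.sort_values(
        "max_abs_logfc", kind="mergesort"
    )  # stable: ties keep input gene order
    if not out["retained"].any():
        warnings.warn(
            f"no genes retained at cutoff {cutoff}; consider relaxing it",
            stacklevel=2,
        )
    return out


def method_concordance(
    fc: pd.DataFrame, cv: pd.DataFrame, n_list: list[int]
) -> dict:
    """Overlap between the fold-change retained set and top-N CV lists.

    For each n in ``n_list``, counts fold-change-retained genes whose CV
    rank is <= n; also reports the worst (maximum) CV rank among retained
    genes. Both tables must share a gene universe.
    """
    if not set(fc.index) & set(cv.index):
        raise ValueError("fold-change and CV tables share no genes")
    retained = fc.index[fc["retained"]]
    missing = [g for g in retained if g not in cv.index]
    if missing:
        raise ValueError(f"retained genes missing from CV table: {missing}")
    ranks = cv.loc[retained, "rank"].dropna()
    return {
        "n_retained": int(len(retained)),
        "overlap": {int(n): int((ranks <= n).sum()) for n in n_list},
        "max_cv_rank": int(ranks.max()) if len(ranks) else None,
    }
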