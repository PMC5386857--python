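"""End-to-end reference-gene selection pipeline and the combined report.

Chains the stages: minimum-expression filter → CV screen → fold-change
screen → optional qPCR validation → cross-batch concordance, and merges
the two screens into a single candidate table with a verdict per gene:

* ``STRONG``  — retained by the fold-change screen AND within the top-N CV
  ranks (scores well by both metrics);
* ``CV_ONLY`` / ``FC_ONLY`` — passes one screen only;
* ``REJECTED`` — neither.

Every output table carries a ``#``-prefixed provenance header (tool
version, config hash, seed) so a result can always be traced to the exact
configuration that produced it. Outputs are a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .concordance import METRIC_CV, METRIC_MEAN, replicate_concordance
from .cv_screen import FilterPolicy, cv_screen, top_n
from .expression_io import (
    ExpressionMatrix,
    UNIT_COUNTS,
    counts_to_fpkm,
    read_expression_matrix,
)
from .fc_screen import NormalizationPolicy, foldchange_screen, method_concordance
from .qpcr import CqDataset, collapse_tech_reps, qpcr_cv, relative_expression

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "candidate_report", "write_table"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and inputs for a full selection run.

    Defaults follow common practice for heterogeneous multi-tissue panels:
    minimum expression 5 FPKM, CV report cutoff 0.5, top-50 CV list,
    fold-change cutoff 0.4. Species are handled independently — run once
    per species matrix.
    """

    min_fpkm: float = 5.0
    cv_cutoff: float = 0.5
    top_n: int = 50
    fc_cutoff: float = 0.4
    pseudocount: float = 0.5
    normalize: str = "none"  # "cpm" for counts input, "none" for FPKM
    min_mean_fpkm_concordance: float = 1.0
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    stability: pd.DataFrame
    foldchange: pd.DataFrame
    report: pd.DataFrame
    top_genes: list[str]
    top_max_cv: float
    cv_below_cutoff: dict[str, int]
    method_overlap: dict
    concordance: pd.DataFrame | None = None
    qpcr_cv: pd.DataFrame | None = None


def candidate_report(
    stability: pd.DataFrame,
    foldchange: pd.DataFrame,
    n_top: int,
    qpcr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge the two screens (and optional qPCR CVs) into one verdict table."""
    ranked = stability[stability["rank"].notna()]
    report = ranked[["cv", "rank"]].rename(columns={"rank": "cv_rank"}).copy()
    report["max_abs_logfc"] = foldchange["max_abs_logfc"].reindex(report.index)
    report["in_fc_list"] = (
        foldchange["retained"].reindex(report.index).fillna(False).astype(bool)
    )
    report["qpcr_cv"] = (
        qpcr["cv"].reindex(report.index) if qpcr is not None else pd.NA
    )
    in_top = report["cv_rank"] <= n_top
    verdict = pd.Series("REJECTED", index=report.index)
    verdict[in_top] = "CV_ONLY"
    verdict[report["in_fc_list"] & ~in_top] = "FC_ONLY"
    verdict[report["in_fc_list"] & in_top] = "STRONG"
    report["verdict"] = verdict
    return report.sort_values("cv_rank")


def _batch_concordance(
    fpkm: ExpressionMatrix, cfg: PipelineConfig
) -> pd.DataFrame | None:
    batches = sorted({s.batch for s in fpkm.samples})
    if len(batches) < 2:
        return None
    rows = []
    a_ids = [s.sample_id for s in fpkm.samples if s.batch == batches[0]]
    b_ids = [s.sample_id for s in fpkm.samples if s.batch == batches[1]]
    if len(a_ids) < 2 or len(b_ids) < 2:
        return None
    a, b = fpkm.subset_samples(a_ids), fpkm.subset_samples(b_ids)
    for metric in (METRIC_MEAN, METRIC_CV):
        rep = replicate_concordance(
            a, b, metric=metric, min_mean_fpkm=cfg.min_mean_fpkm_concordance,
            labels=(batches[0], batches[1]),
        )
        rows.append(
            {
                "metric": rep.metric,
                "source_a": rep.source_a,
                "source_b": rep.source_b,
                "n_genes": rep.n_genes,
                "pearson_r": rep.pearson_r,
                "p_value": rep.p_value,
                "exclusion_rule": rep.exclusion_rule,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    matrix: ExpressionMatrix,
    cfg: PipelineConfig = PipelineConfig(),
    gene_lengths: dict[str, int] | None = None,
    cq_dataset: CqDataset | None = None,
    exclude_tissues: frozenset[str] = frozenset(),
) -> PipelineResult:
    """Execute filter → CV screen → fold-change screen → (qPCR) → concordance."""
    try:
        if matrix.unit == UNIT_COUNTS:
            if gene_lengths is None:
                raise PipelineError("stage counts_to_fpkm: gene lengths required")
            fpkm = counts_to_fpkm(matrix, gene_lengths)
            fc_input, fc_policy = matrix, NormalizationPolicy(
                method="cpm", pseudocount=cfg.pseudocount
            )
        else:
            fpkm = matrix
            fc_input, fc_policy = matrix, NormalizationPolicy(
                method="none", pseudocount=cfg.pseudocount
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage unit_conversion: {exc}") from exc

    policy = FilterPolicy(min_expression=cfg.min_fpkm)
    try:
        stability = cv_screen(fpkm, policy)
    except Exception as exc:
        raise PipelineError(f"stage cv_screen: {exc}") from exc
    passed = stability.index[stability["passed_filter"]]
    top_genes, top_max_cv = top_n(stability, min(cfg.top_n, len(passed)))
    below = {
        "below": int((stability.loc[passed, "cv"] < cfg.cv_cutoff).sum()),
        "total": int(len(passed)),
    }

    try:
        fc = foldchange_screen(
            fc_input.subset_genes(passed), cfg.fc_cutoff, fc_policy
        )
    except Exception as exc:
        raise PipelineError(f"stage fc_screen: {exc}") from exc
    overlap = method_concordance(fc, stability, [cfg.top_n, 200])

    qcv = None
    if cq_dataset is not None:
        try:
            collapsed, _log = collapse_tech_reps(cq_dataset.records)
            rel = relative_expression(
                CqDataset(collapsed, cq_dataset.efficiencies, cq_dataset.calibrator)
            )
            qcv = qpcr_cv(rel, exclude_tissues=exclude_tissues)
        except Exception as exc:
            raise PipelineError(f"stage qpcr: {exc}") from exc

    try:
        conc = _batch_concordance(fpkm, cfg)
    except Exception as exc:
        raise PipelineError(f"stage concordance: {exc}") from exc

    report = candidate_report(stability, fc, cfg.top_n, qcv)
    return PipelineResult(
        stability=stability,
        foldchange=fc,
        report=report,
        top_genes=top_genes,
        top_max_cv=top_max_cv,
        cv_below_cutoff=below,
        method_overlap=overlap,
        concordance=conc,
        qpcr_cv=qcv,
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    cfg: PipelineConfig | None = None,
    index_label: str = "gene_id",
) -> None:
    """Write a TSV with a ``#`` provenance header (version, config hash, seed)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# refstab {__version__}\n")
        if cfg is not None:
            fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def load_pipeline_inputs(
    matrix_path: str | Path, meta_path: str | Path, unit: str
) -> ExpressionMatrix:
    """Read pipeline inputs, wrapping parse errors with the stage name."""
    try:
        return read_expression_matrix(matrix_path, meta_path, unit)
    except Exception as exc:
        raise PipelineError(f"stage read_inputs: {exc}") from exc
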