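"""Efficiency-corrected ΔCq qPCR analysis.

The validation arm of reference-gene selection. Raw input is a long table
of quantification cycles (Cq), one row per technical replicate, keyed by
gene, species, tissue and biological replicate, optionally grouped by run.
The pipeline is:

1. average technical replicates, discarding a single >1 Cq outlier;
2. estimate per-assay amplification efficiency E from a dilution-series
   standard curve, E = 10^(1/−slope);
3. convert Cq to relative expression E^ΔCq against a fixed interplate
   calibrator, ΔCq = Cq_calibrator − Cq_sample;
4. summarize per-gene stability as the CV of tissue-mean relative
   expression (biological replicates averaged within tissue first).

Because ΔCq is differenced against a shared calibrator, changing the
calibrator multiplies every relative expression by one constant — which
leaves the CV untouched. That invariance is what makes qPCR CVs directly
comparable with RNA-seq CVs.

Also included: the MIQE 3′/5′ template-integrity check (acceptable ratio
0.2–5.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CYCLE_CEILING",
    "QpcrError",
    "UnresolvableReplicatesError",
    "CqDataset",
    "DilutionSeries",
    "ThreePrimeFivePrimeQC",
    "average_tech_reps",
    "collapse_tech_reps",
    "fit_efficiency",
    "relative_expression",
    "qpcr_cv",
    "qc_3p5p",
]

#: PCR cycle ceiling; Cq at or above this means no detectable amplification
CYCLE_CEILING = 40.0

#: columns required in a long-format Cq table (tech_rep optional: absent
#: once replicates have been collapsed)
CQ_COLUMNS = ("gene", "species", "tissue", "bio_rep", "cq")


class QpcrError(ValueError):
    """Raised for invalid qPCR inputs (bad Cq, missing calibrator, ...)."""


class UnresolvableReplicatesError(QpcrError):
    """Two technical replicates differ by >1 Cq with no identifiable outlier."""


@dataclass
class CqDataset:
    """Long-format Cq records plus per-gene efficiencies and a calibrator.

    ``records`` must contain the columns gene, species, tissue, bio_rep,
    tech_rep, cq (and optionally run_id). ``calibrator`` designates the
    (gene, sample) combination run on every plate; the sample key is a
    (species, tissue, bio_rep) triple. ``efficiencies`` maps each gene to
    its amplification efficiency E (~1.6–2.1; ideal 2.0).
    """

    records: pd.DataFrame
    efficiencies: dict[str, float]
    calibrator: tuple[str, tuple[str, str, object]]

    def __post_init__(self) -> None:
        missing = [c for c in CQ_COLUMNS if c not in self.records.columns]
        if missing:
            raise QpcrError(f"Cq table missing columns: {missing}")
        cq = self.records["cq"].to_numpy(dtype=float)
        if (cq <= 0).any() or (cq > CYCLE_CEILING).any():
            raise QpcrError(f"Cq values must lie in (0, {CYCLE_CEILING}]")
        genes = set(self.records["gene"])
        no_e = genes - set(self.efficiencies)
        if no_e:
            raise QpcrError(f"no efficiency for genes: {sorted(no_e)}")


@dataclass
class DilutionSeries:
    """A standard curve: matched (dilution factor, Cq) points for one assay.

    Dilution factors are relative template concentrations (1, 1/4, 1/16, ...),
    not step indices. ``fit()`` populates slope and efficiency.
    """

    dilution_factors: Sequence[float]
    cq: Sequence[float]
    gene: str = ""
    slope: float | None = field(default=None)
    efficiency: float | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.dilution_factors) != len(self.cq):
            raise QpcrError("dilution_factors and cq must be the same length")
        if any(d <= 0 for d in self.dilution_factors):
            raise QpcrError("dilution factors must be positive concentrations")

    def fit(self) -> float:
        self.slope, self.efficiency = _fit_standard_curve(
            self.dilution_factors, self.cq
        )
        return self.efficiency


@dataclass(frozen=True)
class ThreePrimeFivePrimeQC:
    """MIQE template-integrity result: 3′/5′ expression ratio and verdict."""

    ratio_3p_5p: float
    pass_: bool

    LOWER: float = 0.2
    UPPER: float = 5.0


# ---------------------------------------------------------------------------
# technical replicates


def average_tech_reps(reps: Sequence[float]) -> tuple[float, int | None]:
    """Average technical-replicate Cq values, dropping one >1 Cq outlier.

    If the spread (max − min) is <= 1 Cq, returns the plain mean. With
    three or more replicates spread wider than 1 Cq, the replicate farthest
    from the median is dropped (ties keep the earlier-listed replicate) and
    the rest are averaged. Two replicates >1 Cq apart are unresolvable.

    Returns (mean Cq, index of the dropped replicate or None).
    """
    reps = [float(r) for r in reps]
    if not reps:
        raise QpcrError("no technical replicates")
    if len(reps) == 1:
        return reps[0], None
    if max(reps) - min(reps) <= 1.0:
        return float(np.mean(reps)), None
    if len(reps) == 2:
        raise UnresolvableReplicatesError(
            f"replicates {reps} differ by >1 Cq with no identifiable outlier"
        )
    med = float(np.median(reps))
    dists = [abs(r - med) for r in reps]
    drop = int(np.argmax(dists))  # argmax keeps the earlier replicate on ties
    kept = [r for i, r in enumerate(reps) if i != drop]
    return float(np.mean(kept)), drop


def collapse_tech_reps(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse a long Cq table to one mean Cq per (gene, sample) group.

    Groups by gene, species, tissue, bio_rep (and run_id if present).
    Returns (collapsed table, log of dropped/excluded replicates). Groups
    whose replicates are unresolvable are excluded and logged.
    """
    keys = ["gene", "species", "tissue", "bio_rep"]
    if "run_id" in records.columns:
        keys.append("run_id")
    rows, log = [], []
    for key, grp in records.groupby(keys, sort=False):
        reps = list(grp["cq"])
        try:
            mean, dropped = average_tech_reps(reps)
        except UnresolvableReplicatesError:
            log.append(dict(zip(keys, key), event="excluded_unresolvable"))
            continue
        if dropped is not None:
            log.append(dict(zip(keys, key), event=f"dropped_rep_{dropped}"))
        rows.append(dict(zip(keys, key), cq=mean))
    return pd.DataFrame(rows), pd.DataFrame(log, columns=[*keys, "event"])


# ---------------------------------------------------------------------------
# efficiency


def _fit_standard_curve(
    dilution_factors: Sequence[float], cq: Sequence[float]
) -> tuple[float, float]:
    if len(cq) < 3:
        raise QpcrError("efficiency fit needs at least 3 dilution points")
    x = np.log10(np.asarray(dilution_factors, dtype=float))
    fit = stats.linregress(x, np.asarray(cq, dtype=float))
    if fit.slope >= 0:
        raise QpcrError(
            f"non-negative standard-curve slope ({fit.slope:.3f}); assay failure"
        )
    efficiency = 10.0 ** (1.0 / -fit.slope)
    return float(fit.slope), float(efficiency)


def fit_efficiency(series: DilutionSeries) -> float:
    """Amplification efficiency from a dilution-series standard curve.

    Ordinary least squares of Cq on log10(relative concentration) gives the
    slope; E = 10^(1/−slope). A perfect assay doubles template each cycle:
    slope −3.3219, E = 2.0. Percent efficiency is (E − 1) × 100.
    """
    return series.fit()


def percent_efficiency(e: float) -> float:
    """Report efficiency the conventional way: E = 2.0 -> 100%."""
    return (e - 1.0) * 100.0


# ---------------------------------------------------------------------------
# relative expression


def relative_expression(ds: CqDataset) -> pd.DataFrame:
    """Calibrator- and efficiency-normalized relative expression.

    rel_expr = E_gene ^ (Cq_calibrator − Cq_sample), with the calibrator Cq
    resolved within each run group when a ``run_id`` column is present,
    otherwise globally. ``ds.records`` must already be collapsed to one Cq
    per (gene, sample); use :func:`collapse_tech_reps` first.

    Returns a long DataFrame with columns gene, species, tissue, bio_rep,
    cq, rel_expr.
    """
    rec = ds.records.copy()
    cal_gene, (cal_species, cal_tissue, cal_rep) = ds.calibrator
    is_cal = (
        (rec["gene"] == cal_gene)
        & (rec["species"] == cal_species)
        & (rec["tissue"] == cal_tissue)
        & (rec["bio_rep"] == cal_rep)
    )
    if "run_id" in rec.columns:
        cal_by_run = rec.loc[is_cal].set_index("run_id")["cq"]
        dup = cal_by_run.index[cal_by_run.index.duplicated()]
        if len(dup):
            raise QpcrError(f"multiple calibrator records in runs: {list(dup)}")
        missing_runs = sorted(set(rec["run_id"]) - set(cal_by_run.index))
        if missing_runs:
            n_aff = int(rec["run_id"].isin(missing_runs).sum())
            raise QpcrError(
                f"no calibrator in runs {missing_runs} ({n_aff} records affected)"
            )
        cal_cq = rec["run_id"].map(cal_by_run)
    else:
        cal_rows = rec.loc[is_cal, "cq"]
        if cal_rows.empty:
            raise QpcrError(
                f"calibrator {ds.calibrator} not found "
                f"({len(rec)} records affected)"
            )
        cal_cq = float(cal_rows.mean())
    eff = rec["gene"].map(ds.efficiencies).to_numpy(dtype=float)
    rec["rel_expr"] = eff ** (np.asarray(cal_cq, dtype=float) - rec["cq"].to_numpy())
    return rec


def qpcr_cv(
    rel: pd.DataFrame, exclude_tissues: set[str] | frozenset[str] = frozenset()
) -> pd.DataFrame:
    """Per-gene expression-stability CV from relative qPCR expression.

    Within each gene: average rel_expr over biological replicates within
    each tissue, then CV = sample SD / mean across the tissue means.
    ``exclude_tissues`` drops tissues (e.g. a divergent petal sample)
    before the computation; at least two tissues must remain.
    """
    data = rel[~rel["tissue"].isin(exclude_tissues)]
    if data["tissue"].nunique() < 2:
        raise QpcrError("qPCR CV needs at least 2 tissues after exclusion")
    out = []
    for gene, grp in data.groupby("gene", sort=False):
        tissue_means = grp.groupby("tissue", sort=False)["rel_expr"].mean()
        mean = float(tissue_means.mean())
        sd = float(tissue_means.std(ddof=1))
        out.append(
            {
                "gene": gene,
                "mean": mean,
                "sd": sd,
                "cv": sd / mean,
                "n_tissues": int(len(tissue_means)),
            }
        )
    return pd.DataFrame(out).set_index("gene")


# ---------------------------------------------------------------------------
# MIQE 3'/5' QC


def qc_3p5p(cq_3p: float, cq_5p: float, efficiency: float = 2.0) -> ThreePrimeFivePrimeQC:
    """3′/5′ template-integrity ratio for one cDNA sample.

    ratio = E^(Cq_5p − Cq_3p): a low-quality or partially reverse-transcribed
    template amplifies later at the 5′ end, inflating the ratio. Passing
    range is [0.2, 5.0].
    """
    ratio = float(efficiency ** (cq_5p - cq_3p))
    ok = ThreePrimeFivePrimeQC.LOWER <= ratio <= ThreePrimeFivePrimeQC.UPPER
    return ThreePrimeFivePrimeQC(ratio_3p_5p=ratio, pass_=ok)
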