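"""Synthetic multi-tissue expression and qPCR data with known ground truth.

The generator emulates the study design every screen in this package is
built for: two biological replicate batches (plants grown in different
greenhouses) × four tissue types per species, ~10^3–10^4 genes, and a
designated subset of truly stable genes. It exists so that filtering,
CV ranking, fold-change screening, ΔCq analysis and concordance analytics
can all be exercised end-to-end — with a known answer — without any
external download.

Count model
-----------
For gene g in sample s = (tissue t, batch b):

    log2 mu_fpkm[g,s] = baseline_g + tissue_effect[g,t] + eps[g,s]
    eps[g,s] ~ Normal(0, noise_sd_g * inflation_b)
    counts[g,s] ~ NegBin(mean = mu_fpkm * len_g/1e3 * libsize_s/1e6,
                         dispersion phi_g)          (gamma–Poisson mixture)

Stable genes have near-zero tissue effects, small sample noise and minimal
dispersion, and baselines high enough to clear a qPCR-worthy minimum
expression; unstable genes draw tissue effects and dispersions from wide
ranges. ``batch_variance_inflation`` multiplies the noise SD (never the
mean) in every batch after the first, modelling an environment that
perturbs expression variability rather than expression level.

The qPCR arm converts true expression to quantification cycles through a
per-gene amplification efficiency E: Cq = Cq_cal − log_E(expr/expr_cal),
plus per-technical-replicate Gaussian cycle noise, for 4 biological
replicates × 3 technical replicates per tissue, and emits a matching
1:4-step dilution series per assay. Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMeta, UNIT_COUNTS
from .qpcr import CYCLE_CEILING, CqDataset, DilutionSeries

__all__ = [
    "QpcrSimConfig",
    "SimConfig",
    "GroundTruth",
    "QpcrSimResult",
    "simulate_expression",
    "simulate_cq",
]


@dataclass(frozen=True)
class QpcrSimConfig:
    """qPCR arm of the simulation.

    Efficiencies are drawn per assay from ``efficiency_range`` (the
    standard-curve method typically reports 83–102%, i.e. E in ~1.83–2.02);
    ``cq_noise_sd`` is technical cycle noise; ``bio_rep_sd`` is log2-normal
    biological variation between individual plants within a tissue.
    """

    efficiency_range: tuple[float, float] = (1.83, 2.02)
    cq_noise_sd: float = 0.15
    bio_rep_sd: float = 0.25
    n_bio_reps: int = 4
    n_tech_reps: int = 3
    calibrator_cq: float = 20.0
    dilution_factors: tuple[float, ...] = (1 / 4, 1 / 16, 1 / 64, 1 / 256, 1 / 1024)
    n_panel_stable: int = 4
    n_panel_unstable: int = 4


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the motivating design: 4 tissues × 2 batches, 5000
    genes of which 50 are designated stable. Log scales are log2; FPKM-like
    baselines span 2^-2 to 2^12 for unstable genes, while stable genes are
    drawn from 2^3 to 2^9 (a usable qPCR reference must be robustly
    expressed). ``batch_variance_inflation`` = 1 means batches are
    exchangeable; the default 1.5 encodes a moderate environment effect on
    expression noise.
    """

    n_genes: int = 5000
    n_stable: int = 50
    tissues: tuple[str, ...] = ("leaf", "stem", "petal", "calyx")
    batches: tuple[str, ...] = ("T1", "T2")
    seed: int = 0
    baseline_log_mean_range: tuple[float, float] = (-2.0, 12.0)
    baseline_log_mean_range_stable: tuple[float, float] = (3.0, 9.0)
    tissue_effect_sd_unstable: float = 1.0
    tissue_effect_sd_stable: float = 0.02
    sample_noise_sd_unstable: float = 0.3
    sample_noise_sd_stable: float = 0.05
    dispersion_range: tuple[float, float] = (0.05, 0.5)
    dispersion_stable: float = 0.002
    batch_variance_inflation: float = 1.5
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_range: tuple[int, int] = (8_000_000, 12_000_000)
    species: str = "synthetic"
    duplicate_leaf: bool = False
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or not self.tissues or not self.batches:
            raise ValueError("degenerate config: need >=1 gene, tissue and batch")
        if self.n_stable > self.n_genes:
            raise ValueError("n_stable cannot exceed n_genes")
        if self.batch_variance_inflation < 1.0:
            raise ValueError("batch_variance_inflation must be >= 1")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator knows and the screens must recover."""

    stable_gene_ids: set[str]
    tissue_log2_means: pd.DataFrame  # gene × tissue, log2 true FPKM
    dispersions: pd.Series  # gene -> NB dispersion phi
    true_fpkm: pd.DataFrame  # gene × sample, noise-free of counting error


@dataclass
class QpcrSimResult:
    """Simulated Cq dataset plus per-assay standard curves and truth."""

    dataset: CqDataset
    dilution_series: dict[str, DilutionSeries]
    true_rel: pd.DataFrame  # gene, tissue, bio_rep -> true expr / calibrator expr
    capped_records: int = 0  # records clipped at the cycle ceiling


def _sample_grid(cfg: SimConfig) -> list[tuple[str, str, str]]:
    """(sample_id, tissue, batch) in column order."""
    grid = []
    for b in cfg.batches:
        for t in cfg.tissues:
            grid.append((f"{t}_{b}", t, b))
    if cfg.duplicate_leaf and len(cfg.batches) > 1:
        b = cfg.batches[-1]
        grid.append((f"{cfg.tissues[0]}_{b}b", cfg.tissues[0], b))
    return grid


def simulate_expression(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, dict[str, int], GroundTruth]:
    """Draw a counts matrix, gene lengths, and the generating truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    n, k = cfg.n_genes, cfg.n_stable
    genes = np.array([f"g{i:05d}" for i in range(n)])
    stable_idx = rng.choice(n, size=k, replace=False)
    is_stable = np.zeros(n, dtype=bool)
    is_stable[stable_idx] = True

    baseline = rng.uniform(*cfg.baseline_log_mean_range, size=n)
    baseline[is_stable] = rng.uniform(*cfg.baseline_log_mean_range_stable, size=k)

    tissue_sd = np.where(
        is_stable, cfg.tissue_effect_sd_stable, cfg.tissue_effect_sd_unstable
    )
    tissue_eff = rng.normal(0.0, 1.0, size=(n, len(cfg.tissues))) * tissue_sd[:, None]

    noise_sd = np.where(
        is_stable, cfg.sample_noise_sd_stable, cfg.sample_noise_sd_unstable
    )
    phi = rng.uniform(*cfg.dispersion_range, size=n)
    phi[is_stable] = cfg.dispersion_stable

    lengths = rng.integers(*cfg.gene_length_range, size=n, endpoint=True)
    grid = _sample_grid(cfg)
    libsizes = rng.integers(*cfg.library_size_range, size=len(grid), endpoint=True)

    tissue_pos = {t: i for i, t in enumerate(cfg.tissues)}
    counts = np.empty((n, len(grid)), dtype=np.int64)
    true_fpkm = np.empty((n, len(grid)))
    for s, (sid, tissue, batch) in enumerate(grid):
        inflation = 1.0 if batch == cfg.batches[0] else cfg.batch_variance_inflation
        eps = rng.normal(0.0, 1.0, size=n) * noise_sd * inflation
        log2_fpkm = baseline + tissue_eff[:, tissue_pos[tissue]] + eps
        fpkm = 2.0 ** log2_fpkm
        true_fpkm[:, s] = fpkm
        mu = fpkm * (lengths / 1e3) * (libsizes[s] / 1e6)
        # gamma-Poisson mixture = negative binomial with var = mu + phi mu^2;
        # phi == 0 degenerates to plain Poisson
        safe_phi = np.where(phi > 0, phi, 1.0)
        lam = np.where(phi > 0, rng.gamma(1.0 / safe_phi, safe_phi * mu), mu)
        counts[:, s] = rng.poisson(lam)

    samples = [
        SampleMeta(
            sample_id=sid,
            species=cfg.species,
            tissue=tissue,
            batch=batch,
            library_size=int(libsizes[s]),
        )
        for s, (sid, tissue, batch) in enumerate(grid)
    ]
    values = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene_id"), columns=[g[0] for g in grid]
    )
    matrix = ExpressionMatrix(values, samples, UNIT_COUNTS)
    gene_lengths = dict(zip(genes, (int(x) for x in lengths)))
    truth = GroundTruth(
        stable_gene_ids=set(genes[is_stable]),
        tissue_log2_means=pd.DataFrame(
            baseline[:, None] + tissue_eff, index=values.index, columns=list(cfg.tissues)
        ),
        dispersions=pd.Series(phi, index=values.index, name="dispersion"),
        true_fpkm=pd.DataFrame(
            true_fpkm, index=values.index, columns=values.columns
        ),
    )
    return matrix, gene_lengths, truth


def simulate_cq(
    truth: GroundTruth,
    m: ExpressionMatrix,
    cfg: SimConfig,
    genes: list[str] | None = None,
) -> QpcrSimResult:
    """Generate a Cq validation dataset for a gene panel.

    By default the panel mirrors a typical validation design: a few
    designated-stable genes plus a few unstable ones. Per-biological-
    replicate expression is the gene's true tissue mean times log2-normal
    individual variation; Cq follows from the gene's amplification
    efficiency relative to the calibrator record, plus cycle noise per
    technical replicate. At zero noise the ΔCq analysis inverts this map
    exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    q = cfg.qpcr
    if genes is None:
        stable_sorted = sorted(g for g in truth.stable_gene_ids if g in m.gene_ids)
        unstable_sorted = sorted(set(m.gene_ids) - truth.stable_gene_ids)
        genes = (
            list(rng.choice(stable_sorted, size=min(q.n_panel_stable, len(stable_sorted)), replace=False))
            + list(rng.choice(unstable_sorted, size=min(q.n_panel_unstable, len(unstable_sorted)), replace=False))
        )
    missing = [g for g in genes if g not in truth.tissue_log2_means.index]
    if missing:
        raise ValueError(f"panel genes absent from ground truth: {missing}")

    efficiencies = {
        g: float(rng.uniform(*q.efficiency_range)) for g in genes
    }
    cal_gene = genes[0]
    cal_tissue = cfg.tissues[0]
    cal_sample = (cfg.species, cal_tissue, 1)

    # per-(gene, tissue, bio_rep) true expression on the FPKM-like scale
    expr: dict[tuple[str, str, int], float] = {}
    for g in genes:
        for t in cfg.tissues:
            base = 2.0 ** truth.tissue_log2_means.at[g, t]
            for r in range(1, q.n_bio_reps + 1):
                expr[(g, t, r)] = base * 2.0 ** rng.normal(0.0, q.bio_rep_sd)

    cal_expr = expr[(cal_gene, cal_tissue, 1)]
    records, capped = [], 0
    for g in genes:
        e = efficiencies[g]
        for t in cfg.tissues:
            for r in range(1, q.n_bio_reps + 1):
                ratio = expr[(g, t, r)] / cal_expr
                cq_true = q.calibrator_cq - np.log(ratio) / np.log(e)
                for tr in range(1, q.n_tech_reps + 1):
                    cq = cq_true + rng.normal(0.0, q.cq_noise_sd)
                    if cq >= CYCLE_CEILING:
                        cq, flag = CYCLE_CEILING, True
                        capped += 1
                    else:
                        flag = False
                    records.append(
                        {
                            "gene": g,
                            "species": cfg.species,
                            "tissue": t,
                            "bio_rep": r,
                            "tech_rep": tr,
                            "cq": float(cq),
                            "run_id": "run1",
                            "at_ceiling": flag,
                        }
                    )
    rec = pd.DataFrame(records)
    dataset = CqDataset(
        records=rec, efficiencies=efficiencies, calibrator=(cal_gene, cal_sample)
    )

    series = {}
    for g in genes:
        e = efficiencies[g]
        d = np.asarray(q.dilution_factors)
        cq0 = q.calibrator_cq  # arbitrary curve anchor
        cqs = cq0 - np.log(d) / np.log(e) + rng.normal(0.0, q.cq_noise_sd, size=len(d))
        series[g] = DilutionSeries(
            dilution_factors=tuple(float(x) for x in d),
            cq=tuple(float(x) for x in cqs),
            gene=g,
        )

    true_rel = pd.DataFrame(
        [
            {
                "gene": g,
                "species": cfg.species,
                "tissue": t,
                "bio_rep": r,
                "true_rel": expr[(g, t, r)] / cal_expr,
            }
            for g in genes
            for t in cfg.tissues
            for r in range(1, q.n_bio_reps + 1)
        ]
    )
    return QpcrSimResult(
        dataset=dataset, dilution_series=series, true_rel=true_rel, capped_records=capped
    )
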