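# refstab

Whole-transcriptome selection and qPCR validation of stably expressed
reference (housekeeping) genes.

Quantitative PCR depends on normalization against reference genes whose
expression barely moves across the tissues and conditions under study.
Traditional housekeeping genes (actin, GAPDH, ubiquitin pathway genes, …)
are often not actually stable, while a multi-tissue RNA-seq experiment
measures every gene's stability at once. `refstab` turns such an expression
matrix — genes × samples with tissue/batch metadata, in FPKM or raw counts —
into ranked candidate reference genes, and provides the qPCR arm needed to
validate them. It is aimed at groups working in emerging or non-model
systems (the motivating application was multi-tissue transcriptomes of two
monkeyflower species) where no validated qPCR references exist yet.

## What it computes

**CV screen.** Genes with expression below a floor (default 5 FPKM) in
*any* sample are excluded as unquantifiable. Survivors are ranked by the
coefficient of variation across all samples,

&nbsp;&nbsp;&nbsp;&nbsp;CV = s / x̄,

with the sample standard deviation (n − 1). Low CV = stable. A CV < 0.5 is
a common acceptability cut-off; the top-N list (default 50) is the
candidate pool.

**Fold-change screen.** After library-size (CPM) normalization, a gene is
eliminated if |log₂ FC| exceeds a cutoff (default 0.4) in *any* pairwise
sample comparison; what survives is a short list that never moves much
between any two libraries. Genes passing both screens are the strongest
candidates.

**qPCR validation.** Technical-replicate Cq values are averaged (a single
replicate deviating > 1 Cq is dropped); per-assay amplification efficiency
is fitted from a dilution series as E = 10^(1/−slope); relative expression
is the efficiency-corrected, calibrator-normalized

&nbsp;&nbsp;&nbsp;&nbsp;RQ = E^ΔCq,&nbsp;&nbsp;ΔCq = Cq_calibrator − Cq_sample,

and per-gene stability is the CV of tissue-mean RQ — directly comparable
with the RNA-seq CV because a change of calibrator rescales all RQ by one
constant and leaves the CV unchanged. A MIQE 3′/5′ integrity check
(acceptable ratio 0.2–5.0) is included.

**Concordance.** Pearson correlations of per-gene means and CVs between
replicate batches and between platforms quantify how transferable a
stability ranking is; means are correlated on the log₁₀ scale.

A seeded synthetic-data generator (negative-binomial counts, 4 tissues × 2
batches, designated stable genes, matching Cq data) makes the whole
workflow testable end-to-end with known ground truth.

## Worked example

```sh
refstab simulate --seed 3 --out-dir sim/
```

writes a synthetic 5000-gene counts matrix (`matrix.tsv`, `meta.tsv`,
`lengths.tsv`), a matching Cq table for an 8-gene validation panel
(`cq.tsv`, `efficiencies.tsv`), and the ground truth (`truth.tsv`). Then,
with a config naming those files (see `refstab run --help`; the calibrator
is the first gene in `efficiencies.tsv`):

```sh
refstab run --config run.yaml
```

prints

```
INFO refstab: pipeline summary: {'n_ranked': 2723, 'cv_below_cutoff': 408,
'top_n_max_cv': 0.12017436535387596, 'fc_retained': 29,
'overlap': {50: 29, 200: 29}, 'strong': 29}
```

meaning: 2723 genes survived the 5-FPKM filter and were ranked; 408 of
them have CV < 0.5; the 50 lowest-CV genes all have CV ≤ 0.120; the
fold-change screen at cutoff 0.4 retained 29 genes, every one of which is
also in the CV top 50 — so all 29 are `STRONG` candidates (both screens
agree). Per-gene tables land in `stability.tsv`, `fc.tsv`, `report.tsv`,
`concordance.tsv` and `qpcr_cv.tsv`, each with a provenance header.

The same operations are importable:

```python
from refstab import cv_screen, foldchange_screen, FilterPolicy
table = cv_screen(fpkm_matrix, FilterPolicy(min_expression=5.0))
```

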