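# Methods

## Problem setting

A qPCR reference gene must satisfy two conditions visible in a
multi-tissue, multi-batch expression matrix: robust expression (detectable
in every sample) and low variability across samples. `refstab` implements
two complementary whole-transcriptome screens for the second condition and
an efficiency-corrected ΔCq analysis to validate candidates on the qPCR
platform, plus concordance analytics to judge how far a stability ranking
transfers across batches and platforms.

The sample unit throughout is (tissue, batch): the reference design is
four tissue types (leaf, stem, petal, calyx) from each of two biological
replicate sets grown in different environments, i.e. eight exchangeable
columns per species. No tissue pairing across batches is assumed. An
optional duplicated leaf sample in the second batch is supported, mirroring
designs in which one batch lacks a tissue.

## CV screen

* **Filter.** A gene is excluded if its expression is below
  `min_expression` (default 5 FPKM) in *any* sample. The comparison is
  strict (`value < threshold` excludes), so a gene exactly at the floor is
  retained. Low-expressed genes are removed not because they are unstable
  but because they cannot be quantified reliably by qPCR.
* **Statistic.** CV = sd/mean per gene over all included samples, with the
  sample (n − 1) standard deviation. CV is scale-free, so it is unaffected
  by per-gene units and by any global rescaling — the property that later
  makes RNA-seq and qPCR CVs comparable.
* **Ranking.** Ascending CV; exact ties broken lexicographically by gene
  id so ranks are a deterministic permutation. Genes with zero mean
  (possible only on unfiltered input) are flagged and left unranked.
* **Summaries.** Counts below a CV threshold use strict `<` (default
  report threshold 0.5, a conventional acceptability cut-off for
  heterogeneous panels); the top-N list (default 50) reports its maximum
  CV.
* For allopolyploids, per-pair homeolog stability is reported as the
  arithmetic mean of the two copies' CVs. This is deliberately *not* the
  CV of the averaged expression (a different and generally smaller
  statistic); expression-level averaging is available separately in
  `average_homeologs`.

## Fold-change screen

Counts are normalized to counts-per-million (plain library-size scaling;
FPKM input is accepted as already normalized via
`NormalizationPolicy("none")`). For every unordered sample pair,
log₂((vᵢ + p)/(vⱼ + p)) is computed with pseudocount p = 0.5 (the usual
prior-count convention; immaterial after the ≥ 5 FPKM pre-filter). A gene
is retained iff its maximum absolute pairwise log₂ fold change is ≤ the
cutoff (default 0.4; the comparison is inclusive because genes are
*eliminated* for exceeding it). The retained list is ordered by worst-pair
fold change, and `method_concordance` reports its overlap with top-N CV
lists. TMM-style compositional normalization is intentionally not used:
the screen's purpose needs only library-size scaling, and any alternative
normalizer can be applied upstream.

## qPCR arm

* **Technical replicates** (typically 3) are averaged. If the spread
  exceeds 1 Cq, the replicate farthest from the median of the trio is
  dropped (ties keep the earlier-listed replicate) and the remaining two
  are averaged; two replicates more than 1 Cq apart have no identifiable
  outlier, so the record is excluded and logged.
* **Efficiency.** OLS of Cq on log₁₀(relative concentration) over a
  dilution series (≥ 3 points; the canonical series is five 1:4 steps).
  E = 10^(1/−slope); a perfect assay gives slope −3.3219 and E = 2. A
  non-negative slope is an assay failure, not a value. Percent efficiency
  is reported as (E − 1) × 100. Dilution factors are entered as
  concentrations (1, 0.25, …), not step indices.
* **Relative expression.** RQ = E_gene^(Cq_cal − Cq_sample). The
  calibrator is one fixed (gene, sample) combination; when a `run_id`
  column is present the calibrator Cq is resolved within each run
  (interplate calibration), otherwise globally. RQ is monotone decreasing
  in sample Cq for E > 1, and RQ = 1 where sample and calibrator Cq agree.
* **Stability.** Per gene, RQ is first averaged over biological replicates
  within each tissue, then CV is taken across the tissue means (≥ 2
  tissues required). Tissues can be excluded (e.g. a divergent floral
  tissue) to probe their influence. Because every RQ shares the calibrator
  factor, the CV is invariant to the calibrator choice.
* **3′/5′ QC.** ratio = E^(Cq_5′ − Cq_3′) with the gene's fitted E
  (default 2.0 when unknown); pass iff 0.2 ≤ ratio ≤ 5.0, bounds
  inclusive. Instrument-side processing (baseline correction, threshold
  setting, melt curves) is out of scope; the analysis starts from Cq.

## Concordance

Pearson r with the two-sided p-value from the t transform of r at n − 2
degrees of freedom (via `scipy.stats.pearsonr`). Replicate (batch-vs-batch)
comparisons exclude genes with mean < 1 FPKM in either batch, whose CVs
are dominated by counting noise. Means are correlated on
log₁₀(value + 10⁻³) by default — per-gene means span orders of magnitude
and the two platforms report on different absolute scales — with a raw-scale
option; CVs are always correlated raw. Platform comparisons take
pre-matched per-gene vectors (a validated panel), so no expression floor is
applied there. Constant vectors make r undefined and raise rather than
returning NaN.

## Synthetic data generator

The generator exists to give every stage a known answer. It draws, per
gene: a log₂ baseline (uniform on (−2, 12) for unstable genes — spanning
sub-FPKM to abundant — and on (3, 9) for designated stable genes, since a
usable reference must clear the expression filter); per-tissue effects
~ N(0, 1.0) log₂ for unstable vs N(0, 0.02) for stable genes; per-sample
environmental noise ~ N(0, 0.3) vs N(0, 0.05); and a negative-binomial
dispersion uniform on (0.05, 0.5) vs 0.002. Counts are gamma–Poisson draws
with mean FPKM·(length/10³)·(libsize/10⁶), lengths uniform on 0.5–5 kb and
library sizes on 8–12 million fragments. `batch_variance_inflation`
(default 1.5) multiplies the noise SD — never the mean — in every batch
after the first, operationalizing an environment that perturbs expression
variability more than expression level; increasing it degrades cross-batch
CV concordance while leaving mean concordance high, and the coupled random
streams make that trend clean under a fixed seed.

The qPCR arm simulates an 8-gene validation panel (4 stable + 4 unstable
by default) with per-assay efficiency uniform on (1.83, 2.02) (the range a
standard-curve method typically reports), biological-replicate variation
log₂-normal with SD 0.25, technical Cq noise N(0, 0.15) cycles, 4
biological × 3 technical replicates per tissue, and a matching noiseless-
slope dilution series per assay. The bio-replicate SD and Cq noise are not
taken from any dataset; they are fixed at values typical of careful qPCR
practice. At zero Cq noise the ΔCq analysis inverts the generator to
floating-point accuracy (the tests check relative error ≤ 10⁻⁹; observed
≈ 10⁻¹⁵).

What the generator does **not** emulate: homeolog sequence cross-talk,
GC/length biases, compositional (highly-expressed-gene) distortions of
library-size normalization, tissue-correlated batch effects, or Cq
censoring beyond a hard ceiling at cycle 40. Passing the synthetic
recovery tests therefore shows the algorithms are implemented correctly
and can separate designed stability classes — not that any particular
biological dataset will behave as cleanly.

## Numerical and interface choices

* Sample SD everywhere (n − 1), matching spreadsheet conventions.
* Log fold changes are log₂; the screen cutoffs are on that scale.
* Delimiter sniffing accepts tab or comma only; a header containing both
  is rejected rather than guessed. Missing cells are errors, not imputed.
* Ranked tables, screens and the pipeline are pure functions of
  (inputs, config, seed); output TSVs carry a `#` header with the tool
  version, a config hash and the seed, and contain no timestamps so reruns
  are byte-identical.
* Default problem sizes in the test-suite and the acceptance script
  (400–5000 genes, 8 samples, 8-gene qPCR panel) were chosen as the
  smallest designs that exercise every code path with comfortable
  statistical margins; the full default design runs in seconds.

## Known limitations

* The fold-change screen's exact retained set depends on the normalization
  and pseudocount convention; with FPKM-only input (no raw counts) the
  library-size normalization is approximated by treating FPKM as already
  normalized, which can shift genes near the cutoff.
* geNorm/NormFinder/BestKeeper-style pairwise-stability statistics and
  multi-reference normalization factors are out of scope by design.
* No differential-expression inference is offered; concordance analytics
  are correlation-level only.
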