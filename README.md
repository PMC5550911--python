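# lfquant

Label-free LC-MS/MS quantitation and differential protein expression for
two-condition designs with a handful of biological replicates — the common
shape of an ecological-physiology shotgun-proteomics experiment (e.g.
ovaries from animals acclimated at a control vs an elevated temperature,
five replicates each).

The package covers the full analysis path:

1. **Quantitation** (`lfquant.quant`) — selected ion chromatogram (SIC)
   extraction within a ppm mass window; peak detection by a multi-pass
   continuous wavelet transform run over increasingly narrower minimum peak
   widths (default schedule 20, 10, 5, 2 s; maximum width 80 s; S/N ≥ 10),
   with peak limits found by descent on the raw trace and areas by
   trapezoidal integration; fixed-window fallback integration around the
   SIC maximum when the detector finds nothing; retention-time alignment
   (monotone piecewise-linear warps through shared anchor peptides) to fill
   in peptides lacking an MS/MS identification in a given run; a minimum
   reportable area of 1000 (sub-floor measurements become *missing*); and
   normalization of every area to the spiked reference peptide DRVYHPF.
2. **Assembly** (`lfquant.assemble`) — peptide→protein rollup (sum of
   normalized areas), removal of proteins missing more than one measurement
   per condition, and log10 transform.
3. **Differential expression** (`lfquant.destats`) — per protein a
   two-sample Student's *t*-test **and** an exact Mann–Whitney *U*-test on
   the log10 intensities, Benjamini–Hochberg Q-values, and a fold-change
   cutoff expressed as 10·log10(FC) ("decibels"). The cutoff is anchored at
   the protein with the smallest fold change among those with Q < 0.05: an
   anchor at 1.6× gives 10·log10(1.6) = 2.04 → 2.0 dB, i.e. linear
   thresholds of 1.58 (up) and 0.63 (down). A protein is called `up`/`down`
   only when *both* p-values are < 0.05 **and** its fold change clears the
   cutoff.
4. **Ordination** (`lfquant.ordination`) — PCA with percent-variance
   reporting from unrotated eigenvalues (optional promax rotation for
   loading presentation) and 1 − Pearson-r average-linkage clustering for
   heatmap row/column ordering.
5. **Enrichment** (`lfquant.enrich`) — exact two-sided hypergeometric
   over/under-representation of annotation categories in the DE set against
   the full quantified reference list, BH-corrected.

A synthetic-data generator (`lfquant.synth`) emulates the study design —
log-normal intensities, a spiked reference row, configurable fractions of
truly regulated proteins with log10 fold changes spanning 0.2–2.2, a
missingness mechanism — and returns ground truth, so the whole pipeline is
testable end-to-end without any external data. External intensity tables
(e.g. a published supplementary matrix) can be ingested through a
column-mapping config instead.

## Worked example

```sh
$ lfquant run-all --seed 2 --outdir results/demo
analyzed 1523 proteins: up=31 down=29 — summary at results/demo/summary.json
```

This generates a 1532-protein synthetic experiment (5 vs 5 replicates,
~2% of proteins truly up- and ~2% truly down-regulated), filters it to the
1523 proteins with at most one missing measurement per condition, runs the
dual-test + anchor-cutoff decision rule, and calls 31 proteins up- and 29
down-regulated. `results/demo/summary.json` records the derived cutoff
(3.8 dB for this seed — the anchor protein's fold change sets it, so it
varies with the data), the linear thresholds, PCA variance fractions of
the DE-protein matrix (PC1 97.4%, PC2 0.6% here: the condition split
dominates), and parameter recovery against ground truth (sensitivity 1.00,
0 false positives for this seed). Stage-by-stage equivalents:
`lfquant synth`, `lfquant quant`, `lfquant de`, `lfquant ordinate`,
`lfquant enrich`.

The same pipeline from Python:

```python
from lfquant import (SynthConfig, DEConfig, generate_intensity_matrix,
                     filter_missingness, log10_transform, call_de)

matrix, truth = generate_intensity_matrix(SynthConfig(seed=2))
filtered, removed = filter_missingness(matrix)
results, meta = call_de(log10_transform(filtered), DEConfig(),
                        exclude=("DRVYHPF",))
print(meta["cutoff_db"], meta["n_up"], meta["n_down"])  # 3.8 31 29
```

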