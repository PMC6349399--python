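# silacq

Downstream analysis of two-condition SILAC (Stable Isotope Labeling with
Amino acids in Cell culture) proteomics, built around the label-swap
replicate design used to profile the proteome of DUX4-expressing muscle
cells, and the comparison of those protein-level changes with RNA-seq
fold changes.

The package is aimed at proteomics analysts who have a PSM
(peptide-spectrum match) level export from a search engine — peptide
sequence, gene symbol, quantification quality flags, heavy/light ratio,
originating run — plus a gene-level RNA log2 fold-change table, and want
reproducible answers to three questions: *which proteins changed*, *is
each change larger than resampling noise*, and *does it agree with the
transcript*.

## The analysis

**Quantification.** Each PSM's heavy/light ratio is converted to an
orientation-corrected log2(treated/control) value: `log2(H/L)` where the
treated sample carries the heavy label, `−log2(H/L)` in label-swap runs.
After per-replicate median centering, a protein's fold change within a
replicate is the **median** of its peptides' log2 ratios, and the final
estimate is the median across the label-swap replicates. The swap design
makes incomplete-labeling artifacts *anticorrelate* between replicates,
so the median merge pulls inefficiently labeled proteins toward
log2 FC = 0 instead of reporting a spurious change. PSMs carrying any of
seven quality flags (`Inconsistently labeled`, `Indistinguishable
channels`, `No quantitative values`, `Not unique`, `Redundant spectra`,
`Single peak spectra`, `Excluded by method`), unmapped peptides,
contaminants (cRAP-style lists) and uncharacterized genes are removed
first; genes seen in only one replicate, or with fewer than two peptides
in total, are set aside in a side table.

**Significance.** For a protein quantified from *n* peptides, the null
distribution is formed by drawing *n* values (with replacement) from the
pool of **all** quantified peptide-level log2 ratios and taking their
median, repeated B = 1000 times. The observed fold change is tested with
a two-tailed Z test against the mean and SD of that null:
`z = (obs − μ₀)/σ₀`, `p = 2(1 − Φ(|z|))`. An empirical-percentile p-value
and optional Benjamini–Hochberg q-values are reported alongside.

**Concordance.** Protein and RNA log2 fold changes are joined by gene
symbol, correlated (Pearson), and every gene is assigned exactly one
class using a change threshold *t* = 2 (4-fold) and a null band *b* = 1:
concordant up/down (both beyond ±t), `rna_only_*` (RNA beyond ±t, protein
within ±b — post-transcriptional *buffering*), `protein_only_*` (the
*discordant* genes, e.g. RNA-surveillance factors degraded without
transcript changes), `opposite`, `unchanged`, and `intermediate`.

A seeded synthetic-data generator produces PSM and RNA tables with known
gene classes, tunable peptide counts and noise, and a configurable
fraction of mislabeled proteins, so the whole pipeline is testable
without any download.

## Worked example

```sh
cat > run.yaml <<EOF
simulate:
  n_genes: 4000
  seed: 1
n_reps: 1000
seed: 1
outdir: report
EOF
silacq run-all --config run.yaml
```

The run logs every filter stage (no PSM is dropped without an
attributable rule) and writes seven files:

```
silacq: stage input_psms: 40090 rows
silacq: stage after_flag_filter: 39272 rows
silacq: stage quantified_genes: 3991 rows
silacq: stage excluded_genes: 9 rows
silacq: stage paired_genes: 3991 rows
```

`summary.tsv` then reads (abridged):

```
metric                              value
pearson_r                           0.5026515210777935
concordance_up_rna_conditioned      0.3220338983050847
concordance_down_rna_conditioned    0.9323308270676691
n_class_rna_only_up                 276.0
n_class_protein_only_down           175.0
n_class_unchanged                   3095.0
n_quantified_genes                  3991.0
```

Reading: the simulated experiment quantified 3991 genes (9 were excluded
for single-replicate coverage or <2 peptides); RNA and protein fold
changes correlate at r ≈ 0.50; 32% of strongly RNA-upregulated genes are
also up ≥4-fold in protein; 276 genes are buffered (RNA up, protein
flat) and 175 show protein-only downregulation. `significance.tsv` holds
the per-gene bootstrap null mean/SD, z, p and empirical p;
`paired.tsv` the per-gene class labels; `contingency.tsv` the 3×3
up/down/neither table. Individual stages are also available as
`silacq simulate | filter | quantify | test | concord`, and as plain
functions (`silacq.filter_psms`, `silacq.compute_significance`, …).

To analyse real data, point `psm_path` at a tab-delimited PSM export
(Proteome Discoverer 2.1 headers by default; other dialects via
`column_map`), `rna_path` at a `gene_id`/`rna_log2fc` TSV, and `design`
at a `replicate_id`/`orientation` table.

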