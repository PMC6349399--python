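# Methods

## Quantification model

A SILAC run measures, per PSM, the abundance ratio between the heavy and
light isotopic channels. With the treated sample heavy ("forward"
orientation) the peptide-level estimate of the treatment effect is
`log2(H/L)`; in a label-swap run the channels are exchanged and the
estimate is `−log2(H/L)`. All downstream statistics operate on these
orientation-corrected log2 ratios.

Peptide ratios are normalized by **per-replicate median centering**: the
median log2 ratio over all peptides in a replicate is subtracted, making
each replicate's peptide median exactly 0. This removes global mixing
offsets under the assumption that most proteins are unchanged; it is the
package default, `none` is available, and the choice is echoed in the run
metadata. Normalization happens at the peptide level, before roll-up, so
the protein summaries and the resampling pool are built from the same
values.

Protein-level roll-up is the **median of peptide log2 ratios per gene per
replicate** (midpoint convention for even counts), then the **median
across replicates**. Merging operates on log2 ratios; for two replicates
this is order-equivalent to taking the median of raw H/L ratios and then
logging, up to the normalization offset. The median-of-medians is what
gives the label-swap design its robustness: a protein that failed to
incorporate the heavy label produces a sign-flipped estimate in the swap
replicate, and the two-replicate median (= mean) pulls the merged value
toward 0 rather than averaging in a wrong sign at full weight. The
guarantee is |merged| ≤ max over replicates of |per-replicate estimate|
(a convex-combination bound); relative to the *correctly labeled*
replicate alone the bound can fail for near-null proteins where noise
dominates the signal.

Genes observed in fewer than `min_replicates` (default 2) replicates, or
with fewer than `min_peptides_total` (default 2) peptides overall, are
excluded from the main table but written to a side table with their
estimate and exclusion reason — single-peptide proteins can carry real
signal (a strongly repressed protein may drop below detection), so the
side table keeps them inspectable. Setting `min_replicates=1` supports
single-orientation designs, where the machinery reduces to orientation
correction plus roll-up.

## Bootstrap significance

The null hypothesis for a protein quantified from *n* peptides: its fold
change is what the median of *n* randomly chosen peptide ratios from the
whole experiment would show. Concretely, `build_null` draws *n* values
**with replacement** from the pool of all surviving peptide-level log2
ratios (pooled across replicates, after normalization), records the
median, and repeats B times (default 1000). The observed statistic tested
is the merged (median-of-medians) log2 FC. The test is a two-tailed Z
test: `z = (obs − mean)/sd`, `p = 2(1 − Φ(|z|))`, with the null SD using
the sample convention (divisor B−1). Each gene gets its own independent
null (vectorized by grouping genes with equal peptide counts), seeded
from a single RNG so the full table is reproducible.

Choices made where alternatives exist:

- *With replacement*: the standard bootstrap; for a pool of ~10⁵–10⁶
  ratios the distinction from without-replacement is negligible.
- *Normal-CDF p-values*: the sample median of n pool draws is
  asymptotically normal, and the Z test keeps p-values continuous at
  modest B; the empirical-percentile p (add-one corrected,
  `(1+k)/(B+1)`) is reported in `p_empirical` for comparison.
- *Degenerate nulls* (sd = 0, e.g. constant pools) raise an error per
  gene rather than yielding p = 0; a run fails only if all genes are
  degenerate.
- Multiple-testing correction is off by default; `correction="bh"` adds
  Benjamini–Hochberg q-values.

Calibration: under an all-null simulation (2000 genes, ≥2 peptides each,
B = 1000) the rejection rate at α = 0.05 and the Kolmogorov–Smirnov
distance of the p-values from uniform are checked by the acceptance
suite. The observed statistic (median-of-medians over two replicates of
~k peptides) and the null statistic (median of 2k pooled draws) have
asymptotically equal variance, so the nominal level is approximately —
not exactly — attained; the test band (±0.015) reflects this.

## Concordance classification

Genes with both protein and RNA measurements are joined by exact,
trimmed, case-sensitive gene symbol (no alias or ortholog mapping).
Correlation is the standard Pearson product-moment r. Classification
uses two thresholds, in log2 units:

- `change_threshold` t = 2 (4-fold), the conventional strong-change cut;
- `null_band` b = 1, the half-width of the "no change" band. This bound
  is a package choice — published scatter-plot gates for buffered and
  discordant regions are generally not stated numerically — so it is
  configurable and recorded in every report.

The class rules (evaluated in order; t and b with b < t): concordant up
(both ≥ t), concordant down (both ≤ −t), opposite (both beyond t,
opposite signs), rna_only_up/down (|RNA| ≥ t, |protein| ≤ b: buffering),
protein_only_up/down (|protein| ≥ t, |RNA| ≤ b: discordance), unchanged
(both ≤ b), intermediate (everything else). Genes between b and t are
deliberately *not* forced into a class; the partition stays exhaustive
and mutually exclusive. The 3×3 contingency table and the directional
concordance fractions (genes up at both levels / genes up at one level)
use t only; empty denominators yield NaN, never 0.

## Synthetic data generator

The generator emulates the features of the real experiment the analysis
relies on; it defines the conditions under which the package's tests are
meaningful.

- **Gene classes** with largest-remainder deterministic allocation:
  `concordant_up/down` (protein and RNA magnitudes drawn independently
  from Uniform(2, 6) log2 units, echoing strongly induced biomarker
  targets), `buffered_rna_up` (RNA Uniform(2, 6), protein within
  ±0.5), `discordant_protein_down` (protein −Uniform(2, 6), RNA within
  ±0.5), and `null` (both 0).
- **Peptide counts**: zero-truncated Poisson per gene per replicate; the
  parameter is the pre-truncation rate (default 5, ZTP mean ≈ 5.03).
  Real per-protein peptide counts are heavier-tailed; the ZTP keeps the
  essential features (variable counts, minimum 1).
- **Noise**: additive Gaussian on peptide log2 ratios (default SD 0.5,
  the magnitude of typical peptide-level scatter) and on RNA log2 FCs
  (default SD 0.5).
- **Mislabeling**: each gene fails heavy-label incorporation with
  probability 0.026 (the few-percent regime reported for incomplete
  SILAC labeling). The model is a sign flip of the corrected log2 ratio
  in swap replicates — the simplest mechanism that produces the
  characteristic anticorrelation between label-swap samples. No
  quantitative model of partial incorporation is attempted; only the
  consequence is reproduced.
- **Quality flags**: 2% of PSMs receive a random flag from the seven-flag
  vocabulary, exercising the filter path.
- **Back-transform**: stored H/L ratios are 2^(±corrected log2) according
  to the replicate's native orientation, with log-normal channel
  abundances consistent with the ratio so labeling-efficiency QC runs on
  simulated tables.

The default class mix {concordant_up 0.036, concordant_down 0.036,
buffered 0.07, discordant 0.05, null 0.808} was calibrated once, by a
small Monte Carlo over candidate mixes, so the default configuration
yields Pearson r ≈ 0.5 between paired RNA and protein estimates at
n_genes = 4000 — the correlation regime the concordance analysis is
designed for — and then frozen.

What the generator does **not** model: spectra, retention times,
search-engine scores, peptide-level FDR, protein-group ambiguity,
missing-value structure correlated with abundance, and shared peptides.
Passing tests therefore demonstrate the correctness and calibration of
the downstream statistics under the stated model, not robustness to
those upstream phenomena.

## Numerical and procedural choices

- Flag matching is exact-string and case-sensitive against the seven-flag
  vocabulary; unknown flags are retained. PSMs with missing or
  non-positive H/L ratios are removed at the quality-filter step.
- "Uncharacterized gene" defaults to `LOC\d+` symbols or names containing
  "uncharacterized"; the predicate is injectable.
- Medians use the midpoint convention for even counts throughout
  (identical to the sort-based definition, checked exactly in tests).
- Orientation round-trips (log2 → ratio → log2) are exact to ~1 ulp;
  "exact recovery" tests use 1e-9 tolerances to cover the float
  round-trip through stored ratios.
- Seeds: every stochastic component (generator, bootstrap) takes an
  explicit seed; sub-streams are derived via `SeedSequence` so tables are
  bit-reproducible across runs and platforms.
- Problem sizes in the test and acceptance runs (2000-gene calibration
  and recovery simulations, 4000-gene calibration run, B = 1000,
  B = 10⁵ for the enumeration comparison) were chosen so Monte-Carlo
  error is well inside each test's tolerance band.

## Known limitations

- The bootstrap null conditions only on peptide count, not on peptide
  intensity or variance heterogeneity between proteins; proteins with
  unusually noisy peptides are anti-conservative under this null.
- Replicate merging assumes exactly the label-swap structure for its
  artifact cancellation; with >2 replicates the median still applies but
  the sign-flip cancellation argument is pairwise.
- Gene-symbol joining will silently miss RNA/protein pairs that differ by
  aliasing; an identifier-mapping layer is out of scope.
- Published gene counts for buffered/discordant regions depend on the
  original authors' unpublished gate bounds and the deposited data; with
  the deposited tables present the pipeline reproduces the overall gene
  tallies (see the accession-gated test), but the region counts require
  the original thresholds.
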