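# Methods

This note documents the models, rules and numerical choices implemented in
`clonecna`, in the order the pipeline applies them, together with what the
synthetic cohort generator does and does not emulate.

## Copy-number states

Inputs are per-region *absolute* total copy numbers on genomic segments,
plus a per-region ploidy. No copy-number inference is performed; both are
upstream products (e.g. of ASCAT-class callers). The copy-number state of a
segment is the ploidy-adjusted log ratio

    r = log2(total_cn / ploidy),      r = −∞ when total_cn = 0.

States use strict thresholds on `r`:

| state      | rule                  | at ploidy 2       |
|------------|-----------------------|-------------------|
| high_gain  | r > log2(4/2) = 1     | > 4 copies        |
| gain       | r > log2(2.5/2)       | > 2.5 copies      |
| loss       | r < log2(1.5/2)       | < 1.5 copies      |
| neutral    | otherwise             |                   |

The gain and high-gain cuts follow the published definitions for this
analysis; a loss cut is needed for the loss frequency track but no published
definition exists, so the package mirrors the gain rule on the linear
copy-number scale (1.5 copies at ploidy 2). It is configurable
(`Thresholds.loss_log_ratio`) and recorded in output headers via the config
hash. Because the inequalities are strict, a segment at exactly 2.5/2 is
neutral and one at exactly 4/2 is a (non-high) gain.

**Focality.** Gains and losses on segments shorter than 20 Mb are *focal*,
otherwise *broad*. The printed threshold is the first broad length, i.e.
`length < 20 Mb → focal`, `= 20 Mb → broad`.

**Gene projection.** A gene's per-region state is taken from the single
*supporting segment*: among segments overlapping the locus, the one with the
largest overlap (ties broken by higher copy number, then leftmost start).
This keeps a gene's state single-valued per region; an `any_gain` projection
(most severe overlapping state wins) is available for sensitivity analysis.
A locus with no overlapping segment yields a `missing` call — a value, not
an error, since real segment tables do not always cover the genome.

## Clonality and tree placement

Per tumour and gene, presence means state ∈ {gain, high_gain} (a switch
restricts presence to high-level only). With `g` gained of `n` informative
regions:

* clonal: `g = n ≥ 1`; subclonal: `1 ≤ g < n`; absent: `g = 0`;
* regions with missing calls are excluded from numerator *and* denominator
  (their count is reported). Treating missing as not-gained would
  artificially convert clonal gains into subclonal ones, so it is rejected.
  A tumour whose every region is missing is `undetermined`, never silently
  absent.

Gains map to the phylogeny edge above the MRCA of the gain-bearing leaves;
clonal gains therefore map to the trunk. A subclonal gain whose bearing
leaves' MRCA subtends additional, non-gained leaves (a parallel-gain /
homoplasy-like pattern that no single edge explains) is mapped to that MRCA
edge and flagged `discordant = true`; it is never promoted to clonal. Trees
are inputs (newick, leaves = region ids); no tree inference is done.

Cohort summaries report, per gene: counts of absent / subclonal / clonal /
undetermined tumours, the gained fraction of the cohort, and the clonal,
subclonal and high-level fractions of gained tumours. Printed percentages
round half away from zero (34/46 → 74%, 39/80 → 48.8%), matching the
convention of the published splits.

## Recurrence: frequency tracks and the permutation null

Frequencies are computed on fixed-width bins, default 1 Mb (the width is a
package choice — no published value exists — and is configurable). A tumour
counts once toward a bin's gain frequency when *any* region has a gain-state
segment overlapping the bin by at least 1 bp; the clonal component counts
tumours whose *every* region covers the bin with a gain. Any-overlap
(rather than fractional weighting) was chosen for simplicity and because
published frequency tracks are step-like.

The null assumes gains and losses occur randomly along the genome. Per
permutation, each tumour's gained intervals — first merged across that
tumour's regions, since their union is what the observed any-region
frequency scores — are relocated independently: a chromosome is drawn with
probability proportional to its length (redrawn until the interval fits), a
start uniformly among valid integer positions, and the length is preserved.
Losses get a separate, identical treatment. All `B × n_bins` null
frequencies are pooled into one empirical distribution per direction, and
the recurrence threshold is its 95% quantile (linear interpolation). The
pooled null (one distribution for gains, one for losses) is an
interpretation; a per-bin mode would give bin-specific thresholds and is not
implemented because bins are exchangeable under uniform relocation.
Recurrent regions are maximal runs of contiguous same-chromosome bins whose
observed frequency strictly exceeds the threshold; each reports its max and
mean frequency.

Calibration note: with `n` tumours, bin frequencies live on a `1/n` grid, so
the strict-exceedance rate of the 95% threshold on a null cohort jumps
between binomial tail atoms around 5% (it is bounded above by 5% in
expectation and can sit well below it for a single cohort at n = 30). The
calibration check therefore averages the rate over replicate cohorts; the
test suite uses 8 replicates of 30 tumours, 500 bins, B = 1,000.

## Association statistics

* **Expression screen.** Per gene, a one-sided Wilcoxon rank-sum test that
  TPM in gained samples is stochastically larger than in non-gained samples.
  The reported statistic W is the Mann–Whitney U of the gained group. The
  p-value is exact (full enumeration) when `n1 + n2 ≤ 12` and there are no
  ties; otherwise a normal approximation with tie-corrected variance and a
  signed 0.5 continuity correction, matching R's `wilcox.test` (in
  particular p = 1 exactly at the null centre of a two-sided test). Genes
  without at least one sample in each group are reported untested.
  Benjamini–Hochberg correction is applied across the tested set — the
  "significantly gained and expressed" flag is `q < 0.05`; BH was chosen as
  the field-standard FDR procedure since no specific procedure is published
  for this screen.
* **Categorical associations.** Pearson chi-squared for driver-status ×
  clonality tables; the Yates continuity correction applies only to 2 × 2
  tables (where it is defined), even when requested for larger ones, so a
  df = 2 table yields the plain Pearson statistic. Zero marginals are
  validation errors.
* **Fisher exact.** Two-sided 2 × 2 p as the sum of hypergeometric
  probabilities of all tables with the observed margins whose probability
  does not exceed the observed table's (with a small relative tolerance on
  the comparison); degenerate tables with a zero margin give p = 1.
* **Segment sizes.** Supporting-segment lengths of clonal vs subclonal gains
  of the focus gene are compared with the two-sided rank test.

## FISH scoring

Cores are scored from paired per-cell target (gene probe) and reference
(1p12 probe) signal counts. The core ratio is `mean(target) /
mean(reference)` over evaluated cells (mean-of-cells; identical to
sum-of-signals for paired cell sets). Categories: ratio ≥ 4 high-level
gain; 2 ≤ ratio < 4 low-level gain; otherwise polysomy when the mean target
count exceeds 3 signals/cell, else no gain. The published low-level
definition ("≥ 2.0 and ≤ 4.0") overlaps the high-level one at exactly 4.0;
the more severe category wins at the boundary. Polysomy is only evaluated
when the ratio rule does not fire, keeping it a distinct non-gain category.
Cores with fewer than 20 cells (configurable) or zero mean reference are QC
failures: reported unscorable, never categorised. TMA summaries report the
gain percentage (high + low level) over scorable cores both excluding and
including polysomies, because published single-figure summaries are
ambiguous about polysomy inclusion.

## Synthetic cohorts

The generator plants events whose recovery the test-suite verifies:

* **Genome and loci.** A desk-scale 3-chromosome genome (100/80/60 Mb) with
  one focus gene per chromosome, so events for different genes can never
  overlap and the planted truth stays exact; an hg38 chromosome table ships
  for realistic runs. The small genome keeps a B = 1,000 permutation null
  in seconds.
* **Trees.** Caterpillar topologies (sufficient to exercise every MRCA
  placement class: leaf edges, internal edges, trunk).
* **Events.** Per tumour and gene: truncal with probability 0.5 (present in
  all regions) else branch with probability 0.2 (present exactly below one
  uniformly chosen non-trunk edge). Copy numbers uniform on {3,4,5,6} at
  ploidy 2, so planted levels split low (3–4) / high (5–6). Lengths are
  focal (exponential, mean 5 Mb, truncated below 20 Mb) with probability
  0.7, else broad (uniform between 20 Mb and the chromosome length). One
  optional truncal loss per tumour (probability 0.3, CN 1) is rejected away
  from gene loci and gain events so it cannot perturb planted gene states
  or focality.
* **Driver coupling.** Each tumour is driver-mutant with probability 0.5;
  when coupling is configured, the focus gene's branch probability is 0.6
  in mutant vs 0.1 in wild-type tumours (the regime used in the power
  checks).
* **Expression.** `log2 TPM = log2(50) + β · log2(cn/ploidy) + N(0, σ)`,
  defaults β = 1 (pure dosage), σ = 0.5. Noise is Gaussian on the log
  scale, so linear TPM is always positive.
* **FISH.** Per-cell Poisson counts with core means at the centre of each
  planted category (no-gain ratio ≈ 1, low ≈ 3, high ≈ 5, polysomy ratio
  ≈ 1.1 with mean target 3.8), so sampling noise over ≥ 20 cells rarely
  crosses a category boundary; reference counts are floored at 1 signal
  (a scorable nucleus shows its reference locus).
* **Uniform null cohorts.** A separate generator places gains uniformly
  along the genome in single-region tumours — by construction a draw from
  the relocation null — for the calibration and power checks.

What the generator does **not** emulate: measurement noise in copy numbers
(segments carry their planted values exactly, which is why 100% label
recovery is expected and informative about the calling logic, not about
robustness to noisy segmentation), purity/subclonal-fraction effects within
a region, correlated events between genes, whole-genome doubling, and
RNA-level regulation beyond linear dosage. Passing tests therefore validate
the decision rules and their composition, not performance on noisy real
segmentations.

## Named fixtures

`make_fixture` builds deterministic cohorts whose planted counts equal
published worked examples, so the summary path can be checked end to end:
`tracerx_luad` (= `tiny_mixed`; 61 tumours: 34 clonal + 12 subclonal gains,
10 high-level), `tracerx_lusc` (32; 19 gained, 1 high), `tcga_luad`
(652; 417 gained, 70 high, single-region), `tcga_lusc` (652; 211 gained,
28 high, single-region), `tiny_clonal`, and `tiny_fish` (three constructed
cores at means 4.5/1.0, 2.2/1.0, 3.5/3.3).

## Numerical and reproducibility choices

* All coordinates are 0-based half-open internally; SEG input is 1-based
  inclusive by default, BED 0-based half-open. Within-region segment
  overlap is an error (a region's segments must partition the genome), and
  chromosome names are matched verbatim unless an alias map is supplied.
* Quantiles use linear interpolation (numpy default); copy numbers are
  written with 6 significant digits and round-trip exactly at that
  precision.
* Every stochastic component takes an explicit seed; the pipeline re-seeds
  stages from its config, writes a config hash + seed into every output
  header, and emits a manifest of SHA-256 checksums. Outputs are written
  via write-then-rename so an aborted run leaves no truncated files.
* Problem sizes used by the test suite and the reproduction script —
  cohorts of 30–100 tumours, 500 × 1 Mb bins, B = 1,000 permutations,
  100 replicates for power estimates — were chosen so each property is
  measured with adequate Monte-Carlo precision while the whole suite stays
  desk-scale.

## Known limitations

* The permutation null relocates merged tumour-level gained intervals
  independently; collisions after relocation are allowed (only bin
  frequency is scored), and within-tumour spatial correlation of gains is
  not preserved.
* The clonality definition is presence/absence per region; identical
  copy-number *state* across regions is not required, and allelic identity
  of gains across regions is unknowable from totals.
* The expression screen treats regions of one tumour as independent
  samples, as the rank test requires; tumour-level pseudo-replication is
  not modelled.
* GISTIC-style peak significance (peel-off, q-values) is out of scope; the
  permutation threshold flags frequent regions, not focal peak boundaries.
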