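# Methods

## Model and assumptions

`crmkit` treats a CRM as a dense cluster of TF binding sites of
cooperating TFs. The observable consequence exploited throughout is
re-occurrence: when the binding peaks of many (TF, cell-type) ChIP-seq
experiments are pooled, the same genomic loci accumulate sites of motifs
that (a) co-occur within datasets, (b) recur as highly similar motifs
across datasets, and (c) sit close together inside peaks. The pipeline is
a chain of filters that keep exactly this structure and discard isolated
or dataset-private signal. Its assumptions, in decreasing order of
importance:

- cooperative TFs are reused across cell types, so pooling datasets from
  heterogeneous cell types enriches (rather than washes out) CRM loci;
- TFBSs of the ChIP-ed TF sit near peak summits, while its cooperators'
  sites may lie anywhere within roughly half an enhancer length — hence
  the fixed 1,000-bp re-windowing of every peak;
- inter-site spacing inside a CRM is at the one-to-two nucleosome scale:
  the 300-bp linking rule and the `150/r` distance weighting in the
  interaction score both encode it;
- selective constraint distinguishes regulatory from neutral sequence,
  which the evaluation and genome-budget modules consume as a per-base
  conservation score with a neutral band `[-δ, +δ]`, δ = 1.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_enrichment` | 20 | score | drop peaks with enrichment < 20 (strict) |
| `min_peaks` | 20 | count | reject datasets with < 20 surviving peaks |
| `window` | 1000 | bp | summit-centered window replacing each peak |
| `sc_cutoff` | 0.7 | — | CP selection: keep pairs with Sc strictly above |
| `sim_cutoff` | 0.8 | — | motif-graph edges: similarity strictly above |
| `max_gap` | 300 | bp | inclusive site-linking distance for CRMCs |
| `delta` | 1 | score | neutral band half-width |
| `p_cutoff` | 0.05 | — | significance call on empirical p-values |

These are the method's published operating points; every one is
overridable per run and recorded in the output directory's
`run_config.toml`.

Windows are clipped, never shifted, at chromosome ends, so the summit
stays centered; coordinates are 0-based half-open everywhere, and abutting
intervals share no base.

## Baseline motif finder

Motif discovery is pluggable (any external finder can be ingested through
the sites-TSV adapter); the built-in baseline is deliberately simple and
fully deterministic:

1. **Seeding.** All k-mers (k = 10, the modal width of mammalian core
   motifs) are counted on both strands. When window coordinates are
   available, counting is restricted to deduplicated genomic positions;
   otherwise several peaks covering one locus would let any background
   pattern repeated across overlapping windows look recurrent. A k-mer
   seeds a motif when its count is significant under a Poisson tail
   against the order-0 background expectation, Bonferroni-corrected over
   the 4^k k-mer space (α = 0.05). A z-score rule was rejected because
   expected per-k-mer counts at desk scale are far below one, where a
   single occurrence already lies many standard deviations above the
   mean.
2. **Estimation.** Starting from the seed (consensus base probability
   0.7), the PWM is re-estimated by ZOOPS-style EM — the single
   best-scoring site per window above 0.45 of the PWM's maximum log-odds —
   until `max |Δp| < 1e-4` or 50 iterations; pseudocount 0.5 per cell.
3. **Acceptance.** A converged motif is kept only if its number of
   high-scoring sites (above 0.65 of the maximum score) significantly
   exceeds (4 sd) the number of windows expected to contain such a hit by
   chance, computed exactly from the PWM's background score distribution
   (column-convolution DP, 0.05-bit bins). Shifted or reverse-complement
   rediscoveries are suppressed by window-position overlap with
   already-reported motifs.
4. **Site report.** The final site list contains *every* occurrence above
   a per-PWM threshold calibrated to a background hit probability of
   `site_fpr = 1e-4` per position (never below log-odds 0). One site per
   window would systematically under-annotate CRMs relative to the
   exhaustive scan used for null sequences and would break the p-value
   calibration; the FPR-calibrated threshold makes real windows and null
   sequences subject to the same site-calling rule. A locus-diversity
   filter (sites at ≥ `min_sites` distinct genomic loci) removes motifs
   whose support is one repeated region.

## Null calibration

Null sequences are sampled, one per CRMC and with exactly its length,
from a 3rd-order Markov chain fitted (pseudocount 1) to the CRMC
sequences themselves — matching length, composition and short-range
structure. A flag allows training on the whole covered region instead.
Each null sequence is scanned with the UM PWMs at the same FPR-calibrated
thresholds used for real site calls, sites are linked with the same
300-bp rule, and the best linked run is scored under a network whose edge
weights are a random permutation of the real ones. A null sequence
yielding fewer than two linked sites scores 0; when several runs form,
the maximum run score stands for the sequence, since the null set is
matched 1:1 to the CRMCs. The empirical p-value `p = #{null > s}/M` is
exact and non-increasing in `s`; zero p-values are rendered `< 1/M` in
reports. The FDR table bins both score sets at one score unit per bin,
sets `FP(b)` to the null count and `TP(b)` to the CRMC excess, and
accumulates both from the highest bin downward.

## Genome budget

The budget module is pure arithmetic over scalar inputs and is emitted in
two modes: full precision, and a printed-rounding mode in which each
checkpoint is rounded the way a report prints it (percentages to two
decimals; the FP fraction ceiled at three decimals of a percent — its
published value rounds upward; the density ratio to four decimals) before
feeding the next step. The printed mode exists because a chain of rounded
intermediates is the only way to reproduce a published chain exactly; the
full-precision column quantifies how much the rounding moves the result
(≲ 0.2 percentage points on the final fraction). The uncovered-region
step takes the covered fraction as an explicit input because published
chains do not always use the same value there as in the coverage
statement; both the covered and uncovered fractions are therefore
independent fields.

## Synthetic data: what it emulates, and what it does not

The generator plants the exact structure the pipeline's filters test for:

- background genome: i.i.d. bases, configurable frequencies (default
  uniform);
- one sharp PWM per TF (consensus probability 0.9 per column — a strong,
  well-defined ChIP consensus); planted sites are PWM draws, so site
  scores have realistic spread;
- 200 CRMs of mean length 1,000 bp (± 15%), mutually separated by
  ≥ 500 bp, each with 6–12 sites at sorted-uniform positions;
- cooperation: TFs are paired; whenever a paired TF is planted its
  partner is co-planted in the same CRM with probability 0.9, emulating
  obligate partnerships (cohesin-like). This choice makes the
  co-occurrence score distribution form a distinct high mode above the
  0.7 cutoff, the structure CP selection presumes; at weaker co-binding
  rates the "cooperative" mode straddles the cutoff and the fixture no
  longer represents the phenomenon the method was built around;
- datasets: one per (TF, cell type); 90% of peaks are centered on a
  planted site of the TF (summit jitter sd 20 bp; every site is sampled
  at least once when the dataset is deep enough), 10% are decoys placed
  outside all CRMs;
- conservation: background scores ~ N(0, 0.3), CRM positions
  ~ N(2.0, 0.3), written as run-length-merged 1-bp bedGraph.

Not modelled: read-level noise, peak calling, fragment-length effects,
repeat families, GC heterogeneity, chromatin-state confounders. Passing
tests therefore demonstrate that the pipeline recovers planted
cooperative structure from peak-level data with decoys and jitter — not
that it is robust to alignment artifacts or biased genomic composition.

## Numerical choices and degenerate inputs

- Interval arithmetic is exact integer half-open arithmetic; the
  CRMC/non-CRMC partition is property-tested against per-bp bitmask
  oracles.
- `S_INTER` floors the site distance at 1 bp (overlapping or abutting
  sites), bounding a peak's contribution at 150; a dataset containing
  both UMs but never in the same peak contributes 0 to the numerator but
  still counts in `|D|`. Distances are edge-to-edge between half-open
  intervals, consistent with the CRM-linking gap.
- `S_CRM` is computed with the identity
  `Σ_{i<j} w_ij (s_i+s_j) = Σ_i s_i Σ_{j≠i} w_ij` (vectorized, O(n²)
  memory in the number of sites); single-site CRMCs score 0 by convention
  since the `2/(n−1)` prefactor is undefined at n = 1, and they can be
  removed downstream by the p-value cutoff.
- PWM similarity requires ≥ 6 aligned columns; shorter overlaps score 0.
- Graph clustering uses greedy modularity communities per connected
  component, split into connected parts, with a density acceptance test
  (mean intra-cluster edge density ≥ cut-edge density) and a fallback to
  plain connected components (zero cut edges) when the test fails; the
  procedure is deterministic, and the seed parameter is part of the
  interface contract.
- Projected sites extending beyond the peak-covered union are kept with a
  warning rather than clipped; clusters whose pooled, deduplicated sites
  number fewer than `min_sites` yield a flagged no-UM record with the
  drop reason instead of disappearing silently.
- Missing conservation scores are excluded from denominators, never
  imputed; the proportion-of-neutrality requires scores for ≥ 99% of
  queried positions.

## Problem sizes

The test suite runs the full pipeline at the fixture's default scale —
2 Mb of genome, 100 datasets, 200 planted CRMs — where recall of planted
CRMs at p ≤ 0.05 is 0.92–0.95 across seeds; the null-calibration
uniformity check uses 5,000 matched null sequences of 600 bp against an
independent replicate. These sizes exercise every stage at meaningful
multiplicity while keeping a complete run in the minutes range on one
core.

## Known limitations

- The baseline finder reports one motif per seed family and at most 10
  per dataset; highly degenerate or variable-width motifs are out of its
  reach (widths are fixed at k within a run).
- `Sc` and `S_o` are peak-count based; a base-pair variant of `S_o` is
  available behind a flag but not used by default.
- The null model inherits 3rd-order composition from the CRMC set, so
  motifs longer than 4 bp are only partially represented in null
  sequences; this is the standard behaviour of Markov-background nulls.
- Functional-state calls are overlap-based (≥ 1 bp between a constituent
  site and an original peak of the cell type) and carry no probabilistic
  interpretation.
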