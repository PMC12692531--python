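# Methods

This note documents the models, defaults and design decisions behind
`carpoligo`, in the spirit of a statistical-methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Transcript model and gene collapsing

Annotations are read in GFF3 or GTF dialect (1-based inclusive intervals;
internal coordinates are 0-based half-open). Spliced sequences concatenate
exon intervals in annotation order and are reverse-complemented for
minus-strand transcripts. Transcripts without a gene parent are retained as
single-isoform genes (`gene_id = transcript_id`) so orphan records stay
designable. `N` bases are kept and masked downstream. Biotype comes from the
`biotype`/`gene_biotype` attribute or the feature type, defaulting to mRNA.

Collapsing picks the longest isoform per gene; length ties break to the
lexicographically smallest transcript id, which makes the operation
deterministic and order-independent (both properties are tested).

## Masking

Three mask sources, merged into disjoint sorted intervals (priority on
overlap: vector > low_complexity > ambiguous):

- **vector**: union of all maximal exact matches ≥ 15 nt to any vector
  sequence or its reverse complement, found as positions covered by any
  shared 15-mer (equivalent to the union of maximal matches ≥ 15).
- **low complexity**: DUST-style score per sliding 64-nt window,
  Σ c(c−1)/2 over triplet counts c divided by (n_triplets − 1); windows
  scoring > 2.0 are masked. Poly(A) and dinucleotide repeats score far above
  the threshold; uniform random sequence sits near 0.5.
- **ambiguous**: every `N` position.

## Probe scoring (declared surrogate)

Vendor base-composition scoring is proprietary. The surrogate used here is
declared and config-exposed:

    score = − gc_weight·|GC − gc_target|
            − homopolymer_weight·max(0, longest_run − max_homopolymer)
            − position_weight·distance_to_3prime/window

Defaults: gc_target 0.45, gc_weight 1.0, homopolymer_weight 0.5 (per excess
base over a 6-nt run), position_weight 0.5, score_floor −4.0, window
1000 nt, probe length 60 nt. The floor only excludes pathological candidates
(e.g. long homopolymers); an ideal candidate scores 0. This reproduces the
documented *behavior* of base-composition ranking — composition balance with
a 3' positional bias — without claiming equivalence to any vendor
implementation. Probes are sense-strand (the labeled cRNA is antisense in
oligo(dT)/T7 workflows, so sense probes hybridize it).

Selection per gene: `too_short` if the representative is < 60 nt, `masked`
if no candidate window survives, `design_fail` if none reaches the floor,
otherwise the top score wins (ties to the smallest start). `duplicate` is
assigned afterwards in gene-id order to exact repeats of an earlier gene's
selected sequence; near-duplicates are left to the cross-hybridization flag.

## Cross-hybridization screen

A probe is flagged iff, against a transcript of a different gene, it has an
exact contiguous match ≥ 25 nt or ≥ 45/60 matching positions in the best
ungapped 60-nt alignment; same-gene isoforms never flag. The exact-run rule
is tested by shared 25-mer lookup (lossless). The identity rule is evaluated
*exactly on every diagonal* using a vectorized sliding-window comparison
rather than seed-and-extend: at 45/60 identity up to 15 mismatches are
allowed, and by pigeonhole no seed longer than 3 nt is guaranteed to
survive, so any practical seeded heuristic provably misses near-threshold
paralog hits (we observed a missed 53/60 alignment with a 15-nt seed during
development). Exhaustive evaluation is exact, and fast at the scales this
package targets; genome-scale screening is out of scope. The screen is
verified against an independently coded scalar brute-force oracle.

## Array layout

Defaults mirror an 8 × 60K format: 8 subarrays × 62,976 features, 1,319
controls, 20 replicate probes × 10 copies. The split of the 1,319 controls
is not public; the declared default manifest is 330 spike-ins (10 dilution
levels × 33), 289 stringency probes, 700 corner markers. Replicate probes
are the first 20 designed probes in probe-id order and occupy only their
replicate-class positions. Remaining capacity takes each unique biological
probe at least once, then round-robin duplication. Placement is a single
seeded permutation per subarray; identical seeds give byte-identical design
tables. Grid width for row/col export defaults to 256.

## Scan QC

SNR = (median_signal − bg_median)/bg_pix_sd; a zero background SD is a hard
error. Detection: robust iff well-above-background AND SNR ≥ 3 (closed lower
bound), cautionary iff SNR ≥ 1.5, else low-confidence. Replicate spots
collapse to the median SNR and mean signal/background; the collapsed
well-above-background state is the conjunction over spots (conservative).
Arrays with non-uniformity/population/saturation flags are excluded from a
probe's SNR statistics but counted. DLRSpread is the robust SD of adjacent
log-ratio differences divided by √2, with IQR/1.349 as the robust SD (the
vendor's exact recipe is proprietary; this estimator is documented and
calibrated on Gaussian ratios in the tests). Spike-in performance is the
least-squares slope and Pearson correlation of observed vs expected log
ratios.

## Normalization and moderated t

Two pipelines, applied in fixed, provenance-recorded order (re-running a
step is an error):

- single channel: log2 (non-positive values floored per array at half the
  smallest positive value), 75th-percentile subtraction (linear
  interpolation between order statistics), baseline-to-median per feature,
  optional gene-level collapsing by median.
- two channel: M = log2 R − log2 G, A = (log2 R + log2 G)/2; LOWESS fit of M
  on A subtracted (span 0.3, 3 robustness iterations — conventional
  MA-normalization defaults, config-exposed).

The moderated t-test estimates the variance prior (d₀, s₀²) by
method-of-moments on log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
the excess of var(e) over ψ′(d_g/2) is inverted through the trigamma
function (Newton, tolerance 1e−13) to give d₀, and s₀² follows from mean(e).
No excess variance ⇒ d₀ = ∞ and the posterior variance equals s₀²
(normal-distribution p-values). Posterior variances are
(d₀s₀² + d_g s²_g)/(d₀ + d_g); p-values use d₀ + d_g df; BH step-up gives q.
Significance combines |logFC| ≥ log2(2.0) with raw p < 0.05 or q ≤ 0.05 — a
`criterion` switch defaulting to `bh_q`, because both conventions are in
live use for this platform class; the validation designs here use `raw_p`.
Contrasts are run on biological/replicate probes only: control features are
never tested for differential expression.

The test-suite reference for the moderated statistics is an independently
coded scalar oracle (bisection trigamma inversion, per-feature loops)
agreeing to 1e−10.

## Synthetic data

The generator's defaults are the study conditions of the validation
designs, chosen once:

- transcriptome: isoform counts 2–14 per gene (isoforms share exon subsets
  with distinct compositions; the longest keeps all exons), paralog families
  by uniform random point mutation to 0.92 identity, 30-nt poly(A) inside
  the terminal exon, vector and AT-repeat injections at 4% of genes each,
  exons 150–400 nt, introns 60–200 nt. Biotype mix 87.4% mRNA / 12.2% ncRNA
  / 0.4% miscRNA, mirroring the platform's detected composition.
- scan model: median = gain·2^expr·exp(ε) + background, ε log-normal with
  0.25 log2-scale SD, background truncated-Gaussian N(50, 10), gain 1,
  processed = max(median − bg_median, 1). Well-above-background when the
  corrected signal exceeds 2.6 background pixel SDs. Flag injection rates
  default to 0.1% (non-uniformity, population) and 0 (saturation).
- presets: `selfself` (3 arrays, identical channel truths for biological
  probes, spike-ins carrying their declared ±2 log2 ratio series) and
  `two_isolations` (8 vs 8 single-channel arrays, exactly 12 probes shifted
  +1.23 log2 units among ~5000 nulls). Base expression N(10, 1.5) log2;
  corner markers near background (2.0), stringency probes at 8.0.

What the simulator does *not* model: scanner physics, spatial background
trends, saturation nonlinearity, sequence-dependent hybridization
efficiency, or correlated probe effects. Passing end-to-end tests therefore
demonstrates the statistical machinery (normalization, shrinkage,
error-rate control, power at the injected effect size) — not robustness to
optical or spatial artifacts of real scanners.

## Problem sizes

Validation designs run at 5,000 biological probes + 100 controls per
subarray and 3 (self-self) or 16 (two-isolation) arrays — large enough for
stable variance-prior estimation and false-positive-rate measurement, small
enough to run in seconds. Brute-force cross-hybridization oracles run on
fixtures of ≤ 20 transcripts. The DLRS calibration uses 10,000 simulated
log ratios.

## Known limitations

- The probe score and the control-manifest composition are declared
  surrogates, not vendor reconstructions.
- Genome-scale design (tens of thousands of genes) is supported by the data
  structures but not performance-tuned; the cross-hybridization screen is
  quadratic in transcript count at probe length granularity.
- Detection-filter choices upstream of "detected transcript" counts on real
  data are exposed as parameters, not fixed: such counts depend on
  filtering conventions the toolkit does not impose.
- qPCR concordance assumes technical-replicate Ct means with no outlier
  rejection.
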