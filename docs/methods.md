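# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make results exactly
reproducible.

## Coordinates and formats

Internal coordinates are 0-based half-open on named chromosomes with strand
`+`, `-` or `.` (unstranded). GFF3 input (1-based closed) is converted at
the file boundary by the exact bijection internal = (gff_start − 1,
gff_end). BEDPE mate pairs follow a declared dialect: the 5' end of a `+`
mate is its start, of a `-` mate its end − 1, and the pair's transcribed
strand is the strand1 column (fixed-orientation library primers make read
orientation encode the RNA strand; the encoding itself is a convention, not
an inference). bedGraph tracks are one file per strand; zero runs may be
omitted on disk and are re-densified on read. Every reader/writer pair is a
lossless round trip on valid data, and every randomized operation is a pure
function of its inputs and an integer seed (numpy `SeedSequence` streams).

## Peak calling

* **Mate-pair filter.** Same chromosome and a 5'-end distance of 20–500
  bases, both bounds inclusive; removed pairs are counted per reason
  (cross-chromosome, too short, too long).
* **Fragment coverage.** Each pair increments every base between its 5'
  ends inclusive, on the pair's strand; the track total therefore equals
  Σ(span + 1), a conservation law the tests assert.
* **Candidate regions.** Maximal runs of raw coverage ≥ `min_region_coverage`
  (default 5 reads). The threshold applies to the raw signal; smoothing may
  dip region edges below it without invalidating the region. For simulated
  libraries whose uniform background is far deeper than 5× — e.g. 200,000
  pairs on 1 Mb give ≈ 20× per strand-base — the threshold must be matched
  to depth: per-base background coverage is Poisson-distributed with mean
  c_bg (computable from library size via `expected_background_coverage`),
  and ceil(c_bg + 6·√c_bg) bounds its upper tail so that false regions are
  expected in ≪ 1 base genome-wide while 20-fold-enriched regions sit far
  above it. The acceptance runs use that rule.
* **Smoothing.** A `w`-tap Gaussian kernel (default w = 5 taps, σ = 1
  base), taps ∝ exp(−offset²/2σ²) normalized to sum 1. The region is
  extracted with (w−1)/2 flanking raw-coverage bases per side (edge
  replication only at chromosome ends) so the smoothed signal has the
  region's length. σ is a free parameter of the method; 1 base is
  the smallest-assumption choice and is configurable.
* **Derivative.** d[i] = s[i+1] − s[i]; ascent is positive. The telescoping
  identity Σd = s[last] − s[first] holds exactly.
* **Pairing rule** (deterministic; ties broken leftmost). Within a
  derivative window, the ascending anchor is the globally maximal positive
  d; its partner is the most negative d after it within the maximum peak
  length. If the pair spans ≥ 20 bases it is accepted and the search
  recurses left of the anchor and right of the descent; otherwise the
  anchor is discarded and the search recurses strictly left and right of
  the anchor position, which guarantees termination and means no peak may
  span a discarded anchor. Peak length bounds (20–500, inclusive) match
  the mate-pair filter. A pure-Python exhaustive reference implementing the
  same declared rules by brute-force scanning is kept in the test suite and
  must agree exactly on random tracks.
* **Peak records.** start = maximal-ascending position, end = descending
  position + 1; the signed derivative extrema, the maximum raw coverage in
  the peak and the number of overlapping fragments are reported.

## Genomic context

Classification is a strict partition: sense if ≥ 1 base of a same-strand
gene is overlapped, else antisense if an opposite-strand gene is, else
intergenic. Sense precedence is declared (the flat three-way split does not
fix it). The genome-wide background is the same partition applied to every
(position, strand) of the genome.

The enrichment null re-places each RAP, keeping its length, uniformly over
all admissible (chromosome, strand, start) triples — chromosomes weighted
by admissible length, no end overhangs, overlaps between randomized RAPs
allowed (independent placement). Feature-class counting is strand-aware
(unstranded features match both strands) and counts RAPs, not bases: one
RAP overlapping three tRNAs adds 1 to the tRNA count. Empirical p-values
carry the +1 correction, p = (1 + #{b: count_b ≥ obs})/(n_boot + 1) for
enrichment and with ≤ for depletion; the result records both tails, the
smaller one with its direction, and enrichment = observed/mean(count_b)
(∞ with p = 1/(n_boot+1) if the expected mean is 0 and the observation is
not). Counting uses merged sorted intervals and `searchsorted`, which is
what makes 10⁵ vectorized randomizations per run affordable.

Calibration is checked by the null-recovery experiment the acceptance suite
runs: RAP sets placed by the randomizer itself must give an
enrichment-tail rejection rate near 5% at p < 0.05 and mean log2
enrichment near 0. The one-tailed rate is the calibrated quantity; the
reported min-tail p is by construction significant about twice as often
under the null, which is the price of reporting direction.

## Expression association

The gene universe is the supplied expression table. TPM segments are
right-closed: (0,1], (1,30], (30,80], (80,∞); zero-TPM genes fall into the
lowest segment and are counted in the log. A gene is a RAP gene if ≥ 1
sense RAP overlaps it, counted once. The cumulative curve orders genes by
ascending TPM (ties broken by id) and accumulates RAP genes; under uniform
assignment it tracks the diagonal.

Per segment, the observed RAP-gene count k is tested against
λ = K·(n_segment/n_total) (K = total RAP genes, so observed and expected
both sum to K) with the two-sided exact Poisson test in the
minimum-likelihood convention: p = Σ of all Poisson(λ) masses ≤ pmf(k)
within relative slack 1 + 1e-7, matching R's `poisson.test` (verified
directly against it and against pure enumeration to < 1e-10). Because
counts are discrete and multinomially constrained across segments, the
per-segment null rejection rate sits at or below the nominal level —
conservative, never anti-conservative.

## Pol II occupancy

All gene-body arithmetic is strand-aware: position 0 is the transcription
start, and `-`-strand genes read the minus bedGraph right-to-left.

* **Trimming.** 200 nt are removed from each gene end — the 5' end to
  avoid the initiation-proximal polymerase peak, the 3' end for symmetry.
  Genes whose trimmed body is shorter than 200 nt are excluded with a
  logged reason.
* **Deciles.** The trimmed body is split at round(i·L/10); density =
  signal sum / segment length. For boundary d ∈ 1..9 the log2 ratio of the
  mean density over deciles 1..d to deciles d+1..10 is computed — the focal
  decile joins the upstream side so each boundary is used exactly once. A
  boundary is "RAP-harboring" when a same-strand RAP overlaps its focal
  decile by ≥ 1 base. Because the ratio distribution depends on d (one
  decile versus nine on a side), harboring and non-harboring samples are
  compared per boundary with a two-sample KS test (exact small-sample
  method) and combined by Bonferroni over the boundaries tested — pooling
  across boundaries would confound RAP position with boundary index.
* **RAP-centric test.** Counts upstream (trimmed start → RAP start) and
  downstream (RAP end → trimmed end) are track sums rounded half-to-even
  (tracks may carry fractional multi-mapper weights; the test needs
  integers). Conditional on the total, n_up is Binomial(n, L_up/(L_up+L_down))
  under equal rates; the two-sided minimum-likelihood p is computed with
  `scipy.stats.binomtest` and cross-checked against enumeration to < 1e-10.
  Significance is strict (p < α, default α = 0.01); the log2 up/down
  density ratio is recorded, or set to 0 when not significant; the call is
  "decrease" when the downstream density is significantly lower. RAPs must
  lie fully inside the trimmed body with ≥ 20 nt on each side.
* **Randomized background.** Each tested RAP is re-placed on
  `n_background_genes` (default 100) eligible genes — trimmed body ≥ 200 nt,
  nonzero signal — sampled without replacement (with replacement only when
  fewer are eligible), at the same relative coordinates within the trimmed
  body (relative scaling preserves the up/down length proportions the test
  conditions on). Placements leaving < 20 nt on a side are re-drawn up to
  10 times, then skipped with a log entry.
* **Comparison.** Expected category counts are background proportions ×
  n_observed; χ² = Σ(obs−exp)²/exp with df = 2, merging increase+decrease
  (df = 1) when any expected count is < 1; the KS test compares the log2
  ratio samples with the nochange zeros included in both, consistent with
  the ratio-set-to-0 rule.

## Synthetic data

The generators produce the statistical structure each stage assumes, with
all truth serialized to JSON for joining by id.

* **Genome.** Chromosomes (default 2 × 500 kb) with 300-nt telomere tracts
  at the ends (unstranded `telomere` features plus a `telomeric_repeat`
  feature on the CA-rich strand; declared convention: `+` at the left end,
  `-` at the right). A repeat-string generator emits exact (C1–3A)n
  sequence. Genes (log-normal lengths, median 1.4 kb, clipped to
  500–4,000 nt; strand fair-coin) and auxiliary features (tRNA, snoRNA,
  ARS, LTR) are placed left to right with ≥ 100-nt gaps; the requested gene
  count is exact or an error is raised.
* **SELEX library.** Background fragments start uniformly over the
  two-stranded genome with lengths uniform on 30–400 nt. Planted fragments
  straddle their RAP with independent geometric overhangs (P(0) = 0.15,
  capped at 20 nt) on each side: late-round SELEX pools bracket the
  binding region closely, and an overhang distribution with its mode at
  zero puts the steepest coverage ascent and descent exactly at the RAP
  boundaries, which is what makes boundary-accurate recovery a fair test of
  the caller rather than of the jitter. Planted counts are sized so the
  expected RAP coverage is fold × background; with fold = 1 the library is
  exactly uniform.
* **Expression.** TPM ~ log-normal(μ = 3, σ = 2) (median 20 TPM; segment
  shares ≈ 6/51/18/25% across the four default segments). RAP-host genes
  are a weighted draw without replacement with weight `odds` (default 1) in
  the (1,30] segment.
* **Occupancy.** Per-base expected density along each gene =
  `mean_density` (default 0.2 read-ends/nt) × 2.0 within the first 200 nt
  (the initiation peak; the analysis trims it away) × an exponential
  decline reaching 60% of the post-peak level at the gene end × (1 − δ)
  downstream of a planted RAP's end (δ defaults to 0.4, the scale of the
  reporter-assay effect the screen motivated). Counts are Poisson;
  intergenic signal is zero.

Not modeled: sequencing-level reads, mapping ambiguity, PCR duplicates,
zero-inflation, per-gene expression-coupled occupancy levels, library-size
variation and replicate structure. Passing tests therefore demonstrate the
pipeline's statistical behaviour under clean Poisson sampling, not
robustness to those real-data artifacts.

## Problem sizes in the standard runs

The test suite and `scripts/acceptance.py` use: 200,000 pairs / 30 planted
RAPs / 1 Mb for peak recovery (recall at ±10 nt boundary tolerance);
100-RAP sets with 2,000 randomizations, 100–200 replicates, for enrichment
calibration (scaled down from the 100,000-randomization production
default); 10,000 placements for the up/down type-I error; 100 planted 40%
drops over a 300-gene cohort (genes ≥ 1.5 kb so both flanks hold enough
signal) with a 100-per-RAP background; 50–100 replicates of a 100-gene
cohort for the null decile comparison; and 2,000 genes / 200 RAP genes /
100–200 replicates for segment-test power. These sizes give each check
comfortable statistical resolution while keeping the full suite under a
minute of compute.

## Known limitations

* The pairing rule's behaviour after a discarded anchor (split at the
  anchor) is one of several defensible completions of the
  maximal-ascent/descent idea; alternatives (e.g. choosing the best anchor that *has* a
  partner) would call slightly different peaks in pathological regions.
* With fragment-length-scale autocorrelation in coverage, the candidate
  threshold is the only guard against false regions; on real libraries the
  default of 5 presumes the sparse background of a late selection
  round, and `--min-cov` should be raised for deeper or less-selected
  libraries (the depth-matching rule above).
* The enrichment randomization treats RAPs as independent; clustered RAPs
  (telomeric arrays) make the null slightly liberal for classes they
  cluster in.
* The decile comparison's Bonferroni combination is conservative when the
  effect spreads over many boundaries.
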