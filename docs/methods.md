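# Methods

This note documents the models, conventions and numerical choices behind
`etsgeo`, and what the synthetic-data tests do and do not establish.

## Coordinates and annotation

All coordinates are 0-based, half-open (BED convention). The TSS of a `+`
strand gene is its smallest annotated start; for a `-` strand gene it is the
rightmost transcribed base (`txEnd − 1`) — annotation sources rarely state
this convention, so it is fixed here once. Multi-transcript genes are
reduced to the most 5′ TSS. Promoters are the 1 kb immediately upstream
(`[tss−1000, tss)` on `+`, `[tss+1, tss+1001)` on `-`); promoters truncated
at a chromosome start are kept and flagged.

Promoter pairs: a `-`-strand TSS at or left of a `+`-strand TSS with
0 ≤ Δ ≤ 1000 on one chromosome is a bidirectional (divergent) pair; the
convergent arrangement within 1 kb is face-to-face. A TSS distance of 0
satisfies both inequalities and is classified bidirectional. Each gene joins
at most one pair: candidate pairs are taken nearest-first with
lexicographic tie-breaks, which makes the assignment independent of input
order. Note that at TSS distances 0–1 the two promoter intervals of a
bidirectional pair do not overlap under the definitions above; overlap is
guaranteed only for distances ≥ 2 (the synthetic generator samples pair
distances ≥ 2).

For region-level counting a bidirectional promoter region is a single unit:
the universe is `n_genes − n_pairs`, a region is bound if either member
gene is bound, and each region contributes once to every count. The
two-per-pair counting mode is exposed as a flag because the appropriate
universe is analysis-dependent.

## Coverage, normalization and binding calls

Each aligned read contributes a total mass of `normalization_factor =
(genome_length/1000) / n_reads` spread evenly over its bases, so the
genome-wide mean is exactly 1 read-equivalent per kb and a promoter
containing m reads scores `m × factor`. Partial overlaps count
proportionally; signal is therefore robust to read length.

The forward/reverse offset (fragment ends flank the binding point) is the
shift k ∈ [0, 500] maximizing the Pearson correlation between the forward
coverage and the reverse coverage translated left by k; reads are then
shifted toward the fragment midpoint by k/2. Note that for coverage (not
read-start) profiles the optimum is approximately `fragment_shift −
read_length`, which is what the estimator self-consistently corrects.

Binding threshold: pooled control promoter signals define s\* as the
smallest signal exceeded by at most a fraction `fdr` (default 0.005) of
control values. A promoter is bound iff **every** treatment replicate is
≥ s\* (replicate intersection — a consensus rule, not an average); if every
control replicate also passes, the promoter is flagged as bias and removed.
With all-zero controls the threshold falls back to the smallest positive
treatment signal, with a warning. The exact FDR estimator used by the
original analysis is not published; this one is deliberately simple and
monotone in `fdr`.

Peak localization inside a promoter uses a fixed 145-bp window (the
analysis's peak width) maximizing the windowed coverage sum. Ties are
resolved to the center of the leftmost maximal plateau: a flat pile-up
narrower than the window then peaks at its own midpoint, while genuinely
distinct tying pile-ups yield the leftmost — the two behaviors one wants
from a deterministic tie-break.

## Motifs and over-representation

Motif patterns are IUPAC strings; scanning reports all (including
overlapping) occurrences on both strands, a `-` hit being a position where
the reverse complement of the pattern matches the forward sequence. `N`
bases never match. The default pattern is the canonical ETS 7-mer
`CCGGAAG`; the fuller ETS motif set behind the published figures is not
available as a matrix, so the pattern list is configurable.

7-mer over-representation uses presence/absence per promoter (not
occurrence counts), counted on either strand, matching the promoter-level
contingency framing: for each of the 4^7 k-mers, an upper-tail
hypergeometric p-value with universe N = all promoters, K = promoters
containing the k-mer, n = bound promoters, k = bound promoters containing
it. Raw p-values are reported alongside a Bonferroni adjustment over the
16384 tests.

The hypergeometric upper tail is computed in log space (gammaln +
logsumexp) so that tails far below float underflow (real-data analyses of
this kind report p ≈ 1e-300 and beyond) remain finite and comparable;
`hypergeom_upper_log` exposes the natural-log tail directly.

## Copy-number curves

Promoters are binned by motif count k = 0..6; promoters with more motifs
(observed up to 13) are excluded as too few to analyze. The probability
curve is the bound fraction per bin. The exponential fit is log-linear
least squares over positive bins, with R the Pearson correlation of ln
value with k (the raw-space R is reported alongside, since which scale the
original correlation used is unstated); zero bins are reported but cannot
enter the log fit. An explicit `exclude_k` reproduces analyses that drop a
discontinuous final point. No standard errors accompany probability points
(they derive from replicate intersection, not averaging).

The signal curve divides each replicate's promoter signals by that
replicate's mean signal per promoter (replicate depth cancels; the grand
mean is exactly 1), summarizes each promoter by its replicate mean, and
reports per-bin means with standard errors across promoters (absent for
single-promoter bins).

## Spacing geometry and the resampling null

For promoters with exactly two opposite-strand motifs, distances are
center-to-center (symmetric, and consistent with the phase computation)
with the 7-mer center at offset + 3. Sign convention: left motif on `+`
and right on `-` point toward each other → face-to-face → negative;
the reverse → back-to-back → positive. Coincident centers are tie-broken
face-to-face at 0. Same-strand pairs are classified `direct` and excluded
from inverted-pair analyses.

The density track counts pairs in half-open 100-bp windows `[p−50, p+50)`
at every integer position p ∈ [−1000, 1000] (2001 positions).

The resampling null draws `sample_size` pairs with replacement from the
all-pairs population per run (default 2500 runs; reduced run counts are
used in tests for speed), computes each run's density track, fits a normal
(sample mean, SD) per position, and converts the observed count to an
upper-tail p-value (enrichment; depletion and two-sided tails are
options). Because window counts are integers, a half-count continuity
correction (obs − 0.5) is applied by default before reading the normal
tail: without it the upper tail is anti-conservative wherever counts are
small and right-skewed (the diminishing shoulders), which measurably
inflates the family-wise error over the 2001 positions. The uncorrected
textbook formula is available via `continuity_correction=False`.
Zero-variance positions are flagged (p = 1 unless the observation exceeds
the null mean, then the smallest positive float). The corrected alpha is
Bonferroni, 0.05/2001 — no correction procedure is named by the original
analysis, so the most conservative standard one is used.

## Helical phase

φ = 360°·(d mod 10.4)/10.4 mapped to (−180°, 180°], implemented via the
nearest-turn fraction to avoid float-mod artifacts at exact multiples of
the pitch (so 104 bp ↦ 0° exactly, 26 bp ↦ 180°). Negative distances use
their absolute value. Real pitch varies by up to ±1 bp/turn with
supercoiling and nucleosome winding — more than a full turn of uncertainty
over 100 bp — so phase profiles identify patterns, not accurate preferred
phases. Profiles use 40° circular windows on a 10° grid (the window is the
published choice; the grid step is ours), report bound/all ratios
normalized to mean 1, and fit a two-harmonic cosine series as the smooth
curve.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* ~4.4% of genes in bidirectional pairs (the human-genome proportion
  implied by 1081 pairs among 24707 genes), TSS distances uniform 2–1000;
  all other genes isolated by >2 kb gaps. Default 1000 genes on one
  chromosome (the full gene universe is ~25× larger; nothing in the
  analysis depends on genome size beyond statistical power).
* Motif copy numbers 0–13 with most promoters at 0–2 and a thin tail
  beyond 6, so the copy-number exclusion rule is exercised.
* Pair spacings from a mixture: 60% of mass uniform within ±49 bp (the
  sharp close peak), the rest with density decaying linearly toward ±1000
  (the diminishing shoulders); signs balanced. Backgrounds are scrubbed of
  spurious pattern occurrences so scanning recovers exactly the planted
  hits.
* Three factor archetypes: `p53` (P(bound|k) = 0.02·e^(0.8k), spacing
  kernel at −200 (SD 30), deep close-spacing depletion, constant signal),
  `ets1` (kernels at −50 and +200, constant signal), `gabpa`
  (zero-centered kernel, no depletion, signal ∝ k/2). The depletion well
  is super-Gaussian, `depth·exp(−(d/width)^8)` with width 70: flat-bottomed
  across the close-spacing range with sharp walls. A Gaussian well cannot
  reproduce the observed valley-at-zero/peak-at-−200 signature here,
  because closely spaced pairs are ~30× denser per bp than the shoulders —
  a well wide enough to suppress them also suppresses the −200 kernel.
  An optional von Mises phase preference (`phase_center`, `phase_kappa`)
  modulates binding by helical phase.
* Reads: uniform Poisson background (0.02 reads/bp per replicate), bound
  promoters add Poisson mass of `enrichment_fold ×` their 1-kb background
  (×k/2 under the proportional law) centered on the planted motifs, with a
  120-bp forward/reverse shift and 50-bp reads; controls are
  background-only. Everything is seeded; identical config + seed gives
  byte-identical outputs.

What the generator does **not** model: sequencing error, GC and
mappability bias, fragment-length spread, duplicate reads, chromatin
accessibility. Passing tests therefore demonstrate correctness of the
analysis pipeline under its own statistical assumptions, not robustness to
real-data artifacts.

## Problem sizes used in tests

The acceptance-level checks run at desk scale chosen for statistical
resolution: null calibration with a 2000-pair population, 400-pair samples,
500 resampling runs × 100 trials; kernel recovery with 6000 pairs; phase
recovery with 20000 pairs; exponent recovery with 2000 promoters per bin;
end-to-end call recovery with 800 genes and 3 + 3 replicates. The full
published analysis operates on ~25000 promoters and genome-scale read
sets; all algorithms here are linear or near-linear in those sizes.

## Known limitations

* The FDR estimator and the binding-overlap rule for isolated-site regions
  (peak center within ±500 bp of the region midpoint) are this package's
  documented choices; the original analysis does not specify either, so
  real-data p-values are universe- and rule-dependent.
* The 7-mer test treats promoters as exchangeable; GC or length
  heterogeneity in real promoter sets is not modeled.
* The resampling null treats pairs as independent draws; promoters
  contribute one pair each here, but correlated structure in real data
  (shared repeats, CpG islands) would narrow the null.
* Genome-wide peak calling is out of scope: binding is promoter-anchored,
  plus fixed windows around isolated motif sites.
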