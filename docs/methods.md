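# Methods

## Model and assumptions

The package operationalizes a regulatory-screen pipeline whose premise is
that the regulators of a small set of highly, cell-type-specifically
expressed genes bind preferentially near those genes' TSSs, on top of their
genome-wide binding. Four stages:

### 1. Regulatory potential

The influence of a TF on a gene is modeled as a sum over the TF's binding
regions of a kernel that decays monotonically with distance from the TSS:

    S(g, t) = Σ_{k : d_k ≤ W} exp(−(α + β · d_k / W))

with distance `d_k` measured from the binding-region **midpoint**
(`⌊(start+end)/2⌋`) to the TSS as an absolute base-pair difference. Midpoint
distance is the standard choice for this family of models and is symmetric in
the region's extent. Defaults: window `W = 100 000` bp, offset `α = 0.5`,
slope `β = 4.0`. At the TSS a single region contributes `exp(−0.5) ≈ 0.6065`;
at the window edge `exp(−4.5) ≈ 0.011`; beyond it, nothing. All three
parameters are configurable (`DecayParams`); the exponential form is one
standard monotone-decay choice and deliberately easy to substitute.

Assumptions: binding influence is additive across regions, chromatin contact
structure (loops) is ignored, and peak strength is not weighted — a region
either exists or it does not.

### 2. Empirical p-values and the target matrix

Scores are calibrated per TF against the whole gene universe:
`p(g) = #{g′ : S(g′) ≥ S(g)} / N`. The `≥` (rather than `>`) convention means
the strict top gene receives `1/N`, never 0, keeping downstream thresholding
semantics clean; tied scores share a p-value. Genes with no nearby binding
for any TF are retained as all-zero rows because they shape this empirical
null — dropping them would deflate every other gene's p-value.

`p ≤ cutoff` (inclusive) defines the binary target matrix. The default
cutoff is 0.01, a conventional stringency; it is surfaced prominently in the
config because it interacts with the universe size: with N genes at most
`⌊cutoff·N⌋` genes per TF can be targets, so small desk-scale universes need
laxer cutoffs for a 4-gene foreground to be admissible at all (see
Limitations).

### 3. Regulator screen

For one background set B and foreground F, each TF's binary target column m
yields

    raw(t) = mean_{f∈F, b∈B} |m(f) − m(b)|  −  mean_{{f,f′}⊂F} |m(f) − m(f′)|
    score(t) = raw(t) · sign(mean_F m − mean_B m)

The between-group term rewards columns that separate foreground from
background; the within-foreground term penalizes columns that are
inconsistent across the foreground itself; the sign keeps only
foreground-enriched TFs on top (sign(0) = 0). Within-background pairs are not
contrasted: background sets are small and numerous, and the discrimination
signal is the between/within-foreground contrast. For binary columns all
three terms are ratios of integer pair counts, and the implementation keeps
the counts integral until one final division, so it is bit-identical to a
literal pair enumeration (a property the test suite checks against an
independent brute-force oracle).

A replicate draws `n_background_sets` (default 1000) background sets of
`background_set_size` (default 8) genes uniformly without replacement from
the universe excluding the foreground, averages the per-set scores
(arithmetic mean: simple, variance-reducing, order-independent), and ranks
TFs descending by score with midranks on ties. The screen is repeated
`n_replicates` (default 7) times; replicate seeds derive deterministically
from the master seed via `SeedSequence(seed, spawn_key=(replicate,))`, so the
whole screen is a pure function of (inputs, seed).

Rank products `RP(t) = (Π_r rank_r(t))^{1/R}` are assessed against a pooled
Monte-Carlo null: each of `n_permutations` (default 10 000) draws an
independent uniform permutation of ranks 1..T per replicate, every TF slot's
rank product enters the pool, and
`p(t) = (1 + #{null ≤ RP(t)}) / (1 + pool size)` with the add-one correction
guaranteeing p > 0. This is distribution-free and exact enough at desk
scale; the gamma approximation to the rank-product null would be a possible
extension. Benjamini–Hochberg step-up q-values (via statsmodels) with the
default `q ≤ 0.05` select the top regulators, ordered by ascending rank
product with alphabetical tie-break.

### 4. CRM calling

Candidate CRM are clusters of selected-regulator binding regions near
foreground TSSs. "Near" is the half-open window `[tss − W, tss + W)` with
`W = 2000` bp by default — both sides of the TSS, since regulatory modules of
this kind occur in promoters and introns alike. Regions intersecting the
window are clipped to it *before* merging and length filtering, keeping the
"within 2 kb" guarantee literal. Merging is single linkage: two regions join
one cluster iff the gap between them is ≤ `max_gap_bp` (default 50 bp;
overlap counts as gap 0). A cluster is reported iff it contains
≥ `min_distinct_tfs` (default 2) distinct regulators, its clipped length lies
in `[min_len_bp, max_len_bp]` (defaults 50–400 bp, bracketing the size range
such modules typically occupy), and — when evidence tracks are supplied — it
overlaps **every** track by ≥ `evidence_min_overlap_bp` (default 1 bp).
Evidence tracks are generic interval filters, not signal tracks: qualitative
"coincides with open chromatin / conservation" semantics without bigWig
machinery.

This caller is a deterministic, parameterized replacement for identifying
such clusters visually in a genome browser; reproducibility is the point.
The thresholds a human applies by eye are unknowable, so every parameter is
explicit, tunable, and echoed in the output headers.

## Coordinate conventions

0-based half-open throughout (BED). For BED-derived annotations the TSS is
`start` on `+` genes and `end − 1` on `−` genes. Chromosome names match as
exact strings; a naming mismatch between annotation and peaks is logged as a
warning rather than silently coerced.

## Synthetic data

`SimConfig` generates one chromosome (default 10 Mb) of `n_genes` (default
200) genes at collision-free uniform TSS positions, `n_tfs` (default 20) TFs
with Poisson(`background_peak_rate`, default 300) uniformly placed fixed-width
peaks (default 200 bp), a foreground of `n_foreground` (default 4) genes
chosen by seeded shuffle, and planted TFs that additionally place — with
probability `planted_bind_prob` (default 1.0) per foreground gene — one peak
whose midpoint offset from the TSS is uniform within
±`planted_offset_max_bp` (default 1500 bp). Planted peaks are additional to
background binding (enrichment over a base rate). Peak overlaps are allowed;
the pipeline is overlap-tolerant and realism there buys nothing testable.

The defaults mirror the screen design the method was built around: a 4-gene
foreground, background sets of 8, 7 replicates, q ≤ 0.05. What the generator
does **not** emulate: multiple chromosomes, sequence content and motifs,
peak-strength variation, read-level noise, and correlated binding between
TFs. Passing tests on this generator therefore demonstrate the statistical
machinery (calibration, ranking, selection, clustering), not performance on
real ChIP-seq compendia.

## Numerical choices

- Empirical p-values are exact rationals k/N computed via min-ranks.
- The discrimination score uses integer pair counts with one final division
  (bitwise equal to pair enumeration).
- Midranks keep rank products well defined and unbiased under exchangeability
  when per-replicate scores tie.
- The permutation-null comparison `null ≤ RP` nudges the observed value by
  one ulp so null values produced by the identical float path count as ties.
- Matrix/ranking TSVs are written with `%.10g` floats, giving byte-identical
  reruns; the run manifest records every parameter, seed and input SHA-256.
- Degenerate inputs: empty peak sets score 0 everywhere; an empty selected-TF
  set yields an empty CRM file; a universe smaller than the background set
  size is a hard error naming both counts.

## Problem sizes used in validation

The test-suite and acceptance-script study conditions are 200 genes × 20 TFs
with 3 planted regulators, screens of 200 background sets × 7 replicates and
2000 permutations, run over batches of seeds — sizes at which every stage
completes in milliseconds to seconds while all Monte-Carlo tolerances (3
standard errors) remain meaningful.

## Known limitations

- **Cutoff/universe interaction.** At the default target-matrix cutoff 0.01 a
  200-gene universe admits at most 2 target genes per TF — fewer than a
  4-gene foreground, so no TF can score positively (3 of 4 foreground targets
  are needed) and the screen cannot select anything. Recovery at desk scale
  requires `cutoff ≥ (n_foreground − 1)/N`; the demonstration analysis uses
  0.05. On genome-scale universes (tens of thousands of genes) 0.01 admits
  hundreds of targets and this ceiling is immaterial.
- **Signal-to-background ratio.** A planted peak contributes ≈ 0.57 to a
  foreground gene's score, while at 300 background peaks per 10 Mb the
  200 kb scoring window holds ~6 background peaks (score mean ≈ 0.9,
  sd ≈ 0.5). Under those densities foreground genes are not reliably among a
  TF's top-ranked targets, so planted-regulator recovery additionally needs
  the sparser background of the demonstration regime (20 peaks per TF,
  offsets ≤ 500 bp) — densities closer, per megabase, to real ChIP-seq
  compendia than the compressed default.
- The exact decay kernel, rank-product null and q-value procedure are this
  package's documented choices within a family of reasonable options; each is
  isolated behind one function so alternatives are one-function swaps.
- No expression-matched or GC-matched background sampling; backgrounds are
  uniform over the non-foreground universe.
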