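# Methods

## Model and procedure

The statistic of interest is motif over-representation in a small
foreground promoter set relative to a universe of promoters.  The
procedure has five stages.

**Promoter universe.** Each gene contributes one fixed window around
its TSS, by default 2000 bp upstream plus the TSS base itself (2001 bp,
reading "(−2000; +1)" as inclusive of position +1; the window geometry
is configurable, so the alternative 2000-bp reading costs one
parameter).  One window per gene: alternative transcripts are collapsed
to the first TSS seen in the input.  Minus-strand windows are
reverse-complemented so position 0 is always the most upstream base.
Equal window lengths matter: every promoter then contributes the same
number of scanning windows, which makes the per-window recognition rate
a universe-wide probability.

**Scoring.** Count matrices become natural-log odds weights:

    w[i,b] = ln((c[i,b] + κ·q_b) / (N_i + κ)) − ln(q_b)

with background q (uniform by default; an option estimates
mononucleotide frequencies from the universe) and pseudocount
κ = 0.25·√N̄ (N̄ = mean column total), a standard motif-library
regularization that grows with matrix depth so deep and shallow
matrices are smoothed comparably.  A window's score is the positional
sum; windows containing N score −∞ and can never be hits, so masked
sequence cannot fabricate matches.  Both strands are scanned by
default; the reverse strand is scored by the reverse-complemented
matrix at the same offset.  Overlapping hits are all counted.

**ERR calibration.** For each motif all window scores over the universe
are pooled.  For each nominal expected recognition rate e on a
geometric grid (30 levels, 5·10⁻⁴ → 1·10⁻⁴), the threshold is the
smallest score t with #{score ≥ t} / #windows ≤ e; the realized ERR is
that fraction.  The choice is conservative (realized ≤ nominal) and
ties at t all count as hits.  The denominator counts windows summed
over positions × strands, excluding N windows; a per-promoter
normalization is available as a config switch for sensitivity analysis.
Thresholds are exact order statistics (full sort), no approximation:
universes at the scales this package targets are desk-sized.  A level
that no finite cutoff can satisfy (e.g. a degenerate motif whose
scores are all equal) gets a +∞ sentinel and realized ERR 0.

**Monte-Carlo enrichment.** The foreground is the promoter set of
significantly regulated genes in one direction (strict cutoffs,
defaults p_adj < 0.1, fold > 2); the background pool holds clearly
non-differential genes (p_adj > 0.1, fold in [0.80, 1.25], inclusive
bounds).  The p-value criteria are complementary, so the sets are
disjoint by construction.  Per threshold level, the foreground site
frequency — by default the fraction of promoters with ≥ 1 hit; a
per-window hit rate is the config alternative — is compared against
n_resamples (default 1000) background groups, each a uniform draw
without replacement of foreground size from the pool.  The same groups
serve all 30 levels (the group is the resampling unit, and per-motif
hit sets are computed once and thresholded per level — observable only
as identical output to naive recomputation).  Z = (AV_FOR − AV_BACK) /
SD_BACK with SD_BACK the sample standard deviation (n−1); the p-value
is the one-sided upper normal tail (enrichment only; depletion is a
flag).  If SD_BACK = 0 the normal fit is undefined: p falls back to 1
when AV_FOR ≤ AV_BACK, else to the Monte-Carlo floor 1/(n_resamples+1),
with a warning.

**Combination and ranking.**  The 30 per-level p-values are highly
correlated, so they are unified with Hartung's inverse-normal method:
t_i = Φ⁻¹(p_i), ρ̂ = 1 − var(t), ρ* = max(−1/(L−1), ρ̂),

    H = Σt_i / sqrt(L + (L²−L)·[ρ* + κ·√(2/(L+1))·(1−ρ*)]),  p = Φ(H)

with equal weights and κ = 0.2, the common default in the method's
literature.  Equal p-values are a fixed point (perfect-dependence
limit); a single p-value is returned unchanged.  Inputs are clamped to
[1e-300, 1−1e-16] before the transform; p-values of exactly 1 (the
SD = 0 fallback) are accepted and clamped rather than rejected, since
the Monte-Carlo step can legitimately produce them.  Unified p-values
are Benjamini–Hochberg adjusted across the collection; motifs are
ranked by p_adj with ties broken by unified p, then motif id, so output
order is deterministic.  Printed reports keep p_adj ≤ 0.05 by default;
full tables always retain every motif.

**Similarity matrix.**  Enriched motifs are often family variants of
one signal.  Pairwise similarity is the best ungapped alignment score —
mean Pearson correlation between aligned probability columns over all
offsets (≥ 4 overlapping columns) and both orientations — against a
null of column-shuffled copies of the second motif; p = (1 + #null ≥
observed)/(n_perm + 1).  This column-permutation test is this package's
own construction with the standard significance convention (p > 0.05 ⇒
distinct, blank cell); it is an interface-compatible stand-in for
permutation tests published elsewhere, and no attempt is made to
reproduce any external tool's numeric similarity values.  Uniform
columns have zero variance and correlate with nothing (contribution 0),
so flat motifs are never significantly similar to anything.

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d. mononucleotide promoters at configurable
base frequencies (default uniform, default length 2001 bp), plants
sites sampled base-by-base from a motif's probability columns at a
per-promoter rate (replacing bases, so length and window bookkeeping
are preserved), and emits DEG tables whose foreground/pool partition
the default selection recovers exactly.  Ground truth (which promoter,
which offset, which site) is always returned, enabling oracle tests.

It does **not** emulate: CpG islands, repeats, GC heterogeneity,
dinucleotide structure, promoter-proximal motif clustering, or
correlated expression noise.  Passing tests therefore demonstrate the
statistical machinery (calibration exactness, null uniformity, power
against planted signal, determinism), not performance on real genomes,
where background composition can inflate or deflate motif hits in ways
uniform backgrounds cannot show.

## Problem sizes in tests and the acceptance script

Simulated checks use desk-scale universes chosen to exercise the
regime that matters for each property:

* **Null calibration** runs 50 decoy motifs over a 300-gene universe at
  the default 2001-bp window with 200 resamples; the empirical fraction
  of unified p < 0.05 stays within the binomial band of 0.05.
* **Power / rank recovery** plants one informative motif (10 bp,
  ~14 bits) in 60 % of a 20-gene foreground over a 500-gene universe
  (500 resamples) and requires rank 1 with p_adj < 0.01.  This check
  uses 500-bp windows: at 2001 bp, a promoter offers ~4000 scan windows,
  so at the loose end of the ERR grid (5·10⁻⁴) the expected background
  hit count per promoter approaches 2 and the presence indicator
  saturates (background presence ≈ 0.86), leaving only the strict half
  of the grid informative.  Shortening the window keeps all 30 levels
  informative for a planted-signal recovery test at desk scale.  The
  saturation itself is a real property of the presence statistic at
  genome-scale windows and is listed under limitations.

## Numerical choices

* Log-odds in natural log; scores compared with ≥ at thresholds.
* Threshold selection: largest realized ERR not exceeding nominal;
  ties counted as hits; +∞ sentinel when unattainable.  Duplicating
  every promoter provably leaves thresholds unchanged.
* BH adjustment implemented as the exact step-up formula (and
  cross-checked against an independent implementation in the tests).
* All Monte-Carlo draws flow from a single integer seed through
  deterministic child streams (one per motif, one per motif pair), so
  identical seed + inputs ⇒ byte-identical output tables; reruns from a
  pipeline manifest reproduce identical output digests.
* Resampling without replacement is implemented by ranking uniform
  variates per row, vectorized across resamples.

## Known limitations

* The presence-based site frequency saturates when windows × ERR ≳ 1
  per promoter (see above); the per-window frequency mode is the
  mitigation but has its own variance behavior for clustered sites.
* The normal fit to the resampled frequency distribution is an
  approximation; for very small foregrounds (< ~10 promoters) and
  extreme ERR levels the discrete frequency lattice makes per-level
  p-values slightly anti-conservative in the far tail.  The acceptance
  checks quantify the aggregate effect at the defaults.
* Uniform scoring background; motifs calibrated on a universe with a
  very different composition than the scoring background may get
  distorted score rankings (the universe-estimated background option
  exists for this).
* The similarity test shuffles whole columns; nulls preserving
  inter-column dependence are out of scope.
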