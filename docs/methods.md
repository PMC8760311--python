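# Methods

This note documents the models, conventions and parameter choices behind
`remiscreen`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Tag lookup tables

A REMI insertion can occur wherever the genome carries a DpnII (`GATC`) or
NlaIII (`CATG`) recognition sequence; both motifs are their own reverse
complements, so enumeration is strand-symmetric.  Coordinates are 1-based
inclusive throughout.

**Tag convention.**  The literature specifies only that 19/20 bp of genomic
sequence flanking the insertion identifies it, not on which side of the cut
each tag starts.  We fix one convention: with the recognition sequence at
positions [p, p+3], the *upstream* tag is the L-mer ending at p+3 and the
*downstream* tag the L-mer starting at p, so both contain the motif at one
end, as the real MmeI-released junction fragments do.  Defaults are L = 19
for DpnII and L = 20 for NlaIII; both lengths are indexed.  All round-trip
guarantees rely only on internal consistency of this convention, which is
what the tests assert.

**Uniqueness.**  Mappability is decided by a genome-wide census: a tag is
`unique` when its sequence (or reverse complement) occurs at exactly one
locus.  Multi-locus tags whose occurrences all fall inside caller-declared
equivalent intervals (the large duplicated region of chromosome 2-style
repeats) are `inverted_repeat`; all other multi-locus tags are `non_unique`
and never contribute counts.  Tags containing `N` are dropped as
unmappable; tags that would run off a chromosome end are omitted with a log
message.

## Read processing

Reads are laid out adapter + vector + index + tag.  Matching is exact by
default (mismatch tolerances are configurable but default to 0, since no
tolerance is standard for these short fixed sequences); rejections are
categorised `no_adapter` / `no_vector` / `bad_length`.  Upstream and
downstream tag counts are summed per insertion point before analysis.

**PCR-artefact rule.**  True insertions generate junction fragments on both
sides of the cassette, hence reads under both vector indices.  An insertion
is flagged as a likely artefact when its reads come from a single index
*and* that index carries fewer than `min_index_support` reads (default 2).
The numeric threshold is a package choice — no standard value exists — and
is exposed in the API and CLI.

**Normalisation.**  `norm = raw × scale / sample_total`, with the default
scale equal to the *mean raw total across samples*.  This keeps normalised
counts on an absolute-read scale so that the ">100 normalised reads"
calling gates remain meaningful; normalising to, say, 10⁶ would silently
rescale those gates.

## Phenotype calling

Mutants are binned on mean normalised starting counts — low [0, 100), mid
[100, 1000], high (1000, ∞), a literal reading of the "<100 / 100–1000 /
>1000" bin definitions.  Log-fold change uses pseudocount 1 (normalised-
count scale) and base 2; both are configurable since no pseudocount is
standard.  z-scores are computed per endpoint sample within each bin using
the sample standard deviation (n−1); zero-variance groups map to z = 0.
Each replicate is z-scored separately and the replicate z's averaged — the
calls use a *mean* z while the count gates apply per replicate, which forces
this order of operations.

Calls: advantaged ⇔ mean z > 1.5 and every endpoint replicate > 100
normalised reads; disadvantaged ⇔ mean z < −1 and mean start > 100; mutants
with start < 100 that drop out (a normalised endpoint count of exactly 0)
are excluded because technical dropout dominates at low depth; the
endpoint-count gate deliberately applies to advantaged calls only and the
start-count gate to disadvantaged calls only.

Pleiotropy classes partition mutants: antagonistic (≥1 advantaged and ≥1
disadvantaged call) takes precedence, then positive (same-direction calls on
≥2 prey), conditional (exactly one non-neutral call), none.  Headline
summaries are restricted to mutants with >100 normalised starting reads.

**Tranche swaps.**  Mutants are split into top 25% / middle 50% / bottom
25% tranches of mean z per prey (tranche size k = round(n/4), ties broken by
stable sort).  Swap counts out of the top/bottom tranche between two prey
are compared against the same count computed between biological replicates
of one prey, which estimates switching attributable to measurement error
alone.

## Competition statistics

Relative growth is end − start frequency against a common reference from a
1:1 start.  A strain that fails to grow entirely on a bacterium (endpoint
frequency 0 in every replicate) receives the floor score −0.5, the largest
possible drop, so it stays rankable.

Means and standard errors per strain × bacterium come from a REML mixed
model with cell-mean fixed effects and random block and bacterium-by-block
intercepts.  With a single block the random effects are unidentifiable and
the fit reduces to raw cell means; if the REML fit fails to converge the
package falls back to an ordinary least-squares fit with sum-coded block
contrasts (block-adjusted cell means).  Reported df are within-cell
replicate df (n−1), used for Welch–Satterthwaite two-sample tests.

Tournaments: t = (m₁−m₂)/√(se₁²+se₂²) for every pair, BH step-up at FDR
5% applied across all pairs within a bacterium (a flag pools across
bacteria instead; "overall FDR" is ambiguous and both readings are
supported).  Win−loss = #significantly-beaten − #significantly-beaten-by;
rank 1 is best, ties broken by mean relative growth, residual ties share
their average rank and count as neither win nor loss.

**Permutation test.**  The null hypothesis is that performance across prey
is random: strain labels are permuted independently within each bacterium
and the number of rank-reversing pairs recomputed.  Since the pairwise test
depends only on each strain's (mean, se, df) — which travel with the label —
relabelling the precomputed per-bacterium rank vectors is mathematically
identical to refitting the tournaments, and is what the implementation does
(a test verifies the equivalence by brute force).  One-tailed
p = (#{null ≤ observed}+1)/(n\_perm+1) asks whether *fewer* reversals occur
than chance predicts; an exhaustive mode enumerates the full permutation
space for small instances.  The published scheme for this test is not fully
specified (raw observations versus estimates, per-permutation significance);
this package fixes the estimate-relabelling scheme and documents it.

Rank correlations use Spearman's ρ on mean performance (not on win-loss
ranks: the "average performance" reading), with unadjusted two-sided
p-values suppressed below 4 strains.

`constraint_threshold(N) = −1/(N−1)`: if overall predatory success is the
equally-weighted average of performance on N prey, an average pairwise
correlation at or below this value removes all genetic variance in the
average, so selection cannot produce a universal best predator.  At N = 6
the threshold is −0.2.

## Synthetic data

The selection simulator mirrors the experimental design: a shared starting
pool with log-normal abundances (σ = 1), duplicate selections per prey,
10 generations of growth per 48-h round, a 2.5×10⁵-cell bottleneck between
rounds, 10 rounds per prey with 20 on *K. aerogenes*, triplicate sequencing
of the start library, and multinomial sequencing at 3×10⁶ reads per sample
for the 10⁴-mutant default (tests use 2,000 mutants at 6×10⁵ reads — same
~300 reads/mutant regime — to keep runtimes in seconds).  Growth within a
round is deterministic exponential: at 2.5×10⁵ cells, within-round drift is
negligible relative to bottleneck and sequencing noise, and determinism
keeps the expectation analytic (E[log₂ fold change] = R·G·log₂ w), which the
tests exploit as an oracle.

Effect classes default to 80% neutral, 8% conditionally deleterious, 4%
conditionally advantaged, 5% positively pleiotropic (90% of them
deleterious), 3% antagonistic — loosely echoing the empirical pattern that
most effects are prey-specific and antagonism is rare.  These are generator
knobs, not biological claims.  The default effect size is ±0.04 log₂ units
per generation (0.4 per round, ±4 over a 10-round selection), the scale at
which the z thresholds should and do recover calls reliably.

Randomness is routed through named substreams (CRC-keyed children of one
seed), so adding a sample or prey never perturbs existing draws and
identical seeds give byte-identical outputs.

Competition observations are generated as start ≈ 0.5 plus effect, Gaussian
block and bacterium-by-block shifts, and Gaussian residual noise, clipped to
[0, 1] — exactly the structure the mixed model assumes.  Real assays publish
no noise model; this stand-in is deliberately matched to the estimator, so
the recovery tests validate the estimator's implementation, not its
robustness to misspecification.

The two-prey mixture model treats the prey supply as replenished: each
predator grows by its consumption-weighted factor x·w₁ + (1−x)·w₂ per
generation.  It reproduces the qualitative coexistence signature (an
interior mixture where neither strain wins) and nothing more.

**What passing tests show.**  The synthetic generators contain no PCR bias,
no index hopping, no chromatin-dependent insertion preferences, no
batch-varying library prep, and Gaussian competition noise.  Green tests
therefore certify the *computational* contract — exact round trips, correct
statistics, calibrated permutation p-values, faithful recovery under the
stated noise model — not performance on any particular real library.

## Numerical choices and degenerate inputs

- Bin edges are closed as [100, 1000]; boundary values fall in the middle
  bin.
- Zero-variance z-score groups and single-member bins yield z = 0.
- A pooled se of 0 in a pairwise test gives p = 0 for unequal means, p = 1
  for equal means; zero within-group variance in the ANOVA reports F = ∞,
  p = 0.
- Permutation tests with a single bacterium return observed = 0, p = 1.
- `n_perm` below 199 triggers a warning but still runs.
- Tranches require ≥4 mutants; tournaments with one strain are empty.

## Known limitations

- Tag lookup is exact-match by design; sequencing errors in the tag lose the
  read rather than being rescued by alignment.
- No gene-level aggregation of insertions, essentiality inference, or
  GO-term enrichment (the latter requires an external annotation database).
- The mixed model assumes Gaussian residuals on frequency differences;
  frequencies near 0 or 1 violate this.
- The permutation null median for reversal counts is scheme-sensitive;
  comparisons across studies should fix the scheme first.
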