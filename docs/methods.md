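# Methods

## Model and procedure

`lshotu` bins 16S rRNA reads into OTUs without computing pairwise
alignments. The unit of comparison is a randomized hash key: `k` distinct
positions are drawn uniformly without replacement from the admissible
centers of a read of effective length `n_eff`, and the key is the ordered
tuple of the `w`-wide windows (w-mers) centered at those positions. Two
keys are compared symbol-wise; a symbol either matches exactly or counts
as one mismatch, so the filter is a Hamming test over `k` w-mer symbols.
Widening `w` makes the filter strictly more stringent (fewer false
positives) at no extra sampling cost; allowing a mismatch budget > 0 and
repeating the whole procedure over `l` independent hash draws (merged by
union) reduces false negatives.

The greedy assignment is a leader algorithm: the pool is shuffled (or kept
in input order under the deterministic debug mode), the first unassigned
read seeds a new OTU, one sweep pulls in every pool read within the
mismatch budget *of the seed*, assigned reads leave the pool, and the
process repeats until the pool is empty. The union step is a transitive
closure: reads co-clustered in at least one iteration are joined in a
disjoint-set structure, so the final OTU count is monotonically
non-increasing in `l`. "Union" admits no other well-defined reading over
partitions, and transitivity is what lets a low-error read chain two
noisier reads of the same species together.

### Effective length

Hash indices are drawn once per iteration over a single `n_eff`, taken as
the length of the *shortest* read in the sample, so every read supports
every sampled window. Positions beyond `n_eff` in longer reads are never
sampled; for samples with strong length heterogeneity this discards
information from the read tails, a known limitation (trimming or binning
by length first is the practical workaround).

### Cutoff-to-budget calibration

The mismatch budget is the knob that maps the user-facing distance cutoff
`p` (maximum intra-OTU pairwise divergence, e.g. 0.03–0.10) onto the
symbol filter. Two modes exist:

- `symbol_fraction`: the literal rule `floor(p * k)` — `p` is the fraction
  of the `k` sampled symbols allowed to differ (k = 64, p = 10% → 6). This
  is exact for `w = 1` reads whose divergence is measured at the sampled
  positions themselves, but for `w > 1` it ignores that each substitution
  corrupts up to `w` windows.
- `divergence` (default): `p` is the target nucleotide divergence. Under
  an independent-mismatch approximation a window differs with probability
  `q = 1 − (1 − p)^w`, the number of differing windows is
  Binomial(`k`, `q`), and the budget is its `(1 − alpha)` quantile
  (`alpha = 0.05`). The per-comparison false-negative rate for a pair
  exactly at the cutoff is then at most `alpha`, and the `l` iterations
  drive the residual miss rate toward zero. At `p = 0` the budget is 0 in
  both modes: exact symbol identity.

The calibrated mode is the default because the literal rule demonstrably
over-splits at realistic settings: with k = 30, w = 3, p = 0.04 it allows
a single differing window, while two same-species reads each carrying 3%
error differ in ~5 windows on expectation. `alpha = 0.05` is a
conventional one-sided level, not a fitted constant; `alpha = 0.10` gives
a budget of 6 instead of 7 at the standard operating point and behaves
near-identically. The calibration assumes the reference species are
substantially more divergent than the cutoff region; when true
inter-species divergence approaches `p`, the binomial tail admits false
merges and the post-hoc validation step is the appropriate check.

### Collision probability

For `w = 1` and two reads differing at ≤ `m` of `n` positions, the
probability that their keys are identical is at least `(1 − m/n)^k` when
each index is drawn independently and uniformly. The implementation
samples indices *without replacement*, under which the exact collision
probability is the hypergeometric product `∏_{j<k} (n−m−j)/(n−j)` — at
n = 100, k = 30, m = 3 that is 0.3385 against the i.i.d. bound's 0.4010.
The Monte-Carlo verification of the bound therefore draws indices i.i.d.,
matching the bound's own probability model; the without-replacement choice
for the clustering hash is deliberate (repeated indices add no
discriminative power).

### Determinism

One master seed governs a run. Iteration `t` uses the generator seeded by
`(master_seed, t)`, consumed first by the index draw and then by the pool
shuffle, so iteration streams are nested: runs with `l` and `l + 1`
iterations share their first `l` hash functions. Given identical inputs,
parameters and seed, `otus.tsv` is byte-identical across runs. OTU labels
are `OTU_<i>` in order of cluster creation (first member's input-order
position after merging).

## Distances and validation

The clustering never aligns reads; `validate_cutoff` measures compliance
after the fact by computing all within-OTU pairwise distances and
reporting each OTU's maximum and the global maximum against the cutoff.

- **Global-alignment distance**: unit-cost Needleman-Wunsch (match 0,
  mismatch 1, gap 1, no end-gap discount) via edlib, normalized by the
  aligned-column count, giving values on the same [0, 1] scale as the
  cutoff. Co-optimal alignments can differ in gap-column count; the
  implementation canonicalizes the argument order so the reported value is
  symmetric and deterministic.
- **k-mer distance**: `1 − Σ min(count_a, count_b) / (min(n_a, n_b) − K + 1)`
  over K-mer multisets (default K = 6), the profile-distance family used
  by alignment-free OTU pickers. This exact form is this package's
  reconstruction of that family, configurable via `kmer_size`.

For very large OTUs an optional `max_pairs` subsample turns the per-OTU
maximum into a lower bound; the report is flagged `sampled`.

## Richness estimators

All estimators consume the OTU size histogram only (a sufficient
statistic). Chao1 uses the singleton/doubleton counts with the `+1`
regularizer so it stays finite when no doubletons exist. Shannon H′ is
reported in nats. ACE splits OTUs at `abund = 10` (the conventional
default) and exposes every intermediate (N_rare, coverage C, γ²) for
audit; its γ² term is `max((S_rare/C) · Σ i(i−1)n_i / (N_rare(N_rare−1)) − 1, 0)`,
with γ² = 0 when N_rare ≤ 1 (no variance estimable from ≤ 1 rare read).
Degenerate regimes: no rare OTUs → S_ACE = S_abund with no correction;
every rare OTU a singleton → coverage 0 and ACE is reported as undefined
(an error in the API, `NaN` in the CLI table) rather than extrapolated.

## Sample comparison

Samples from a *joint* clustering are reduced to presence/absence sets of
OTU labels; abundance-weighted variants are deliberately out of scope.
Jaccard similarity is computed pairwise, and samples are agglomerated by
average linkage on 1 − J (configurable), the standard choice for
beta-diversity heatmaps. Trees serialize to Newick with branch lengths
derived from merge heights. 1 − J is a metric, so average-linkage heights
are well-behaved; scipy's deterministic tie handling fixes the topology
for equal-height merges.

## Synthetic data generator

The generator emulates a marker-gene benchmark with known ground truth:

- **References**: uniform-random sequences, rejection-sampled to enforce a
  minimum pairwise Hamming divergence (default panel: 43 species, 200 bp,
  ≥ 0.20). Random panels in practice sit near 75% divergence; the floor is
  a guarantee, not the typical separation.
- **Reads**: full-length copies of a reference with a per-read
  substitution count drawn uniform on `[0, floor(error_rate · length)]`
  ("up to x% error" as a per-read maximum, not a per-base rate), positions
  uniform without replacement, every substitution changing the base.
- **Truth**: read → reference labels, scored by OTU count and
  majority-label purity. Purity rewards over-splitting (all singletons are
  pure), so it must be read jointly with the count.

What this does *not* emulate: indels and homopolymer errors (the hash
filter is position-based; real 454/Nanopore indel noise would require an
alignment-aware filter), chimeras, abundance skew, length variation, and
conserved/variable region structure of real 16S genes (uniform-random
references are far "cleaner" targets than real taxa, which share conserved
blocks). Passing the recovery benchmark therefore demonstrates the
algorithm's correctness under substitution noise and honest separation,
not field performance on raw amplicon data.

## Problem sizes

The shipped benchmark uses 43 species × 20 reads (860 reads, 200 bp) and
10 replicates, which one CPU clusters in a few seconds; the same code path
scales to the tens-of-thousands-of-reads regime linearly in reads × seeds
per iteration. Test-suite property checks use smaller draws (N ≤ 30 for
the brute-force equivalence oracle, 10⁵ draws for the collision-bound
Monte Carlo).

## Known limitations

- The greedy leader pass is order-dependent; the random seeding mode
  averages this out across iterations, but single-iteration partitions are
  not canonical.
- `n_eff = min(read length)` wastes tail information on heterogeneous
  samples.
- The divergence calibration assumes independent substitution errors;
  correlated errors (homopolymers) would inflate window mismatches beyond
  the binomial model.
- OTU-count monotonicity in the budget holds for the leader algorithm
  empirically but is not a theorem; pathological acceptance structures can
  in principle split differently.
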