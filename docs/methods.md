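# Methods

## Spaced words and frequency profiles

A *pattern* `P` is a string over `{1, 0}` of length `l` whose `k` ones mark
*match* positions and whose zeros mark *don't-care* positions; the first and
last characters must be `1`.  A *spaced word* under `P` is the tuple of
characters a sequence window shows at the match positions.  For a sequence of
length `n` there is one window per start position `i = 1 .. n-l+1`; a window
is valid when every match-position character belongs to the declared alphabet
(DNA `ACGT` or the 20 amino acids).  Ambiguity codes on don't-care positions
are tolerated by default (`strict=True` discards those windows too).  The
counts of all spaced words over the valid windows, divided by the number of
valid windows, form the sequence's relative-frequency profile under `P` — a
probability vector indexed by spaced words.

Compared with contiguous `k`-mers, spaced words of the same weight `k` have
the same expected frequencies under an i.i.d. model but much weaker
correlation between overlapping windows, which makes frequency-based distance
estimates less noisy.  Averaging over many random patterns suppresses the
remaining noise further; this is the package's *multiple-pattern* estimator.

## Hashing

Spaced words are identified by a 64-bit cyclic-polynomial (Buzhash) key.  A
fixed table `rtab` maps each of the 256 byte values to a 64-bit word; each of
the 64 bit columns of the table holds exactly 128 ones, built by shuffling
each column independently (the balance holds by construction, for every
seed).  With `s` the one-bit left barrel rotation, the hash of a window `w`
of length `L` is `XOR_j s^(L-j)(rtab[w_j])`, updatable in O(1) when the
window slides.  The spaced-word key keeps only the match-position terms; it
can be obtained either by XOR-removing the `l-k` don't-care terms from the
full-window hash or by accumulating the `k` match terms directly, and the
engine picks whichever route is cheaper per window (`l-k <= k` selects
removal).  All rotation exponents are reduced modulo 64.

Distinct spaced words may in principle collide on one 64-bit key; collisions
are not corrected, the key is simply treated as the word identity.  With
balanced tables the probability is negligible (the test suite audits every
fixture corpus and fails loudly on a collision; none has been observed).
Counting uses an associative container keyed by the full 64-bit value; the
classical fixed-capacity table sizing rule (smallest `b` with `2^b >=
min(|Sigma|^k, n-l+1)`) is exposed as `table_size_bits` for fidelity checks.

## Distances

For profiles `P`, `Q` (probability vectors over the union of observed keys,
absent keys counting as zero):

* Jensen–Shannon: `JS(P,Q) = KL(P,M)/2 + KL(Q,M)/2` with `M = (P+Q)/2` and
  `KL` in bits (`log2`, `0·log 0 = 0`).  With these half weights JS is
  symmetric, zero iff `P = Q`, and bounded by 1 bit (attained on disjoint
  supports).  The divergence itself is used; `sqrt_js=True` applies the
  square root (which makes it a metric) for sensitivity analysis.
* Euclidean: the L2 norm of `P - Q` over the union of supports.

A single pattern gives one distance matrix; a pattern set gives the plain
average of the per-pattern matrices.  Input probability vectors are validated
to unit sum within 1e-6.  The production path evaluates both metrics with a
compiled linear merge over the sorted sparse key arrays; keys unique to one
profile contribute closed forms (`p/2` bits for JS, `p^2` for the squared
norm), so logarithms are needed only on the support intersection.  The pure
Python map-based implementations in `distances` are the reference the kernels
are tested against.

## Trees

`neighbor_joining` implements Saitou–Nei agglomeration with the Q criterion;
ties are broken toward the lowest index pair, so results are identical across
runs and platforms.  On additive matrices the generating tree is recovered
exactly, branch lengths included.  Negative branch lengths on non-additive
input are kept (with a warning) for PHYLIP-compatible behaviour;
`clamp_negative=True` clamps them to zero.  `robinson_foulds` counts the
symmetric difference of the non-trivial bipartitions induced by internal
edges; multifurcations contribute exactly their induced splits.  Trees are
stored on dendropy structures, with Newick parsing/writing delegated to
dendropy (labels sanitized, branch lengths printed to 6 significant digits).

## Sequence-family simulator

The simulator produces families with a known reference tree, so benchmark
quality can be measured as the RF distance between estimated and generating
topologies.

*Tree model.*  A random binary topology is built by joining two uniformly
chosen lineages at a time.  Edge lengths model a radiation-like family:
terminal edges have unit base length, internal edges base length 0.12
(`internal_edge_scale`), each multiplied by an independent uniform factor in
[0.75, 1.25] (`edge_jitter=0.25`); all lengths are then rescaled so the mean
leaf-pair path length equals the *relatedness* parameter exactly (PAM units,
1 PAM = 0.01 expected substitutions per site).  Divergence is therefore
dominated by the terminal branches while the short internal edges set the
difficulty of topology recovery: at the default operating point (50 taxa,
16 kb, relatedness 70) roughly half of the splits sit below the noise floor
of contiguous 8-mer distances, the regime in which pattern averaging is
decisive.  The `internal_edge_scale` knob (default 0.12) moves the benchmark between the
trivially easy (near-ultrametric, large values) and the saturation-dominated
(very small values) regimes.

*Substitutions.*  Jukes–Cantor with equal base frequencies for DNA; for
proteins a 20-state equal-rate analogue of the same process, scaled so one
PAM equals 0.01 substitutions per site.  (A Dayhoff-style empirical rate
matrix would differentiate amino-acid exchangeabilities; the equal-rate
process was chosen because the package ships no empirical matrix data, and
the word statistics under study depend on divergence far more than on
exchange preferences.)  The per-branch difference probability is the closed
form `p = (A-1)/A (1 - exp(-A/(A-1) · 0.01 b))`, Monte-Carlo-verified in the
tests.

*Indels.*  Along a branch of `b` PAM, indel events arrive as
Poisson(`indel_rate · b · length`) with `indel_rate = 3e-4` events per site
per PAM; insertions and deletions are equiprobable, lengths geometric with
mean 2, positions uniform, insertion content i.i.d. uniform.  Leaves are
emitted unaligned.

*What the simulator does not model.*  Rate heterogeneity across sites,
GC/compositional bias, repeats and low-complexity regions, rearrangements,
codon structure, and empirical amino-acid exchangeabilities.  Passing
benchmarks therefore demonstrate estimator behaviour under a clean
substitution+indel process, not performance on genomes with strong skews or
repeat content.

## Benchmark and evaluation protocols

`run_benchmark` runs the full pipeline per replicate — simulate a family,
profile it, build the (multi-)pattern distance matrix, NJ, RF against the
generating tree — and reports the mean and sample SD of RF across
replicates.  Family seeds and pattern-set seeds are drawn per replicate from
one master generator, so a single seed fixes the whole experiment and the
contiguous and multi-pattern estimators can be run on identical families by
reusing the seed.

`rf_sweep` scans a grid of `(k, l, mode, m)` cells on one sequence set.
Single-pattern cells run one tree per distinct pattern (all patterns when
fewer exist than the resample budget — in particular the contiguous cell has
exactly one pattern and no SD); multi-pattern cells resample whole pattern
sets, or use the single all-patterns set when at most `m` patterns exist.

`variation_coefficients` isolates estimator stability: independent two-taxon
families are simulated at one relatedness (their true distance is then
identical by construction), the distance is estimated for every pair, and the
coefficient of variation (sample SD over mean, `ddof=1` throughout) of those
estimates is reported per configuration.

*Problem sizes.*  The shipped acceptance checks use 10 replicate families of
50 x 16 kb for the tree benchmark and 30 pairs for the CV protocol; both
match the reference operating point in sequence length, taxon count,
divergence and pattern budget, with replicate counts kept at the point where
the replicate SD is small against the tolerance bands.

## Numerical and design choices

* Frequencies are normalized by the number of *valid* windows, so profiles
  are exact probability vectors (required by JS); sequences shorter than the
  pattern yield empty profiles, which compare at distance 0 to each other
  and refuse comparison against non-empty ones.
* Pattern sampling is uniform without replacement; a request exceeding the
  number of existing patterns returns all of them.  For a length range, each
  pattern's length is drawn uniformly before its mask.
* Degenerate patterns: `k = l` is the contiguous word; `k = 1` exists only
  as the single-position pattern `"1"`.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical calls give identical results, and
  thread-parallel profiling (`workers`) never changes output.
* Reverse-complement canonicalization is deliberately absent by default:
  the method is defined on the given strand.

## Known limitations

* The JS estimate of between-profile distance saturates once divergence
  pushes shared word content to the random background level (around 60 PAM
  for contiguous 8-mers on 16 kb, around 120 PAM for 100-pattern averaging);
  splits whose resolution requires contrasts beyond that range are
  unrecoverable for any configuration of this estimator family.
* Multiple-pattern runtime grows linearly in the number of patterns.
* NJ is O(n^3) in taxa and the in-memory profile grid is O(m·n) in patterns
  and sequences; genome-scale inputs fit comfortably, but very large taxon
  sets will be NJ-bound.
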