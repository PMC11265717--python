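# Methods

## The design problem

Multistate protein sequence design asks for a single amino-acid sequence
that is simultaneously compatible with several structural states of the same
protein — the two folds of a fold-switching protein, the alternative binding
modes of a hub protein, the protomers of an oligomer.  `modesign` frames
this as Pareto optimization: one objective per state (plus optional
sequence-only objectives), minimization convention throughout, and an
explicit approximation of the Pareto front by an elitist genetic algorithm.
A design problem fixes the designable positions (1-based reference
numbering), the states, and a hand-curated tie map recording where each
position appears in each state; a position may occur in several chain copies
of one state (both protomers of a homodimer are tied to the same letter) or
be absent from a state.  Insertions and deletions are not modeled: the
design region has fixed length.

## Selection machinery

NSGA-II: at each iteration the population of size N is doubled by binary
tournament selection (lower front rank wins, larger crowding distance breaks
rank ties, a fair coin breaks the rest), n-point crossover (n = 2 by
default, applied with probability 0.9) and the mutation operator (applied
with probability 1.0).  The combined 2N pool is partitioned by repeated
non-dominated sorting; whole fronts are admitted until the limit, and the
last front is truncated by descending crowding distance.  Crowding distances
normalize by the front's own per-objective range; a zero-range objective
contributes zero (the degenerate case is well-defined).

NSGA-III replaces the last-front truncation with reference-direction
niching for higher-dimensional objective spaces.  Reference directions (one
per population slot) are generated by minimizing a Riesz s-energy
`sum 1/||x_i - x_j||^s` over the unit simplex: Dirichlet(1) initialization,
normalized gradient steps with Euclidean projection back onto the simplex,
s = d² and 1000 iterations by default.  The exponent and iteration count are
our choices; the two-point, two-dimensional case provably converges to the
simplex corners, which the tests assert to 1e-6.  Pool normalization uses
the ideal point and per-axis maxima of the current pool rather than
hyperplane intercepts — simpler and safe under degenerate pools (the
intercept construction can fail when the extreme points are affinely
dependent).  Members associate with the direction of smallest perpendicular
distance; the least-populated niches fill first, closest member for an empty
niche, random member otherwise, with seeded tie-breaks.

All randomness flows from a single seeded generator per run; each offspring
pair receives a spawned child generator in documented order
(generation-major, pair-minor), so serial and parallel evaluation give
bit-identical runs.  Duplicated sequences are allowed; the engine never
deduplicates, and population-average metrics count duplicates multiply
(population semantics).

## Mutation operator

The composite mutation operator factorizes into position selection and
residue proposal:

* **random** selection: each designable position enters the redesign set
  independently with probability mu; an empty draw is replaced by one
  uniform position, so the selected count follows Bin(n, mu) with the zero
  mass moved to one.
* **ranked** selection: positions are scored by the per-position
  log-probability of the current residue under a ranking profile (a
  language-model-style single-pass score); the k lowest-scored positions are
  taken, k = max(1, Bin(n, mu)), ties broken by lower index for determinism.
* **uniform** proposal: selected positions are resampled i.i.d. uniformly
  over the 20 standard amino acids (self-substitution allowed — the
  operator resets, it does not force a change).
* **conditional** proposal: selected positions are redesigned in a uniformly
  random decoding order; at each step the per-state logits (conditioned on
  the current sequence when the model carries pairwise couplings) are
  averaged with normalized non-negative state weights, divided by the
  sampling temperature (default 0.3), softmax-normalized, and sampled.
  With weights (1, 0) this reduces exactly to single-state decoding; with a
  flat table it is distributionally identical to uniform resetting.

Crossover draws its cut points without replacement among the L-1 junctions
and exchanges alternating segments (complementary offspring).  A note on the
uniform operator: picking each position from either parent with equal
probability agrees with the (L-1)-point operator in every single-position
marginal (under randomized parent order), but not in cross-position linkage
— maximal alternation is deterministic, per-position choice is independent.
The equivalence tests therefore compare the marginals and the per-position
offspring letter distributions, which is the level at which the two
operators are interchangeable inside the GA.

## Surrogate scorers

The scorers that would require neural-network inference at production scale
are replaced by pure table-driven surrogates behind the same contracts, so
that every scored quantity in the tests has a closed-form oracle:

* **Per-state log-likelihood**: the negative mean log-softmax of the raw
  per-position logits at the sequence's residues, over the positions present
  in the state.  Temperature-independent, shift-invariant, lower is better.
* **Folding-propensity composite**: the real metric is a product of three
  structure-prediction confidence terms, each in [0, 1].  The surrogate
  mirrors the product structure with three logistic squashings of the
  state's mean log-likelihood (midpoints and widths are fixture
  parameters; a sequence at all three midpoints scores 0.5³ = 0.125).  It
  is a declared stand-in with the right range, monotonicity and
  product form — not a calibrated equivalent.  As an objective the score is
  negated, making the origin the natural hypervolume reference point.
* **Per-position pseudo-likelihood**: log-probability of each current
  residue under a profile table in a single pass; the mean is the sequence
  score, and the per-position vector drives ranked position selection.
* Scorer averaging over stochastic repeats is a no-op for these
  deterministic surrogates; the bundle contract accepts any callable from
  sequence to float, so external adapters (including stochastic ones that
  average internally) plug in unchanged.

## Multistate assembly

States are combined into one coordinate file by rigid translation along +x
in input order, with neighboring centroids separated by exactly
`2·max(r_i, r_j) + r_min` where `r_i` is each state's CA bounding radius and
`r_min = 24 Å`.  For a collinear layout the adjacent separations imply the
pairwise inequality for every pair (each intermediate separation already
contains `2·max + r_min` terms), and the inequality in turn bounds every
inter-state CA-CA distance below by `r_min`; the tests verify the bound
exhaustively on random assemblies.  Chains are re-lettered A..Z, a..z, 0..9
deterministically (at most 62 chains) with original residue numbering
preserved, and a sidecar JSON records the chain renaming and the tied
position groups; unmodeled residues are omitted and never appear in tie
groups.

## Hypervolume

Exact mode slices recursively along the last objective (practical to ~8
dimensions; the 1-D and 2-D bases are an interval and a staircase sweep).
Points that do not strictly dominate the reference point contribute nothing
and are filtered first; an empty set has hypervolume 0.  Monte-Carlo mode
samples uniformly in the box between the points' componentwise minimum and
the reference point, and sizes the sample from the multiplicative Chernoff
bound `n ≥ 3 ln(2/δ) / (ε² p)` using a pilot estimate of the dominated
fraction p (with a one-sided lower confidence correction), targeting
relative error ≤ ε = 0.1 with probability ≥ 1 − δ = 0.95 by default.  The
(ε, δ) contract matches the published approximation scheme's operating
point; the internals (orthant rejection sampling) are our own.

## Synthetic data

The two-state toy generator plants a wild-type sequence and assigns each
position one of three classes: *non-conflicting* (both states give the
wild-type letter a logit margin `base_gap = 1.3` over a flat background),
*conflicting* (the wild type sits at `conflict_base = 2.4` in both states
while each state prefers a different alternative letter
`conflict_gap = 0.5` higher — the wild type is the runner-up in both
states, and the argmax of the equal-weight average), and *neutral* (flat
logits).  The defaults (24 non-conflicting + 12 conflicting positions,
mirroring a 36-residue design region) were set from the closed-form softmax
before any benchmark runs: at decoding temperature 0.3 the averaged
per-position wild-type probability is ≈0.80 at non-conflicting and ≈0.92 at
conflicting positions.  This construction gives the generator its purpose:
single-state decoding drifts to the state-specific optima, single-pass
averaged decoding recovers ≈0.84 of the wild type per sequence, and the
iterative GA's selection pressure is what closes the remaining gap — the
mechanism, not the numbers, of the full-scale behavior.  What the toy does
*not* emulate: context-dependent logits (an optional pairwise-coupling hook
exists but the default tables are position-independent), realistic score
correlations between states, or the score distributions of real structure
and language models; passing benchmarks on the toy demonstrates the
optimizer and operator machinery, not transferability to real proteins.

The enumerable biobjective problem restricts proposals' useful alphabet to 4
letters by making the other 16 strictly worse in both objectives at every
position, so the exhaustively enumerated 4-letter Pareto set is provably the
full 20-letter Pareto set (replacing an outside letter improves both
objectives).  Additive per-position objectives keep enumeration exact at
≤ 4⁸ sequences.

Toy structures are isotropic Gaussian CA clouds (σ = 6 Å — compact-domain
scale); reference sequence sets are i.i.d.-substitution clouds around the
planted wild type (positive set) and around a random decoy (negative set),
gap-free and aligned to the design region.

## Sequence analysis conventions

* BLOSUM62 similarity is the mean per-position substitution score;
  normalization divides by the geometric mean of the two self-similarity
  means, fixing `sim(a, a) = 1` and keeping the measure symmetric (the
  normalization convention was an open choice; this one is documented
  rather than inferred).
* The spectral embedding feeds the similarity matrix as a precomputed
  affinity after shifting by its global minimum plus a small positive floor
  (monotone, keeps weights positive); a disconnected affinity graph is an
  error that reports component sizes.
* Percentiles use linear interpolation between order statistics.
* Consensus ties break alphabetically; the representative sequence is the
  member with the highest identity to the consensus, ties by population
  index.
* Post hoc front baselines subsample without replacement, 100 resamples by
  default.
* Objective-space effective dimension is the number of principal components
  above the largest consecutive gap in the eigenvalue spectrum; per-position
  logit effective dimension is the cluster count from single-linkage
  clustering of the Pearson correlation matrix over per-chain logit vectors,
  cut at correlation 0.8 (equivalently distance 1 − r at 0.2).  A constant
  logit vector has undefined correlation and raises an error naming the
  state.

## Problem sizes used in the shipped benchmarks

The planted-recovery benchmark runs population 100 for 50 generations over
5 seeds, the paper-scale defaults of the algorithm; engine-correctness
checks run 500 random sorting instances (n ≤ 200, d ≤ 5) and 10 seeded GA
runs on the enumerable problem; operator statistics use 1e5 draws per
mutation rate; the Monte-Carlo hypervolume contract is audited on 200
3-point, 3-D instances.  These sizes are the package's own test design:
large enough for the distributional assertions' stated significance levels,
small enough to run on one CPU in minutes.

## Known limitations

* The surrogate scorers are context-free by default; autoregressive context
  effects (a large part of real inverse-folding behavior) are exercised
  only through the optional coupling fixtures.
* The composite folding-propensity surrogate shares its underlying signal
  with the log-likelihood score; at production scale the two objective
  families come from independent models and can disagree.
* Exact hypervolume is exponential in dimension (capped at 8 objectives);
  higher dimensions must use the Monte-Carlo mode.
* The shipped RfaH/PapD/CaM problem definitions carry real topology
  (states, chain multiplicities, designable positions) but synthetic
  placeholder wild-type sequences; analyses that depend on residue
  identities should load a real wild type into `make_problem`.
* No constraint handling, no structure relaxation, no alignment-based
  inference of tied positions.
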