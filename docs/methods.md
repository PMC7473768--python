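# Methods

## Model and assumptions

The population is well mixed, haploid, and single-trophic: individuals
compete but never prey on each other, and all types share the same
per-capita birth rate λ_b and background death rate λ_d (λ_b > λ_d, or
the population collapses). Competition kills: an individual of type *i*
dies from an encounter with a *j* individual at rate
d_ij = α + e^(−A_ij). The exponential map keeps every rate positive (so
the dynamics stays in the competitive Lotka–Volterra class) while letting
payoffs evolve unboundedly; α > 0 is the floor that caps the population
near (λ_b − λ_d)/α. Payoffs carry no trade-off, so selection pushes them
upward without limit and the interesting quantities are payoff
*differences*.

Mutation is resolved at birth: a newborn is a mutant with probability μ
(an equivalent factorization of the split birth rates λ_b(1−μ) and
λ_bμ). A mutant receives a fresh row, column, and diagonal of the payoff
matrix, each entry equal to the parent's corresponding entry plus an
independent Normal(0, σ²) draw. Independence per entry is a modeling
choice: a single shared draw would make the new row and column
rank-deficient and would leave the mutant's relations to all residents
perfectly correlated. The parent–offspring interaction is handled as the
self-interaction case of the same kernel: both A_i′i and A_ii′ start
from A_ii with independent noise.

Within-pair outcomes follow the sign pattern of (A_ii − A_ji,
A_ij − A_jj): both positive, type *i* excludes *j*; both negative, the
reverse; own-column advantage on both sides gives bistability;
cross-column advantage gives coexistence. Exact ties raise an error
rather than being silently broken — they have probability zero under
continuous payoffs, and silent tie-breaking would corrupt the
enumeration oracles that the classifiers are tested against.

## Simulation engine

The stochastic process is simulated with the exact (direct) Gillespie
method; no tau-leaping. Same-type competition uses ordered victim–killer
pairs among distinct individuals, rate d_ii x_i (x_i − 1): an individual
cannot kill itself, and the O(1/N) difference from x_i² is invisible at
Lotka–Volterra scale. Analyses are indexed by the mutation-event counter
t (one unit per mutant birth); continuous reaction time is recorded but
not used as an axis. Snapshots of (abundances, payoff matrix) are taken
at every mutation event.

The founder's self-payoff is drawn from Normal(ln 1000, 1), and the
founding abundance is set to the rounded deterministic one-type
equilibrium (λ_b − λ_d)/d₁₁ (configurable to any fixed integer). Starting
at equilibrium keeps early stochastic extinction from dominating
small-α comparisons; extinction statistics are still collected and
extinct runs are excluded from ensemble averages, which for triplet
quantities also require at least three extant types at the time point.
Each realization r of an ensemble uses seed (base + r); identical
configurations reproduce byte-identical outputs.

## Deterministic verification layer

The two-type sign-rule classifier is verified against direct integration
of the Lotka–Volterra equations (LSODA, relative tolerance 1e-8).
Outcomes are read from the asymptotic state reached from a grid of
initial conditions: fractions {1−1e-6, 0.99, 0.5, 0.01, 1e-6} of the
single-type carrying capacities. The tiny-invader starts matter: a
bistable pair can have a basin of attraction far thinner than one
percent (a near-tie in one column puts the interior saddle at a
vanishing abundance of one type), and percent-scale starts then fix the
same winner from every start. Integration proceeds in chunks with a
fourfold-growing horizon until every type is either clearly extinct
(below 1e-9 of total density) or clearly persistent (above 1e-4);
a pair that shows opposite winners from different starts is bistable
even if the symmetric start converges to the saddle itself. Draws that
never settle are flagged indeterminate, never silently classified.

## Triplet statistics

The interaction network assigns each unordered pair its outcome class;
every 3-subset is then cyclic (the three dominance links form a directed
cycle), non-cyclic (a transitive tournament), or mixed, and
χ = cyclic/(cyclic + non-cyclic). Two code paths exist: a scalar,
tie-checking route through the network objects, and a vectorized census
straight from the payoff matrix used for time series; the test suite
holds them equal on random matrices.

Triplet identity for lifespan tracking is the unordered member set plus
the motif class and its orientation (cycle direction, or source/sink).
A link flip that changes the motif closes the old record and opens a new
one — a flipped link is a different motif. A record closes at the first
snapshot where the motif is absent; its lifespan is the difference of
the two snapshot times, in mutation events. Records still open at the
last snapshot are right-censored and excluded from lifespan
distributions (reported separately). Lifespan distributions are
summarized as complementary cumulative distribution functions,
CCDF(x) = P(lifespan > x).

## Trait-vector similarity

Member *l* of triplet {i, j, k} is summarized by the 6-vector
(A_li, A_lj, A_lk, A_il, A_jl, A_kl); the diagonal entry legitimately
occupies two slots (row copy and column copy). One shift constant per
triplet — the mean of the 18 pooled entries — is subtracted before each
vector is normalized, making the three pairwise scalar products
invariant to the global payoff drift and to positive rescaling. The
pooled per-triplet shift is the default (a whole-matrix shift is
possible via the lower-level API, but it destroys the cyclic < random
ordering of mean similarities and is not used). Note that the
shift-then-normalize map is not exactly idempotent: re-normalized
vectors have a small nonzero pooled mean, so reprocessing moves entries
at the 1e-3 level. The meaningful invariances (shift, scale,
relabeling) are exact and tested.

## Genealogy-conditioned χ

A rooted 3-leaf genealogy is reduced to five branch mutation counts
(w₁, w₂, x, y, z) around the two divergence times; the topology flag is
which pair forms the cherry. Extraction from a simulation log walks each
leaf's ancestral path (counting mutations of extinct intermediaries on
the way), finds the last common ancestor, identifies the cherry as the
pair whose lineages diverge last, and assigns each mutation to
pre-/post-divergence by its event time. A divergence is booked as an
exact copy of the parental lineage; the mutation that created the
diverging type is an ordinary mutation inside its branch count
(copy-with-noise is distributionally identical to exact-copy followed by
one mutation), so extracted genealogies satisfy w₁ + x ≥ 1 and
y + z ≥ 1 while the sampler accepts any non-negative counts.

Replaying a genealogy under the inheritance kernel makes the nine matrix
entries jointly Gaussian, and because every mutation contributes an
independent draw per touched entry, entries covary only through draws
copied at a split: the outgroup's cross entries share the w₁ + x
epoch-one draws of the parental row (respectively column), and the four
cherry-block entries all inherit the stem diagonal's x draws. The
resulting closed-form 9×9 covariance drives a vectorized sampler
(eigendecomposition factor, robust to the singular cases); the
event-by-event replay sampler is kept as the slow reference, and the
tests hold its empirical covariance to the closed form and the two χ
routes to each other. The ancestral self-payoff is fixed at 0 —
classification compares entries that all share the ancestral level — and
χ(genealogy) is σ-invariant because the correlation structure is σ-free;
both facts are tested, not assumed.

The extremizer search screens a deterministic candidate set — a
logarithmic grid up to 1000 mutations per branch plus asymptotic corner
configurations with 10⁶ mutations standing in for the all-pre and
all-post divergence limits — by successive halving: each round keeps the
best quarter of the field and quadruples the Monte-Carlo sample size, so
a true optimum cannot be crowded out of a single top-k cut by lucky
noisy screens. The winner is re-estimated with fresh draws (default
10⁶), so the reported χ carries no selection bias. The maximizer found
is the regime with nearly all mutations after the three lineages
separate (χ → 1/6); the minimizer concentrates mutations before the
last divergence and pushes χ below 10⁻³, often to an estimate of 0 at
10⁶ samples.

## Numerical choices

* exp(−A) is clamped to 0 for A > 700 (natural-log units) so death rates
  never underflow; payoffs themselves are never clamped.
* Monte-Carlo χ estimates carry the binomial standard error computed on
  the dominance-triplet subsample; samples with a mixed triplet are
  excluded from the denominator, matching the definition of χ.
* Undefined statistics (fewer than three types, no dominance triplets,
  zero-mutation genealogy) raise a dedicated signal and are excluded
  from averages — never recorded as zero.
* Type IDs are persistent and never reused within a run; matrices shrink
  when types go extinct and survivor entries are preserved bit-exactly.

## Scaled-down study conditions

The full-scale study conditions (λ_b = 0.9, λ_d = 0.4, α = 5·10⁻⁶,
σ = 1, μ = 10⁻⁵; 10⁴ mutation events; 5000 realizations) imply
populations of ~10⁵ individuals and ~10⁸ reactions per mutation event —
cluster-scale work. The package's test and example ensembles instead use
α = 10⁻³ (population ≈ 500) and μ = 5·10⁻³ over 400 mutation events and
12 realizations, with the same demographic rates and σ. This keeps every
qualitative conclusion testable in minutes: χ stabilizes far below the
random-network 0.25 (measured ≈ 0.05 at the desk scale versus ≈ 0.033 at
full scale), non-cyclic dominance outnumbers cyclic many-fold, mean
payoffs trend upward, the population tracks the α-bound once payoffs
mature, and the mean-similarity ordering (cyclic < random < non-cyclic)
is clear.

What the desk scale does *not* reproduce: the full-scale point values
(χ ≈ 0.033, triplet proportions 0.0036 and 0.105, mean triplet lifespan
≈ 5 mutation events, 4889/5000 survival), and the observation that the
per-triplet standard deviation of similarities is much smaller for
evolved triplets than for random matrices. The latter is a relatedness
effect: at μ = 10⁻⁵ the members of a surviving triplet are far closer
relatives than at the desk-scale mutation supply, and at desk scale the
measured standard deviations are slightly *larger* than random. Passing
desk-scale tests therefore demonstrates the mechanisms and the
implementation, not the full-scale numbers.

## Known limitations

* No spatial structure, immigration, recombination, or higher-order
  interactions; payoffs have no trade-offs or bounds.
* Pair outcomes only are classified dynamically; the character of a
  triplet is the composition of its pairwise links, and no n ≥ 3
  stability analysis is attempted.
* The genealogy machinery covers exactly three leaves (the motif of
  interest), not general clade sizes.
* The Gillespie engine is pure Python/numpy and comfortable up to
  populations of a few thousand; the full-scale regime needs a compiled
  engine and a cluster, not this package.
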