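# Methods

`cohortnet` reconstructs the association structure among the risk factors,
genotypes and follow-up outcome of a case-control cohort in four stages:
indicator recoding, evolutionary feature selection, Auto Contractive Map
(Auto-CM) similarity learning, and spanning-tree / regular-graph analysis
with complexity indices. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Indicator recoding

Every variable becomes a complete, mutually exclusive set of 0/1 category
columns: the three genotypic classes for a SNP (1 = common homozygote,
2 = heterozygote, 3 = rare homozygote), empirical tertiles for a continuous
trait (1 = lowest third, chosen to mirror the three genotypic classes), and
a yes/no pair for a binary trait. No reference category is dropped — the
selection stage is prediction-oriented and decides for itself when one of
two complementary columns is redundant. Tertiles are assigned by rank
against the 1/3 and 2/3 empirical quantile positions; bin sizes differ by at
most one, larger bins first, and ties break by original row order (a
deterministic choice; permutation equivariance therefore holds exactly only
for distinct values). Rows with any missing value are dropped with a logged
count; imputation is upstream of this package's scope. The follow-up
outcome can be appended as the complementary `Event` / `No_Event` pair so it
participates in the similarity graph as two nodes.

## Synthetic cohorts

Real cohorts of this design are rarely redistributable, so the generator
emulates the statistical skeleton the analysis assumes:

* genotypes drawn per SNP from Hardy-Weinberg proportions (allele counts
  `Binomial(2, q)`), one SNP per locus, no linkage disequilibrium;
* continuous phenotypes = additive per-allele effects (in phenotype SD
  units) plus correlated Gaussian noise with a configurable positive-
  definite correlation matrix;
* a binary exposure with configurable prevalence (default 0.28, a
  plausible mid-1990s male smoking rate);
* a liability-threshold (probit) outcome: liability is a weighted sum of
  standardized phenotypes, centred allele counts and binaries plus
  `N(0, 1)` noise; the threshold is the empirical `(1 - case_fraction)`
  quantile of an oversampled pool (default case fraction 0.15, matching a
  ~10–15% ten-year event rate in middle-aged men), after which exactly
  `n_cases` cases and `n_controls` controls are drawn — the default design
  is 102 / 150.

The per-variable liability weights define the planted truth used by
recovery tests. Because an additive effect shifts the case/control
frequencies of the *extreme* categories most (the heterozygote / middle
tertile is nearly balanced by symmetry), the planted "informative
indicators" are the class-1 and class-3 columns of each weighted
three-class variable and both columns of a weighted binary. The default
study-shaped configuration also designates one SNP as a pleiotropic hub
with effects on six phenotypes, emulating a lipase-like hub locus.

What the generator does **not** emulate: linkage disequilibrium, epistasis,
measurement error specific to individual assays, age structure, or
ascertainment bias. Passing recovery tests on these cohorts shows the
machinery behaves as designed under its own assumptions, not that any
particular real-data finding is correct.

## Evolutionary split and feature selection

Both searches optimize a fixed-length bit vector with the same genetic
algorithm: tournament selection in which the tournament loser occasionally
reproduces (probability 0.1), uniform crossover (rate 0.9), per-bit
mutation (rate 1/L), elitism (2), and a fraction (10%) of each generation
replaced by fresh random immigrants. The immigrant injection plus loser
retention operationalizes "genetic doping" — deliberate instability that
guards against premature convergence. Elitism makes the best-ever fitness
trace non-decreasing by construction. Default run length is a population
of 100 for 500 generations; the bundled pipeline and tests use shorter,
documented runs (e.g. population 30 for 60–200 generations), which already
converge on the problem sizes involved.

*Split search.* The train/test split's fitness is the **minimum** over the
two cross-prediction directions (train on A, test on B, and vice versa) of
learner-bank accuracy: a split is only as good as its worse direction,
which penalizes unrepresentative subsets. Splits are repaired to the
target size (default 50/50) and to contain both outcome classes on both
sides. A plain stratified split is available wherever the search is not
wanted.

*Feature search.* A mask's fitness is `1 − misclassification` (or RMSE,
selectable) on the frozen testing set using only the masked columns,
averaged over the enabled learners. Outcome indicator columns are excluded
from the feature space by construction, and learners never receive testing
labels during fitting.

*Learner bank.* Four learners are implemented from their defining
computations: Bernoulli naive Bayes with Laplace smoothing; logistic
regression by batch gradient ascent (150 iterations, small L2);
k-nearest-neighbours under Hamming distance (k = 5, odd to avoid vote
ties, distance ties by training order); and a one-hidden-layer sigmoid
network trained by backpropagation (8 hidden units, deterministic
initialization). The bank is pluggable; the default pair (naive Bayes +
logistic) keeps the inner loop fast, and the heavier members can be
enabled where runtime allows. The protocol's logic is learner-agnostic.

## Auto Contractive Map

The Auto-CM is a three-layer network trained on the records of the binary
indicator matrix. With contraction parameter `C`, mono-connections `v`
and the square connection matrix `W`:

    hidden   m^h_i = x_i (1 − v_i/C)
    net      Net_i = (1/C) Σ_j m^h_j W_ji
    output   m^t_i = m^h_i (1 − Net_i/C)
    Δv_i  = (x_i − m^h_i)(1 − v_i/C)
    ΔW_ji = (m^h_i − m^t_i)(1 − W_ji/C) m^h_j

Per-record deltas are **averaged** over each epoch and applied at the
epoch boundary. The mean (rather than the raw sum) keeps the update
bounded independently of the number of records — writing `u = v/C`, the
epoch map is `u ← u + x̄ u(1−u)/C`, a logistic step that can never leave
[0, 1] — while remaining invariant to record order and identical to the
single-record dynamics when n = 1. Every `v_i` rises monotonically toward
`C`, the output signal contracts toward zero (training stops when its mean
drops below `tol = 1e-6`, or at 1000 epochs), and `W` freezes having
absorbed the co-activation structure. Weights start at a uniform
`init_eps = 0.01`; zero initialization provably stalls the dynamics.

The similarity read-out is `S_ij = (W_ij + W_ji)/(2C)`, clipped to [0, 1],
diagonal 1; distances are `D = 1 − S`. Interpretive cut-points label a
link null/very-low (≤ 0.33), quite-low (≤ 0.66), quite-high (≤ 0.84) or
very-high (> 0.84).

**Choosing C.** Integrating the update equations shows the total
log-growth of a connection weight over training is approximately
`N x̄² ln(C/eps) / C` (`N` columns, overall activation mean `x̄`). Two
regimes follow:

* `C = N` (the conservative default of `train_autocm`): growth is a few
  percent; all monotonicity/contraction invariants hold with a wide
  margin, and the *ranking* of S — which alone determines the MST — is
  discriminative. The absolute values of S stay near zero.
* `C ≈ N x̄²` (the `saturating_C` helper, default of the mapping and
  per-group stages): the self-consistent marginal value at which genuinely
  co-occurring columns saturate toward `C` while chance co-occurrence does
  not. Only in this regime do the similarities populate the interpretable
  [0, 1] scale that the strength labels and the regular-graph noise floor
  assume. The two defaults are two operating points of the same
  dynamics; the MST is essentially unchanged between them.

Constant columns never contract relative to the rest and are rejected;
callers (the per-group pipeline in particular, where outcome columns are
constant by definition) drop them first.

## Graphs and complexity indices

*MST.* Kruskal's algorithm over `D = 1 − S` with deterministic
lexicographic tie-breaking on node-label pairs; minimizing total distance
maximizes total similarity. Every build asserts the tree facts (N−1
edges, connected, acyclic).

*Meta-MST.* The Auto-CM and MST are retrained on each of k = 10 record
subsamples (each excluding 10% of rows); edges recurring in at least 9 of
the 10 trees survive, with their support count as an edge attribute. The
result may be disconnected — it is a stability filter, not a tree.

*Hubness.* `H = Σ_i max(0, deg_i − 2) / (2A − N)`. On a tree the
denominator equals `N − 2`, giving the familiar closed forms (path 0, star
`(N−3)/(N−2)`); on every connected graph the numerator is bounded by the
denominator, so `H ∈ [0, 1]` always. This normalization also makes the
regular-graph search self-limiting: an added edge between two nodes of
degree ≥ 2 never lowers H (since `δ = 2` and `H ≤ 1` imply
`(Σ+2)/(D+2) ≥ Σ/D`), but indiscriminate densification eventually does.

*Pruning cycles.* Repeatedly delete every node of degree ≤ 1; when only
cycles remain, delete every node of the current minimum degree; `P` is the
number of waves needed to empty the graph.

*Topological entropy.* `E_G = (A/P) · H_S`, where `H_S` is the Shannon
entropy (bits) of the degree distribution `p_i = deg_i / Σ deg`. It rises
with edge density per pruning depth and with the evenness/information of
the degree distribution.

*MRG.* Non-tree pairs with similarity above the noise floor (default
0.33) are sorted by descending similarity and re-added to the MST one at a
time, recording H after each addition. The returned graph is the one of
maximal H along this sequence, taking the **last** graph attaining the
maximum so ties keep the largest number of re-introduced connections
(consistent with maximizing added links while preserving the tree
skeleton). With no candidate above the floor the MRG is the MST.

*Per-group contrast.* Auto-CM → MST → MRG run separately on case rows and
control rows (outcome columns excluded; within-group constant columns
dropped), reporting both complexity reports and the differences
ΔH, ΔE_G (control − case, so a positive ΔE_G means the event-free group
carries the more complex network). The contrast generator used in tests
builds equal groups (150/150) differing only in within-block correlation
density, so the measured Δ is attributable to the planted density
difference rather than to sample size.

## Numerical and determinism choices

* One integer seed per run; stage seeds derive from it through
  `numpy.random.SeedSequence` and stay below 2³¹.
* All edge orderings, GA tie-breaks and output files are deterministic;
  rerunning a config reproduces artifacts byte for byte.
* Graph exports: GraphML via networkx, DOT and TSV edge lists via small
  deterministic writers (lexicographic edge order).
* Degenerate inputs fail loudly with named rows/columns: genotype values
  outside {0, 1, 2}, fewer than three distinct values for tertiles,
  constant columns in Auto-CM, single-class training labels, empty graphs.

## Known limitations

* The Auto-CM similarity scale depends on the contraction regime; absolute
  similarity values should be compared only across runs with the same `C`
  policy. Rankings are robust across regimes.
* The MRG is a greedy, single-sequence search; it does not enumerate
  graphs off the monotone re-insertion path.
* The learner bank is a compact stand-in for a large heterogeneous model
  family; selection results on small cohorts remain sensitive to the
  bank's composition, which is why the bank is explicit configuration
  rather than hidden default.
* Best-ever held-out fitness is an optimistically biased estimate (it is a
  maximum over many evaluated masks); on pure-noise data it settles a few
  points above 1/2 rather than at it. An unbiased estimate would need a
  third, untouched validation set, which the small-cohort design precludes.
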