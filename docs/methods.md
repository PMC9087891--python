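# Methods

## Model representation and conventions

An MSci model is a rooted ultrametric species tree (leaves at time 0,
time increasing strictly rootward) augmented with pairs of introgression
nodes. A *BDI* line inserts two hybridization nodes at a shared time,
one on each of two contemporaneous branches, with horizontal links
pointing at each other; a *UDI* line inserts a hybrid node on the
recipient branch and a plain pass-through node on the donor branch.
Every branch — named by its daughter node, root stem included — carries
a population size θ > 0; every internal node a time τ > 0; every hybrid
node an introgression probability φ ∈ [0, 1].

**φ convention.** φ at a hybrid node is the probability that a lineage
traced backwards through the node takes the *horizontal* (cross-species)
parent path; 1 − φ is the vertical path. Sample-table readers map other
header conventions through an explicit `column_map`, so bpp-style
columns can be bound to either orientation by the user.

The free-parameter count is forced by these conventions: one θ per node
(= per branch), one τ per speciation node plus one shared τ per
introgression pair, one φ per hybrid node. The two-species single-BDI
model has 9 parameters, the stacked double-BDI model 14, and the
four-species two-UDI network rendering 18.

The model text format is bespoke rather than extended Newick because
extended-Newick hybrid notations leave the BDI pairing and the φ
orientation ambiguous; the `bdi`/`udi` lines make both explicit, and
`write_model` emits the same dialect so parse∘write is the identity on
canonical specs.

## Tower structure

A BDI event between *sister* branches (same parent after condensing
every BDI pair to a single node) creates within-model unidentifiability:
the involution that complements both φs and swaps the two parental θs
leaves the gene-tree density unchanged. A *nonsister* event creates
cross-model unidentifiability: the same parameter moves plus a topology
edit (the two subtrees swap). With m sister and n nonsister events the
posterior has 2^n model variants × 2^m within-model towers.

Two BDI events are *stacked* when the parental branches of the lower
pair are exactly the two child branches of the upper pair. The four
joint transforms then replace the two independent involutions — the
lower-event transform must carry the upper event's φ and θ values across
because swapping the lower subtrees exchanges which upper node sits
above each; the set {z0, z1, z2, z3} is closed under composition with
XOR group structure, and every element is self-inverse. The classifier
condenses all BDI pairs simultaneously (iterated condensation reaches
its fixed point in one pass because merging is pairwise); configurations
whose nesting goes beyond these canonical cases are still enumerated
event-wise but should be reviewed by the user.

Tower IDs are deterministic: variant 0 keeps the input leaf order, and
within a variant towers are coded in binary over events with the
youngest event as the least-significant bit.

## Relabeling algorithms

All three algorithms operate on the event parameters only — four
coordinates (φ_X, φ_Y, θ_X, θ_Y) per single event, eight for a stacked
pair — and copy every other column through unchanged. Labels initialize
at z = 0 iff φ_X + φ_Y < 1 (the boundary falls in "otherwise"); for four
towers the initializer prefers, in order, images with φ_X + φ_Y < 1 and
φ_Z + φ_W < 1, then φ_X + φ_Y < 1 alone, then the smallest φ_X + φ_Y —
i.e. the tower in which the introgression probabilities are small.

* **CoG0** iterates: recompute the center of gravity μ (the mean over
  current positions), then move each draw to the transform image nearest
  μ in Euclidean distance. Both half-steps are non-increasing in the
  summed squared distance, so the recorded objective trajectory is
  monotone and the algorithm terminates.
* **CoGN** uses variance weights 1/ν_j recomputed each iteration, so φ
  and θ coordinates on scales three orders of magnitude apart contribute
  comparably. Because ν is refit, the weighted sum of squares
  self-normalizes (it equals kN immediately after each center/variance
  update), so only the within-iteration assignment step is guaranteed
  non-increasing; the monotone-objective guarantee is CoG0's.
* **β–γ** fits independent beta densities to the φ columns and gamma
  densities to the θ columns by maximum likelihood over the current
  positions, then moves each draw to the image with the highest log
  density. Both half-steps are exact maximizations, so the log
  likelihood is nondecreasing across all half-steps and the algorithm
  converges. With the beta/gamma densities replaced by equal-variance
  normals the selection rule reduces to CoG0's nearest-center rule.
  For a stacked pair the 16-dimensional ω optimization separates into
  eight independent 2-D problems, which is how it is implemented.

Ties in the assignment step keep the current label, which guarantees
termination with the monotone objective; a hard cap of 1000 iterations
(with a warning) backs this up. Density evaluation clamps φ to
[10⁻⁹, 1 − 10⁻⁹] and θ to ≥ 10⁻¹² — posterior samples can contain exact
boundary values and the log densities diverge there — while the stored
values are never modified: the output table is exactly the row-wise
image of the input under the selected transforms.

**ML fits.** The beta likelihood depends on the data only through
mean(log x) and mean(log(1−x)); it is maximized by BFGS on
(log p, log q) from a moment-matching start (gradient tolerance 10⁻¹⁰).
For the gamma the rate is profiled out exactly (b = a/mean, the
first-order condition, so the fitted mean equals the sample mean by
construction) and the remaining equation log a − ψ(a) = log(mean) −
mean(log) is solved by Newton from the standard closed-form start.

**Multiple events** are processed sequentially, one pass per sister
event or stacked pair, in ascending event time with ties broken by node
label (the processing order is not prescribed by the theory; any order
converges since each pass is idempotent). Nonsister events are reported
but not relabeled: a fixed-model MCMC visits a single model variant, and
mapping summaries onto the mirrored variants is a reporting step, not a
sample transform. Samples from multiple runs may be concatenated before
relabeling.

**Accuracy metric.** Against known truth, accuracy is the fraction of
agreeing labels maximized over the valid global relabelings — the flip
for two towers, the four Klein-group translations (XOR with a fixed
code) for four. Mirror towers are equally correct answers; an arbitrary
permutation of tower indices is *not* a symmetry and is not credited.

## Posterior summaries

HPD intervals are the shortest contiguous window of ⌈level·N⌉ order
statistics, ties resolved toward the smallest lower endpoint — a
deterministic rule matching the reporting style of coalescent MCMC
software; kernel-density HPDs were deliberately avoided. ESS is
N / (1 + 2 Σ ρ̂_k) with the autocorrelation sum truncated by the
initial-positive-sequence rule (stop at the first nonpositive pair
ρ̂_{2m} + ρ̂_{2m+1}), clipped to [1, N]; the estimator is standard and
conservative, and for an AR(1) chain reproduces the closed form
(1 − ρ)/(1 + ρ) · N. Summaries assume a relabeled table; a φ-like column
whose middle-decile mass is far below its flanking deciles triggers an
advisory bimodality warning. The dip heuristic is deliberately
conservative: poorly separated towers produce a nearly flat mixture that
no marginal test can flag reliably.

## Synthetic data

`simulate_label_switching_samples` emulates the posterior sample the
relabelers consume: within the reference tower each φ column follows a
specified beta law and each θ column a gamma law; other towers are
realized by pushing reference draws through the corresponding tower
mapping, so the mirror structure is exact by construction; the occupied
tower follows a Markov chain with transition matrix
s·I + (1 − s)·1·wᵀ, which keeps the stationary weights w for any stay
probability s.

Two stock configurations define the study conditions:

* single BDI, poorly separated: φ_X ~ beta(7, 3) (mean 0.7),
  φ_Y ~ beta(2, 8) (mean 0.2), θ_X ~ gamma(8, 800) (mean 0.01),
  θ_Y ~ gamma(8, 4000) (mean 0.002), equal weights, stay probability
  0.999, N = 2×10⁵ — the regime where the raw φ means collapse to 1/2;
* stacked double BDI: φ means (0.1, 0.2, 0.2, 0.3) and θ means
  alternating 0.005 / 0.02 at tight concentration, four equal-weight
  towers.

The emulator reproduces the *tower structure* of a real MSci posterior
— exact mirror symmetry, within-tower beta/gamma marginals, Markov
switching — but not its full dependence structure: real posteriors have
correlated parameters within a tower, non-beta/gamma marginal shapes and
data-driven asymmetries between towers. Passing tests therefore show
that the algorithms remove label switching under the assumed tower
geometry, not that a particular biological dataset is well estimated.

`simulate_gene_trees` draws genealogies by the standard backwards-in-time
construction: within each population of k lineages, exponential
coalescent waiting times at rate k(k−1)/θ; at a hybridization time every
lineage in the child population independently goes horizontal with
probability φ; populations merge at speciation times and the root
population coalesces to completion. Each locus uses an independent
generator derived from (seed, locus index), so extending a simulation
does not perturb earlier loci. Times are expected substitutions per site
throughout; sequence evolution on the gene trees is out of scope since
no sequence-level inference engine is included.

The analytic check of the unidentifiability rule is the closed-form
density of the coalescent time between one A and one B sequence under
the two-species single-BDI model: zero before τ_X; between τ_X and τ_R
a two-component mixture with weights (1 − φ_X)φ_Y (both lineages left,
rate 2/θ_X) and φ_X(1 − φ_Y) (both right, rate 2/θ_Y); past τ_R the
surviving mass times the root exponential. The density integrates to
one, matches simulation histograms (KS), and is pointwise identical
under a parameter point and its mirror — while complementing the φs
without swapping the θs breaks the identity, confirming the mapping is
exactly the tower involution and nothing looser.

## Heuristic statistics

The site-pattern module counts ABBA/BABA/BBAA columns (biallelic, clean
2/2 split; gaps and ambiguity codes excluded entirely, since the
patterns are defined on two distinct nucleotides) and computes
D = (n_ABBA − n_BABA)/(n_ABBA + n_BABA) and
φ̂ = (n_BBAA − n_BABA)/(n_BBAA − 2 n_BABA + n_ABBA). Zero denominators
are reported as undefined rather than raised. φ̂ assumes a symmetric
hybrid-speciation geometry and can be biased when that symmetry fails;
no correction is attempted and no block-jackknife variance is provided.
These genome-wide averages discard the across-locus genealogical
variance that full-likelihood analysis uses — they cannot detect sister
gene flow or resolve direction, which is why they are included only as a
contrast.

## Problem sizes and determinism

The test suite exercises the algorithms at N = 10⁴ draws for accuracy
checks, N = 2×10⁵ for mixture-collapse checks, and 10⁵ loci for the
simulation-vs-mirror KS test; these sizes give Monte-Carlo tolerances
(quoted as ~3σ in the tests) well below the effects being measured while
keeping a full run under half a minute. All randomness flows through
seeded `numpy` generators; hypothesis-based property tests run
derandomized.

## Known limitations

* No sequence-level MSci sampler is included: the package postprocesses
  and emulates MCMC samples, it does not produce them from alignments.
* Nonsister (cross-model) events are enumerated and reported with their
  parameter renames and topology edits, but sample tables are not
  automatically mapped across model variants.
* UDI events are represented, counted and simulated, but no tower
  enumeration is attempted for them beyond reporting the nodes.
* The double-BDI joint transforms cover one stacked pair; deeper stacks
  between the same two species are not enumerated jointly (consistent
  with the practical difficulty of estimating parameters of multiple
  ancient events).
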