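# Methods

This note documents the model the package implements, the design choices
made where the method leaves room, the numerical details that matter for
reproducing results, and what the synthetic studies do and do not establish.

## Model and assumptions

A category is a probability distribution p(x|c) over a finite item set.  The
measurement device is a two-alternative forced choice: offered a current
item x and a proposal x', the responder picks x' with probability

    P(x'; x | c) = p(x'|c)^γ / ( p(x'|c)^γ + p(x|c)^γ ),

the exponentiated Luce ratio rule.  For γ = 1 this is the Barker acceptance
function, so a chain whose state moves to whichever item was chosen is a
Metropolis–Hastings sampler for p(x|c) — provided the proposal distribution
q(x'; x) is symmetric.  For general γ the same chain targets p^γ
renormalized: relative probabilities are identified only up to a power, but
item ordering is preserved.  The engine itself never needs γ; it is a
property of the chooser.

Assumptions inherited from this construction:

* choices are independent across trials given the current pair (no learning,
  fatigue, or sequence effects);
* a single fixed p(x|c) per responder population (chains linked across
  responders estimate the population mixture);
* the similarity matrix used to build the proposal graph affects only
  *efficiency*, never the stationary distribution, because acceptance
  depends only on the target.

Proposal symmetry is obtained structurally: the proposal graph is
degree-regular (each node has b neighbours), walks choose uniformly among
neighbours, and the uniform jump is symmetric by construction.  On the
message-passing solver's mildly irregular graphs the walk is only
approximately symmetric; the package exposes exact enumeration
(`proposal_distribution`) so the residual asymmetry can be measured rather
than assumed away.

## Graph construction

The graph maximizes total edge similarity subject to per-node degree b
(the printed constraint Σ_ij G_ij = b is read per node, matching the
requirement that every node have the same degree — a globally-summed
constraint would not produce a regular graph).

**Exact solver** (`bmatch_exact`): branch-and-bound enumeration over
node-by-node neighbour assignments, with an admissible bound (each unfilled
node optimistically takes its residual-many best remaining partners, halved)
and heavy-partner-first branch ordering.  Ties between equal-weight optima
break to the lexicographically smallest edge set via explicit comparison, so
the answer is independent of visit order.  Capped at 12 nodes: it is a test
oracle, not a production path.

**Message-passing solver** (`bmatch_message_passing`): scalar max-product
messages m(i→j) = −(b-th best competing score among i's other options);
each node keeps the b partners with the highest belief (similarity +
incoming message), and mutual selections become edges.  Three
implementation details depart from the plainest scheme, each forced by
observed failures of plain loopy max-product on non-bipartite instances
(roughly one random 8-node instance in ten converged to a suboptimal or
degree-deficient fixed point):

1. *Positive weight shift.*  All b-regular graphs on n nodes have nb/2
   edges, so adding a constant to every weight leaves the argmax unchanged
   while preventing the decision rule from preferring missing edges when
   similarities are negative (as negated distances are).
2. *Seeded random restarts* (default 8, damping cycling 0.7/0.5/0.9, random
   initial messages): loopy max-product has multiple fixed points; restarts
   escape bad ones.  The best restart is kept by shifted objective.
3. *Deficit completion and 2-exchange polish.*  Mutual selection can leave
   node pairs one edge short of b even when the missing edge is optimal;
   deficient pairs are joined greedily by belief (never pushing a node above
   b).  A degree-preserving 2-exchange hill climb then removes local
   pair-swap errors; being quadratic in edge count it is enabled only below
   300 nodes.

With these, the solver reproduces the brute-force optimum on all tested
random 8-node instances while remaining O(n²) per iteration.  Outputs may
still be irregular on hard instances; a min/mean/max degree report travels
with every graph, and `largest_connected_component` handles disconnected
matchings (ties between equal components break to the one containing the
smallest original index).

A seeded symmetric jitter of magnitude 1e-12 breaks weight ties
deterministically; it is orders of magnitude below any meaningful similarity
difference.

## Proposals

* `uniform_neighbor`: uniform over the current node's neighbours.
* `geometric_walk`: step count k ~ Geometric(geom_param) supported on
  {1, 2, ...} — a 0-step walk would propose the current item and waste a
  trial — followed by k uniform-neighbour steps.  The endpoint may equal the
  start.
* Uniform jump with probability `jump_prob` (default 0.10), drawn *before*
  the base proposal; the jump may land on the current state.

A proposal equal to the current state is redrawn (limit 100) rather than
shown: asking which of two identical images is the better category member is
meaningless.  Left/right display order is randomized and logged even though
the engine is order-blind, so recorded human sessions replay faithfully.

`proposal_distribution` enumerates Q exactly; the geometric series is
truncated (default 64 terms) with the un-accumulated mass (1−p)^K reported
and flagged above 1e-6.

## Sessions, catch trials, exclusion

A session is: n_practice practice trials first (random pairs, excluded from
analysis), then chain trials interleaved round-robin over chains with
n_catch catch trials inserted at seeded uniform-random positions.  The
reference configuration (4 chains × 100 trials, 12 practice, 40 catch)
yields 452 trials.  Practice and catch trials never advance chain state.
Chains start at uniform-random items unless linked, in which case each chain
continues from the previous session's final state.

Catch trials pair an item of very high target probability with one of very
low probability (top versus bottom decile); the high item is recorded as
correct.  The conventional pass threshold of 27/40 is the engine default.
The exact binomial computation (`binomial_catch_threshold`, integer-exact
tail summation) gives 28 for α = .01 — P(X ≥ 27) ≈ .0192, P(X ≥ 28) ≈
.0083 under random guessing — so the conventional threshold is one trial
more lenient than its stated criterion; both are available and the
discrepancy is asserted in the tests.

## Estimation and diagnostics

`empirical_distribution` counts chosen items of chain trials, with burn-in
applied per chain.  Count modes "choices" and "states" coincide because the
post-trial state *is* the chosen item; both ignore practice/catch trials.
Burn-in defaults to 0 (cross-trial averages), with an explicit parameter for
stationary-distribution work.

Convergence diagnostics compare cumulative histograms of chains (default:
normalized item-frequency vectors; any histogram function, e.g. basic-color
histograms of chosen images, can be supplied) via L1 distance at ~40
log-spaced trial counts (duplicates after integer rounding removed).
Within-category distances falling below between-category distances indicate
chains converging to their own category's region.  Sliding cumulative
feature averages use a 50-trial window (all trials so far when fewer).

The 11 basic-color histogram bins pixels by nearest CSS prototype in
Euclidean RGB with ties to the lower bin index — a stated simplification of
published color-naming boundaries, adequate for comparing palettes of
chosen-image sets.

## Synthetic fixtures and what the studies show

`make_stimuli` draws i.i.d. standard-normal feature vectors;
`make_target_distribution` evaluates a mixture of isotropic Gaussian kernels
at the item features (kernel widths in feature sd units).  Gaussian kernels
were chosen for smooth, controllable multimodality; the method itself never
sees the kernel, only the resulting item probabilities.
`perturb_similarity` adds symmetric zero-mean Gaussian noise scaled by
noise_level × sd(off-diagonal of S), making noise_level unit-free
(1 ≈ noise as large as the signal's own spread).

**Stationary-recovery study** (50 items, 2-d features, bimodal target with
unit-width kernels at ±2 on the first axis; exactly 6-regular
similarity-ordered ring graph; geometric-walk proposals with parameter 0.5
and 10% jump — the widest-exploration session condition; 20,000 trials,
burn-in 2,000).  Problem sizes were set so the diagnostic has statistical
power: with 18,000 retained samples over 50 items the pure multinomial
sampling floor is TV ≈ 0.020, and chain autocorrelation roughly doubles it,
so observed TV ≈ 0.04 sits below the 0.05 criterion with the sampler working
correctly and would not with a broken acceptance rule or asymmetric
proposal.  The γ=2 variant recovers p² renormalized, which differs from p by
TV > 0.1 — the check genuinely distinguishes the two laws.

**Noise-robustness study** (same items, kernel width 0.35, uniform-neighbour
proposals, graphs rebuilt by message passing from similarity perturbed at
noise levels 0/1/4, 5,000 trials, 10 seeds).  The concentrated target is
deliberate: graph–target alignment drives acceptance of local proposals,
giving similarity noise a mechanism to hurt.  With broad targets the effect
can invert — a randomized graph gains expander-like mixing that offsets lost
acceptance — which is itself informative: similarity quality matters most
when categories are concentrated relative to the similarity structure.

What passing these studies does *not* show: that real responders follow the
Luce rule, that real similarity measures resemble Gaussian feature
distances, or anything about response times, lapses, learning, or
population heterogeneity.  The fixtures validate the machinery (acceptance
arithmetic, proposal symmetry, estimator correctness), not the psychology.

## Numerical details

* All randomness flows through explicit seeds or `numpy.random.Generator`
  handles; no global RNG state.  Linked sessions derive per-session
  generators from (config seed, session index).
* `luce_choice_prob` computes in log-ratio form, exact at probability
  ratios beyond 1e300 and for large γ; a zero-probability option is never
  chosen, and both-zero raises rather than coin-flipping, so degenerate
  targets surface in tests.
* Similarity combination rescales each source by the standard deviation of
  its off-diagonal entries only (the diagonal is meaningless for matching)
  and zeroes the output diagonal; zero-variance sources raise, naming the
  offending matrix.
* Distance-to-similarity conversion is negation — the minimal monotone
  transform; any strictly decreasing transform yields the same matching when
  weights are distinct.
* File formats are tab-separated UTF-8 text with strict validation on load
  (log invariants, matrix symmetry to 1e-9 with an opt-in
  symmetrize-and-warn mode, graph headers); parse errors carry line numbers.

## Known limitations

* The exact matcher's practical range depends sharply on b (n = 10, b = 3
  takes tens of seconds); beyond toy sizes the message-passing solver is the
  only path, and its optimality is empirical, not guaranteed.
* On irregular approximate graphs the proposal is mildly asymmetric and the
  stationary distribution correspondingly biased; the package measures this
  (enumeration, degree reports) but does not correct for it, matching the
  method's empirical stance.
* Feature extraction for real images/words (Gabor/PCA, SIFT, latent
  semantic analysis) is out of scope; users supply feature matrices or
  precomputed similarity matrices.
* Replay assumes the original session's config seed, so proposals regenerate
  identically; replaying logs produced by other software requires mapping
  into the package's log format first.
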