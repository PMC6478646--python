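# Methods

## Dynamics

One step of the spreading process maps the activation vector $a_t$ to

$$a_{t+1}(n) = (1-d)\Big[\, r\,a_t(n) + \sum_{m \,:\, n \in N(m)} (1-r)\,a_t(m)\,\sigma(m \to n) \Big]$$

followed by suppression: any entry strictly below $s$ is set to 0. The
outflow share $\sigma(m \to n)$ is $1/\deg(m)$ on unweighted graphs and
$w_{mn} / \sum_k w_{mk}$ on weighted ones; on directed graphs outflow
follows out-edges and inflow sums over in-edges. Parameters, with
defaults used by the study pipelines:

| parameter | meaning | range | study default |
|---|---|---|---|
| `retention` r | share of activation a node keeps per step | [0, 1] | grid (see below) |
| `decay` d | share of total activation destroyed per step | [0, 1] | 0 |
| `suppress` s | floor below which activation is zeroed (activation units) | ≥ 0 | 0 |
| `time_steps` T | number of steps; history covers t = 0 … T | ≥ 1 | 10 |

Choices where the verbal description of the process is genuinely open:

* **Within-step order.** Retention + inflow are aggregated first, then
  decay multiplies every node, then suppression is applied. This makes
  the decay law exactly geometric — total(t) = total(0)·(1−d)^t — which
  the tests exploit as a closed-form oracle.
* **Suppression comparison is strict.** A value exactly equal to `s`
  survives; suppressed mass is destroyed, never redistributed, so with
  s > 0 the total is bounded above by the decay law.
* **Degree-zero nodes.** The outflow share divides by the degree, so it
  is undefined at degree 0. Isolated nodes (and zero-out-degree nodes
  in directed graphs) retain all their activation regardless of r.
* **Normalization.** Networks are simple graphs: self-loops are removed
  and duplicate edges collapsed (weights summed when weighted) on
  construction and in every reader. Node labels are strings; unlabeled
  nodes are auto-named "1" … "N" in input order.
* **Zero-activation gate.** Nodes with zero activation emit zero
  outflow automatically (outflow scales with the activation); no epsilon
  gate beyond `s` exists.

The per-node loop in `engine.spread_step` is the implementation;
`engine.transition_operator` builds the equivalent linear operator
M[i,j] = r·[i=j] + (1−r)·σ(j→i), valid when d = s = 0. The two routes
are kept independent so matrix powers can serve as an oracle for the
loop; the suite checks agreement to 1e−9 sup-norm over random instances.
All floating-point test comparisons use absolute tolerance 1e−9 unless
a line states otherwise.

## Random-walk correspondence

For the transition probability of the simple walk we use the standard
row normalization T[i,j] = A_ij / deg(i) (for the symmetric adjacency
matrices used throughout, row and column normalization coincide;
directed inputs use out-degree normalization). Isolated nodes self-loop
with probability 1 to keep the matrix stochastic. On a connected
undirected graph the stationary law is deg(n)/2|E| in closed form; the
conservative spreading process with r ∈ (0, 1) is a lazy walk and
converges to the same limit, which `compare_with_spreading` measures as
an L1 distance after `t_long` steps (2000 by default in the examples).
Monte-Carlo walk ensembles track two summaries per node: the fraction
of walks that visited it at least once (`visited_fraction`, counted at
most once per walk — not a distribution; `visitation_prob` is its
normalized version) and the empirical endpoint distribution, which
converges to the t-step matrix power at the O(1/√n_walks) rate.

## Synthetic testbeds

The generators are pure functions of their seeds; per-network seeds fan
out from a master seed through `numpy.random.SeedSequence`.

**Two-hop testbeds** (`make_two_hop_testbed`) emulate the structure of
a word's phonological neighborhood: a target with exactly `k` one-hop
neighbors, `round(c·k(k−1)/2)` neighbor–neighbor edges placed uniformly
at random (round half up — so the achieved clustering coefficient equals
the request up to that rounding), and `outer_per_neighbor` fresh
two-hop nodes per neighbor (default 2 in the study driver). What they
do **not** emulate: real two-hop shells are interconnected (two-hop
nodes link to each other and to several one-hop neighbors), whereas the
generated shell is leaf-like. This matters for one readout; see
"Known limitations".

**Semantic testbeds** (`make_semantic_testbed`) use a preferential-
attachment graph (Barabási–Albert, 2 edges per node) for the
heavy-tailed degree distribution typical of free-association networks,
then draw disjoint (target, related prime, unrelated prime) triples:
the related prime is a neighbor of the target, the unrelated prime is
sampled among nodes at shortest-path distance ≥ 3. Association strength,
directionality and word covariates (frequency, length, orthographic
neighborhood) are not modeled — relatedness is controlled purely by
graph distance, so the priming contrast isolates the structural effect.

## Study pipelines and problem sizes

All three studies run the dynamics for T = 10 steps with d = s = 0 and
a 100-unit activation budget, and read out the target's activation at
T. The clustering studies cross matched low/high-C testbed pairs
(C_low = .1, C_high = .7; default degree grid k = 3 … 14, giving 24
networks and 216 runs over the nine-value retention grid .1 … .9) with
two initialization schemes: all 100 units on the target (lexical
retrieval) or 100/deg(target) units on each neighbor and none on the
target (false memory; a degree-3 target's neighbors each receive
100/3 ≈ 33.33 units — internal arithmetic keeps full precision). The
priming study uses a 500-word testbed with 50 triples and retention
grid {.2, .4, .6, .8}, 400 runs (an 800-run manifest corresponds to 100
triples). These sizes run the whole suite in seconds while leaving the
directional effects far from their decision boundaries.

Summaries:

* **Standardized OLS** (`standardized_ols`): predictors are z-scored;
  the outcome is z-scored by default with a switch
  (`standardize_outcome=False`) for raw-outcome betas, since the
  "standardized beta" convention is ambiguous about the outcome.
  Standardizing the outcome rescales betas and SEs by the same factor,
  so t, p, R² and the signs — the quantities the studies interpret —
  are identical either way. Rank-deficient designs and zero-variance
  outcomes are rejected.
* **Difference scores** (`difference_scores`): final activations are
  z-scored across the whole result table, then the high-C value is
  subtracted from the low-C value within each (degree, retention) cell;
  per-degree means are averaged over retention values and reported with
  both SD and SE (the dispersion convention is not pinned, so both are
  emitted). Unmatched cells are rejected listing the orphans.
* **Priming contrast** (`priming_contrast`): mean target activation by
  prime type and retention, with a seeded percentile bootstrap (2000
  resamples over targets) on the paired difference.

Because the dynamics are linear in the initial vector when d = s = 0,
every readout — and hence every contrast — scales exactly with the
budget; the 100-unit budget is a unit convention, not a tuned value.

## What passing tests do and do not show

The synthetic studies demonstrate that the *directional* effects are
structural consequences of the dynamics: low-clustering targets
out-activate matched high-clustering targets under both initialization
schemes (100% of cells here), degree and clustering carry negative
standardized betas, and related primes beat unrelated primes at every
retention value. Coefficient *magnitudes* are not comparable to any
empirical analysis — they depend on the particular word networks and
reaction-time data, which are not modeled.

## Known limitations

* **Retention sign under neighbor initialization.** On the leaf-shell
  two-hop testbeds, the target's final activation is an inverted-U in
  retention: it rises over r ≈ .1–.6 but collapses at r = .9, because
  highly retentive neighbors have not passed their activation on by
  T = 10. A linear fit therefore gives retention a small *negative*
  standardized beta (≈ −0.09) under the neighbor scheme, across seeds
  and shell sizes. Empirical two-hop networks, whose denser shells mix
  more slowly, can place the peak beyond the grid and yield a small
  positive coefficient instead; the sign of this one term is a property
  of neighborhood topology, not of the engine. The retention effect
  under target initialization, and the degree/clustering effects under
  both schemes, are robust.
* Degenerate inputs: empty initializations propagate as all-zero
  histories; disconnected networks are rejected where a stationary law
  is required; regular graphs make the rank correlation against the
  (constant) stationary law trivial, and it is reported as 1.
* No retrieval thresholds or resting activation levels — final
  activation is the readout; no interactive-activation machinery, no
  learning of weights, no reaction-time modeling.
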