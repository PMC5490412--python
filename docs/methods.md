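# Methods

This note documents the models and algorithms implemented in `woundnet`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer would want recorded.

## Network construction

The STRING-dialect reader accepts both score dialects in the wild: integer
milli-scores (0–999, divided by 1000) and floats in [0, 1], auto-detected
per column from the literal form of the values. An edge qualifies when its
combined confidence is **strictly** greater than the threshold (default
0.7, the conventional "high confidence" cut) *and* at least one required
evidence channel (default: experimental, database) is positive. The
evidence requirement is deliberately a union: requiring both channels
jointly is plausible but stricter than the stated rule, so conjunction is
available via `require_all=True` rather than being the default. Reversed
duplicate pairs keep the maximum combined score; self-loops are dropped.

Seed expansion keeps the seeds and their direct neighbors and then takes
the **induced** subgraph: neighbor–neighbor edges are retained, because the
neighborhood's internal wiring is exactly what the downstream topology
stages measure. Seeds with no surviving interaction stay as isolated,
flagged nodes so the output faithfully reports which inputs found support.

Degree percentiles use numpy's linear-interpolation definition, and all
threshold selections are strict (`>`): a 90th-percentile rule therefore
yields a possibly non-integer cut (e.g. "degree > 203.5"-style thresholds)
with an unambiguous survivor set.

## Cohesiveness clustering

Clusters maximize f(M) = w_in / (w_in + w_bound + α·|M|). The growth
procedure seeds from the highest weighted-degree uncovered node, and at
each step applies the single best addition of a boundary node or removal of
a member, requiring a strict cohesiveness increase (ε = 1e−12), which
guarantees termination; ties prefer additions and then the
lexicographically smallest label, making the procedure fully deterministic.
Candidates below 3 members or weighted density 0.3 are discarded, and
candidate pairs with overlap ω = |A∩B|²/(|A|·|B|) ≥ 0.8 are merged
transitively. α = 2, the size/density/overlap thresholds, and the
percentile are the published defaults of the cohesiveness-clustering
approach this follows; no problem-specific tuning is applied, and all are
caller-configurable.

Cluster significance is the one-sided Mann–Whitney U test comparing member
in-weights (to other members) against out-weights (to the rest of the
network), alternative "in-weights larger". The exact null distribution is
used when both samples have ≤ 20 values and no ties occur; otherwise the
normal approximation with tie correction. When every in-weight equals every
out-weight the comparison is degenerate and carries no evidence; the
p-value is reported as 1.

Weighted density is internal weight divided by the member-pair count
|M|(|M|−1)/2 — an identity the acceptance suite verifies against a
published-style cluster table. Unclustered nodes are reported as an "OUT"
group rather than silently dropped.

## Bridging centrality

RWBC is current-flow betweenness with edge confidences as conductances
(networkx implementation), computed per connected component and normalized
by the intra-component source–target pair count; nodes in components
smaller than 3 score 0, since they can never be intermediates. The test
suite validates the implementation against an independent brute-force
oracle that solves the grounded Laplacian system per source–target pair
(agreement to 1e−9), and against shortest-path betweenness on trees, where
the two notions coincide.

BCoeff uses **unweighted** degrees — the definition is stated in terms of
neighbor counts even though edges carry weights — with a weighted-degree
variant behind a flag. Isolated nodes get BCoeff 0 by convention. Note
BCoeff is not bounded by 1 (a leaf attached to a high-degree node exceeds
it); only the product BR is used for selection.

S_KEGG/S_GO rescaling divides each bridge's reference-term count by the
per-category **maximum over the bridge set** (0 if the maximum is 0). The
alternative min–max rescaling would force the least-annotated bridge to
exactly 0 even when it carries annotations; max-division preserves that
information and maps "rescaled between 0 and 1" onto the simplest formula.
S_tot ties are broken by BR, then lexicographically.

## Boolean network and continuous dynamics

KGML relations with subtype activation/expression map to +1,
inhibition/repression to −1; other subtypes (binding, phosphorylation
without a sign, …) are skipped with a warning since they carry no usable
sign. Group entries expand to one regulation per component on either side
of a relation. Each target's update rule is the inhibitor-dominant
convention `OR(activators) AND NOT OR(inhibitors)`; targets with only
inhibitors use `NOT OR(inhibitors)`, and unregulated nodes are constant
inputs. Contradictory pairs (both signs on the same edge) are kept on both
sides — the AND NOT structure makes inhibition dominate — and logged.

The continuous transform interpolates each rule multilinearly over the unit
hypercube. Because the rule factorizes over disjoint regulator sets, the
interpolation has the closed form
`B̃ = (1 − Π_a (1 − h(x_a))) · Π_i (1 − h(x_i))`,
with h the identity (BooleCube), the Hill function x^n/(x^n + k^n)
(HillCube), or the normalized Hill h(x)/h(1) (normalized HillCube, the
default: it restores exact corner agreement with the Boolean rule while
keeping sigmoidal responses). Defaults n = 3, k = 0.5, τ = 1, horizon 10 —
standard choices for qualitative pathway simulation where only the
relative ordering of responses is interpreted, not absolute time. The ODE
`dx/dt = (B̃(x) − x)/τ` keeps [0,1]^n forward-invariant; integration uses
RK45 at rtol 1e−6, and the integrator's right-hand side clips trial states
to the hypercube since rejected trial steps may momentarily overshoot.

Treatment simulation initializes target genes to their stated values and
draws all other genes independently Bernoulli(0.5), 1000 Monte-Carlo runs
by default. Targets are *initialized*, not held, by default — modeling a
transient stimulus — with clamping available for a sustained one. A gene
counts as switched when its final value lies strictly on the opposite side
of 0.5 from its initial value; evaluating the endpoint rather than path
crossings makes the statistic a net state change, insensitive to transient
excursions (a path-crossing reading would also count decaying pulses).
Randomness comes from one seeded generator; node order is canonical
(lexicographic), so rankings are reproducible and independent of input
ordering.

## Enrichment and expression statistics

Enrichment uses the exact hypergeometric upper tail P(X ≥ k) (scipy), tests
only terms overlapping the query, and applies Benjamini–Hochberg within
each category (KEGG and GO are reported and corrected separately). The
significance threshold (default 0.001) applies to adjusted values by
default; a raw-p mode exists because "p < 0.001" thresholds are sometimes
applied before correction, and both readings are defensible. The default
background is the catalog's annotated universe; callers can restrict it to
the network's nodes.

Welch's t-test (scipy, unequal variances, Welch–Satterthwaite df) handles
per-gene comparisons; identical groups short-circuit to (t = 0, p = 1), and
zero-variance groups raise an error naming the group. The Stouffer
combination uses the one-sided transform Z = Φ⁻¹(1 − p) applied to the
two-sided t-test p-values — the combination is directionless, and the
combined p reduces to the input at n = 1. A signed variant (direction from
fold change) would require fold-change input and is intentionally out of
scope. No cross-gene multiplicity correction is applied: the combined p
*is* the set-level summary for small, underpowered designs.

## Synthetic data

The planted-network generator wires `n_modules` dense modules (default two
of 20 nodes, p_in = 0.9) with sparse cross edges (p_out = 0.02) and one or
more connector nodes attached to two modules with 2 edges each. In-module
weights are uniform on (0.7, 1.0) — above the score filter — while
cross-module weights default to (0.4, 0.7), below it, so reading the
emitted STRING-dialect table through the standard filter exercises edge
rejection; recovery benchmarks that need surviving cross edges pass a
(0.7, 1.0) cross-module range explicitly. The expression generator mirrors
a four-condition (scratch × treatment) × two-timepoint design with three
biological replicates, baseline 5.0 log2 units and Gaussian noise (default
sd 0.25, a typical qPCR replicate spread); effects are stated log2 fold
changes. The annotation generator embeds the network in a 1000-gene filler
background so the network is a small, enrichable subset of the universe, as
it would be against a genome-wide catalog.

What the generators do **not** emulate: real STRING score distributions
(scores here are uniform within bands), scale-free degree structure, GO's
term hierarchy and annotation propagation, correlated expression noise, or
realistic pathway topologies (the random 44-node/49-edge pathway matches a
mid-sized signaling pathway in size only). Passing the recovery and
calibration suites therefore demonstrates correctness of the algorithms
under controlled conditions, not performance guarantees on real databases.

## Problem sizes and determinism

The test and acceptance workloads use two scales: the 41-node two-module
benchmark for recovery statistics (50 generator seeds in the tests, 25 in
the acceptance script) and a three-module, ~450-node / ~25,000-edge network
for the end-to-end run, matching the magnitude of a real seed-expanded
interactome. All stages are deterministic given their seed; the Monte-Carlo
stages derive every draw from one named generator.

## Known limitations

* The clustering growth is greedy with a single candidate per seed; unlike
  simulated-annealing variants it can miss weakly cohesive modules
  straddling strong ones (overlap merging mitigates but does not remove
  this).
* Current-flow betweenness is exact but dense; networks beyond a few
  thousand nodes would need the approximate solver.
* KGML parsing covers gene/group entries and signed PPrel/GErel subtypes;
  compound-mediated (ECrel) chains are not resolved through the compound.
* The Boolean rule family is fixed to the OR/AND-NOT convention;
  per-node custom logic would require a rules-file extension.
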