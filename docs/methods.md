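# Methods

This note documents the models and algorithmic choices behind the
package, what the synthetic-data generator does and does not emulate, and
the numerical conventions used throughout.

## Pedigrees and meiotic distances

A pedigree is a forest of rooted trees with directed father→son edges; a
node is *genotyped* iff it carries a label. The meiotic distance between
two genotyped men is the number of edges on the unique undirected tree
path, computed as depth(a) + depth(b) − 2·depth(mrca) from each node's
patrilineal ancestor chain. A pair is *lineal* when one man is a
patrilineal ancestor of the other (the path is monotone in edge
direction, equivalently distance = |depth difference|). Genotyped pairs
split across connected components carry no defined distance; batch runs
skip them with a warning rather than aborting, so one malformed file does
not kill a large analysis.

TGF dialect: whitespace-separated fields, mandatory `#` separator, edge
labels ignored, node ids opaque strings. Validation enforces at most one
father per node and directed acyclicity; given the one-father rule,
acyclicity of the directed graph is exactly the forest property, which is
why no separate undirected check is performed.

## Conservative mutation counting

Single-copy loci follow the stepwise mutation model: the count between
alleles a and b is |a − b| in whole repeat units, so 15 vs 17 is two
single-step events. A fractional offset (15 vs 15.2) cannot arise from
stepwise mutation between compatible ladders; it is counted as one event
and logged, since real capillary-electrophoresis data do contain
microvariant mismatches and a hard error would be unhelpful.

Alleles are stored as tenth-precision decimals (CE nomenclature, e.g.
23.2) and all step arithmetic is done on tenths of a repeat to avoid
float-representation artifacts.

Multi-copy loci: the copy-richest individual in the comparison pool
(pedigree, or all samples in population mode) fixes the assumed copy
count C. A sample with fewer observed alleles is padded to C by
duplicating its own alleles; which allele is duplicated is not knowable,
so the count minimizes over every admissible padding of both samples of
the minimum-weight perfect matching on the C×C step-cost matrix
(`scipy.optimize.linear_sum_assignment`). This is the most conservative
(smallest) number of mutations consistent with the pair. The exhaustive
permutations×paddings enumeration lives only in the test suite as an
independent oracle.

Differentiation rates use the exact Clopper–Pearson binomial interval
(Beta quantiles, α = 0.05 by default, exposed as a parameter). The median
number of pairwise differences is reported as a diversity summary; note
it is *not* the population-genetic R_ST statistic despite sometimes being
labelled that way in the field.

## Mutation placement on pedigrees

Per marker, the minimum number of stepwise mutations explaining the
genotypes is found by bottom-up dynamic programming (Sankoff) over the
subtree spanning the genotyped men. Candidate ancestral states are the
integer-step ladders around each observed allele ±2 repeats; a
minimum-cost solution cannot profit from states outside the observed
hull, the margin is kept for safety. Edge costs encode one deliberate
asymmetry: between two *genotyped* endpoints (an observed father–son
transmission) any difference costs 1 — a 10→12 change across one meiosis
is a single two-step event — while across edges with an untyped endpoint
the cost is the full step distance, so the same 2-repeat difference in
cousins decomposes into two independent single-step events.

Ties are broken rootward: among equal-cost assignments the top-down pass
prefers the child state with the smallest remaining subtree cost, which
pushes each change onto the topmost edge that can carry it; among
equal-cost root states the one carried by the most genotyped individuals
wins (then the smallest allele, for determinism). Tie-breaking never
changes the optimal cost, only where events are drawn. Recurrent parallel
mutations are knowingly merged when parsimony favours a single ancestral
event — an inherent limitation of pedigrees with untyped members that a
manual analysis shares.

Multi-copy loci in the tree context: genotypes are padded to the
pedigree-wide copy count, each sample choosing the self-duplication
padding with minimum stepwise cost against the copy-richest individual's
sorted alleles, and copies are aligned by sorted rank. For 1-D step costs
the sorted matching is an optimal assignment, so this realizes the
founder-anchored minimum-cost alignment; each rank slot is then
reconstructed as an independent single-copy chain. How the original
analysis aligns copy slots across a tree is not documented anywhere we
know of; this is one defensible reading, and it is isolated in a single
helper.

Rates pool events and covered meioses (edges of the spanning subtree —
edges to untyped dead ends are never counted) across pedigrees:
μ̂ = Σ events / Σ meioses. The Clopper–Pearson CI treats meioses as
Bernoulli trials, an approximation whenever one meiosis carries several
events (the event count is clamped to the trial count in that rare case).

## Dendrograms

Distances d(a,b) = Σ_m n_m(a,b)·w_m with w_m = 1 (unweighted) or
−log₁₀(μ_m), requiring 0 < μ_m < 1 so weights are finite and positive.
Rapidly mutating loci, whose variants recur within a pedigree, are
thereby down-weighted relative to slow loci whose variants mark deep
branches. Clustering is scipy complete linkage on the condensed matrix;
the cluster count maximizes the mean silhouette computed directly on the
precomputed distance matrix (no embedding), over candidates 2..min(n−1,
10) — the cap avoids trivially high-k silhouette artifacts and is
user-overridable; ties take the smallest k. With fewer than three
samples, or when every candidate degenerates, k falls back with a
warning.

## Pair simulator

Stated world: per locus a pair separated by g meioses is a g-step chain
over non-negative deviation states. From 0: stay 1−μ, +1 with 0.97μ, +2
with 0.03μ (DYF1000: 0.94μ/0.06μ, because its mixed tri-/hexanucleotide
structure makes single- and multi-step changes indistinguishable). From
state s>0 the mutation mass halves and becomes directional: ±1 each
0.97μ/2, ±2 each 0.03μ/2. Two corner decisions: (i) the halved regime
applies whenever the current state is nonzero — the only reading
consistent with arbitrary-length chains; (ii) from state 1 a backward
two-step would go negative, so its mass (0.03μ/2) is reassigned to the
backward one-step, preserving the total mutation probability. Copies of a
multi-copy locus run independently at μ/copies and are summed per marker.
Every distance is simulated from fresh chains; one `numpy` Generator
seeded per run makes output bitwise reproducible.

The forward companion (`simulate_pedigree_genotypes`) evolves actual
allele values down a pedigree — per edge: mutate with the locus
probabilities, direction uniform — and is the ground-truth generator for
the rate-recovery tests. Defaults there (founder allele 15, panels
spanning μ = 10⁻³..7·10⁻² from slow to rapidly mutating loci, pedigrees
of 6–12 members) reflect typical Y-STR panels and study pedigrees. What
the generator does **not** emulate: allele-dependent and haplogroup- or
age-dependent rate variation, copy-number mutations
(duplications/deletions), genotyping error, and microvariant creation —
so a green recovery test establishes correctness of the estimation
machinery under the stepwise model, not robustness to those real-data
phenomena.

## Classifiers

Double cross-validation: outer stratified K folds (default 5); within
each fold a `RandomizedSearchCV` (default J = 50 draws, inner 3-fold,
macro-F1) searches each requested family's pre-defined space (logistic
regression, linear/RBF SVC, random forest, histogram gradient boosting,
k-NN, small MLP); the fold-best model is evaluated once on the held-out
fold. Held-out indices never reach the inner search (asserted in tests).
The deployable model refits the best fold configuration on all data — the
alternative of keeping K fold models without a designated predictor is
ambiguous, and a single refit model is reproducible and simple to ship.
Probability calibration is deliberately not applied.

Confidence ranges: from the modal meiotic distance, grow a contiguous
interval one class at a time toward the neighbour with the higher
probability (ties prefer the smaller distance) until the cumulative mass
reaches each level; by construction the 85% range nests inside the 95%
inside the 99%. This greedy modal-growth rule is one reconstruction of a
procedure that is not fully specified in the literature we build on; it
is isolated behind `confidence_ranges` for easy replacement.

## Numerical conventions and degenerate inputs

- Allele comparisons on tenths of repeat units; probability sums checked
  to 1e-9 (config validation) and 1e-6 (prediction input).
- Empty allele cells are rejected rather than guessed at (locus dropout
  vs true deletion is not encodable in CE repeat counts).
- Incomplete profiles are a hard error naming sample and marker;
  `drop_incomplete` removes either samples or markers, logged.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  CLI outputs carry a provenance header with version, seed and command.

## Known limitations

- Non-tree pedigrees (half-siblings through different fathers, loops),
  maternal lines and GEDCOM input are out of scope.
- Parsimony-based rates are conservative: hidden and parallel mutations
  in sparsely typed pedigrees bias μ̂ downward, most visibly for rapidly
  mutating loci in deep pedigrees.
- The classifier's accuracy depends on the simulated rates matching the
  study population; models should be rebuilt per marker panel and, where
  known, per population.
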