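# Methods

## Model and assumptions

netboxpy treats the prior interactome as an undirected simple graph:
interaction direction, type, and confidence are ignored (labels are parsed
and preserved for output, never used in inference). Identifiers are matched
by exact string equality after stripping surrounding whitespace — no case
folding or aliasing, because silent identifier coercion produces
irreproducible mappings; inputs must be pre-harmonized to one namespace.
Self-loops are dropped and duplicate undirected edges merged (first-seen
label wins).

## Linker test

For a candidate linker (an unaltered gene with ≥ 1 altered neighbor) with
global degree *k*, the null model treats its neighbor set as a uniform draw
of *k* nodes from the *N* = (nodes in the prior network − 1) other nodes,
of which *A* = (mapped altered genes) are altered. The p-value is the
hypergeometric upper tail Pr(X ≥ x), computed via `scipy.stats.hypergeom.sf`
(log-space internally, stable to interactome scale, N ~ 10⁵). Choices worth
making explicit:

- **Population.** The candidate itself is excluded from the urn (it cannot
  be its own neighbor); altered genes are not excluded (the candidate is
  unaltered by definition, so A needs no correction). This is the standard
  urn reading; the choice is isolated in one helper so alternates are
  one-line changes. Isolated nodes count toward N — adding disconnected
  nodes to the input network therefore shifts every p-value, which is
  intended: the population is the network the user supplied.
- **Hypotheses.** BH runs across the candidate set only — candidates are
  the hypotheses actually tested. Altered genes are never tested.
- **Acceptance is inclusive**: adjusted p exactly equal to the cutoff
  (default 0.05) is accepted.
- **legacy_point mode** scores Pr(X = x) instead of the tail, for
  comparison with the original NetBox implementation's raw p-values. The
  accepted sets typically coincide at FDR 0.05; the tail test is the
  default and the statistically defensible one.

The extended network is the induced subgraph on mapped altered genes plus
accepted linkers — all induced edges, including linker–linker, since a
module is defined by its internal density, not by edge class. Altered genes
left isolated within that node set are dropped from clustering but reported
separately.

## Community detection

Both methods maximize Newman modularity Q = Σ_c (e_cc − a_c²), computed
exactly from edge counts.

- **Girvan–Newman (default).** Iteratively remove the edge of maximal
  betweenness; after each removal score the connected-component partition;
  return the best-Q level of the dendrogram. Betweenness ties (within
  1e-12 relative) break to the lexicographically smallest endpoint pair,
  making the run fully deterministic. Cost is roughly O(|E|²·|V|); above
  2,000 nodes a warning suggests the spectral method instead (no automatic
  switch — the method is part of the analysis definition).
- **Leading eigenvector.** Recursive bisection by the sign of the leading
  eigenvector of the generalized modularity matrix
  B⁽g⁾ = B_g − diag(B_g·1), starting from connected components. A group is
  left whole when the leading eigenvalue is non-positive, when it is
  degenerate with the second (within 1e-10 relative — the eigenbasis
  rotation would be arbitrary, so splitting would be nondeterministic), or
  when the sign split does not increase Q. No Kernighan–Lin fine-tuning is
  applied; on benchmark-scale planted graphs the plain spectral split
  recovers the blocks.

Module ids are contiguous integers ordered by descending size, ties broken
by smallest member — identical groupings always serialize identically.
Edgeless networks partition into singletons with Q reported as 0 (Q is
otherwise undefined without edges). Disconnected inputs are partitioned
jointly; components fall into separate modules naturally.

## Significance tests

- **Global connectivity (LCC).** Observed statistic: LCC of the subgraph
  induced by mapped altered genes on the *full prior network* (the frame
  they were mapped onto, hence also the null's sampling frame). Null: the
  same number of genes drawn uniformly without replacement from all
  network nodes. p = (r + 1)/(trials + 1) with r the count of null LCCs ≥
  observed — the +1 pseudocount keeps p a proper probability in
  [1/(trials+1), 1]. Default 1000 trials. Uniform (not degree-matched)
  drawing is used; degree-matched nulls are a possible extension.
- **Modularity null.** Degree-preserving randomization by double-edge
  swaps: ⌈swap_factor·|E|⌉ attempts (default swap_factor 10, a common
  mixing heuristic), each picking two edges uniformly and proposing the
  crossed replacement, rejected if it would create a self-loop or
  duplicate. Community detection is **re-run** on every rewired network —
  the null must allow each random network its own best partition; scoring
  the observed assignment on rewired graphs would inflate z. z =
  (Q_obs − mean)/sd over (default) 100 rewired networks, reported with the
  one-sided upper-tail normal p (high modularity = significant). If the
  null is degenerate (sd = 0, e.g. a triangle, which no admissible swap
  can change), z is NaN and p falls back to the empirical fraction with
  the same pseudocount.

Per-trial seeds derive from the master seed via `numpy.random.SeedSequence`
spawning; identical inputs + seed give bit-identical reports across
processes (graph construction uses canonical sorted insertion order so
floating-point summation order never depends on hash ordering).

## Planted-module benchmark

The generator is a stochastic block model: `n_modules` blocks of
`module_sizes` nodes wired internally with `p_intra` = 0.6, between blocks
with `p_inter` = 0.02, plus `background_nodes` = 40 nodes whose every edge
(to anything) appears with `p_background` = 0.02. The altered list takes
`altered_fraction_in_modules` = 0.7 of each block (rounded) plus
`altered_background` = 5 random background genes as noise. Unaltered block
members with ≥ 1 altered neighbor are recorded as **withheld linkers** —
the genes the linker test ought to recover. The reference configuration is
3 blocks × 12 genes (76 nodes total): large enough that edge-betweenness
clustering is exercised non-trivially, small enough that the full
20-benchmark recovery study runs in seconds.

What it emulates: modular pathway structure, incomplete alteration
coverage, a noise floor of unrelated altered genes. What it does not:
scale-free degree distributions, hub proteins, edge-confidence structure,
or a realistically large unaffected interactome. The last gap matters for
interpretation: with ~29 of 76 nodes altered, A/N ≈ 0.4 and the
hypergeometric tail is intrinsically weak — a withheld linker with 5 of 7
neighbors altered is only mildly surprising (null expectation ≈ 3), so at
FDR 0.05 few withheld linkers are recovered at this benchmark scale
(median recall over 20 seeds is 0.0; even uncorrected p ≤ 0.05 yields only
~0.25). In a real interactome (N ~ 10⁴, A/N ≤ 0.05) the same x/k ratio is
dramatic evidence. Module recovery (ARI) and false-positive control are
unaffected and are the quantities this benchmark validates strongly;
linker recall at desk scale mainly demonstrates the direction of the test,
and its dependence on A/N is documented behavior, not a defect of the
implementation.

Recovery scoring: ARI (scikit-learn) between planted and inferred
assignments restricted to planted module members present in the result;
withheld-linker recall; count of background nodes falsely accepted as
linkers.

## Numerical and degenerate-input choices

- Empirical p-values always use the (r+1)/(n+1) pseudocount.
- Q comparisons in the Girvan–Newman cut selection use a 1e-12 absolute
  margin so float noise cannot flip the selected level.
- A gene list with zero mapped genes, an empty network file, a malformed
  line (reported with its line number), community detection on an empty
  network, rewiring with < 2 edges, and modularity of an edgeless network
  are all hard errors rather than silent degradation.
- The LCC-test calibration study draws a fresh random network per
  replicate: the empirical p is discrete (the LCC takes few values on any
  one graph), so calibration is a property of the ensemble, and the draw
  size is chosen near the induced-subgraph percolation threshold where the
  null LCC distribution is widest.

## Problem sizes used in the test suite

Exhaustive partition oracles run on graphs of ≤ 8 nodes (≤ 4,140
partitions); exact hypergeometric enumeration on N ≤ 12; the recovery
study uses 20 benchmark draws of the 76-node reference configuration; null
calibration uses 200 replicates × 99 trials; the modularity null uses
20–100 rewirings depending on the test. These sizes were chosen so the
whole suite gives tight statistical checks while remaining quick to run on
a laptop.

## Known limitations

- Undirected, unweighted analysis only; no edge-confidence weighting.
- Uniform LCC null (no degree matching).
- No overlapping modules; Louvain/Leiden are out of scope.
- Functional annotation of discovered modules (GO enrichment) is left to
  dedicated enrichment tooling downstream.
- Identifier harmonization is the user's responsibility.
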