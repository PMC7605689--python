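# netboxpy

De novo discovery of candidate pathway modules from cancer-genomics (or any
other) altered-gene lists, by combining a prior-knowledge interaction
network with network clustering — no curated gene sets required.

## Who this is for

You have a list of genes that are significantly altered in a dataset
(mutations, copy-number changes, expression shifts) and a curated
interactome (e.g. exported from Pathway Commons as SIF). Recurrence-based
gene lists miss rarely mutated genes that nonetheless sit in the middle of
an affected process. netboxpy maps your list onto the interactome, pulls in
statistically supported unaltered **linker genes**, partitions the
resulting network into **modules**, and tells you whether the structure it
found could have arisen by chance.

## The method

1. **Mapping.** Altered genes are mapped onto the prior network.
2. **Linker inference.** A candidate linker is an unaltered gene adjacent
   to altered genes. For a candidate with global degree *k* and *x* altered
   neighbors among the *A* altered genes in the *N*-node network, the
   p-value is the hypergeometric upper tail

   Pr(X ≥ x) = Σᵢ₌ₓ C(A, i)·C(N−A, k−i) / C(N, k),

   Benjamini–Hochberg corrected across all candidates; candidates with
   adjusted p ≤ 0.05 (inclusive) become linkers. A `legacy_point` mode
   scores Pr(X = x) instead, reproducing the raw p-values of the original
   NetBox implementation.
3. **Module detection.** The extended network (connected altered genes +
   accepted linkers) is partitioned by Girvan–Newman edge-betweenness
   clustering (or the leading-eigenvector spectral method for large
   networks), returning the partition that maximizes Newman modularity
   Q = Σ_c (e_cc − a_c²).
4. **Significance.** Two permutation tests: an empirical p-value for the
   size of the largest connected component (LCC) of the altered genes
   against uniformly drawn gene sets, and a z-score for the observed Q
   against degree-preserving double-edge-swap rewirings of the extended
   network (community detection re-run per rewiring).

A self-contained planted-module benchmark (stochastic block model with
background nodes, partially altered modules, and withheld linkers) provides
ground truth for testing recovery — no downloads needed.

## Worked example

Generate a planted benchmark (3 modules × 12 genes, 40 background genes,
70% of module members altered) and run the full workflow on it:

```bash
netbox simulate --seed 3 -o demo_truth
netbox run --network demo_truth/network.sif --genes demo_truth/altered_genes.txt \
    --lcc-trials 1000 --mod-trials 100 --seed 1 -o demo_run
netbox score --truth demo_truth --result demo_run
```

which prints

```
Network module discovery results
==============================================
Prior network          70 nodes, 172 edges
Altered genes          29 requested, 29 mapped, 0 unmapped
Linker candidates      28 tested, 1 accepted (BH-adjusted p <= 0.05, mode=tail)
Extended network       27 nodes, 63 edges (3 isolated altered genes dropped)
Modules                3 (edge_betweenness), modularity Q = 0.5649
----------------------------------------------
LCC test               observed 26, p = 0.01798 (1000 trials)
Modularity null        mean 0.2809, sd 0.0271, z = 10.48, p = 5.541e-26 (100 rewired networks)
{
  "ari": 1.0,
  "linker_recall": 0.08333333333333333,
  "linker_false_positives": 0,
  "n_withheld": 12,
  "n_module_nodes_in_result": 25
}
```

Reading it: all 29 altered genes mapped; of the 28 unaltered neighbors
tested, one passed the FDR threshold; 26 of the altered genes form a single
connected component, larger than almost every random draw (p ≈ 0.018); the
detected 3-module partition (Q = 0.565) sits 10 standard deviations above
its rewired null; and the scored partition matches the planted modules
exactly (ARI = 1.0). Withheld-linker recall is low at this benchmark size
because the altered genes are a large fraction of the 76-node network,
which caps the power of the hypergeometric test (see `docs/methods.md`).

The same workflow is available as a library:

```python
from netboxpy import NetBoxModel

model = NetBoxModel.from_files("network.sif", "altered_genes.txt")
results = model.fit(cutoff=0.05, community_method="edge_betweenness")
results.assess_significance(seed=1)
print(results.summary())
results.linker_table   # pandas DataFrame: gene, degree, x, p_raw, p_adjusted, accepted
results.module_table   # pandas DataFrame: gene, module_id, role
```

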