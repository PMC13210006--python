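# rhizonet

Network and nutrient-cycling analysis for rhizosphere microbiome studies
with factorial field designs — typically a tillage (no-tillage NT vs
moldboard tillage MT) by straw-return (none/half/full: NS/HS/TS) experiment
with replicated plots, amplicon-derived taxon abundance tables for bacteria
and fungi, soil carbon/nitrogen/phosphorus fraction measurements, and
PICRUSt2-style predicted enzyme-gene abundances.

The package is aimed at soil microbial ecologists who want the full chain
from abundance tables to mechanism candidates as reproducible, seeded,
tested code rather than a collection of ad-hoc R snippets:

1. **Co-occurrence networks** — Spearman rank correlation ρ between all
   taxon pairs, Benjamini–Hochberg FDR across the pair family, edges kept
   when |ρ| > 0.70 and adjusted p < 0.01; per-treatment subnetworks,
   topological parameters (degree, density, path length, betweenness,
   clustering, modularity, positive-edge share), and a one-number
   **network complexity** score per subnetwork (axis 1 of a PCoA of the
   z-scored topology table, oriented so average degree loads positively).
2. **Modules** — fast-greedy (CNM) modularity maximisation on |ρ|-weighted
   edges, with modules smaller than 20 taxa merged into their strongest
   neighbour; module relative abundance; OLS module–nutrient regressions
   with significance stars.
3. **Core taxa** — random-forest %IncMSE (out-of-bag permutation
   importance) of module members for each nutrient, with a
   response-permutation significance screen (add-one p-value).
4. **Pathways** — a looser bipartite screen (|ρ| > 0.60, raw p < 0.05) of
   microbe↔gene and gene↔nutrient correlations, joined into complete
   microbe → enzyme gene → nutrient pathways (both edges must hold
   simultaneously); sign products label pathways promoting/inhibiting;
   Cytoscape-ready SIF/GraphML export.
5. **Multivariate statistics** — Shannon and Chao1, Bray–Curtis
   dissimilarity, PCoA, two-factor PERMANOVA (sequential SS, 999 free
   permutations), Mantel tests, and variation partitioning (VPA) via
   redundancy-analysis R² with the Ezekiel adjustment.
6. **PLS path modeling** — Lohmöller's alternating algorithm (Mode A,
   path weighting scheme), design coded tillage ∈ {0,1} and straw ∈
   {0, 0.5, 1}, bootstrap percentile CIs (1000 draws by default) and
   GoF = √(mean communality × mean R²).

A first-class **synthetic-data generator** plants known module structure,
module-driven nutrients and taxon-driven genes with tunable noise, and
saves the ground truth — every stage above is validated by recovering what
was planted.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from rhizonet.cooccurrence import spearman_matrix, build_network, topology_summary
from rhizonet.community import detect_modules, enforce_min_size
from rhizonet.synthetic import GeneratorConfig, generate_community

table, meta, truth = generate_community(GeneratorConfig(seed=42))
net = build_network(spearman_matrix(table), r_min=0.70, p_max=0.01)
topo = topology_summary(net)
part = enforce_min_size(detect_modules(net), net, min_size=20)
```

Running `python examples/02_network_and_modules.py` (the script version of
the above) prints:

```
network: 103 nodes, 1068 edges, density 0.203, positive edges 90.4%
modules of >= 20 taxa: {'module_1': 28, 'module_2': 25, 'module_3': 24, 'module_4': 23}  (modularity Q = 0.603)
adjusted Rand index vs planted modules: 0.95
```

Of the 120 simulated taxa, 103 pass the correlation screen; the four
detected modules match the four planted co-abundance groups almost
perfectly (adjusted Rand index 0.95), and Q ≈ 0.6 indicates a strongly
modular network. The other `examples/` scripts walk through
module–nutrient regression and core-taxon screening (`03`), pathway
enumeration (`04`), PERMANOVA/Mantel/VPA (`05`) and the PLS path model
(`06`), each printing what the numbers mean.

A thin CLI mirrors the pipeline: `rhizonet simulate`, `rhizonet run-all
--seed 1 --out outdir` (writes every intermediate table, the networks and
a manifest with checksums).

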