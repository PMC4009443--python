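# seedgraph

Seed-based functional connectivity and signed graph-network analysis of
resting-state time series.

Spontaneous low-frequency (0.008–0.08 Hz) BOLD fluctuations are
temporally correlated across the brain regions of a functional network.
`seedgraph` implements the full analysis chain used to characterize such
a resting-state network from a seed region outward: nuisance correction
and temporal filtering of multivariate time series, seed correlation maps
with group inference and cluster extraction, construction of a signed
weighted adjacency matrix over network nodes, principled selection of the
binarization threshold range, community detection on the signed network
with null-model significance, and node-role / hub classification.
It is aimed at researchers who want each of these stages as a tested,
reusable component, together with a synthetic-data generator that plants
known structure so every stage can be validated end to end without access
to scanner data.

## The model at the core

Communities of a signed weighted network are scored with the signed
modularity

```
Q± = (1/v±) Σᵢⱼ [ w±ᵢⱼ − s±ᵢ s±ⱼ / v± ] δ(mᵢ, mⱼ)
Q* = Q⁺ − ( v⁻ / (v⁺ + v⁻) ) · Q⁻
```

where `w⁺`/`w⁻` are the positive and (absolute) negative weights,
`s±ᵢ` the signed strengths and `v±` the total signed weight.  Positive
weights dominate because they assign a node to a module; negative
weights only exclude it.  `Q*` is maximized by a two-phase Louvain
heuristic (greedy local moves, aggregation, finest-level refinement)
repeated from 100 random orders; the most frequent canonical partition
is kept.  Significance comes from degree-preserving signed rewirings of
the network with the weight multiset reassigned within each sign.

Node roles on the thresholded graph use the participation coefficient
`Pᵢ = 1 − Σₛ (kᵢₛ/kᵢ)²` and the within-module degree z-score; hubs are
nodes whose degree *and* betweenness exceed the network mean by at least
one standard deviation, and a hub with the highest participation
coefficient of its module is a connector hub.

Thresholds for the binarized graph analyses are admitted over a grid
(default Fisher-z 0.20–0.27 in steps of 0.01) when every node keeps at
least one edge and the wiring cost (edge density) stays ≤ 0.5; the
small-world criterion — global efficiency close to, and local efficiency
clearly above, degree-matched random rewirings — is additionally honoured
whenever it is attainable.

## Worked example

```python
from seedgraph import (SimulationConfig, simulate_study, preprocess_panel,
                       build_adjacency, first_level_split,
                       modularity_significance, select_threshold_range)
from seedgraph.modularity import consensus_partition

config = SimulationConfig(seed=0)            # 18 subjects x 25 nodes x 196 TRs
panel, truth = simulate_study(config)
clean = preprocess_panel(panel)              # CompCor + 0.008-0.08 Hz band-pass
adj = build_adjacency(clean)                 # mean Fisher-z adjacency

first = first_level_split(adj, truth.sign_labels, seed=1)
print(f"first level: {first.consensus.chosen.n_modules} modules, "
      f"Q* = {first.consensus.chosen.q_star:.3f}, "
      f"ARI vs sign labels = {first.ari_vs_sign:.2f}")

pos = [n for n, s in zip(adj.node_ids, truth.sign_labels) if s > 0]
report = select_threshold_range(adj.select(pos), seed=2)
print(f"admissible thresholds: {report.selected_range[0]:.2f}-"
      f"{report.selected_range[-1]:.2f}")

W = adj.select(pos).weights.copy()
W[W < 0.27] = 0.0
second = consensus_partition(W, seed=3, level="second")
print(f"second level at z >= 0.27: {second.chosen.n_modules} modules, "
      f"Q* = {second.chosen.q_star:.3f}")

ens = modularity_significance(adj, n_null=100, seed=4, n_runs=20)
print(f"null-model test: Q* = {ens.q_star_empirical:.3f} vs "
      f"{ens.q_star_values.mean():.3f} +/- {ens.q_star_values.std(ddof=1):.3f}, "
      f"p = {ens.p_quantile:.4f}")
```

Output:

```
first level: 2 modules, Q* = 0.718, ARI vs sign labels = 1.00
admissible thresholds: 0.20-0.27
second level at z >= 0.27: 3 modules, Q* = 0.492
null-model test: Q* = 0.718 vs 0.593 +/- 0.023, p = 0.0099
```

The unthresholded signed network splits exactly into the positive and
the anticorrelated block (ARI 1.0 against the planted sign labels); the
thresholded positive sub-network recovers the three planted modules;
and the empirical Q* sits far above the rewired-null distribution
(smallest attainable p at 100 nulls is 1/101 ≈ 0.0099).

The same pipeline is scriptable from the shell:

```
seedgraph simulate --out study/
seedgraph run-all --data study/ --out study/results/
seedgraph report --out study/results/
```

which writes the cluster table, node list, adjacency, threshold report,
metric tables, partitions, null-ensemble summary, and a run log with
every seed and setting.

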