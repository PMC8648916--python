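# rknet

Co-occurrence network analysis of *r*/*K*-selection-switch microbial time
series.

## The problem

In aquaculture and other managed aquatic systems, steady nutrient supply
selects for slow-growing, high-affinity **K-strategists**, while pulsed
feeding favours fast-growing opportunists (**r-strategists**, which include
many fish pathogens). A crossover microcosm experiment probes this
directly: communities inoculated from seawater are kept under one selection
regime for four weeks and then switched to the other (selection groups RK
and KR, crossed with high/low resource supply, three replicates each, 17
sampling days over 50 days with the switch between days 28 and 29).

`rknet` provides the analysis chain for such data — and a synthetic
generator with planted guild structure so every stage can be validated
against ground truth:

- **Preprocessing**: relative abundances, max-abundance filtering (named
  thresholds 5·10⁻³ / 10⁻³ / 5·10⁻⁴), scaling to absolute abundances by
  flow-cytometry total densities, and the *errthresh* prevalence rule
  (exclude OTUs absent in more than *n*·10^(−4/*n*) of *n* samples).
- **ReBoot association testing**: for each OTU pair, a bootstrap
  distribution of the similarity *f*\*(**x**, **y**) = *f*(**x** + ε*ₓ*,
  **y** + ε*ᵧ*) — Pearson or Spearman with optional Gaussian noise of SD
  γ = *s*·*x*<sub>min</sub> injected to break double-zero artefacts — is
  compared with a column-permutation null by a two-sided Z-test;
  Benjamini–Yekutieli q-values control the FDR under dependence.
  Permutations of relative abundances can be renormalized to respect the
  compositional sum constraint.
- **Network construction**: edge selection by q-threshold or top-*k*
  significance, edge sign from the Z-statistic, and walktrap module
  detection (walk length 20) on the positive-edge subgraph.
- **Temporal decomposition**: per-facet day means *x*<sub>i,.,k</sub>,
  z-scores *z*<sub>i,k</sub> = (*x*<sub>i,.,k</sub> − *x*<sub>.,.,k</sub>)/σ<sub>k</sub>
  (population SD), and node/edge styling rules built on the identity
  ρ<sub>k,l</sub> = (1/*N*) Σᵢ *z*<sub>i,k</sub>·*z*<sub>i,l</sub>, which
  decomposes each network correlation across sampling days.
- **Community statistics**: Bray–Curtis PCoA with per-microcosm trajectory
  export, and sequential (Type-I) PERMANOVA on 1 − Spearman dissimilarity
  with selection group entered before current regime.

## Worked example

```python
from rknet import (SimulationConfig, generate_experiment,
                   guild_recovery_score, infer_network)

counts, metadata, density, truth = generate_experiment(SimulationConfig(seed=1))
res = infer_network(counts, filter_level="low", measure="spearman",
                    noise="low", iterations=1000, edge_mode="top_k",
                    k=500, steps=20, seed=2)
print(len(res.network.nodes), len(res.network.negative_edges()))
print(guild_recovery_score(res.modules, truth))
```

Running `python examples/infer_network.py` (which adds a few summaries)
prints:

```
associations tested: 3160 OTU pairs
q <= 0.05: 2755 pairs; effective q of edge 500: 7.05e-26
network: 60 nodes, 320 positive / 180 negative edges
modules (by size): {2: 30, 1: 30}
negative edges running between guilds: 100.0%
adjusted Rand index vs planted guilds: 1.000
```

The 500 most significant edges connect exactly the 60 guild OTUs (the 20
planted neutral OTUs never make the cut); walktrap splits them into two
modules of 30 that coincide perfectly with the planted K- and r-strategist
guilds (adjusted Rand index 1.0), with positive edges inside modules and
every negative edge running between them — the signature of two guilds
responding in opposite directions to the selection regime.

The other scripts in `examples/` demonstrate the generator
(`simulate_experiment.py`), the temporal z-score styling
(`temporal_dynamics.py`: the K-strategist node turns from black to orange
as the regime switches to K-selection while its cross-guild edge stays
red), and the ordination/PERMANOVA layer (`ordination_permanova.py`: on
synthetic day-28/50 samples the current regime explains ~99% of the
dissimilarity variance while the historical selection group explains none,
i.e. the communities carry no memory of their selection history).

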