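# coralnet

Resistance and robustness analysis of bipartite coral–symbiont association
networks.

Reef-building corals depend on endosymbiotic algae (family Symbiodiniaceae),
and bleaching — the breakdown of that association under heat stress — can be
modeled as the removal of links from a bipartite network of coral hosts and
symbiont ITS2 types. `coralnet` is a library for ecologists and network
scientists who want to ask how such a network responds to warming and to
targeted or random attacks: it builds geographically resolved host–symbiont
networks from association records, assigns thermal tolerances to both
partners, simulates temperature-ramp bleaching, and quantifies resistance and
ecological robustness against null-network controls.

## The model

Each host node is a coral species in a specific subregion and carries that
subregion's mean monthly maximum SST, *T*<sub>MMM</sub>. Each symbiont ITS2
type is a single node regardless of location. Every association link gets an
absolute thermal threshold

> *W*<sub>h,s</sub> = *T*<sub>MMM</sub> + *T*<sub>Δ</sub> (τ<sub>symbiont</sub> + τ<sub>host</sub>) / 2

where *T*<sub>Δ</sub> = 3.0 °C is the upper thermal limit of the mutualism
and τ ∈ [0, 1] are partner tolerances: hosts from a Bleaching Resistance
Index (τ<sub>host</sub> = 1 − BRI/100), symbionts from rank-aggregated
tolerance scores (τ<sub>symbiont</sub> = √rank / 10). As temperature ramps
up, a link breaks once *T* ≥ *W*, and a host is **bleached** when it has no
links left. Two summary metrics:

- **Resistance** *R* = ΔT(10% → 90% of hosts bleached) / *T*<sub>Δ</sub> —
  how spread out the collapse is on the temperature axis.
- **Robustness** *R*50 — the fraction of links or nodes that must be removed
  (five attack orderings: random links, bleaching order, susceptible links
  by averaged/host/symbiont tolerance, random nodes, susceptible nodes)
  before only half of the original nodes retain at least one link.

Four null constructions (shuffled tolerances, uniform random tolerances,
degree-conserving rewiring, and a fully random bipartite graph) separate the
contributions of the tolerance distribution and the association structure.
Ensembles of replicate simulations are compared with pooled randomization
tests and compact-letter displays.

Missing taxa are handled the way the source meta-analyses require: unlisted
hosts draw a BRI from their closest listed relatives' Normal distribution,
and unlisted symbionts draw a rank from genus-weighted high/medium/low
tolerance-class mixtures, redrawn independently in every replicate.

## Worked example

The synthetic "global-like" preset reproduces the real global network's
marginals (685 hosts across 14 subregions, 250 symbionts, 1,697 links, three
generalist hubs with degree ≥ 140):

```python
import coralnet as cn

bundle = cn.generate_network(cn.global_like_spec(seed=1))
net = bundle.network()
cfg = cn.BleachingConfig(replicates=50)

natural = cn.resistance_ensemble(net, bundle.tables, cfg, seed=10,
                                 taxonomy=bundle.taxonomy)
null = cn.resistance_ensemble(net, bundle.tables, cfg, seed=11,
                              taxonomy=bundle.taxonomy, null="random_tolerance")
print(f"natural R = {natural.mean:.3f} +/- {natural.sd:.3f}")
print(f"uniform-tolerance null R = {null.mean:.3f} +/- {null.sd:.3f}")
```

prints

```
natural R = 0.748 +/- 0.010
uniform-tolerance null R = 0.874 +/- 0.030
```

i.e. the natural (BRI/rank-derived) tolerance distribution concentrates the
collapse into a narrower temperature band than a uniform one — real
tolerance structure makes the network *less* resistant. Robustness shows the
same asymmetry as the real data (`examples/03_robustness_attacks.py`):

```
random_links                 R50 = 0.752 +/- 0.007
bleaching                    R50 = 0.616 +/- 0.004
susceptible_links:host       R50 = 0.600 +/- 0.004
susceptible_links:symbiont   R50 = 0.697 +/- 0.010
random_nodes                 R50 = 0.397 +/- 0.026
```

Link attacks leave the network far more intact than node attacks, and the
environmentally informed bleaching order is more damaging than random link
removal. The `examples/` directory has one short script per capability
(network building and degree fits, resistance vs nulls, the five attacks,
family-level susceptibility, and the end-to-end pipeline with its
reproducibility manifest). A thin CLI mirrors the pipeline stages
(`bleach synth | build | simulate | robustness | nulls | compare | run`).

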