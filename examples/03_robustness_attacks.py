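"""Ecological robustness (R50) under the five removal models.

R50 is the fraction of links or nodes that must be removed before only half
of the original nodes still hold at least one link (secondary isolations
count as losses).
"""

import coralnet as cn
from coralnet.robustness import RemovalModel

bundle = cn.generate_network(cn.global_like_spec(seed=1))
net = bundle.network()
cfg = cn.BleachingConfig(replicates=30)

for label in ("random_links", "bleaching", "susceptible_links:averaged",
              "susceptible_links:host", "susceptible_links:symbiont",
              "random_nodes", "susceptible_nodes"):
    res = cn.robustness_ensemble(net, RemovalModel.parse(label), bundle.tables,
                                 cfg, seed=20, taxonomy=bundle.taxonomy)
    print(f"{label:<28} R50 = {res.mean:.3f} +/- {res.sd:.3f}")

# Link attacks leave higher R50 than node attacks (an isolated host loses one
# association at a time, while removing a generalist symbiont node strands
# every partner at once), and the environmentally-informed bleaching order
# degrades the network faster than random link removal.
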