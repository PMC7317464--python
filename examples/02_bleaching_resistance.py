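"""Simulate temperature-ramp bleaching and compare against null networks.

Each link carries a thermal threshold W = T_MMM + T_delta*(tau_s + tau_h)/2;
as temperature rises, links break and a host is bleached when it loses its
last symbiont. Resistance R is the temperature rise taking the network from
10% to 90% of hosts bleached, normalized by T_delta = 3 degC.
"""

import coralnet as cn

bundle = cn.generate_network(cn.global_like_spec(seed=1))
net = bundle.network()
cfg = cn.BleachingConfig(replicates=50)

groups = {}
natural = cn.resistance_ensemble(net, bundle.tables, cfg, seed=10,
                                 taxonomy=bundle.taxonomy)
groups["natural"] = natural.values
print(f"natural network:       R = {natural.mean:.3f} +/- {natural.sd:.3f}")

for kind in ("shuffled_tolerance", "random_tolerance", "rbdc", "rbndc"):
    res = cn.resistance_ensemble(net, bundle.tables, cfg, seed=11,
                                 taxonomy=bundle.taxonomy, null=kind)
    groups[kind] = res.values
    print(f"{kind:<22} R = {res.mean:.3f} +/- {res.sd:.3f}")

cmp = cn.compare_ensembles(groups, alpha=0.05, n_perm=999, seed=12)
print("\nsignificance letters (groups sharing a letter are not distinguishable):")
for label, letter in zip(cmp.labels, cmp.letters):
    print(f"  {label:<22} {letter}")

# Higher R means bleaching is spread over a wider temperature range. The
# uniform random-tolerance null is the most resistant: the natural tolerance
# distribution concentrates thresholds and makes real reefs more fragile.
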