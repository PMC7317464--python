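# Methods

This note documents the models implemented in `coralnet`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make seeded runs exactly
reproducible.

## Network construction

Association records (host species, subregion, symbiont ITS2 type) are
filtered to scleractinian, in-situ samples with a known subregion and
deduplicated on the (species, subregion, symbiont) triple, so each surviving
record is one geographically unique association and becomes one link. Host
identity is the (species, subregion) pair after whitespace normalization —
a species observed in three subregions is three host nodes, each carrying
its subregion's T_MMM — while a symbiont ITS2 type is always a single node.
Networks may be disconnected; nodes are stored in lexicographic order so
that every seeded computation is order-independent.

Two connectance conventions circulate for these networks: the bipartite fill
L/(hosts × symbionts) and the whole-matrix L/N². Both are reported with
provenance labels and neither feeds any downstream metric.

Degree-distribution diagnostics fit discrete power-law, truncated power-law
and exponential models by maximum likelihood (normalizing constants by
direct summation over the support, exact for bounded degrees) and compare
them by AIC. The fit is descriptive only. The exponent and the exponential
cutoff trade off strongly in any single truncated-power-law fit, so
parameter-recovery statements are made about the median over replicate
generations, not single fits.

## Tolerances

* Hosts: τ = 1 − BRI/100, where BRI is the percentage of tissue expected to
  bleach (0–100). Species missing from the source table draw
  BRI ~ Normal(mean, sd) of their closest listed relative group — congeners
  first, then confamilials, then the global mean/sd of the table — clamped
  to [0, 100] rather than redrawn, which preserves the stated draw while
  guaranteeing τ ∈ [0, 1]. If the table is entirely empty (a degenerate but
  supported configuration), a vague mid-scale prior Normal(50, 20) is used.
* Symbionts: τ = √rank / 10 for rank scores on [0, 100]; the square root
  deliberately narrows ordinal gaps. Unlisted ITS2 types draw a
  tolerance class (high/medium/low) with genus-specific mixing proportions,
  then a rank from that class's truncated normal on [0, 100]. Defaults:
  class means 75/45/15 (sd 10), and genus proportions that make Durusdinium
  predominantly heat-tolerant and Breviolum/Cladocopium skew lower; both are
  configurable (YAML) because the empirical class distributions come from an
  external meta-analysis and should be overridden when available.

Measured tolerances are replicate-invariant. Imputed symbiont tolerances are
redrawn for every simulation replicate; imputed host tolerances are redrawn
per replicate as well, for symmetry, with a `host_impute_once` switch to
freeze them — the redraw convention for hosts is genuinely open, and the
switch makes both readings testable.

## Bleaching model and resistance

Each link's threshold is W = T_MMM(host) + T_Δ (τ_s + τ_h)/2 with
T_Δ = 3.0 °C. The simulation is event-driven: links sorted by W, all links
sharing a threshold break in one event (closed threshold, T ≥ W — for
continuous tolerance draws open vs closed is immaterial, and closed makes
tied toy cases deterministic), and a host is bleached when its degree
reaches zero. The response curve is therefore an exact step function; a
fine-grid ramp is used only as a test oracle. The ramp is in absolute °C
(curves of different subregions separate naturally) but resistance depends
only on the ΔT between crossings.

R = [T(≥90% bleached) − T(≥10% bleached)] / T_Δ, with crossings at the step
function's first passage, no interpolation — bleaching is a discrete
isolation event per host node, and the denominator counts host nodes
(geographic), not species. R is computed per replicate and then averaged
(the alternative — computing ΔT on the mean curve — differs only when
replicate curves have very different shapes). On a single-subregion network
all W lie within [T_MMM, T_MMM + T_Δ], hence R ≤ 1; multi-subregion
networks can exceed 1 because their T_MMM baselines spread the thresholds
over a wider range.

Ensemble curves for reporting are averaged on a 0.01 °C grid with
1.5th–98.5th percentile bands (a central-97% band across replicates).

## Robustness

Attacks remove links or nodes one at a time; after each removal a node
"remains" only while it holds ≥ 1 link, so secondary isolations count as
losses for both attack classes — this puts link and node attacks on one
comparable axis, following the food-web robustness convention. The removal
fraction is over the original entity count, and only primary removals count
toward it for node attacks. R50 is the smallest removed fraction at which
no more than half of the original nodes remain (survival requires strictly
more than half).

Orderings: random permutation (links or nodes); links ascending by W
("bleaching"); links ascending by averaged, host-only, or symbiont-only
tolerance; nodes ascending by tolerance with hosts and symbionts pooled (a
`node_class` option restricts the attack to one class). Ties are broken by
a fresh uniform shuffle per replicate, so a zero ensemble sd occurs exactly
when the order is forced.

The family-susceptibility summary runs the bleaching model per replicate,
takes each replicate's first 100 bleached host nodes (isolation-event order,
shuffled within ties), intersects the sets across replicates, and tallies
the surviving hosts by family and subregion.

## Null networks

* shuffled tolerance — tolerances permuted within each node class
  (sampling without replacement preserves the multiset exactly; a
  with-replacement flag covers the other reading of "drawn from within the
  original distribution").
* random tolerance — every τ ~ Uniform(0, 1).
* RBDC — bipartite double-edge swaps (swap partners of two links when no
  duplicate arises), default budget 10 L swaps; preserves every node degree
  and simplicity by construction. Stub-matching was rejected because it can
  create multi-links. Tolerances are then shuffled.
* RBNDC — L distinct host–symbiont pairs placed uniformly at random
  (fixed-L rather than fixed-probability, preserving L exactly), tolerances
  shuffled. Host nodes keep their subregion so T_MMM stays defined.

Null constructions are re-applied fresh in every replicate of an ensemble.

## Randomization tests

Two replicate ensembles are compared by a pooled-relabeling permutation test
on |Δmean|, p = (1 + #{|Δ*| ≥ |Δ|}) / (n_perm + 1), with 9,999 permutations
and α = 0.05 by default; the pooled sample is sorted before relabeling so
the Monte Carlo p is exactly invariant to swapping the groups (equal sizes).
Pairwise p-values become a compact-letter display via greedy clique cover;
no multiple-testing correction by default (letters encode raw pairwise
outcomes), with a Holm option. This is the simplest defensible procedure
for ensemble comparison and is labeled as such; parametric ANOVA/Tukey
machinery is deliberately out of scope.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* Symbiont degrees from a discrete truncated power law (defaults α = 2.0,
  cutoff rate 0.005) with three planted generalist hubs of degree ≥ 140,
  nudged by ±1 steps to hit the link count exactly; host degrees are low
  (≥ 1 each, extras spread by a lognormal propensity so most hosts have few
  partners). Wiring picks each symbiont's hosts without replacement,
  weighted by remaining host quota, which guarantees simplicity and exact
  symbiont degrees; a repair pass guarantees every host at least one link.
* Hosts partitioned into the fourteen packaged subregions in the real
  host-count proportions; the "global-like" preset reproduces the real
  marginals exactly (685 hosts, 250 symbionts, 1,697 links).
* Host BRI ~ TruncNormal(45, 20) on [0, 100] with per-species sd 5 —
  mid-scale bleaching susceptibility with broad spread; symbiont ranks from
  the genus-weighted class mixture above. A configurable fraction of taxa
  (default 0.2 for both classes) is withheld from the source tables to
  exercise the imputation paths.

What the generator does **not** emulate: real species labels, nestedness,
and — importantly — any correlation between a node's degree and its
tolerance. The real data's strong susceptible-node result (targeted node
attack far more damaging than random) partly reflects empirically
low-tolerance generalists; with independently drawn tolerances the synthetic
preset reproduces the link-vs-node asymmetry and the bleaching-vs-random
ordering, but not that specific gap. Passing synthetic tests therefore
validates the machinery and the structural/directional claims, not the
real data's exact values.

## Reproducibility and problem sizes

All randomness flows from numpy `SeedSequence` substreams: one master seed
spawns independent per-stage and per-replicate streams (stage streams are
derived from stable stage/scope/model labels via SHA-256), so adding a stage
or replicate never perturbs the others, and re-running a configuration
reproduces outputs bit for bit; the pipeline manifest records input hashes
and the seed. Default ensemble size is 100 replicates, matching the study
design; the bundled examples use 20–50 replicates and the test suite uses
10–30 for the stochastic checks, which is ample for the directional and
stability assertions made there. Desk-scale oracles (exhaustive permutation
averages, fine-grid ramps) run on networks of ≤ 8 links or ≤ 11 nodes where
enumeration is exact.

## Known limitations

Temperature is the only stressor (no degree-heating-weeks, irradiance, or
flow), links cannot rewire adaptively after a disturbance, ITS2 types
understate symbiont diversity and host specificity, and the tolerance class
model defaults are placeholders for external empirical distributions. The
exact curation pipeline that produced the real 1,697-record table from raw
database records is not reconstructable from its description, so the filter
rules are exposed as configuration rather than hard-coded.
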