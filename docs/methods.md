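# Methods

## Interaction-map model

The map is an undirected simple graph over gene identifiers. Repeated
records of a pair collapse to one edge carrying the set of source-dataset
labels; the pair's *evidence count* is the number of distinct labels, the
unit of the "independent studies" used by the rescue rule. Self-loops are
dropped on load. Identifiers are canonicalized by trimming and
case-folding only — alias/symbol resolution is a database concern and out
of scope, so two identifiers that differ beyond case are two genes.

Hub filtering operates on *edges*, not nodes: a bait whose distinct-partner
count in the extracted bait neighborhood strictly exceeds
`max_bait_degree` (default 30) has its incident edges removed; a removed
edge returns if its evidence count is ≥ `multi_study_min` (default 2) or
if it touches a rescue bait. Consequences of the edge-wise reading: a
partner reached through both a hub bait and a non-hub bait keeps its
non-hub edge and remains an interactor. Degrees are measured once, in the
pre-filter neighborhood, making the pass idempotent; the degree reference
is configurable because the choice between the raw database and the
extracted neighborhood is genuinely open.

Role assignment is a strict precedence partition: bait > interactor
(non-bait with a surviving filtered edge) > non-interactor candidate
(adjacent, in the *full* map, to neither a bait nor an interactor) >
unclassified (everything else, e.g. neighbors of interactors or pruned
partners). The non-interactor pool is the sampling frame for random
comparison genes; sampling is uniform without replacement and seeded.

The confidence filter is separate and composable: strictly greater than
the threshold, unscored edges dropped (an unscored interaction cannot
demonstrate high confidence); it is not applied unless requested.

## Degree-matched permutation test

Excess interconnectivity of a gene set is confounded by degree, so the
null resamples *degree-matched* groups: query degrees are counted in
half-open bins (defaults 1–49, 50–99, 100–199, 200+, the top bin
open-ended), and each null group draws, without replacement, the same
number of nodes per bin from all eligible map nodes (the query itself
included; zero-degree query genes are excluded from matching and reported
separately). Statistics: number of within-group edges, or size of the
largest connected component of the induced subgraph.

The empirical p-value uses the add-one estimator
(1 + #{null ≥ observed}) / (n_iter + 1): it is never 0, and under a true
null it is uniform on {1/(n+1), …, 1}. Tail probabilities far beyond
1/(n_iter+1) — real bait sets can sit dozens of null SDs out — are
reported through the one-sided normal tail of z = (obs − mean)/sd, clearly
separated as a parametric approximation (including its log₁₀ for
underflow-free magnitudes). With a degenerate null (sd = 0) z and the tail
are NaN and only the empirical p is meaningful.

## Screen normalization and hit calling

A *plate* is one physical plate: a (plate_id, replicate_id) pair;
duplicate plates are normalized independently and averaged afterwards.
Per parameter, g = mean of all non-control wells across plates, p = the
plate's non-control mean, and every well on the plate (controls included)
is multiplied by g/p. Two exact algebraic consequences, both tested: after
normalization each plate's non-control mean equals g to floating-point
precision, and multiplying any plate's raw values by a positive constant
changes nothing downstream — the constant enters p and cancels.

Control statistics pool normalized GFP wells across plates (mean and
sample SD, ddof = 1); at least two control wells are required and a zero
SD is an error rather than a silent all-hit call. A `sigma_source="all"`
switch scores against all non-control wells instead. Hit calling is
one-sided and strict: parameter flagged iff z > k (default 3); decreases
are never flagged. Genes aggregate from amplicons by the any-hit rule with
phenotype-class union and the maximum z per parameter.

Because σ is *estimated*, the realized null false-call rate is only
asymptotically Φ(−k). With a few hundred control wells the SD estimate's
sampling error dominates the binomial variation of the exceedance count
(the count is overdispersed roughly twofold at 200 controls and 10,000
genes). The null-calibration study therefore scores an all-null simulated
screen with `sigma_source="all"`, under which σ̂ comes from ~20,000 wells
and the observed per-parameter rate is binomial around Φ(−3); with the
control-pooled default the same study demonstrates the overdispersion, a
practical argument for carrying more than 1–3 controls per plate when
calibration matters.

g/p normalization assumes plate composition is exchangeable — that a
plate's expected non-control mean is the global mean. Plates blocked by
role class violate this (a class with a high hit rate inflates its own
plates' means and is shrunk toward the controls), so recovery studies
interleave classes across plates, as a screening library whose order is
arbitrary with respect to class does naturally.

## Validation model

A primary hit is validated when an independent second dsRNA for the gene
is itself a hit sharing at least one phenotype class among
{G1, G2/M, >G2/M, subG1} (`shared-class` rule; an `exact-set` rule is
available). Screen overlaps are always computed on the intersection of
tested universes, never whole genomes. The high-confidence set is
validated hits ∪ (hits in both the current and a prior screen), with
provenance recorded per gene; novel regulators are validated hits absent
from both prior screens and an annotation list.

## Synthetic generators

**Network.** Chung-Lu background with Pareto node weights (shape 1.6,
rescaled to mean degree 4 at 500 nodes): heavy-tailed degrees as
interaction databases show. The first `n_hubs` nodes are topped up past
degree 30 to guarantee sticky hubs for the filter to act on. A planted
module (30 of 500 nodes by default, within-module edge probability 0.25
against a background density of ~0.008) stands in for the mutually
interacting regulators; module members are drawn from non-hub nodes so
hub pruning cannot erase the signal being studied. Each edge gets one of
7 dataset labels, and a second distinct label with probability 0.2,
providing multi-study pairs for the rescue rule.

**Screen.** The baseline is a five-part composition over G1 / S / G2/M /
>G2/M / subG1 of 48 / 12 / 32 / 5 / 3 percent — an asynchronous
S2R+-like culture — of which only the four gated parameters are reported,
so reported sums stay below 100 as gated data do. Per class, a gene is a
true regulator with the class probability (defaults 0.26 / 0.118 / 0.045
for bait / interactor / non-interactor, the enrichment gradient a
bait-centric design produces); a regulator shifts one uniformly chosen
gate upward by `effect_size_sd` (default 6) well-noise SDs. Each physical
plate draws a multiplicative log-normal batch factor per gate (log-SD
0.08) — multiplicative because that is the distortion g/p removes
exactly — and each well adds Gaussian noise (SD 1.5 percentage points,
clipped at 0). Plates hold 96 wells, 1–3 of them GFP controls, in
duplicate. Off-target events (non-regulator dsRNA acting on a random
gate) and knockdown failures (regulator dsRNA showing nothing) are
per-dsRNA Bernoulli draws; a simulated validation screen inherits
regulator status and affected gate but redraws both event flags — the
independence that makes second-reagent validation estimate the
true-positive fraction. All generators are deterministic given the seed.

What the generators do *not* emulate: event-level flow cytometry and
gating, well-position (edge) effects, correlated off-target families from
shared sequence, S-phase redistribution when one gate is perturbed, and
plate-to-plate cell-density trends. Passing recovery tests therefore
shows the pipeline's statistics are correct under the stated noise model,
not that real screens are free of these artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run: networks of 200–900 nodes (the
script's network study plants a 60-node module at within-module
probability 0.08 so module degrees overlap the background — a module of
uniformly high-degree nodes would make the degree-matched LCC null
trivially large and the test uninformative);
permutation tests at 1000 iterations (200 replicates × 99 iterations for
the null-uniformity check, judged by a Kolmogorov–Smirnov test at
p > 0.01); null calibration at 10,000 genes / one replicate; recovery at
500 genes per class in duplicate with off-target rate 0.11, which places
~40% of hits off-target at these class rates. Recovered counts are judged
against central 99% binomial intervals around the analytic expectations
implied by the configuration (p_eff + (1 − p_eff)·p_null, with p_eff the
effective-reagent probability and p_null the replicate-averaged four-gate
false-call probability). Normalization identity is asserted at 1e-9;
phase values are clipped at 0; ties at exactly k SDs are non-hits by the
strict inequality.

## Known limitations

Gene identifiers are matched textually; cross-dataset aliasing must be
resolved upstream. The permutation null resamples nodes only — no
edge-rewiring (configuration-model) null is provided. No FCS parsing or
cell-cycle curve fitting: the four gate percentages are the input
contract. Validation-rate differences between strata are reported with
counts but not tested inferentially.
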