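# Methods

This note records the models implemented in `exhaustnet`, the parameter
defaults and why they hold, what the synthetic generators do and do not
emulate, and the places where the design was genuinely open.

## Differential features and prizes

Replicate abundances are modelled as additive on the log2 scale. For each
feature, the stimulated-vs-resting contrast is `log2(mean_stim/mean_rest)`
with a Welch t-test on the log2-transformed replicates — a deliberately
assumption-light choice for 3–5 replicates per condition; no replicate
pairing or variance moderation is attempted. Raw p-values are adjusted by
Benjamini–Hochberg separately per layer (proteins and phosphosites), because
differential counts are conventionally reported per layer and the two layers
have very different feature counts and noise. Features with adjusted
p < 0.05 (strict inequality) receive prize `|log2FC|`; everything else has
implicit prize zero.

Phosphosite identifiers use `GENE:site`. When a gene carries both protein
and phosphosite evidence, prizes are merged at the gene level with the
maximum (default) rather than the sum: the forest should chase the strongest
single piece of evidence for a gene, not reward genes for being measured in
two layers. The sum is available (`merge="sum"`) for users who prefer
accumulation.

Timecourse composition is genuinely underdetermined: per-timepoint analyses
"factor in" earlier comparisons in an unspecified way. `per_timepoint_series`
therefore offers two explicit modes — `independent` (each timepoint stands
alone) and `cumulative` (a node's prize at time t is the running maximum over
timepoints ≤ t, so early evidence persists) — and claims neither as canonical.

## Interactome and edge costs

Self-loops are dropped before anything else (they can never occur in a
forest and would distort outdegrees), and duplicate (source, target) pairs
are collapsed — with kinds concatenated into provenance — before outdegree
computation, so duplicated annotations cannot dilute edge weights. With
`w(e) = 1/k_out(x)` the out-edge weights of every node then sum to exactly 1
and costs `c(e) = 1 − w(e)` lie in [0, 1). Node identifiers are treated as
opaque case-sensitive symbols; identifier mapping is out of scope.

The dummy root is attached to the prized nodes by default (rooting trees at
terminals); `policy="all"` is available. Each dummy edge costs ω, and a
solution using κ dummy edges pays ω·κ — exactly the objective's tree-count
term, which is why the dummy construction and the printed objective agree.

## PCSF objective and solvers

```
f(F) = Σ_{v∉V_F} [β·p(v) − μ·degree(v)] + Σ_{e∈E_F} c(e) + ω·κ
```

Defaults β=1, μ=0, ω=1, D=5. μ is implemented exactly as written (subtracted
from excluded-node terms) and is inert at its default of 0; the
outdegree-reciprocal edge costs already penalize hubs. Depth D counts edges
from a tree's root (the node attached to the dummy, depth 0) to a node; the
dummy edge does not count. Trees are out-arborescences respecting edge
direction.

**Exact solver.** A forest within the depth bound is equivalent to an
assignment of the included nodes to layers 0..D in which every layer-d node
takes an in-edge from a layer-(d−1) node (layer-0 nodes take a dummy edge at
cost ω), and for a fixed layering the best choice per node is its cheapest
in-edge from the previous layer. The solver searches all layerings with a
dynamic program memoized on (previous layer, used set, remaining depth) —
equivalent to branch-and-bound over arborescences but with shared
subproblems. It is globally optimal and practical to roughly a dozen nodes
(`exact_max_nodes`, default 12); beyond that it raises and directs callers
to the heuristic. Ties between equal-objective solutions are broken toward
fewer edges, then the lexicographically smallest sorted edge list (applied
greedily within the DP), so results are bit-for-bit reproducible.

**Heuristic solver.** Greedy gain-based attachment: a depth-layered
multi-source Dijkstra (states are node×depth pairs, sources are current
forest nodes at their depths plus unopened roots at cost ω) finds each
unincluded prized node's cheapest depth-feasible connection; the node with
the largest positive net gain β·p(v) − μ·deg(v) − cost is attached along its
path, repeating until no positive gain remains. A strong-pruning pass then
removes subtrees whose edge cost exceeds their collected score and whole
trees whose net value does not cover ω. The result is always a valid forest,
hence never better than the exact optimum; on the small-instance benchmark
the median relative gap is ~0–2% and over half the instances are solved to
optimality. All iteration orders and heap tie-breaks are lexicographic, so
the heuristic is deterministic without randomness (the config seed exists
for workflow provenance).

Objective comparisons in tests use an absolute tolerance of 1e−9: edge costs
like 1 − 1/3 are not exactly representable, so two different edge orders can
differ at the 1e−16 level.

## CASCADE PBM analysis

Log fluorescence is median-centered per array and then z-transformed against
the background probes' log-fluorescence mean and SD (ddof=1). The centering
is inert for z-scores (the background anchor absorbs any global shift) and
is kept only so exported log values are comparable across replicates; it
stands in for full array normalization, which the background-anchored
z-transform makes redundant here. The log base is natural; z-scores are
base-invariant.

Δz at position i, base b is the probe z minus the median z across the four
base variants at i, so each position's four Δz entries have median exactly 0.
The PWM transform is a per-position softmax `exp(λ·Δz)/Σ exp(λ·Δz)` with
λ = 1 by default (λ is a free inverse-temperature; the published transform
it replaces is not specified in-text), and IC is `2 + Σ p log2 p` bits,
clipped to [0, 2] against rounding.

Significance requires (1) consensus-probe z > 0.5 (strict), (2) a contiguous
5-column window with mean IC > 1 bit (motifs shorter than 5 use their full
length, flagged), and (3), when a motif database is supplied, a significant
best match. Criterion 3's printed direction reads backwards for a
significance filter; the default here is adjusted p < 0.05, with the printed
`>` direction available via `match_direction="gt"` for auditing. The internal
comparator scores the best Pearson correlation of flattened column
probabilities over ungapped offsets (≥4 overlapping columns), with a null
built from 999 column shuffles and BH adjustment across references.

Motif strength is the mean per-probe Δz of the top ⌈0.15·n⌉ probes. The
ranking dimension for "top probes" is not pinned down by the published
description; here an SV probe's scalar Δz is its z minus the median at its
varied position, and the consensus probe takes its Δz at its most preferred
position (ranking by raw z is available via `rank_by="z"`). Family strength
is the mean over the family's significant motifs; interactions must be
significant in ≥2 replicate arrays (strength averaged over the replicates
where seen); the contrast is exhausted minus acute, with single-condition
entries contrasted against 0 and flagged gain/loss.

## Synthetic generators

`NetworkScenario` defaults define the reference network benchmark: 300
nodes, Poisson(3) out-degrees (zero-truncated by resampling), a planted
12-node arborescence within depth 5, planted |log2FC| ~ N(2, 0.5) with
random sign, null effects 0, and 5 replicates/condition with SD-0.3
log2-scale noise around an N(10, 1) baseline. These sizes keep a full
20-seed pipeline benchmark in seconds while leaving the planted module
recoverable but not trivial (nulls do occasionally pass the FDR gate, as
they should at ~α rates).

`ArrayScenario` defaults: 30 models of length 6–10 in 6 families, 200
background probes, unit energy scale, SD-0.2 log-fluorescence noise, 3
replicates per condition. Probes follow the 60-bp template (GC cap +
2-bp pad + site + variable pad + fixed 24-bp primer) with
non-repeating-adjacent-base pads. Variant energies are negative penalties
−|N(1, 0.5)| with consensus energy 0; a model's log fluorescence adds
amplitude × (affinity + Σ energies) over the background baseline.

A condition effect is implemented as a fractional amplitude multiplier
(1 + shift) on the planted energy contribution in the exhausted condition,
not an additive log-fluorescence offset: a uniform additive shift on a
model's probes cancels exactly in the per-position median-centering of Δz
and could never reach a recruitment contrast, whereas a stronger recruited
cofactor genuinely widens the dynamic range between consensus and damaged
sites — which is what motif strength measures.

What the generators do **not** emulate: real interactome topology (degree
distributions are Poisson, optionally power-law in spirit but not
implemented), TMT reporter structure, peptide-to-protein inference,
sequence-dependent background binding, spatial array artefacts, or real
genomic background sequence. Passing the planted-recovery benchmarks
therefore demonstrates correctness of the algorithms under their assumed
noise model, not performance on real arrays or real interactomes.

Determinism: every generator is a pure function of its scenario; one
run-level seed fans out through named `SeedSequence` children (graph,
effects, noise, probes) so components are reproducible in isolation. All
writers emit sorted rows, making outputs byte-identical across reruns.

## Benchmark problem sizes

The shipped benchmarks use 200 random ≤8-node instances for exact-vs-brute
force agreement and heuristic admissibility, 20 seeds of the reference
network scenario for pipeline F1, and 20 seeds of the reference array
scenario for Δz recovery and contrast sign — sizes chosen so the whole suite
and the acceptance script each run in well under a minute on one CPU while
the binomial error bars on the reported rates stay informative.

## Known limitations

- The exact solver's tie-breaking is applied greedily inside the DP; among
  exactly cost-tied global optima it deterministically returns one, but not
  necessarily the lexicographic minimum over the full solution space.
- The heuristic ignores prizes of intermediate path nodes when scoring an
  attachment (they are collected once attached, but do not lower the
  apparent path cost), which is the main source of its optimality gap.
- The PBM comparator is a pragmatic internal stand-in for full motif-database
  matching; it supports the significance interface but is not a TomTom
  replacement.
- No identifier normalization: interactome node symbols must already match
  the feature identifiers.
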