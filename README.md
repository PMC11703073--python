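# exhaustnet

Network and microarray analysis for chronic T-cell stimulation studies:
a prize-collecting Steiner forest (PCSF) over differential
proteomic/phosphoproteomic features that nominates upstream drivers of
CD4+ T-cell exhaustion, and a CASCADE protein-binding-microarray (PBM)
Δz-score analysis of transcription-factor–cofactor recruitment. Both arms
come with a synthetic-data module that plants known structure, so the whole
pipeline runs and is scored offline, with no experimental downloads.

It is a library first (everything is importable from `exhaustnet`), with a
thin `exhaustnet` CLI for file-to-file runs and narrative scripts under
`examples/`.

## The models

**PCSF.** Given a directed interactome *G(V, E)*, node prizes *p(v)* and
edge costs *c(e)*, find a forest *F(V_F, E_F)* of vertex-disjoint
out-arborescences minimizing

```
f(F) = Σ_{v ∉ V_F} [β·p(v) − μ·degree(v)] + Σ_{e ∈ E_F} c(e) + ω·κ
```

where κ is the number of trees and every node lies within depth *D* of its
tree root. Prizes are `p_t(v) = |log2(m_t(v)/m_0(v))|` for features passing a
Benjamini–Hochberg FDR < 0.05 gate (Welch t-test on log2 replicate
abundances); edge weights are the reciprocal source outdegree,
`w(e) = 1/k_out(x)`, with `c(e) = 1 − w(e)`, so edges leaving promiscuous
hubs are expensive. An artificial dummy root attached to candidate roots at
cost ω realizes the ω·κ term; it is stripped from solutions. Defaults: β=1,
μ=0, ω=1, D=5. Two solvers: an exact layered dynamic program (globally
optimal, small graphs) and a greedy attachment + strong-pruning heuristic
(scales to thousands of nodes, never better than the exact optimum).

**CASCADE PBM.** Each TF-binding model is a consensus site plus all
single-nucleotide variants, embedded in 60-bp probes (GC cap 2 + target 34 +
primer 24). Per array, log fluorescence is z-transformed against background
probes; the base preference at position *i* is
`Δz[i,b] = z(probe with base b) − median z across the 4 base variants at i`.
Δz maps to a PWM by per-position softmax, with information content
`IC = 2 + Σ p·log2 p` bits. A motif is significant when the consensus z
exceeds 0.5, some 5-bp window has mean IC above 1 bit, and (optionally) the
best database match is significant. Motif strength is the mean Δz of the top
15% of a model's probes; family strength averages significant members;
reported interactions must recur in ≥2 replicate arrays; the readout is the
exhausted-minus-acute strength contrast per (cofactor, TF family).

## Worked example

`python examples/02_forest_inference.py` generates the reference network
scenario (300 nodes, a planted 12-node regulatory module with
|log2FC| ≈ N(2, 0.5) effects, 5 replicates/condition) and runs the full
prizes → costs → solve pipeline:

```
graph: 300 nodes, 939 edges; 12 prized
forest: 13 nodes, 8 edges, kappa=5, objective=10.214
planted-module recovery: precision=0.92 recall=1.00
hub N0061 neighbourhood (radius 1): 4 nodes, 3 edges
```

All 12 planted nodes are recovered (recall 1.00) with one spurious node
(precision 0.92); the forest splits into κ=5 trees because ω=1 makes opening
a tree cheaper than buying expensive hub edges between distant module parts.

`python examples/04_pbm_recruitment.py` runs the array arm with a planted
recruitment gain (+50% energy amplitude for family FAM00 in the exhausted
condition):

```
median Pearson r (planted energies vs recovered Δz): 0.963

cofactor  family  acute  exhausted  contrast  status
COF1     FAM00     2.74      4.14     +1.39  both
COF1     FAM01     2.87      2.96     +0.09  both
...
```

The boosted family stands out with a +1.39 Δz-unit contrast while unshifted
families sit near zero. The other examples show prize assignment from
replicate tables (`01`) and independent-vs-cumulative timecourse series
(`03`).

The same pipeline runs from the shell:

```bash
exhaustnet simulate --out-dir sim --seed 1
exhaustnet prizes --features sim/features.tsv --out prizes.tsv
exhaustnet solve --edges sim/edges.tsv --prizes prizes.tsv --out-prefix forest
exhaustnet pbm --probes sim/probes.tsv --models sim/models.tsv \
    --array sim/array.tsv --out-dir pbm_out
```

## Layout

- `src/exhaustnet/diffprize.py` — differential testing, BH adjustment, prizes
- `src/exhaustnet/interactome.py` — network assembly, outdegree costs, dummy root
- `src/exhaustnet/pcsf.py` — objective, exact + heuristic solvers, validation,
  hub-subnetwork extraction, timecourse series
- `src/exhaustnet/pbm.py` — z-transform, Δz motifs, PWM/IC, significance,
  strength, family/replicate/contrast logic
- `src/exhaustnet/synth.py` — planted-structure generators for both arms
- `src/exhaustnet/io.py`, `src/exhaustnet/cli.py` — formats, manifests, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
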