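"""Infer a prize-collecting Steiner forest on a planted synthetic network.

Generates the reference scenario (300 nodes, planted 12-node arborescence,
|log2FC| ~ N(2, 0.5) effects, 5 replicates), runs the full prizes -> costs ->
solve pipeline with the published parameter defaults (beta=1, mu=0, omega=1,
D=5), and scores recovery of the planted module. The planted root plays the
part of the main hub (as p300 does in the real network), so its
neighbourhood is extracted at the end.
"""

from exhaustnet import (
    NetworkScenario,
    PCSFConfig,
    attach_dummy,
    differential_pipeline,
    extract_subnetwork,
    gen_differential,
    gen_interactome,
    solve_heuristic,
    strip_dummy,
    validate_forest,
)

sc = NetworkScenario(seed=0)
g, planted = gen_interactome(sc)
measurements, _ = gen_differential(sc, planted)
_, prizes = differential_pipeline(measurements, "stim")
print(f"graph: {len(g.nodes)} nodes, {g.n_edges} edges; {len(prizes)} prized")

cfg = PCSFConfig(solver="heuristic")
ag = attach_dummy(g, policy="prized", omega=cfg.omega, prizes=prizes)
forest = strip_dummy(solve_heuristic(ag, prizes, cfg))
assert validate_forest(forest, ag, cfg) == []

truth = set(planted["nodes"])
recovered = set(forest.real_nodes)
tp = len(recovered & truth)
precision, recall = tp / len(recovered), tp / len(truth)
print(
    f"forest: {len(recovered)} nodes, {len(forest.real_edges)} edges, "
    f"kappa={forest.kappa}, objective={forest.objective:.3f}"
)
print(f"planted-module recovery: precision={precision:.2f} recall={recall:.2f}")

hub = planted["root"]
if hub in recovered:
    frag = extract_subnetwork(forest, hub, radius=1)
    print(f"hub {hub} neighbourhood (radius 1): "
          f"{len(frag.real_nodes)} nodes, {len(frag.real_edges)} edges")
print(
    "\nThe objective trades excluded prizes against edge costs (1 - 1/outdegree)"
    " and a per-tree penalty; high recall at high precision means the forest"
    " concentrates on the planted regulatory module."
)
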