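"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators mirror the two arms of the analysis:

* :func:`gen_interactome` / :func:`gen_differential` build a random directed
  network with a planted out-arborescence and replicate abundance tables in
  which the planted nodes carry a real log2 fold change (|log2FC| drawn
  around 2) against a background of null features, so prize assignment and
  forest recovery can be scored against known truth.
* :func:`gen_probe_array` builds a CASCADE-style probe design (consensus +
  all single-nucleotide variants per TF-binding model, plus genomic-like
  background 34-mers) and fluorescence measurements generated from planted
  per-position binding energies with log-scale Gaussian noise.

All generators are pure functions of their scenario (seed included): the same
scenario yields byte-identical outputs. One run-level seed fans out to named
child streams (graph, effects, noise, probes) so each component is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .diffprize import FeatureMeasurement, PrizeMap
from .interactome import Interaction, Interactome, assemble, compute_costs
from .pbm import BASES, ProbeDesign, TFBindingModel

__all__ = [
    "NetworkScenario",
    "ArrayScenario",
    "gen_interactome",
    "gen_differential",
    "gen_probe_array",
    "gen_small_pcsf_instance",
    "PRIMER",
]

# Fixed 24-bp primer tail shared by every probe (arbitrary but constant).
PRIMER = "GTCTTGATTCGCTTGACGCTGCTG"

_STREAMS = ("graph", "effects", "noise", "probes")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class NetworkScenario:
    """Random interactome + differential-table generator settings.

    Defaults define the reference benchmark: a 300-node directed graph with
    Poisson(3) out-degrees, a planted 12-node arborescence of depth <= 5
    whose nodes carry |log2FC| ~ N(2, 0.5) effects, and 5 replicates per
    condition with SD-0.3 log2-scale replicate noise.
    """

    n_nodes: int = 300
    mean_out_degree: float = 3.0
    planted_size: int = 12
    planted_depth: int = 5
    effect_logfc: tuple[float, float] = (2.0, 0.5)
    null_logfc_sd: float = 0.3
    n_replicates: int = 5
    baseline_log2: tuple[float, float] = (10.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_size > self.n_nodes:
            raise ValueError("planted_size cannot exceed n_nodes")
        if self.planted_depth < 1 or self.mean_out_degree <= 0:
            raise ValueError("planted_depth and mean_out_degree must be positive")


@dataclass(frozen=True)
class ArrayScenario:
    """CASCADE-style synthetic array settings.

    Defaults: 30 TF-binding models (consensus length 6-10, grouped into 6
    families), 200 background probes, unit energy scale with SD-0.2
    log-fluorescence noise and 3 replicates per condition. A family entry in
    ``condition_effects`` scales that family's planted energy amplitude by
    (1 + shift) in the exhausted condition, emulating a recruitment change.
    """

    n_models: int = 30
    motif_length: tuple[int, int] = (6, 10)
    n_families: int = 6
    n_background: int = 200
    energy_scale: float = 1.0
    noise_sd: float = 0.2
    n_replicates: int = 3
    condition_effects: Mapping[str, float] = field(default_factory=dict)
    cofactor: str = "COF1"
    bg_log_mean: float = 7.0
    consensus_affinity: tuple[float, float] = (1.0, 0.2)
    variant_penalty: tuple[float, float] = (1.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 50:
            raise ValueError("need at least 50 background probes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.motif_length
        if lo < 4 or hi > 32 or lo > hi:
            raise ValueError("motif_length must satisfy 4 <= lo <= hi <= 32")
        object.__setattr__(self, "condition_effects", dict(self.condition_effects))


def gen_interactome(sc: NetworkScenario) -> tuple[Interactome, dict]:
    """Random directed graph with a planted out-arborescence.

    Out-degrees are Poisson(mean_out_degree), resampled to keep every node's
    out-degree at least 1; the planted module is a connected arborescence of
    ``planted_size`` nodes within depth ``planted_depth`` of its root, and
    its edges are guaranteed present in the graph.
    """
    rng = _child_rngs(sc.seed)["graph"]
    nodes = [f"N{i:04d}" for i in range(sc.n_nodes)]

    planted_nodes = [nodes[i] for i in rng.choice(sc.n_nodes, sc.planted_size, replace=False)]
    root = planted_nodes[0]
    depth = {root: 0}
    planted_edges: list[tuple[str, str]] = []
    for v in planted_nodes[1:]:
        eligible = [u for u in depth if depth[u] < sc.planted_depth]
        parent = eligible[rng.integers(len(eligible))]
        planted_edges.append((parent, v))
        depth[v] = depth[parent] + 1

    interactions = [Interaction(u, v, kind="other", provenance="planted")
                    for u, v in planted_edges]
    for i, u in enumerate(nodes):
        k = 0
        while k == 0:
            k = int(rng.poisson(sc.mean_out_degree))
        k = min(k, sc.n_nodes - 1)
        choices = rng.choice(sc.n_nodes - 1, size=k, replace=False)
        for c in choices:
            j = c if c < i else c + 1  # skip self
            interactions.append(Interaction(u, nodes[j]))

    g = compute_costs(assemble(interactions))
    planted = {"nodes": list(planted_nodes), "edges": list(planted_edges), "root": root}
    return g, planted


def gen_differential(
    sc: NetworkScenario, planted: Mapping
) -> tuple[list[FeatureMeasurement], dict[str, float]]:
    """Replicate abundance tables for rest and stimulated conditions.

    Planted nodes receive a true log2 fold change of random sign with
    magnitude ~ N(effect mean, effect sd); null nodes have true effect 0.
    Replicate log2 abundances are baseline + effect (stimulated only) +
    N(0, null_logfc_sd). Returns the measurements and the true effect map.
    """
    if sc.n_replicates < 3:
        raise ValueError("n_replicates must be >= 3")
    rngs = _child_rngs(sc.seed)
    rng_eff, rng_noise = rngs["effects"], rngs["noise"]
    nodes = [f"N{i:04d}" for i in range(sc.n_nodes)]
    planted_set = set(planted["nodes"])

    mean, sd = sc.effect_logfc
    truth: dict[str, float] = {}
    for v in nodes:
        if v in planted_set:
            sign = 1.0 if rng_eff.random() < 0.5 else -1.0
            truth[v] = sign * rng_eff.normal(mean, sd)
        else:
            truth[v] = 0.0

    b_mean, b_sd = sc.baseline_log2
    measurements: list[FeatureMeasurement] = []
    for v in nodes:
        base = rng_eff.normal(b_mean, b_sd)
        rest = base + rng_noise.normal(0.0, sc.null_logfc_sd, sc.n_replicates)
        stim = base + truth[v] + rng_noise.normal(0.0, sc.null_logfc_sd, sc.n_replicates)
        measurements.append(
            FeatureMeasurement(v, "rest", tuple(np.exp2(rest)), layer="protein")
        )
        measurements.append(
            FeatureMeasurement(v, "stim", tuple(np.exp2(stim)), layer="protein")
        )
    return measurements, truth


def _nonrepeating_pad(rng: np.random.Generator, length: int) -> str:
    """Random pad in which sequential positions never repeat a nucleotide."""
    out: list[str] = []
    for _ in range(length):
        options = [b for b in BASES if not out or b != out[-1]]
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def _probe_sequence(rng: np.random.Generator, site: str) -> tuple[str, str, str]:
    """60-bp probe embedding `site`: GC cap + (pad5 2bp + site + pad3) + primer."""
    pad5 = _nonrepeating_pad(rng, 2)
    pad3 = _nonrepeating_pad(rng, 32 - len(site))
    target = pad5 + site + pad3
    return "GC" + target + PRIMER, pad5, pad3


def gen_probe_array(
    sc: ArrayScenario,
) -> tuple[list[ProbeDesign], list[TFBindingModel], pd.DataFrame, dict[str, dict]]:
    """CASCADE-style probe design, models, measurements and planted energies.

    Per model: a consensus probe plus all 3L single-nucleotide variants,
    each embedded in the 60-bp template (GC cap 2 + target 34 + primer 24)
    with non-repeating-adjacent-base pads. Log fluorescence of a model probe
    is bg baseline + amp * (affinity + sum_i E[i, base_i]) + N(0, noise_sd),
    where E[i, consensus base] = 0 and variant energies are negative
    penalties; amp = energy_scale, scaled by (1 + condition_effects[family])
    in the exhausted condition. Background probes carry baseline + noise only.

    Returns (design, models, measurements, planted) where planted maps
    model_id -> {"energy": E, "delta": E median-centered per position,
    "affinity": a, "family": f}.
    """
    lo, hi = sc.motif_length
    if hi > 32 - 2:
        raise ValueError("motif longer than the 34-bp target region allows")
    rngs = _child_rngs(sc.seed)
    rng_p, rng_eff, rng_noise = rngs["probes"], rngs["effects"], rngs["noise"]

    families = [f"FAM{j:02d}" for j in range(sc.n_families)]
    models: list[TFBindingModel] = []
    design: list[ProbeDesign] = []
    planted: dict[str, dict] = {}
    probe_energy: dict[str, tuple[str, float]] = {}  # probe_id -> (model_id, sum E)

    for m in range(sc.n_models):
        model_id = f"M{m:03d}"
        L = int(rng_p.integers(lo, hi + 1))
        consensus = "".join(BASES[i] for i in rng_p.integers(0, 4, L))
        family = families[m % sc.n_families]
        models.append(TFBindingModel(model_id, consensus, family))

        pen_mean, pen_sd = sc.variant_penalty
        energy = np.zeros((L, 4))
        for i, cb in enumerate(consensus):
            for b in BASES:
                if b != cb:
                    energy[i, BASES.index(b)] = -abs(rng_eff.normal(pen_mean, pen_sd))
        aff = rng_eff.normal(*sc.consensus_affinity)
        planted[model_id] = {
            "energy": energy,
            "delta": energy - np.median(energy, axis=1, keepdims=True),
            "affinity": float(aff),
            "family": family,
        }

        seq, _, _ = _probe_sequence(rng_p, consensus)
        pid = f"{model_id}_cons"
        design.append(ProbeDesign(pid, seq, "consensus", model_id))
        probe_energy[pid] = (model_id, 0.0)
        for i, cb in enumerate(consensus):
            for b in BASES:
                if b == cb:
                    continue
                variant = consensus[:i] + b + consensus[i + 1 :]
                seq, _, _ = _probe_sequence(rng_p, variant)
                pid = f"{model_id}_sv{i:02d}{b}"
                design.append(ProbeDesign(pid, seq, "sv", model_id, i, b))
                probe_energy[pid] = (model_id, float(energy[i, BASES.index(b)]))

    for i in range(sc.n_background):
        site = "".join(BASES[j] for j in rng_p.integers(0, 4, 32))
        seq, _, _ = _probe_sequence(rng_p, site)
        design.append(ProbeDesign(f"BG{i:04d}", seq, "background"))

    rows = []
    for condition in ("acute", "exhausted"):
        for rep in range(1, sc.n_replicates + 1):
            noise = rng_noise.normal(0.0, sc.noise_sd, len(design))
            for probe, eps in zip(design, noise):
                logf = sc.bg_log_mean + eps
                if probe.probe_id in probe_energy:
                    model_id, e_sum = probe_energy[probe.probe_id]
                    amp = sc.energy_scale
                    fam = planted[model_id]["family"]
                    if condition == "exhausted" and fam in sc.condition_effects:
                        amp *= 1.0 + sc.condition_effects[fam]
                    logf += amp * (planted[model_id]["affinity"] + e_sum)
                rows.append(
                    {
                        "probe_id": probe.probe_id,
                        "replicate": f"r{rep}",
                        "condition": condition,
                        "cofactor": sc.cofactor,
                        "fluorescence": float(np.exp(logf)),
                    }
                )
    measurements = pd.DataFrame(rows)
    return design, models, measurements, planted


def gen_small_pcsf_instance(
    seed: int,
    n_nodes: tuple[int, int] = (4, 8),
    mean_out_degree: float = 1.8,
    prize_prob: float = 0.5,
) -> tuple[Interactome, PrizeMap]:
    """Tiny random PCSF instance for oracle comparison.

    Sparse random directed graph (4-8 nodes by default) with a random subset
    of nodes prized |N(1.5, 1)|. Small enough that the optimum can be found
    by exhaustive enumeration over all valid sub-forests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(rng.integers(n_nodes[0], n_nodes[1] + 1))
    nodes = [f"n{i}" for i in range(n)]
    interactions = []
    for i, u in enumerate(nodes):
        k = min(int(rng.poisson(mean_out_degree)), n - 1)
        for c in rng.choice(n - 1, size=k, replace=False):
            j = c if c < i else c + 1
            interactions.append(Interaction(u, nodes[j]))
    g = compute_costs(assemble(interactions))
    # assemble() only records nodes that touch an edge; keep isolated ones too
    for v in nodes:
        g.graph.add_node(v)
    prizes = {
        v: float(abs(rng.normal(1.5, 1.0)))
        for v in nodes
        if rng.random() < prize_prob
    }
    prizes = {v: p for v, p in prizes.items() if p > 0}
    return g, PrizeMap(prizes=prizes)
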