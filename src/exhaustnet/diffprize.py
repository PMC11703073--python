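"""Differential-abundance testing and prize assignment.

Turns replicate abundance measurements (proteins or phosphosites) into the
node prizes used by the prize-collecting Steiner forest: a feature that is
significantly differential at a timepoint (Benjamini-Hochberg FDR below the
threshold, default 0.05) contributes a prize equal to the absolute log2 fold
change of its stimulated-vs-resting means,

    p_t(v) = |log2(m_t(v) / m_0(v))|.

Features that fail the FDR gate are simply absent from the prize map (implicit
prize zero). Phosphosite features use ``GENE:site`` identifiers; when a gene
carries both a protein prize and phosphosite prizes the evidence is merged at
the gene level (maximum by default, to keep the strongest signal without
double counting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureMeasurement",
    "DifferentialRecord",
    "PrizeMap",
    "compute_log2fc",
    "bh_adjust",
    "assign_prizes",
    "differential_pipeline",
    "gene_of",
]

LAYERS = ("protein", "phosphosite")


@dataclass(frozen=True)
class FeatureMeasurement:
    """Replicate abundances for one feature in one condition.

    ``replicate_values`` are linear (not log) abundances and must be positive;
    ``layer`` distinguishes protein from phosphosite features so that
    multiple-testing correction can be applied per layer.
    """

    feature_id: str
    condition: str
    replicate_values: tuple[float, ...]
    layer: str = "protein"

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        vals = tuple(float(v) for v in self.replicate_values)
        if len(vals) < 1:
            raise ValueError(f"{self.feature_id}: at least one replicate required")
        if any((not math.isfinite(v)) or v <= 0 for v in vals):
            raise ValueError(
                f"{self.feature_id}: abundances must be finite and > 0, got {vals}"
            )
        object.__setattr__(self, "replicate_values", vals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))


@dataclass(frozen=True)
class DifferentialRecord:
    """One feature's differential result at one timepoint."""

    feature_id: str
    timepoint: str
    log2_fc: float
    p_raw: float | None = None
    fdr: float | None = None
    layer: str = "protein"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_fc):
            raise ValueError(f"{self.feature_id}: log2_fc must be finite")
        for name in ("p_raw", "fdr"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.feature_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PrizeMap:
    """node_id -> non-negative prize at one timepoint; missing nodes have prize 0."""

    prizes: Mapping[str, float]
    timepoint: str = ""

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.prizes.items() if v < 0 or not math.isfinite(v)}
        if bad:
            raise ValueError(f"prizes must be finite and >= 0, offending: {bad}")
        object.__setattr__(self, "prizes", dict(self.prizes))

    def get(self, node: str) -> float:
        return self.prizes.get(node, 0.0)

    def __len__(self) -> int:
        return len(self.prizes)


def gene_of(feature_id: str) -> str:
    """Gene symbol for a feature: phosphosites are ``GENE:site``."""
    return feature_id.split(":", 1)[0]


def compute_log2fc(
    stim: FeatureMeasurement, rest: FeatureMeasurement
) -> DifferentialRecord:
    """Differential record for one feature: stimulated vs resting.

    log2 fold change is computed on the replicate means; the p-value comes
    from a Welch t-test on the log2-transformed replicate abundances (the
    replicate noise model is additive on the log2 scale). The FDR field is
    left unset until :func:`bh_adjust`.
    """
    if stim.feature_id != rest.feature_id:
        raise ValueError(
            f"feature id mismatch: {stim.feature_id!r} vs {rest.feature_id!r}"
        )
    log2_fc = float(np.log2(stim.mean / rest.mean))
    a = np.log2(stim.replicate_values)
    b = np.log2(rest.replicate_values)
    if len(a) >= 2 and len(b) >= 2 and (np.std(a) > 0 or np.std(b) > 0):
        p_raw = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        # Degenerate (single replicate or zero variance): no test is possible.
        p_raw = 1.0 if np.isclose(log2_fc, 0.0) else float("nan")
        if math.isnan(p_raw):
            raise ValueError(
                f"{stim.feature_id}: cannot test with <2 replicates or zero variance"
            )
    return DifferentialRecord(
        feature_id=stim.feature_id,
        timepoint=stim.condition,
        log2_fc=log2_fc,
        p_raw=min(1.0, p_raw),
        layer=stim.layer,
    )


def bh_adjust(
    records: Sequence[DifferentialRecord], per_layer: bool = True
) -> list[DifferentialRecord]:
    """Benjamini-Hochberg step-up adjustment of raw p-values.

    Proteins and phosphosites are adjusted separately by default, matching
    the convention of reporting differential counts per layer.
    """
    records = list(records)
    if not records:
        return []
    if any(r.p_raw is None for r in records):
        raise ValueError("all records must carry p_raw before adjustment")
    out: list[DifferentialRecord | None] = [None] * len(records)
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.layer if per_layer else "all", []).append(i)
    for idx in groups.values():
        pvals = np.array([records[i].p_raw for i in idx])
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for i, q in zip(idx, fdr):
            out[i] = replace(records[i], fdr=float(q))
    return [r for r in out if r is not None]


def assign_prizes(
    records: Sequence[DifferentialRecord],
    fdr_threshold: float = 0.05,
    merge: str = "max",
) -> PrizeMap:
    """Prize map from FDR-gated differential records.

    Nodes with ``fdr < fdr_threshold`` receive prize ``|log2_fc|``; everything
    else is absent. Protein and phosphosite records of one gene are merged
    (``merge``: "max" keeps the strongest evidence, "sum" accumulates it).
    """
    if fdr_threshold < 0:
        raise ValueError(f"fdr_threshold must be >= 0, got {fdr_threshold}")
    if merge not in ("max", "sum"):
        raise ValueError(f"merge must be 'max' or 'sum', got {merge!r}")
    records = list(records)
    timepoints = {r.timepoint for r in records}
    if len(timepoints) > 1:
        raise ValueError(f"records span multiple timepoints: {sorted(timepoints)}")
    prizes: dict[str, float] = {}
    for r in records:
        if r.fdr is None:
            raise ValueError(f"{r.feature_id}: fdr unset; run bh_adjust first")
        if r.fdr >= fdr_threshold:
            continue
        gene = gene_of(r.feature_id)
        prize = abs(r.log2_fc)
        if merge == "max":
            prizes[gene] = max(prizes.get(gene, 0.0), prize)
        else:
            prizes[gene] = prizes.get(gene, 0.0) + prize
    timepoint = next(iter(timepoints)) if timepoints else ""
    return PrizeMap(prizes=prizes, timepoint=timepoint)


def differential_pipeline(
    measurements: Iterable[FeatureMeasurement],
    stim_condition: str,
    rest_condition: str = "rest",
    fdr_threshold: float = 0.05,
    merge: str = "max",
) -> tuple[list[DifferentialRecord], PrizeMap]:
    """Full test -> adjust -> gate pipeline for one timepoint contrast."""
    by_feature: dict[tuple[str, str], dict[str, FeatureMeasurement]] = {}
    for m in measurements:
        by_feature.setdefault((m.feature_id, m.layer), {})[m.condition] = m
    records = []
    for (fid, _layer), conds in sorted(by_feature.items()):
        if stim_condition in conds and rest_condition in conds:
            records.append(compute_log2fc(conds[stim_condition], conds[rest_condition]))
    adjusted = bh_adjust(records)
    return adjusted, assign_prizes(adjusted, fdr_threshold=fdr_threshold, merge=merge)
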