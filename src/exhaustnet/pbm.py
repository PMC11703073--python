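"""CASCADE protein-binding-microarray analysis: Δz motifs and recruitment.

A CASCADE array probes cofactor (COF) recruitment to transcription-factor
binding sites: each TF-binding model contributes a consensus probe plus every
single-nucleotide variant (SV) of the consensus, and genomic-background
probes anchor the fluorescence scale. The analysis chain is:

1. z-transform: per array, log fluorescence is standardized against the
   background probes (z = (log F - bg mean) / bg SD).
2. Δz motif: at each consensus position, the base preference is the z-score
   of the base's probe minus the median z across the four base variants at
   that position. Δz is analogous to a change in binding energy.
3. PWM/IC: the Δz matrix maps to base probabilities by a per-position
   softmax; information content is 2 + Σ p log2 p bits per column.
4. Significance: a motif counts only if (1) the consensus probe's z exceeds
   0.5, (2) some 5-bp window has mean IC above 1 bit, and (3) when a motif
   database is supplied, the best-match adjusted p-value passes.
5. Motif strength: mean Δz of the top 15% of a model's probes; TF-family
   strength averages the significant member motifs; reported interactions
   must recur in at least 2 replicate arrays; the acute-vs-exhausted contrast
   is the per-(cofactor, family) strength difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BASES",
    "TFBindingModel",
    "ProbeDesign",
    "ZScores",
    "DeltaZMotif",
    "PWMatrix",
    "RecruitmentProfile",
    "z_transform",
    "build_delta_z_motif",
    "pwm_from_delta_z",
    "significance_filter",
    "motif_strength",
    "per_probe_delta_z",
    "family_aggregate",
    "replicate_consensus",
    "condition_contrast",
    "match_best_pvalue",
    "analyze_replicate",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

PROBE_CLASSES = ("consensus", "sv", "background")


@dataclass(frozen=True)
class TFBindingModel:
    """A consensus binding site and the TF family it clusters into."""

    model_id: str
    consensus: str
    family: str = ""

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if len(cons) < 4 or any(b not in BASES for b in cons):
            raise ValueError(
                f"{self.model_id}: consensus must be >=4 bp of ACGT, got {cons!r}"
            )
        object.__setattr__(self, "consensus", cons)

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class ProbeDesign:
    """One 60-bp probe: GC cap (2) + target region (34) + primer (24)."""

    probe_id: str
    sequence: str
    probe_class: str
    model_id: str | None = None
    sv_position: int | None = None  # 0-based index into the consensus
    sv_base: str | None = None

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")
        if self.probe_class == "background" and self.model_id is not None:
            raise ValueError(f"{self.probe_id}: background probes carry no model")
        if self.probe_class == "sv" and (
            self.sv_position is None or self.sv_base is None
        ):
            raise ValueError(f"{self.probe_id}: sv probes need sv_position and sv_base")


@dataclass(frozen=True)
class ZScores:
    """Per-probe z-scores on the background log-fluorescence scale."""

    z: Mapping[str, float]
    bg_mean: float
    bg_sd: float

    def __post_init__(self) -> None:
        if self.bg_sd <= 0:
            raise ValueError("bg_sd must be > 0")
        object.__setattr__(self, "z", dict(self.z))


@dataclass(frozen=True)
class DeltaZMotif:
    """L x 4 matrix of Δz base preferences for one TF-binding model."""

    model_id: str
    delta_z: np.ndarray  # shape (L, 4), columns ordered ACGT
    consensus_z: float
    consensus: str
    significant: bool | None = None
    criteria: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dz = np.asarray(self.delta_z, dtype=float)
        if dz.ndim != 2 or dz.shape[1] != 4:
            raise ValueError(f"delta_z must be L x 4, got {dz.shape}")
        object.__setattr__(self, "delta_z", dz)
        object.__setattr__(self, "criteria", dict(self.criteria))

    @property
    def length(self) -> int:
        return self.delta_z.shape[0]


@dataclass(frozen=True)
class PWMatrix:
    """Position weight matrix (per-position base probabilities) with IC."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    ic: np.ndarray     # (L,), bits in [0, 2]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probs rows must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "ic", np.asarray(self.ic, dtype=float))


@dataclass(frozen=True)
class RecruitmentProfile:
    """(cofactor, family, condition) -> motif strength, with support counts."""

    strengths: Mapping[tuple[str, str, str], float]
    support: Mapping[tuple[str, str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strengths", dict(self.strengths))
        object.__setattr__(self, "support", dict(self.support))

    def get(self, cofactor: str, family: str, condition: str) -> float | None:
        return self.strengths.get((cofactor, family, condition))

    def __len__(self) -> int:
        return len(self.strengths)


def _design_index(design: Iterable[ProbeDesign]) -> dict[str, ProbeDesign]:
    return {p.probe_id: p for p in design}


def z_transform(
    measurements: pd.DataFrame,
    design: Iterable[ProbeDesign],
    center: bool = True,
) -> ZScores:
    """Standardize one array's log-fluorescence against its background probes.

    `measurements` holds one replicate array: columns ``probe_id`` and
    ``fluorescence`` (positive, linear units). Log fluorescence is
    median-centered per array (inert for z-scores, kept so exported logs are
    comparable across replicates) and then z-transformed with the mean and SD
    of the background probes' log fluorescence.
    """
    probes = _design_index(design)
    df = measurements[["probe_id", "fluorescence"]].copy()
    if (df["fluorescence"] <= 0).any():
        raise ValueError("fluorescence values must be > 0")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe measurements: {dupes[:5]}")
    logf = np.log(df["fluorescence"].to_numpy(dtype=float))
    if center:
        logf = logf - np.median(logf)
    is_bg = np.array(
        [probes[p].probe_class == "background" for p in df["probe_id"]], dtype=bool
    )
    if is_bg.sum() < 2:
        raise ValueError("need at least 2 background probes to anchor the z-scale")
    bg_mean = float(np.mean(logf[is_bg]))
    bg_sd = float(np.std(logf[is_bg], ddof=1))
    if bg_sd == 0:
        raise ValueError("background probes have zero variance; cannot z-transform")
    z = (logf - bg_mean) / bg_sd
    return ZScores(z=dict(zip(df["probe_id"], z)), bg_mean=bg_mean, bg_sd=bg_sd)


def _model_probe_table(
    model: TFBindingModel, design: Iterable[ProbeDesign]
) -> tuple[ProbeDesign, dict[tuple[int, str], ProbeDesign]]:
    consensus_probe = None
    sv: dict[tuple[int, str], ProbeDesign] = {}
    for p in design:
        if p.model_id != model.model_id:
            continue
        if p.probe_class == "consensus":
            consensus_probe = p
        elif p.probe_class == "sv":
            sv[(p.sv_position, p.sv_base.upper())] = p
    if consensus_probe is None:
        raise ValueError(f"{model.model_id}: consensus probe missing from design")
    return consensus_probe, sv


def _z_matrix(
    model: TFBindingModel,
    zs: ZScores,
    design: Iterable[ProbeDesign],
) -> tuple[np.ndarray, float]:
    """(L, 4) raw z matrix (consensus base cells = consensus probe z)."""
    consensus_probe, sv = _model_probe_table(model, design)
    if consensus_probe.probe_id not in zs.z:
        raise ValueError(f"{model.model_id}: consensus probe not z-scored")
    cz = zs.z[consensus_probe.probe_id]
    L = model.length
    zmat = np.empty((L, 4))
    for i, cons_base in enumerate(model.consensus):
        for b in BASES:
            if b == cons_base:
                zmat[i, _BASE_IDX[b]] = cz
                continue
            probe = sv.get((i, b))
            if probe is None or probe.probe_id not in zs.z:
                raise ValueError(
                    f"{model.model_id}: missing z-scored SV probe at position {i}"
                    f" base {b}"
                )
            zmat[i, _BASE_IDX[b]] = zs.z[probe.probe_id]
    return zmat, cz


def build_delta_z_motif(
    model: TFBindingModel,
    zs: ZScores,
    design: Iterable[ProbeDesign],
) -> DeltaZMotif:
    """Δz motif: per position, z of each base minus the median z across the
    four base variants (consensus + 3 SV probes) at that position."""
    zmat, cz = _z_matrix(model, zs, design)
    medians = np.median(zmat, axis=1, keepdims=True)
    return DeltaZMotif(
        model_id=model.model_id,
        delta_z=zmat - medians,
        consensus_z=float(cz),
        consensus=model.consensus,
    )


def pwm_from_delta_z(motif: DeltaZMotif, lam: float = 1.0) -> PWMatrix:
    """Softmax transform of Δz to base probabilities (Boltzmann weights with
    inverse temperature lam), plus per-column information content in bits."""
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    dz = motif.delta_z
    if not np.all(np.isfinite(dz)):
        raise ValueError("delta_z must be finite")
    x = lam * dz
    x = x - x.max(axis=1, keepdims=True)
    w = np.exp(x)
    probs = w / w.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return PWMatrix(probs=probs, ic=np.clip(ic, 0.0, 2.0))


def significance_filter(
    motif: DeltaZMotif,
    pwm: PWMatrix,
    match_pvalue: float | None = None,
    consensus_z_min: float = 0.5,
    ic_window: int = 5,
    ic_min: float = 1.0,
    match_alpha: float = 0.05,
    match_direction: str = "lt",
) -> tuple[bool, dict[str, object]]:
    """Three-criterion significance call for a Δz motif.

    (1) consensus probe z strictly above `consensus_z_min`; (2) the mean IC of
    at least one contiguous `ic_window`-column window strictly above `ic_min`
    bits; (3) if a database match p-value is supplied, it must be below
    `match_alpha` (`match_direction="gt"` flips to the printed-backwards
    direction for auditing). Motifs shorter than the window use their full
    length, flagged in the criteria record.
    """
    crit: dict[str, object] = {}
    crit["consensus_z"] = motif.consensus_z
    crit["pass_consensus_z"] = bool(motif.consensus_z > consensus_z_min)

    L = len(pwm.ic)
    win = min(ic_window, L)
    crit["window_truncated"] = bool(win < ic_window)
    window_means = [float(np.mean(pwm.ic[i : i + win])) for i in range(L - win + 1)]
    crit["best_window_ic"] = max(window_means)
    crit["pass_ic_window"] = bool(crit["best_window_ic"] > ic_min)

    if match_pvalue is None:
        crit["pass_match"] = True
        crit["match_pvalue"] = None
    else:
        crit["match_pvalue"] = float(match_pvalue)
        if match_direction == "lt":
            crit["pass_match"] = bool(match_pvalue < match_alpha)
        elif match_direction == "gt":
            crit["pass_match"] = bool(match_pvalue > match_alpha)
        else:
            raise ValueError(f"match_direction must be 'lt' or 'gt'")
    significant = bool(
        crit["pass_consensus_z"] and crit["pass_ic_window"] and crit["pass_match"]
    )
    return significant, crit


def per_probe_delta_z(
    model: TFBindingModel,
    zs: ZScores,
    design: Iterable[ProbeDesign],
) -> dict[str, float]:
    """Per-probe Δz used for strength ranking.

    An SV probe's Δz is its z minus the median z of the four base variants at
    its varied position; the consensus probe takes its Δz at its most
    preferred position (the position where the consensus base stands out
    most). This gives every probe of the model one scalar on the Δz scale.
    """
    zmat, _ = _z_matrix(model, zs, design)
    medians = np.median(zmat, axis=1)
    consensus_probe, sv = _model_probe_table(model, design)
    out: dict[str, float] = {}
    cons_dz = [
        zmat[i, _BASE_IDX[b]] - medians[i] for i, b in enumerate(model.consensus)
    ]
    out[consensus_probe.probe_id] = float(max(cons_dz))
    for (pos, base), probe in sv.items():
        out[probe.probe_id] = float(zmat[pos, _BASE_IDX[base]] - medians[pos])
    return out


def motif_strength(
    model: TFBindingModel,
    zs: ZScores,
    design: Iterable[ProbeDesign],
    top_frac: float = 0.15,
    rank_by: str = "delta_z",
) -> float:
    """Mean Δz of the top `top_frac` of the model's probes (default top 15%).

    Probes are ranked by per-probe Δz (or raw z with rank_by="z"); the top
    ceil(top_frac * n) values are averaged on the Δz scale.
    """
    if not (0 < top_frac <= 1):
        raise ValueError(f"top_frac must be in (0, 1], got {top_frac}")
    dz = per_probe_delta_z(model, zs, design)
    if not dz:
        raise ValueError(f"{model.model_id}: no probes to rank")
    if rank_by == "delta_z":
        keys = sorted(dz, key=lambda p: (-dz[p], p))
    elif rank_by == "z":
        keys = sorted(dz, key=lambda p: (-zs.z[p], p))
    else:
        raise ValueError(f"rank_by must be 'delta_z' or 'z', got {rank_by!r}")
    k = math.ceil(top_frac * len(keys))
    return float(np.mean([dz[p] for p in keys[:k]]))


def family_aggregate(
    motif_results: pd.DataFrame,
) -> RecruitmentProfile:
    """Aggregate one replicate's motifs into a family-level profile.

    `motif_results` columns: cofactor, condition, model_id, family,
    significant (bool), strength. The family strength is the mean strength of
    the family's significant motifs; families with none are absent.
    """
    required = {"cofactor", "condition", "model_id", "family", "significant", "strength"}
    missing = required - set(motif_results.columns)
    if missing:
        raise ValueError(f"motif_results missing columns: {sorted(missing)}")
    sig = motif_results[motif_results["significant"].astype(bool)]
    strengths: dict[tuple[str, str, str], float] = {}
    support: dict[tuple[str, str, str], int] = {}
    for (cof, fam, cond), grp in sig.groupby(["cofactor", "family", "condition"]):
        key = (str(cof), str(fam), str(cond))
        strengths[key] = float(grp["strength"].mean())
        support[key] = int(len(grp))
    return RecruitmentProfile(strengths=strengths, support=support)


def replicate_consensus(
    profiles: Sequence[RecruitmentProfile],
    min_reps: int = 2,
) -> RecruitmentProfile:
    """Keep interactions seen in at least `min_reps` replicate profiles;
    retained strength is the mean across the replicates where seen."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one replicate profile")
    if min_reps > len(profiles):
        raise ValueError(
            f"min_reps={min_reps} exceeds replicate count {len(profiles)}"
        )
    seen: dict[tuple[str, str, str], list[float]] = {}
    for prof in profiles:
        for key, val in prof.strengths.items():
            seen.setdefault(key, []).append(val)
    strengths = {
        key: float(np.mean(vals)) for key, vals in seen.items() if len(vals) >= min_reps
    }
    support = {key: len(seen[key]) for key in strengths}
    return RecruitmentProfile(strengths=strengths, support=support)


def condition_contrast(
    acute: RecruitmentProfile,
    exhausted: RecruitmentProfile,
) -> pd.DataFrame:
    """Exhausted-minus-acute strength per (cofactor, family).

    Entries present in only one condition are contrasted against 0 and
    flagged "gain" (exhausted only) or "loss" (acute only).
    """
    def _by_pair(prof: RecruitmentProfile) -> dict[tuple[str, str], float]:
        return {(c, f): v for (c, f, _cond), v in prof.strengths.items()}

    a = _by_pair(acute)
    e = _by_pair(exhausted)
    rows = []
    for cof, fam in sorted(set(a) | set(e)):
        in_a, in_e = (cof, fam) in a, (cof, fam) in e
        status = "both" if (in_a and in_e) else ("gain" if in_e else "loss")
        rows.append(
            {
                "cofactor": cof,
                "family": fam,
                "acute": a.get((cof, fam), 0.0),
                "exhausted": e.get((cof, fam), 0.0),
                "contrast": e.get((cof, fam), 0.0) - a.get((cof, fam), 0.0),
                "status": status,
            }
        )
    return pd.DataFrame(
        rows, columns=["cofactor", "family", "acute", "exhausted", "contrast", "status"]
    )


def match_best_pvalue(
    pwm: PWMatrix,
    references: Mapping[str, PWMatrix],
    n_shuffles: int = 999,
    seed: int = 0,
    min_overlap: int = 4,
) -> float:
    """Permutation p-value for the motif's best database match.

    Similarity to a reference is the best Pearson correlation of flattened
    column-probability vectors over all ungapped offsets with at least
    `min_overlap` overlapping columns. The null shuffles the query's columns
    (positions) `n_shuffles` times; per-reference p-values are BH-adjusted
    and the smallest adjusted p is returned.
    """
    if not references:
        raise ValueError("need at least one reference motif")
    rng = np.random.default_rng(seed)
    q = pwm.probs

    def best_corr(query: np.ndarray, ref: np.ndarray) -> float:
        lq, lr = query.shape[0], ref.shape[0]
        best = -1.0
        for off in range(-(lq - min_overlap), lr - min_overlap + 1):
            lo_q, lo_r = max(0, -off), max(0, off)
            n = min(lq - lo_q, lr - lo_r)
            if n < min_overlap:
                continue
            x = query[lo_q : lo_q + n].ravel()
            y = ref[lo_r : lo_r + n].ravel()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            best = max(best, float(np.corrcoef(x, y)[0, 1]))
        return best

    ref_ids = sorted(references)
    obs = np.array([best_corr(q, references[r].probs) for r in ref_ids])
    shuffled = [q[rng.permutation(q.shape[0])] for _ in range(n_shuffles)]
    pvals = []
    for j, r in enumerate(ref_ids):
        null = np.array([best_corr(s, references[r].probs) for s in shuffled])
        pvals.append((1 + np.sum(null >= obs[j])) / (1 + n_shuffles))
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return float(np.min(adjusted))


def analyze_replicate(
    measurements: pd.DataFrame,
    design: Sequence[ProbeDesign],
    models: Sequence[TFBindingModel],
    lam: float = 1.0,
    top_frac: float = 0.15,
    **filter_kwargs,
) -> pd.DataFrame:
    """Motif table for one replicate array (one cofactor, one condition).

    `measurements` columns: probe_id, fluorescence, cofactor, condition,
    replicate (constant within a replicate array). Returns one row per
    TF-binding model with Δz-derived significance and strength.
    """
    for col in ("cofactor", "condition", "replicate"):
        if measurements[col].nunique() != 1:
            raise ValueError(f"analyze_replicate expects a single {col}")
    cof = str(measurements["cofactor"].iloc[0])
    cond = str(measurements["condition"].iloc[0])
    rep = str(measurements["replicate"].iloc[0])
    zs = z_transform(measurements, design)
    rows = []
    for model in models:
        motif = build_delta_z_motif(model, zs, design)
        pwm = pwm_from_delta_z(motif, lam=lam)
        significant, crit = significance_filter(motif, pwm, **filter_kwargs)
        strength = motif_strength(model, zs, design, top_frac=top_frac)
        rows.append(
            {
                "cofactor": cof,
                "condition": cond,
                "replicate": rep,
                "model_id": model.model_id,
                "family": model.family,
                "significant": significant,
                "strength": strength,
                "consensus_z": motif.consensus_z,
                "best_window_ic": crit["best_window_ic"],
            }
        )
    return pd.DataFrame(rows)
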