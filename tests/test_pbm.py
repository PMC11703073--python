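"""Δz motifs, PWM/IC, significance criteria, strength and recruitment logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exhaustnet.pbm import (
    BASES,
    DeltaZMotif,
    ProbeDesign,
    RecruitmentProfile,
    TFBindingModel,
    ZScores,
    build_delta_z_motif,
    condition_contrast,
    family_aggregate,
    match_best_pvalue,
    motif_strength,
    per_probe_delta_z,
    pwm_from_delta_z,
    replicate_consensus,
    significance_filter,
    z_transform,
)
from exhaustnet.synth import ArrayScenario, gen_probe_array


def tiny_design(consensus="ACGT" + "AC", model_id="M0"):
    """Consensus + all SV probes + background probes with dummy sequences."""
    L = len(consensus)
    seq = "GC" + "A" * 34 + "G" * 24  # placeholder sequence, layout not under test
    probes = [ProbeDesign(f"{model_id}_cons", seq, "consensus", model_id)]
    for i, cb in enumerate(consensus):
        for b in BASES:
            if b != cb:
                probes.append(
                    ProbeDesign(f"{model_id}_sv{i:02d}{b}", seq, "sv", model_id, i, b)
                )
    for j in range(60):
        probes.append(ProbeDesign(f"BG{j:03d}", seq, "background"))
    return TFBindingModel(model_id, consensus), probes


class TestZTransform:
    def make_measurements(self, design, rng, model_boost=2.0):
        rows = []
        for p in design:
            logf = 5.0 + rng.normal(0, 0.3)
            if p.probe_class != "background":
                logf += model_boost
            rows.append({"probe_id": p.probe_id, "fluorescence": math.exp(logf)})
        return pd.DataFrame(rows)

    def test_background_probes_standardized(self):
        model, design = tiny_design()
        df = self.make_measurements(design, np.random.default_rng(0))
        zs = z_transform(df, design)
        bg = [zs.z[p.probe_id] for p in design if p.probe_class == "background"]
        assert np.mean(bg) == pytest.approx(0.0, abs=1e-12)
        assert np.std(bg, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_z_is_sd_units_above_background(self):
        model, design = tiny_design()
        df = self.make_measurements(design, np.random.default_rng(1))
        zs = z_transform(df, design)
        probe = design[0].probe_id
        logf = math.log(float(df.loc[df.probe_id == probe, "fluorescence"].iloc[0]))
        logf -= np.median(np.log(df["fluorescence"]))
        assert zs.z[probe] == pytest.approx((logf - zs.bg_mean) / zs.bg_sd)

    def test_invariant_to_global_scaling(self):
        model, design = tiny_design()
        df = self.make_measurements(design, np.random.default_rng(2))
        zs1 = z_transform(df, design)
        df2 = df.assign(fluorescence=df.fluorescence * 37.5)
        zs2 = z_transform(df2, design)
        for pid in zs1.z:
            assert zs1.z[pid] == pytest.approx(zs2.z[pid], abs=1e-9)

    def test_requires_background_probes(self):
        model, design = tiny_design()
        no_bg = [p for p in design if p.probe_class != "background"]
        df = self.make_measurements(no_bg, np.random.default_rng(3))
        with pytest.raises(ValueError, match="background"):
            z_transform(df, no_bg)

    def test_rejects_nonpositive_fluorescence(self):
        model, design = tiny_design()
        df = self.make_measurements(design, np.random.default_rng(4))
        df.loc[0, "fluorescence"] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            z_transform(df, design)


class TestDeltaZMotif:
    def zscores_for(self, design, values):
        return ZScores(z={p.probe_id: values.get(p.probe_id, 0.0) for p in design},
                       bg_mean=0.0, bg_sd=1.0)

    def test_median_subtraction_worked_example(self):
        # position 0 z-scores: A 1.2 (consensus), C 0.1, G 0.0, T -0.3
        # median = 0.05; Δz = (1.15, 0.05, -0.05, -0.35)
        model, design = tiny_design(consensus="ACGT")
        values = {"M0_cons": 1.2, "M0_sv00C": 0.1, "M0_sv00G": 0.0, "M0_sv00T": -0.3}
        motif = build_delta_z_motif(model, self.zscores_for(design, values), design)
        assert motif.delta_z[0] == pytest.approx([1.15, 0.05, -0.05, -0.35])

    def test_flat_position_gives_zero_deltas(self):
        model, design = tiny_design(consensus="ACGT")
        values = {p.probe_id: 0.7 for p in design if p.model_id == "M0"}
        motif = build_delta_z_motif(model, self.zscores_for(design, values), design)
        assert np.allclose(motif.delta_z, 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-4, 4, allow_nan=False), min_size=12, max_size=12))
    def test_median_of_four_deltas_is_zero(self, sv_values):
        model, design = tiny_design(consensus="ACGT")
        values = {"M0_cons": 0.9}
        it = iter(sv_values)
        for p in design:
            if p.probe_class == "sv":
                values[p.probe_id] = next(it)
        motif = build_delta_z_motif(model, self.zscores_for(design, values), design)
        medians = np.median(motif.delta_z, axis=1)
        assert np.all(np.abs(medians) <= 1e-12)

    def test_missing_sv_probe_names_position(self):
        model, design = tiny_design(consensus="ACGT")
        pruned = [p for p in design if p.probe_id != "M0_sv02A"]
        zs = self.zscores_for(pruned, {})
        with pytest.raises(ValueError, match="position 2"):
            build_delta_z_motif(model, zs, pruned)


class TestPWM:
    def test_zero_column_is_uniform_zero_ic(self):
        motif = DeltaZMotif("m", np.zeros((5, 4)), 1.0, "AAAAA")
        pwm = pwm_from_delta_z(motif)
        assert np.allclose(pwm.probs, 0.25)
        assert np.allclose(pwm.ic, 0.0, atol=1e-12)

    def test_small_lambda_approaches_uniform(self):
        dz = np.random.default_rng(0).normal(size=(6, 4))
        dz -= np.median(dz, axis=1, keepdims=True)
        motif = DeltaZMotif("m", dz, 1.0, "AAAAAA")
        pwm = pwm_from_delta_z(motif, lam=1e-6)
        assert np.allclose(pwm.probs, 0.25, atol=1e-5)
        assert np.all(pwm.ic < 1e-6)

    def test_dominant_base_saturates_to_two_bits(self):
        dz = np.zeros((5, 4))
        dz[:, 0] = 10.0
        motif = DeltaZMotif("m", dz, 1.0, "AAAAA")
        pwm = pwm_from_delta_z(motif, lam=10.0)
        assert np.all(pwm.probs[:, 0] > 0.999)
        assert np.all(pwm.ic > 1.99)

    def test_columns_sum_to_one_and_ic_bounded(self):
        rng = np.random.default_rng(1)
        dz = rng.normal(scale=2.0, size=(8, 4))
        motif = DeltaZMotif("m", dz, 1.0, "A" * 8)
        pwm = pwm_from_delta_z(motif)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((pwm.ic >= 0) & (pwm.ic <= 2))

    def test_ic_invariant_under_base_permutation(self):
        rng = np.random.default_rng(2)
        dz = rng.normal(size=(6, 4))
        motif = DeltaZMotif("m", dz, 1.0, "A" * 6)
        permuted = DeltaZMotif("m", dz[:, [2, 0, 3, 1]], 1.0, "A" * 6)
        assert np.allclose(
            pwm_from_delta_z(motif).ic, pwm_from_delta_z(permuted).ic
        )

    def test_nonpositive_lambda_rejected(self):
        motif = DeltaZMotif("m", np.zeros((5, 4)), 1.0, "AAAAA")
        with pytest.raises(ValueError):
            pwm_from_delta_z(motif, lam=0.0)


class TestSignificance:
    def one_hot_motif(self, L=5, consensus_z=2.0):
        dz = np.zeros((L, 4))
        dz[:, 0] = 8.0
        motif = DeltaZMotif("m", dz, consensus_z, "A" * L)
        return motif, pwm_from_delta_z(motif, lam=5.0)

    def test_consensus_z_gate_is_strict(self):
        for cz, expected in [(0.4, False), (0.5, False), (0.5001, True)]:
            motif, pwm = self.one_hot_motif(consensus_z=cz)
            significant, crit = significance_filter(motif, pwm)
            assert significant is expected
            assert crit["pass_consensus_z"] is expected

    def test_one_hot_window_passes_uniform_fails(self):
        motif, pwm = self.one_hot_motif()
        _, crit = significance_filter(motif, pwm)
        assert crit["best_window_ic"] == pytest.approx(2.0, abs=1e-6)
        assert crit["pass_ic_window"]

        flat = DeltaZMotif("m", np.zeros((6, 4)), 2.0, "A" * 6)
        _, crit = significance_filter(flat, pwm_from_delta_z(flat))
        assert crit["best_window_ic"] == pytest.approx(0.0, abs=1e-12)
        assert not crit["pass_ic_window"]

    def test_short_motif_uses_full_length_flagged(self):
        motif, _ = self.one_hot_motif(L=4)
        pwm = pwm_from_delta_z(motif, lam=5.0)
        significant, crit = significance_filter(motif, pwm)
        assert crit["window_truncated"]
        assert significant

    def test_match_pvalue_direction(self):
        motif, pwm = self.one_hot_motif()
        assert significance_filter(motif, pwm, match_pvalue=0.01)[0]
        assert not significance_filter(motif, pwm, match_pvalue=0.5)[0]
        # printed-backwards direction, kept available for auditing
        assert significance_filter(
            motif, pwm, match_pvalue=0.5, match_direction="gt"
        )[0]

    def test_internal_match_comparator_separates_true_from_shuffled(self):
        rng = np.random.default_rng(0)
        dz = rng.normal(scale=3.0, size=(8, 4))
        motif = DeltaZMotif("m", dz, 2.0, "A" * 8)
        pwm = pwm_from_delta_z(motif)
        refs = {"self": pwm}
        for j in range(4):
            other = rng.normal(scale=3.0, size=(8, 4))
            refs[f"r{j}"] = pwm_from_delta_z(DeltaZMotif("x", other, 1.0, "A" * 8))
        p_self = match_best_pvalue(pwm, {"self": refs["self"]}, n_shuffles=199, seed=1)
        assert p_self < 0.05


class TestMotifStrength:
    def test_identical_z_gives_zero_strength(self):
        model, design = tiny_design(consensus="ACGTAC")
        zs = ZScores(z={p.probe_id: 1.3 for p in design}, bg_mean=0.0, bg_sd=1.0)
        assert motif_strength(model, zs, design) == pytest.approx(0.0)

    def test_top_frac_one_averages_everything(self):
        model, design = tiny_design(consensus="ACGT")
        rng = np.random.default_rng(0)
        zs = ZScores(z={p.probe_id: float(rng.normal()) for p in design},
                     bg_mean=0.0, bg_sd=1.0)
        dz = per_probe_delta_z(model, zs, design)
        expected = np.mean(list(dz.values()))
        assert motif_strength(model, zs, design, top_frac=1.0) == pytest.approx(expected)

    def test_top_15_percent_of_20_probes_is_top_3(self):
        # rank-and-average oracle: ceil(0.15 * n) values from the sorted list
        model, design = tiny_design(consensus="ACGTACG")  # L=7 -> 22 model probes
        rng = np.random.default_rng(1)
        zs = ZScores(z={p.probe_id: float(rng.normal()) for p in design},
                     bg_mean=0.0, bg_sd=1.0)
        dz = per_probe_delta_z(model, zs, design)
        n = len(dz)
        k = math.ceil(0.15 * n)
        expected = np.mean(sorted(dz.values(), reverse=True)[:k])
        assert motif_strength(model, zs, design, top_frac=0.15) == pytest.approx(expected)

    def test_invalid_top_frac(self):
        model, design = tiny_design()
        zs = ZScores(z={p.probe_id: 0.0 for p in design}, bg_mean=0.0, bg_sd=1.0)
        with pytest.raises(ValueError):
            motif_strength(model, zs, design, top_frac=0.0)


def profile(entries):
    return RecruitmentProfile(strengths=dict(entries))


class TestAggregation:
    def table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["cofactor", "condition", "model_id", "family", "significant", "strength"],
        )

    def test_single_significant_motif_carries_family(self):
        t = self.table([("p300", "acute", "m1", "bZIP", True, 1.7)])
        prof = family_aggregate(t)
        assert prof.get("p300", "bZIP", "acute") == pytest.approx(1.7)

    def test_family_strength_is_mean_of_significant(self):
        t = self.table([
            ("p300", "acute", "m1", "bZIP", True, 1.0),
            ("p300", "acute", "m2", "bZIP", True, 3.0),
            ("p300", "acute", "m3", "bZIP", False, 99.0),
        ])
        prof = family_aggregate(t)
        assert prof.get("p300", "bZIP", "acute") == pytest.approx(2.0)

    def test_family_without_significant_motifs_absent(self):
        t = self.table([("p300", "acute", "m1", "ETS", False, 5.0)])
        assert len(family_aggregate(t)) == 0


class TestReplicateConsensus:
    def test_seen_once_in_four_is_dropped(self):
        key = ("p300", "bZIP", "acute")
        profiles = [profile({key: 1.0})] + [profile({})] * 3
        assert len(replicate_consensus(profiles, min_reps=2)) == 0

    def test_seen_twice_kept_with_mean_strength(self):
        key = ("p300", "bZIP", "acute")
        profiles = [profile({key: 1.0}), profile({key: 2.0})]
        out = replicate_consensus(profiles, min_reps=2)
        assert out.strengths[key] == pytest.approx(1.5)
        assert out.support[key] == 2

    def test_min_reps_exceeding_replicates_rejected(self):
        with pytest.raises(ValueError, match="min_reps"):
            replicate_consensus([profile({})], min_reps=2)


class TestConditionContrast:
    def test_equal_profiles_zero_contrast(self):
        key_a = ("p300", "bZIP", "acute")
        key_e = ("p300", "bZIP", "exhausted")
        out = condition_contrast(profile({key_a: 2.0}), profile({key_e: 2.0}))
        assert out.contrast.tolist() == [0.0]
        assert out.status.tolist() == ["both"]

    def test_gain_and_loss_flags(self):
        acute = profile({("p300", "ETS", "acute"): 1.5})
        exhausted = profile({("p300", "bZIP", "exhausted"): 2.0})
        out = condition_contrast(acute, exhausted).set_index("family")
        assert out.loc["bZIP", "contrast"] == pytest.approx(2.0)
        assert out.loc["bZIP", "status"] == "gain"
        assert out.loc["ETS", "contrast"] == pytest.approx(-1.5)
        assert out.loc["ETS", "status"] == "loss"


class TestEndToEnd:
    def test_planted_energies_recovered_from_generated_array(self):
        sc = ArrayScenario(seed=5, n_models=8)
        design, models, meas, planted = gen_probe_array(sc)
        one = meas[(meas.condition == "acute") & (meas.replicate == "r1")]
        zs = z_transform(one, design)
        for model in models:
            motif = build_delta_z_motif(model, zs, design)
            r = np.corrcoef(
                planted[model.model_id]["delta"].ravel(), motif.delta_z.ravel()
            )[0, 1]
            assert r > 0.8
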