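"""Synthetic-data generator: ground truth, chase matrices, qPCR, pre-mRNA."""

import math

import numpy as np
import pandas as pd
import pytest

from decaychase import (
    ChaseDesign,
    ConfigError,
    SimConfig,
    generate_truth,
    simulate_chase,
    simulate_pre_mrna,
    simulate_qpcr,
)
from decaychase.config import LN2
from decaychase.simulate import detection_pvalue

DESIGN = ChaseDesign()


def truth_frames(truth):
    ref = truth.condition_table(truth.design.reference)
    kd = truth.condition_table(truth.design.perturbed)
    return ref, kd


class TestGenerateTruth:
    def test_steady_state_balance_is_exact(self):
        truth = generate_truth(SimConfig(n_transcripts=100, seed=1), DESIGN)
        t = truth.table
        np.testing.assert_allclose(
            t["true_steady_state"], t["true_synthesis"] * t["true_thalf"] / LN2, rtol=0
        )

    @pytest.mark.parametrize(
        "beta,expected_log_ratio_factor",
        [(0.0, 1.0), (1.0, 0.0), (1.3, -0.3), (0.5, 0.5)],
    )
    def test_buffering_couples_abundance_to_halflife_change(self, beta, expected_log_ratio_factor):
        """log(abundance ratio) = (1 - beta) * log(half-life multiplier)."""
        cfg = SimConfig(n_transcripts=200, buffering_exponent_beta=beta, seed=2)
        ref, kd = truth_frames(generate_truth(cfg, DESIGN))
        log_ab = np.log(kd["true_steady_state"] / ref["true_steady_state"])
        log_mult = np.log(ref["thalf_multiplier"])
        np.testing.assert_allclose(log_ab, expected_log_ratio_factor * log_mult, atol=1e-12)

    def test_perfect_buffering_doubled_halflife_halves_synthesis(self):
        cfg = SimConfig(
            n_transcripts=50,
            frac_stabilized=1.0,
            frac_destabilized=0.0,
            stabilization_fc_range=(2.0, 2.0),
            buffering_exponent_beta=1.0,
            seed=3,
        )
        ref, kd = truth_frames(generate_truth(cfg, DESIGN))
        np.testing.assert_allclose(kd["true_synthesis"], ref["true_synthesis"] / 2)
        np.testing.assert_allclose(kd["true_steady_state"], ref["true_steady_state"])

    def test_uncoupled_doubled_halflife_doubles_abundance(self):
        cfg = SimConfig(
            n_transcripts=50,
            frac_stabilized=1.0,
            frac_destabilized=0.0,
            stabilization_fc_range=(2.0, 2.0),
            buffering_exponent_beta=0.0,
            seed=3,
        )
        ref, kd = truth_frames(generate_truth(cfg, DESIGN))
        np.testing.assert_allclose(kd["true_steady_state"], 2 * ref["true_steady_state"])

    def test_planted_class_proportions(self):
        """2.9% of 1389 transcripts -> 40 stabilized; 1.73% -> 24 destabilized."""
        truth = generate_truth(SimConfig(n_transcripts=1389, seed=4), DESIGN)
        counts = truth.classes().value_counts()
        assert counts["stabilized"] == 40
        assert counts["destabilized"] == 24

    def test_class_labels_match_multiplier_direction(self):
        truth = generate_truth(SimConfig(n_transcripts=500, seed=5), DESIGN)
        ref, _ = truth_frames(truth)
        assert (ref.loc[ref["class_label"] == "stabilized", "thalf_multiplier"] > 1).all()
        assert (ref.loc[ref["class_label"] == "destabilized", "thalf_multiplier"] < 1).all()
        assert (ref.loc[ref["class_label"] == "unchanged", "thalf_multiplier"] == 1).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frac_stabilized=0.7, frac_destabilized=0.5),
            dict(thalf_log_median=0.0),
            dict(stabilization_fc_range=(0.8, 2.0)),
            dict(noise_cv=-0.1),
            dict(buffering_exponent_beta=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)


class TestSimulateChase:
    def test_noiseless_value_after_one_halflife(self):
        cfg = SimConfig(
            n_transcripts=5, thalf_log_median=110, thalf_log_sigma=0, synth_log_sigma=0,
            frac_stabilized=0, frac_destabilized=0, noise_cv=0, seed=6,
        )
        truth = generate_truth(cfg, DESIGN)
        matrix = simulate_chase(truth)
        A = truth.condition_table("CTRL")["true_steady_state"].iloc[0]
        at_110 = matrix[(matrix["time_min"] == 110)]["intensity"]
        np.testing.assert_allclose(at_110, A / 2)

    def test_same_seed_is_bitwise_identical(self):
        cfg = SimConfig(n_transcripts=40, noise_cv=0.2, seed=7)
        a = simulate_chase(generate_truth(cfg, DESIGN))
        b = simulate_chase(generate_truth(cfg, DESIGN))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_noise_mean_matches_decay_expectation(self):
        """Sample mean of many draws at one (t, t_half) sits on the decay curve."""
        cfg = SimConfig(
            n_transcripts=4000, thalf_log_median=120, thalf_log_sigma=0, synth_log_median=1.0,
            synth_log_sigma=0, frac_stabilized=0, frac_destabilized=0, noise_cv=0.15, seed=8,
        )
        truth = generate_truth(cfg, DESIGN)
        matrix = simulate_chase(truth)
        sub = matrix[(matrix["condition"] == "CTRL") & (matrix["time_min"] == 50)]
        A = truth.condition_table("CTRL")["true_steady_state"].iloc[0]
        expected = A * math.exp(-LN2 * 50 / 120)
        assert abs(sub["intensity"].mean() - expected) / expected < 0.01

    def test_background_floor_added_and_detection_p_attached(self):
        cfg = SimConfig(
            n_transcripts=30, noise_cv=0.0, background_level=5.0, seed=9,
        )
        truth = generate_truth(cfg, DESIGN)
        matrix = simulate_chase(truth)
        assert (matrix["intensity"] >= 5.0).all()
        t0 = matrix[matrix["time_min"] == 0]
        assert t0["detection_p"].notna().all()
        assert matrix[matrix["time_min"] > 0]["detection_p"].isna().all()

    def test_detection_p_decreases_with_signal(self):
        p = detection_pvalue(np.array([1.0, 5.0, 50.0, 500.0]), background_level=5.0)
        assert (np.diff(p) < 0).all()
        assert p[1] == pytest.approx(0.5)  # signal at the background median
        assert ((p >= 0) & (p <= 1)).all()


class TestSimulateQpcr:
    DESIGN3 = ChaseDesign(time_points=(0.0, 60.0, 120.0, 180.0))

    def _flat_truth(self, thalf=60.0, seed=10):
        cfg = SimConfig(
            n_transcripts=3, thalf_log_median=thalf, thalf_log_sigma=0, synth_log_sigma=0,
            frac_stabilized=0, frac_destabilized=0, noise_cv=0, seed=seed,
        )
        return generate_truth(cfg, self.DESIGN3)

    def test_halving_raises_ct_by_one_cycle(self):
        ct = simulate_qpcr(self._flat_truth(thalf=60.0), noise_sd_cycles=0.0)
        one = ct[(ct["transcript_id"] == "T00000") & (ct["condition"] == "CTRL") & (ct["replicate"] == 1)]
        by_t = one.set_index("time_min")["ct_target"]
        assert by_t[60.0] - by_t[0.0] == pytest.approx(1.0)
        assert by_t[120.0] - by_t[60.0] == pytest.approx(1.0)

    def test_reference_gene_is_flat_without_noise(self):
        ct = simulate_qpcr(self._flat_truth(), noise_sd_cycles=0.0)
        assert ct["ct_reference"].nunique() == 1

    def test_ct_noise_sd_is_calibrated(self):
        cfg = SimConfig(
            n_transcripts=120, thalf_log_sigma=0, synth_log_sigma=0,
            frac_stabilized=0, frac_destabilized=0, noise_cv=0, seed=11,
        )
        truth = generate_truth(cfg, DESIGN)
        ct = simulate_qpcr(truth, noise_sd_cycles=0.2)
        resid = ct["ct_reference"] - 20.0  # pure noise around the reference baseline
        assert len(resid) >= 1000
        assert abs(resid.std() - 0.2) / 0.2 < 0.10

    def test_unknown_transcript_rejected(self):
        with pytest.raises(KeyError):
            simulate_qpcr(self._flat_truth(), transcripts=["NOPE"])


class TestSimulatePreMrna:
    @pytest.mark.parametrize("beta,expected", [(1.0, 0.5), (0.0, 1.0), (1.3, 2 ** -1.3)])
    def test_condition_ratio_tracks_synthesis(self, beta, expected):
        cfg = SimConfig(
            n_transcripts=20, frac_stabilized=1.0, frac_destabilized=0.0,
            stabilization_fc_range=(2.0, 2.0), buffering_exponent_beta=beta, seed=12,
        )
        truth = generate_truth(cfg, DESIGN)
        pre = simulate_pre_mrna(truth, n_replicates=3, noise_cv=0.0)
        means = pre.groupby(["transcript_id", "condition"])["relative_quantity"].mean().unstack()
        np.testing.assert_allclose(means["KD"] / means["CTRL"], expected)

    def test_quantities_positive(self):
        cfg = SimConfig(n_transcripts=50, seed=13)
        pre = simulate_pre_mrna(generate_truth(cfg, DESIGN), noise_cv=0.3)
        assert (pre["relative_quantity"] > 0).all()


class TestChaseDesign:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ConfigError):
            ChaseDesign(time_points=(0, 50, 10))

    def test_rejects_nonzero_start(self):
        with pytest.raises(ConfigError):
            ChaseDesign(time_points=(10, 50, 110))

    def test_rejects_single_replicate(self):
        with pytest.raises(ConfigError):
            ChaseDesign(n_replicates=1)
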