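"""Stage features, membership probabilities, overrides, and summaries.

Membership expectations are hand-computed from the piecewise-linear anchor
rules; recovery tests close the loop through the synthetic generator.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ephyskit.recording import segment_epochs
from ephyskit.sleep import (
    STAGE_ORDER,
    MembershipAnchors,
    Stage,
    StageFeatures,
    classify_epoch,
    compute_stage_features,
    score_recording,
    stage_probabilities,
    summarize_hypnogram,
)
from ephyskit.synth import SleepArchitectureSpec, generate_sleep_recording

from conftest import make_recording

IDX = {s: i for i, s in enumerate(STAGE_ORDER)}


def feats(dr=1.0, tdr=1.0, emg=1.0, act=0.0):
    return StageFeatures(dr, tdr, emg, act)


class TestStageProbabilities:
    def test_sws_example_hand_computed(self):
        p = stage_probabilities(feats(dr=2.0, tdr=0.5, emg=0.3, act=0.0))
        # delta:[0,0,1,0] theta:[0,.5,.5,0] emg:[0,0,.5,.5] act:[0,1/3,1/3,1/3]
        assert np.allclose(p, [0, 5 / 24, 14 / 24, 5 / 24])
        assert STAGE_ORDER[np.argmax(p)] is Stage.SWS

    def test_paradoxical_example_hand_computed(self):
        p = stage_probabilities(feats(dr=0.4, tdr=4.0, emg=0.5, act=0.0))
        assert np.allclose(p, [0, 5 / 24, 5 / 24, 14 / 24])
        assert STAGE_ORDER[np.argmax(p)] is Stage.PARADOXICAL

    def test_neutral_anchors_tie_breaks_to_wake(self):
        p = stage_probabilities(feats(dr=0.5, tdr=1.3, emg=1.0, act=0.0))
        assert np.allclose(p, [0, 1 / 3, 1 / 3, 1 / 3])
        assert classify_epoch(p, feats(dr=0.5, tdr=1.3, emg=1.0)) is Stage.WAKE

    def test_undefined_theta_ratio_uses_uniform_evidence(self):
        p = stage_probabilities(feats(dr=2.0, tdr=math.nan, emg=0.3))
        # theta evidence replaced by [.25]*4
        expected = (
            np.array([0, 0, 1, 0.0])
            + np.full(4, 0.25)
            + np.array([0, 0, 0.5, 0.5])
            + np.array([0, 1 / 3, 1 / 3, 1 / 3])
        ) / 4
        assert np.allclose(p, expected)

    def test_probabilities_sum_to_one(self):
        for dr in (0, 0.7, 3):
            for emg in (0.2, 1.5, 5):
                assert stage_probabilities(feats(dr=dr, emg=emg)).sum() == pytest.approx(1)

    @given(
        dr=st.floats(0, 5), dr2=st.floats(0, 5),
        tdr=st.floats(0, 6), emg=st.floats(0, 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_delta_monotonicity_for_sws(self, dr, dr2, tdr, emg):
        lo, hi = sorted((dr, dr2))
        p_lo = stage_probabilities(feats(dr=lo, tdr=tdr, emg=emg))
        p_hi = stage_probabilities(feats(dr=hi, tdr=tdr, emg=emg))
        assert p_hi[IDX[Stage.SWS]] >= p_lo[IDX[Stage.SWS]] - 1e-12

    @given(emg=st.floats(0, 3.5), emg2=st.floats(0, 3.5))
    @settings(max_examples=40, deadline=None)
    def test_emg_monotonicity_for_wake(self, emg, emg2):
        lo, hi = sorted((emg, emg2))
        p_lo = stage_probabilities(feats(emg=lo))
        p_hi = stage_probabilities(feats(emg=hi))
        assert p_hi[IDX[Stage.WAKE]] >= p_lo[IDX[Stage.WAKE]] - 1e-12


class TestOverrides:
    def test_activity_above_threshold_forces_active_wake(self):
        p = stage_probabilities(feats(dr=2.0, act=0.5))  # SWS-looking otherwise
        assert classify_epoch(p, feats(dr=2.0, act=0.5)) is Stage.ACTIVE_WAKE

    def test_emg_15x_rule_forces_active_wake(self):
        f = feats(emg=3.7, act=0.0)  # 3.7 >= 1.5 * 2.4
        assert classify_epoch(stage_probabilities(f), f) is Stage.ACTIVE_WAKE

    def test_no_override_below_both(self):
        f = feats(dr=2.0, tdr=0.5, emg=0.5, act=0.0)
        assert classify_epoch(stage_probabilities(f), f) is Stage.SWS

    def test_activity_threshold_is_strict(self):
        f = feats(emg=0.5, act=0.1)  # exactly at the threshold: no override
        assert classify_epoch(stage_probabilities(f), f) is not Stage.ACTIVE_WAKE

    def test_default_emg_override_level(self):
        assert MembershipAnchors().emg_active_wake_at == pytest.approx(3.6)


class TestFeatures:
    def test_missing_channel_named_in_error(self, rng):
        rec = make_recording(rng.normal(0, 10, 500 * 120))
        grid = segment_epochs(rec, 10)
        with pytest.raises(KeyError, match="EMG"):
            compute_stage_features(rec, grid)

    def test_self_normalization_means_one(self, rng):
        n = 500 * 600
        rec = make_recording(
            rng.normal(0, 30, n), emg=rng.normal(0, 30, n),
            activity=np.zeros(200 * 600),
        )
        f = compute_stage_features(rec, segment_epochs(rec, 10))
        assert np.mean([x.delta_ratio for x in f]) == pytest.approx(1.0, abs=1e-9)
        assert np.mean([x.emg_ratio for x in f]) == pytest.approx(1.0, abs=1e-9)

    def test_louder_epoch_has_quadratically_larger_delta_ratio(self, rng):
        # deterministic delta tone: doubling its amplitude in one epoch
        # must quadruple that epoch's delta ratio
        n10 = 500 * 10
        t = np.arange(n10 * 12) / 500.0
        eeg = (50 * np.sin(2 * np.pi * 1.5 * t)).reshape(12, n10)
        eeg[3] *= 2.0
        rec = make_recording(eeg.ravel(), emg=rng.normal(0, 20, n10 * 12),
                             activity=np.zeros(200 * 120))
        f = compute_stage_features(rec, segment_epochs(rec, 10))
        others = np.mean([x.delta_ratio for i, x in enumerate(f) if i != 3])
        assert f[3].delta_ratio / others == pytest.approx(4.0, rel=0.01)

    def test_zero_delta_power_flags_theta_ratio(self):
        n = 500 * 100
        t = np.arange(n) / 500.0
        rec = make_recording(
            30 * np.sin(2 * np.pi * 6 * t),  # pure theta: near-zero delta
            emg=np.zeros(n), activity=np.zeros(200 * 100),
        )
        f = compute_stage_features(rec, segment_epochs(rec, 10))
        # EMG identically zero -> ratio undefined, delta tiny but nonzero
        assert all(math.isnan(x.emg_ratio) for x in f)


class TestRecovery:
    def test_all_sws_sequence_scores_sws(self):
        spec = SleepArchitectureSpec(stage_sequence=[Stage.SWS], seed=7)
        rec, _ = generate_sleep_recording(spec, 600)
        hyp = score_recording(rec)
        frac = np.mean([s is Stage.SWS for s in hyp.stages])
        assert frac >= 0.9

    def test_markov_architecture_recovered(self):
        rec, truth = generate_sleep_recording(SleepArchitectureSpec(seed=11), 1800)
        hyp = score_recording(rec)
        pairs = [(a, b) for a, b in zip(hyp.stages, truth.stages)
                 if a is not Stage.ARTIFACT]
        agreement = np.mean([a is b for a, b in pairs])
        assert agreement >= 0.9

    def test_epoch_permutation_permutes_hypnogram(self):
        # no temporal smoothing: staging is epoch-local
        spec = SleepArchitectureSpec(
            stage_sequence=[Stage.SWS, Stage.WAKE, Stage.PARADOXICAL,
                            Stage.ACTIVE_WAKE],
            seed=3,
        )
        rec, _ = generate_sleep_recording(spec, 400)
        hyp = score_recording(rec)
        perm = np.random.default_rng(0).permutation(hyp.n_epochs)
        chans = []
        from ephyskit.recording import Channel, TimeSeriesRecording
        for ch in rec.channels:
            n = int(10 * ch.sampling_rate)
            blocks = ch.samples.reshape(-1, n)[perm]
            chans.append(Channel(ch.label, blocks.ravel(), ch.sampling_rate))
        hyp_perm = score_recording(TimeSeriesRecording(chans))
        assert [hyp_perm.stages[i] for i in range(hyp.n_epochs)] == [
            hyp.stages[j] for j in perm
        ]


class TestSummary:
    def test_uniform_hypnogram_is_100_percent(self):
        from ephyskit.sleep import Hypnogram

        hyp = Hypnogram(
            stages=[Stage.WAKE] * 40, epoch_length=10.0,
            epoch_starts=np.arange(40) * 10.0,
            probabilities=np.full((40, 4), np.nan),
            override_fired=np.zeros(40, dtype=bool),
        )
        summary = summarize_hypnogram(hyp)
        assert summary.percent["WAKE"] == 100.0
        assert sum(summary.percent.values()) == pytest.approx(100.0, abs=0.01)

    def test_balanced_sequence_quarters(self):
        spec = SleepArchitectureSpec(
            stage_sequence=[Stage.ACTIVE_WAKE, Stage.WAKE, Stage.SWS,
                            Stage.PARADOXICAL],
            seed=9,
        )
        rec, truth = generate_sleep_recording(spec, 1200)
        summary = summarize_hypnogram(score_recording(rec))
        for stage in STAGE_ORDER:
            assert summary.percent[stage.value] == pytest.approx(25.0, abs=5.0)
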