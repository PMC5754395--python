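"""Synthetic activation truth, sEMG emulation and dataset assembly."""

import numpy as np
import pytest
from scipy.signal import periodogram

from emgface.muscles import SIDES, measured_labels, model_labels
from emgface.synthetic import (
    ActivationTruth,
    CrosstalkModel,
    DatasetConfig,
    concatenate_session,
    gen_activation_truth,
    kinematic_trajectories,
    make_dataset,
    measured_envelopes,
    synth_semg,
    truth_to_activation,
)


def nonzero_channels(truth):
    return {truth.labels[j] for j in
            np.nonzero(truth.values.any(axis=1))[0]}


class TestActivationTruth:
    def test_purse_lips_activates_orbicularis_and_buccinator(self):
        truth = gen_activation_truth("A", 2.0, seed=1)
        expected = {f"{m}_{s}" for m in ("OOP", "OOM", "BUC")
                    for s in SIDES}
        assert nonzero_channels(truth) == expected

    def test_raise_upper_lip_activates_exactly_two_channels(self):
        for seed in (0, 3, 99):
            truth = gen_activation_truth("B", 2.0, seed=seed)
            assert nonzero_channels(truth) == {"LLSAN_L", "LLSAN_R"}

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            gen_activation_truth("A", 0.0)

    def test_unknown_instruction_named_in_error(self):
        with pytest.raises(ValueError, match="purse lips"):
            gen_activation_truth("X", 2.0)

    def test_values_in_unit_interval_and_slew_limited(self):
        for ins in "ABCDEF":
            truth = gen_activation_truth(ins, 2.0, seed=5)
            assert truth.values.min() >= 0.0
            assert truth.values.max() <= 1.0
            assert np.abs(np.diff(truth.values, axis=1)).max() <= 0.08

    def test_symmetric_instructions_have_equal_sides(self):
        for ins in "ABCD":
            truth = gen_activation_truth(ins, 2.0, seed=2)
            np.testing.assert_array_equal(truth.values[:10],
                                          truth.values[10:])

    def test_asymmetric_instruction_alternates_dominance(self):
        truth = gen_activation_truth("E", 3.0, seed=0)
        left = truth.values[truth.labels.index("OOP_L")]
        right = truth.values[truth.labels.index("OOP_R")]
        assert not np.array_equal(left, right)
        # right dominates in the middle phase, left at the ends
        mid = slice(truth.n_frames // 2 - 10, truth.n_frames // 2 + 10)
        assert right[mid].max() > left[mid].max()
        third = truth.n_frames // 3
        assert left[:third].max() > right[:third].max()

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            ActivationTruth(values=np.full((20, 4), 1.2),
                            times=np.arange(4.0),
                            labels=model_labels(), instruction="A")


class TestCrosstalk:
    def test_default_rows_sum_to_one(self):
        xt = CrosstalkModel.default(0.1)
        np.testing.assert_allclose(xt.mixing.sum(axis=1), 1.0)
        assert np.all(xt.mixing >= 0)

    def test_negative_mixing_rejected(self):
        M = np.eye(14)
        M[0, 1] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            CrosstalkModel(M)


class TestSynthSemg:
    def test_zero_activation_zero_noise_gives_silence(self):
        truth = gen_activation_truth("A", 1.0, seed=0)
        truth.values[:] = 0.0
        rec = synth_semg(truth, CrosstalkModel.identity(), seed=0)
        assert np.all(rec.samples == 0.0)

    def test_same_seed_is_bit_identical(self):
        truth = gen_activation_truth("D", 1.0, seed=4)
        a = synth_semg(truth, seed=9)
        b = synth_semg(truth, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seed_differs(self):
        truth = gen_activation_truth("D", 1.0, seed=4)
        assert not np.array_equal(synth_semg(truth, seed=1).samples,
                                  synth_semg(truth, seed=2).samples)

    def test_low_sample_rate_rejected(self):
        truth = gen_activation_truth("A", 1.0)
        with pytest.raises(ValueError, match="band"):
            synth_semg(truth, fs=800.0)

    def test_windowed_rms_monotone_in_envelope(self):
        """Higher envelope level gives strictly larger mid-window RMS
        (computed directly on the generated cross-talk-free signal)."""
        labels = model_labels()
        rms = []
        for level in (0.0, 0.25, 0.5, 0.75, 1.0):
            values = np.zeros((20, 201))
            values[labels.index("MEN_L")] = level
            truth = ActivationTruth(values=values,
                                    times=np.arange(201) / 100.0,
                                    labels=labels, instruction="C",
                                    duration=2.0)
            rec = synth_semg(truth, CrosstalkModel.identity(), seed=3)
            ch = rec.labels.index("MEN_L")
            mid = rec.samples[ch, 1024:3072]
            rms.append(np.sqrt(np.mean(mid**2)))
        assert all(b > a for a, b in zip(rms, rms[1:]) if b > 0)
        assert rms[0] == 0.0

    def test_carrier_power_confined_to_band(self):
        from emgface.synthetic import band_limited_noise
        rng = np.random.default_rng(0)
        x = band_limited_noise(2**16, 2048.0, rng)
        f, p = periodogram(x, fs=2048.0)
        in_band = p[(f >= 15.0) & (f <= 500.0)].sum()
        assert in_band / p.sum() >= 0.95


class TestMeasuredEnvelopes:
    def test_orbicularis_truth_maps_to_both_electrode_sites(self):
        truth = gen_activation_truth("A", 2.0, seed=0)
        env = measured_envelopes(truth)
        ml = measured_labels()
        oop = truth.values[truth.labels.index("OOP_L")]
        np.testing.assert_array_equal(env[ml.index("OOS_L")], oop)
        np.testing.assert_array_equal(env[ml.index("OOI_L")], oop)
        # buccinator floods the risorius and zygomaticus sites
        buc = truth.values[truth.labels.index("BUC_L")]
        np.testing.assert_array_equal(env[ml.index("RIS_L")], buc)


class TestMakeDataset:
    def test_record_count(self):
        cfg = DatasetConfig(instructions=("A", "B"), repetitions=2,
                            duration=1.0, seed=0)
        records = make_dataset(cfg)
        assert len(records) == 4
        # six instructions x four repetitions is the full protocol
        assert len(DatasetConfig().instructions) * \
            DatasetConfig().repetitions == 24

    def test_zero_repetitions_gives_empty_collection(self):
        assert make_dataset(DatasetConfig(repetitions=0)) == []

    def test_fem_mode_requires_model(self):
        with pytest.raises(ValueError, match="model"):
            make_dataset(DatasetConfig(trajectory_source="fem"))

    def test_deterministic_per_seed(self):
        cfg = DatasetConfig(instructions=("C",), repetitions=1,
                            duration=1.0, seed=7)
        a = make_dataset(cfg)[0]
        b = make_dataset(cfg)[0]
        np.testing.assert_array_equal(a.emg.samples, b.emg.samples)
        np.testing.assert_array_equal(a.trajectories.positions,
                                      b.trajectories.positions)

    def test_surrogate_trajectories_at_marker_rate(self):
        rec = make_dataset(DatasetConfig(instructions=("B",),
                                         repetitions=1, duration=2.0))[0]
        assert rec.trajectories.frame_rate == 100.0
        assert rec.trajectories.n_markers == 10

    def test_surrogate_mirror_symmetry(self):
        truth = gen_activation_truth("A", 2.0, seed=0)
        traj = kinematic_trajectories(truth)
        mirror = [4, 3, 2, 1, 0, 9, 8, 7, 6, 5]
        flipped = traj.positions[mirror] * np.array([-1.0, 1.0, 1.0])
        np.testing.assert_allclose(traj.positions, flipped, atol=1e-12)

    def test_session_concatenation_inserts_rest(self):
        cfg = DatasetConfig(instructions=("A",), repetitions=2,
                            duration=1.0)
        records = make_dataset(cfg)
        stream = concatenate_session(records, rest=2.0)
        fs = records[0].emg.fs
        expected = 2 * records[0].emg.n_samples + int(2.0 * fs)
        assert stream.shape == (14, expected)


class TestTruthToActivation:
    def test_resamples_to_model_grid(self):
        truth = gen_activation_truth("A", 2.0, seed=0)
        act = truth_to_activation(truth, 160)
        assert act.n_frames == 160
        assert act.values.min() >= 0.0 and act.values.max() <= 1.0
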