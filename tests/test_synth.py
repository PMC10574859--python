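import numpy as np
import pytest

from wmeeg.features import extract_features
from wmeeg.recording import Montage
from wmeeg.synth import (
    SynthConfig,
    features_matrix,
    generate_dataset,
    labels_vector,
    simulate_abilities,
    simulate_band_ratios,
    simulate_labels,
    simulate_subject_offsets,
    simulate_timeseries,
)


class TestAbilities:
    def test_reproducible_per_seed(self):
        cfg = SynthConfig(seed=42)
        np.testing.assert_array_equal(simulate_abilities(cfg), simulate_abilities(cfg))

    def test_standard_normal_at_large_n(self):
        cfg = SynthConfig(n_subjects=10_000, seed=0)
        theta = simulate_abilities(cfg)
        assert abs(theta.mean()) < 0.05 and abs(theta.std() - 1) < 0.05


class TestBandRatios:
    def test_noiseless_task_shift_has_proposition_signs_everywhere(self):
        cfg = SynthConfig(noise_sd=0.0, seed=1)
        theta = np.zeros(5)
        offsets = np.random.default_rng(1).normal(0, 0.5, size=(5, 10, 4))
        rest = simulate_band_ratios(theta, "rest", cfg, offsets=offsets)
        task = simulate_band_ratios(theta, "task", cfg, offsets=offsets)
        delta = task - rest
        assert np.all(delta[:, :, 0] < 0)  # alpha down
        assert np.all(delta[:, :, 1] > 0)  # beta up
        assert np.all(delta[:, :, 2] > 0)  # gamma up

    def test_abler_subjects_shift_more(self):
        cfg = SynthConfig(noise_sd=0.0, seed=1)
        offsets = np.zeros((2, 10, 4))
        task = simulate_band_ratios(np.array([-2.0, 2.0]), "task", cfg, offsets=offsets)
        assert np.all(task[1, :, 0] < task[0, :, 0])  # lower alpha
        assert np.all(task[1, :, 1] > task[0, :, 1])
        assert np.all(task[1, :, 2] > task[0, :, 2])

    def test_ratios_valid_composition(self):
        cfg = SynthConfig(seed=2)
        r = simulate_band_ratios(np.random.default_rng(2).normal(size=200), "task", cfg)
        assert np.all((r > 0) & (r < 1))
        assert np.all(r.sum(axis=2) <= 0.95 + 1e-12)

    def test_null_effect_makes_rest_and_task_exchangeable(self):
        cfg = SynthConfig(effect_size=0.0, seed=3, n_subjects=500)
        rng = np.random.default_rng(3)
        theta = rng.standard_normal(500)
        offsets = np.zeros((500, 10, 4))
        rest = simulate_band_ratios(theta, "rest", cfg, np.random.default_rng(10), offsets)
        task = simulate_band_ratios(theta, "task", cfg, np.random.default_rng(11), offsets)
        frac = (task[:, :, 0] < rest[:, :, 0]).mean()
        assert 0.45 < frac < 0.55

    def test_noise_degrades_satisfaction_monotonically(self):
        rates = []
        for noise in (0.0, 0.3, 1.5):
            cfg = SynthConfig(noise_sd=noise, seed=4, n_subjects=500)
            theta = np.zeros(500)
            offsets = np.zeros((500, 10, 4))
            rng = np.random.default_rng(4)
            rest = simulate_band_ratios(theta, "rest", cfg, rng, offsets)
            task = simulate_band_ratios(theta, "task", cfg, rng, offsets)
            rates.append(float((task[:, :, 0] < rest[:, :, 0]).mean()))
        assert rates[0] == 1.0
        assert 1.0 > rates[1] > rates[2] > 0.5


class TestTimeseries:
    def test_feature_extractor_recovers_targets(self):
        cfg = SynthConfig(segment_seconds=10.0, seed=5)
        targets = np.tile([0.6, 0.2, 0.1], (10, 1))
        rec = simulate_timeseries(targets, cfg)
        fv = extract_features(rec, montage=Montage())
        np.testing.assert_allclose(fv.as_matrix(), targets, atol=0.05)

    def test_different_seeds_same_spectrum_different_waveform(self):
        cfg = SynthConfig(segment_seconds=5.0)
        targets = np.tile([0.4, 0.3, 0.2], (10, 1))
        a = simulate_timeseries(targets, cfg, np.random.default_rng(1))
        b = simulate_timeseries(targets, cfg, np.random.default_rng(2))
        assert not np.allclose(a.data, b.data)
        fa = extract_features(a, montage=Montage()).as_matrix()
        fb = extract_features(b, montage=Montage()).as_matrix()
        np.testing.assert_allclose(fa, fb, atol=0.1)

    def test_degenerate_targets_rejected(self):
        cfg = SynthConfig()
        with pytest.raises(ValueError, match="ratios"):
            simulate_timeseries(np.tile([0.0, 0.0, 0.0], (10, 1)), cfg)

    def test_low_sampling_rate_rejected(self):
        cfg = SynthConfig(fs=60.0)
        with pytest.raises(ValueError, match="gamma"):
            simulate_timeseries(np.tile([0.4, 0.3, 0.2], (10, 1)), cfg)


class TestLabels:
    def test_monotone_in_ability_without_noise(self):
        cfg = SynthConfig(label_noise_sd=0.0)
        times, labels = simulate_labels(np.array([0.0, 1.0]), cfg)
        assert times[1] < times[0]
        assert labels[1].z > labels[0].z

    def test_cohort_standardization(self):
        cfg = SynthConfig(seed=6)
        _, labels = simulate_labels(np.random.default_rng(6).normal(size=300), cfg)
        z = np.array([lab.z for lab in labels])
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_ability_label_correlation_exceeds_threshold(self):
        cfg = SynthConfig(seed=7)
        theta = np.random.default_rng(7).normal(size=500)
        _, labels = simulate_labels(theta, cfg)
        z = np.array([lab.z for lab in labels])
        assert np.corrcoef(theta, z)[0, 1] > 0.7


class TestGenerateDataset:
    def test_default_profile_yields_120_task_records(self, default_cohort):
        assert len(default_cohort) == 120
        assert len({r.subject_id for r in default_cohort}) == 20

    def test_minimal_profile_runs_end_to_end(self):
        recs = generate_dataset(SynthConfig(n_subjects=1, n_sessions=1, n_trials_per_session=1))
        assert len(recs) == 1
        assert recs[0].label is not None and len(recs[0].task_features) == 30

    def test_reproducible_per_seed(self):
        a = generate_dataset(SynthConfig(seed=9))
        b = generate_dataset(SynthConfig(seed=9))
        np.testing.assert_array_equal(features_matrix(a), features_matrix(b))
        np.testing.assert_array_equal(labels_vector(a), labels_vector(b))

    def test_subject_offsets_shared_between_states(self):
        cfg = SynthConfig(seed=10)
        offs = simulate_subject_offsets(cfg)
        assert offs.shape == (20, 10, 4)
        assert np.abs(offs).max() <= 2 * cfg.subject_offset_sd + 1e-12

    def test_tables_written_to_disk(self, tmp_path):
        import pandas as pd

        generate_dataset(
            SynthConfig(n_subjects=3, n_sessions=1, n_trials_per_session=2, seed=0),
            outdir=tmp_path,
        )
        tasks = pd.read_csv(tmp_path / "task_features.tsv", sep="\t")
        labels = pd.read_csv(tmp_path / "labels.tsv", sep="\t")
        assert len(tasks) == 6 and len(labels) == 6
        assert tasks.shape[1] == 3 + 30
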