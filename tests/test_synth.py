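"""Generator tests: SOA sampling, run layout, behaviour, neural amplitudes,
and the linear BOLD forward model."""

import numpy as np
import pandas as pd
import pytest

from rtbold.config import (
    BehaviorConfig,
    ConfigurationError,
    ExGaussian,
    ExperimentConfig,
    GenerativeModelConfig,
    TaskDesignConfig,
    tiny_experiment,
)
from rtbold.hrf import canonical_hrf
from rtbold.synth import (
    generate_dataset,
    generate_run_design,
    generate_subject,
    neural_amplitudes,
    neural_to_bold,
    sample_behavior,
    sample_soas,
    simulate_bold,
    simulate_motion,
)

from conftest import make_events


class TestSampleSoas:
    def test_degenerate_distribution(self, msit_cfg):
        cfg = TaskDesignConfig(soa_weights=(1.0, 0.0, 0.0, 0.0))
        assert np.all(sample_soas(10, cfg, seed=0) == 2.5)

    def test_halving_weights_frequencies(self, msit_cfg):
        """Empirical frequencies of the 8:4:2:1 scheme land within 3
        multinomial standard errors of 8/15, 4/15, 2/15, 1/15."""
        n = 10_000
        draws = sample_soas(n, msit_cfg, seed=42)
        for value, w in zip(msit_cfg.soa_values, msit_cfg.soa_weights):
            freq = np.mean(draws == value)
            se = np.sqrt(w * (1 - w) / n)
            assert abs(freq - w) < 3 * se

    @pytest.mark.parametrize("seed", range(5))
    def test_range(self, msit_cfg, seed):
        draws = sample_soas(500, msit_cfg, seed=seed)
        assert draws.min() >= 2.5 and draws.max() <= 6.25

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            TaskDesignConfig(soa_weights=(0.5, 0.5, 0.0))  # wrong length
        with pytest.raises(ConfigurationError):
            TaskDesignConfig(soa_weights=(0.1, 0.2, 0.3, 0.4))  # increasing

    def test_reproducible(self, msit_cfg):
        assert np.array_equal(sample_soas(50, msit_cfg, 3), sample_soas(50, msit_cfg, 3))


class TestRunDesign:
    def test_msit_counts_and_split(self, msit_cfg):
        ev = generate_run_design("msit", 0, msit_cfg, seed=0)
        assert len(ev) == 96
        assert (ev["condition"] == "congruent").sum() == 48
        assert (ev["condition"] == "incongruent").sum() == 48

    def test_simple_all_one_condition(self, simple_cfg):
        ev = generate_run_design("simple", 0, simple_cfg, seed=0)
        assert len(ev) == 96
        assert (ev["condition"] == "simple").all()

    def test_onsets_consistent_with_soas(self, msit_cfg):
        ev = generate_run_design("msit", 0, msit_cfg, seed=1)
        onsets = ev["onset"].to_numpy()
        diffs = np.diff(onsets)
        assert np.all(np.isin(np.round(diffs, 6), msit_cfg.soa_values))
        assert onsets[0] >= msit_cfg.discard_duration
        assert onsets[-1] + msit_cfg.stimulus_duration <= msit_cfg.run_duration

    def test_single_trial_onset(self):
        cfg = TaskDesignConfig(n_trials_per_run=1)
        ev = generate_run_design("msit", 0, cfg, seed=0)
        offset = ev["onset"].iloc[0] - cfg.discard_duration
        assert len(ev) == 1
        assert np.round(offset, 6) in cfg.soa_values

    def test_overfull_run_rejected(self):
        with pytest.raises(ConfigurationError):
            TaskDesignConfig(n_trials_per_run=96, n_volumes_per_run=100)


class TestBehavior:
    def test_degenerate_exgaussian_hits_mu(self):
        cfg = BehaviorConfig(
            rt={
                "congruent": ExGaussian(661, 0, 0),
                "incongruent": ExGaussian(858, 0, 0),
                "simple": ExGaussian(376, 0, 0),
            }
        )
        ev = make_events([np.nan] * 20, condition=["congruent", "incongruent"] * 10)
        out = sample_behavior(ev, cfg, None, seed=0)
        assert np.all(out.loc[out["condition"] == "congruent", "rt_ms"] == 661)
        assert np.all(out.loc[out["condition"] == "incongruent", "rt_ms"] == 858)

    def test_perfect_accuracy_no_errors(self, behavior_cfg):
        cfg = BehaviorConfig(accuracy={"congruent": 1.0, "incongruent": 1.0, "simple": 1.0})
        ev = make_events([np.nan] * 50, condition=["simple"] * 50, task="simple")
        out = sample_behavior(ev, cfg, None, seed=0)
        assert out["correct"].all()
        assert out["rt_ms"].notna().all()

    def test_simple_errors_are_misses(self):
        cfg = BehaviorConfig(accuracy={"congruent": 0.998, "incongruent": 0.981, "simple": 0.3})
        ev = make_events([np.nan] * 200, condition=["simple"] * 200, task="simple")
        out = sample_behavior(ev, cfg, None, seed=0)
        wrong = ~out["correct"].to_numpy(dtype=bool)
        assert wrong.any()
        assert out.loc[wrong, "rt_ms"].isna().all()
        assert out.loc[~wrong, "rt_ms"].notna().all()


class TestNeuralAmplitudes:
    def test_zero_slope_depends_only_on_condition(self):
        gen = GenerativeModelConfig(time_on_task_slope=0.0)
        ev = make_events([500, 700, 900, 1100], condition=["congruent", "congruent",
                                                           "incongruent", "incongruent"])
        amp = neural_amplitudes(ev, gen, {"baseline": {"congruent": 1.0, "incongruent": 2.0},
                                          "slope_b": 0.0})
        assert np.allclose(amp, [1, 1, 2, 2])

    def test_direct_substitution(self):
        gen = GenerativeModelConfig()
        ev = make_events([500.0])
        amp = neural_amplitudes(ev, gen, {"baseline": {"congruent": 0.0}, "slope_b": 1.0})
        assert amp[0] == pytest.approx(0.5)

    def test_conflict_simple_trials_flat(self):
        """A one-choice task engenders no conflict: amplitude variance is
        zero within the simple condition no matter the RT spread."""
        gen = GenerativeModelConfig.conflict_monitoring()
        ev = make_events([300, 400, 500, 900], condition=["simple"] * 4, task="simple")
        amp = neural_amplitudes(ev, gen, None)
        assert np.ptp(amp) == 0.0

    def test_time_on_task_amp_rt_correlation_positive(self):
        rng = np.random.default_rng(0)
        gen = GenerativeModelConfig(time_on_task_slope=1.0)
        for cond, task in [("congruent", "msit"), ("incongruent", "msit"), ("simple", "simple")]:
            rts = rng.uniform(300, 1000, 40)
            ev = make_events(rts, condition=[cond] * 40, task=task)
            amp = neural_amplitudes(ev, gen, None)
            assert np.corrcoef(amp, rts)[0, 1] > 0.999

    def test_miss_gets_zero_amplitude(self):
        gen = GenerativeModelConfig()
        ev = make_events([400, np.nan], condition=["simple", "simple"], task="simple",
                         correct=[True, False])
        amp = neural_amplitudes(ev, gen, None)
        assert amp[1] == 0.0


class TestSimulateBold:
    noiseless = GenerativeModelConfig(noise_sd=0.0, drift_amplitude=0.0, n_units=1,
                                      unit_names=("u",))

    def test_impulse_response_is_hrf(self):
        cfg = TaskDesignConfig(n_trials_per_run=1, n_volumes_per_run=60)
        ev = make_events([500.0], start=10.0)  # onset on the volume grid
        series = simulate_bold(ev, np.array([1.0]), self.noiseless, cfg, seed=0)[0]
        kernel = canonical_hrf(cfg.tr, 16)[::16]  # HRF at TR resolution
        onset_vol = int(10.0 / cfg.tr) - cfg.n_discard_volumes
        got = series[onset_vol : onset_vol + len(kernel)]
        assert np.allclose(got, kernel[: len(got)], atol=1e-12)

    def test_superposition(self):
        """The forward model is linear: summed amplitude vectors produce the
        summed noise-free series, and doubling an amplitude doubles its
        response."""
        cfg = TaskDesignConfig(n_trials_per_run=2, n_volumes_per_run=120)
        ev = make_events([500.0, 500.0], start=10.0, soa=60.0)  # non-overlapping
        a = neural_to_bold(ev["onset"].to_numpy(), [1.0, 0.0], cfg)
        b = neural_to_bold(ev["onset"].to_numpy(), [0.0, 2.0], cfg)
        both = neural_to_bold(ev["onset"].to_numpy(), [1.0, 2.0], cfg)
        assert np.allclose(a + b, both, atol=1e-12)
        onset_vols = (ev["onset"].to_numpy() / cfg.tr).astype(int)
        assert np.allclose(2 * a[onset_vols[0] : onset_vols[0] + 20],
                           b[onset_vols[1] : onset_vols[1] + 20], atol=1e-12)

    def test_white_noise_lag1_autocorrelation(self):
        gen = GenerativeModelConfig(noise_sd=1.0, ar1_rho=0.0, drift_amplitude=0.0,
                                    n_units=8, unit_names=tuple("abcdefgh"))
        cfg = TaskDesignConfig(n_trials_per_run=1, n_volumes_per_run=297)
        ev = make_events([500.0], start=10.0)
        series = simulate_bold(ev, np.array([0.0]), gen, cfg, seed=5)
        r = series - series.mean(axis=1, keepdims=True)
        rho = np.sum(r[:, 1:] * r[:, :-1]) / np.sum(r * r)
        n_eff = r.size
        assert abs(rho) < 3 / np.sqrt(n_eff)

    def test_ar1_noise_marginal_sd(self):
        gen = GenerativeModelConfig(noise_sd=2.0, ar1_rho=0.5, drift_amplitude=0.0,
                                    n_units=40, unit_names=tuple(str(i) for i in range(40)))
        cfg = TaskDesignConfig(n_trials_per_run=1, n_volumes_per_run=297)
        ev = make_events([500.0], start=10.0)
        series = simulate_bold(ev, np.array([0.0]), gen, cfg, seed=5)
        assert series.std() == pytest.approx(2.0, rel=0.05)


class TestDatasets:
    def test_same_seed_bit_identical(self):
        cfg = tiny_experiment(seed=3)
        d1 = generate_dataset(cfg=cfg)
        d2 = generate_dataset(cfg=cfg)
        for a, b in zip(d1, d2):
            pd.testing.assert_frame_equal(a.events, b.events)
            for run in a.timeseries:
                assert np.array_equal(a.timeseries[run], b.timeseries[run])
                assert np.array_equal(a.motion[run], b.motion[run])

    def test_default_structure(self, default_cfg):
        data = generate_dataset(cfg=default_cfg, events_only=True)
        assert len(data) == 24
        ds = data[0]
        assert sorted(ds.run_tasks.values()) == ["msit"] * 4 + ["simple"] * 2
        for run in ds.run_tasks:
            assert (ds.events["run_index"] == run).sum() == 96

    def test_timeseries_shape_tiny(self, tiny_cfg):
        ds = generate_dataset(cfg=tiny_cfg)[0]
        for run in ds.run_tasks:
            assert ds.timeseries[run].shape == (1, 80)  # 85 volumes - 5 discarded
            assert ds.motion[run].shape == (80, 6)
        assert (ds.events["onset"] >= tiny_cfg.msit.discard_duration).all()

    def test_zero_between_subject_sd_identical_truth(self):
        cfg = tiny_experiment(seed=0)
        cfg.behavior.subject_shift_sd = 0.0
        cfg.behavior.condition_shift_sd = 0.0
        cfg.model.baseline_sd = 0.0
        cfg.model.slope_sd = 0.0
        cfg.model.gain_sd = 0.0
        data = generate_dataset(cfg=cfg, events_only=True)
        t0 = data[0].truth
        for ds in data[1:]:
            assert ds.truth["slope_b"] == t0["slope_b"]
            assert ds.truth["baseline"] == t0["baseline"]
            assert ds.truth["rt_shift"] == t0["rt_shift"]

    def test_too_few_subjects_rejected(self, tiny_cfg):
        with pytest.raises(ConfigurationError):
            generate_dataset(n_subjects=1, cfg=tiny_cfg)

    def test_motion_bounded_and_smooth(self):
        m = simulate_motion(200, seed=0)
        assert m.shape == (200, 6)
        assert np.abs(m).max() <= 1.0
        assert np.abs(np.diff(m, axis=0)).max() < 0.5
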