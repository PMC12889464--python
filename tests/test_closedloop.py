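import numpy as np
import pandas as pd
import pytest

from livesort.closedloop import (
    TriggerConfig,
    WaveformClass,
    analyze_prestim,
    classify_waveforms,
    run_trigger_session,
)
from livesort.io_probe import SortedOutput

FS = 30000.0


def _sorted_from_trains(trains: dict, fs=FS):
    times, clusters = [], []
    for c, t in trains.items():
        times.extend(t)
        clusters.extend([c] * len(t))
    order = np.argsort(times)
    times = np.asarray(times)[order]
    clusters = np.asarray(clusters)[order]
    n = len(times)
    return SortedOutput(
        times=times, clusters=clusters, templates=clusters,
        amplitudes=np.ones(n), positions=np.zeros((n, 2)), fs=fs,
    )


def _bank_with_widths(widths_samples):
    """Minimal bank-like object with templates of given trough-to-peak."""

    class _Spec:
        fs = FS

    class _Bank:
        preproc = _Spec()

        def __init__(self):
            self.templates = np.zeros((len(widths_samples), 61, 4))
            for k, w in enumerate(widths_samples):
                self.templates[k, 30, 0] = -10.0
                if w is not None:
                    self.templates[k, 30 + w, 0] = 5.0

        @property
        def n_templates(self):
            return self.templates.shape[0]

    return _Bank()


class TestClassifyWaveforms:
    def test_150us_is_fs(self):
        # 150 us at 30 kHz = 4.5 samples; 4 samples = 133 us < 200
        bank = _bank_with_widths([4])
        assert classify_waveforms(bank)[0].label == "FS"

    def test_exactly_200us_is_rs(self):
        # 6 samples at 30 kHz = 200 us exactly: strict inequality -> RS
        bank = _bank_with_widths([6])
        cls = classify_waveforms(bank)[0]
        assert cls.trough_to_peak_us == pytest.approx(200.0)
        assert cls.label == "RS"

    def test_five_samples_is_fs(self):
        bank = _bank_with_widths([5])  # 166.7 us
        assert classify_waveforms(bank)[0].label == "FS"

    def test_monophasic_is_rs(self):
        bank = _bank_with_widths([None])
        assert classify_waveforms(bank)[0].label == "RS"

    def test_waveform_class_invariant_enforced(self):
        with pytest.raises(ValueError):
            WaveformClass(unit_id=0, trough_to_peak_us=150.0, label="RS")


def _poisson_trains(rate_hz, n_clusters, duration_s, seed):
    rng = np.random.default_rng(seed)
    return {
        c: (
            np.sort(rng.uniform(0, duration_s, rng.poisson(rate_hz * duration_s))) * FS
        ).astype(np.int64)
        for c in range(n_clusters)
    }


def _trials_spec(n, start_s=20.0, kind="closedloop"):
    return pd.DataFrame(
        {
            "fixation_start_s": start_s + np.arange(n) * 1.2,
            "kind": kind,
            "direction_deg": np.zeros(n),
        }
    )


class TestTriggerSession:
    def test_infinite_threshold_never_triggers(self, small_bank):
        trains = _poisson_trains(20.0, 2, 60.0, 0)
        out = _sorted_from_trains(trains)
        cfg = TriggerConfig(threshold_sd=np.inf)
        table = run_trigger_session(out, small_bank, [0, 1], cfg, _trials_spec(10))
        assert (table["condition"] == "non_triggered").all()
        # non-triggered onset at the end of the 1 s fixation
        fix = _trials_spec(10)["fixation_start_s"].to_numpy()
        assert np.allclose(table["onset_sample"], (fix + 1.0) * FS)

    def test_rate_step_triggers_in_expected_window(self, small_bank):
        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(0, 60.0, 600))  # 10 Hz baseline
        t0 = 20.0  # single trial; rate step at +300 ms
        burst = t0 + 0.3 + np.sort(rng.uniform(0, 0.2, 200))
        trains = {0: (np.sort(np.r_[base, burst]) * FS).astype(np.int64)}
        out = _sorted_from_trains(trains)
        table = run_trigger_session(
            out, small_bank, [0], TriggerConfig(), _trials_spec(1, start_s=t0)
        )
        assert table.iloc[0]["condition"] == "triggered"
        assert 300.0 <= table.iloc[0]["trigger_latency_ms"] <= 400.0

    def test_zero_baseline_sd_errors(self, small_bank):
        trains = {0: (np.arange(0.05, 60.0, 0.1) * FS).astype(np.int64)}  # metronome
        out = _sorted_from_trains(trains)
        with pytest.raises(ValueError, match="baseline"):
            run_trigger_session(out, small_bank, [0], TriggerConfig(), _trials_spec(5))

    def test_empty_fs_population_rejected(self, small_bank):
        out = _sorted_from_trains(_poisson_trains(10.0, 1, 30.0, 2))
        with pytest.raises(ValueError, match="fs_units"):
            run_trigger_session(out, small_bank, [], TriggerConfig(), _trials_spec(5))

    def test_trigger_ignores_rs_units(self, small_bank):
        # perturbing spikes of non-FS clusters leaves the TrialTable unchanged
        rng = np.random.default_rng(3)
        trains = _poisson_trains(15.0, 3, 60.0, 4)
        out1 = _sorted_from_trains(trains)
        trains_perturbed = dict(trains)
        trains_perturbed[2] = (np.sort(rng.uniform(0, 60.0, 500)) * FS).astype(np.int64)
        out2 = _sorted_from_trains(trains_perturbed)
        cfg = TriggerConfig()
        spec = _trials_spec(12)
        t1 = run_trigger_session(out1, small_bank, [0, 1], cfg, spec, seed=7)
        t2 = run_trigger_session(out2, small_bank, [0, 1], cfg, spec, seed=7)
        pd.testing.assert_frame_equal(t1, t2)


class TestAnalyzePrestim:
    def test_normalized_response_arithmetic(self):
        onsets = (np.arange(10) * 2.0 + 5.0) * FS
        spikes = []
        for o in onsets:
            spikes.append(o - 0.05 * FS)  # 1 spike / 100 ms pre -> 10 Hz
            spikes.extend(o + np.array([0.1, 0.15, 0.2, 0.22]) * FS)  # 4 / 200 ms -> 20 Hz
        trains = {0: np.sort(np.asarray(spikes)).astype(np.int64)}
        trials = pd.DataFrame(
            {
                "onset_sample": onsets.astype(np.int64),
                "condition": ["triggered"] * 5 + ["non_triggered"] * 5,
                "direction_deg": 0.0,
            }
        )
        classes = [WaveformClass(unit_id=0, trough_to_peak_us=150.0, label="FS")]
        res = analyze_prestim(trains, trials, classes, fs=FS)
        row = res["units"].iloc[0]
        assert row["prestim_hz"] == pytest.approx(10.0)
        assert row["evoked_hz"] == pytest.approx(20.0)
        assert row["normalized"] == pytest.approx(2.0)

    def test_zero_prestim_excluded_from_normalized_only(self):
        onsets = (np.arange(10) * 2.0 + 5.0) * FS
        spikes = np.concatenate([o + np.array([0.1, 0.2]) * FS for o in onsets])
        trains = {0: np.sort(spikes).astype(np.int64)}
        trials = pd.DataFrame(
            {
                "onset_sample": onsets.astype(np.int64),
                "condition": ["triggered"] * 5 + ["non_triggered"] * 5,
                "direction_deg": 0.0,
            }
        )
        classes = [WaveformClass(unit_id=0, trough_to_peak_us=150.0, label="FS")]
        res = analyze_prestim(trains, trials, classes, fs=FS)
        row = res["units"].iloc[0]
        assert row["evoked_hz"] > 0
        assert np.isnan(row["normalized"])

    def test_identical_conditions_show_no_effect(self):
        rng = np.random.default_rng(5)
        onsets = (np.arange(40) * 2.0 + 5.0) * FS
        spikes = np.sort(rng.uniform(0, 90.0, 2000) * FS).astype(np.int64)
        trains = {0: spikes}
        trials = pd.DataFrame(
            {
                "onset_sample": onsets.astype(np.int64),
                "condition": ["triggered", "non_triggered"] * 20,
                "direction_deg": 0.0,
            }
        )
        classes = [WaveformClass(unit_id=0, trough_to_peak_us=150.0, label="FS")]
        res = analyze_prestim(trains, trials, classes, fs=FS)
        p = res["contrasts"]["fs_pre_triggered_vs_non_triggered"]["p_value"]
        assert p > 0.05

    def test_too_few_trials_rejected(self):
        trials = pd.DataFrame(
            {
                "onset_sample": [100000, 200000],
                "condition": ["triggered", "non_triggered"],
                "direction_deg": 0.0,
            }
        )
        classes = [WaveformClass(unit_id=0, trough_to_peak_us=150.0, label="FS")]
        with pytest.raises(ValueError, match="trials"):
            analyze_prestim({0: np.array([1000])}, trials, classes, fs=FS)
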