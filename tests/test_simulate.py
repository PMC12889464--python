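import numpy as np
import pytest

from livesort.simulate import (
    ClippingError,
    StateParams,
    make_probe,
    make_templates,
    make_trials,
    make_units,
    render_recording,
    simulate_state_session,
    simulate_trains,
    trough_to_peak_us,
    von_mises_rate,
)


class TestTemplates:
    def test_width_150us_is_4_to_5_samples(self):
        geom = make_probe(8)
        tpl, peaks, _ = make_templates(
            geom, 1, seed=0, widths_us=np.array([150.0]), fs=30000.0
        )
        w = tpl[0, :, peaks[0]]
        trough = np.argmin(w)
        peak = trough + 1 + np.argmax(w[trough + 1 :])
        assert 4 <= peak - trough <= 5

    def test_amplitude_strictly_decreases_with_distance(self):
        geom = make_probe(16)
        tpl, peaks, _ = make_templates(geom, 1, seed=2)
        amp = np.abs(tpl[0]).max(axis=0)
        d = geom.distances_from(int(peaks[0]))
        order = np.argsort(d)
        for i, j in zip(order[:-1], order[1:]):
            if d[j] > d[i]:
                assert amp[j] < amp[i]

    def test_seed_determinism(self):
        geom = make_probe(8)
        a = make_templates(geom, 3, seed=5)[0]
        b = make_templates(geom, 3, seed=5)[0]
        assert np.array_equal(a, b)

    def test_too_many_units_rejected(self):
        with pytest.raises(ValueError, match="density"):
            make_templates(make_probe(4), 5, seed=0)

    def test_trough_to_peak_monophasic_is_nan(self):
        tpl = np.zeros((21, 2))
        tpl[10, 0] = -5.0  # pure trough, no positive peak after
        assert np.isnan(trough_to_peak_us(tpl, 30000.0))


class TestTrains:
    def test_poisson_count_and_refractory(self):
        geom = make_probe(4)
        units = make_units(geom, 1, seed=0, rate_range_hz=(10.0, 10.0), depth=0.0)
        gt = simulate_trains(units, 100.0, None, seed=1, geometry=geom)
        n = len(gt.spikes[0])
        assert abs(n - 1000) < 5 * np.sqrt(1000)
        ref_samples = int(round(units[0].refractory_ms * 30))
        assert np.diff(gt.spikes[0]).min() >= ref_samples

    def test_zero_concentration_is_direction_independent(self):
        rates = von_mises_rate(np.arange(0, 360, 30), pref_deg=90.0, kappa=0.0, depth=2.0)
        assert np.allclose(rates, 3.0)

    def test_tuning_peak_matches_preferred_direction(self):
        # oracle = the generating rate function: with depth 2 and kappa 4 the
        # empirical tuning curve must peak at the preferred direction
        geom = make_probe(4)
        units = make_units(
            geom, 1, seed=3, rate_range_hz=(20.0, 20.0), kappa=4.0, depth=2.0
        )
        pref = units[0].tuning[0]
        trials = make_trials(120, seed=4)
        dur = trials["onset_sample"].max() / 30000.0 + 1.0
        gt = simulate_trains(units, dur, trials, seed=5, geometry=geom)
        t = gt.spikes[0]
        fs = gt.fs
        dirs = np.arange(0, 360, 30)
        counts = []
        for d in dirs:
            onsets = trials.loc[trials["direction_deg"] == d, "onset_sample"]
            c = sum(
                np.count_nonzero((t >= o) & (t < o + 0.25 * fs)) for o in onsets
            ) / len(onsets)
            counts.append(c)
        peak_dir = dirs[int(np.argmax(counts))]
        delta = abs((peak_dir - pref + 180) % 360 - 180)
        assert delta <= 30

    def test_determinism(self):
        geom = make_probe(4)
        units = make_units(geom, 2, seed=0)
        a = simulate_trains(units, 10.0, None, seed=9, geometry=geom)
        b = simulate_trains(units, 10.0, None, seed=9, geometry=geom)
        for sa, sb in zip(a.spikes, b.spikes):
            assert np.array_equal(sa, sb)


class TestRender:
    def test_zero_noise_is_exact_superposition(self):
        geom = make_probe(8)
        units = make_units(geom, 1, seed=0)
        gt = simulate_trains(units, 2.0, None, seed=1, geometry=geom)
        rec = render_recording(gt, noise_sd_uv=0.0, amp_jitter=0.0, seed=2, quantize=False)
        t = gt.spikes[0][0]
        # pick a spike isolated from its neighbors
        for t in gt.spikes[0]:
            if np.min(np.abs(gt.spikes[0][gt.spikes[0] != t] - t)) > 200:
                break
        seg = rec.data[t - 30 : t + 31]
        assert np.allclose(seg, units[0].template)

    def test_noise_sd_calibration(self):
        geom = make_probe(4)
        units = make_units(geom, 1, seed=0)
        gt = simulate_trains(units, 60.0, None, seed=1, geometry=geom)
        gt.spikes = [np.empty(0, dtype=np.int64)]  # noise only
        rec = render_recording(gt, noise_sd_uv=5.0, amp_jitter=0.0, seed=3)
        sd_uv = rec.data.std(axis=0) * rec.gain
        assert np.all(np.abs(sd_uv - 5.0) / 5.0 < 0.05)

    def test_overlapping_spikes_superpose_linearly(self):
        geom = make_probe(8)
        units = make_units(geom, 2, seed=0)
        from livesort.simulate import GroundTruth
        import pandas as pd

        gt = GroundTruth(
            units=units,
            spikes=[np.array([1000]), np.array([1020])],
            trials=pd.DataFrame(columns=["onset_sample", "direction_deg", "condition"]),
            fs=30000.0,
            duration_samples=3000,
            geometry=geom,
        )
        rec = render_recording(gt, noise_sd_uv=0.0, amp_jitter=0.0, seed=0, quantize=False)
        expected = np.zeros((3000, 8))
        expected[970:1031] += units[0].template
        expected[990:1051] += units[1].template
        assert np.allclose(rec.data, expected)

    def test_clipping_raises(self):
        geom = make_probe(4)
        units = make_units(geom, 1, seed=0)
        gt = simulate_trains(units, 1.0, None, seed=1, geometry=geom)
        with pytest.raises(ClippingError):
            render_recording(gt, noise_sd_uv=0.0, amp_jitter=0.0, seed=0, gain_uv=1e-4)


class TestStateSession:
    def test_fixed_gain_matches_plain_trains(self):
        geom = make_probe(4)
        units = make_units(geom, 2, seed=0, widths_us=np.array([150.0, 300.0]),
                           rate_range_hz=(10.0, 10.0), depth=0.0)
        params = StateParams(gain_low=1.0, gain_high=1.0)
        gt = simulate_state_session(units, params, seed=1, duration_s=100.0, geometry=geom)
        plain = simulate_trains(units, 100.0, None, seed=2, geometry=geom)
        for s_state, s_plain in zip(gt.spikes, plain.spikes):
            # same rate process distributionally: counts within 5 SD
            assert abs(len(s_state) - len(s_plain)) < 5 * np.sqrt(len(s_plain))

    def test_two_state_rates_follow_latent_trace(self):
        # oracle = direct rate computation from the latent trace
        geom = make_probe(4)
        units = make_units(geom, 1, seed=0, widths_us=np.array([150.0]),
                           rate_range_hz=(20.0, 20.0), depth=0.0)
        params = StateParams(gain_low=1.0, gain_high=3.0, mean_dwell_s=1.0)
        gt = simulate_state_session(units, params, seed=5, duration_s=300.0, geometry=geom)
        edges = np.append(gt.state["edges_s"], 300.0)
        gains = gt.state["gains"]
        t = gt.spikes[0] / gt.fs
        rates = {1.0: [0.0, 0.0], 3.0: [0.0, 0.0]}  # [spikes, seconds]
        for lo, hi, g in zip(edges[:-1], edges[1:], gains):
            rates[g][0] += np.count_nonzero((t >= lo) & (t < hi))
            rates[g][1] += hi - lo
        r_low = rates[1.0][0] / rates[1.0][1]
        r_high = rates[3.0][0] / rates[3.0][1]
        assert r_high / r_low == pytest.approx(3.0, rel=0.2)

    def test_seed_reproducibility(self):
        geom = make_probe(4)
        units = make_units(geom, 2, seed=0, widths_us=np.array([150.0, 300.0]))
        a = simulate_state_session(units, StateParams(), seed=3, duration_s=20.0, geometry=geom)
        b = simulate_state_session(units, StateParams(), seed=3, duration_s=20.0, geometry=geom)
        assert np.array_equal(a.state["edges_s"], b.state["edges_s"])
        for sa, sb in zip(a.spikes, b.spikes):
            assert np.array_equal(sa, sb)


def test_trial_structure_timing():
    trials = make_trials(5, seed=0, fs=30000.0, start_s=1.0)
    assert len(trials) == 15  # 3 stimuli per trial
    onsets = trials["onset_sample"].to_numpy() / 30000.0
    gaps = np.diff(onsets[:3])
    assert np.allclose(gaps, 0.4)  # 0.25 s stimulus + 0.15 s ISI
    dirs, counts = np.unique(trials["direction_deg"], return_counts=True)
    assert set(dirs) <= set(range(0, 360, 30))
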