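"""Synthetic-data generator: stimulus, templates, LNP spikes, raw traces, light."""

import numpy as np
import pytest
from scipy import signal, stats

import erflnp as E
from erflnp.synthetic import _reflect_steps, default_spike_template

from conftest import cosine


class TestReflectedWalk:
    @pytest.mark.parametrize("steps, limit, expected", [
        ([0.5, 0.5], 10.0, [0.5, 1.0]),          # no reflection
        ([9.0, 2.0], 10.0, [9.0, 7.0]),          # second step reflected
        ([-9.0, -2.0], 10.0, [-9.0, -7.0]),      # symmetric case
    ])
    def test_hand_examples(self, steps, limit, expected):
        np.testing.assert_allclose(_reflect_steps(np.array(steps), limit), expected)

    def test_matches_scalar_oracle_and_stays_bounded(self):
        rng = np.random.default_rng(7)
        steps = rng.standard_normal(50_000)
        walk = _reflect_steps(steps, 10.0)
        # independent one-line scalar oracle
        total, oracle = 0.0, np.empty(50_000)
        for i, s in enumerate(steps):
            s = -s if abs(total + s) > 10.0 else s
            total = np.clip(total + s, -10.0, 10.0)
            oracle[i] = total
        np.testing.assert_array_equal(walk, oracle)
        assert np.max(np.abs(walk)) <= 10.0

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            E.generate_reflected_walk(0, 10.0, 0)
        with pytest.raises(ValueError):
            E.generate_reflected_walk(10, -1.0, 0)


class TestStimulus:
    def test_default_length_and_voltage_limits(self, stimulus, voltage_command):
        assert stimulus.n_samples == 50_000
        assert voltage_command.volts.min() >= 0.0
        assert voltage_command.volts.max() <= 2.5

    def test_determinism(self):
        a, _ = E.generate_stimulus(E.StimulusConfig(seed=3))
        b, _ = E.generate_stimulus(E.StimulusConfig(seed=3))
        c, _ = E.generate_stimulus(E.StimulusConfig(seed=4))
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_current_integrates_to_voltage_command(self):
        cfg = E.StimulusConfig(seed=5)
        stim, cmd = E.generate_stimulus(cfg)
        rebuilt = np.cumsum(stim.raw_current() / cfg.sampling_rate) + cmd.volts[0]
        assert np.max(np.abs(rebuilt - cmd.volts)) < 1e-9

    def test_psd_flat_then_drops(self):
        """Median PSD above the cutoff is far below the passband, every seed."""
        for seed in range(100):
            stim, _ = E.generate_stimulus(E.StimulusConfig(seed=seed))
            f, p = signal.welch(stim.samples, fs=stim.sampling_rate, nperseg=4096)
            passband = np.median(p[(f >= 10) & (f <= 90)])
            stopband = np.median(p[(f >= 110) & (f <= 500)])
            assert stopband < 0.10 * passband

    def test_standardized(self, stimulus):
        assert abs(stimulus.samples.mean()) < 1e-12
        assert abs(stimulus.samples.std() - 1.0) < 1e-12

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            E.StimulusConfig(cutoff=6000.0)


class TestTemplateFilters:
    def test_monophasic_negative_peak_position(self):
        filt = E.make_template_filter("monophasic_negative", peak_latency=-3.7)
        assert abs(E.TAP_TIMES_MS[np.argmin(filt.taps)] - (-3.7)) <= 0.1

    def test_zero_amplitude_gives_zero_filter(self):
        filt = E.make_template_filter("biphasic", amplitude=0.0)
        np.testing.assert_array_equal(filt.taps, 0.0)

    def test_biphasic_lobes_and_zero_crossing(self):
        filt = E.make_template_filter("biphasic")
        t = E.TAP_TIMES_MS
        i_pos, i_neg = np.argmax(filt.taps), np.argmin(filt.taps)
        assert t[i_pos] < t[i_neg]          # positive lobe precedes negative
        assert abs(t[i_pos] - (-5.2)) <= 0.3
        assert abs(t[i_neg] - 0.2) <= 0.3
        seg = filt.taps[i_pos:i_neg + 1]
        assert np.any(np.diff(np.sign(seg[seg != 0])) != 0)  # crossing between

    def test_latency_outside_window_rejected(self):
        with pytest.raises(ValueError):
            E.make_template_filter("monophasic_negative", peak_latency=-25.0)


class TestLNPSimulation:
    def test_constant_half_probability(self, stimulus):
        neuron = E.GroundTruthNeuron(
            E.LinearFilter(np.zeros(300)), E.Sigmoid(y_max=1, g=1, x0=0, y_min=0))
        trains = E.simulate_lnp_spikes(neuron, stimulus, n_repetitions=1, seed=0)
        n_bins = 4971
        frac = trains[0].n_spikes / n_bins
        ci = 3 * np.sqrt(0.25 / n_bins)
        assert abs(frac - 0.5) < ci

    def test_zero_nonlinearity_never_spikes(self, stimulus):
        neuron = E.GroundTruthNeuron(
            E.LinearFilter(np.zeros(300)), E.Sigmoid(y_max=0, g=1, x0=0, y_min=0))
        trains = E.simulate_lnp_spikes(neuron, stimulus, n_repetitions=3, seed=0)
        assert all(tr.n_spikes == 0 for tr in trains)

    def test_probability_outside_unit_interval_rejected(self, stimulus):
        neuron = E.GroundTruthNeuron(
            E.LinearFilter(np.zeros(300)), E.Sigmoid(y_max=3.0, g=1, x0=0))
        with pytest.raises(ValueError):
            E.simulate_lnp_spikes(neuron, stimulus, seed=0)

    def test_constant_rate_total_count_is_binomial(self, stimulus):
        """Total spikes over bins x reps follow Binomial(BR, p): exact test."""
        p = 0.05
        neuron = E.GroundTruthNeuron(
            E.LinearFilter(np.zeros(300)), E.Sigmoid(y_max=0, g=1, x0=0, y_min=p))
        failures = 0
        for seed in range(30):
            trains = E.simulate_lnp_spikes(neuron, stimulus, n_repetitions=2,
                                           seed=seed)
            total = sum(tr.n_spikes for tr in trains)
            pval = stats.binomtest(total, 2 * 4971, p).pvalue
            failures += pval < 0.001
        assert failures <= 1

    def test_end_to_end_sta_recovery(self, stimulus, biphasic_neuron,
                                     biphasic_trains):
        model = E.fit_sta_model(stimulus, biphasic_trains)
        assert cosine(model.filter.taps, biphasic_neuron.filter.taps) > 0.8


class TestRawRecording:
    def test_template_only_insertion(self, stimulus):
        spikes = E.SpikeTrain(np.array([1.0]))
        raw = E.synthesize_raw_recording(stimulus, spikes, artefact_gain=0.0,
                                         noise_sd=0.0)
        tmpl = default_spike_template(stimulus.sampling_rate)
        s = int(round(1.0 * stimulus.sampling_rate))
        half = tmpl.size // 2
        np.testing.assert_allclose(raw.samples[s - half:s - half + tmpl.size], tmpl)
        mask = np.ones(raw.samples.size, bool)
        mask[s - half:s - half + tmpl.size] = False
        assert np.all(raw.samples[mask] == 0.0)

    def test_pure_artefact_factor_recovered(self, stimulus):
        raw = E.synthesize_raw_recording(stimulus, E.SpikeTrain(np.array([])),
                                         artefact_gain=2.0, noise_sd=0.0)
        assert E.estimate_artefact_factor(raw, stimulus) == pytest.approx(2.0)

    def test_default_artefact_dominates_spikes(self, stimulus):
        spikes = E.SpikeTrain(np.arange(0.5, 4.5, 0.05))
        raw = E.synthesize_raw_recording(stimulus, spikes, seed=1)
        spike_peak = np.max(np.abs(default_spike_template(1e4)))
        assert np.sqrt(np.mean(raw.samples ** 2)) >= 10 * spike_peak

    def test_out_of_range_spikes_rejected(self, stimulus):
        with pytest.raises(ValueError):
            E.synthesize_raw_recording(stimulus, E.SpikeTrain(np.array([9.0])))


class TestLightResponses:
    def test_pure_on_transient_profile(self):
        trains = E.generate_light_responses("ON", transiency=0.9, n_trials=200,
                                            rate=60.0, seed=0)
        m = E.light_response_metrics(trains, onset_times=[0.0], offset_times=[0.5])
        assert m.bias_index == 1.0
        assert m.polarity_class == "ON"
        assert abs(m.transiency_index - 0.9) < 0.02

    def test_sustained_profile_low_transiency(self):
        trains = E.generate_light_responses("OFF", transiency=0.0, n_trials=400,
                                            rate=80.0, seed=1)
        m = E.light_response_metrics(trains, onset_times=[0.0], offset_times=[0.5])
        assert m.polarity_class == "OFF"
        assert m.transiency_index < 0.1

    def test_on_off_bias_near_zero(self):
        """Symmetric ON-OFF profile: |BI| < 0.25 in >=95% of runs at 50 Hz."""
        hits = 0
        for seed in range(50):
            trains = E.generate_light_responses("ON-OFF", transiency=0.5,
                                                n_trials=10, rate=50.0, seed=seed)
            m = E.bias_index(trains, [0.0], [0.5])
            hits += abs(m.bias_index) < 0.25
        assert hits >= 45

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            E.generate_light_responses("BOTH")
        with pytest.raises(ValueError):
            E.generate_light_responses("ON", transiency=0.95)
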