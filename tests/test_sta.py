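"""Whitened spike-triggered averaging and nonlinearity estimation."""

import numpy as np
import pytest
from scipy import signal, stats

import erflnp as E
from erflnp.sta import NonlinearityEstimate, SnippetEnsemble, WhiteningOperator

from conftest import cosine

FS = 10_000.0


class TestSnippets:
    def test_default_geometry_count(self, stimulus):
        ens = E.extract_snippets(stimulus)
        assert ens.n_snippets == (50_000 - 300) // 10 + 1 == 4971

    def test_single_snippet_equals_stimulus(self):
        x = np.arange(300, dtype=float)
        ens = E.extract_snippets(E.StimulusTrace(x, FS))
        assert ens.n_snippets == 1
        np.testing.assert_array_equal(ens.snippets[0], x)

    def test_non_overlapping_stride(self):
        x = np.arange(600, dtype=float)
        ens = E.extract_snippets(E.StimulusTrace(x, FS), stride=300)
        assert ens.n_snippets == 2
        np.testing.assert_array_equal(ens.snippets[1], x[300:])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            E.extract_snippets(E.StimulusTrace(np.zeros(100), FS))


class TestWhiteningOperator:
    def test_white_input_gives_identity(self):
        rng = np.random.default_rng(0)
        ens = SnippetEnsemble(rng.standard_normal((20_000, 30)), stride=0)
        op = E.compute_whitening_operator(ens)
        off = op.matrix - np.diag(np.diag(op.matrix))
        assert np.max(np.abs(off)) < 0.05
        assert np.allclose(np.diag(op.matrix), 1.0, atol=0.05)

    def test_diagonal_covariance_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200_000, 3)) * np.array([2.0, 1.0, 1.0])
        op = E.compute_whitening_operator(SnippetEnsemble(X, stride=0))
        np.testing.assert_allclose(op.matrix, np.diag([0.5, 1.0, 1.0]), atol=0.02)

    def test_whitened_covariance_near_identity_on_retained_modes(
            self, stimulus, whitened_bundle):
        ens, op, _ = whitened_bundle
        white = ens.snippets @ op.matrix.T
        lam = np.linalg.eigvalsh(np.cov(white, rowvar=False))[::-1]
        assert np.all(np.abs(lam[:op.rank] - 1.0) < 0.05)

    def test_zero_ensemble_rejected(self):
        with pytest.raises(ValueError):
            E.compute_whitening_operator(SnippetEnsemble(np.zeros((10, 5))))


class TestWhitenedStimulus:
    def test_identity_operator_partition_of_unity(self, stimulus):
        op = WhiteningOperator(np.eye(300), 300, np.ones(300))
        out = E.whiten_stimulus(stimulus, op)
        assert np.max(np.abs(out.samples - stimulus.samples)) < 1e-9

    def test_autocorrelation_collapses(self, stimulus, whitened_bundle):
        _, _, white = whitened_bundle

        def acf(x, lags):
            x = x - x.mean()
            return np.array([np.corrcoef(x[:-l], x[l:])[0, 1] for l in lags])

        lags = np.arange(1, 21) * 10  # 1..20 ms
        assert acf(stimulus.samples, [10])[0] > 0.5
        assert np.max(np.abs(acf(white.samples, lags))) < 0.2

    def test_psd_flattened(self, stimulus, whitened_bundle):
        _, _, white = whitened_bundle
        f, p = signal.welch(white.samples, fs=FS, nperseg=4096)
        passband = np.median(p[(f >= 10) & (f <= 90)])
        above = np.median(p[(f >= 110) & (f <= 500)])
        assert above > passband / 3
        assert above < passband * 3

    def test_near_idempotent(self, stimulus, whitened_bundle):
        """Whitening an already-whitened stimulus barely changes it.

        The second operator is computed from the whitened ensemble; its
        retention floor (1e-2) keeps the unit-variance whitened modes and
        drops the tiny edge-taper leakage modes, so it acts as an
        (approximate) projector rather than re-amplifying leakage.
        """
        _, _, white = whitened_bundle
        op2 = E.compute_whitening_operator(E.extract_snippets(white),
                                           retention=1e-2)
        twice = E.whiten_stimulus(white, op2)
        delta = np.sqrt(np.mean((twice.samples - white.samples) ** 2))
        once = np.sqrt(np.mean((white.samples - stimulus.samples) ** 2))
        assert delta < 0.1 * once

    def test_geometry_mismatch_rejected(self, stimulus):
        op = WhiteningOperator(np.eye(100), 100, np.ones(100))
        with pytest.raises(ValueError):
            E.whiten_stimulus(stimulus, op)


class TestSTA:
    def test_matches_scalar_double_loop_oracle(self, whitened_bundle):
        _, _, white = whitened_bundle
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0.05, 4.9, 40))
        sta = E.compute_sta(white, E.SpikeTrain(times))
        x = white.samples
        oracle = np.zeros(300)
        for t in times:
            s = int(round(t * FS))
            for j in range(300):
                oracle[j] += x[s - 200 + j]
        oracle /= times.size
        assert np.max(np.abs(sta.taps - oracle)) < 1e-12

    def test_single_spike_returns_its_snippet(self, whitened_bundle):
        _, _, white = whitened_bundle
        sta = E.compute_sta(white, E.SpikeTrain(np.array([1.0])))
        s = int(round(1.0 * FS))
        np.testing.assert_array_equal(sta.taps, white.samples[s - 200:s + 100])

    def test_unconditioned_average_vanishes(self, whitened_bundle):
        _, _, white = whitened_bundle
        # a spike in every 1 ms bin: the STA degenerates to an
        # unconditioned mean of (near-)white noise
        times = np.arange(200, 49_900, 10) / FS
        sta = E.compute_sta(white, E.SpikeTrain(times))
        sigma = white.samples.std()
        assert np.max(np.abs(sta.taps)) < 3 * sigma / np.sqrt(times.size) * 5

    def test_no_usable_spikes_rejected(self, whitened_bundle):
        _, _, white = whitened_bundle
        with pytest.raises(ValueError):
            E.compute_sta(white, E.SpikeTrain(np.array([0.001])))

    def test_recovers_planted_filter(self, stimulus, biphasic_neuron,
                                     biphasic_trains):
        model = E.fit_sta_model(stimulus, biphasic_trains)
        assert cosine(model.filter.taps, biphasic_neuron.filter.taps) > 0.8


class TestNonlinearityEstimate:
    def test_ste_equal_fe_gives_flat_ratio(self, whitened_bundle):
        ens, _, white = whitened_bundle
        filt = E.LinearFilter(np.ones(300))
        fe = E.extract_snippets(white, stride=10)
        est = E.estimate_nonlinearity(filt, fe, fe)
        assert np.allclose(est.ratio[est.mask], 1.0)

    def test_threshold_construction(self, whitened_bundle):
        _, _, white = whitened_bundle
        rng = np.random.default_rng(3)
        filt = E.LinearFilter(rng.standard_normal(300))
        fe = E.extract_snippets(white, stride=10)
        proj = fe.snippets @ filt.taps
        top = np.quantile(proj, 0.9)
        ste = SnippetEnsemble(fe.snippets[proj >= top], stride=0)
        est = E.estimate_nonlinearity(filt, fe, ste)
        low = est.bin_centers < np.quantile(proj, 0.5)
        assert np.all(est.ratio[est.mask & low] == 0.0)
        assert np.any(est.ratio[est.mask & ~low] > 0)

    def test_empty_ste_rejected(self, whitened_bundle):
        _, _, white = whitened_bundle
        fe = E.extract_snippets(white, stride=10)
        with pytest.raises(ValueError):
            E.estimate_nonlinearity(E.LinearFilter(np.ones(300)), fe,
                                    SnippetEnsemble(np.empty((0, 300))))

    def test_recovers_sigmoid_shape(self, stimulus, biphasic_neuron,
                                    biphasic_trains):
        model = E.fit_sta_model(stimulus, biphasic_trains)
        est = model.nonlinearity_estimate
        x = est.bin_centers[est.mask]
        y = est.ratio[est.mask]
        # the true nonlinearity evaluated on a matching projection axis must
        # rank-correlate with the histogram ratio
        true_scaled = biphasic_neuron.nonlinearity(
            x / np.linalg.norm(model.filter.taps)
            * np.linalg.norm(biphasic_neuron.filter.taps))
        rho = stats.spearmanr(y, true_scaled).statistic
        assert rho > 0.9


class TestNonlinearityFit:
    def test_noiseless_sigmoid_self_consistency(self):
        x = np.linspace(-3, 3, 25)
        truth = E.Sigmoid(y_max=1.0, g=2.0, x0=0.0, y_min=0.0)
        est = NonlinearityEstimate(x, truth(x), np.ones(25, bool))
        est = E.fit_nonlinearity(est, kind="sigmoid")
        for name, val in truth.params().items():
            assert est.params[name] == pytest.approx(val, abs=0.01)

    def test_constant_ratio_degenerates_gracefully(self):
        x = np.linspace(-2, 2, 25)
        est = NonlinearityEstimate(x, np.full(25, 0.3), np.ones(25, bool))
        est = E.fit_nonlinearity(est, kind="sigmoid")
        fitted = est.fitted()(x)
        assert np.max(np.abs(fitted - 0.3)) < 1e-6
        assert est.fit_residual < 1e-10

    def test_noisy_threshold_recovered_across_seeds(self):
        x = np.linspace(-3, 3, 25)
        truth = E.Sigmoid(y_max=1.0, g=2.0, x0=0.4, y_min=0.05)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = truth(x) + 0.05 * rng.standard_normal(25)
            est = E.fit_nonlinearity(
                NonlinearityEstimate(x, y, np.ones(25, bool)), kind="sigmoid")
            errs.append(abs(est.params["x0"] - 0.4))
        assert np.median(errs) < 0.2  # input SD is 1 on this axis

    def test_too_few_bins_rejected(self):
        est = NonlinearityEstimate(np.arange(4.0), np.arange(4.0),
                                   np.ones(4, bool))
        with pytest.raises(ValueError):
            E.fit_nonlinearity(est)
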