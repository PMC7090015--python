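"""Synthetic inputs with known ground truth.

Everything the downstream pipeline consumes can be generated here:

* the smooth electrical Gaussian-noise stimulus (reflected random walk,
  100 Hz low-pass, rescaled to a 0--2.5 V capacitive voltage command),
* template temporal filters for the three archetypes seen in wild-type
  retina (monophasic negative, monophasic positive, biphasic),
* Bernoulli spike trains from a ground-truth LNP cell,
* artefact-dominated raw traces (stimulation artefact orders of magnitude
  larger than the spikes), and
* light-flash responses with controlled polarity and transiency.

All randomness flows through explicit integer seeds; one master seed is
expanded into per-component child seeds with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import (
    BIN_MS,
    FILTER_LEN,
    POST_SAMPLES,
    PRE_SAMPLES,
    TAP_TIMES_MS,
    GroundTruthNeuron,
    LinearFilter,
    RawTrace,
    Sigmoid,
    SpikeTrain,
    StimulusConfig,
    StimulusTrace,
    VoltageCommand,
)

__all__ = [
    "generate_reflected_walk",
    "generate_stimulus",
    "make_template_filter",
    "make_archetype_neuron",
    "simulate_lnp_spikes",
    "default_spike_template",
    "synthesize_raw_recording",
    "generate_light_responses",
]

FILTER_CLASSES = ("monophasic_negative", "monophasic_positive", "biphasic")


def generate_reflected_walk(n_samples: int, reflect_limit: float = 10.0,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Cumulative sum of standard-normal steps with a reflecting boundary.

    Whenever adding a step would push the absolute value of the running sum
    above ``reflect_limit`` the step's sign is inverted before adding. If
    (pathologically) the inverted step would also violate the limit, the sum
    is clamped to ``+/- reflect_limit``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if reflect_limit <= 0:
        raise ValueError("reflect_limit must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.standard_normal(n_samples)
    return _reflect_steps(steps, reflect_limit)


def _reflect_steps(steps: np.ndarray, reflect_limit: float) -> np.ndarray:
    """Apply the reflection rule to a given step sequence (testable core)."""
    walk = np.empty(steps.size)
    total = 0.0
    for i, step in enumerate(steps):
        if abs(total + step) > reflect_limit:
            step = -step
        total += step
        if abs(total) > reflect_limit:  # double violation: clamp
            total = np.sign(total) * reflect_limit
        walk[i] = total
    return walk


def generate_stimulus(config: StimulusConfig | None = None,
                      capacitance_scale: float = 1.0,
                      ) -> tuple[StimulusTrace, VoltageCommand]:
    """Generate the stimulus trace and its paired voltage command.

    Pipeline: reflected random walk -> causal Butterworth low-pass
    (``config.cutoff`` Hz, ``config.filter_order``) -> affine rescale into
    ``config.voltage_range`` = voltage command.  The current-proportional
    stimulus trace is the discrete first difference of the command times
    the sampling rate and capacitance, standardized to zero mean / unit SD
    (the affine constants are kept in ``StimulusTrace.standardization``).
    """
    config = config or StimulusConfig()
    walk = generate_reflected_walk(config.n_samples, config.reflect_limit, config.seed)
    nyq = config.sampling_rate / 2.0
    if config.cutoff >= nyq:
        raise ValueError("cutoff must be below Nyquist")
    sos = signal.butter(config.filter_order, config.cutoff,
                        btype="low", fs=config.sampling_rate, output="sos")
    smooth = signal.sosfilt(sos, walk)  # single causal pass
    lo, hi = config.voltage_range
    span = smooth.max() - smooth.min()
    if span == 0:
        volts = np.full_like(smooth, (lo + hi) / 2.0)
    else:
        volts = lo + (smooth - smooth.min()) * (hi - lo) / span
    command = VoltageCommand(volts, config.sampling_rate, capacitance_scale)
    current = np.diff(volts, prepend=volts[0]) * config.sampling_rate * capacitance_scale
    mean, sd = float(current.mean()), float(current.std())
    if sd == 0:
        raise ValueError("degenerate stimulus: zero variance current")
    trace = StimulusTrace((current - mean) / sd, config.sampling_rate,
                          standardization=(mean, sd))
    return trace, command


# ---------------------------------------------------------------------------
# template filters and LNP cells


def _gauss(t_ms: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center_ms) / sigma_ms) ** 2)


def make_template_filter(filter_class: str,
                         peak_latency: float | None = None,
                         width: float = 2.0,
                         amplitude: float = 1.0,
                         second_latency: float | None = None) -> LinearFilter:
    """Parametric stand-in for the three empirical filter archetypes.

    Latency defaults follow the median peak latencies of recorded cells:
    monophasic negative peaks -3.7 ms before the spike, monophasic positive
    -4.7 ms, and the biphasic shape has a positive lobe at -5.2 ms followed
    by a negative lobe at +0.2 ms.  ``width`` is the Gaussian sigma of each
    lobe in ms; latencies must lie inside the -20 ... +10 ms filter window.
    """
    if filter_class not in FILTER_CLASSES:
        raise ValueError(f"unknown filter_class {filter_class!r}")
    t = TAP_TIMES_MS
    defaults = {"monophasic_negative": -3.7, "monophasic_positive": -4.7,
                "biphasic": -5.2}
    lat = defaults[filter_class] if peak_latency is None else float(peak_latency)
    if not (t[0] <= lat <= t[-1]):
        raise ValueError("peak latency outside the -20...+10 ms filter window")
    if filter_class == "monophasic_negative":
        taps = -amplitude * _gauss(t, lat, width)
    elif filter_class == "monophasic_positive":
        taps = amplitude * _gauss(t, lat, width)
    else:
        lat2 = 0.2 if second_latency is None else float(second_latency)
        if not (t[0] <= lat2 <= t[-1]):
            raise ValueError("second latency outside the filter window")
        if lat >= lat2:
            raise ValueError("biphasic positive lobe must precede the negative lobe")
        taps = amplitude * (_gauss(t, lat, width) - _gauss(t, lat2, max(width * 0.6, 0.8)))
    return LinearFilter(taps, method="template")


def make_archetype_neuron(filter_class: str,
                          stimulus: StimulusTrace | None = None,
                          target_rate: float = 40.0,
                          amplitude: float = 1.5,
                          y_max: float = 0.3,
                          gain: float = 2.0,
                          cell_id: str | None = None) -> GroundTruthNeuron:
    """Ground-truth LNP cell for one archetype, calibrated to a firing rate.

    The sigmoid threshold ``x0`` is placed analytically from the SD of the
    filter projections of ``stimulus`` (if given) so the mean Bernoulli
    probability per 1 ms bin approximates ``target_rate`` spikes/s; without a
    stimulus a unit-SD projection is assumed.
    """
    filt = make_template_filter(filter_class, amplitude=amplitude)
    # normalize filter so projections of a unit-variance stimulus have a
    # predictable scale, then restore the requested amplitude
    if stimulus is not None:
        proj = _snippet_projections(stimulus, filt.taps)
        sd = float(proj.std()) or 1.0
    else:
        sd = float(np.linalg.norm(filt.taps))
    p_target = min(target_rate * BIN_MS / 1000.0, 0.45)
    g = gain / sd
    x0 = _calibrate_sigmoid_x0(sd, g, y_max, p_target)
    nl = Sigmoid(y_max=y_max, g=g, x0=x0, y_min=0.0)
    return GroundTruthNeuron(filt, nl, filter_class=filter_class,
                             target_rate=target_rate,
                             cell_id=cell_id or filter_class)


def _calibrate_sigmoid_x0(proj_sd: float, g: float, y_max: float,
                          p_target: float) -> float:
    """Pick x0 so E[sigmoid(N(0, sd^2))] = p_target, via bisection."""
    x = np.linspace(-6 * proj_sd, 6 * proj_sd, 2001)
    w = np.exp(-0.5 * (x / proj_sd) ** 2)
    w /= w.sum()

    def mean_rate(x0: float) -> float:
        return float(np.sum(w * y_max / (1.0 + np.exp(-g * (x - x0)))))

    lo, hi = -10 * proj_sd, 10 * proj_sd
    if p_target >= y_max:
        raise ValueError("target rate not reachable with given y_max")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) > p_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _snippet_projections(stimulus: StimulusTrace, taps: np.ndarray) -> np.ndarray:
    """Filter response at every valid 1-ms bin anchor (vectorized)."""
    stride = int(round(stimulus.sampling_rate * BIN_MS / 1000.0))
    x = stimulus.samples
    if x.size < FILTER_LEN:
        raise ValueError("stimulus shorter than one snippet")
    windows = np.lib.stride_tricks.sliding_window_view(x, FILTER_LEN)[::stride]
    return windows @ taps


def valid_bins(n_samples: int, sampling_rate: float = 10_000.0) -> tuple[int, int]:
    """Half-open range of 1-ms bin indices whose snippet lies inside the trace.

    Bin ``t`` is anchored at sample ``10 t`` (its start) and uses samples
    ``[10t - 200, 10t + 100)``.
    """
    stride = int(round(sampling_rate * BIN_MS / 1000.0))
    n_bins = n_samples // stride
    first = int(np.ceil(PRE_SAMPLES / stride))
    last = min(n_bins, (n_samples - POST_SAMPLES) // stride + 1)
    return first, last


def simulate_lnp_spikes(neuron: GroundTruthNeuron,
                        stimulus: StimulusTrace,
                        bin_ms: float = BIN_MS,
                        n_repetitions: int = 1,
                        seed: int = 0) -> list[SpikeTrain]:
    """Draw Bernoulli spike trains from the ground-truth LNP cell.

    For each 1 ms bin ``t`` the firing probability is
    ``nonlinearity(filter . snippet_t)``; bins whose -20...+10 ms window
    exits the trace produce no spikes.  One independent Bernoulli draw per
    bin per repetition; the spike time is the bin start.
    """
    if bin_ms != BIN_MS:
        raise ValueError("only 1 ms bins are supported")
    proj = _snippet_projections(stimulus, neuron.filter.taps)
    # row i of the sliding ensemble is anchored at sample 10*i, i.e. the
    # snippet covering bins whose start sample is 10*i + PRE_SAMPLES
    mu = np.asarray(neuron.nonlinearity(proj), dtype=float)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("nonlinearity produced probabilities outside [0, 1]")
    first, last = valid_bins(stimulus.n_samples, stimulus.sampling_rate)
    n_valid = last - first
    mu = mu[:n_valid]
    bin_starts = (np.arange(first, last)) * (bin_ms / 1000.0)
    rng = np.random.default_rng(seed)
    trains = []
    for rep in range(n_repetitions):
        fired = rng.random(mu.size) < mu
        trains.append(SpikeTrain(bin_starts[fired], repetition_id=rep,
                                 cell_id=neuron.cell_id))
    return trains


def ground_truth_rate(neuron: GroundTruthNeuron, stimulus: StimulusTrace
                      ) -> np.ndarray:
    """Per-1-ms-bin Bernoulli probability mu_t over the valid bins."""
    proj = _snippet_projections(stimulus, neuron.filter.taps)
    first, last = valid_bins(stimulus.n_samples, stimulus.sampling_rate)
    return np.asarray(neuron.nonlinearity(proj), dtype=float)[: last - first]


# ---------------------------------------------------------------------------
# raw traces with stimulation artefact


def default_spike_template(sampling_rate: float = 10_000.0,
                           amplitude: float = 1.0) -> np.ndarray:
    """Biphasic 1 ms extracellular spike waveform (negative-leading)."""
    n = int(round(sampling_rate / 1000.0))  # 1 ms
    t = np.linspace(-0.5, 0.5, n, endpoint=False)
    w = -t * np.exp(-0.5 * (t / 0.18) ** 2)  # derivative-of-Gaussian
    w = w / np.max(np.abs(w)) * amplitude
    return w


def synthesize_raw_recording(stimulus: StimulusTrace,
                             spikes: SpikeTrain,
                             artefact_gain: float = 50.0,
                             spike_template: np.ndarray | None = None,
                             noise_sd: float = 0.05,
                             seed: int = 0) -> RawTrace:
    """Raw electrode trace: scaled artefact + embedded spikes + noise.

    Defaults put the artefact RMS well over 10x the spike-template peak
    (the regime in which raw spikes are invisible until artefact removal).
    """
    if artefact_gain < 0:
        raise ValueError("artefact_gain must be >= 0")
    fs = stimulus.sampling_rate
    template = (default_spike_template(fs) if spike_template is None
                else np.asarray(spike_template, dtype=float))
    out = artefact_gain * stimulus.samples.copy()
    n = out.size
    if spikes.n_spikes and (spikes.times.min() < 0
                            or spikes.times.max() >= stimulus.duration):
        raise ValueError("spike times outside the stimulus duration")
    half = template.size // 2
    for t in spikes.times:
        s = int(round(t * fs))
        a, b = s - half, s - half + template.size
        ta, tb = max(0, -a), template.size - max(0, b - n)
        out[max(a, 0):min(b, n)] += template[ta:tb]
    if noise_sd > 0:
        out += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return RawTrace(out, fs)


# ---------------------------------------------------------------------------
# light-flash responses


def generate_light_responses(polarity: str = "ON",
                             transiency: float = 0.5,
                             n_trials: int = 5,
                             rate: float = 50.0,
                             seed: int = 0) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson responses to a 1 Hz full-field flash.

    Each trial is one 1 s cycle: light on over [0, 0.5) s, off over
    [0.5, 1.0) s.  The response to the preferred phase(s) follows a
    10-bin (50 ms) rate profile whose expected transiency index equals
    ``transiency``: the first bin has relative rate 1 and the remaining
    nine have relative rate ``c = (10 (1 - transiency) - 1) / 9``.
    ``rate`` is the mean firing rate (Hz) during a preferred 500 ms window.
    """
    if polarity not in ("ON", "OFF", "ON-OFF"):
        raise ValueError("polarity must be ON, OFF or ON-OFF")
    if not 0.0 <= transiency <= 0.9:
        raise ValueError("transiency must lie in [0, 0.9]")
    c = max((10.0 * (1.0 - transiency) - 1.0) / 9.0, 0.0)
    w = np.array([1.0] + [c] * 9)
    lam = rate * w / w.mean()  # per-bin rate in Hz
    onsets = {"ON": [0.0], "OFF": [0.5], "ON-OFF": [0.0, 0.5]}[polarity]
    rng = np.random.default_rng(seed)
    trains = []
    for trial in range(n_trials):
        times = []
        for start in onsets:
            for j in range(10):
                lo = start + 0.05 * j
                k = rng.poisson(lam[j] * 0.05)
                times.extend(lo + 0.05 * rng.random(k))
        trains.append(SpikeTrain(np.sort(np.asarray(times)),
                                 repetition_id=trial, cell_id="light"))
    return trains
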