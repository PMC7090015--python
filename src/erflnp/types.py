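"""Core containers shared across the pipeline.

Conventions used everywhere:

* Stimulus samples run at ``sampling_rate`` (default 10 kHz).
* Spikes are binned at 1 ms; bin ``t`` covers the half-open interval
  ``[t, t+1) ms`` and a spike on a bin edge belongs to the later bin.
* A temporal filter has 300 taps spanning -20 ms ... +9.9 ms relative to
  the spike in 0.1 ms steps (200 samples of past stimulus, 100 of
  "future"); the stimulus snippet paired with spike sample ``a`` is
  ``samples[a-200 : a+100]``.
* Sample indexing is 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: default stimulus sampling rate, Hz
DEFAULT_FS = 10_000.0
#: filter length in stimulus samples (30 ms at 10 kHz)
FILTER_LEN = 300
#: samples of stimulus before the spike included in a snippet (20 ms)
PRE_SAMPLES = 200
#: samples of stimulus after the spike included in a snippet (10 ms)
POST_SAMPLES = 100
#: tap times in ms relative to the spike (negative = before the spike)
TAP_TIMES_MS = (np.arange(FILTER_LEN) - PRE_SAMPLES) / 10.0
#: spike binning resolution for model fitting/prediction, ms
BIN_MS = 1.0


@dataclass
class StimulusConfig:
    """Parameters of the smooth electrical Gaussian-noise stimulus."""

    sampling_rate: float = DEFAULT_FS
    duration: float = 5.0
    reflect_limit: float = 10.0
    cutoff: float = 100.0
    filter_order: int = 5
    voltage_range: tuple[float, float] = (0.0, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.reflect_limit <= 0:
            raise ValueError("reflect_limit must be positive")
        if self.cutoff * 2 >= self.sampling_rate:
            raise ValueError("cutoff must be below the Nyquist frequency")
        lo, hi = self.voltage_range
        if not lo < hi:
            raise ValueError("voltage_range must be an increasing pair")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


@dataclass
class StimulusTrace:
    """Current-proportional stimulus, standardized to zero mean / unit SD.

    ``standardization`` records the affine constants ``(mean, sd)`` of the
    raw (physical-scale) current so the voltage command can be recovered.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_FS
    standardization: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def raw_current(self) -> np.ndarray:
        """Undo the standardization, returning the physical-scale current."""
        if self.standardization is None:
            return self.samples.copy()
        mean, sd = self.standardization
        return self.samples * sd + mean


@dataclass
class VoltageCommand:
    """Voltage applied to the capacitive stimulation electrodes.

    The delivered current density is proportional to dV/dt scaled by the
    specific electrode capacitance, so the command is the (rescaled)
    integral of the desired current.
    """

    volts: np.ndarray
    sampling_rate: float = DEFAULT_FS
    capacitance_scale: float = 1.0

    def __post_init__(self) -> None:
        self.volts = np.asarray(self.volts, dtype=float)


@dataclass
class RawTrace:
    """Recorded electrode signal (spikes buried under the stimulation artefact)."""

    samples: np.ndarray
    sampling_rate: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class SpikeTrain:
    """Sorted spike times of one cell during one stimulus repetition."""

    times: np.ndarray
    repetition_id: int = 0
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted ascending")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class LinearFilter:
    """300-tap temporal filter, -20 ... +10 ms around the spike."""

    taps: np.ndarray
    method: str = "template"
    tap_times_ms: np.ndarray = field(default_factory=lambda: TAP_TIMES_MS.copy())

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.taps.shape != (FILTER_LEN,):
            raise ValueError(f"filter must have exactly {FILTER_LEN} taps")
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("filter taps must be finite")


# ---------------------------------------------------------------------------
# static nonlinearities


@dataclass
class Sigmoid:
    """Saturating nonlinearity y_max / (1 + exp(-g (x - x0))) + y_min."""

    y_max: float = 1.0
    g: float = 1.0
    x0: float = 0.0
    y_min: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.y_max / (1.0 + np.exp(-self.g * (x - self.x0))) + self.y_min

    def params(self) -> dict:
        return {"y_max": self.y_max, "g": self.g, "x0": self.x0, "y_min": self.y_min}


@dataclass
class Exponential:
    """Accelerating nonlinearity a * exp(g x) + y_min."""

    a: float = 1.0
    g: float = 1.0
    y_min: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(self.g * x) + self.y_min

    def params(self) -> dict:
        return {"a": self.a, "g": self.g, "y_min": self.y_min}


@dataclass
class Logistic:
    """Standard logistic link 1 / (1 + exp(-(offset + x))) used by the GLM."""

    offset: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-(self.offset + x)))

    def params(self) -> dict:
        return {"offset": self.offset}


@dataclass
class GroundTruthNeuron:
    """Generative LNP cell with a known filter and nonlinearity.

    ``nonlinearity(filter . snippet)`` is used as a per-1-ms-bin Bernoulli
    spike probability, so its output must stay in [0, 1].
    """

    filter: LinearFilter
    nonlinearity: Sigmoid | Exponential | Logistic
    filter_class: str = "monophasic_negative"
    target_rate: float = 40.0
    cell_id: str = "cell"


@dataclass
class LNPModel:
    """Fitted linear-nonlinear model: filter, static nonlinearity, metadata."""

    filter: LinearFilter
    nonlinearity: Sigmoid | Exponential | Logistic
    method: str = "STA"
    fit_metadata: dict = field(default_factory=dict)

    def firing_probability(self, projections: np.ndarray) -> np.ndarray:
        return self.nonlinearity(projections)


def bin_spikes(spikes: SpikeTrain | list[SpikeTrain], duration: float,
               bin_ms: float = BIN_MS) -> np.ndarray:
    """Bin spike times into counts, summed across repetitions.

    Half-open bins [t, t+bin); a spike exactly at ``duration`` is dropped.
    """
    trains = spikes if isinstance(spikes, list) else [spikes]
    n_bins = int(round(duration * 1000.0 / bin_ms))
    edges = np.arange(n_bins + 1) * (bin_ms / 1000.0)
    counts = np.zeros(n_bins)
    for tr in trains:
        t = tr.times[(tr.times >= 0) & (tr.times < edges[-1])]
        counts += np.histogram(t, bins=edges)[0]
    return counts
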