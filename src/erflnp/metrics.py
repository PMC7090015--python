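"""Response reliability and light-response metrics.

* Reliability Index (RI): mean leave-one-out Pearson correlation between
  the pooled histogram of n-1 repetitions and the held-out repetition's
  histogram (2 ms bins).  Cells with RI > 0.15 count as reliable.
* Bias Index (BI): (R_ON - R_OFF) / (R_ON + R_OFF) of spike counts in the
  300 ms after light onset vs offset, summed across repetitions.  BI < -0.25
  -> OFF, -0.25 <= BI <= 0.5 -> ON-OFF, BI > 0.5 -> ON.
* Transiency Index (TI): 1 minus the mean of the max-normalized 10-bin
  (50 ms) histogram over the 500 ms after the preferred stimulus phase;
  0 = sustained, 0.9 = all spikes in the first bin.  For ON-OFF cells the
  TI is the mean of the ON-phase and OFF-phase TIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SpikeTrain

__all__ = [
    "ReliabilityResult",
    "LightResponseMetrics",
    "reliability_index",
    "classify_reliable",
    "bias_index",
    "transiency_index",
    "light_response_metrics",
]


@dataclass
class ReliabilityResult:
    ri: float
    bin_ms: float = 2.0
    n_repetitions: int = 0
    degenerate: bool = False


@dataclass
class LightResponseMetrics:
    bias_index: float = np.nan
    transiency_index: float = np.nan
    polarity_class: str = "unknown"
    r_on: float = 0.0
    r_off: float = 0.0
    flags: list[str] = field(default_factory=list)


def _histogram(train: SpikeTrain, duration: float, bin_ms: float) -> np.ndarray:
    n_bins = int(round(duration * 1000.0 / bin_ms))
    edges = np.arange(n_bins + 1) * (bin_ms / 1000.0)
    t = train.times[(train.times >= 0) & (train.times < edges[-1])]
    return np.histogram(t, bins=edges)[0].astype(float)


def reliability_index(trials: list[SpikeTrain], duration: float,
                      bin_ms: float = 2.0) -> ReliabilityResult:
    """Mean leave-one-out correlation between pooled and held-out histograms."""
    if len(trials) < 2:
        raise ValueError("reliability needs at least 2 repetitions")
    hists = np.stack([_histogram(tr, duration, bin_ms) for tr in trials])
    total = hists.sum(axis=0)
    corrs = []
    for i in range(len(trials)):
        h = hists[i]
        H = total - h
        if H.std() == 0 or h.std() == 0:
            return ReliabilityResult(np.nan, bin_ms, len(trials), degenerate=True)
        corrs.append(float(np.corrcoef(H, h)[0, 1]))
    return ReliabilityResult(float(np.mean(corrs)), bin_ms, len(trials))


def classify_reliable(result: ReliabilityResult, threshold: float = 0.15) -> bool:
    """True iff RI strictly exceeds the threshold (NaN counts as unreliable)."""
    if np.isnan(result.ri):
        return False
    return result.ri > threshold


def _window_count(trials: list[SpikeTrain], events: np.ndarray,
                  window_s: float) -> float:
    total = 0
    for tr in trials:
        for ev in np.atleast_1d(events):
            total += int(np.sum((tr.times >= ev) & (tr.times < ev + window_s)))
    return float(total)


def bias_index(trials: list[SpikeTrain], onset_times, offset_times,
               window_ms: float = 300.0) -> LightResponseMetrics:
    """ON/OFF spike-count preference in the first 300 ms after each event."""
    w = window_ms / 1000.0
    r_on = _window_count(trials, np.asarray(onset_times, dtype=float), w)
    r_off = _window_count(trials, np.asarray(offset_times, dtype=float), w)
    m = LightResponseMetrics(r_on=r_on, r_off=r_off)
    if r_on + r_off == 0:
        m.flags.append("undefined_bias")
        return m
    bi = (r_on - r_off) / (r_on + r_off)
    m.bias_index = bi
    if bi < -0.25:
        m.polarity_class = "OFF"
    elif bi <= 0.5:
        m.polarity_class = "ON-OFF"
    else:
        m.polarity_class = "ON"
    return m


def _phase_ti(trials: list[SpikeTrain], events: np.ndarray,
              window_ms: float, bin_ms: float) -> float:
    n_bins = int(round(window_ms / bin_ms))
    hist = np.zeros(n_bins)
    for tr in trials:
        for ev in np.atleast_1d(events):
            rel = (tr.times - ev) * 1000.0
            sel = rel[(rel >= 0) & (rel < window_ms)]
            hist += np.histogram(sel, bins=n_bins, range=(0, window_ms))[0]
    if hist.max() == 0:
        return np.nan
    return 1.0 - float((hist / hist.max()).mean())


def transiency_index(trials: list[SpikeTrain], preferred_events,
                     window_ms: float = 500.0, bin_ms: float = 50.0
                     ) -> LightResponseMetrics:
    """TI of the trial-summed, max-normalized histogram after the preferred phase."""
    ti = _phase_ti(trials, np.asarray(preferred_events, dtype=float),
                   window_ms, bin_ms)
    m = LightResponseMetrics(transiency_index=ti)
    if np.isnan(ti):
        m.flags.append("undefined_transiency")
    return m


def light_response_metrics(trials: list[SpikeTrain], onset_times, offset_times,
                           bias_window_ms: float = 300.0,
                           ti_window_ms: float = 500.0,
                           ti_bin_ms: float = 50.0) -> LightResponseMetrics:
    """Combined BI/TI report with the preferred-phase rule applied.

    The preferred phase is light onset for ON cells, offset for OFF cells;
    ON-OFF cells average the two phase TIs.
    """
    onsets = np.asarray(onset_times, dtype=float)
    offsets = np.asarray(offset_times, dtype=float)
    m = bias_index(trials, onsets, offsets, bias_window_ms)
    if m.polarity_class == "ON":
        m.transiency_index = _phase_ti(trials, onsets, ti_window_ms, ti_bin_ms)
    elif m.polarity_class == "OFF":
        m.transiency_index = _phase_ti(trials, offsets, ti_window_ms, ti_bin_ms)
    elif m.polarity_class == "ON-OFF":
        ti_on = _phase_ti(trials, onsets, ti_window_ms, ti_bin_ms)
        ti_off = _phase_ti(trials, offsets, ti_window_ms, ti_bin_ms)
        m.transiency_index = float(np.nanmean([ti_on, ti_off]))
    if np.isnan(m.transiency_index):
        m.flags.append("undefined_transiency")
    return m
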