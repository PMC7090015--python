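"""Firing-rate prediction and blockwise cross-validated evaluation.

A fitted LNP model predicts a rate per 1 ms bin by applying its static
nonlinearity to the filter response of the stimulus snippet around the
bin; performance is the Pearson correlation between predicted and true
firing rate at 1 kHz resolution.  Evaluation follows the 4 s train / 1 s
test scheme: the recording is cut into five contiguous 1 s blocks, each
held out once while the model is fit on the remaining four seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import glm as _glm
from . import sta as _sta
from .synthetic import _snippet_projections, valid_bins
from .types import BIN_MS, LinearFilter, LNPModel, SpikeTrain, StimulusTrace, bin_spikes

__all__ = [
    "PredictionResult",
    "CrossValidationPlan",
    "predict_firing_rate",
    "linear_stage_prediction",
    "prediction_performance",
    "run_blockwise_cv",
]


@dataclass
class PredictionResult:
    predicted_rate: np.ndarray
    true_rate: np.ndarray | None = None
    performance: float = np.nan
    split_id: int = -1
    linear_only: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class CrossValidationPlan:
    n_splits: int = 5
    test_span: float = 1.0

    def splits(self, duration: float) -> list[tuple[float, float]]:
        if abs(duration - self.n_splits * self.test_span) > 1e-9:
            raise ValueError("recording duration does not divide into the CV plan")
        return [(i * self.test_span, (i + 1) * self.test_span)
                for i in range(self.n_splits)]


def _filter_response(filt: LinearFilter, stimulus: StimulusTrace) -> np.ndarray:
    """Filter projection per 1-ms bin; NaN at bins without a full window."""
    proj = _snippet_projections(stimulus, filt.taps)
    first, last = valid_bins(stimulus.n_samples, stimulus.sampling_rate)
    stride = int(round(stimulus.sampling_rate * BIN_MS / 1000.0))
    n_bins = stimulus.n_samples // stride
    out = np.full(n_bins, np.nan)
    out[first:last] = proj[: last - first]
    return out


def predict_firing_rate(model: LNPModel, stimulus: StimulusTrace) -> np.ndarray:
    """Nonlinearity applied to the filter response; one value per 1 ms bin.

    For an STA model the response is computed on the whitened stimulus the
    model was fit on (attach it as ``model.whitened_stimulus``, as
    ``fit_sta_model`` does); for an MLE model on the raw stimulus.
    """
    if model.method == "STA" and hasattr(model, "whitened_stimulus"):
        stim = model.whitened_stimulus
        if stim.n_samples != stimulus.n_samples:
            stim = stimulus
    else:
        stim = stimulus
    z = _filter_response(model.filter, stim)
    rate = np.full_like(z, np.nan)
    ok = np.isfinite(z)
    rate[ok] = model.nonlinearity(z[ok])
    return rate


def linear_stage_prediction(filt: LinearFilter, stimulus: StimulusTrace
                            ) -> np.ndarray:
    """Filter response without the static nonlinearity (may be negative)."""
    return _filter_response(filt, stimulus)


def prediction_performance(true_rate: np.ndarray, predicted_rate: np.ndarray
                           ) -> tuple[float, list[str]]:
    """Pearson correlation at 1 kHz; NaN-with-flag on degenerate input.

    Bins where either vector is NaN are excluded pairwise.
    """
    r = np.asarray(true_rate, dtype=float)
    p = np.asarray(predicted_rate, dtype=float)
    if r.size != p.size:
        raise ValueError("true and predicted rate must have equal length")
    ok = np.isfinite(r) & np.isfinite(p)
    r, p = r[ok], p[ok]
    if r.size < 2:
        return np.nan, ["too_few_bins"]
    if r.std() == 0 or p.std() == 0:
        return np.nan, ["zero_variance"]
    return float(np.corrcoef(r, p)[0, 1]), []


def _restrict_spikes(trains: list[SpikeTrain], windows: list[tuple[float, float]]
                     ) -> list[SpikeTrain]:
    out = []
    for tr in trains:
        keep = np.zeros(tr.times.size, dtype=bool)
        for lo, hi in windows:
            keep |= (tr.times >= lo) & (tr.times < hi)
        out.append(SpikeTrain(tr.times[keep], tr.repetition_id, tr.cell_id))
    return out


def run_blockwise_cv(stimulus: StimulusTrace,
                     spikes: SpikeTrain | list[SpikeTrain],
                     method: str = "STA",
                     plan: CrossValidationPlan | None = None,
                     seed: int = 0,
                     glm_config: "_glm.ElasticNetConfig | None" = None,
                     retention: float = 1e-7,
                     linear_only: bool = False,
                     whitened: StimulusTrace | None = None
                     ) -> list[PredictionResult]:
    """Fit on four fifths of the recording, predict each held-out block.

    Per split the model is fit on spikes from the training blocks only
    (pooling repetitions) and predicts the held-out block; the true rate is
    the 1 ms binned spike count summed across repetitions.  Returns one
    result per split.
    """
    trains = spikes if isinstance(spikes, list) else [spikes]
    plan = plan or CrossValidationPlan()
    duration = stimulus.duration
    splits = plan.splits(duration)
    true_all = bin_spikes(trains, duration)
    if method == "STA" and whitened is None:
        ens = _sta.extract_snippets(stimulus)
        op = _sta.compute_whitening_operator(ens, retention=retention)
        whitened = _sta.whiten_stimulus(stimulus, op)
    design = _glm.build_design(stimulus, trains) if method == "MLE" else None
    results = []
    for split_id, (lo, hi) in enumerate(splits):
        train_windows = [w for w in splits if w != (lo, hi)]
        train_spikes = _restrict_spikes(trains, train_windows)
        if method == "STA":
            model = _sta.fit_sta_model(stimulus, train_spikes, whitened=whitened)
        elif method == "MLE":
            X, y, bins = design
            in_test = (bins * BIN_MS / 1000.0 >= lo) & (bins * BIN_MS / 1000.0 < hi)
            model = _glm.fit_glm_elasticnet(
                stimulus, train_spikes, config=glm_config, seed=seed,
                design=(X[~in_test], y[~in_test], bins[~in_test]))
        else:
            raise ValueError("method must be 'STA' or 'MLE'")
        if linear_only:
            pred = linear_stage_prediction(model.filter, stimulus)
        else:
            pred = predict_firing_rate(model, stimulus)
        bin_lo, bin_hi = int(round(lo * 1000)), int(round(hi * 1000))
        p_test = pred[bin_lo:bin_hi]
        t_test = true_all[bin_lo:bin_hi]
        perf, flags = prediction_performance(t_test, p_test)
        results.append(PredictionResult(p_test, t_test, perf, split_id,
                                        linear_only, flags))
    return results
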