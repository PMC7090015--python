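"""LNP fitting by whitened spike-triggered averaging.

The stimulus is 100 Hz low-passed, so it is strongly autocorrelated and a
plain STA is smeared by the stimulus correlations.  The correction used
here whitens stimulus snippets with the square root of the pseudo-inverse
of the snippet covariance: eigendecompose C, invert-and-square-root the
largest L eigenvalues, zero the rest.  The whitened continuous stimulus is
rebuilt by overlap-adding the whitened snippets with Hann-tapered weights
(normalized to unity at every sample), the STA is computed on it, and the
static nonlinearity is estimated as the binwise histogram ratio of
spike-triggered vs full-ensemble filter projections, then fit with a
sigmoid or an exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .types import (
    FILTER_LEN,
    POST_SAMPLES,
    PRE_SAMPLES,
    Exponential,
    LinearFilter,
    LNPModel,
    Sigmoid,
    SpikeTrain,
    StimulusTrace,
)

__all__ = [
    "SnippetEnsemble",
    "WhiteningOperator",
    "NonlinearityEstimate",
    "extract_snippets",
    "compute_whitening_operator",
    "whiten_stimulus",
    "compute_sta",
    "spike_triggered_ensemble",
    "estimate_nonlinearity",
    "fit_nonlinearity",
    "fit_sta_model",
]


@dataclass
class SnippetEnsemble:
    """Matrix of contiguous stimulus slices (rows) taken ``stride`` apart."""

    snippets: np.ndarray  # (n_snippets, length)
    stride: int = 10
    anchor_samples: np.ndarray | None = None  # start sample of each row

    @property
    def n_snippets(self) -> int:
        return self.snippets.shape[0]


@dataclass
class WhiteningOperator:
    matrix: np.ndarray  # (300, 300) symmetric PSD
    rank: int
    eigen_spectrum: np.ndarray  # retained eigenvalues, descending
    retention_rule: str = ""


@dataclass
class NonlinearityEstimate:
    bin_centers: np.ndarray
    ratio: np.ndarray  # H_STE / H_FE per unmasked bin
    mask: np.ndarray  # True where H_FE had enough counts
    fitted_kind: str | None = None
    params: dict = field(default_factory=dict)
    fit_residual: float = np.nan

    def fitted(self) -> Sigmoid | Exponential:
        if self.fitted_kind == "sigmoid":
            return Sigmoid(**self.params)
        if self.fitted_kind == "exponential":
            return Exponential(**self.params)
        raise ValueError("nonlinearity has not been fit")


def extract_snippets(stimulus: StimulusTrace | np.ndarray,
                     length: int = FILTER_LEN, stride: int = 10
                     ) -> SnippetEnsemble:
    """Slice the stimulus into overlapping rows ``x[i*stride : i*stride+length]``."""
    x = stimulus.samples if isinstance(stimulus, StimulusTrace) else np.asarray(stimulus)
    if x.size < length:
        raise ValueError("stimulus shorter than one snippet")
    rows = np.lib.stride_tricks.sliding_window_view(x, length)[::stride]
    anchors = np.arange(rows.shape[0]) * stride
    return SnippetEnsemble(np.ascontiguousarray(rows), stride, anchors)


def compute_whitening_operator(ensemble: SnippetEnsemble,
                               retention: float = 1e-7) -> WhiteningOperator:
    """C^{-1/2} from the eigendecomposition of the snippet covariance.

    Eigenvalues >= ``retention`` x lambda_max are inverted and square-rooted;
    the rest are zeroed.  The retention floor is deliberately deep: the
    stimulus PSD tail falls off steeply above the 100 Hz cutoff, and modes
    out to several hundred Hz must be rescaled for whitening to flatten the
    spectrum and kill the autocorrelation (they carry real, if small,
    stimulus power).
    """
    X = ensemble.snippets
    if np.allclose(X, 0):
        raise ValueError("degenerate input: all-zero snippet ensemble")
    C = np.cov(X, rowvar=False)
    lam, vec = np.linalg.eigh(C)  # ascending
    lam, vec = lam[::-1], vec[:, ::-1]
    keep = lam >= retention * lam[0]
    L = int(keep.sum())
    inv_sqrt = np.zeros_like(lam)
    inv_sqrt[:L] = lam[:L] ** -0.5
    W = (vec * inv_sqrt) @ vec.T
    return WhiteningOperator(W, rank=L, eigen_spectrum=lam[:L],
                             retention_rule=f"eigenvalues >= {retention:g} * lambda_max")


def _overlap_add_window(length: int) -> np.ndarray:
    # strictly positive Hann taper so every sample gets nonzero weight
    return signal.windows.hann(length + 2)[1:-1]


def whiten_stimulus(stimulus: StimulusTrace, operator: WhiteningOperator,
                    stride: int = 10, length: int = FILTER_LEN) -> StimulusTrace:
    """Whiten each snippet and rebuild the trace by tapered overlap-add.

    The Hann weights are normalized to sum to one at every sample, so an
    identity operator returns the input unchanged.
    """
    if operator.matrix.shape != (length, length):
        raise ValueError("operator geometry does not match the snippet length")
    ens = extract_snippets(stimulus, length, stride)
    white = ens.snippets @ operator.matrix.T
    win = _overlap_add_window(length)
    out = np.zeros(stimulus.n_samples)
    weight = np.zeros(stimulus.n_samples)
    for i, a in enumerate(ens.anchor_samples):
        out[a:a + length] += win * white[i]
        weight[a:a + length] += win
    covered = weight > 0
    out[covered] /= weight[covered]
    # trailing samples not covered by any snippet start keep the original value
    out[~covered] = stimulus.samples[~covered]
    return StimulusTrace(out, stimulus.sampling_rate,
                         standardization=stimulus.standardization)


def _usable_spike_samples(spikes: SpikeTrain, n_samples: int, fs: float
                          ) -> tuple[np.ndarray, int]:
    s = np.round(spikes.times * fs).astype(int)
    ok = (s >= PRE_SAMPLES) & (s + POST_SAMPLES <= n_samples)
    return s[ok], int((~ok).sum())


def compute_sta(whitened: StimulusTrace, spikes: SpikeTrain | list[SpikeTrain],
                ) -> LinearFilter:
    """Average the whitened stimulus snippets around every usable spike.

    Tap j holds the mean stimulus value at spike_sample - 200 + j, i.e.
    tap times run -20 ms ... +9.9 ms.  Spikes whose window exits the trace
    are skipped (their count is recorded on the returned filter's metadata).
    """
    trains = spikes if isinstance(spikes, list) else [spikes]
    fs = whitened.sampling_rate
    x = whitened.samples
    acc = np.zeros(FILTER_LEN)
    n_used = n_skipped = 0
    for tr in trains:
        s, skipped = _usable_spike_samples(tr, x.size, fs)
        n_skipped += skipped
        for a in s:
            acc += x[a - PRE_SAMPLES:a + POST_SAMPLES]
        n_used += s.size
    if n_used == 0:
        raise ValueError("no usable spikes for the STA")
    filt = LinearFilter(acc / n_used, method="STA")
    filt.n_spikes_used = n_used
    filt.n_spikes_skipped = n_skipped
    return filt


def spike_triggered_ensemble(whitened: StimulusTrace,
                             spikes: SpikeTrain | list[SpikeTrain]
                             ) -> SnippetEnsemble:
    """Snippets of the whitened stimulus around each usable spike."""
    trains = spikes if isinstance(spikes, list) else [spikes]
    fs = whitened.sampling_rate
    x = whitened.samples
    rows, anchors = [], []
    for tr in trains:
        s, _ = _usable_spike_samples(tr, x.size, fs)
        for a in s:
            rows.append(x[a - PRE_SAMPLES:a + POST_SAMPLES])
            anchors.append(a - PRE_SAMPLES)
    if not rows:
        raise ValueError("no usable spikes for the spike-triggered ensemble")
    return SnippetEnsemble(np.asarray(rows), stride=0,
                           anchor_samples=np.asarray(anchors))


def estimate_nonlinearity(filt: LinearFilter, full_ensemble: SnippetEnsemble,
                          ste: SnippetEnsemble, n_bins: int = 25,
                          min_count: int = 5) -> NonlinearityEstimate:
    """Histogram-ratio estimate of the static nonlinearity.

    Both ensembles are projected onto the filter; shared equal-width bins
    span the central 99% of the full-ensemble projections, and the ratio
    H_STE / H_FE is reported per bin (bins where H_FE < ``min_count`` are
    masked out).  With the full ensemble at 1 ms stride and one STE row per
    spike the ratio is directly the spike probability per 1 ms bin.
    """
    if ste.n_snippets == 0:
        raise ValueError("empty spike-triggered ensemble")
    p_fe = full_ensemble.snippets @ filt.taps
    p_ste = ste.snippets @ filt.taps
    lo, hi = np.percentile(p_fe, [0.5, 99.5])
    if lo == hi:
        raise ValueError("degenerate projections")
    edges = np.linspace(lo, hi, n_bins + 1)
    h_fe = np.histogram(p_fe, bins=edges)[0].astype(float)
    h_ste = np.histogram(p_ste, bins=edges)[0].astype(float)
    mask = h_fe >= min_count
    centers = 0.5 * (edges[:-1] + edges[1:])
    ratio = np.full(n_bins, np.nan)
    ratio[mask] = h_ste[mask] / h_fe[mask]
    return NonlinearityEstimate(bin_centers=centers, ratio=ratio, mask=mask)


def _fit_form(x: np.ndarray, y: np.ndarray, kind: str) -> tuple[dict, float]:
    """Least-squares fit of one parametric form with deterministic multi-starts."""
    span = max(y.max() - y.min(), 1e-12)
    xr = max(x.max() - x.min(), 1e-12)
    if kind == "sigmoid":
        def f(p):
            y_max, g, x0, y_min = p
            return y_max / (1.0 + np.exp(-np.clip(g * (x - x0), -500, 500))) + y_min
        starts = [
            (span, 4.0 / xr, np.median(x), y.min()),
            (span, 1.0 / xr, x[np.argmax(y >= y.min() + span / 2)], y.min()),
            (2 * span, 8.0 / xr, np.median(x), y.min()),
            (span, -4.0 / xr, np.median(x), y.min()),
            (y.max(), 2.0 / xr, 0.0, 0.0),
        ]
    else:  # exponential
        def f(p):
            a, g, y_min = p
            return a * np.exp(np.clip(g * x, -500, 500)) + y_min
        starts = [
            (span / np.e, 1.0 / xr, y.min()),
            (span, 2.0 / xr, 0.0),
            (span / 10, 4.0 / xr, y.min()),
            (-span / np.e, -1.0 / xr, y.max()),
            (np.mean(y), 0.1 / xr, 0.0),
        ]
    best, best_cost = None, np.inf
    for p0 in starts:
        try:
            res = optimize.least_squares(lambda p: f(p) - y, p0, method="lm",
                                         max_nfev=5000)
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res.x, res.cost
    if best is None:
        raise RuntimeError(f"nonlinearity {kind} fit failed from all starts")
    residual = float(2 * best_cost)  # sum of squares
    if kind == "sigmoid":
        params = dict(zip(("y_max", "g", "x0", "y_min"), map(float, best)))
    else:
        params = dict(zip(("a", "g", "y_min"), map(float, best)))
    return params, residual


def fit_nonlinearity(estimate: NonlinearityEstimate,
                     kind: str | None = None) -> NonlinearityEstimate:
    """Fit the histogram ratio with a sigmoid and/or exponential form.

    When ``kind`` is None both forms are fit and the lower-residual one is
    kept.  Requires at least 5 unmasked bins.
    """
    x = estimate.bin_centers[estimate.mask]
    y = estimate.ratio[estimate.mask]
    if x.size < 5:
        raise ValueError("need at least 5 unmasked bins to fit the nonlinearity")
    kinds = [kind] if kind in ("sigmoid", "exponential") else ["sigmoid", "exponential"]
    best_kind, best_params, best_res = None, None, np.inf
    for k in kinds:
        try:
            params, res = _fit_form(x, y, k)
        except RuntimeError:
            continue
        if res < best_res:
            best_kind, best_params, best_res = k, params, res
    if best_kind is None:
        raise RuntimeError("nonlinearity fit did not converge for any form")
    estimate.fitted_kind = best_kind
    estimate.params = best_params
    estimate.fit_residual = best_res
    return estimate


def fit_sta_model(stimulus: StimulusTrace, spikes: SpikeTrain | list[SpikeTrain],
                  retention: float = 1e-7, stride: int = 10,
                  n_bins: int = 25, nonlinearity_kind: str | None = None,
                  whitened: StimulusTrace | None = None) -> LNPModel:
    """Full STA pipeline: whiten, average, estimate + fit the nonlinearity.

    The full ensemble used for the nonlinearity is taken at 1 ms stride so
    the histogram ratio is a per-1-ms-bin spike probability.  A precomputed
    ``whitened`` trace may be passed to avoid recomputation.
    """
    if whitened is None:
        ens = extract_snippets(stimulus, stride=stride)
        op = compute_whitening_operator(ens, retention=retention)
        whitened = whiten_stimulus(stimulus, op, stride=stride)
    filt = compute_sta(whitened, spikes)
    fe = extract_snippets(whitened, stride=10)  # 1 ms stride at 10 kHz
    ste = spike_triggered_ensemble(whitened, spikes)
    # FE counts one row per 1 ms bin; with R repetitions the STE holds R
    # rows per bin on average, so scale the ratio to a per-repetition
    # probability via the FE duplication factor.
    trains = spikes if isinstance(spikes, list) else [spikes]
    n_reps = max(len(trains), 1)
    est = estimate_nonlinearity(filt, fe, ste, n_bins=n_bins)
    est.ratio = est.ratio / n_reps
    est = fit_nonlinearity(est, nonlinearity_kind)
    model = LNPModel(filter=filt, nonlinearity=est.fitted(), method="STA",
                     fit_metadata={"n_repetitions": n_reps,
                                   "nonlinearity": est.params,
                                   "nonlinearity_kind": est.fitted_kind,
                                   "retention": retention})
    model.nonlinearity_estimate = est
    model.whitened_stimulus = whitened
    return model
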