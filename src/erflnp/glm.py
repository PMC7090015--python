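"""Maximum-likelihood LNP fitting: elastic-net Bernoulli GLM with logit link.

The spike train is binned at 1 ms into binary labels (any spike in a bin
-> 1); the design row for bin t is the raw (not whitened) 300-sample
stimulus snippet spanning -20...+10 ms around the bin.  The loss is the
average negative Bernoulli log-likelihood (normalizer N = number of binned
observations, which keeps the lambda grid on the conventional scale), plus
the elastic-net penalty:

    J = -(1/N) sum_t [y_t log mu_t + (1-y_t) log(1-mu_t)]
        + lambda [ (1-alpha) * 1/2 ||beta||^2 + alpha ||beta||_1 ]

with mu_t = 1/(1+exp(-(beta_0 + beta . s_t))).  The intercept is never
penalized.  Solving is delegated to scikit-learn's LogisticRegression
(SAGA for alpha > 0, lbfgs for the pure-L2 case) through the exact
C = 1/(N lambda) correspondence; the loss/gradient implemented here is the
contract the solver is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .types import (
    BIN_MS,
    FILTER_LEN,
    LinearFilter,
    LNPModel,
    Logistic,
    SpikeTrain,
    StimulusTrace,
)
from .synthetic import valid_bins

__all__ = [
    "ElasticNetConfig",
    "elastic_net_loss",
    "build_design",
    "fit_glm_elasticnet",
]


@dataclass
class ElasticNetConfig:
    """Hyperparameter grids for the cross-validated search."""

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, -2, 5))
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.01, 0.1, 0.5, 1.0]))
    cv_folds: int = 5
    max_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self) -> None:
        self.lambda_grid = np.atleast_1d(np.asarray(self.lambda_grid, dtype=float))
        self.alpha_grid = np.atleast_1d(np.asarray(self.alpha_grid, dtype=float))
        if np.any(self.lambda_grid <= 0):
            raise ValueError("all lambda values must be positive")
        if np.any((self.alpha_grid < 0) | (self.alpha_grid > 1)):
            raise ValueError("alpha values must lie in [0, 1]")


def elastic_net_loss(beta0: float, beta: np.ndarray, X: np.ndarray,
                     y: np.ndarray, lam: float, alpha: float,
                     n_norm: float) -> tuple[float, float, np.ndarray]:
    """Penalized average negative log-likelihood and its gradient.

    ``n_norm`` is the likelihood normalizer (number of observations).  The
    gradient of the L1 term uses sign(beta) (subgradient; exact wherever
    beta_j != 0).  Returns (loss, dJ/dbeta0, dJ/dbeta).
    """
    z = beta0 + X @ beta
    mu = 1.0 / (1.0 + np.exp(-z))
    eps = 1e-12
    ll = np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
    penalty = lam * ((1 - alpha) * 0.5 * np.sum(beta ** 2)
                     + alpha * np.sum(np.abs(beta)))
    loss = -ll / n_norm + penalty
    resid = mu - y
    g0 = float(np.sum(resid)) / n_norm
    g = (X.T @ resid) / n_norm + lam * ((1 - alpha) * beta
                                        + alpha * np.sign(beta))
    return float(loss), g0, g


def build_design(stimulus: StimulusTrace,
                 spikes: SpikeTrain | list[SpikeTrain]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix, binary labels and bin indices for the GLM.

    One row per valid 1 ms bin per repetition (repetitions share the
    stimulus rows); labels clip multiple spikes per bin to 1.  Returns
    (X, y, bin_index) with repetitions stacked.
    """
    trains = spikes if isinstance(spikes, list) else [spikes]
    stride = int(round(stimulus.sampling_rate * BIN_MS / 1000.0))
    x = stimulus.samples
    rows = np.lib.stride_tricks.sliding_window_view(x, FILTER_LEN)[::stride]
    first, last = valid_bins(stimulus.n_samples, stimulus.sampling_rate)
    rows = rows[: last - first]
    bins = np.arange(first, last)
    n_bins_total = stimulus.n_samples // stride
    X_parts, y_parts, b_parts = [], [], []
    for tr in trains:
        counts = np.zeros(n_bins_total)
        idx = np.floor(tr.times * 1000.0 / BIN_MS).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins_total)]
        np.add.at(counts, idx, 1)
        y = (counts[first:last] > 0).astype(float)
        X_parts.append(rows)
        y_parts.append(y)
        b_parts.append(bins)
    return np.vstack(X_parts), np.concatenate(y_parts), np.concatenate(b_parts)


def _fit_single(X: np.ndarray, y: np.ndarray, lam: float, alpha: float,
                n_norm: float, max_iter: int, tol: float, seed: int
                ) -> tuple[float, np.ndarray]:
    C = 1.0 / (n_norm * lam)
    if alpha == 0.0:
        clf = LogisticRegression(C=C, solver="lbfgs",
                                 max_iter=max_iter * 5, tol=tol)
    else:
        clf = LogisticRegression(C=C, l1_ratio=alpha,
                                 solver="saga", max_iter=max_iter, tol=tol,
                                 random_state=seed)
    clf.fit(X, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _held_out_loglik(beta0: float, beta: np.ndarray, X: np.ndarray,
                     y: np.ndarray) -> float:
    z = beta0 + X @ beta
    mu = 1.0 / (1.0 + np.exp(-z))
    eps = 1e-12
    return float(np.mean(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))


def fit_glm_elasticnet(stimulus: StimulusTrace,
                       spikes: SpikeTrain | list[SpikeTrain],
                       config: ElasticNetConfig | None = None,
                       seed: int = 0,
                       design: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                       ) -> LNPModel:
    """Fit the elastic-net logistic GLM, selecting (lambda, alpha) by CV.

    Hyperparameters are chosen by grid search over ``config`` with
    contiguous (unshuffled) folds on the time axis, scored by held-out mean
    log-likelihood; a singleton grid skips the search.  Features are
    centered/scaled internally and the coefficients back-transformed; the
    intercept is unpenalized throughout.
    """
    config = config or ElasticNetConfig()
    X, y, bins = design if design is not None else build_design(stimulus, spikes)
    n_spikes = float(y.sum())
    if n_spikes == 0 or n_spikes == y.size:
        raise ValueError("degenerate labels: all-zero or all-one spike bins")
    n_norm = float(y.size)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    combos = [(lam, al) for lam in config.lambda_grid for al in config.alpha_grid]
    if len(combos) > 1:
        # contiguous time folds (repetitions share fold assignment per bin)
        order = np.unique(bins)
        fold_of_bin = {b: int(i * config.cv_folds / order.size)
                       for i, b in enumerate(order)}
        folds = np.array([fold_of_bin[b] for b in bins])
        scores = np.full(len(combos), -np.inf)
        for ci, (lam, al) in enumerate(combos):
            ll = []
            for k in range(config.cv_folds):
                tr, te = folds != k, folds == k
                if y[tr].sum() in (0, y[tr].size):
                    continue
                b0, b = _fit_single(Xs[tr], y[tr], lam, al, float(y[tr].size),
                                    config.max_iter, config.tol, seed)
                ll.append(_held_out_loglik(b0, b, Xs[te], y[te]))
            if ll:
                scores[ci] = float(np.mean(ll))
        best = combos[int(np.argmax(scores))]
    else:
        best = combos[0]
    lam, alpha = best
    beta0_s, beta_s = _fit_single(Xs, y, lam, alpha, n_norm,
                                  config.max_iter, config.tol, seed)
    beta = beta_s / scale
    beta0 = beta0_s - float(mean @ beta)
    filt = LinearFilter(beta, method="MLE")
    return LNPModel(filter=filt, nonlinearity=Logistic(offset=beta0),
                    method="MLE",
                    fit_metadata={"lambda": float(lam), "alpha": float(alpha),
                                  "n_spikes": n_spikes, "n_bins": int(y.size),
                                  "seed": seed})
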