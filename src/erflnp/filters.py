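"""Population analysis of temporal filters.

Filters are reduced by PCA to the components retaining 90% of the
variance, clustered by average-linkage hierarchical clustering on the
euclidean distance between PC projections, optionally projected onto a
reference population's components (e.g. degenerated-retina filters onto
wild-type PCs), and summarized by their peak latencies relative to the
spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .types import FILTER_LEN, TAP_TIMES_MS, LinearFilter

__all__ = [
    "FilterClustering",
    "PeakLatencyReport",
    "pca_filters",
    "cluster_filters",
    "project_onto_components",
    "peak_latencies",
    "pc_session_variance_ratio",
]


@dataclass
class FilterClustering:
    components: np.ndarray = field(default_factory=lambda: np.empty((0, FILTER_LEN)))
    explained_variance: np.ndarray = field(default_factory=lambda: np.empty(0))
    projections: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    mean: np.ndarray = field(default_factory=lambda: np.zeros(FILTER_LEN))
    linkage: np.ndarray | None = None
    labels: np.ndarray | None = None
    selected_pcs: list[int] | None = None
    degenerate: bool = False


@dataclass
class PeakLatencyReport:
    negative_peak_latency: float = np.nan
    positive_peak_latency: float = np.nan
    shape_class: str = "undefined"


def _as_matrix(filters: list[LinearFilter] | np.ndarray) -> np.ndarray:
    if isinstance(filters, np.ndarray):
        return np.atleast_2d(filters)
    return np.stack([f.taps for f in filters])


def pca_filters(filters: list[LinearFilter] | np.ndarray,
                variance_target: float = 0.9) -> FilterClustering:
    """Mean-centered PCA keeping the fewest PCs reaching the variance target.

    Sign convention: each component is oriented so its largest-magnitude
    loading is positive (deterministic, reproducible projections).
    """
    F = _as_matrix(filters)
    if F.shape[0] < 2:
        raise ValueError("PCA needs at least 2 filters")
    if np.allclose(F.var(axis=0), 0):
        return FilterClustering(mean=F.mean(axis=0), degenerate=True)
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(F)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target) + 1)
    comps = pca.components_[:k].copy()
    pr = proj[:, :k].copy()
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            pr[:, i] *= -1
    return FilterClustering(components=comps,
                            explained_variance=pca.explained_variance_ratio_[:k],
                            projections=pr, mean=pca.mean_)


def cluster_filters(clustering_or_proj: FilterClustering | np.ndarray,
                    n_clusters: int | None = None,
                    selected_pcs: list[int] | None = None,
                    gap_window: int = 10) -> FilterClustering:
    """Average-linkage euclidean clustering of the PC projections.

    ``n_clusters=None`` chooses the count automatically from the merge
    heights: every prominent jump among the last ``gap_window`` merges
    marks a cluster boundary and the tree is cut below the deepest one
    (the scriptable analogue of choosing the count from the dendrogram by
    eye, including sub-clusters of a dominant split); ``selected_pcs``
    restricts the PC coordinates used (e.g. dropping a between-session
    component).
    """
    if isinstance(clustering_or_proj, FilterClustering):
        fc = clustering_or_proj
        proj = fc.projections
    else:
        proj = np.atleast_2d(np.asarray(clustering_or_proj, dtype=float))
        fc = FilterClustering(projections=proj)
    if selected_pcs is not None:
        proj = proj[:, selected_pcs]
        fc.selected_pcs = list(selected_pcs)
    n = proj.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 points")
    if n_clusters is not None and n_clusters > n:
        raise ValueError("n_clusters cannot exceed the number of points")
    Z = hierarchy.linkage(proj, method="average", metric="euclidean")
    if n_clusters is None:
        heights = Z[:, 2]
        w = min(gap_window, heights.size)
        tail = heights[-w:]
        if tail[-1] == 0 or w < 2:
            n_clusters = 1
        else:
            # read the dendrogram the way one does by eye: every merge whose
            # height jumps up by an outlying factor relative to the typical
            # recent jump (and by at least 20%) marks a cluster boundary;
            # cut just below the deepest such merge.  Cutting between
            # tail[i] and tail[i+1] leaves w - i clusters.
            floor = 1e-12 * tail[-1]
            ratios = tail[1:] / np.maximum(tail[:-1], floor)
            typical_excess = float(np.median(ratios - 1.0))
            threshold = max(1.2, 1.0 + 8.0 * max(typical_excess, 0.0))
            prominent = ratios > threshold
            if not prominent.any():
                n_clusters = 1
            else:
                i = int(np.argmax(prominent))  # deepest prominent jump
                n_clusters = w - i
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    fc.linkage = Z
    fc.labels = labels
    return fc


def project_onto_components(filters: list[LinearFilter] | np.ndarray,
                            reference: FilterClustering) -> np.ndarray:
    """Project filters onto a reference population's PCs (no refitting)."""
    F = _as_matrix(filters)
    if reference.components.size == 0:
        raise ValueError("reference clustering has no components")
    if F.shape[1] != reference.components.shape[1]:
        raise ValueError("filter tap geometry does not match the reference")
    return (F - reference.mean) @ reference.components.T


def peak_latencies(filt: LinearFilter, biphasic_ratio: float = 0.3
                   ) -> PeakLatencyReport:
    """Latencies of the global minimum and maximum taps, with a shape call.

    The shape is biphasic when the secondary extremum reaches at least
    ``biphasic_ratio`` of the primary's magnitude, otherwise monophasic
    with the primary's sign.  All-zero filters are flagged undefined.
    """
    taps = filt.taps
    if np.allclose(taps, 0):
        return PeakLatencyReport()
    i_min, i_max = int(np.argmin(taps)), int(np.argmax(taps))
    neg_lat = float(TAP_TIMES_MS[i_min])
    pos_lat = float(TAP_TIMES_MS[i_max])
    a_neg, a_pos = abs(taps[i_min]), abs(taps[i_max])
    primary_neg = a_neg >= a_pos
    secondary = a_pos if primary_neg else a_neg
    primary = max(a_neg, a_pos)
    if secondary >= biphasic_ratio * primary:
        shape = "biphasic"
    else:
        shape = "monophasic_negative" if primary_neg else "monophasic_positive"
    return PeakLatencyReport(neg_lat, pos_lat, shape)


def pc_session_variance_ratio(projections: np.ndarray,
                              session_labels: np.ndarray) -> np.ndarray:
    """Between-session / within-session variance per PC (diagnostic).

    High values flag components dominated by recording-session differences,
    candidates for exclusion from clustering via ``selected_pcs``.
    """
    proj = np.atleast_2d(projections)
    groups = np.asarray(session_labels)
    out = np.zeros(proj.shape[1])
    for j in range(proj.shape[1]):
        col = proj[:, j]
        grand = col.mean()
        between = within = 0.0
        for g in np.unique(groups):
            sel = col[groups == g]
            between += sel.size * (sel.mean() - grand) ** 2
            within += float(np.sum((sel - sel.mean()) ** 2))
        out[j] = between / within if within > 0 else np.inf
    return out
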