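"""Cluster a population of temporal filters.

Builds 60 noisy filters from the three archetypes, reduces them with PCA
to the components holding 90% of the variance, clusters the projections
by average-linkage hierarchical clustering, and reports peak latencies.
"""

import numpy as np

import erflnp as E

rng = np.random.default_rng(8)
filters, truth = [], []
for label, fclass in enumerate(E.FILTER_CLASSES):
    base = E.make_template_filter(fclass).taps
    amp = np.max(np.abs(base))
    for _ in range(20):
        filters.append(E.LinearFilter(base + 0.1 * amp * rng.standard_normal(300)))
        truth.append(label)

fc = E.pca_filters(filters)
fc = E.cluster_filters(fc)  # automatic count from the dendrogram

print(f"PCs kept for 90% variance: {fc.components.shape[0]} "
      f"(explained: {np.round(fc.explained_variance, 3)})")
print(f"clusters found automatically: {len(set(fc.labels.tolist()))}")
F = np.stack([f.taps for f in filters])
for label, fclass in enumerate(E.FILTER_CLASSES):
    members = fc.labels[np.array(truth) == label]
    class_mean = E.LinearFilter(F[np.array(truth) == label].mean(axis=0))
    rep = E.peak_latencies(class_mean)
    print(f"  {fclass:22s} -> cluster {np.bincount(members).argmax()}, "
          f"mean-filter shape {rep.shape_class}")
print()
print("The leading PCs dominate the variance and the dendrogram cut")
print("recovers the three planted archetypes; in recordings the same")
print("procedure separates cathodic-preferring, anodic-preferring and")
print("biphasic cells.")
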