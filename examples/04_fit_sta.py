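"""Fit an LNP model by whitened spike-triggered averaging.

Simulates a ground-truth biphasic cell, whitens the stimulus (pseudo-
inverse square root of the snippet covariance), averages the whitened
snippets around every spike and fits the histogram-ratio nonlinearity.
"""

import numpy as np

import erflnp as E

stimulus, _ = E.generate_stimulus(E.StimulusConfig(seed=0))
neuron = E.make_archetype_neuron("biphasic", stimulus)
trains = E.simulate_lnp_spikes(neuron, stimulus, n_repetitions=5, seed=5)

model = E.fit_sta_model(stimulus, trains)

k, k_hat = neuron.filter.taps, model.filter.taps
cos = abs(k @ k_hat) / (np.linalg.norm(k) * np.linalg.norm(k_hat))
rep = E.peak_latencies(model.filter)

print(f"spikes used:         {model.filter.n_spikes_used}")
print(f"cosine(STA, truth):  {cos:.3f}")
print(f"shape / latencies:   {rep.shape_class}, "
      f"positive {rep.positive_peak_latency:+.1f} ms, "
      f"negative {rep.negative_peak_latency:+.1f} ms")
print(f"nonlinearity:        {model.fit_metadata['nonlinearity_kind']}, "
      f"params {({k: round(v, 3) for k, v in model.fit_metadata['nonlinearity'].items()})}")
print()
print("The whitened STA points almost exactly along the planted filter")
print("(cosine near 1) and recovers its lobe latencies; the fitted static")
print("nonlinearity maps filter projections to spike probability per 1 ms.")
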