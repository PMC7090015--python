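"""Fit the LNP filter by elastic-net maximum likelihood (Bernoulli GLM).

The GLM is fit on the raw (unwhitened) stimulus — maximum likelihood
corrects for stimulus correlations intrinsically — with an elastic-net
penalty whose strength comes from the lambda/alpha grids.
"""

import numpy as np

import erflnp as E
from erflnp.glm import ElasticNetConfig

stimulus, _ = E.generate_stimulus(E.StimulusConfig(seed=0))
neuron = E.make_archetype_neuron("monophasic_negative", stimulus)
trains = E.simulate_lnp_spikes(neuron, stimulus, n_repetitions=5, seed=6)


def cos(a, b):
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


mle = E.fit_glm_elasticnet(stimulus, trains,
                           config=ElasticNetConfig(lambda_grid=[1e-2],
                                                   alpha_grid=[0.0]))
sta = E.fit_sta_model(stimulus, trains)

print(f"lambda / alpha:        {mle.fit_metadata['lambda']} / "
      f"{mle.fit_metadata['alpha']}")
print(f"intercept beta0:       {mle.nonlinearity.offset:.2f} "
      f"(baseline rate {1000 / (1 + np.exp(-mle.nonlinearity.offset)):.1f} Hz)")
print(f"cosine(MLE, truth):    {cos(mle.filter.taps, neuron.filter.taps):.3f}")
print(f"cosine(STA, truth):    {cos(sta.filter.taps, neuron.filter.taps):.3f}")
print()
print("Both estimators recover the planted filter; the ridge-dominated")
print("penalty suppresses noise in stimulus directions that carry almost")
print("no power (everything far above the 100 Hz cutoff).")
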