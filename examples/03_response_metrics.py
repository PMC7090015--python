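"""Response reliability and light-response indices.

Computes the Reliability Index of an LNP cell's repeated responses to the
electrical stimulus, and the Bias/Transiency Indices of simulated
light-flash responses.
"""

import erflnp as E

stimulus, _ = E.generate_stimulus(E.StimulusConfig(seed=0))
neuron = E.make_archetype_neuron("monophasic_negative", stimulus)
trains = E.simulate_lnp_spikes(neuron, stimulus, n_repetitions=5, seed=3)

res = E.reliability_index(trains, stimulus.duration)
print(f"RI over 5 repetitions:   {res.ri:.3f} "
      f"(reliable: {E.classify_reliable(res)}; criterion RI > 0.15)")

light = E.generate_light_responses("OFF", transiency=0.7, n_trials=8,
                                   rate=50.0, seed=4)
m = E.light_response_metrics(light, onset_times=[0.0], offset_times=[0.5])
print(f"light response:          BI = {m.bias_index:.2f} -> {m.polarity_class}, "
      f"TI = {m.transiency_index:.2f} (target 0.7)")
print()
print("RI is the mean leave-one-out correlation of 2 ms response histograms")
print("(1 = identical repetitions).  BI < -0.25 marks an OFF cell; TI near 0")
print("is sustained, near 0.9 fully transient.")
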