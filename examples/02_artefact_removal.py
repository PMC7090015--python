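"""Remove the stimulation artefact from a synthetic raw recording.

The raw trace is the stimulus scaled 50x (the artefact dwarfs the spikes),
plus embedded spike waveforms and noise.  Band-pass filtering followed by
scaled stimulus subtraction recovers the spikes.
"""

import numpy as np

import erflnp as E
from erflnp.preprocessing import remove_artefact

stimulus, _ = E.generate_stimulus(E.StimulusConfig(seed=0))
rng = np.random.default_rng(1)
times = np.sort(rng.uniform(0.1, 4.9, 120))
times = times[np.insert(np.diff(times) > 3e-3, 0, True)]  # 3 ms refractory

raw = E.synthesize_raw_recording(stimulus, E.SpikeTrain(times),
                                 artefact_gain=50.0, noise_sd=0.05, seed=2)
clean, fit = remove_artefact(raw, stimulus)
detected = E.detect_spikes_threshold(clean)

tol = 0.5e-3
sens = np.mean([np.min(np.abs(detected.times - t)) < tol for t in times])
prec = np.mean([np.min(np.abs(times - d)) < tol for d in detected.times])

print(f"true artefact gain:      50.0")
print(f"estimated factor f:      {fit.factor:.3f}")
print(f"stimulus-band power drop: {-10 * np.log10(fit.residual_power_ratio):.1f} dB")
print(f"inserted / detected:     {times.size} / {detected.n_spikes}")
print(f"sensitivity / precision: {sens:.3f} / {prec:.3f}")
print()
print("The projection coefficient recovers the artefact gain to within a")
print("percent, the stimulus band collapses by tens of dB, and simple")
print("thresholding then finds nearly all embedded spikes.")
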