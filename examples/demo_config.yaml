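# Demo configuration for `erflnp run --config examples/demo_config.yaml
#                                    --out run/ --seed 5`
# Simulates one cell per filter archetype, removes the artefact from a
# synthetic raw trace, computes reliability, fits STA models, runs the
# blockwise cross-validated prediction and clusters the filters.
n_cells_per_class: 1
n_repetitions: 3
target_rate: 40.0
fit_methods: [STA]
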