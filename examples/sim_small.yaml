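# Scaled-down coverage-study design for a quick smoke run.
reps: 200
n_grid: [50, 500]
mg_grid: [100, 1000]
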