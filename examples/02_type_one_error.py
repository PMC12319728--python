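"""Small Type-I error check of the four methods under the null.

Reduced replicate count for speed; the full validation run uses the
defaults (see README).  Expect the adjusted modality test (method 1)
near the nominal 5% and the unadjusted variants (3, 4) far above it.
"""

from modality_iwas import SimParams, run_null_experiment

table = run_null_experiment(
    SimParams(),
    n_reps=200,
    alpha_levels=(0.05,),
    methods=(1, 3, 4),
    seed=7,
)
print(table.to_string(index=False))
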