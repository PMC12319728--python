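"""Small power comparison of the modality test vs the per-IDP
Bonferroni comparator across signal scales.

Reduced replicate count for speed.  In the dense scenario (all tested
IDPs carry signal) the modality test dominates; in the sparse scenario
(one IDP carries signal) the per-IDP test catches up.
"""

from modality_iwas import SimParams, run_power_experiment

table = run_power_experiment(
    SimParams(),
    tau_grid=(0.1, 0.25, 0.5),
    scenarios=("dense", "sparse"),
    n_reps=100,
    methods=(1, 2),
    seed=11,
)
print(table.to_string(index=False))
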