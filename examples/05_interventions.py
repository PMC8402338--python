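"""Modelling interventions against the anti-vaccination avalanche.

Two counter-measures are built into the model: raising the doctor-visit
ratio PVD (more institutional pro-vaccination contact) and capping the
number of simultaneously active anti-vaccination messages (culling).
This example measures the success ratio in a hot regime under each.
"""

from avopinion import EnsembleSpec, ModelParams, run_ensemble

base = ModelParams(n_patients=500, activism_threshold=-1.7,
                   writing_probability=0.45)

grid = (
    {},                               # baseline hot regime
    {"doctor_visit_ratio": 0.8},      # stronger doctor contact
    {"message_cap": 20},              # culling: cap active AV messages
)
labels = ("baseline", "PVD 0.5 -> 0.8", "message cap 20")

spec = EnsembleSpec(base, grid, n_reps=10, base_seed=7)
result = run_ensemble(spec)
for label, ratio in zip(labels, result.summary.success_ratio):
    print(f"{label:18s}: AV success ratio {ratio:.2f}")

# Raising PVD lowers the success probability without eliminating it;
# a tight message cap chokes the positive feedback loop entirely.
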