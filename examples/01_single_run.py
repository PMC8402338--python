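"""A single simulation run in the spiky regime.

Runs the model at its defaults (2000 patients, activism threshold -1.8,
writing probability 0.45) and summarises the activity: the new-message
series shows isolated bursts over a near-zero background, driven by
transient activists appearing in the population tail.
"""

from avopinion import ModelParams, run_simulation

params = ModelParams()
result = run_simulation(params, seed=4)
m = result.metrics

print(f"ticks simulated      : {len(m)}")
print(f"AV success           : {result.av_success}")
print(f"median antivaxxers   : {m.n_antivax.median():.0f} of {params.n_patients}")
print(f"peak antivaxxers     : {m.n_antivax.max()} of {params.n_patients}")
print(f"peak activists       : {m.n_activists.max()}")
print(f"max new messages/tick: {m.new_messages.max()} (initiators excluded)")
print(f"ticks with >5 new msg: {(m.new_messages > 5).sum()}")

# The handful of high-activity ticks relative to 20,000 quiet ones is the
# model's burstiness: short-lived activist cascades that usually die out.
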