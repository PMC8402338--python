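# avopinion

An agent-based model of anti-vaccination (AV) opinion dynamics in the
infosphere, together with the ensemble and burst-statistics machinery
needed to characterise its two signature behaviours: **spiky,
random-looking bursts** of anti-vaccination messaging over a low
background, and a **catastrophic stochastic transition** in which the
whole population suddenly tips into vaccine refusal.

The package is for computational social scientists and epidemiological
modellers who want a fast, reproducible re-implementation of this model
class — patients, doctors, professional "initiator" agitators and
finite-lifetime infosphere messages — with a statistically honest
analysis layer (peak detection, lognormal / bounded power-law /
log-Cauchy / sigmoid fitting) that works on simulated or external
activity series.

## The model in brief

Opinions live on [−2, +2].  A reader i meeting a source S moves

    O_i ← O_i (1 − α f_iS) + O_S α f_iS,    α = 0.66,

where the filtering factor f_iS encodes emotionally asymmetric biased
assimilation: moderate readers (|O_i| ≤ FT = 1) accept everything;
committed readers discount opposing sources by (2 − |O_i|)/(2 − FT);
*messages* bypass filtering entirely for non-activists (narrative
appeal); *activists* (O_i < AT) damp even friendly sources and totally
reject opposing ones.  Each tick: doctors' commitment adjusts to the
antivaxxer fraction (NDU = k·NAV/NP), agents age and are replaced,
initiators and activists write Bernoulli(PW) messages, patients visit
doctors with probability PVD (uncommitted doctors deflect them to the
message pool), and every patient meets one random source (doctor, other
patient, or message).  Messages carry a finite attention span: each is
read at most `message_read_capacity` (default 6) times.  See
`docs/methods.md` for the full specification and the reasoning behind
every default.

## Worked example

```python
from avopinion import ModelParams, run_simulation

result = run_simulation(ModelParams(), seed=4)   # AT=-1.8, PW=0.45
m = result.metrics
print(len(m), result.av_success, int(m.n_antivax.median()), int(m.new_messages.max()))
```

prints `20000 False 9 25`: over 20,000 ticks the movement never
succeeds — a median of 9 of 2000 patients refuse vaccination — but the
new-message series spikes to 25 messages per tick during short activist
bursts (the background is near zero).  Lowering the activism barrier
turns the same system catastrophic:

```python
import numpy as np
from avopinion import fit_powerlaw_bounded

params = ModelParams(activism_threshold=-1.7, writing_probability=0.45)
times = [r.transition_time for s in range(60)
         if (r := run_simulation(params, s)).av_success]
fit = fit_powerlaw_bounded(np.array(times, float), xmin=100., xmax=20000.)
print(len(times), int(np.median(times)), round(fit.params["gamma"], 2))
```

prints `59 3073 -0.69`: success is now almost certain (59/60 runs), but
its onset is unpredictable — transition times spread from ~225 to
~13,000 ticks and follow a bounded power law with a shallow exponent
near −0.75.  Once triggered, the tip from 50% to 95% refusal takes only
a handful of ticks.

The `examples/` directory contains one short narrative script per
capability: a single spiky run, burst statistics with time-rescaling,
the sigmoidal phase boundary and its shift with the activism threshold,
the transition-time distribution, and intervention experiments (raising
doctor contact, capping AV messages).  A thin CLI wraps the same
library: `avopinion simulate|sweep|analyze|fixtures --help`.

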