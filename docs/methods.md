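# Methods

## The model

`avopinion` simulates the growth dynamics of an online anti-vaccination
(AV) movement as a discrete-time agent-based model of four entity
classes interacting through a shared opinion scale
O ∈ [−2, +2] (+2 strong support for vaccination, −2 strong opposition):

* **patients** — the studied population (constant size NP, default
  2000).  A patient with O < VT (vaccination threshold, −1) is an
  *antivaxxer*; below AT (activism threshold, sweep variable, default
  −1.8) it becomes an *activist* and starts writing messages.
* **doctors** — institutional pro-vaccination contact (ND = 100).  A
  fraction NDU/ND = k·NAV/NP of doctors (k = 0.5) is *uncommitted*:
  visited patients are deflected to the message pool instead of being
  counselled.  Committed doctors hold opinions uniform in [1, 2],
  uncommitted ones in [−0.25, 0].
* **initiators** — NI = 5 fixed-opinion professional agitators at the
  lower opinion bound; they seed the message stream and never change.
* **messages** — infosphere items cloning their author's opinion at
  creation, aging out after 90 ticks.

### Opinion update

An encounter of reader i with source S updates

    O_i ← O_i (1 − α f_iS) + O_S α f_iS,          α = 0.66,

a convex move toward the source damped by the *filtering factor*
f_iS ∈ [0, 1] encoding biased assimilation with emotional asymmetry
(B = 2 is the opinion-bound magnitude, FT = 1 the filtering threshold):

| reader                      | same-sign source | opposing source |
|-----------------------------|------------------|-----------------|
| non-activist, |O_i| ≤ FT    | 1                | 1               |
| non-activist, |O_i| > FT    | 1                | (B−|O_i|)/(B−FT)|
| non-activist, source = message | 1             | 1 (exemption)   |
| activist                    | (B−|O_i|)/(B−FT) | 0               |

The message exemption models the emotional/narrative appeal of AV
content; activists are inflexible and reject all opposing sources
outright.  An opinion of exactly 0 counts as agreeing with either sign
(inert at the default FT, but fixed for determinism), and the damping is
capped at 1 so a reader inside the no-filtering band is never amplified.
Both update operands always lie in bounds, so no clipping is ever
needed; the engine asserts rather than clamps.

### The tick

Each tick executes, in order: (0) doctor-commitment refresh using the
previous tick's NAV, the uncommitted subset re-drawn uniformly each time
and flipped doctors re-drawing their opinion from the new range;
(1) aging — non-activists age +1, activists +0.5 per tick, patients
reaching age 90 are replaced in place by fresh truncated-normal
(OC = 0, OSD = 0.5) agents, expired messages disappear; (2) writing —
every initiator and activist makes five independent Bernoulli(PW)
write attempts, each success cloning its current opinion; (3) doctor
visits — each patient visits a uniform random doctor with probability
PVD; (4) external exposure — every patient, in a fresh random
permutation, meets one source drawn uniformly from the pooled union of
doctors, other patients and active messages.  Updates are sequential
(asynchronous): earlier updates in the permutation are visible to later
readers.  Activist status for aging and writing is frozen at tick
start; for filtering it is evaluated live.

### Finite attention (message read capacity)

Each message is readable a finite number of times
(`message_read_capacity`, default 6) before it deactivates.  This is
the one mechanism whose form the model's verbal description leaves
open, and it is load-bearing: with an unlimited standing pool, NI·5·PW·90 ≈ 10³
initiator messages accumulate, per-patient message-contact rates reach
tens of percent per tick, and the population avalanches into AV
dominance within ~30–170 ticks for *any* parameter setting —
no metastable spiky regime exists.  With finite capacity the message
channel becomes write-rate-limited (reads/tick ≈ writes/tick), the
background state is metastable, and the documented phenomenology
(bursts, sigmoid phase boundary, shallow power-law transition times)
emerges.  Capacity `None` restores the persistent-pool variant, and
`source_mode="category"` replaces union-uniform source choice with
category-then-member choice, for comparison studies.

### Calibration

Two parameters without canonical values — the doctor-visit ratio PVD
and the read capacity — were calibrated once, jointly, against the regime
map the model is known to produce, and then frozen: at (AT, PW) =
(−1.8, 0.45) the system must be metastable over 20,000 ticks with
intermittent activist bursts; at (−1.7, 0.45) and (−1.8, 0.70) AV
success must be almost certain, with onset times spread over the whole
window.  PVD = 0.5 and capacity 6 satisfy all three simultaneously;
no quantity reported by the test suite was used in choosing them.

### AV success and transition times

Success is declared when NAV/NP ≥ 0.95 holds for one patient lifetime
(90 consecutive ticks); the transition time is the first tick of that
window, and the transition duration runs from the last upward crossing
of NAV/NP = 0.5 to the first tick at or above 0.95.  All three
thresholds are configurable (`success_low`, `success_high`,
`success_window`).  Runs stop early once success is confirmed (the
dominant state is absorbing in practice); this is switchable off.

## Randomness and reproducibility

A root seed spawns six named `numpy` substreams (initialization,
doctors, replacement, writing, visits, exposure) via `SeedSequence`.
The production engine is a numba-compiled kernel; a naive per-agent
reference implementation consumes the identical draw sequence (uniform
integers realised as ⌊u·n⌋, truncated normals by rejection, subsets and
permutations by forward Fisher–Yates), and the test suite asserts
bit-identical output of the two.  Ensembles seed cell i, replicate j
with `base_seed + i·n_reps + j`.

## Burst analysis

Peak detection (no canonical method exists for series like these, so
this is the package's own): the background is a rolling median over 21 bins;
bins exceeding 5× the background (floored at ε = 1 count to guard
near-zero backgrounds) are candidates; candidate runs closer than
3 bins merge into one peak at their maximum.  Relative height is
apex/background.  All knobs are exposed.

Fitters: lognormal by exact MLE on logs; log-Cauchy by Cauchy MLE on
logs (median/half-IQR start); bounded power law C·x^γ on [xmin, xmax]
either by exact truncated MLE (well defined for any real γ, as required
by shallow exponents like −0.75 that are non-normalizable on unbounded
support) or by least squares on a log-binned histogram (15 bins/decade,
density = count/(width·n)).  The KS distance is the uniform goodness
measure.  Transition-time fits use xmin = 100 ticks (the transition
itself takes of order one patient lifetime, so earlier onsets are not
meaningful) and xmax = the 20,000-tick window.

## Problem sizes in the shipped checks

The statistical tests and `scripts/acceptance.py` use reduced ensemble
profiles chosen as the package's own defaults for routine validation:
200 (tests) / 150 (script) runs for the transition-time exponent at
full NP = 2000; 100/60 runs for the transition-duration check; a
7-point PW grid × 20 replicates at NP = 500 for the phase boundary;
20 seeds for the spiky regime.  A full-scale study (1000 replicates per
cell) uses the same code paths via `EnsembleSpec`.

## What the synthetic fixtures do and do not show

`generate_synthetic_bursts` plants lognormal-height peaks at
lognormal-gap positions over Poisson background with known ground
truth; it validates the detector and the fitters end-to-end
(≥95% recovery, parameter recovery within stated tolerances).  It does
not emulate real comment streams: empirical series have trends,
weekly/diurnal cycles and heavy-tailed backgrounds that the fixtures
omit, so detector performance on real corpora is not established by
these tests.

## Known limitations

* No social-network topology: all contacts are global-uniform, by
  design of the underlying model.
* The finite-attention mechanism is inferred from the regime map the
  model is designed to exhibit; its capacity value is a calibrated, not
  measured, quantity.
* Burst frequency in the metastable regime is sensitive to the
  calibration: around 3–4 detected bursts per 20,000 ticks at the
  defaults, with substantial run-to-run variance.
* Fixed lifetimes (90 ticks) for patients and messages; real attention
  spans are distributed.
* The sequential-update order within a tick is one concrete choice
  among the schedules agent-based frameworks typically use; the substream design isolates it so
  that alternative schedules could be compared without losing
  reproducibility.
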