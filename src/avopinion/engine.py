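"""Simulation engine: the four-process tick, metrics and success detection.

Each simulation tick executes, in order:

0. doctor-commitment refresh (proportional to the antivaxxer fraction of
   the previous tick),
1. aging and replacement of patients (activists at a reduced pace) and
   expiry of messages,
2. message writing by initiators and activists (Bernoulli trials with the
   writing probability, up to five messages per author),
3. doctor visits (a committed doctor persuades directly; an uncommitted
   one deflects the patient to a random infosphere message),
4. external exposure of every patient, in a fresh random order, to one
   random source (doctor, other patient, or message).

Two interchangeable implementations exist: a naive per-agent reference
written against :class:`~avopinion.model_core.Patient` objects (this
module) and a compiled kernel (:mod:`avopinion._kernel`).  Both consume
identically ordered draws from five named substreams, so their outputs
are bit-identical; the equivalence is exercised by the test suite.

Randomness: a root seed spawns named substreams via
``numpy.random.SeedSequence.spawn`` in the fixed order
(initialization, doctors, replacement, writing, visits, exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .model_core import (
    Doctor,
    Message,
    ModelParams,
    Patient,
    draw_initial_opinion,
    filtering_factor,
    partial_shuffle_prefix,
    rand_index,
    rand_uniform,
    refresh_doctor_commitment,
    update_opinion,
)

__all__ = [
    "SimulationState",
    "TickMetrics",
    "SimulationResult",
    "init_state",
    "make_substreams",
    "age_and_replace",
    "write_messages",
    "doctor_visit_process",
    "external_exposure_process",
    "simulation_tick",
    "detect_av_success",
    "run_simulation",
    "run_reference_simulation",
]

METRIC_COLUMNS = _kernel.METRIC_COLUMNS

STREAM_NAMES = ("initialization", "doctors", "replacement", "writing", "visits", "exposure")


def make_substreams(seed: int) -> dict:
    """Spawn the named, independent random substreams from a root seed."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(STREAM_NAMES, children)
    }


@dataclass
class SimulationState:
    """Full mutable state of one simulation run (reference engine)."""

    tick: int
    patients: List[Patient]
    doctors: List[Doctor]
    initiators: List[float]  # fixed opinions
    messages: List[Message]
    streams: dict
    activist_flags: Optional[np.ndarray] = None  # frozen at tick start


@dataclass(frozen=True)
class TickMetrics:
    tick: int
    new_messages: int  # authored by activists this tick (initiators excluded)
    new_messages_total: int
    active_messages: int
    n_antivax: int
    n_activists: int
    n_uncommitted_doctors: int
    mean_opinion: float


@dataclass
class SimulationResult:
    params: ModelParams
    seed: int
    metrics: pd.DataFrame  # one row per executed tick, METRIC_COLUMNS
    av_success: bool
    transition_time: Optional[int]
    transition_duration: Optional[int]


def init_state(params: ModelParams, seed: int) -> SimulationState:
    """Create the tick-0 state.

    Patients draw an opinion from the truncated normal and a uniformly
    staggered starting age in [0, lifetime) — one opinion draw (possibly
    more under rejection) followed by one age draw per patient, from the
    ``initialization`` stream.  Doctors start committed with uniform
    opinions from the committed range.  The message pool starts empty.
    """
    streams = make_substreams(seed)
    g = streams["initialization"]
    patients = []
    for i in range(params.n_patients):
        op = draw_initial_opinion(g, params)
        age = g.random() * params.patient_lifetime
        patients.append(Patient(id=i, opinion=op, age=age))
    c_lo, c_hi = params.committed_doctor_opinion_range
    doctors = [
        Doctor(id=d, opinion=rand_uniform(g, c_lo, c_hi), committed=True)
        for d in range(params.n_doctors)
    ]
    initiators = [params.initiator_opinion] * params.n_initiators
    return SimulationState(
        tick=0, patients=patients, doctors=doctors, initiators=initiators,
        messages=[], streams=streams,
    )


# ---------------------------------------------------------------------------
# reference (naive per-agent) implementations of the four processes
# ---------------------------------------------------------------------------

def age_and_replace(state: SimulationState, params: ModelParams) -> None:
    """Age patients (activists at the reduced factor) and messages.

    A patient reaching its lifetime is replaced in place by a fresh agent
    with a truncated-normal opinion and age 0; expired messages are
    dropped without replacement.  Patient count is conserved.
    """
    g = state.streams["replacement"]
    flags = state.activist_flags
    for i, p in enumerate(state.patients):
        p.age += params.activist_aging_factor if flags[i] else 1.0
        if p.age >= params.patient_lifetime:
            p.opinion = draw_initial_opinion(g, params)
            p.age = 0.0
    survivors = []
    for m in state.messages:
        m.age += 1
        if m.age < params.message_lifetime:
            survivors.append(m)
    state.messages = survivors


def write_messages(state: SimulationState, params: ModelParams) -> Tuple[int, int]:
    """Initiators then activists each attempt up to five Bernoulli writes.

    Each success clones the author's current opinion into a fresh message.
    When the intervention cap is active, writes beyond the cap are
    discarded (newest rejected) and not counted.  Returns
    (activist-authored count, total count).
    """
    g = state.streams["writing"]
    cap = params.effective_message_cap
    new_act = 0
    new_tot = 0
    for op in state.initiators:
        for _ in range(params.max_messages_per_author_per_tick):
            if g.random() < params.writing_probability:
                if len(state.messages) < cap:
                    state.messages.append(Message(
                        opinion=op, age=0, authored_by_initiator=True,
                        reads_left=params.message_read_capacity))
                    new_tot += 1
    flags = state.activist_flags
    for i, p in enumerate(state.patients):
        if flags[i]:
            for _ in range(params.max_messages_per_author_per_tick):
                if g.random() < params.writing_probability:
                    if len(state.messages) < cap:
                        state.messages.append(Message(
                            opinion=p.opinion, age=0, authored_by_initiator=False,
                            reads_left=params.message_read_capacity))
                        new_tot += 1
                        new_act += 1
    return new_act, new_tot


def _apply(p: Patient, o_s: float, is_msg: bool, params: ModelParams) -> None:
    is_act = p.opinion < params.activism_threshold
    f = filtering_factor(p.opinion, o_s, is_act, is_msg, params)
    p.opinion = update_opinion(p.opinion, o_s, params.alpha, f)


def _consume_message(state: SimulationState, m: int, params: ModelParams) -> None:
    """Spend one unit of a message's read capacity; swap-remove at zero."""
    msgs = state.messages
    if msgs[m].reads_left is None:
        return
    msgs[m].reads_left -= 1
    if msgs[m].reads_left <= 0:
        msgs[m] = msgs[-1]
        msgs.pop()


def doctor_visit_process(state: SimulationState, params: ModelParams) -> None:
    """Each patient independently visits a random doctor with probability PVD.

    A committed doctor persuades directly (ordinary filtering); an
    uncommitted doctor deflects the patient to a uniform random message
    (message filtering rules, i.e. exempt for non-activists).  An empty
    pool leaves the patient unchanged.
    """
    g = state.streams["visits"]
    nd = params.n_doctors
    for p in state.patients:
        if g.random() < params.doctor_visit_ratio:
            doc = state.doctors[rand_index(g, nd)]
            if doc.committed:
                _apply(p, doc.opinion, False, params)
            elif state.messages:
                m = rand_index(g, len(state.messages))
                _apply(p, state.messages[m].opinion, True, params)
                _consume_message(state, m, params)


def external_exposure_process(state: SimulationState, params: ModelParams) -> None:
    """Expose every patient, in a fresh random order, to one random source.

    Updates are sequential: a patient updated early in the permutation
    exposes its new opinion to patients later in the same permutation.
    Source selection follows ``params.source_mode``: either one uniform
    entity from the union of doctors, other patients and messages
    (``"union"``), or a uniform category followed by a uniform member
    (``"category"``).  Initiators are never direct contacts; their
    influence flows only through messages.
    """
    g = state.streams["exposure"]
    np_ = params.n_patients
    nd = params.n_doctors
    perm = partial_shuffle_prefix(g, np_, np_ - 1)
    for i in perm:
        p = state.patients[i]
        n_msg = len(state.messages)
        if params.source_mode == "union":
            tot = nd + (np_ - 1) + n_msg
            r = rand_index(g, tot)
            if r < nd:
                _apply(p, state.doctors[r].opinion, False, params)
            elif r < nd + np_ - 1:
                j = r - nd
                if j >= i:
                    j += 1
                _apply(p, state.patients[j].opinion, False, params)
            else:
                m = r - nd - (np_ - 1)
                _apply(p, state.messages[m].opinion, True, params)
                _consume_message(state, m, params)
        else:
            ncat = 1 + (1 if np_ > 1 else 0) + (1 if n_msg > 0 else 0)
            c = rand_index(g, ncat)
            if np_ == 1 and c >= 1:
                c += 1
            if c == 0:
                _apply(p, state.doctors[rand_index(g, nd)].opinion, False, params)
            elif c == 1:
                j = rand_index(g, np_ - 1)
                if j >= i:
                    j += 1
                _apply(p, state.patients[j].opinion, False, params)
            else:
                m = rand_index(g, n_msg)
                _apply(p, state.messages[m].opinion, True, params)
                _consume_message(state, m, params)


def simulation_tick(state: SimulationState, params: ModelParams) -> TickMetrics:
    """Run one full tick (processes 0-4) and return the tick's metrics."""
    nav_prev = sum(1 for p in state.patients if p.opinion < params.vaccination_threshold)
    refresh_doctor_commitment(nav_prev, state.doctors, params, state.streams["doctors"])
    state.activist_flags = np.array(
        [p.opinion < params.activism_threshold for p in state.patients])
    age_and_replace(state, params)
    new_act, new_tot = write_messages(state, params)
    doctor_visit_process(state, params)
    external_exposure_process(state, params)
    state.tick += 1
    ops = [p.opinion for p in state.patients]
    vt, at = params.vaccination_threshold, params.activism_threshold
    total = 0.0  # sequential sum matches the kernel bit-for-bit
    for o in ops:
        total += o
    return TickMetrics(
        tick=state.tick,
        new_messages=new_act,
        new_messages_total=new_tot,
        active_messages=len(state.messages),
        n_antivax=sum(1 for o in ops if o < vt),
        n_activists=sum(1 for o in ops if o < at),
        n_uncommitted_doctors=sum(1 for d in state.doctors if not d.committed),
        mean_opinion=total / params.n_patients,
    )


# ---------------------------------------------------------------------------
# success detection
# ---------------------------------------------------------------------------

def detect_av_success(
    nav_fraction: np.ndarray,
    params: ModelParams,
) -> Tuple[bool, Optional[int], Optional[int]]:
    """Detect the anti-vaccination dominance transition in a NAV/NP series.

    Success is declared when the antivaxxer fraction stays at or above
    ``success_high`` (default 0.95) for ``success_window`` consecutive
    ticks (default one patient lifetime).  ``transition_time`` is the
    first tick of that window (1-based, matching the metrics table).
    ``transition_duration`` spans from the last upward crossing of
    ``success_low`` (default 0.5) to the first tick at or above
    ``success_high`` after that crossing.
    """
    frac = np.asarray(nav_fraction, dtype=float)
    if frac.size == 0:
        return False, None, None
    high = frac >= params.success_high
    window = params.success_window
    run = 0
    start = None
    for t, h in enumerate(high):
        run = run + 1 if h else 0
        if run >= window:
            start = t - window + 1
            break
    if start is None:
        return False, None, None
    above_low = frac >= params.success_low
    cross = 0  # default: already above low at t=0
    for t in range(start, 0, -1):
        if above_low[t] and not above_low[t - 1]:
            cross = t
            break
    t_high = cross
    while not high[t_high]:
        t_high += 1
    return True, start + 1, t_high - cross


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _metrics_frame(arr: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(arr, columns=list(METRIC_COLUMNS))
    for col in METRIC_COLUMNS[:-1]:
        df[col] = df[col].astype(np.int64)
    return df


def run_simulation(
    params: ModelParams,
    seed: int,
    *,
    early_stop: bool = True,
    engine: str = "fast",
) -> SimulationResult:
    """Run one simulation to ``max_ticks`` (or early stop after success).

    Deterministic given ``(params, seed)``: identical inputs give
    bit-identical metric series whichever engine is used.  ``engine`` is
    ``"fast"`` (compiled kernel, default) or ``"reference"`` (naive
    per-agent implementation, for testing and small instances).
    """
    if engine == "reference":
        return run_reference_simulation(params, seed, early_stop=early_stop)
    if engine != "fast":
        raise ValueError(f"unknown engine '{engine}'")

    state = init_state(params, seed)
    np_ = params.n_patients
    pat_op = np.array([p.opinion for p in state.patients])
    pat_age = np.array([p.age for p in state.patients])
    doc_op = np.array([d.opinion for d in state.doctors])
    doc_unc = np.array([not d.committed for d in state.doctors])
    cap = params.effective_message_cap
    msg_op = np.empty(cap)
    msg_age = np.empty(cap, dtype=np.int32)
    msg_init = np.empty(cap, dtype=np.bool_)
    msg_reads = np.empty(cap, dtype=np.int64)
    read_cap = (np.iinfo(np.int64).max if params.message_read_capacity is None
                else params.message_read_capacity)
    out = np.empty((params.max_ticks, len(METRIC_COLUMNS)))

    ticks_done, _ = _kernel.run_kernel(
        pat_op, pat_age, doc_op, doc_unc, msg_op, msg_age, msg_init, msg_reads,
        params.n_initiators, params.initiator_opinion, params.alpha,
        params.opinion_center, params.opinion_sd,
        params.opinion_bounds[0], params.opinion_bounds[1],
        params.vaccination_threshold, params.activism_threshold,
        params.filtering_threshold, params.writing_probability,
        params.doctor_visit_ratio, params.doctor_hesitancy_factor,
        params.patient_lifetime, params.message_lifetime,
        params.activist_aging_factor, params.max_messages_per_author_per_tick,
        params.committed_doctor_opinion_range[0],
        params.committed_doctor_opinion_range[1],
        params.uncommitted_doctor_opinion_range[0],
        params.uncommitted_doctor_opinion_range[1],
        cap, params.max_ticks, params.source_mode == "union", read_cap,
        params.success_high, params.success_window, early_stop,
        state.streams["doctors"], state.streams["replacement"],
        state.streams["writing"], state.streams["visits"],
        state.streams["exposure"], out,
    )
    metrics = _metrics_frame(out[:ticks_done])
    frac = metrics["n_antivax"].to_numpy() / np_
    success, t_time, t_dur = detect_av_success(frac, params)
    return SimulationResult(params, seed, metrics, success, t_time, t_dur)


def run_reference_simulation(
    params: ModelParams,
    seed: int,
    *,
    early_stop: bool = True,
    n_ticks: Optional[int] = None,
) -> SimulationResult:
    """Naive per-agent driver; bit-identical to the fast engine."""
    state = init_state(params, seed)
    limit = params.max_ticks if n_ticks is None else n_ticks
    rows = []
    run = 0
    for _ in range(limit):
        tm = simulation_tick(state, params)
        rows.append(tm)
        if tm.n_antivax / params.n_patients >= params.success_high:
            run += 1
        else:
            run = 0
        if early_stop and run >= params.success_window:
            break
    metrics = pd.DataFrame([t.__dict__ for t in rows], columns=list(METRIC_COLUMNS))
    frac = metrics["n_antivax"].to_numpy() / params.n_patients
    success, t_time, t_dur = detect_av_success(frac, params)
    return SimulationResult(params, seed, metrics, success, t_time, t_dur)
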