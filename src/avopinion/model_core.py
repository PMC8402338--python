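"""Core agent types and the mathematical heart of the opinion model.

The model describes a population of *patients* exchanging opinions about
vaccination on a bounded scale (default [-2, +2]; +2 = strong support,
-2 = strong opposition) with three other entity classes: *doctors*
(pro-vaccination communication, partly "uncommitted" when hesitancy is
widespread), *initiators* (a handful of fixed-opinion anti-vaccination
professionals) and *messages* (infosphere items that clone their author's
opinion and age out).

This module holds the pure functions: the convex opinion update, the
emotionally asymmetric filtering factor, initial-opinion sampling, patient
classification and the doctor-commitment refresh.  Everything here is
deterministic given an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelParams",
    "Patient",
    "Doctor",
    "Message",
    "filtering_factor",
    "update_opinion",
    "draw_initial_opinion",
    "classify_patient",
    "refresh_doctor_commitment",
    "rand_index",
    "rand_uniform",
    "VACCINATOR",
    "ANTIVAXXER",
    "ACTIVIST",
]

VACCINATOR = "vaccinator"
ANTIVAXXER = "antivaxxer"
ACTIVIST = "activist"

#: How a reading patient picks its information source during external
#: exposure: ``"category"`` first picks uniformly among the non-empty
#: source classes {doctor, other patient, message}, then a uniform member;
#: ``"union"`` picks one uniform entity from the pooled union of all three
#: classes, so each class is weighted by its current size.
SOURCE_MODES = ("category", "union")


@dataclass(frozen=True)
class ModelParams:
    """Validated record of every model parameter.

    Defaults reproduce the model's baseline study configuration:
    2000 patients, 100 doctors, acceptance rate ``alpha = 0.66``, initial
    opinions from a truncated normal centred at 0 with SD 0.5 on [-2, 2],
    vaccination threshold -1, filtering threshold 1, 90-tick lifetimes and
    half-pace aging for activists.  ``activism_threshold`` and
    ``writing_probability`` are the usual sweep variables.
    """

    n_patients: int = 2000
    n_doctors: int = 100
    n_initiators: int = 5
    initiator_opinion: Optional[float] = None  # default: lower opinion bound
    alpha: float = 0.66
    opinion_center: float = 0.0
    opinion_sd: float = 0.5
    opinion_bounds: Tuple[float, float] = (-2.0, 2.0)
    vaccination_threshold: float = -1.0
    activism_threshold: float = -1.8
    filtering_threshold: float = 1.0
    writing_probability: float = 0.45
    doctor_visit_ratio: float = 0.5
    doctor_hesitancy_factor: float = 0.5
    patient_lifetime: int = 90
    message_lifetime: int = 90
    activist_aging_factor: float = 0.5
    max_messages_per_author_per_tick: int = 5
    committed_doctor_opinion_range: Tuple[float, float] = (1.0, 2.0)
    uncommitted_doctor_opinion_range: Tuple[float, float] = (-0.25, 0.0)
    message_cap: Optional[int] = None
    max_ticks: int = 20000
    source_mode: str = "union"
    #: finite attention span of the infosphere: a message is deactivated
    #: after this many reads (None = unlimited, messages persist until
    #: they age out).  Small capacities make the message channel
    #: write-rate-limited, which is what keeps the background state
    #: metastable instead of avalanching immediately.
    message_read_capacity: Optional[int] = 6
    # AV-success detection thresholds (fractions of the patient population);
    # the success window length defaults to one patient lifetime.
    success_low: float = 0.5
    success_high: float = 0.95
    success_window: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "initiator_opinion",
            self.opinion_bounds[0]
            if self.initiator_opinion is None
            else float(self.initiator_opinion),
        )
        object.__setattr__(
            self,
            "success_window",
            self.patient_lifetime if self.success_window is None else int(self.success_window),
        )
        self._validate()

    # -- derived quantities -------------------------------------------------
    @property
    def bound_magnitude(self) -> float:
        """Magnitude B of the symmetric opinion bounds [-B, B]."""
        return self.opinion_bounds[1]

    @property
    def effective_message_cap(self) -> int:
        """Hard pool ceiling: the intervention cap, or the natural maximum."""
        natural = (
            (self.n_initiators + self.n_patients)
            * self.max_messages_per_author_per_tick
            * self.message_lifetime
        )
        return natural if self.message_cap is None else min(self.message_cap, natural)

    def _validate(self) -> None:
        lo, hi = self.opinion_bounds
        def fail(key: str, constraint: str) -> None:
            raise ValueError(f"parameter '{key}': {constraint}")

        if not lo < hi:
            fail("opinion_bounds", "lower bound must be below upper bound")
        if not math.isclose(-lo, hi):
            fail("opinion_bounds", "bounds must be symmetric [-B, B]")
        for key in ("n_patients", "n_doctors", "patient_lifetime", "message_lifetime",
                    "max_messages_per_author_per_tick", "max_ticks"):
            if getattr(self, key) <= 0:
                fail(key, "must be a positive count")
        if self.n_initiators < 0:
            fail("n_initiators", "must be a non-negative count")
        if not 0.0 < self.alpha <= 1.0:
            fail("alpha", "acceptance rate must lie in (0, 1]")
        for key in ("writing_probability", "doctor_visit_ratio"):
            if not 0.0 <= getattr(self, key) <= 1.0:
                fail(key, "probability must lie in [0, 1]")
        if not 0.0 < self.doctor_hesitancy_factor < 1.0:
            fail("doctor_hesitancy_factor", "k must lie strictly in (0, 1)")
        if self.opinion_sd < 0.0:
            fail("opinion_sd", "standard deviation must be non-negative")
        at, vt, ft = self.activism_threshold, self.vaccination_threshold, self.filtering_threshold
        if not (lo <= at < vt <= 0.0 < ft <= hi):
            fail("activism_threshold",
                 f"thresholds must satisfy {lo} <= AT < VT <= 0 < FT <= {hi} "
                 f"(got AT={at}, VT={vt}, FT={ft})")
        if ft >= hi:
            fail("filtering_threshold", "FT equal to the opinion bound divides by zero")
        if self.n_initiators and not self.initiator_opinion < at:
            fail("initiator_opinion", "must lie below the activism threshold")
        c_lo, c_hi = self.committed_doctor_opinion_range
        u_lo, u_hi = self.uncommitted_doctor_opinion_range
        if not (lo <= c_lo <= c_hi <= hi and lo <= u_lo <= u_hi <= hi):
            fail("committed_doctor_opinion_range", "doctor ranges must lie within the opinion bounds")
        if self.message_cap is not None and self.message_cap <= 0:
            fail("message_cap", "cap, if set, must be positive")
        if self.message_read_capacity is not None and self.message_read_capacity <= 0:
            fail("message_read_capacity", "read capacity, if set, must be positive")
        if not 0.0 < self.activist_aging_factor <= 1.0:
            fail("activist_aging_factor", "must lie in (0, 1]")
        if not 0.0 <= self.success_low < self.success_high <= 1.0:
            fail("success_low", "success thresholds must satisfy 0 <= low < high <= 1")
        if self.success_window <= 0:
            fail("success_window", "must be a positive tick count")
        if self.source_mode not in SOURCE_MODES:
            fail("source_mode", f"must be one of {SOURCE_MODES}")

    def with_overrides(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass
class Patient:
    """A member of the studied population.

    Age is fractional because activists age at a reduced factor
    (default 0.5) while holding activist status.
    """

    id: int
    opinion: float
    age: float = 0.0


@dataclass
class Doctor:
    id: int
    opinion: float
    committed: bool = True


@dataclass
class Message:
    """An infosphere item cloning its author's opinion at creation time.

    ``reads_left`` counts down the message's remaining attention span
    when a read capacity is configured; ``None`` means unlimited reads.
    """

    opinion: float
    age: int = 0
    authored_by_initiator: bool = False
    reads_left: Optional[int] = None


# ---------------------------------------------------------------------------
# randomness primitives (the draw contract shared with the compiled kernel)
# ---------------------------------------------------------------------------

def rand_index(rng: np.random.Generator, n: int) -> int:
    """Uniform integer in [0, n) realised as floor(u * n) from one draw."""
    return int(rng.random() * n)


def rand_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Uniform real in [lo, hi) realised as lo + u * (hi - lo)."""
    return lo + rng.random() * (hi - lo)


# ---------------------------------------------------------------------------
# the mathematical core
# ---------------------------------------------------------------------------

def filtering_factor(
    o_i: float,
    o_s: float,
    is_activist: bool,
    source_is_message: bool,
    params: ModelParams,
) -> float:
    """Biased-assimilation discount f applied to a source's influence.

    Non-activist readers with a moderate opinion (|o_i| <= FT) do not
    filter at all.  More extreme non-activists accept same-sign sources in
    full and discount opposing ones by (B - |o_i|) / (B - FT), where B is
    the opinion-bound magnitude.  Messages are exempt from non-activist
    filtering altogether, reflecting the emotional appeal of narrative
    anti-vaccination content.  Activists are inflexible: they discount
    even same-sign sources by the same factor and reject opposing sources
    completely (f = 0), messages included.

    An opinion of exactly 0 is treated as agreeing with either sign.
    """
    b = params.bound_magnitude
    ft = params.filtering_threshold
    same_sign = o_i * o_s >= 0.0
    # the damping only bites for |o_i| > FT; capped at 1 so that a reader
    # inside the no-filtering band is never amplified
    damp = min((b - abs(o_i)) / (b - ft), 1.0)
    if is_activist:
        return damp if same_sign else 0.0
    if source_is_message:
        return 1.0
    if abs(o_i) <= ft or same_sign:
        return 1.0
    return damp


def update_opinion(o_i: float, o_s: float, alpha: float, f: float) -> float:
    """Convex opinion update: o_i * (1 - alpha*f) + o_s * alpha*f.

    The result always lies between reader and source, so opinions never
    leave the bounds if both operands are inside them.
    """
    w = alpha * f
    return o_i * (1.0 - w) + o_s * w


def draw_initial_opinion(rng: np.random.Generator, params: ModelParams) -> float:
    """Sample a fresh patient opinion: normal(OC, OSD) truncated to bounds.

    Implemented by rejection so that the exact draw sequence is part of
    the reproducibility contract shared with the compiled engine.  A zero
    SD degenerates to the centre without consuming randomness.
    """
    if params.opinion_sd == 0.0:
        return params.opinion_center
    lo, hi = params.opinion_bounds
    while True:
        x = rng.normal(params.opinion_center, params.opinion_sd)
        if lo <= x <= hi:
            return x


def classify_patient(opinion: float, params: ModelParams) -> str:
    """Classify an opinion as vaccinator, antivaxxer or activist.

    Strict inequalities: opinion < AT is an activist (which also counts as
    an antivaxxer in population tallies), AT <= opinion < VT a plain
    antivaxxer, opinion >= VT a vaccinator.
    """
    if opinion < params.activism_threshold:
        return ACTIVIST
    if opinion < params.vaccination_threshold:
        return ANTIVAXXER
    return VACCINATOR


def target_uncommitted(n_antivax: int, params: ModelParams) -> int:
    """Number of uncommitted doctors: round-half-up of ND * k * NAV / NP."""
    exact = (
        params.n_doctors * params.doctor_hesitancy_factor * n_antivax / params.n_patients
    )
    return int(math.floor(exact + 0.5))


def partial_shuffle_prefix(
    rng: np.random.Generator, n: int, m: int
) -> np.ndarray:
    """Forward Fisher-Yates selecting a uniform m-subset into idx[:m].

    Part of the draw contract: one uniform draw per position j, swapping
    idx[j] with idx[j + floor(u * (n - j))].  With m = n - 1 this yields a
    full uniform permutation.
    """
    idx = np.arange(n)
    for j in range(min(m, n - 1)):
        t = j + rand_index(rng, n - j)
        idx[j], idx[t] = idx[t], idx[j]
    return idx


def refresh_doctor_commitment(
    n_antivax: int,
    doctors: Sequence[Doctor],
    params: ModelParams,
    rng: np.random.Generator,
) -> None:
    """Re-draw which doctors are uncommitted, in proportion to hesitancy.

    The uncommitted head-count is round(ND * k * NAV / NP); the subset is
    a fresh uniform sample at every refresh.  A doctor whose commitment
    flips receives a new opinion drawn uniformly from the range of its new
    group ([1, 2] committed, [-0.25, 0] uncommitted); doctors whose status
    is unchanged keep their opinion.  Mutates ``doctors`` in place.
    """
    nd = params.n_doctors
    ndu = target_uncommitted(n_antivax, params)
    idx = partial_shuffle_prefix(rng, nd, ndu)
    uncommitted = np.zeros(nd, dtype=bool)
    uncommitted[idx[:ndu]] = True
    c_lo, c_hi = params.committed_doctor_opinion_range
    u_lo, u_hi = params.uncommitted_doctor_opinion_range
    for d in range(nd):
        doc = doctors[d]
        new_status = bool(uncommitted[d])
        if doc.committed == (not new_status):
            continue
        doc.committed = not new_status
        if new_status:
            doc.opinion = rand_uniform(rng, u_lo, u_hi)
        else:
            doc.opinion = rand_uniform(rng, c_lo, c_hi)
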