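"""Engine tests: process contracts, conservation laws, success detection,
and the compiled-kernel vs naive-reference equivalence oracle."""

import numpy as np
import pytest

from avopinion import (
    ModelParams,
    detect_av_success,
    init_state,
    run_reference_simulation,
    run_simulation,
)
from avopinion.engine import (
    age_and_replace,
    doctor_visit_process,
    external_exposure_process,
    simulation_tick,
    write_messages,
)
from avopinion.model_core import Doctor, Message, Patient


def _flags(state, params):
    state.activist_flags = np.array(
        [p.opinion < params.activism_threshold for p in state.patients])


class TestReferenceProcesses:
    def test_doctor_visit_noop_when_pvd_zero(self, tiny_params):
        params = tiny_params.with_overrides(doctor_visit_ratio=0.0)
        state = init_state(params, 3)
        before = [p.opinion for p in state.patients]
        doctor_visit_process(state, params)
        assert [p.opinion for p in state.patients] == before

    def test_committed_visit_applies_update(self, tiny_params):
        """A neutral patient pulled by a committed doctor at 1.5 lands on 0.99."""
        params = tiny_params.with_overrides(doctor_visit_ratio=1.0, n_patients=1)
        state = init_state(params, 3)
        state.patients = [Patient(id=0, opinion=0.0, age=0.0)]
        state.doctors = [Doctor(id=d, opinion=1.5, committed=True)
                         for d in range(params.n_doctors)]
        doctor_visit_process(state, params)
        assert state.patients[0].opinion == pytest.approx(0.99)

    def test_uncommitted_visit_with_empty_pool_is_noop(self, tiny_params):
        params = tiny_params.with_overrides(doctor_visit_ratio=1.0)
        state = init_state(params, 3)
        for d in state.doctors:
            d.committed = False
            d.opinion = -0.1
        before = [p.opinion for p in state.patients]
        doctor_visit_process(state, params)
        assert [p.opinion for p in state.patients] == before

    def test_writing_counts(self, tiny_params):
        # PW=0 writes nothing; PW=1 writes exactly 5 per initiator
        for pw, expected in ((0.0, 0), (1.0, 5 * tiny_params.n_initiators)):
            params = tiny_params.with_overrides(writing_probability=pw)
            state = init_state(params, 5)
            _flags(state, params)
            new_act, new_tot = write_messages(state, params)
            assert new_act == 0  # no activists in a near-neutral start
            assert new_tot == expected
            assert len(state.messages) == expected

    def test_writing_mean_rate(self, tiny_params):
        """Initiators and activists write Binomial(5, PW) messages each."""
        params = tiny_params.with_overrides(writing_probability=0.45)
        state = init_state(params, 5)
        # force 4 activists
        for p in state.patients[:4]:
            p.opinion = -1.9
        _flags(state, params)
        totals = []
        for _ in range(400):
            state.messages = []
            _, new_tot = write_messages(state, params)
            totals.append(new_tot)
        expected = (params.n_initiators + 4) * 5 * 0.45
        assert np.mean(totals) == pytest.approx(expected, rel=0.08)

    def test_message_cap_enforced(self, tiny_params):
        params = tiny_params.with_overrides(writing_probability=1.0, message_cap=7)
        state = init_state(params, 5)
        _flags(state, params)
        new_act, new_tot = write_messages(state, params)
        assert len(state.messages) == 7
        assert new_tot == 7  # discarded writes are not counted

    def test_aging_replacement_and_expiry(self, tiny_params):
        params = tiny_params
        state = init_state(params, 9)
        state.patients[0].age = 89.5
        state.patients[0].opinion = -1.9  # activist: ages at half pace
        state.patients[1].age = 89.5      # regular: replaced this tick
        state.messages = [Message(opinion=-2.0, age=89) for _ in range(10)]
        _flags(state, params)
        age_and_replace(state, params)
        # 89.5 + 0.5 (activist pace) and 89.5 + 1.0 both reach the lifetime:
        # replaced in place by fresh age-0 agents
        assert state.patients[0].age == 0.0
        assert state.patients[1].age == 0.0
        assert len(state.patients) == params.n_patients
        assert state.messages == []  # all messages aged out

    def test_activist_ages_at_half_pace(self, tiny_params):
        state = init_state(tiny_params, 9)
        state.patients[0].opinion = -1.9
        state.patients[0].age = 10.0
        state.patients[1].opinion = 0.5
        state.patients[1].age = 10.0
        _flags(state, tiny_params)
        age_and_replace(state, tiny_params)
        assert state.patients[0].age == pytest.approx(10.5)
        assert state.patients[1].age == pytest.approx(11.0)

    def test_sequential_exposure_matches_draw_contract(self, tiny_params):
        """Hand-rolled replay of the documented draw order reproduces the
        sequential (asynchronous) exposure updates exactly."""
        from avopinion.model_core import filtering_factor, update_opinion

        params = tiny_params.with_overrides(
            n_patients=2, n_doctors=1, n_initiators=0, doctor_visit_ratio=0.0)
        state = init_state(params, 21)
        state.patients[0].opinion = 0.0
        state.patients[1].opinion = 1.0
        state.doctors[0].opinion = 1.5
        # independent replay using a generator in the same substream state
        import copy
        replay = copy.deepcopy(state.streams["exposure"])
        ops = [0.0, 1.0]
        perm = [0, 1]
        j = 0 + int(replay.random() * 2)  # single Fisher-Yates swap draw
        perm[0], perm[j] = perm[j], perm[0]
        for i in perm:
            r = int(replay.random() * 2)  # union of 1 doctor + 1 other patient
            o_s = 1.5 if r == 0 else ops[1 - i]
            f = filtering_factor(ops[i], o_s, False, False, params)
            ops[i] = update_opinion(ops[i], o_s, params.alpha, f)
        external_exposure_process(state, params)
        assert [p.opinion for p in state.patients] == pytest.approx(ops)


class TestConservationAndBounds:
    def test_patient_count_and_opinion_bounds(self, tiny_params):
        params = tiny_params.with_overrides(writing_probability=0.6)
        state = init_state(params, 11)
        for _ in range(40):
            tm = simulation_tick(state, params)
            assert len(state.patients) == params.n_patients
            assert all(-2.0 <= p.opinion <= 2.0 for p in state.patients)
            assert tm.n_activists <= tm.n_antivax <= params.n_patients
            assert tm.n_uncommitted_doctors <= params.n_doctors

    def test_message_pool_bounded_by_cap(self):
        params = ModelParams(
            n_patients=100, n_doctors=10, max_ticks=150, message_cap=30,
            writing_probability=0.9)
        res = run_simulation(params, 13, early_stop=False)
        assert (res.metrics["active_messages"] <= 30).all()

    def test_pro_attractor_without_av_forcing(self):
        """With no initiators and no writing, committed doctors pull the
        population mean into the pro-vaccination basin."""
        params = ModelParams(
            n_patients=150, n_doctors=10, n_initiators=0,
            writing_probability=0.0, max_ticks=300)
        res = run_simulation(params, 17, early_stop=False)
        m = res.metrics
        assert not res.av_success
        assert (m["active_messages"] == 0).all()
        assert m["mean_opinion"].iloc[-1] > m["mean_opinion"].iloc[0]
        assert m["mean_opinion"].iloc[-1] > params.vaccination_threshold
        assert m["n_antivax"].iloc[-1] < 0.05 * params.n_patients


class TestSuccessDetection:
    def test_no_success_on_flat_zero(self):
        ok, t, d = detect_av_success(np.zeros(500), ModelParams())
        assert (ok, t, d) == (False, None, None)

    def test_step_series(self):
        frac = np.concatenate([np.zeros(100), np.ones(300)])
        ok, t, d = detect_av_success(frac, ModelParams())
        assert ok and t == 101 and d == 0  # ticks are 1-based

    def test_ramp_duration(self):
        frac = np.concatenate([
            np.zeros(50), np.linspace(0.5, 0.95, 81), np.full(200, 0.96)])
        ok, t, d = detect_av_success(frac, ModelParams())
        assert ok and d == 80

    def test_short_excursion_not_success(self):
        frac = np.zeros(400)
        frac[100:150] = 1.0  # shorter than the success window (90)
        ok, _, _ = detect_av_success(frac, ModelParams())
        assert not ok


class TestEngineEquivalenceAndDeterminism:
    def test_kernel_matches_reference_engine(self, tiny_params):
        """Production kernel and naive per-agent engine are bit-identical
        under the shared draw contract (NP=20, ND=5, 50 ticks)."""
        params = tiny_params.with_overrides(max_ticks=50)
        fast = run_simulation(params, 7, early_stop=False)
        ref = run_reference_simulation(params, 7, early_stop=False)
        assert fast.metrics.equals(ref.metrics)
        assert (fast.av_success, fast.transition_time) == (ref.av_success, ref.transition_time)

    def test_kernel_matches_reference_with_unlimited_reads(self, tiny_params):
        params = tiny_params.with_overrides(
            max_ticks=40, message_read_capacity=None, source_mode="category")
        fast = run_simulation(params, 19, early_stop=False)
        ref = run_reference_simulation(params, 19, early_stop=False)
        assert fast.metrics.equals(ref.metrics)

    def test_same_seed_bit_identical(self, tiny_params):
        a = run_simulation(tiny_params, 42)
        b = run_simulation(tiny_params, 42)
        assert a.metrics.equals(b.metrics)

    def test_different_seeds_differ(self, tiny_params):
        a = run_simulation(tiny_params, 1)
        b = run_simulation(tiny_params, 2)
        assert not a.metrics.equals(b.metrics)

    def test_no_av_success_without_forcing(self):
        params = ModelParams(
            n_patients=100, n_doctors=10, n_initiators=0,
            writing_probability=0.0, max_ticks=400)
        for seed in (1, 2, 3):
            assert not run_simulation(params, seed).av_success

    def test_initial_antivax_fraction(self):
        """Tick-0 NAV matches the truncated-normal tail below VT."""
        from scipy import stats
        state = init_state(ModelParams(), 5)
        nav = sum(1 for p in state.patients if p.opinion < -1.0)
        assert nav == pytest.approx(2000 * stats.norm.cdf(-2.0), abs=15)
        na = sum(1 for p in state.patients if p.opinion < -1.8)
        assert na <= 3  # Phi(-3.6) * 2000 ~ 0.3
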