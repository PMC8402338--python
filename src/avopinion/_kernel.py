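"""Compiled simulation kernel (numba).

This is the production path of the engine.  It executes the same
per-agent, sequential-update semantics as the naive reference
implementation in :mod:`avopinion.engine`, consuming random draws from
five named substreams in a fixed, documented order (the "draw contract"):

per tick, in order:

1. doctor refresh (stream ``doctors``): a forward Fisher-Yates partial
   shuffle selecting the uncommitted subset (one uniform draw per selected
   position), then one uniform draw per doctor whose status flipped, in
   ascending doctor index order;
2. aging/replacement (stream ``replacement``): patients in index order,
   one rejection-sampled truncated-normal draw per replaced patient;
3. message writing (stream ``writing``): initiators in index order then
   activist patients in index order, ``max_messages_per_author_per_tick``
   Bernoulli draws each;
4. doctor visits (stream ``visits``): patients in index order; one visit
   draw each; on a visit one doctor-index draw; if the doctor is
   uncommitted and the pool is non-empty, one message-index draw;
5. external exposure (stream ``exposure``): a full Fisher-Yates shuffle of
   the patient order (one draw per position), then per patient either one
   draw over the pooled entity union (``source_mode="union"``) or a
   category draw followed by a member draw (``source_mode="category"``).

Uniform integers in [0, n) are realised as ``floor(u * n)`` from a single
``random()`` call so that the compiled and interpreted paths are
bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# metric column order produced by the kernel
METRIC_COLUMNS = (
    "tick",
    "new_messages",
    "new_messages_total",
    "active_messages",
    "n_antivax",
    "n_activists",
    "n_uncommitted_doctors",
    "mean_opinion",
)


@njit(cache=True)
def _ffactor(o_i, o_s, is_act, is_msg, b, ft):
    same = o_i * o_s >= 0.0
    damp = min((b - abs(o_i)) / (b - ft), 1.0)
    if is_act:
        return damp if same else 0.0
    if is_msg:
        return 1.0
    if abs(o_i) <= ft or same:
        return 1.0
    return damp


@njit(cache=True)
def _trunc_normal(g, mu, sd, lo, hi):
    if sd == 0.0:
        return mu
    while True:
        x = g.normal(mu, sd)
        if lo <= x <= hi:
            return x


@njit(cache=True)
def run_kernel(
    pat_op,
    pat_age,
    doc_op,
    doc_unc,
    msg_op,
    msg_age,
    msg_init,
    msg_reads,
    ni,
    init_opinion,
    alpha,
    oc,
    osd,
    lo,
    hi,
    vt,
    at,
    ft,
    pw,
    pvd,
    k_hes,
    pat_life,
    msg_life,
    aging_factor,
    max_msgs,
    c_lo,
    c_hi,
    u_lo,
    u_hi,
    cap,
    max_ticks,
    union_mode,
    read_cap,
    succ_high,
    succ_window,
    early_stop,
    g_doc,
    g_repl,
    g_write,
    g_visit,
    g_expo,
    out,
):
    np_ = pat_op.shape[0]
    nd = doc_op.shape[0]
    b = hi

    act_flag = np.empty(np_, dtype=np.bool_)
    perm = np.empty(np_, dtype=np.int64)
    idx = np.empty(nd, dtype=np.int64)
    unc_new = np.empty(nd, dtype=np.bool_)

    n_msg = 0
    nav_prev = 0
    for i in range(np_):
        if pat_op[i] < vt:
            nav_prev += 1

    succ_run = 0
    ticks_done = 0

    for t in range(max_ticks):
        # ---- 0. doctor commitment refresh -------------------------------
        ndu = int(np.floor(nd * k_hes * nav_prev / np_ + 0.5))
        for d in range(nd):
            idx[d] = d
        m_sel = ndu if ndu < nd - 1 else nd - 1
        for j in range(m_sel):
            tj = j + int(g_doc.random() * (nd - j))
            tmp = idx[j]
            idx[j] = idx[tj]
            idx[tj] = tmp
        for d in range(nd):
            unc_new[d] = False
        for j in range(ndu):
            unc_new[idx[j]] = True
        for d in range(nd):
            if doc_unc[d] != unc_new[d]:
                doc_unc[d] = unc_new[d]
                if unc_new[d]:
                    doc_op[d] = u_lo + g_doc.random() * (u_hi - u_lo)
                else:
                    doc_op[d] = c_lo + g_doc.random() * (c_hi - c_lo)

        # activist status frozen at tick start (used for aging + writing)
        for i in range(np_):
            act_flag[i] = pat_op[i] < at

        # ---- 1. aging and replacement -----------------------------------
        for i in range(np_):
            if act_flag[i]:
                pat_age[i] += aging_factor
            else:
                pat_age[i] += 1.0
            if pat_age[i] >= pat_life:
                pat_op[i] = _trunc_normal(g_repl, oc, osd, lo, hi)
                pat_age[i] = 0.0
        kept = 0
        for m in range(n_msg):
            a = msg_age[m] + 1
            if a < msg_life:
                msg_op[kept] = msg_op[m]
                msg_age[kept] = a
                msg_init[kept] = msg_init[m]
                msg_reads[kept] = msg_reads[m]
                kept += 1
        n_msg = kept

        # ---- 2. message writing -----------------------------------------
        new_act = 0
        new_tot = 0
        for _ in range(ni):
            for _ in range(max_msgs):
                if g_write.random() < pw:
                    if n_msg < cap:
                        msg_op[n_msg] = init_opinion
                        msg_age[n_msg] = 0
                        msg_init[n_msg] = True
                        msg_reads[n_msg] = read_cap
                        n_msg += 1
                        new_tot += 1
        for i in range(np_):
            if act_flag[i]:
                for _ in range(max_msgs):
                    if g_write.random() < pw:
                        if n_msg < cap:
                            msg_op[n_msg] = pat_op[i]
                            msg_age[n_msg] = 0
                            msg_init[n_msg] = False
                            msg_reads[n_msg] = read_cap
                            n_msg += 1
                            new_tot += 1
                            new_act += 1

        # ---- 3. doctor visits -------------------------------------------
        for i in range(np_):
            if g_visit.random() < pvd:
                d = int(g_visit.random() * nd)
                o_i = pat_op[i]
                if not doc_unc[d]:
                    f = _ffactor(o_i, doc_op[d], o_i < at, False, b, ft)
                    w = alpha * f
                    pat_op[i] = o_i * (1.0 - w) + doc_op[d] * w
                elif n_msg > 0:
                    m = int(g_visit.random() * n_msg)
                    o_s = msg_op[m]
                    f = _ffactor(o_i, o_s, o_i < at, True, b, ft)
                    w = alpha * f
                    pat_op[i] = o_i * (1.0 - w) + o_s * w
                    msg_reads[m] -= 1
                    if msg_reads[m] <= 0:
                        n_msg -= 1
                        msg_op[m] = msg_op[n_msg]
                        msg_age[m] = msg_age[n_msg]
                        msg_init[m] = msg_init[n_msg]
                        msg_reads[m] = msg_reads[n_msg]

        # ---- 4. external exposure ---------------------------------------
        for i in range(np_):
            perm[i] = i
        for j in range(np_ - 1):
            tj = j + int(g_expo.random() * (np_ - j))
            tmp = perm[j]
            perm[j] = perm[tj]
            perm[tj] = tmp
        for pi in range(np_):
            i = perm[pi]
            o_i = pat_op[i]
            o_s = 0.0
            is_msg = False
            have_source = False
            m_read = -1
            if union_mode:
                tot = nd + (np_ - 1) + n_msg
                r = int(g_expo.random() * tot)
                if r < nd:
                    o_s = doc_op[r]
                    have_source = True
                elif r < nd + np_ - 1:
                    j = r - nd
                    if j >= i:
                        j += 1
                    o_s = pat_op[j]
                    have_source = True
                else:
                    m_read = r - nd - (np_ - 1)
                    o_s = msg_op[m_read]
                    is_msg = True
                    have_source = True
            else:
                ncat = 1
                if np_ > 1:
                    ncat += 1
                if n_msg > 0:
                    ncat += 1
                c = int(g_expo.random() * ncat)
                if np_ == 1 and c >= 1:
                    c += 1  # skip the patient category when unavailable
                if c == 0:
                    o_s = doc_op[int(g_expo.random() * nd)]
                    have_source = True
                elif c == 1:
                    j = int(g_expo.random() * (np_ - 1))
                    if j >= i:
                        j += 1
                    o_s = pat_op[j]
                    have_source = True
                else:
                    m_read = int(g_expo.random() * n_msg)
                    o_s = msg_op[m_read]
                    is_msg = True
                    have_source = True
            if have_source:
                f = _ffactor(o_i, o_s, o_i < at, is_msg, b, ft)
                w = alpha * f
                pat_op[i] = o_i * (1.0 - w) + o_s * w
                if m_read >= 0:
                    msg_reads[m_read] -= 1
                    if msg_reads[m_read] <= 0:
                        n_msg -= 1
                        msg_op[m_read] = msg_op[n_msg]
                        msg_age[m_read] = msg_age[n_msg]
                        msg_init[m_read] = msg_init[n_msg]
                        msg_reads[m_read] = msg_reads[n_msg]

        # ---- metrics ------------------------------------------------------
        nav = 0
        na = 0
        s = 0.0
        for i in range(np_):
            if pat_op[i] < vt:
                nav += 1
            if pat_op[i] < at:
                na += 1
            s += pat_op[i]
        out[t, 0] = t + 1
        out[t, 1] = new_act
        out[t, 2] = new_tot
        out[t, 3] = n_msg
        out[t, 4] = nav
        out[t, 5] = na
        out[t, 6] = ndu
        out[t, 7] = s / np_
        nav_prev = nav
        ticks_done = t + 1

        if nav / np_ >= succ_high:
            succ_run += 1
        else:
            succ_run = 0
        if early_stop and succ_run >= succ_window:
            break

    return ticks_done, n_msg
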