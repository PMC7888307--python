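"""Numba kernels for exact stochastic simulation.

All kernels work in seconds.  The time-varying promoter activation propensity
q01(t) = gamma * u(t) is handled by thinning (rejection) against piecewise
upper bounds of u precomputed by :class:`burstinfer.input_signal.InputSeconds`
— the simulation is exact, with no time-discretisation error.

Randomness uses numba's internal np.random state; call :func:`nb_seed` before
a deterministic run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=False)
def nb_seed(seed):
    np.random.seed(seed)


@njit(cache=False)
def expm_action_nonneg(G, dt, v):
    """e^{G dt} v for a Metzler matrix G and non-negative v, by uniformization.

    With q >= max(-G_ii), P = I + G/q is entrywise non-negative, so the
    series e^{G dt} v = e^{-q dt} sum_k (q dt)^k / k! P^k v has no
    cancellation; the step is split so q*delta stays moderate.
    """
    n = G.shape[0]
    if dt <= 0.0:
        return v.copy()
    q = 1e-12
    for i in range(n):
        d = -G[i, i]
        if d > q:
            q = d
    n_steps = int(np.ceil(q * dt / 10.0))
    if n_steps < 1:
        n_steps = 1
    delta = dt / n_steps
    a = q * delta
    out = v.copy()
    for _ in range(n_steps):
        term = out.copy()
        acc = out.copy()  # k = 0 term (weight 1, scaled at end)
        w = 1.0
        for k in range(1, 200):
            term = term + (G @ term) / q
            w *= a / k
            big_t = 0.0
            big_a = 1e-300
            for i in range(n):
                acc[i] += w * term[i]
                if term[i] > big_t:
                    big_t = term[i]
                if acc[i] > big_a:
                    big_a = acc[i]
            if w * big_t < 1e-16 * big_a:
                break
        ea = np.exp(-a)
        for i in range(n):
            out[i] = acc[i] * ea
    return out


@njit(cache=False)
def _u_eval(t, seg_times, seg_levels, seg_flags, u0, k1s, k2s):
    """Evaluate u at time t (s) from the chained segment representation."""
    n = seg_times.shape[0]
    i = -1
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi) // 2
        if seg_times[mid] <= t:
            lo = mid + 1
        else:
            hi = mid
    i = lo - 1
    if i < 0:
        return 0.0
    t0 = seg_times[i]
    if t0 < -1e29:
        return 0.0
    us = seg_levels[i]
    dt = t - t0
    if seg_flags[i] == 1:
        return u0 - (u0 - us) * np.exp(-k1s * dt)
    return us * np.exp(-k2s * dt)


@njit(cache=False)
def _piece_index(break_s, t):
    n = break_s.shape[0]
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi) // 2
        if break_s[mid] <= t:
            lo = mid + 1
        else:
            hi = mid
    j = lo - 1
    if j < 0:
        j = 0
    if j > n - 2:
        j = n - 2
    return j


@njit(cache=False)
def extend_promoter(
    state,
    ta,
    tb,
    gamma,
    q10,
    q12,
    q21,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    u_upper,
    out_t,
    out_s,
):
    """Extend a 3-state promoter path from ta to tb (seconds).

    Writes jump times/states into out_t/out_s and returns the jump count,
    or -1 on buffer overflow.  State 0 exits at rate gamma*u(t) (thinned);
    states 1 and 2 have constant exit rates.
    """
    t = ta
    cap = out_t.shape[0]
    n_out = 0
    while t < tb - _EPS:
        if state == 0:
            if gamma <= 0.0:
                t = tb
                break
            j = _piece_index(break_s, t)
            nb = break_s.shape[0]
            jumped = False
            while j < nb - 1 and t < tb - _EPS:
                piece_end = break_s[j + 1]
                if piece_end > tb:
                    piece_end = tb
                bound = gamma * u_upper[j]
                if bound <= 1e-300:
                    t = piece_end
                else:
                    while t < piece_end:
                        t = t + np.random.exponential(1.0 / bound)
                        if t >= piece_end:
                            t = piece_end
                            break
                        uu = _u_eval(t, seg_times, seg_levels, seg_flags, u0, k1s, k2s)
                        if np.random.random() * bound <= gamma * uu:
                            state = 1
                            if n_out >= cap:
                                return -1
                            out_t[n_out] = t
                            out_s[n_out] = 1
                            n_out += 1
                            jumped = True
                            break
                if jumped:
                    break
                j += 1
            if not jumped:
                t = tb
        elif state == 1:
            rate = q10 + q12
            if rate <= 0.0:
                t = tb
                break
            t = t + np.random.exponential(1.0 / rate)
            if t >= tb:
                t = tb
                break
            if np.random.random() * rate < q10:
                state = 0
            else:
                state = 2
            if n_out >= cap:
                return -1
            out_t[n_out] = t
            out_s[n_out] = state
            n_out += 1
        else:
            if q21 <= 0.0:
                t = tb
                break
            t = t + np.random.exponential(1.0 / q21)
            if t >= tb:
                t = tb
                break
            state = 1
            if n_out >= cap:
                return -1
            out_t[n_out] = t
            out_s[n_out] = 1
            n_out += 1
    return n_out


@njit(cache=False)
def smc_particle_step(
    state,
    t_prev,
    t_k,
    mu,
    sigma,
    G0,
    G1,
    G2,
    P,
    gamma,
    q10,
    q12,
    q21,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    u_upper,
    jump_t,
    jump_s,
    ly,
    eta2,
    do_update,
):
    """One filter step for one particle: extend the promoter path by SSA,
    push the logarithmic moments (mu, sigma; modified in place) through the
    window via raw-moment propagation, and score/condition on the
    observation log y = ly with noise variance eta2.

    Returns (status, final_state, n_jumps, log_inc); status 0 = ok,
    -1 = jump buffer overflow, -2 = degenerate moments (particle killed).
    """
    nj = 0
    if t_k > t_prev:
        nj = extend_promoter(
            state,
            t_prev,
            t_k,
            gamma,
            q10,
            q12,
            q21,
            seg_times,
            seg_levels,
            seg_flags,
            u0,
            k1s,
            k2s,
            break_s,
            u_upper,
            jump_t,
            jump_s,
        )
        if nj < 0:
            return -1, state, 0, 0.0
    # log-normal -> raw moments (13 monomials + constant)
    m14 = np.empty(14)
    for r in range(13):
        lv = 0.0
        for c in range(3):
            lv += P[r, c] * mu[c]
        quad = 0.0
        for a in range(3):
            ps = 0.0
            for b in range(3):
                ps += P[r, b] * sigma[b, a]
            quad += ps * P[r, a]
        lv += 0.5 * quad
        if lv > 700.0:
            return -2, state, nj, 0.0
        m14[r] = np.exp(lv)
    m14[13] = 1.0
    # propagate segment-wise
    t_seg = t_prev
    s_seg = state
    for j in range(nj):
        dtj = jump_t[j] - t_seg
        if dtj > 0:
            if s_seg == 0:
                m14 = expm_action_nonneg(G0, dtj, m14)
            elif s_seg == 1:
                m14 = expm_action_nonneg(G1, dtj, m14)
            else:
                m14 = expm_action_nonneg(G2, dtj, m14)
        t_seg = jump_t[j]
        s_seg = int(jump_s[j])
    dtl = t_k - t_seg
    if dtl > 0:
        if s_seg == 0:
            m14 = expm_action_nonneg(G0, dtl, m14)
        elif s_seg == 1:
            m14 = expm_action_nonneg(G1, dtl, m14)
        else:
            m14 = expm_action_nonneg(G2, dtl, m14)
    # raw moments -> log-normal; moments of a decaying species can underflow
    # to zero (silent promoter), so floor them to keep the log-normal defined
    for r in range(14):
        if not np.isfinite(m14[r]):
            return -2, s_seg, nj, 0.0
    m1 = np.empty(3)
    m1[0] = m14[0] if m14[0] > 1e-30 else 1e-30
    m1[1] = m14[1] if m14[1] > 1e-30 else 1e-30
    m1[2] = m14[11] if m14[11] > 1e-30 else 1e-30
    m2 = np.empty((3, 3))
    m2[0, 0] = m14[2]
    m2[0, 1] = m14[3]
    m2[0, 2] = m14[4]
    m2[1, 0] = m14[3]
    m2[1, 1] = m14[5]
    m2[1, 2] = m14[6]
    m2[2, 0] = m14[4]
    m2[2, 1] = m14[6]
    m2[2, 2] = m14[12]
    for a in range(3):
        val = m2[a, a] / (m1[a] * m1[a])
        if not np.isfinite(val) or val < 1.0 + 1e-12:
            val = 1.0 + 1e-12
        sigma[a, a] = np.log(val)
    for a in range(3):
        for b in range(a + 1, 3):
            val = m2[a, b] / (m1[a] * m1[b])
            if not np.isfinite(val) or val <= 0.0:
                val = 1.0  # uninformative correlation for degenerate moments
            c = np.log(val)
            # keep the implied correlation inside the PSD cone
            lim = 0.999 * np.sqrt(sigma[a, a] * sigma[b, b])
            if c > lim:
                c = lim
            elif c < -lim:
                c = -lim
            sigma[a, b] = c
            sigma[b, a] = c
    for a in range(3):
        mu[a] = np.log(m1[a]) - 0.5 * sigma[a, a]
    # score: y ~ LN(mu_N, eta^2 + Sigma_NN)
    v = eta2 + sigma[1, 1]
    log_inc = -0.5 * np.log(2.0 * np.pi * v) - (ly - mu[1]) ** 2 / (2.0 * v) - ly
    if do_update == 1:
        sw0 = sigma[0, 1]
        sw1 = sigma[1, 1]
        sw2 = sigma[2, 1]
        s_ = sw1 + eta2
        g0 = sw0 / s_
        g1 = sw1 / s_
        g2 = sw2 / s_
        d = ly - mu[1]
        mu[0] += g0 * d
        mu[1] += g1 * d
        mu[2] += g2 * d
        s00 = sigma[0, 0] - g0 * sw0
        s01 = sigma[0, 1] - g0 * sw1
        s02 = sigma[0, 2] - g0 * sw2
        s11 = sigma[1, 1] - g1 * sw1
        s12 = sigma[1, 2] - g1 * sw2
        s22 = sigma[2, 2] - g2 * sw2
        sigma[0, 0] = s00
        sigma[0, 1] = s01
        sigma[1, 0] = s01
        sigma[0, 2] = s02
        sigma[2, 0] = s02
        sigma[1, 1] = s11
        sigma[1, 2] = s12
        sigma[2, 1] = s12
        sigma[2, 2] = s22
    return 0, s_seg, nj, log_inc


@njit(cache=False)
def ssa_full(
    state,
    T,
    z0,
    z1,
    z2,
    gamma,
    q10,
    q12,
    q21,
    c1,
    c2,
    A,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    u_upper,
    sample_times,
    out_state,
    out_m,
    out_n,
    jump_t,
    jump_s,
):
    """Exact SSA of the joint (promoter, mRNA, protein) process on [0, T].

    Samples (state, M, N) at ``sample_times`` (left limits at event times) and
    records promoter jumps.  Returns the number of promoter jumps, -1 on jump
    buffer overflow.
    """
    t = 0.0
    m = 0
    n = 0
    k = 0
    nj = 0
    Ks = sample_times.shape[0]
    cap = jump_t.shape[0]
    zs = (z0, z1, z2)
    while k < Ks and sample_times[k] <= t:
        out_state[k] = state
        out_m[k] = m
        out_n[k] = n
        k += 1
    while t < T - _EPS:
        const_prop = zs[state] + c1 * m + A * m + c2 * n
        if state == 0:
            j = _piece_index(break_s, t)
            horizon = break_s[j + 1]
            if horizon > T:
                horizon = T
            exit_bound = gamma * u_upper[j]
        elif state == 1:
            horizon = T
            exit_bound = q10 + q12
        else:
            horizon = T
            exit_bound = q21
        bound = const_prop + exit_bound
        if bound <= 1e-300:
            t_new = horizon
            while k < Ks and sample_times[k] < t_new:
                out_state[k] = state
                out_m[k] = m
                out_n[k] = n
                k += 1
            t = t_new
            continue
        dt = np.random.exponential(1.0 / bound)
        t_new = t + dt
        if t_new >= horizon:
            while k < Ks and sample_times[k] < horizon:
                out_state[k] = state
                out_m[k] = m
                out_n[k] = n
                k += 1
            t = horizon
            continue
        while k < Ks and sample_times[k] < t_new:
            out_state[k] = state
            out_m[k] = m
            out_n[k] = n
            k += 1
        t = t_new
        # actual propensities at t
        a_tx = zs[state]
        a_mdeg = c1 * m
        a_tl = A * m
        a_pdeg = c2 * n
        if state == 0:
            a_exit = gamma * _u_eval(t, seg_times, seg_levels, seg_flags, u0, k1s, k2s)
        else:
            a_exit = exit_bound
        r = np.random.random() * bound
        if r < a_tx:
            m += 1
        elif r < a_tx + a_mdeg:
            m -= 1
        elif r < a_tx + a_mdeg + a_tl:
            n += 1
        elif r < a_tx + a_mdeg + a_tl + a_pdeg:
            n -= 1
        elif r < a_tx + a_mdeg + a_tl + a_pdeg + a_exit:
            if state == 0:
                state = 1
            elif state == 1:
                if np.random.random() * (q10 + q12) < q10:
                    state = 0
                else:
                    state = 2
            else:
                state = 1
            if nj >= cap:
                return -1
            jump_t[nj] = t
            jump_s[nj] = state
            nj += 1
        # else: thinning rejection, no event
    while k < Ks:
        out_state[k] = state
        out_m[k] = m
        out_n[k] = n
        k += 1
    return nj


@njit(cache=False)
def ssa_zmn_segment(
    state,
    m,
    n,
    ta,
    tb,
    z0,
    z1,
    z2,
    gamma,
    q10,
    q12,
    q21,
    c1,
    c2,
    A,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    u_upper,
):
    """Propagate one (state, M, N) particle from ta to tb; returns
    (state, m, n, time spent in states 1 or 2)."""
    t = ta
    t_active = 0.0
    zs = (z0, z1, z2)
    while t < tb - _EPS:
        const_prop = zs[state] + c1 * m + A * m + c2 * n
        if state == 0:
            j = _piece_index(break_s, t)
            horizon = break_s[j + 1]
            if horizon > tb:
                horizon = tb
            exit_bound = gamma * u_upper[j]
        elif state == 1:
            horizon = tb
            exit_bound = q10 + q12
        else:
            horizon = tb
            exit_bound = q21
        bound = const_prop + exit_bound
        if bound <= 1e-300:
            if state > 0:
                t_active += horizon - t
            t = horizon
            continue
        dt = np.random.exponential(1.0 / bound)
        t_new = t + dt
        if t_new >= horizon:
            if state > 0:
                t_active += horizon - t
            t = horizon
            continue
        if state > 0:
            t_active += t_new - t
        t = t_new
        a_tx = zs[state]
        a_mdeg = c1 * m
        a_tl = A * m
        a_pdeg = c2 * n
        if state == 0:
            a_exit = gamma * _u_eval(t, seg_times, seg_levels, seg_flags, u0, k1s, k2s)
        else:
            a_exit = exit_bound
        r = np.random.random() * bound
        if r < a_tx:
            m += 1
        elif r < a_tx + a_mdeg:
            m -= 1
        elif r < a_tx + a_mdeg + a_tl:
            n += 1
        elif r < a_tx + a_mdeg + a_tl + a_pdeg:
            n -= 1
        elif r < a_tx + a_mdeg + a_tl + a_pdeg + a_exit:
            if state == 0:
                state = 1
            elif state == 1:
                if np.random.random() * (q10 + q12) < q10:
                    state = 0
                else:
                    state = 2
            else:
                state = 1
    return state, m, n, t_active


@njit(cache=False)
def propagate_bootstrap_particles(
    states,
    ms,
    ns,
    As,
    t_active,
    ta,
    tb,
    z0,
    z1,
    z2,
    gamma,
    q10,
    q12,
    q21,
    c1,
    c2,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    u_upper,
):
    for i in range(states.shape[0]):
        s, m, n, da = ssa_zmn_segment(
            states[i],
            ms[i],
            ns[i],
            ta,
            tb,
            z0,
            z1,
            z2,
            gamma,
            q10,
            q12,
            q21,
            c1,
            c2,
            As[i],
            seg_times,
            seg_levels,
            seg_flags,
            u0,
            k1s,
            k2s,
            break_s,
            u_upper,
        )
        states[i] = s
        ms[i] = m
        ns[i] = n
        t_active[i] += da


@njit(cache=False)
def memory_model_ensemble(
    n_runs,
    T,
    c1,
    c2,
    c3,
    c4,
    c5,
    c6,
    c7,
    c8,
    z,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    u_upper,
    sample_times,
    rate_sum,
    output_sum,
):
    """Ensemble SSA of the interval-memory promoter (states P0..P3 with
    activator I1 and inhibitor I2 counters).  Accumulates the transcription
    rate z*1{P2} and cumulative output at the sample times."""
    Ks = sample_times.shape[0]
    for _ in range(n_runs):
        state = 0  # 0:P0 1:P1 2:P2 3:P3
        i1 = 0
        i2 = 0
        t = 0.0
        k = 0
        cum = 0.0
        while True:
            if t >= T - _EPS:
                while k < Ks:
                    rate_sum[k] += z if state == 2 else 0.0
                    output_sum[k] += cum
                    k += 1
                break
            if state == 0:
                j = _piece_index(break_s, t)
                horizon = break_s[j + 1]
                if horizon > T:
                    horizon = T
                bound = c1 * u_upper[j] + c5 * i2 + c8 * i1
            else:
                horizon = T
                if state == 1:
                    bound = c2 + c3 * i1 + c7
                elif state == 2:
                    bound = c4
                else:
                    bound = c6
            has_event = False
            if bound <= 1e-300:
                t_new = horizon
            else:
                t_new = t + np.random.exponential(1.0 / bound)
                if t_new >= horizon:
                    t_new = horizon
                else:
                    has_event = True
            while k < Ks and sample_times[k] <= t_new:
                s = sample_times[k]
                rate_sum[k] += z if state == 2 else 0.0
                output_sum[k] += cum + (z * (s - t) if state == 2 else 0.0)
                k += 1
            if state == 2:
                cum += z * (t_new - t)
            t = t_new
            if not has_event:
                continue
            # event at t
            if state == 0:
                a_act = c1 * _u_eval(t, seg_times, seg_levels, seg_flags, u0, k1s, k2s)
                a_i2 = c5 * i2
                a_conv = c8 * i1
                r = np.random.random() * bound
                if r < a_act:
                    state = 1
                elif r < a_act + a_i2:
                    state = 3
                elif r < a_act + a_i2 + a_conv:
                    i1 -= 1
                    i2 += 1
                # else thinning rejection
            elif state == 1:
                r = np.random.random() * bound
                if r < c2:
                    state = 0
                elif r < c2 + c3 * i1:
                    state = 2
                else:
                    i1 += 1
            elif state == 2:
                state = 1
            else:
                state = 0


@njit(cache=False)
def context_model_counts(
    n_runs,
    T,
    g1,
    c2,
    g3,
    g4,
    c6,
    g5,
    n3,
    n4,
    n5,
    V3,
    V4,
    V5,
    u_scale,
    seg_times,
    seg_levels,
    seg_flags,
    u0,
    k1s,
    k2s,
    break_s,
    bound_exit0,
    bound_exit1,
    counts,
):
    """Tally state transitions of the 4-state context-dependent promoter over
    n_runs SSA realisations; counts[i, j] accumulates j -> i transitions."""
    for _ in range(n_runs):
        state = 0
        t = 0.0
        while t < T - _EPS:
            j = _piece_index(break_s, t)
            horizon = break_s[j + 1]
            if horizon > T:
                horizon = T
            if state == 0:
                bound = bound_exit0[j]
            elif state == 1:
                bound = bound_exit1[j]
            elif state == 2:
                bound = g4  # c4 <= g4
            else:
                bound = c6
            if bound <= 1e-300:
                t = horizon
                continue
            t_new = t + np.random.exponential(1.0 / bound)
            if t_new >= horizon:
                t = horizon
                continue
            t = t_new
            u = u_scale * _u_eval(t, seg_times, seg_levels, seg_flags, u0, k1s, k2s)
            un3 = u**n3
            un4 = u**n4
            un5 = u**n5
            r1 = g1 * u
            r3 = g3 * (1.0 - un3 / (V3**n3 + un3))
            r4 = g4 * un4 / (V4**n4 + un4)
            r5 = g5 * un5 / (V5**n5 + un5)
            r = np.random.random() * bound
            if state == 0:
                if r < r1:
                    counts[1, 0] += 1.0
                    state = 1
            elif state == 1:
                if r < c2:
                    counts[0, 1] += 1.0
                    state = 0
                elif r < c2 + r3:
                    counts[2, 1] += 1.0
                    state = 2
                elif r < c2 + r3 + r5:
                    counts[3, 1] += 1.0
                    state = 3
            elif state == 2:
                if r < r4:
                    counts[1, 2] += 1.0
                    state = 1
            else:
                if r < c6:
                    counts[0, 3] += 1.0
                    state = 0
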