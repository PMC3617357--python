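"""Compiled event-propagation and population-simulation kernels.

Single source of truth for the cell-fate dynamics: the closed-form piecewise
propagation of one cell (``_advance``) and the event-driven clone simulation
(``run_clone``).  Everything here is numba-jitted; the Python API in
:mod:`endoclone.trajectory` and :mod:`endoclone.engine` wraps these.

Model recap (time in months).  A cell born at ``t_n`` has cycle status
``c(t) = int_{t_n}^t alpha(s) ds`` with ``c = +1`` triggering division and
``c = -1`` death.  ``alpha`` relaxes toward the programmed proliferation
curve ``alpha_p(g) = a_scale * (g_limit - g)`` with strength
``k = max(0, k_p(g) + sum m_i)`` under hormonal forcing ``beta``:

    d(alpha)/dt = k * (alpha_p - alpha) + beta

``g = 1 + floor(C_max)`` where ``C`` is the lineage-cumulative cycle
integral and ``C_max`` its running maximum (senescence is irreversible).
Between generation increments the coefficients are constant, so each piece
has the closed form ``alpha(s) = alpha* + (alpha0 - alpha*) exp(-k s)``
with ``alpha* = alpha_p + beta/k``; the code below uses an algebraically
equivalent formulation that is stable for k -> 0 and covers k = 0 exactly.

Parameter-array layout (see ``ModelParameters.to_array``):
  0 g_limit, 1 alpha_p_scale, 2 kp_saturation, 3 kp_rate, 4 kp_linear,
  5 beta_mean, 6 beta_sd, 7 mutations_per_daughter, 8 mutation family,
  9 point value / gaussian loc, 10 gaussian scale / mixture bulk sd,
  11 mixture tail prob, 12 mixture tail scale, 13 inheritance noise sd,
  14 alpha_initial, 15 detect_threshold, 16 k_floor, 17 max_sim_time,
  18 poisson mutation counts flag, 19 max_cells,
  20 alpha_p form: 0 saturating (superlinear post-limit senescence pull,
     saturating at -scale), 1 clipped scale*max((g_limit-g)/g_limit, -1),
     2 linear scale*(g_limit-g)/g_limit, 3 rational scale*(g_limit-g)/g,
  21 senescence span (generations past g_limit to full pull, saturating form),
  22 beta truncation (resample hormone draws beyond this many SD; <= 0 off),
  23 exponent of the post-limit senescence pull (saturating form).
"""

import math

import numpy as np
from numba import njit

# event codes stored per cell
EV_DIV = 1
EV_DIE = 2
EV_CAP = 3  # censored: no event before the time cap

# clone outcome codes
ST_EXTINCT = 0
ST_DETECTED = 1
ST_CENSORED = 2
ST_MEMCAP = 3

_INF = np.inf


@njit(cache=True)
def _em_ou(u):
    """(1 - exp(-u)) / u, stable as u -> 0."""
    if u < 1e-5:
        return 1.0 - 0.5 * u + u * u / 6.0
    return -math.expm1(-u) / u


@njit(cache=True)
def _psi(u):
    """(u - (1 - exp(-u))) / u**2, stable as u -> 0 (limit 1/2)."""
    if u < 1e-3:
        return 0.5 - u / 6.0 + u * u / 24.0 - u * u * u / 120.0
    return (u + math.expm1(-u)) / (u * u)


@njit(cache=True)
def _cint(s, a0, k, ap, beta):
    """Integral of alpha over [0, s] on one piece; exact for all k >= 0."""
    u = k * s
    return (ap * k + beta) * s * s * _psi(u) + a0 * s * _em_ou(u)


@njit(cache=True)
def _aval(s, a0, k, ap, beta):
    """alpha(s) on one piece; exact for all k >= 0."""
    u = k * s
    em = -math.expm1(-u)
    return ap * em + beta * s * _em_ou(u) + a0 * (1.0 - em)


@njit(cache=True)
def _alpha_sign_change(a0, k, ap, beta):
    """Time at which alpha crosses zero, or inf if it keeps its sign.

    alpha is monotone on a piece, so there is at most one crossing; this
    splits the piece into at most two intervals on which c is monotone.
    """
    if k > 0.0:
        a_star = ap + beta / k
        if a0 == 0.0 or a_star == 0.0 or (a0 > 0.0) == (a_star > 0.0):
            return _INF
        return math.log1p(-a0 / a_star) / k
    if beta == 0.0 or a0 == 0.0 or (a0 > 0.0) == (beta > 0.0):
        return _INF
    return -a0 / beta


@njit(cache=True)
def _solve_level(a0, k, ap, beta, c0, L, lo, hi, flo, fhi):
    """Root of c0 + I(s) - L on a bracketing interval: safeguarded Newton."""
    x = 0.5 * (lo + hi)
    for _ in range(200):
        f = c0 + _cint(x, a0, k, ap, beta) - L
        if f == 0.0:
            return x
        if (f > 0.0) == (fhi > 0.0):
            hi = x
            fhi = f
        else:
            lo = x
            flo = f
        if hi - lo < 1e-12 * (1.0 + hi):
            return 0.5 * (lo + hi)
        df = _aval(x, a0, k, ap, beta)
        xn = 0.5 * (lo + hi)
        if df != 0.0:
            xt = x - f / df
            if lo < xt < hi:
                xn = xt
        if abs(xn - x) < 1e-13 * (1.0 + x):
            return xn
        x = xn
    return x


@njit(cache=True)
def _hit_time(a0, k, ap, beta, c0, L, horizon):
    """Earliest s in (0, horizon] with c(s) = L, or inf.

    Scans the (at most two) monotone intervals of c determined by the sign
    change of alpha, bracketing each and refining with Newton/bisection.
    """
    if horizon <= 0.0:
        return _INF
    f0 = c0 - L
    s0 = _alpha_sign_change(a0, k, ap, beta)
    b1 = horizon if s0 >= horizon else s0
    fa = f0
    a = 0.0
    if b1 > 0.0:
        fb = c0 + _cint(b1, a0, k, ap, beta) - L
        if fb == 0.0:
            return b1
        if fa != 0.0 and (fa > 0.0) != (fb > 0.0):
            return _solve_level(a0, k, ap, beta, c0, L, a, b1, fa, fb)
        a = b1
        fa = fb
    if s0 < horizon:
        fh = c0 + _cint(horizon, a0, k, ap, beta) - L
        if fh == 0.0:
            return horizon
        if fa != 0.0 and (fa > 0.0) != (fh > 0.0):
            return _solve_level(a0, k, ap, beta, c0, L, a, horizon, fa, fh)
    return _INF


@njit(cache=True)
def _advance(a0, c0, msum, beta, Cbirth, Cmax, rel_cap, P):
    """Propagate one cell from its current state to its next fate event.

    Processes intermediate generation increments (C_max crossing the next
    integer updates g, hence k_p, alpha_p, and re-clamps k).  Returns
    ``(code, s_end, alpha_end, g_end, k_end, c_end, Cmax_end)`` where
    ``s_end`` is relative to the entry time and code is EV_DIV / EV_DIE /
    EV_CAP (no event before ``rel_cap``).
    """
    s_base = 0.0
    c_base = c0
    a = a0
    g = math.floor(Cmax) + 1.0
    for _ in range(64):
        k = P[2] * (1.0 - math.exp(-P[3] * g)) + P[4] * g + msum
        if k < P[16]:
            k = P[16]
        if P[20] == 0.0:
            if g <= P[0]:
                ap = P[1] * (P[0] - g) / P[0]
            else:
                x = (g - P[0]) / P[21]
                if x >= 1.0:
                    ap = -P[1]
                else:
                    ap = -P[1] * x ** P[23]
        elif P[20] == 1.0:
            ap = P[1] * (P[0] - g) / P[0]
            if ap < -P[1]:
                ap = -P[1]
        elif P[20] == 2.0:
            ap = P[1] * (P[0] - g) / P[0]
        else:
            ap = P[1] * (P[0] - g) / g
        horizon = rel_cap - s_base
        if horizon <= 0.0:
            return EV_CAP, rel_cap, a, g, k, c_base, Cmax
        nxt = math.floor(Cmax) + 1.0
        c_gen = nxt - Cbirth
        t_div = _hit_time(a, k, ap, beta, c_base, 1.0, horizon)
        t_die = _hit_time(a, k, ap, beta, c_base, -1.0, horizon)
        if c_gen < 1.0:
            t_gen = _hit_time(a, k, ap, beta, c_base, c_gen, horizon)
        else:
            t_gen = _INF
        if t_gen < t_div and t_gen < t_die:
            a = _aval(t_gen, a, k, ap, beta)
            s_base += t_gen
            c_base = c_gen
            Cmax = nxt
            g = nxt + 1.0  # C_max exactly integer n => g = n + 1
            continue
        if t_div == _INF and t_die == _INF:
            c_end = c_base + _cint(horizon, a, k, ap, beta)
            a_end = _aval(horizon, a, k, ap, beta)
            return EV_CAP, rel_cap, a_end, g, k, c_end, Cmax
        if t_div <= t_die:
            a_end = _aval(t_div, a, k, ap, beta)
            nm = Cbirth + 1.0
            if nm > Cmax:
                Cmax = nm
            return EV_DIV, s_base + t_div, a_end, g, k, 1.0, Cmax
        a_end = _aval(t_die, a, k, ap, beta)
        return EV_DIE, s_base + t_die, a_end, g, k, -1.0, Cmax
    return EV_CAP, rel_cap, a, g, k, c_base, Cmax


@njit(cache=True)
def _draw_beta(P):
    """Per-cell hormone environment: Normal(beta_mean, beta_sd^2), optionally
    truncated (by resampling) at beta_truncate_sd standard deviations."""
    z = np.random.standard_normal()
    if P[22] > 0.0:
        while abs(z) > P[22]:
            z = np.random.standard_normal()
    return P[5] + P[6] * z


@njit(cache=True)
def _draw_mut_delta(P):
    """Sum of one daughter's new mutational effects on k (1/month)."""
    if P[18] == 1.0:
        n = np.random.poisson(P[7])
    else:
        n = int(P[7])
    fam = int(P[8])
    tot = 0.0
    for _ in range(n):
        if fam == 0:
            tot += P[9]
        elif fam == 1:
            tot += P[9] + P[10] * np.random.standard_normal()
        else:
            if np.random.random() < P[11]:
                tot -= np.random.exponential() * P[12]
            else:
                tot += P[9] + P[10] * np.random.standard_normal()
    return tot


# ---------------------------------------------------------------------------
# binary heap keyed by (event time, cell index): deterministic tie-break by
# birth order, which for synchronous generations equals lineage-code
# lexicographic order (children are pushed first-daughter first).


@njit(cache=True)
def _heap_push(ht, hi, size, t, i):
    j = size
    ht[j] = t
    hi[j] = i
    while j > 0:
        p = (j - 1) >> 1
        if ht[p] > ht[j] or (ht[p] == ht[j] and hi[p] > hi[j]):
            ht[p], ht[j] = ht[j], ht[p]
            hi[p], hi[j] = hi[j], hi[p]
            j = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hi, size):
    t0 = ht[0]
    i0 = hi[0]
    size -= 1
    ht[0] = ht[size]
    hi[0] = hi[size]
    j = 0
    while True:
        l = 2 * j + 1
        if l >= size:
            break
        r = l + 1
        m = l
        if r < size and (ht[r] < ht[l] or (ht[r] == ht[l] and hi[r] < hi[l])):
            m = r
        if ht[m] < ht[j] or (ht[m] == ht[j] and hi[m] < hi[j]):
            ht[m], ht[j] = ht[j], ht[m]
            hi[m], hi[j] = hi[j], hi[m]
            j = m
        else:
            break
    return t0, i0, size


@njit(cache=True)
def _grow_f8(a, newcap):
    b = np.empty(newcap, np.float64)
    b[: a.size] = a
    return b


@njit(cache=True)
def _grow_i8(a, newcap):
    b = np.empty(newcap, np.int64)
    b[: a.size] = a
    return b


@njit(cache=True)
def _grow_i4(a, newcap):
    b = np.empty(newcap, np.int32)
    b[: a.size] = a
    return b


@njit(cache=True)
def _grow_i1(a, newcap):
    b = np.empty(newcap, np.int8)
    b[: a.size] = a
    return b


@njit(cache=True)
def run_clone(P, seed, init_alpha, init_g, init_k, phenotype_mode):
    """Event-driven simulation of one clone from a single root cell.

    The root is either a tissue progenitor (d = 1, g = 1, no mutations,
    alpha = alpha_initial) or, in phenotype mode, a tumor-initiating cell
    with the given (k, alpha, g); its mutation sum is set so that
    k = k_p(g) + sum(m_i) holds, and it carries its implied ancestry
    d = g (the model's generation/division near-identity).

    Per-daughter random draw order at a division: mutation effects, alpha
    inheritance noise, beta; daughter 1 before daughter 2.

    Returns a tuple of scalars and per-cell record arrays (trimmed to the
    number of cells ever born).
    """
    np.random.seed(seed)
    max_cells = int(P[19])
    thresh = P[15]
    tmax = P[17]

    cap = 4096
    parent = np.empty(cap, np.int64)
    digit = np.empty(cap, np.int8)
    depth = np.empty(cap, np.int32)
    t_birth = np.empty(cap, np.float64)
    a_birth = np.empty(cap, np.float64)
    beta_a = np.empty(cap, np.float64)
    msum_a = np.empty(cap, np.float64)
    t_event = np.empty(cap, np.float64)
    a_event = np.empty(cap, np.float64)
    code_a = np.empty(cap, np.int8)

    hcap = 4096
    ht = np.empty(hcap, np.float64)
    hi = np.empty(hcap, np.int64)
    hsize = 0

    g0 = float(init_g)
    Cb0 = g0 - 1.0
    beta0 = _draw_beta(P)
    if phenotype_mode:
        kp0 = P[2] * (1.0 - math.exp(-P[3] * g0)) + P[4] * g0
        msum0 = init_k - kp0
        a0 = init_alpha
    else:
        msum0 = 0.0
        a0 = P[14]

    parent[0] = -1
    digit[0] = 1
    depth[0] = int(init_g)  # division depth from the original tissue progenitor
    t_birth[0] = 0.0
    a_birth[0] = a0
    beta_a[0] = beta0
    msum_a[0] = msum0
    code, s_end, a_end, g_e, k_e, c_e, Cmx = _advance(a0, 0.0, msum0, beta0, Cb0, Cb0, tmax, P)
    t_event[0] = s_end
    a_event[0] = a_end
    code_a[0] = code

    n = 1
    living = 1
    peak = 1
    t_last = 0.0
    n_cens = 0
    status = -1
    t_det = -1.0

    if living >= thresh:
        status = ST_DETECTED
        t_det = 0.0
    else:
        hsize = _heap_push(ht, hi, hsize, t_event[0], 0)

    while hsize > 0 and status == -1:
        te, i, hsize = _heap_pop(ht, hi, hsize)
        ci = code_a[i]
        if ci == EV_CAP:
            n_cens += 1
            continue
        if ci == EV_DIE:
            living -= 1
            t_last = te
            if living == 0:
                status = ST_EXTINCT
            continue
        # division
        if n + 2 > max_cells:
            status = ST_MEMCAP
            t_det = te
            break
        if n + 2 > cap:
            cap = cap * 2
            parent = _grow_i8(parent, cap)
            digit = _grow_i1(digit, cap)
            depth = _grow_i4(depth, cap)
            t_birth = _grow_f8(t_birth, cap)
            a_birth = _grow_f8(a_birth, cap)
            beta_a = _grow_f8(beta_a, cap)
            msum_a = _grow_f8(msum_a, cap)
            t_event = _grow_f8(t_event, cap)
            a_event = _grow_f8(a_event, cap)
            code_a = _grow_i1(code_a, cap)
        if hsize + 2 > hcap:
            hcap = hcap * 2
            ht = _grow_f8(ht, hcap)
            hi = _grow_i8(hi, hcap)
        t_last = te
        pa = a_event[i]
        pd = depth[i]
        pmsum = msum_a[i]
        Cb = float(pd)  # daughter C at birth = d_child - 1
        for which in range(1, 3):
            md = _draw_mut_delta(P)
            anew = pa + P[13] * np.random.standard_normal()
            bnew = _draw_beta(P)
            mnew = pmsum + md
            parent[n] = i
            digit[n] = which
            depth[n] = pd + 1
            t_birth[n] = te
            a_birth[n] = anew
            beta_a[n] = bnew
            msum_a[n] = mnew
            code, s_end, a_end, g_e, k_e, c_e, Cmx = _advance(
                anew, 0.0, mnew, bnew, Cb, Cb, tmax - te, P
            )
            t_event[n] = te + s_end
            a_event[n] = a_end
            code_a[n] = code
            hsize = _heap_push(ht, hi, hsize, t_event[n], n)
            n += 1
        living += 1
        if living > peak:
            peak = living
        if living >= thresh:
            status = ST_DETECTED
            t_det = te

    if status == -1:
        # queue exhausted with censored cells still alive at the horizon
        status = ST_CENSORED
        t_last = tmax

    return (
        status,
        n,
        living,
        peak,
        t_det,
        t_last,
        n_cens,
        parent[:n].copy(),
        digit[:n].copy(),
        depth[:n].copy(),
        t_birth[:n].copy(),
        a_birth[:n].copy(),
        beta_a[:n].copy(),
        msum_a[:n].copy(),
        t_event[:n].copy(),
        a_event[:n].copy(),
        code_a[:n].copy(),
    )


@njit(cache=True)
def snapshot_at(P, t_snap, depth, t_birth, a_birth, beta_a, msum_a, t_event):
    """Phenotypes of the cells alive at ``t_snap`` (e.g. tumor detection).

    A cell is alive if it was born at or before ``t_snap`` and its fate
    event is strictly later.  Each live cell is re-propagated from birth to
    ``t_snap`` with the same closed-form pieces used by the simulation.
    """
    n = depth.size
    alive = np.zeros(n, np.bool_)
    a_now = np.zeros(n, np.float64)
    k_now = np.zeros(n, np.float64)
    g_now = np.zeros(n, np.float64)
    c_now = np.zeros(n, np.float64)
    for i in range(n):
        if t_birth[i] <= t_snap and t_event[i] > t_snap:
            alive[i] = True
            Cb = depth[i] - 1.0
            code, s_end, a_end, g_e, k_e, c_e, Cmx = _advance(
                a_birth[i], 0.0, msum_a[i], beta_a[i], Cb, Cb, t_snap - t_birth[i], P
            )
            a_now[i] = a_end
            k_now[i] = k_e
            g_now[i] = g_e
            c_now[i] = c_e
    return alive, a_now, k_now, g_now, c_now


@njit(cache=True)
def descendant_counts_arrays(parent, alive):
    """Per-node count of final-mass descendants (the node itself included
    if alive).  Children always carry a larger index than their parent, so
    one reverse sweep is a post-order accumulation."""
    n = parent.size
    cnt = np.zeros(n, np.int64)
    for i in range(n):
        if alive[i]:
            cnt[i] = 1
    for i in range(n - 1, 0, -1):
        cnt[parent[i]] += cnt[i]
    return cnt
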