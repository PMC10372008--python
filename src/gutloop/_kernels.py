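"""Compiled inner loops for full simulation runs.

The per-step semantics are exactly those of the public single-step operations
(`dynamics.step_normalized` / `dynamics.step_glv` plus the feedback ops); a
consistency test holds a kernel run equal to a composition of those steps.
Because the host moves only along the first axis, strain geometry reduces to
two arrays: the first feature coordinate and the squared norm of the
remaining coordinates.

Step order within one time point t:
  1. host trend indicator from the behavior history window,
  2. feedback effect M(t) from the strain histories and current composition,
  3. behavior update b1 <- clamp(b1 + base_step + M),
  4. growth rates at the new behavior, dynamics step,
  5. push composition and b1 into the rolling histories.

Error codes: 0 ok, 1 degenerate community (all-zero with no inflow),
2 GLV divergence.
"""

import numpy as np
from numba import njit

ERR_OK = 0
ERR_DEGENERATE = 1
ERR_DIVERGED = 2

PHASE_EQUILIBRIUM = 0
PHASE_ADDICTION = 1
PHASE_WITHDRAWAL = 2
PHASE_WALK = 3

DYN_NORMALIZED = 0
DYN_GLV = 1
FB_REWARD = 0
FB_DIRECT_PULL = 1
INFLOW_SCALED = 0
INFLOW_CONSTANT = 1
INFLOW_NONE = 2


def slope_weights(w: int) -> np.ndarray:
    """OLS slope as a dot product: slope = weights @ window (oldest first)."""
    j = np.arange(w, dtype=float)
    jc = j - j.mean()
    return jc / (jc @ jc)


@njit(cache=False)
def _dyn_step(x, r, cost, active_from, tnow, s, mu, delta,
              inflow_mode, dyn_variant, ceiling):
    n = x.shape[0]
    na = 0
    for i in range(n):
        if active_from[i] <= tnow:
            na += 1
    if dyn_variant == DYN_NORMALIZED:
        tot = 0.0
        for i in range(n):
            if active_from[i] <= tnow:
                xi = x[i] + x[i] * (r[i] - s * x[i] - cost[i])
                if xi < 0.0:
                    xi = 0.0
            else:
                xi = 0.0
            x[i] = xi
            tot += xi
        if inflow_mode == INFLOW_NONE:
            if tot <= 0.0:
                return ERR_DEGENERATE
            for i in range(n):
                x[i] /= tot
            return ERR_OK
        if tot > 0.0:
            for i in range(n):
                x[i] /= tot
        inflow = mu / na if inflow_mode == INFLOW_SCALED else mu
        tot2 = 0.0
        for i in range(n):
            if active_from[i] <= tnow:
                x[i] += inflow
            tot2 += x[i]
        if tot2 <= 0.0:
            return ERR_DEGENERATE
        for i in range(n):
            x[i] /= tot2
        return ERR_OK
    # GLV: absolute abundances, no normalization
    S = 0.0
    for i in range(n):
        if active_from[i] <= tnow:
            S += x[i]
    if inflow_mode == INFLOW_NONE:
        inflow = 0.0
    elif inflow_mode == INFLOW_SCALED:
        inflow = mu / na
    else:
        inflow = mu
    for i in range(n):
        if active_from[i] <= tnow:
            xi = x[i] + x[i] * (r[i] - (1.0 - delta) * x[i] - delta * S) + inflow
            if xi < 0.0:
                xi = 0.0
            if xi > ceiling:
                return ERR_DIVERGED
            x[i] = xi
        else:
            x[i] = 0.0
    return ERR_OK


@njit(cache=False)
def _growth(r, feat0, rest2, bindep, r_indep, b1, alpha, beta, floor_rate):
    n = r.shape[0]
    for i in range(n):
        if bindep[i] == 1:
            r[i] = r_indep
        else:
            db = b1 - feat0[i]
            g = 1.0 - beta * (db * db + rest2[i]) ** (alpha * 0.5)
            r[i] = floor_rate + (g if g > 0.0 else 0.0)


@njit(cache=False)
def _push_composition(Hm, m_head, x, active_from, tnow, dyn_variant):
    n = x.shape[0]
    if dyn_variant == DYN_GLV:
        S = 0.0
        for i in range(n):
            if active_from[i] <= tnow:
                S += x[i]
        for i in range(n):
            Hm[m_head, i] = x[i] / S if S > 0.0 else 0.0
    else:
        for i in range(n):
            Hm[m_head, i] = x[i]


@njit(cache=False)
def simulate_run(
    feat0, rest2, d, cost, bindep, r_indep, active_from, x0,
    draws, phase, b1_init, lo, hi, r_gate,
    eq_cap, eq_tol, eq_window,
    alpha, beta, floor_rate,
    s, mu, delta,
    inflow_mode, dyn_variant, fb_variant,
    wm, wh, slope_tol, thin, ceiling,
):
    n = x0.shape[0]
    T = draws.shape[0]
    omega_m = wm.shape[0]
    omega_h = wh.shape[0]

    x = x0.copy()
    r = np.empty(n)
    Hm = np.zeros((omega_m, n))
    hb = np.zeros(omega_h)
    m_head = 0
    h_head = 0
    m_fill = 0
    h_fill = 0
    b1 = b1_init

    b1_out = np.empty(T)
    n_thin = (T + thin - 1) // thin
    x_thin = np.zeros((n_thin, n))
    err = ERR_OK
    err_step = -1
    eq_len = 0
    stabilized = 1

    # --- phase 1: equilibrium at b = b1_init, fixed growth rates ----------
    if eq_cap > 0:
        stabilized = 0
        _growth(r, feat0, rest2, bindep, r_indep, b1, alpha, beta, floor_rate)
        xprev = np.empty(n)
        run = 0
        for _ in range(eq_cap):
            for i in range(n):
                xprev[i] = x[i]
            e = _dyn_step(x, r, cost, active_from, -1, s, mu, delta,
                          inflow_mode, dyn_variant, ceiling)
            if e != ERR_OK:
                x_final = x.copy()
                return (e, -1, eq_len, 0, b1_out, x_thin, x_final, x.copy())
            _push_composition(Hm, m_head, x, active_from, -1, dyn_variant)
            m_head = (m_head + 1) % omega_m
            if m_fill < omega_m:
                m_fill += 1
            hb[h_head] = b1
            h_head = (h_head + 1) % omega_h
            if h_fill < omega_h:
                h_fill += 1
            eq_len += 1
            maxdiff = 0.0
            for i in range(n):
                delta_i = x[i] - xprev[i]
                if delta_i < 0.0:
                    delta_i = -delta_i
                if delta_i > maxdiff:
                    maxdiff = delta_i
            if maxdiff < eq_tol:
                run += 1
                if run >= eq_window:
                    stabilized = 1
                    break
            else:
                run = 0
    x_after_eq = x.copy()

    # --- main loop over the scheduled timeline ----------------------------
    for t in range(T):
        sig = draws[t]
        siga = sig if sig >= 0.0 else -sig
        ph = phase[t]

        # host trend
        Ib = 0
        if h_fill >= omega_h:
            bs = 0.0
            for k in range(omega_h):
                bs += wh[k] * hb[(h_head + k) % omega_h]
            if bs > slope_tol:
                Ib = 1
            elif bs < -slope_tol:
                Ib = -1

        # relative abundances for feedback weighting
        if dyn_variant == DYN_GLV:
            S = 0.0
            for i in range(n):
                if active_from[i] <= t:
                    S += x[i]
        else:
            S = 1.0

        M = 0.0
        if fb_variant == FB_REWARD:
            if Ib != 0 and m_fill >= omega_m and S > 0.0:
                acc = 0.0
                for i in range(n):
                    if d[i] != 0.0 and active_from[i] <= t:
                        sl = 0.0
                        for k in range(omega_m):
                            sl += wm[k] * Hm[(m_head + k) % omega_m, i]
                        if sl > slope_tol:
                            acc += (x[i] / S) * d[i]
                        elif sl < -slope_tol:
                            acc -= (x[i] / S) * d[i]
                M = siga * Ib * acc
        else:
            if S > 0.0:
                acc = 0.0
                for i in range(n):
                    if d[i] != 0.0 and active_from[i] <= t:
                        dx = feat0[i] - b1
                        nrm = np.sqrt(dx * dx + rest2[i])
                        if nrm >= 1e-12:
                            acc += (x[i] / S) * d[i] * dx / nrm
                M = siga * acc

        if ph == PHASE_ADDICTION:
            base = sig if b1 < r_gate else 0.0
        else:
            base = sig
        nb = b1 + (base + M)
        if nb < lo:
            nb = lo
        elif nb > hi:
            nb = hi
        b1 = nb

        _growth(r, feat0, rest2, bindep, r_indep, b1, alpha, beta, floor_rate)
        e = _dyn_step(x, r, cost, active_from, t, s, mu, delta,
                      inflow_mode, dyn_variant, ceiling)
        if e != ERR_OK:
            err = e
            err_step = t
            break

        _push_composition(Hm, m_head, x, active_from, t, dyn_variant)
        m_head = (m_head + 1) % omega_m
        if m_fill < omega_m:
            m_fill += 1
        hb[h_head] = b1
        h_head = (h_head + 1) % omega_h
        if h_fill < omega_h:
            h_fill += 1

        b1_out[t] = b1
        if t % thin == 0:
            for i in range(n):
                x_thin[t // thin, i] = x[i]

    return (err, err_step, eq_len, stabilized, b1_out, x_thin, x.copy(), x_after_eq)


@njit(cache=False)
def baseline_schedule(draws, phase, b1_init, lo, hi, r_gate):
    """Behavior under the baseline schedule alone (no microbiome effect)."""
    T = draws.shape[0]
    out = np.empty(T)
    b1 = b1_init
    for t in range(T):
        sig = draws[t]
        if phase[t] == PHASE_ADDICTION:
            base = sig if b1 < r_gate else 0.0
        else:
            base = sig
        nb = b1 + (base + 0.0)
        if nb < lo:
            nb = lo
        elif nb > hi:
            nb = hi
        b1 = nb
        out[t] = b1
    return out
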