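"""Compiled fixed-step integrator for the closed-loop model.

The right-hand side mirrors, index for index, the laws exposed by
``chambers``, ``valves`` and ``circulation`` (the test suite checks the two
implementations against each other on random states).  A fixed-step
classical Runge-Kutta scheme at sub-millisecond steps is used: the valve
rate law is the fastest time scale (K * |dP| up to ~2000 1/s with the
default rate constants), comfortably stable at dt = 0.25 ms.

State layout (see ``parameters.STATE_NAMES``)::

    y[0:10]  volumes: lv la rv ra ao sa sv vc pa pv     (mL)
    y[10:14] valve flows: mitral aortic tricuspid pulmonary (mL/s)
    y[14:18] valve opening fractions xi                  (-)

Parameter layout: see ``parameters.pack_kernel_params``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_CAP = 40.0


@njit(cache=True)
def _double_hill(tau, T, a1, a2, n1, n2, k):
    if tau <= 0.0:
        return 0.0
    x1 = (tau / (a1 * T)) ** n1
    x2 = (tau / (a2 * T)) ** n2
    return k * (x1 / (1.0 + x1)) / (1.0 + x2)


@njit(cache=True)
def rhs(y, tau_lv, tau_rv, tau_la, tau_ra, p, dy):
    T = p[0]

    # ventricular pressures (driver-weighted ESPVR/EDPVR blend)
    e_lv = _double_hill(tau_lv, T, p[6], p[7], p[8], p[9], p[10])
    x = p[4] * (y[0] - p[5])
    if x > _EXP_CAP:
        x = _EXP_CAP
    P_lv = e_lv * p[1] * (y[0] - p[2]) + (1.0 - e_lv) * p[3] * (np.exp(x) - 1.0)

    e_rv = _double_hill(tau_rv, T, p[16], p[17], p[18], p[19], p[20])
    x = p[14] * (y[2] - p[15])
    if x > _EXP_CAP:
        x = _EXP_CAP
    P_rv = e_rv * p[11] * (y[2] - p[12]) + (1.0 - e_rv) * p[13] * (np.exp(x) - 1.0)

    # atrial pressures (Gaussian-driven linear elastance)
    E_la = p[21] * np.exp(-p[24] * (tau_la - p[25]) ** 2) + p[22]
    P_la = E_la * (y[1] - p[23])
    E_ra = p[26] * np.exp(-p[29] * (tau_ra - p[30]) ** 2) + p[27]
    P_ra = E_ra * (y[3] - p[28])

    # vessel pressures
    P_ao = p[55] * (y[4] - p[61])
    P_sa = p[56] * (y[5] - p[62])
    P_sv = p[57] * (y[6] - p[63])
    P_vc = p[58] * (y[7] - p[64])
    P_pa = p[59] * (y[8] - p[65])
    P_pv = p[60] * (y[9] - p[66])

    # valves: mitral la->lv, aortic lv->ao, tricuspid ra->rv, pulmonary rv->pa
    for i in range(4):
        base = 31 + 6 * i
        if i == 0:
            dP = P_la - P_lv
        elif i == 1:
            dP = P_lv - P_ao
        elif i == 2:
            dP = P_ra - P_rv
        else:
            dP = P_rv - P_pa
        xi = y[14 + i]
        A = (p[base] - p[base + 1]) * xi + p[base + 1]
        B = p[base + 2] / (A * A)
        L = p[base + 3] / A
        Q = y[10 + i]
        dy[10 + i] = (dP - B * Q * np.abs(Q)) / L
        if dP > 0.0:
            dy[14 + i] = (1.0 - xi) * p[base + 4] * dP
        else:
            dy[14 + i] = xi * p[base + 5] * dP

    # resistive flows along the loop
    q_ao_sa = (P_ao - P_sa) / p[67]
    q_sa_sv = (P_sa - P_sv) / p[68]
    q_sv_vc = (P_sv - P_vc) / p[69]
    q_vc_ra = (P_vc - P_ra) / p[70]
    q_pa_pv = (P_pa - P_pv) / p[71]
    q_pv_la = (P_pv - P_la) / p[72]

    Q_mit = y[10]
    Q_aor = y[11]
    Q_tri = y[12]
    Q_pul = y[13]

    dy[0] = Q_mit - Q_aor          # lv
    dy[1] = q_pv_la - Q_mit        # la
    dy[2] = Q_tri - Q_pul          # rv
    dy[3] = q_vc_ra - Q_tri        # ra
    dy[4] = Q_aor - q_ao_sa        # ao
    dy[5] = q_ao_sa - q_sa_sv      # sa
    dy[6] = q_sa_sv - q_sv_vc      # sv
    dy[7] = q_sv_vc - q_vc_ra      # vc
    dy[8] = Q_pul - q_pa_pv        # pa
    dy[9] = q_pa_pv - q_pv_la      # pv


@njit(cache=True)
def _tau(t, act, i, T):
    # time since the most recent activation at or before t; before the first
    # activation a virtual previous activation at act[0] - T is assumed
    if act.size == 0:
        return t + T
    if act[i] <= t:
        return t - act[i]
    return t - (act[0] - T)


@njit(cache=True)
def integrate(y0, t0, t_end, dt, sample_every, p,
              act_lv, act_rv, act_la, act_ra):
    """RK4 integration from t0 to t_end; samples every ``sample_every`` steps.

    Returns (ts, ys, ok); ok = False means a non-finite state was hit and
    the trailing samples are invalid.
    """
    T = p[0]
    n_steps = int(round((t_end - t0) / dt))
    n_samples = n_steps // sample_every + 1
    n = y0.size
    ys = np.empty((n_samples, n))
    ts = np.empty(n_samples)
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    i_lv = 0
    i_rv = 0
    i_la = 0
    i_ra = 0
    ts[0] = t0
    ys[0] = y
    s = 1
    ok = True
    for step in range(n_steps):
        t = t0 + step * dt
        while i_lv + 1 < act_lv.size and act_lv[i_lv + 1] <= t:
            i_lv += 1
        while i_rv + 1 < act_rv.size and act_rv[i_rv + 1] <= t:
            i_rv += 1
        while i_la + 1 < act_la.size and act_la[i_la + 1] <= t:
            i_la += 1
        while i_ra + 1 < act_ra.size and act_ra[i_ra + 1] <= t:
            i_ra += 1
        tau_lv = _tau(t, act_lv, i_lv, T)
        tau_rv = _tau(t, act_rv, i_rv, T)
        tau_la = _tau(t, act_la, i_la, T)
        tau_ra = _tau(t, act_ra, i_ra, T)
        h = dt
        rhs(y, tau_lv, tau_rv, tau_la, tau_ra, p, k1)
        for j in range(n):
            yt[j] = y[j] + 0.5 * h * k1[j]
        rhs(yt, tau_lv + 0.5 * h, tau_rv + 0.5 * h,
            tau_la + 0.5 * h, tau_ra + 0.5 * h, p, k2)
        for j in range(n):
            yt[j] = y[j] + 0.5 * h * k2[j]
        rhs(yt, tau_lv + 0.5 * h, tau_rv + 0.5 * h,
            tau_la + 0.5 * h, tau_ra + 0.5 * h, p, k3)
        for j in range(n):
            yt[j] = y[j] + h * k3[j]
        rhs(yt, tau_lv + h, tau_rv + h, tau_la + h, tau_ra + h, p, k4)
        for j in range(n):
            y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        # xi boundaries are invariant manifolds of the exact flow; clip the
        # O(dt^5) discretisation overshoot
        for j in range(14, 18):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if (step + 1) % sample_every == 0:
            finite = True
            for j in range(n):
                if not np.isfinite(y[j]):
                    finite = False
            if not finite:
                ok = False
                break
            ts[s] = t + dt
            ys[s] = y
            s += 1
    if s < n_samples:
        ts = ts[:s]
        ys = ys[:s]
    return ts, ys, ok
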