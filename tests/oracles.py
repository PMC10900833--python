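"""Independent numerical oracles used by the test suite.

A fixed-step 4th-order Runge-Kutta integrator for the one-compartment
infusion ODE dC/dt = r/Vd - ke*C, run piecewise over the same segment
boundaries as the analytic engine but accumulating its own state, and a
dense-grid (midpoint-sampling) estimate of time spent above a threshold.
"""

import numpy as np


def rk4_integrate(c0, ke, r0, vd, dt, n_steps):
    """Integrate dC/dt = r0/vd - ke*C over dt with n_steps RK4 steps."""
    c = np.asarray(c0, dtype=float).copy()
    h = dt / n_steps

    def f(y):
        return r0 / vd - ke * y

    for _ in range(n_steps):
        k1 = f(c)
        k2 = f(c + 0.5 * h * k1)
        k3 = f(c + 0.5 * h * k2)
        k4 = f(c + h * k3)
        c = c + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return c


def rk4_profile_conc(profiles, max_step=0.005):
    """Re-integrate a whole CohortProfiles trajectory with RK4.

    Returns concentrations at the profile's segment boundaries, computed
    entirely from the oracle's own running state (only segment ke/rate
    definitions are shared with the engine).
    """
    times = profiles.times
    m = profiles.rates.size
    conc = np.zeros((m + 1, profiles.n))
    c = np.zeros(profiles.n)
    for i in range(m):
        dt = times[i + 1] - times[i]
        n_steps = max(1, int(np.ceil(dt / max_step)))
        c = rk4_integrate(c, profiles.ke[i], profiles.rates[i], profiles.vd, dt, n_steps)
        conc[i + 1] = c
    return conc


def dense_grid_hours_above(profiles, threshold, window, free=False, dt=5e-4):
    """Midpoint-sampled time above threshold: dt * #{grid midpoints above}."""
    a, b = window
    mids = np.arange(a + dt / 2.0, b, dt)
    idx = np.clip(np.searchsorted(profiles.times, mids, side="right") - 1,
                  0, profiles.rates.size - 1)
    thr = np.broadcast_to(
        np.asarray(threshold, dtype=float) / (profiles.fu if free else 1.0),
        (profiles.n,),
    )
    out = np.zeros(profiles.n)
    # chunk over patients to bound memory at ~ len(mids) x chunk floats
    chunk = max(1, int(2_000_000 // max(len(mids), 1)))
    dtau = mids - profiles.times[idx]
    for lo in range(0, profiles.n, chunk):
        hi = min(lo + chunk, profiles.n)
        ke = profiles.ke[idx, lo:hi]  # (T, chunk)
        c0 = profiles.conc[idx, lo:hi]
        r0 = profiles.rates[idx][:, None]
        vd = profiles.vd[lo:hi][None, :]
        decay = np.exp(-ke * dtau[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            accrual = np.where(ke > 0, r0 / (ke * vd) * (1 - decay),
                               r0 * dtau[:, None] / vd)
        c = c0 * decay + accrual
        out[lo:hi] = dt * np.sum(c > thr[lo:hi][None, :], axis=0)
    return out
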