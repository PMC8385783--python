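"""Independent reference implementations used only to cross-check the package."""

import numpy as np


def rk4_integrate(f, y0, t0, t1, dt, sample_every=1):
    """Classic fixed-step fourth-order Runge-Kutta integration.

    Deliberately naive: a plain loop at constant step ``dt``, recording
    every ``sample_every``-th step.  Serves as the brute-force oracle for
    the adaptive solver.  Returns ``(times, states)``.
    """
    n_steps = int(round((t1 - t0) / dt))
    y = np.asarray(y0, dtype=float)
    times = [t0]
    states = [y.copy()]
    t = t0
    for i in range(1, n_steps + 1):
        k1 = np.asarray(f(t, y))
        k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
        k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
        k4 = np.asarray(f(t + dt, y + dt * k3))
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + i * dt
        if i % sample_every == 0 or i == n_steps:
            times.append(t)
            states.append(y.copy())
    return np.array(times), np.array(states)


def exponential_decay_tau(times, values, floor=1.0):
    """Log-linear least-squares estimate of an e-folding time.

    Fits log(values - floor) against time; returns the negative
    reciprocal slope.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = values - floor > 0
    slope, _ = np.polyfit(times[mask], np.log(values[mask] - floor), 1)
    return -1.0 / slope
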