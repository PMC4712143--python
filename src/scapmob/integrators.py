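"""Runge-Kutta-Merson adaptive integration.

The classic 5-stage embedded scheme: a 4th-order solution with a
built-in error estimate, driven by a relative accuracy target.  Chosen
because its error control maps directly onto the "relative accuracy"
contract used for the forward-dynamics simulations (1e-4 target means
roughly four significant digits in the integrated states).
"""

from __future__ import annotations

import numpy as np

__all__ = ["IntegrationError", "rk_merson"]


class IntegrationError(RuntimeError):
    pass


def rk_merson(
    f,
    y0,
    t0: float,
    t1: float,
    rtol: float = 1e-4,
    atol: float = 1e-10,
    h0: float | None = None,
    hmax: float | None = None,
    hmin: float = 1e-12,
    fixed_step: float | None = None,
    callback=None,
    max_steps: int = 1_000_000,
):
    """Integrate ``ydot = f(t, y)`` from t0 to t1.

    Returns ``(times, states)`` at accepted steps (including t0 and t1).
    ``callback(t, y) -> y`` runs after each accepted step and may return a
    corrected state (used for constraint projection).  ``fixed_step``
    disables the error control (for order-verification studies).
    """
    y = np.asarray(y0, dtype=float).copy()
    t = float(t0)
    hmax = (t1 - t0) if hmax is None else hmax
    h = fixed_step if fixed_step is not None else (h0 or (t1 - t0) / 100.0)
    times = [t]
    states = [y.copy()]
    for _ in range(max_steps):
        if t >= t1 - 1e-14 * max(1.0, abs(t1)):
            return np.array(times), np.array(states)
        h_try = min(h, t1 - t)
        k1 = f(t, y)
        k2 = f(t + h_try / 3.0, y + h_try * k1 / 3.0)
        k3 = f(t + h_try / 3.0, y + h_try * (k1 + k2) / 6.0)
        k4 = f(t + h_try / 2.0, y + h_try * (k1 + 3.0 * k3) / 8.0)
        k5 = f(t + h_try, y + h_try * (k1 - 3.0 * k3 + 4.0 * k4) / 2.0)
        y_new = y + h_try * (k1 + 4.0 * k4 + k5) / 6.0
        if fixed_step is not None:
            accept = True
        else:
            err = h_try * (2.0 * k1 - 9.0 * k3 + 8.0 * k4 - k5) / 30.0
            scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_new))
            errnorm = float(np.max(np.abs(err) / scale))
            accept = errnorm <= 1.0
            factor = 0.7 * (errnorm + 1e-16) ** (-0.2)
            h = float(np.clip(h_try * np.clip(factor, 0.2, 2.5), hmin, hmax))
            if not accept and h_try <= hmin * 1.001:
                raise IntegrationError(
                    f"step size underflow at t={t:.6g} (errnorm={errnorm:.3g})"
                )
        if accept:
            t = t + h_try
            y = y_new
            if callback is not None:
                y = np.asarray(callback(t, y), dtype=float)
            times.append(t)
            states.append(y.copy())
    raise IntegrationError("maximum number of steps exceeded")
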