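"""Independent numerical oracles used by the tests.

Deliberately simple and separate from the package: fixed-step classical
Runge-Kutta integration of the governing ODEs, against which the package's
closed-form solutions are checked.
"""

from __future__ import annotations

import numpy as np


def rk4(deriv, y0, t_end: float, h: float):
    """Integrate dy/dt = deriv(t, y) from t=0 to t_end with fixed step h."""
    y = np.asarray(y0, dtype=float) if np.ndim(y0) else float(y0)
    t = 0.0
    n = int(round(t_end / h))
    for _ in range(n):
        k1 = deriv(t, y)
        k2 = deriv(t + h / 2, y + h / 2 * k1)
        k3 = deriv(t + h / 2, y + h / 2 * k2)
        k4 = deriv(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


def rk4_two_compartment(vol1, vol2, perm, c1_0, c2_0, t_end, h=0.05):
    def deriv(t, y):
        c1, c2 = y
        return np.array(
            [perm * (c2 - c1) / vol1, perm * (c1 - c2) / vol2]
        )

    return rk4(deriv, np.array([c1_0, c2_0]), t_end, h)


def rk4_efflux(vol_in, perm, c_in_0, alpha, t_end, h=0.05):
    return rk4(lambda t, c: (alpha - perm * c) / vol_in, c_in_0, t_end, h)


def rk4_recipient(c1, c2_t0, rate, duration, h=0.05):
    return rk4(lambda t, c: rate * (c1 - c), c2_t0, duration, h)
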