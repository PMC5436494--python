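"""Shared independent oracle for the residence-time transform."""

import numpy as np
from scipy.optimize import brentq

from rampkin.flow import ML_MIN_TO_M3_S


def tau_numeric_oracle(geom, ramp, t_exit_s, beta=1.0):
    """Invert beta * int_{t-tau}^{t} Q(t') dt' = V for tau by bisection
    on a dense trapezoidal quadrature (independent of the closed form)."""
    V = geom.volume_m3

    def swept(tau):
        ts = np.linspace(t_exit_s - tau, t_exit_s, 20001)
        Q = np.where(
            ts < 0, ramp.Q_start, ramp.Q_start - ramp.alpha * ts / 60.0
        ) * ML_MIN_TO_M3_S
        return beta * np.trapezoid(Q, ts) - V

    return brentq(swept, 1e-3, t_exit_s + ramp.hold_min * 60.0, xtol=1e-10)
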