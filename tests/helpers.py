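"""Independent oracles used by the test suite.

These deliberately avoid the package's own integration and derivative code
paths: the derivative oracle rebuilds the dynamics from a bookkeeping list of
individual fluxes, and the trajectory oracle is a brute-force fixed-step
fourth-order Runge-Kutta scheme that restarts at every quality switch.
"""

from __future__ import annotations

import math

import numpy as np

# state vector order: X, Z1, Y1, B1, Z2, Y2, B2, P
IX, IZ1, IY1, IB1, IZ2, IY2, IB2, IP = range(8)


def flux_rhs(state, mu, p1, p2, phi1, phi2, T):
    """Derivative assembled flux-by-flux: each flux leaves its source and
    enters its sink, so conservation is true by construction."""
    X, Z1, Y1, B1, Z2, Y2, B2, P = state
    pool = P > 0
    fluxes = [
        (mu * X, IX, IZ1),                      # discovery of nest 1
        (mu * X, IX, IZ2),                      # discovery of nest 2
        (p1.k * Z1, IZ1, IY1),                  # acceptance at nest 1
        (p1.rho * Z1, IZ1, IX),                 # assessor abandonment, nest 1
        (p1.rho * Y1, IY1, IX),                 # transporter abandonment, nest 1
        (p2.k * Z2, IZ2, IY2),
        (p2.rho * Z2, IZ2, IX),
        (p2.rho * Y2, IY2, IX),
        (phi1 * Y1 * (1.0 if (Y1 > T and pool) else 0.0), IP, IB1),  # carrying
        (phi2 * Y2 * (1.0 if (Y2 > T and pool) else 0.0), IP, IB2),
    ]
    d = np.zeros(8)
    for rate, src, dst in fluxes:
        d[src] -= rate
        d[dst] += rate
    return d


def rk4_windowed(config, dt=0.001):
    """Fixed-step classical RK4 over the scenario horizon.

    Restarts at every nest-quality switch time; all switch times of the
    presets are integer multiples of ``dt`` so the steps align exactly with
    the windows. Returns the state vector at the horizon.
    """
    mu, phi1, phi2, T = config.mu, config.phi1, config.phi2, config.T

    def f(y, k1, r1, k2, r2):
        X, Z1, Y1, B1, Z2, Y2, B2, P = y
        h1 = 1.0 if Y1 > T else 0.0
        h2 = 1.0 if Y2 > T else 0.0
        pool = 1.0 if P > 0 else 0.0
        tr1 = phi1 * Y1 * h1 * pool
        tr2 = phi2 * Y2 * h2 * pool
        return np.array([
            -2.0 * mu * X + r1 * (Z1 + Y1) + r2 * (Z2 + Y2),
            mu * X - (k1 + r1) * Z1,
            k1 * Z1 - r1 * Y1,
            tr1,
            mu * X - (k2 + r2) * Z2,
            k2 * Z2 - r2 * Y2,
            tr2,
            -tr1 - tr2,
        ])

    bounds = np.concatenate(([0.0], config.switch_times(), [config.horizon]))
    y = config.initial.to_array()
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        pp1, pp2 = config.params_at(t0)
        args = (pp1.k, pp1.rho, pp2.k, pp2.rho)
        n = round((t1 - t0) / dt)
        assert math.isclose(t0 + n * dt, t1, abs_tol=1e-9), "steps must tile the window"
        for _ in range(n):
            k1 = f(y, *args)
            k2 = f(y + 0.5 * dt * k1, *args)
            k3 = f(y + 0.5 * dt * k2, *args)
            k4 = f(y + dt * k3, *args)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y
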