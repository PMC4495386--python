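"""Deterministic integration of the nest-choice model.

The rate coefficients jump at the quality-switch times of each nest's
schedule, and the right-hand side is discontinuous where a potential-
transporter count crosses the quorum threshold or the passive pool empties.
A generic adaptive solver is not guaranteed to resolve those discontinuities,
so the time domain is segmented into windows of constant nest quality; the
solver restarts at every window boundary from the previous end state, and
within a window the quorum/pool crossings are located by event detection and
used as further restart points. Between restarts the right-hand side is
smooth (indeed linear), so high-order adaptive integration is accurate.

Also provides the "averaged nest" construction used in the homogenization
comparison: a constant nest whose rates are the time-weighted means of a
fluctuating nest's phase rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    ColonyState,
    NestSchedule,
    PhaseParams,
    ScenarioConfig,
    STATE_FIELDS,
    heaviside,
    rhs_array,
)

__all__ = [
    "Trajectory",
    "ComparisonMetrics",
    "integrate_windowed",
    "nest_population",
    "averaged_nest",
    "quorum_time",
    "compare",
]

# indices into the state vector
_IY = {1: STATE_FIELDS.index("Y1"), 2: STATE_FIELDS.index("Y2")}
_IP = STATE_FIELDS.index("P")


@dataclass
class Trajectory:
    """Solution sampled on a uniform grid, with event bookkeeping.

    ``window_boundaries`` are the restart times actually used (quality
    switches plus located crossings); ``quorum_events`` records, per nest,
    the first time its potential-transporter count exceeded the quorum.
    """

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 8), columns in STATE_FIELDS order
    window_boundaries: list[float] = field(default_factory=list)
    quorum_events: list[tuple[int, float]] = field(default_factory=list)

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def active_total(self) -> np.ndarray:
        s = self.states
        return s[:, 0] + s[:, 1] + s[:, 2] + s[:, 4] + s[:, 5]

    @property
    def passive_total(self) -> np.ndarray:
        s = self.states
        return s[:, 3] + s[:, 6] + s[:, 7]

    def final_state(self) -> ColonyState:
        return ColonyState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_min", self.times)
        df["pop1"] = nest_population(self, 1)
        df["pop2"] = nest_population(self, 2)
        cols = ["time_min", "X", "Z1", "Y1", "B1", "Z2", "Y2", "B2", "P", "pop1", "pop2"]
        return df[cols]

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ComparisonMetrics:
    """Sup-norm and RMS distance between two series on a shared grid."""

    sup_norm: float
    rms: float
    component: str = ""


def averaged_nest(schedule: NestSchedule) -> NestSchedule:
    """Constant nest with the time-average of a fluctuating nest's rates.

    The model is linear in the quality rates, so the homogenized (fast-
    fluctuation) limit replaces each rate by its mean over one cycle: the
    good-phase value weighted by the good fraction plus the poor-phase value
    weighted by the rest.
    """
    if schedule.is_constant:
        params = schedule.params_at(0.0)
        return NestSchedule.constant(params)
    g = schedule.good_fraction
    k = g * schedule.good.k + (1.0 - g) * schedule.poor.k
    rho = g * schedule.good.rho + (1.0 - g) * schedule.poor.rho
    return NestSchedule.constant(PhaseParams(k, rho))


def _segment_boundaries(config: ScenarioConfig) -> np.ndarray:
    interior = config.switch_times()
    return np.concatenate(([0.0], interior, [config.horizon]))


def integrate_windowed(
    config: ScenarioConfig,
    grid_dt: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
) -> Trajectory:
    """Integrate the scenario over its horizon with windowed restarts.

    Output is sampled on the uniform grid ``0, grid_dt, ..., horizon``;
    restart points (quality switches, quorum crossings, pool exhaustion) are
    located exactly and are not snapped to the grid.
    """
    grid = np.arange(0.0, config.horizon + grid_dt / 2, grid_dt)
    out = np.empty((len(grid), len(STATE_FIELDS)))
    state = config.initial.to_array()
    out[0] = state

    T = config.T
    # quorum regime flags, fixed within each integration segment
    h = {i: heaviside(state[_IY[i]], T) for i in (1, 2)}
    pool_open = state[_IP] > 0

    boundaries = _segment_boundaries(config)
    used_boundaries: list[float] = []
    quorum_events: list[tuple[int, float]] = []
    seen_quorum: set[int] = set()

    gi = 1
    t = 0.0
    for t_end in boundaries[1:]:
        p1, p2 = config.params_at(t)
        while t < t_end - 1e-12:
            def f(tt, y, _p1=p1, _p2=p2):
                return rhs_array(y, config.mu, _p1, _p2, config.phi1, config.phi2,
                                 T, h1=h[1], h2=h[2])

            events = []
            event_tags = []
            for i in (1, 2):
                direction = -1.0 if h[i] else 1.0

                def cross(tt, y, idx=_IY[i], _d=direction):
                    return y[idx] - T

                cross.terminal = True
                cross.direction = direction
                events.append(cross)
                event_tags.append(("quorum", i))
            if pool_open and (h[1] or h[2]):
                def pool_empty(tt, y):
                    return y[_IP]

                pool_empty.terminal = True
                pool_empty.direction = -1.0
                events.append(pool_empty)
                event_tags.append(("pool", 0))

            sol = solve_ivp(f, (t, t_end), state, method=method, rtol=rtol,
                            atol=atol, dense_output=True, events=events)
            if not sol.success:
                raise RuntimeError(
                    f"integration failed in window [{t}, {t_end}]: {sol.message}")

            seg_end = sol.t[-1]
            while gi < len(grid) and grid[gi] <= seg_end + 1e-9:
                out[gi] = sol.sol(min(grid[gi], seg_end))
                gi += 1

            state = sol.y[:, -1].copy()
            hit = [j for j, te in enumerate(sol.t_events) if len(te)]
            if hit:
                j = hit[0]
                kind, i = event_tags[j]
                t_ev = float(sol.t_events[j][0])
                state = sol.y_events[j][0].copy()
                if kind == "quorum":
                    h[i] = 0.0 if h[i] else 1.0
                    if h[i] and i not in seen_quorum:
                        seen_quorum.add(i)
                        quorum_events.append((i, t_ev))
                else:
                    pool_open = False
                    state[_IP] = 0.0
                used_boundaries.append(t_ev)
                t = t_ev
            else:
                t = t_end
        if t_end < config.horizon:
            used_boundaries.append(float(t_end))

    if out.min() < -1e-7:
        raise RuntimeError(
            f"negative state beyond tolerance (min {out.min():.3e}) in trajectory")
    np.clip(out, 0.0, None, out=out)
    return Trajectory(times=grid, states=out,
                      window_boundaries=sorted(used_boundaries),
                      quorum_events=sorted(quorum_events, key=lambda e: e[1]))


def nest_population(traj: Trajectory, i: int) -> np.ndarray:
    """Ants visible in nest ``i``: assessors + potential transporters + carried items."""
    if i not in (1, 2):
        raise ValueError(f"nest index must be 1 or 2, got {i}")
    return traj.component(f"Z{i}") + traj.component(f"Y{i}") + traj.component(f"B{i}")


def quorum_time(traj: Trajectory, T: float) -> float | None:
    """Earliest grid time at which some potential-transporter count exceeds ``T``.

    Resolution is the trajectory's output grid; the exactly-located first
    crossings for the scenario's own threshold are in ``traj.quorum_events``.
    """
    exceeded = (traj.component("Y1") > T) | (traj.component("Y2") > T)
    idx = np.flatnonzero(exceeded)
    if len(idx) == 0:
        return None
    return float(traj.times[idx[0]])


def compare(a: np.ndarray, b: np.ndarray, component: str = "") -> ComparisonMetrics:
    """Sup-norm and RMS difference of two equally gridded series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    return ComparisonMetrics(sup_norm=float(diff.max()),
                             rms=float(np.sqrt(np.mean(diff ** 2))),
                             component=component)
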