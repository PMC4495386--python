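"""Core compartment model of collective nest-site choice.

A colony of active scouts chooses between two candidate nest sites. Scouts
discover each nest independently at per-capita rate ``mu``, assess it
(compartments ``Z1``, ``Z2``), and either accept it — becoming potential
transporters (``Y1``, ``Y2``) — at rate ``k_i`` or abandon it back to the
uncommitted pool ``X`` at rate ``rho_i``. Abandonment also applies to
potential transporters, so allegiance switches only *indirectly* through the
pool; there is no direct nest-to-nest transfer and no tandem-run recruitment.
Once the number of potential transporters at nest *i* exceeds the quorum
threshold ``T``, each of them carries passive ants and brood items from the
original nest (pool ``P``) into nest *i* (compartment ``B_i``) at per-capita
rate ``phi_i``.

Nest quality may fluctuate: each nest carries a periodic schedule that
alternates its assessment/abandonment rates between a "good" and a "poor"
phase, good phase first. All rates are per minute and the state is a
continuous (mean-field) count of ants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhaseParams",
    "NestSchedule",
    "ColonyState",
    "ScenarioConfig",
    "STATE_FIELDS",
    "params_at",
    "heaviside",
    "rhs",
    "rhs_array",
]

#: order of the state vector used by the integrators
STATE_FIELDS = ("X", "Z1", "Y1", "B1", "Z2", "Y2", "B2", "P")


@dataclass(frozen=True)
class PhaseParams:
    """Quality-dependent rates of one nest phase (per minute).

    ``k``: rate at which an assessor accepts the nest (becomes a potential
    transporter); ``rho``: rate at which an assessor or potential transporter
    abandons the nest and returns to the uncommitted pool.
    """

    k: float
    rho: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.rho < 0:
            raise ValueError(f"rates must be nonnegative, got k={self.k}, rho={self.rho}")


@dataclass(frozen=True)
class NestSchedule:
    """Piecewise-constant periodic quality program for one nest.

    The nest cycles with the given ``period`` (minutes), spending
    ``good_fraction`` of each cycle in the good phase. With ``good_first``
    (the experimental convention) the good phase occupies the half-open
    interval ``[0, good_fraction * period)`` of every cycle. A constant nest
    is represented by ``good_fraction = 1`` with a single set of phase
    parameters.
    """

    good: PhaseParams
    poor: PhaseParams | None = None
    period: float = 10.0
    good_fraction: float = 1.0
    good_first: bool = True

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if not 0.0 <= self.good_fraction <= 1.0:
            raise ValueError(f"good_fraction must lie in [0, 1], got {self.good_fraction}")
        if self.poor is None and self.good_fraction < 1.0:
            raise ValueError("a fluctuating schedule needs poor-phase parameters")

    @classmethod
    def constant(cls, params: PhaseParams) -> "NestSchedule":
        return cls(good=params, good_fraction=1.0)

    @property
    def is_constant(self) -> bool:
        return self.poor is None or self.good_fraction in (0.0, 1.0)

    def params_at(self, t: float) -> PhaseParams:
        """Phase parameters in force at time ``t`` (minutes), right-continuous."""
        if t < 0:
            raise ValueError(f"time must be nonnegative, got {t}")
        if self.poor is None:
            return self.good
        if self.good_fraction >= 1.0:
            return self.good
        if self.good_fraction <= 0.0:
            return self.poor
        tau = math.fmod(t, self.period)
        split = self.good_fraction * self.period
        if not self.good_first:
            split = (1.0 - self.good_fraction) * self.period
            return self.poor if tau < split else self.good
        return self.good if tau < split else self.poor

    def switch_times(self, horizon: float) -> np.ndarray:
        """Interior times in ``(0, horizon)`` at which the rates jump."""
        if self.is_constant:
            return np.empty(0)
        frac = self.good_fraction if self.good_first else 1.0 - self.good_fraction
        times = []
        t = 0.0
        while t < horizon:
            for s in (t + frac * self.period, t + self.period):
                if 0.0 < s < horizon:
                    times.append(s)
            t += self.period
        return np.asarray(times)

    def with_period(self, period: float) -> "NestSchedule":
        return replace(self, period=period)


@dataclass(frozen=True)
class ColonyState:
    """Continuous compartment counts.

    ``X``: uncommitted active scouts; ``Z_i``: assessors of nest *i*;
    ``Y_i``: potential transporters to nest *i*; ``B_i``: passive ants and
    brood items carried into nest *i*; ``P``: passive ants and brood still at
    the original nest.
    """

    X: float = 0.0
    Z1: float = 0.0
    Z2: float = 0.0
    Y1: float = 0.0
    Y2: float = 0.0
    B1: float = 0.0
    B2: float = 0.0
    P: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be nonnegative")

    @classmethod
    def initial(cls, n_scouts: float, n_passive: float) -> "ColonyState":
        """Pre-emigration state: all scouts uncommitted, all passives at home."""
        return cls(X=n_scouts, P=n_passive)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ColonyState":
        return cls(**dict(zip(STATE_FIELDS, map(float, arr))))

    @property
    def active_total(self) -> float:
        return self.X + self.Z1 + self.Z2 + self.Y1 + self.Y2

    @property
    def passive_total(self) -> float:
        return self.P + self.B1 + self.B2


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a two-nest emigration scenario.

    Defaults are the study's values: discovery rate ``mu = 0.03``/min,
    transport rates ``phi = 0.099``/min, quorum threshold ``T = 7`` potential
    transporters, 180-min horizon. ``nest1`` is conventionally the constant
    mediocre nest and ``nest2`` the fluctuating (or averaged) nest.
    """

    nest1: NestSchedule
    nest2: NestSchedule
    mu: float = 0.03
    phi1: float = 0.099
    phi2: float = 0.099
    T: float = 7.0
    horizon: float = 180.0
    initial: ColonyState = ColonyState(X=16.0, P=80.0)

    def __post_init__(self) -> None:
        if self.mu < 0 or self.phi1 < 0 or self.phi2 < 0:
            raise ValueError("rates mu, phi1, phi2 must be nonnegative")
        if self.T <= 0:
            raise ValueError(f"quorum threshold must be positive, got {self.T}")
        if self.horizon <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon}")

    def params_at(self, t: float) -> tuple[PhaseParams, PhaseParams]:
        return self.nest1.params_at(t), self.nest2.params_at(t)

    def switch_times(self) -> np.ndarray:
        times = np.union1d(self.nest1.switch_times(self.horizon),
                           self.nest2.switch_times(self.horizon))
        return times


def params_at(schedule: NestSchedule, t: float) -> PhaseParams:
    """Phase parameters of ``schedule`` in force at time ``t`` minutes."""
    return schedule.params_at(t)


def heaviside(y: float, T: float) -> float:
    """Quorum indicator H(y − T): 1 when y strictly exceeds T, else 0.

    The threshold itself does not trigger transport (H(0) = 0), matching the
    convention that transporters begin to carry only once their number
    *exceeds* the quorum.
    """
    return 1.0 if y > T else 0.0


def rhs_array(
    state,
    mu: float,
    p1: PhaseParams,
    p2: PhaseParams,
    phi1: float,
    phi2: float,
    T: float,
    h1: float | None = None,
    h2: float | None = None,
) -> np.ndarray:
    """Time derivative of the state vector ``(X, Z1, Y1, B1, Z2, Y2, B2, P)``.

    ``h1``/``h2`` optionally pin the quorum indicators to a fixed regime
    (used by the windowed integrator between located crossings); by default
    they are evaluated from the state. Transport stops when the passive pool
    is exhausted.
    """
    if mu < 0 or phi1 < 0 or phi2 < 0:
        raise ValueError("rates mu, phi1, phi2 must be nonnegative")
    X, Z1, Y1, B1, Z2, Y2, B2, P = state
    if h1 is None:
        h1 = heaviside(Y1, T)
    if h2 is None:
        h2 = heaviside(Y2, T)
    pool = 1.0 if P > 0 else 0.0
    tr1 = phi1 * Y1 * h1 * pool
    tr2 = phi2 * Y2 * h2 * pool
    return np.array([
        -2.0 * mu * X + p1.rho * (Z1 + Y1) + p2.rho * (Z2 + Y2),
        mu * X - (p1.k + p1.rho) * Z1,
        p1.k * Z1 - p1.rho * Y1,
        tr1,
        mu * X - (p2.k + p2.rho) * Z2,
        p2.k * Z2 - p2.rho * Y2,
        tr2,
        -tr1 - tr2,
    ])


def rhs(
    state: ColonyState,
    mu: float,
    p1: PhaseParams,
    p2: PhaseParams,
    phi1: float,
    phi2: float,
    T: float,
) -> ColonyState:
    """Flux balance of the model, returned as a state-shaped derivative.

    Conserves the active total X+Z1+Z2+Y1+Y2 and the passive total P+B1+B2
    exactly: every flux appears once as a source and once as a sink.
    """
    d = rhs_array(state.to_array(), mu, p1, p2, phi1, phi2, T)
    # a derivative may be negative; bypass ColonyState's nonnegativity check
    obj = ColonyState.__new__(ColonyState)
    for name, val in zip(STATE_FIELDS, d):
        object.__setattr__(obj, name, float(val))
    return obj
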