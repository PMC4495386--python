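"""Named scenario presets for the study's treatments and robustness variants.

Treatments pit a constant mediocre nest (nest 1) against a fluctuating nest
(nest 2) that is good for 25%, 50% or 75% of every cycle, good phase first.
The ``*_avg`` presets replace the fluctuating nest by its averaged (constant)
counterpart; the ``magnified_*`` presets widen the good/poor rate amplitude
close to its feasible maximum, and the ``period30_*`` presets slow the
fluctuation cycle from 10 to 30 minutes.
"""

from __future__ import annotations

from dataclasses import replace

from .model import ColonyState, NestSchedule, PhaseParams, ScenarioConfig
from .dynamics import averaged_nest

__all__ = [
    "CONSTANT_MEDIOCRE", "FLUCT_GOOD", "FLUCT_POOR",
    "MAGNIFIED_GOOD", "MAGNIFIED_POOR",
    "MU", "PHI", "QUORUM", "HORIZON", "X0", "P0",
    "GOOD_FRACTIONS", "TREATMENT_LABELS", "PRESETS",
    "scenario", "overlap_tolerance",
]

# constant-nest and fluctuating-phase rates (per minute)
CONSTANT_MEDIOCRE = PhaseParams(k=0.020, rho=0.008)
FLUCT_GOOD = PhaseParams(k=0.024, rho=0.004)
FLUCT_POOR = PhaseParams(k=0.016, rho=0.012)
# amplitude magnified close to the feasible maximum
MAGNIFIED_GOOD = PhaseParams(k=0.038, rho=0.001)
MAGNIFIED_POOR = PhaseParams(k=0.002, rho=0.015)

MU = 0.03          # per-nest discovery rate, per minute
PHI = 0.099        # per-transporter carrying rate, per minute
QUORUM = 7.0       # quorum threshold on potential transporters
HORIZON = 180.0    # observation horizon, minutes
#: default initial condition: 16 uncommitted scouts, 80 passive items.
#: Calibrated once so that under the default rates no treatment attains the
#: quorum within the horizon while nest populations still rise somewhat above
#: the threshold count, then frozen.
X0 = 16.0
P0 = 80.0

GOOD_FRACTIONS = {"t25": 0.25, "t50": 0.50, "t75": 0.75}
#: dataset labels for the three treatments
TREATMENT_LABELS = {"t25": "25%G", "t50": "50%G", "t75": "75%G"}

PRESETS = tuple(
    [*GOOD_FRACTIONS]
    + [f"{t}_avg" for t in GOOD_FRACTIONS]
    + [f"magnified_{t}" for t in GOOD_FRACTIONS]
    + [f"period30_{t}" for t in GOOD_FRACTIONS]
)

#: frozen sup-norm tolerances (ants) quantifying the "heavy overlap" between
#: the fluctuating nest and its averaged counterpart
_DEFAULT_TOL = 0.5
_ROBUSTNESS_TOL = 1.5


def overlap_tolerance(name: str) -> float:
    """Documented fluctuating-vs-averaged overlap tolerance for a preset."""
    if name.startswith(("magnified_", "period30_")):
        return _ROBUSTNESS_TOL
    return _DEFAULT_TOL


def _fluctuating(name: str) -> NestSchedule:
    if name.startswith("magnified_"):
        good, poor, key, period = MAGNIFIED_GOOD, MAGNIFIED_POOR, name[10:], 10.0
    elif name.startswith("period30_"):
        good, poor, key, period = FLUCT_GOOD, FLUCT_POOR, name[9:], 30.0
    else:
        good, poor, key, period = FLUCT_GOOD, FLUCT_POOR, name, 10.0
    avg = key.endswith("_avg")
    if avg:
        key = key[:-4]
    if key not in GOOD_FRACTIONS:
        raise KeyError(name)
    sched = NestSchedule(good=good, poor=poor, period=period,
                         good_fraction=GOOD_FRACTIONS[key])
    return averaged_nest(sched) if avg else sched


def scenario(
    name: str,
    *,
    period: float | None = None,
    x0: float | None = None,
    p0: float | None = None,
    horizon: float | None = None,
) -> ScenarioConfig:
    """Build a preset scenario, optionally overriding period or initial counts."""
    try:
        nest2 = _fluctuating(name)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}") from None
    if period is not None:
        nest2 = nest2.with_period(period)
    cfg = ScenarioConfig(
        nest1=NestSchedule.constant(CONSTANT_MEDIOCRE),
        nest2=nest2,
        mu=MU, phi1=PHI, phi2=PHI, T=QUORUM,
        horizon=HORIZON if horizon is None else horizon,
        initial=ColonyState(X=X0 if x0 is None else x0,
                            P=P0 if p0 is None else p0),
    )
    return cfg
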