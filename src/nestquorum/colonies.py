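"""Stochastic colony emulator and synthetic experiment generator.

The emulator is the integer-count, continuous-time Markov chain counterpart
of the mean-field model: each compartment transition of the flux diagram
becomes a Poisson event with the corresponding aggregate rate (discovery
``mu*X`` per nest, acceptance ``k_i*Z_i``, abandonment ``rho_i*(Z_i+Y_i)``,
and — once the potential transporters at a nest strictly exceed the quorum —
transport of one passive item per event at aggregate rate ``phi_i*Y_i``).
Rates are constant between nest-quality switches, so exponential waiting
times with clocks redrawn at each switch simulate the chain exactly.

An emigration replicate ends at the first transport event (the experimental
signature of a committed choice: social carrying) or is censored at the
horizon. Ant counts per nest are recorded every ten minutes, and the
"observed" quorum threshold is the total occupancy of the chosen nest when
carrying begins — observers count every ant present, not just the potential
transporters the model's threshold is defined on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ColonyState, ScenarioConfig
from . import presets as _presets

__all__ = [
    "Colony",
    "ExperimentDesign",
    "EmigrationRecord",
    "sample_colony",
    "simulate_emigration",
    "generate_dataset",
    "records_to_frame",
    "write_dataset",
    "read_dataset",
]

WORKER_RANGE = (24, 92)


@dataclass(frozen=True)
class Colony:
    """One colony's census: workers, scouting minority, passive items.

    ``n_active`` scouts search for nests; ``n_passive`` counts the passive
    workers plus brood items (brood roughly as numerous as the workers) that
    remain at the original nest until carried.
    """

    id: str
    n_workers: int
    n_active: int
    n_passive: int

    def __post_init__(self) -> None:
        if self.n_workers <= 0 or self.n_active < 0 or self.n_passive < 0:
            raise ValueError("colony counts must be nonnegative (workers positive)")


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the synthetic experiment.

    Mirrors the study design: 30 colonies of 24-92 workers, each run under
    two of the three treatments in randomized order, counts every 10 min,
    censoring at 180 min.
    """

    n_colonies: int = 30
    treatments_per_colony: int = 2
    treatments: tuple[str, ...] = ("t25", "t50", "t75")
    horizon: float = 180.0
    count_interval: float = 10.0
    active_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_colonies <= 0:
            raise ValueError("n_colonies must be positive")
        if not 1 <= self.treatments_per_colony <= len(self.treatments):
            raise ValueError("treatments_per_colony must be between 1 and the "
                             "number of treatments")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")
        if self.horizon <= 0 or self.count_interval <= 0:
            raise ValueError("horizon and count_interval must be positive")

    @property
    def count_times(self) -> np.ndarray:
        return np.arange(self.count_interval, self.horizon + 1e-9,
                         self.count_interval)


@dataclass
class EmigrationRecord:
    """Outcome of one colony x treatment replicate.

    ``chosen`` is ``"FN"``/``"CN"`` or ``None`` when censored;
    ``quorum_threshold`` is the occupancy of the chosen nest at the first
    carrying event; counts after the choice are ``None`` (the replicate has
    ended).
    """

    colony_id: str
    n_workers: int
    treatment: str
    chosen: str | None
    quorum_threshold: int | None
    time_to_quorum: float | None
    cn_counts: list[int | None]
    fn_counts: list[int | None]


def sample_colony(design: ExperimentDesign, rng: np.random.Generator,
                  colony_id: str = "c000") -> Colony:
    """Draw one colony: workers uniform on 24..92, brood roughly as numerous."""
    n_workers = int(rng.integers(WORKER_RANGE[0], WORKER_RANGE[1] + 1))
    n_active = int(round(design.active_fraction * n_workers))
    brood = int(rng.poisson(n_workers))
    n_passive = (n_workers - n_active) + brood
    return Colony(id=colony_id, n_workers=n_workers,
                  n_active=n_active, n_passive=n_passive)


# transitions: (source component delta applied inside the loop); order matters
_EVENT_NAMES = (
    "discover1", "discover2", "accept1", "abandon_Z1", "abandon_Y1",
    "accept2", "abandon_Z2", "abandon_Y2", "transport1", "transport2",
)


def simulate_emigration(
    colony: Colony,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    count_interval: float = 10.0,
    treatment: str = "",
    log_events: bool = False,
    stop_at_choice: bool = True,
):
    """Simulate one emigration replicate of ``colony`` under ``scenario``.

    Returns an :class:`EmigrationRecord`; with ``log_events`` also returns
    the event log as ``(time, event name, state tuple)`` entries, the state
    being ``(X, Z1, Y1, B1, Z2, Y2, B2, P)`` after the event.

    By default the replicate ends at the first transport event, as the
    experiment does. With ``stop_at_choice=False`` the chain keeps running to
    the horizon (transports continue; ``chosen`` still names the nest of the
    first one), which is the exact stochastic counterpart of the mean-field
    dynamics and is used for mean-field agreement checks.
    """
    horizon = scenario.horizon
    marks = np.arange(count_interval, horizon + 1e-9, count_interval)
    cn: list[int | None] = [None] * len(marks)
    fn: list[int | None] = [None] * len(marks)

    X = colony.n_active
    Z1 = Y1 = B1 = Z2 = Y2 = B2 = 0
    P = colony.n_passive
    mu, phi1, phi2, T = scenario.mu, scenario.phi1, scenario.phi2, scenario.T

    chosen: str | None = None
    qthr: int | None = None
    tq: float | None = None
    events: list[tuple[float, str, tuple]] = []

    bounds = list(scenario.switch_times()) + [horizon]
    t = 0.0
    mark_i = 0
    exp = rng.exponential
    uni = rng.random
    done = False
    for t_end in bounds:
        if done:
            break
        p1, p2 = scenario.params_at(t)
        k1, r1, k2, r2 = p1.k, p1.rho, p2.k, p2.rho
        while True:
            rates = (
                mu * X, mu * X,
                k1 * Z1, r1 * Z1, r1 * Y1,
                k2 * Z2, r2 * Z2, r2 * Y2,
                phi1 * Y1 if (Y1 > T and P > 0) else 0.0,
                phi2 * Y2 if (Y2 > T and P > 0) else 0.0,
            )
            total = sum(rates)
            t_next = t + exp(1.0 / total) if total > 0.0 else math.inf
            t_step = min(t_next, t_end)
            while mark_i < len(marks) and marks[mark_i] <= t_step + 1e-9:
                cn[mark_i] = Z1 + Y1 + B1
                fn[mark_i] = Z2 + Y2 + B2
                mark_i += 1
            if t_next >= t_end:
                t = t_end
                break
            t = t_next
            u = uni() * total
            acc = 0.0
            for ev, r in enumerate(rates):
                acc += r
                if u < acc:
                    break
            if ev == 0:
                X -= 1; Z1 += 1
            elif ev == 1:
                X -= 1; Z2 += 1
            elif ev == 2:
                Z1 -= 1; Y1 += 1
            elif ev == 3:
                Z1 -= 1; X += 1
            elif ev == 4:
                Y1 -= 1; X += 1
            elif ev == 5:
                Z2 -= 1; Y2 += 1
            elif ev == 6:
                Z2 -= 1; X += 1
            elif ev == 7:
                Y2 -= 1; X += 1
            elif ev == 8:
                if chosen is None:
                    chosen, qthr, tq = "CN", Z1 + Y1 + B1, t
                P -= 1; B1 += 1
            else:
                if chosen is None:
                    chosen, qthr, tq = "FN", Z2 + Y2 + B2, t
                P -= 1; B2 += 1
            if log_events:
                events.append((t, _EVENT_NAMES[ev],
                               (X, Z1, Y1, B1, Z2, Y2, B2, P)))
            if chosen is not None and stop_at_choice:
                done = True
                break

    record = EmigrationRecord(
        colony_id=colony.id, n_workers=colony.n_workers, treatment=treatment,
        chosen=chosen, quorum_threshold=qthr, time_to_quorum=tq,
        cn_counts=cn, fn_counts=fn,
    )
    return (record, events) if log_events else record


def _assign_treatments(design: ExperimentDesign,
                       rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Balanced assignment of treatment subsets, randomized order per colony."""
    combos = list(itertools.combinations(design.treatments,
                                         design.treatments_per_colony))
    per = [design.n_colonies // len(combos)] * len(combos)
    for j in range(design.n_colonies % len(combos)):
        per[j] += 1
    assignment: list[tuple[str, ...]] = []
    for combo, n in zip(combos, per):
        assignment.extend([combo] * n)
    order = rng.permutation(len(assignment))
    out = []
    for idx in order:
        combo = list(assignment[idx])
        rng.shuffle(combo)
        out.append(tuple(combo))
    return out


def generate_dataset(
    design: ExperimentDesign,
    seed: int,
    scenarios: Mapping[str, ScenarioConfig] | None = None,
) -> list[EmigrationRecord]:
    """Generate one record per colony x assigned treatment, reproducibly.

    ``scenarios`` maps treatment names to scenario presets (schedules, rates,
    quorum); each colony's initial state is its own census (scouts
    uncommitted, passives at home), overriding the preset's initial state.
    """
    if scenarios is None:
        scenarios = {t: _presets.scenario(t, horizon=design.horizon)
                     for t in design.treatments}
    rng = np.random.default_rng(seed)
    assignment = _assign_treatments(design, rng)
    width = len(str(design.n_colonies))
    records: list[EmigrationRecord] = []
    for c in range(design.n_colonies):
        colony = sample_colony(design, rng, colony_id=f"c{c + 1:0{width}d}")
        for tname in assignment[c]:
            cfg = replace(
                scenarios[tname],
                initial=ColonyState.initial(colony.n_active, colony.n_passive),
                horizon=design.horizon,
            )
            rec = simulate_emigration(
                colony, cfg, rng, count_interval=design.count_interval,
                treatment=_presets.TREATMENT_LABELS.get(tname, tname),
            )
            records.append(rec)
    return records


def _count_columns(n_marks: int, prefix: str) -> list[str]:
    return [f"{prefix}_t{int(10 * (i + 1)):03d}" for i in range(n_marks)]


def records_to_frame(records: Sequence[EmigrationRecord]) -> pd.DataFrame:
    """Tabulate records: one row per replicate, count columns per 10-min mark."""
    n_marks = max(len(r.cn_counts) for r in records)
    rows = []
    for r in records:
        row = {
            "colony_id": r.colony_id,
            "n_workers": r.n_workers,
            "treatment": r.treatment,
            "chosen": r.chosen if r.chosen is not None else "none",
            "quorum_threshold": r.quorum_threshold,
            "time_to_quorum_min": r.time_to_quorum,
        }
        for col, v in zip(_count_columns(n_marks, "cn"), r.cn_counts):
            row[col] = v
        for col, v in zip(_count_columns(n_marks, "fn"), r.fn_counts):
            row[col] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(records: Sequence[EmigrationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"colony_id": str})
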