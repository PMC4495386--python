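"""Summary statistics for emigration datasets and model-derived quantities.

Covers the study's headline numbers that do not require mixed-model
machinery: per-treatment choice proportions with Wilson intervals, the
pooled exact binomial comparison of fluctuating-vs-constant choices,
log-linear (Poisson) accumulation slopes of nest counts over time, and the
desk quantities derived from the rate parameters — the probability
``p = k/(k + rho)`` that a discoverer eventually assesses a nest positively,
the characteristic assessment/abandonment times ``1/k`` and ``1/rho``, and
the averaged-nest rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .model import NestSchedule, PhaseParams
from .dynamics import averaged_nest
from . import presets as _presets

__all__ = [
    "ChoiceTable",
    "SlopeEstimate",
    "choice_table",
    "pooled_binomial",
    "acceptance_probability",
    "characteristic_times",
    "accumulation_slope",
    "summary_report",
    "write_report",
]


@dataclass(frozen=True)
class ChoiceTable:
    """Per-treatment choice counts and FN proportion with 95% Wilson interval."""

    table: pd.DataFrame  # index: treatment; columns n_FN, n_CN, n_none,
    #                      proportion_FN, ci_low, ci_high

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def write_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass(frozen=True)
class SlopeEstimate:
    """Log-linear accumulation rate of ant counts over time (per minute)."""

    rate: float
    intercept: float
    se_rate: float
    nest: str
    treatment: str


def choice_table(dataset: pd.DataFrame) -> ChoiceTable:
    """Tabulate choices per treatment.

    Censored replicates (no carrying before the horizon) are counted in
    ``n_none`` but excluded from the proportion, which compares only actual
    choices. An empty stratum yields an undefined (NaN) proportion.
    """
    if "chosen" not in dataset.columns:
        raise ValueError("dataset must have a 'chosen' column")
    rows = []
    for treatment, grp in dataset.groupby("treatment", sort=True):
        n_fn = int((grp["chosen"] == "FN").sum())
        n_cn = int((grp["chosen"] == "CN").sum())
        n_none = int(len(grp) - n_fn - n_cn)
        n_choices = n_fn + n_cn
        if n_choices > 0:
            prop = n_fn / n_choices
            lo, hi = proportion_confint(n_fn, n_choices, alpha=0.05,
                                        method="wilson")
        else:
            prop = lo = hi = float("nan")
        rows.append({"treatment": treatment, "n_FN": n_fn, "n_CN": n_cn,
                     "n_none": n_none, "proportion_FN": prop,
                     "ci_low": float(lo), "ci_high": float(hi)})
    return ChoiceTable(pd.DataFrame(rows).set_index("treatment"))


def pooled_binomial(n_fn: int, n_cn: int, alternative: str = "greater") -> float:
    """Exact fair-coin binomial probability for a pooled choice comparison.

    With ``alternative="greater"`` (the primary form) this is the upper-tail
    probability of at least ``max(n_fn, n_cn)`` successes in ``n_fn + n_cn``
    trials at p = 1/2, computed by direct summation of the binomial mass;
    ``"two-sided"`` doubles it (capped at 1).
    """
    if n_fn < 0 or n_cn < 0:
        raise ValueError("counts must be nonnegative")
    n = n_fn + n_cn
    if n == 0:
        raise ValueError("at least one choice is required")
    m = max(n_fn, n_cn)
    tail = sum(math.comb(n, i) for i in range(m, n + 1)) / 2.0 ** n
    if alternative == "greater":
        return tail
    if alternative == "two-sided":
        return min(1.0, 2.0 * tail)
    raise ValueError(f"unknown alternative {alternative!r}")


def acceptance_probability(params: PhaseParams) -> float:
    """Probability that a discoverer eventually assesses the nest positively.

    An assessor leaves the assessment state by acceptance (rate k) or
    abandonment (rate rho); the race between the two exponential clocks gives
    p = k/(k + rho).
    """
    if params.k + params.rho <= 0:
        raise ValueError("k + rho must be positive")
    return params.k / (params.k + params.rho)


def characteristic_times(params: PhaseParams) -> tuple[float, float]:
    """Mean assessment time 1/k and mean abandonment time 1/rho, in minutes."""
    if params.k <= 0 or params.rho <= 0:
        raise ValueError("characteristic times need strictly positive rates")
    return 1.0 / params.k, 1.0 / params.rho


def _long_counts(dataset: pd.DataFrame, nest: str,
                 treatment: str, choosers_only: bool = True) -> pd.DataFrame:
    prefix = {"CN": "cn", "FN": "fn"}.get(nest.upper())
    if prefix is None:
        raise ValueError(f"nest must be 'CN' or 'FN', got {nest!r}")
    grp = dataset[dataset["treatment"] == treatment]
    if choosers_only:
        grp = grp[grp["chosen"].isin(["FN", "CN"])]
    cols = [c for c in dataset.columns if c.startswith(prefix + "_t")]
    times = {c: float(c.split("_t")[1]) for c in cols}
    long = grp[cols].melt(var_name="mark", value_name="count")
    long["time_min"] = long["mark"].map(times)
    long = long.dropna(subset=["count"])
    long["count"] = long["count"].astype(float)
    return long


def accumulation_slope(dataset: pd.DataFrame, nest: str, treatment: str,
                       choosers_only: bool = True) -> SlopeEstimate:
    """Poisson log-linear slope of nest counts versus time.

    Pools the 10-min counts of the given nest across all replicates of the
    treatment (by default those that made a choice) and fits
    ``log E[count] = intercept + rate * time`` by maximum likelihood. This is
    the single-level analogue of the study's count regression: no per-colony
    random effects.
    """
    long = _long_counts(dataset, nest, treatment, choosers_only)
    informative = long.groupby("time_min")["count"].sum()
    if (informative.index.size < 3) or (informative > 0).sum() < 3:
        raise ValueError(
            f"slope undefined for nest {nest}, treatment {treatment!r}: "
            "need >= 3 time points with nonzero counts")
    exog = sm.add_constant(long["time_min"].to_numpy())
    model = sm.GLM(long["count"].to_numpy(), exog,
                   family=sm.families.Poisson())
    res = model.fit()
    return SlopeEstimate(rate=float(res.params[1]),
                         intercept=float(res.params[0]),
                         se_rate=float(res.bse[1]),
                         nest=nest.upper(), treatment=treatment)


def _derived_quantities() -> dict:
    """Desk quantities implied by the default rate parameterization."""
    phases = {"poor": _presets.FLUCT_POOR,
              "mediocre": _presets.CONSTANT_MEDIOCRE,
              "good": _presets.FLUCT_GOOD}
    out: dict = {"acceptance_probability_pct": {}, "characteristic_times_min": {},
                 "averaged_nest_rates": {}}
    for name, p in phases.items():
        out["acceptance_probability_pct"][name] = round(
            100.0 * acceptance_probability(p))
        t_assess, t_abandon = characteristic_times(p)
        out["characteristic_times_min"][name] = {
            "assessment": t_assess, "abandonment": t_abandon}
    for tname, g in _presets.GOOD_FRACTIONS.items():
        sched = NestSchedule(good=_presets.FLUCT_GOOD, poor=_presets.FLUCT_POOR,
                             good_fraction=g)
        avg = averaged_nest(sched).good
        out["averaged_nest_rates"][_presets.TREATMENT_LABELS[tname]] = {
            "k": avg.k, "rho": avg.rho}
    return out


def summary_report(dataset: pd.DataFrame) -> dict:
    """Full JSON-ready summary: choices, pooled test, slopes, derived quantities."""
    ct = choice_table(dataset)
    n_fn = int(ct.table["n_FN"].sum())
    n_cn = int(ct.table["n_CN"].sum())
    slopes = {}
    for treatment in ct.table.index:
        slopes[treatment] = {}
        for nest in ("CN", "FN"):
            try:
                est = accumulation_slope(dataset, nest, treatment)
                slopes[treatment][nest] = {
                    "rate_per_min": est.rate, "intercept": est.intercept,
                    "se_rate": est.se_rate}
            except ValueError as err:
                slopes[treatment][nest] = {"undefined": str(err)}
    report = {
        "choice_table": ct.table.reset_index().to_dict(orient="records"),
        "pooled_test": {
            "n_FN": n_fn, "n_CN": n_cn,
            "p_value_one_sided": pooled_binomial(n_fn, n_cn)
            if (n_fn + n_cn) else None,
        },
        "slopes": slopes,
        "derived_quantities": _derived_quantities(),
    }
    return report


def write_report(report: dict, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=True)
        fh.write("\n")
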