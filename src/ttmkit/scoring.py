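"""Vehicle-referenced probability scoring and MOA assignment.

Each baseline-normalized kinetic parameter *x* is compared against the
Gaussian fitted to the vehicle wells.  The "no change" score is the
mean-normalized Gaussian density scaled to a 0–10 range,

    PS_=(x) = 10 · exp(−(x − μ)² / (2 σ²)),

and the "increase"/"decrease" scores take the complementary mass on their
side of the mean:

    PS_↑(x) = 0 for x < μ, else 10 − PS_=(x)
    PS_↓(x) = 10 − PS_=(x) for x ≤ μ, else 0.

Pointwise PS_= + PS_↑ + PS_↓ = 10, so a negated expectation ("not up" etc.)
scores exactly 10 − PS_effect.  Summing over the ten parameters gives each
MOA hypothesis a total between 0 and 100; the highest total is the assigned
mechanism.  Channel-restricted subsets (AP only, Ca only, Co only) sum 4 or
3 parameters and are bounded by 40 / 30 / 30.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateVehicleError,
    InputError,
    MissingVehicleError,
    SchemaError,
)
from .hypotheses import (
    AP_PARAMS,
    CA_PARAMS,
    CO_PARAMS,
    Effect,
    HypothesisTable,
    KineticParameter,
    MOA,
    builtin_table,
)

__all__ = [
    "SUBSETS",
    "VehicleStats",
    "fit_vehicle",
    "ps_same",
    "ps_up",
    "ps_down",
    "ps_effect",
    "score_hypotheses",
    "Assignment",
    "assign_moa",
    "concentration_response",
]

SUBSETS: dict[str, tuple[KineticParameter, ...]] = {
    "ALL": tuple(KineticParameter),
    "AP": AP_PARAMS,
    "Ca": CA_PARAMS,
    "Co": CO_PARAMS,
}


@dataclass(frozen=True)
class VehicleStats:
    """Per-parameter Gaussian of the vehicle population.

    ``mean`` / ``sd`` map each kinetic parameter to the mean and spread of
    the normalized vehicle well values; ``n`` is the number of vehicle
    wells.  ``sd_mode`` records whether ``sd`` is the sample standard
    deviation ("sd", default) or the standard error of the mean ("sem").
    """

    mean: Mapping[KineticParameter, float]
    sd: Mapping[KineticParameter, float]
    n: int
    sd_mode: str = "sd"

    def __post_init__(self) -> None:
        for p in KineticParameter:
            if p not in self.mean or p not in self.sd:
                raise InputError(f"vehicle stats missing parameter {p.name}")
            if not self.sd[p] > 0:
                raise DegenerateVehicleError(
                    f"vehicle sd for {p.name} is not positive; scoring impossible"
                )
        if self.n < 2:
            raise InputError("vehicle stats need at least 2 wells")


def fit_vehicle(vehicle_values: Mapping[KineticParameter, Sequence[float]],
                sd_mode: str = "sd") -> VehicleStats:
    """Fit the per-parameter vehicle Gaussian from normalized well values.

    ``sd_mode="sd"`` uses the sample standard deviation (ddof=1);
    ``"sem"`` divides it by sqrt(n) for users who read the density's width
    parameter as a standard error of the mean.
    """
    if sd_mode not in ("sd", "sem"):
        raise InputError(f"unknown sd_mode {sd_mode!r}")
    means, sds, ns = {}, {}, set()
    for p in KineticParameter:
        vals = np.asarray(vehicle_values[p], dtype=float)
        if vals.size < 2:
            raise InputError(f"need >= 2 vehicle values for {p.name}")
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise DegenerateVehicleError(
                f"identical vehicle values for {p.name}; sd is zero"
            )
        if sd_mode == "sem":
            sd /= math.sqrt(vals.size)
        means[p] = float(np.mean(vals))
        sds[p] = sd
        ns.add(vals.size)
    return VehicleStats(mean=means, sd=sds, n=min(ns), sd_mode=sd_mode)


# ---- the three probability-score spaces -----------------------------------


def ps_same(x: float, stats: VehicleStats, param: KineticParameter) -> float:
    """Score (0–10) for "no change": mean-normalized Gaussian density × 10."""
    mu, sd = stats.mean[param], stats.sd[param]
    return 10.0 * math.exp(-((x - mu) ** 2) / (2.0 * sd * sd))


def ps_up(x: float, stats: VehicleStats, param: KineticParameter) -> float:
    """Score (0–10) for "increase": 0 below the vehicle mean, else 10 − PS_=."""
    if x < stats.mean[param]:
        return 0.0
    return 10.0 - ps_same(x, stats, param)


def ps_down(x: float, stats: VehicleStats, param: KineticParameter) -> float:
    """Score (0–10) for "decrease": 10 − PS_= below/at the mean, else 0."""
    if x > stats.mean[param]:
        return 0.0
    return 10.0 - ps_same(x, stats, param)


_PLAIN = {Effect.SAME: ps_same, Effect.UP: ps_up, Effect.DOWN: ps_down}


def ps_effect(x: float, stats: VehicleStats, param: KineticParameter,
              effect: Effect) -> float:
    """Score any expected effect; a negated cell scores 10 − PS_effect.

    Because the three plain scores partition 10 pointwise, 10 − PS_e is
    exactly the combined score of the two admissible alternatives.
    """
    if not isinstance(effect, Effect):
        raise InputError(f"unknown effect {effect!r}")
    if effect.is_negated:
        return 10.0 - _PLAIN[effect.negates](x, stats, param)
    return _PLAIN[effect](x, stats, param)


def score_hypotheses(params: Mapping[KineticParameter, float],
                     stats: VehicleStats,
                     table: HypothesisTable | None = None,
                     subset: str = "ALL") -> dict[MOA, float]:
    """Total probability score per MOA over the chosen parameter subset."""
    table = table or builtin_table()
    try:
        members = SUBSETS[subset]
    except KeyError as exc:
        raise InputError(f"unknown subset {subset!r}") from exc
    missing = [p.name for p in members if p not in params]
    if missing:
        raise InputError(f"missing parameter(s) in subset {subset}: {missing}")
    totals = {}
    for moa in MOA:
        totals[moa] = sum(
            ps_effect(float(params[p]), stats, p, table.expected_effect(moa, p))
            for p in members
        )
    return totals


@dataclass(frozen=True)
class Assignment:
    """Winning MOA of one score table row; ``tied`` lists near-equal winners."""

    moa: MOA
    total: float
    tie: bool
    tied: tuple[MOA, ...]


def assign_moa(totals: Mapping[MOA, float], tie_epsilon: float = 1e-6) -> Assignment:
    """Argmax over hypothesis totals; flags ties within ``tie_epsilon``."""
    if not totals:
        raise InputError("empty totals")
    ranked = sorted(totals.items(), key=lambda kv: kv[1], reverse=True)
    best_moa, best = ranked[0]
    tied = tuple(m for m, v in ranked if best - v < tie_epsilon)
    return Assignment(moa=best_moa, total=best, tie=len(tied) > 1, tied=tied)


# ---- concentration-response scoring ---------------------------------------

PARAM_COLUMNS = [p.name for p in KineticParameter]


def _well_values(df: pd.DataFrame) -> dict[KineticParameter, np.ndarray]:
    return {p: df[p.name].to_numpy(dtype=float) for p in KineticParameter}


def concentration_response(params: pd.DataFrame,
                           table: HypothesisTable | None = None,
                           sd_mode: str = "sd",
                           tie_epsilon: float = 1e-6,
                           subsets: Iterable[str] = ("ALL", "AP", "Ca", "Co"),
                           ) -> pd.DataFrame:
    """Score every drug × concentration × channel subset of a parameter table.

    ``params`` is a per-well table with columns ``drug``, ``concentration_uM``,
    ``well`` and the ten parameter columns, values already normalized to each
    well's baseline.  Vehicle wells are the rows with concentration 0; they
    define the Gaussian reference.  The value scored per parameter is the
    across-well mean at that concentration.  The vehicle condition itself is
    scored per well with leave-current-well-out statistics (falling back to
    plain scoring when fewer than 3 vehicle wells exist) to avoid trivial
    self-inflation.

    Returns one row per condition and subset with the six MOA totals, the
    assigned MOA and a tie flag.
    """
    table = table or builtin_table()
    required = {"drug", "concentration_uM", "well", *PARAM_COLUMNS}
    missing = sorted(required - set(params.columns))
    if missing:
        raise SchemaError(f"parameter table missing column(s): {missing}")
    vehicle = params[params["concentration_uM"] == 0]
    if vehicle.empty:
        raise MissingVehicleError("no vehicle (concentration 0) rows in table")
    veh_vals = _well_values(vehicle)
    stats = fit_vehicle(veh_vals, sd_mode=sd_mode)

    rows = []
    for (drug, conc), group in params.groupby(["drug", "concentration_uM"], sort=True):
        for subset in subsets:
            if conc == 0:
                totals = _vehicle_self_totals(group, veh_vals, table, sd_mode, subset)
            else:
                x = {p: float(np.mean(v)) for p, v in _well_values(group).items()}
                totals = score_hypotheses(x, stats, table, subset)
            assignment = assign_moa(totals, tie_epsilon)
            row = {
                "drug": drug,
                "concentration_uM": conc,
                "subset": subset,
                "n_wells": group["well"].nunique(),
                "assigned": assignment.moa.name,
                "tie": assignment.tie,
                "tied": "|".join(m.name for m in assignment.tied),
            }
            row.update({moa.name: totals[moa] for moa in MOA})
            rows.append(row)
    return pd.DataFrame(rows)


def _vehicle_self_totals(group: pd.DataFrame,
                         veh_vals: dict[KineticParameter, np.ndarray],
                         table: HypothesisTable, sd_mode: str,
                         subset: str) -> dict[MOA, float]:
    """Score the vehicle condition against itself.

    With n >= 3 vehicle wells, each well is scored against statistics fitted
    on the remaining wells and the per-well totals are averaged; with 2
    wells the leave-one-out fit is degenerate, so plain scoring of the
    across-well mean is used instead.
    """
    n = len(group)
    if n < 3:
        stats = fit_vehicle(veh_vals, sd_mode=sd_mode)
        x = {p: float(np.mean(v)) for p, v in _well_values(group).items()}
        return score_hypotheses(x, stats, table, subset)
    per_well = []
    vals = _well_values(group)
    for i in range(n):
        loo = {p: np.delete(v, i) for p, v in vals.items()}
        stats = fit_vehicle(loo, sd_mode=sd_mode)
        x = {p: float(v[i]) for p, v in vals.items()}
        per_well.append(score_hypotheses(x, stats, table, subset))
    return {moa: float(np.mean([t[moa] for t in per_well])) for moa in MOA}
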