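"""Fortification-level assignment by linear programming.

Decision variables are the fortification levels f_g, one per allowed food
group, expressed as µg of nutrient per 10 MJ of the group's energy.  The
per-10 MJ basis is the safety device of the whole design: recommended
energy intake is roughly 10 MJ/day for most population groups, so a common
cap ``0 ≤ f_g ≤ C`` guarantees that even a hypothetical consumer whose
entire energy intake came from fortified foods would receive at most
C µg/day of added nutrient.

For stratum s with median background intake B_s (µg/day) and median group
energies E_{s,g} (MJ/day), the modelled post-fortification median intake is

    T_s = B_s + Σ_g f_g · E_{s,g} / 10        [µg/day]

and the program is

    minimize    Σ_s d_s            (or max_s d_s in minimax mode)
    subject to  T_s ≥ RI_s                       (target attainment, hard)
                d_s ≥ T_s − RI_s,  d_s ≥ 0       (overshoot)
                0 ≤ f_g ≤ C

Because attainment is a hard constraint, deviation from target equals
overshoot, and both objective modes are faithful linearizations of
"smallest variation in deviation from target".  Solved with HiGHS via
``scipy.optimize.linprog``; the method and variable ordering are pinned so
runs are deterministic.  LP optima need not be unique — ties between
groups with proportional energy profiles can break either way — which is
documented rather than resolved by a secondary objective.

:func:`find_min_cap` recovers the smallest integer cap at which the
program is feasible by sweeping C upward; feasibility is monotone in C,
and the feasibility threshold is solver-independent even where the
optimal scheme is not unique.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import linprog

from .survey_data import StratumAggregates, StratumDef

__all__ = [
    "StratumTarget",
    "TargetSpec",
    "Scenario",
    "LPModel",
    "FortificationScheme",
    "default_targets",
    "build_lp",
    "solve_scheme",
    "find_min_cap",
    "brute_force_scheme_oracle",
    "InfeasibleError",
]

ATTAINMENT_TOL = 1e-6  # µg/day slack allowed on T_s >= RI_s in feasibility checks


class InfeasibleError(RuntimeError):
    """No cap in the searched range yields a feasible program."""


class StratumTarget(BaseModel):
    ri_ug_per_day: float = Field(gt=0)
    ul_ug_per_day: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "StratumTarget":
        if not self.ri_ug_per_day < self.ul_ug_per_day:
            raise ValueError("require 0 < RI < UL")
        return self


class TargetSpec(BaseModel):
    """Per-stratum recommended intake (RI) and tolerable upper level (UL)."""

    targets: dict[str, StratumTarget]

    def ri(self, stratum_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.targets[s].ri_ug_per_day for s in stratum_ids])

    def ul(self, stratum_id: str) -> float:
        return self.targets[stratum_id].ul_ug_per_day


def default_targets(
    strata: Sequence[StratumDef],
    ri_ug_per_day: float = 10.0,
    ul_child_ug_per_day: float = 50.0,
    ul_adult_ug_per_day: float = 100.0,
    child_age_max: int = 10,
) -> TargetSpec:
    """RI 10 µg/day everywhere; UL 50 µg/day for strata entirely within
    ages 4–10, 100 µg/day otherwise."""
    t = {}
    for s in strata:
        ul = ul_child_ug_per_day if s.age_max <= child_age_max else ul_adult_ug_per_day
        t[s.stratum_id] = StratumTarget(ri_ug_per_day=ri_ug_per_day, ul_ug_per_day=ul)
    return TargetSpec(targets=t)


class Scenario(BaseModel):
    """One fortification policy to optimize: a cap and an allow-list."""

    name: str
    cap_ug_per_10mj: float = Field(gt=0)
    allowed_groups: list[str] = Field(min_length=1)
    objective_mode: str = "sum_overshoot"

    @model_validator(mode="after")
    def _mode(self) -> "Scenario":
        if self.objective_mode not in ("sum_overshoot", "max_overshoot"):
            raise ValueError("objective_mode must be sum_overshoot or max_overshoot")
        return self


@dataclass
class LPModel:
    """Assembled program: data matrices plus the pinned variable order."""

    scenario: Scenario
    group_ids: list[str]          # decision-variable order (pinned)
    stratum_ids: list[str]        # constraint-row order (pinned)
    energy_mj: np.ndarray         # E_{s,g}, shape (n_strata, n_groups)
    background_ug: np.ndarray     # B_s, shape (n_strata,)
    ri_ug: np.ndarray             # RI_s, shape (n_strata,)

    @property
    def contribution(self) -> np.ndarray:
        """µg/day delivered in stratum s per µg/10 MJ in group g: E_{s,g}/10."""
        return self.energy_mj / 10.0

    def modelled_intake(self, levels: np.ndarray) -> np.ndarray:
        """T_s = B_s + Σ_g f_g E_{s,g}/10 for a level vector in group order."""
        return self.background_ug + self.contribution @ np.asarray(levels, dtype=float)


@dataclass
class FortificationScheme:
    """Solved levels for one scenario, µg/10 MJ per group.

    ``levels_ug_per_10mj`` holds the continuous optimum (authoritative);
    ``levels_rounded`` the nearest-integer report form.  Per-100 g levels
    are attached later by the conversion step.
    """

    scenario: str
    feasible: bool
    levels_ug_per_10mj: dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    modelled_intake_ug: dict[str, float] = field(default_factory=dict)
    levels_ug_per_100g: dict[str, float] = field(default_factory=dict)
    solver_status: str = ""

    @property
    def levels_rounded(self) -> dict[str, int]:
        return {g: int(round(v)) for g, v in self.levels_ug_per_10mj.items()}

    def nonzero_groups(self, tol: float = 1e-6) -> list[str]:
        return [g for g, v in self.levels_ug_per_10mj.items() if v > tol]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.levels_ug_per_10mj):
            rows.append({
                "group_id": g,
                "level_ug_per_10mj": self.levels_ug_per_10mj[g],
                "level_ug_per_10mj_rounded": self.levels_rounded[g],
                "level_ug_per_100g": round(self.levels_ug_per_100g[g], 3) if g in self.levels_ug_per_100g else np.nan,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "feasible": self.feasible,
            "objective_value": self.objective_value,
            "levels_ug_per_10mj": self.levels_ug_per_10mj,
            "levels_ug_per_10mj_rounded": self.levels_rounded,
            "levels_ug_per_100g": self.levels_ug_per_100g,
            "modelled_intake_ug": self.modelled_intake_ug,
            "solver_status": self.solver_status,
        }


def build_lp(
    aggregates: StratumAggregates,
    scenario: Scenario,
    targets: TargetSpec,
) -> LPModel:
    """Assemble the program for one scenario.

    Groups in the scenario's allow-list become decision variables, in
    sorted order; disallowed groups simply get no variable (equivalent to
    fixing them at zero).  One attainment row per stratum in ``targets``.
    """
    stratum_ids = [s for s in aggregates.stratum_ids if s in targets.targets]
    missing = set(targets.targets) - set(aggregates.stratum_ids)
    if missing:
        raise ValueError(f"targets reference strata absent from aggregates: {sorted(missing)}")
    group_ids = sorted(scenario.allowed_groups)
    unknown = set(group_ids) - set(aggregates.group_ids)
    if unknown:
        raise ValueError(f"allowed_groups not in aggregates: {sorted(unknown)}")
    energy = aggregates.group_energy_matrix(group_ids, stratum_ids)
    dead = [g for j, g in enumerate(group_ids) if np.all(energy[:, j] == 0)]
    if dead:
        warnings.warn(
            f"allowed group(s) with zero median energy in every stratum (no effect): {dead}",
            stacklevel=2,
        )
    return LPModel(
        scenario=scenario,
        group_ids=group_ids,
        stratum_ids=stratum_ids,
        energy_mj=energy,
        background_ug=aggregates.background(stratum_ids),
        ri_ug=targets.ri(stratum_ids),
    )


def solve_scheme(model: LPModel) -> FortificationScheme:
    """Solve one assembled program with HiGHS.

    Infeasible programs return ``feasible=False`` with no levels; genuine
    solver failures raise with the solver status attached.
    """
    n_g = len(model.group_ids)
    n_s = len(model.stratum_ids)
    A = model.contribution  # (n_s, n_g)
    rhs = model.ri_ug - model.background_ug  # required added µg/day per stratum
    C = model.scenario.cap_ug_per_10mj

    if model.scenario.objective_mode == "sum_overshoot":
        # variables: [f_1..f_G, d_1..d_S]
        c = np.concatenate([np.zeros(n_g), np.ones(n_s)])
        aux = n_s
        # d_s >= A f - rhs  <=>  A f - d_s <= rhs
        A_over = np.hstack([A, -np.eye(n_s)])
        b_over = rhs
    else:  # max_overshoot: single auxiliary t >= every overshoot
        c = np.concatenate([np.zeros(n_g), np.ones(1)])
        aux = 1
        A_over = np.hstack([A, -np.ones((n_s, 1))])
        b_over = rhs
    # attainment: A f >= rhs  <=>  -A f <= -rhs
    A_att = np.hstack([-A, np.zeros((n_s, aux))])
    A_ub = np.vstack([A_att, A_over])
    b_ub = np.concatenate([-rhs, b_over])
    bounds = [(0.0, C)] * n_g + [(0.0, None)] * aux

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 2:  # infeasible
        return FortificationScheme(scenario=model.scenario.name, feasible=False, solver_status=res.message)
    if not res.success:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")

    levels = np.clip(res.x[:n_g], 0.0, C)
    intake = model.modelled_intake(levels)
    return FortificationScheme(
        scenario=model.scenario.name,
        feasible=True,
        levels_ug_per_10mj=dict(zip(model.group_ids, levels.tolist())),
        objective_value=float(res.fun),
        modelled_intake_ug=dict(zip(model.stratum_ids, intake.tolist())),
        solver_status=res.message,
    )


def find_min_cap(
    aggregates: StratumAggregates,
    allowed_groups: Sequence[str],
    targets: TargetSpec,
    start: int = 10,
    step: int = 1,
    cap_max: int = 100,
    objective_mode: str = "sum_overshoot",
    bisect: bool = False,
) -> tuple[int, FortificationScheme]:
    """Smallest cap in {start, start+step, …, cap_max} giving a feasible
    program, found by sweeping the cap upward from ``start``.

    ``bisect=True`` exploits feasibility monotonicity for a log-number of
    solves; the default linear sweep mirrors the procedural definition.
    """
    if start < 1:
        raise ValueError("start must be >= 1")

    def attempt(cap: float) -> FortificationScheme:
        scenario = Scenario(
            name=f"mincap@{cap:g}", cap_ug_per_10mj=cap,
            allowed_groups=list(allowed_groups), objective_mode=objective_mode,
        )
        return solve_scheme(build_lp(aggregates, scenario, targets))

    caps = list(range(start, cap_max + 1, step))
    if bisect:
        lo, hi = 0, len(caps) - 1
        if not attempt(caps[hi]).feasible:
            _raise_infeasible(aggregates, allowed_groups, targets, cap_max)
        best = attempt(caps[hi])
        while lo < hi:
            mid = (lo + hi) // 2
            scheme = attempt(caps[mid])
            if scheme.feasible:
                hi, best = mid, scheme
            else:
                lo = mid + 1
        return caps[hi], best

    for cap in caps:
        scheme = attempt(cap)
        if scheme.feasible:
            return cap, scheme
    _raise_infeasible(aggregates, allowed_groups, targets, cap_max)


def _raise_infeasible(aggregates, allowed_groups, targets, cap_max) -> None:
    sids = [s for s in aggregates.stratum_ids if s in targets.targets]
    E = aggregates.group_energy_matrix(sorted(allowed_groups), sids)
    best = aggregates.background(sids) + cap_max * E.sum(axis=1) / 10.0
    gap = targets.ri(sids) - best
    worst = sids[int(np.argmax(gap))]
    raise InfeasibleError(
        f"no feasible scheme up to cap {cap_max} µg/10 MJ; most-violated stratum "
        f"{worst!r} falls {gap.max():.3g} µg/day short of RI even at the cap"
    )


def brute_force_scheme_oracle(
    aggregates: StratumAggregates,
    scenario: Scenario,
    targets: TargetSpec,
    grid_step: float = 0.01,
) -> FortificationScheme:
    """Exhaustive grid search over f_g ∈ {0, grid_step, …, C}.

    Independent check of the LP on tiny instances; refuses more than three
    groups (the grid is combinatorial).
    """
    if len(scenario.allowed_groups) > 3:
        raise ValueError("grid oracle limited to <= 3 groups")
    model = build_lp(aggregates, scenario, targets)
    C = scenario.cap_ug_per_10mj
    axis = np.arange(0.0, C + grid_step / 2, grid_step)
    grids = np.meshgrid(*([axis] * len(model.group_ids)), indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)  # (n_points, n_groups)
    best_obj, best_levels = np.inf, None
    A = model.contribution
    chunk = 1_000_000
    for lo in range(0, len(combos), chunk):
        block = combos[lo:lo + chunk]
        over = block @ A.T + (model.background_ug - model.ri_ug)  # T_s - RI_s
        feasible = np.all(over >= -ATTAINMENT_TOL, axis=1)
        if not feasible.any():
            continue
        obj = over.sum(axis=1) if scenario.objective_mode == "sum_overshoot" else over.max(axis=1)
        obj = np.where(feasible, obj, np.inf)
        i = int(np.argmin(obj))
        if obj[i] < best_obj - 1e-12:
            best_obj, best_levels = float(obj[i]), block[i]
    if best_levels is None:
        return FortificationScheme(scenario=scenario.name, feasible=False, solver_status="grid: infeasible")
    intake = model.modelled_intake(best_levels)
    return FortificationScheme(
        scenario=scenario.name,
        feasible=True,
        levels_ug_per_10mj=dict(zip(model.group_ids, best_levels.tolist())),
        objective_value=best_obj,
        modelled_intake_ug=dict(zip(model.stratum_ids, intake.tolist())),
        solver_status="grid",
    )
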