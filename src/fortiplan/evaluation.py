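"""Scheme verification against the full individual-level survey.

The LP sees only stratum medians; whether a scheme actually lifts the
population is checked here by recomputing every individual's nutrient
intake on the fortified food-composition table and summarizing each
stratum's distribution:

* median, P5 and P95 (linear interpolation between closest ranks);
* a notch — the 95% confidence interval of the median,
  median ± 1.57·IQR/√n, the standard notched-boxplot rule;
* ``target_reached``: median ≥ RI_s;
* ``ul_exceeded``: P95 > UL_s (the upper-level screen is against the
  95th percentile, not the maximum).

:func:`scenario_comparison_table` assembles the long-format
background-vs-scenarios table and per-stratum boxplot statistics
(quartiles, 1.5·IQR whiskers, notches) for external plotting.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .optimizer import TargetSpec
from .survey_data import (
    StratumDef,
    assign_strata,
    compute_person_group_totals,
    person_totals,
)

__all__ = [
    "percentile",
    "notch_ci",
    "boxplot_stats",
    "summarize_intakes",
    "evaluate_scenario",
    "scenario_comparison_table",
]


def percentile(values, p: float) -> float:
    """p-th percentile by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty input")
    if not 0 <= p <= 100:
        raise ValueError("p must be in [0, 100]")
    return float(np.percentile(arr, p, method="linear"))


def notch_ci(values) -> tuple[float, float]:
    """95% CI of the median: median ± 1.57·IQR/√n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("notch of empty input")
    med = float(np.median(arr))
    iqr = percentile(arr, 75) - percentile(arr, 25)
    half = 1.57 * iqr / np.sqrt(arr.size)
    return med - half, med + half


def boxplot_stats(values) -> dict[str, float]:
    """Plot-ready summary: quartiles, 1.5·IQR whiskers clipped to the data,
    and the median notch."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = (percentile(arr, p) for p in (25, 50, 75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    notch_low, notch_high = notch_ci(arr)
    return {
        "q1": q1, "median": med, "q3": q3,
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "notch_low": notch_low, "notch_high": notch_high,
        "n": int(arr.size),
    }


def summarize_intakes(
    nutrient_ug: pd.Series,
    persons: pd.DataFrame,
    strata: Sequence[StratumDef],
    targets: TargetSpec | None = None,
) -> pd.DataFrame:
    """Per-stratum distribution summary of a person-indexed intake series.

    ``nutrient_ug`` must be indexed by person_id (µg/day).  Returns one row
    per stratum with n, median, P5, P95, the notch, and — when targets are
    given — the RI/UL flags.
    """
    membership = assign_strata(persons, strata)
    rows = []
    for stratum in strata:
        pids = membership.index[membership == stratum.stratum_id]
        vals = nutrient_ug.reindex(pids)
        if vals.empty or vals.isna().any():
            raise ValueError(f"stratum {stratum.stratum_id!r} empty or missing intakes")
        arr = vals.to_numpy()
        notch_low, notch_high = notch_ci(arr)
        row = {
            "stratum_id": stratum.stratum_id,
            "n": int(arr.size),
            "median_ug": percentile(arr, 50),
            "p5_ug": percentile(arr, 5),
            "p95_ug": percentile(arr, 95),
            "notch_low": notch_low,
            "notch_high": notch_high,
        }
        if targets is not None and stratum.stratum_id in targets.targets:
            t = targets.targets[stratum.stratum_id]
            row["target_reached"] = bool(row["median_ug"] >= t.ri_ug_per_day)
            row["ul_exceeded"] = bool(row["p95_ug"] > t.ul_ug_per_day)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_scenario(
    records: pd.DataFrame,
    persons: pd.DataFrame,
    fortified_items: pd.DataFrame,
    strata: Sequence[StratumDef],
    targets: TargetSpec | None = None,
) -> pd.DataFrame:
    """Full individual-level verification of a fortified food table.

    Recomputes each person's nutrient total on the fortified table and
    summarizes per stratum.  Evaluating the *unfortified* table yields the
    background column of the comparison.
    """
    totals = person_totals(compute_person_group_totals(records, fortified_items, persons))
    series = totals.set_index("person_id")["nutrient_ug"]
    return summarize_intakes(series, persons, strata, targets)


def scenario_comparison_table(
    background: pd.DataFrame,
    scenarios: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Long-format comparison: one row per (stratum, scenario), background
    included as scenario "background", with a formatted "median (P5, P95)"
    column.  Column and row order are deterministic: strata in background
    order, scenarios background-first then insertion order.
    """
    base = set(background["stratum_id"])
    for name, summ in scenarios.items():
        if set(summ["stratum_id"]) != base:
            raise ValueError(f"scenario {name!r} summarizes different strata than background")
    frames = []
    for name, summ in [("background", background), *scenarios.items()]:
        f = summ.copy()
        f.insert(0, "scenario", name)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    order = {s: i for i, s in enumerate(background["stratum_id"])}
    out = out.sort_values(["stratum_id", "scenario"],
                          key=lambda c: c.map(order) if c.name == "stratum_id" else c.map(
                              {n: i for i, n in enumerate(["background", *scenarios])})
                          ).reset_index(drop=True)
    out["median_p5_p95"] = out.apply(
        lambda r: f"{r['median_ug']:.1f} ({r['p5_ug']:.1f}, {r['p95_ug']:.1f})", axis=1
    )
    return out
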