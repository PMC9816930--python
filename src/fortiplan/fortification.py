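"""Unit conversion of fortification levels and food-table rewriting.

Fortification levels are optimized per 10 MJ of a food group's energy but
must be implemented per 100 g of food.  The bridge is the group's
population-level energy density

    ρ_g = (total population energy from group g, MJ)
          ÷ (total population grams of group g)        [MJ/g]

so 100 g of "average" group-g food carries 100·ρ_g MJ and the conversion
factor is

    k_g = 10 · ρ_g      [µg/100 g per µg/10 MJ],
    level_µg_per_100g = f_g · k_g.

A group-average conversion deliberately trades exactness for schemes that
are simple to implement: within a group, items denser in energy than the
average end up under-fortified relative to the per-10 MJ level and vice
versa.  The exact alternative — converting per food item with its own
energy density — is available as ``mode="per_item"``.

:func:`fortify_food_table` then emits a new food-composition table in
which every item of a fortified group gains the group's per-100 g level
(100% of items in a group are fortified; partial market penetration is
not modelled).
"""

from __future__ import annotations

from typing import Mapping

import warnings

import numpy as np
import pandas as pd

from .optimizer import FortificationScheme
from .survey_data import _KJ_PER_100G_TO_MJ_PER_G

__all__ = ["group_energy_density", "convert_scheme", "fortify_food_table"]


def group_energy_density(records: pd.DataFrame, items: pd.DataFrame) -> pd.DataFrame:
    """Population-level energy density ρ_g and conversion factor k_g per group.

    Sums run over every intake record of every person (both sexes, all
    ages).  Groups with zero recorded grams get ρ_g = 0 and a warning —
    they cannot carry fortificant.

    Returns a DataFrame ``group_id, rho_mj_per_g, k_ug_per_100g_per_10mj``.
    """
    merged = records.merge(
        items[["food_code", "group_id", "energy_kj_per_100g"]], on="food_code", how="left"
    )
    merged["energy_mj"] = merged["grams_per_day"] * merged["energy_kj_per_100g"] * _KJ_PER_100G_TO_MJ_PER_G
    sums = merged.groupby("group_id", sort=True).agg(
        grams=("grams_per_day", "sum"), energy_mj=("energy_mj", "sum")
    )
    # groups present in the food table but never consumed still get a row
    sums = sums.reindex(sorted(items["group_id"].unique()), fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(sums["grams"] > 0, sums["energy_mj"] / sums["grams"], 0.0)
    zero = sums.index[sums["grams"] == 0].tolist()
    if zero:
        warnings.warn(f"group(s) with no recorded intake get rho=0: {zero}", stacklevel=2)
    return pd.DataFrame({
        "group_id": sums.index,
        "rho_mj_per_g": rho,
        "k_ug_per_100g_per_10mj": 10.0 * rho,
    }).reset_index(drop=True)


def convert_scheme(scheme: FortificationScheme, density: pd.DataFrame) -> FortificationScheme:
    """Attach per-100 g levels: level_µg/100g = f_g · k_g.

    Full precision is stored on the scheme; ``to_frame`` reports 3-decimal
    rounding alongside.  A fortified group with k_g = 0 cannot carry the
    fortificant and is a hard error.
    """
    k = density.set_index("group_id")["k_ug_per_100g_per_10mj"]
    missing = [g for g in scheme.levels_ug_per_10mj if g not in k.index]
    if missing:
        raise ValueError(f"no energy density for group(s): {missing}")
    per100g = {}
    for g, f in scheme.levels_ug_per_10mj.items():
        if f > 0 and k[g] == 0:
            raise ValueError(f"group {g!r} has zero energy density and cannot carry fortificant")
        per100g[g] = f * float(k[g])
    scheme.levels_ug_per_100g = per100g
    return scheme


def fortify_food_table(
    items: pd.DataFrame,
    scheme: FortificationScheme,
    mode: str = "per_group",
) -> pd.DataFrame:
    """New food-composition table with the scheme's fortificant added.

    ``per_group`` (default): every item in a fortified group gains the
    group's per-100 g level — requires :func:`convert_scheme` first.
    ``per_item``: each item gains f_g scaled by its *own* energy density
    (exact per-10 MJ dosing, at the cost of item-specific levels).

    Items in unfortified groups are returned bit-identical.
    """
    out = items.copy()
    if mode == "per_group":
        if not scheme.levels_ug_per_100g and any(v > 0 for v in scheme.levels_ug_per_10mj.values()):
            raise ValueError("scheme has no per-100 g levels; run convert_scheme first")
        add = out["group_id"].map(scheme.levels_ug_per_100g).fillna(0.0)
    elif mode == "per_item":
        f = out["group_id"].map(scheme.levels_ug_per_10mj).fillna(0.0)
        # item's own k: 10 MJ/g-energy-density → µg/100 g per µg/10 MJ
        k_item = 10.0 * out["energy_kj_per_100g"] * _KJ_PER_100G_TO_MJ_PER_G
        add = f * k_item
    else:
        raise ValueError("mode must be per_group or per_item")
    if (add < 0).any():
        raise ValueError("negative fortification increment")
    out["nutrient_ug_per_100g"] = out["nutrient_ug_per_100g"] + add
    return out
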