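"""Reading, validation and stratified aggregation of dietary-survey inputs.

The planner consumes three tables, all CSV with a header row, UTF-8, "."
decimal separator:

* a food-composition table: one row per food item with an energy density
  (kJ/100 g), a nutrient density (µg/100 g) and a food-group assignment;
* a person roster: ``person_id, sex, age_years``;
* intake records: ``person_id, food_code, grams_per_day`` — mean daily
  intake in grams over the recording period (multi-day records are assumed
  pre-averaged to grams/day).

From these, :func:`compute_person_group_totals` derives each individual's
per-food-group intake of mass (g/day), energy (MJ/day) and nutrient
(µg/day), and :func:`aggregate_strata` reduces those to the per-stratum
medians the optimizer consumes: group energy E_{s,g}, group grams, group
nutrient, total energy and the background (unfortified) nutrient intake
B_s.  Medians are taken over *all* persons in a stratum — non-consumers of
a group count as zeros — and even-sized samples use the mean of the two
central order statistics.  No misreporter screening is applied: the
median-based design is deliberately robust to intake under- and
over-reporting, so energy-plausibility filtering is not part of the model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "FOOD_TABLE_COLUMNS",
    "GROUP_COLUMNS",
    "PERSON_COLUMNS",
    "RECORD_COLUMNS",
    "StratumDef",
    "StratumAggregates",
    "read_food_table",
    "read_groups",
    "read_persons",
    "read_intake_records",
    "validate_food_table",
    "validate_persons",
    "validate_records",
    "compute_person_group_totals",
    "person_totals",
    "assign_strata",
    "aggregate_strata",
    "default_strata",
]

FOOD_TABLE_COLUMNS = ["food_code", "name", "group_id", "energy_kj_per_100g", "nutrient_ug_per_100g"]
GROUP_COLUMNS = ["group_id", "name", "fortifiable"]
PERSON_COLUMNS = ["person_id", "sex", "age_years"]
RECORD_COLUMNS = ["person_id", "food_code", "grams_per_day"]

#: kJ → MJ and per-100 g → per-g combined: grams × kJ/100 g → MJ/day.
_KJ_PER_100G_TO_MJ_PER_G = 1.0 / 100.0 / 1000.0


class SurveyValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class StratumDef(BaseModel):
    """A sex × age-band population subgroup.

    The LP carries one target-attainment constraint per stratum.  A set of
    strata used together must partition the survey: every person maps to
    exactly one stratum.
    """

    stratum_id: str
    sexes: tuple[str, ...]
    age_min: int
    age_max: int

    @model_validator(mode="after")
    def _check(self) -> "StratumDef":
        if not self.sexes or any(s not in ("M", "F") for s in self.sexes):
            raise ValueError(f"stratum {self.stratum_id!r}: sexes must be a non-empty subset of M/F")
        if self.age_min > self.age_max:
            raise ValueError(f"stratum {self.stratum_id!r}: age_min > age_max")
        return self

    def contains(self, sex: str, age_years: int) -> bool:
        return sex in self.sexes and self.age_min <= age_years <= self.age_max


#: Age bands of the default analysis partition.
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (4, 6), (7, 10), (11, 14), (15, 17), (18, 50), (51, 75),
)

#: Coarser four-band partition used for comparison tables.
REPORTING_AGE_BANDS: tuple[tuple[int, int], ...] = ((4, 10), (11, 17), (18, 69), (70, 75))


def default_strata(
    age_bands: Sequence[tuple[int, int]] = DEFAULT_AGE_BANDS,
    by_sex: bool = True,
) -> list[StratumDef]:
    """Sex × age-band strata over the survey age range (default 4–75)."""
    strata = []
    for lo, hi in age_bands:
        if by_sex:
            for sex in ("M", "F"):
                strata.append(StratumDef(stratum_id=f"{sex}_{lo}-{hi}", sexes=(sex,), age_min=lo, age_max=hi))
        else:
            strata.append(StratumDef(stratum_id=f"MF_{lo}-{hi}", sexes=("M", "F"), age_min=lo, age_max=hi))
    return strata


# ---------------------------------------------------------------------------
# Readers and validators
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in columns if not c.endswith(("_100g", "_day", "years"))})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{path}: missing columns {missing}")
    return df[columns].copy()


def validate_food_table(items: pd.DataFrame, groups: pd.DataFrame | None = None) -> None:
    dup = items["food_code"][items["food_code"].duplicated()]
    if not dup.empty:
        raise SurveyValidationError(f"duplicate food_code(s): {sorted(dup.unique())}")
    for col in ("energy_kj_per_100g", "nutrient_ug_per_100g"):
        vals = pd.to_numeric(items[col], errors="coerce")
        bad = items.index[~np.isfinite(vals) | (vals < 0)]
        if len(bad):
            raise SurveyValidationError(
                f"non-finite or negative {col} at row(s) {list(bad + 2)} (1-based, incl. header)"
            )
    if groups is not None:
        if groups.empty:
            raise SurveyValidationError("groups table is empty")
        if groups["group_id"].duplicated().any():
            raise SurveyValidationError("duplicate group_id in groups table")
        unknown = set(items["group_id"]) - set(groups["group_id"])
        if unknown:
            raise SurveyValidationError(f"items reference unknown group_id(s): {sorted(unknown)}")


def read_food_table(path: str | Path, groups_path: str | Path | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the food-composition table; the group set is read from a
    companion groups file or inferred from the items.

    Returns ``(items, groups)`` DataFrames.
    """
    items = _read_csv(path, FOOD_TABLE_COLUMNS)
    items["energy_kj_per_100g"] = items["energy_kj_per_100g"].astype(float)
    items["nutrient_ug_per_100g"] = items["nutrient_ug_per_100g"].astype(float)
    if groups_path is not None:
        groups = read_groups(groups_path)
    else:
        gids = items["group_id"].drop_duplicates().tolist()
        groups = pd.DataFrame({"group_id": gids, "name": gids, "fortifiable": True})
    validate_food_table(items, groups)
    return items, groups


def read_groups(path: str | Path) -> pd.DataFrame:
    groups = _read_csv(path, GROUP_COLUMNS)
    groups["fortifiable"] = groups["fortifiable"].astype(str).str.lower().isin(("true", "1", "yes"))
    return groups


def validate_persons(persons: pd.DataFrame, age_range: tuple[int, int] = (4, 75)) -> None:
    if persons["person_id"].duplicated().any():
        raise SurveyValidationError("duplicate person_id in roster")
    if not persons["sex"].isin(["M", "F"]).all():
        bad = sorted(set(persons["sex"]) - {"M", "F"})
        raise SurveyValidationError(f"sex must be M or F, got {bad}")
    ages = persons["age_years"]
    if ((ages < age_range[0]) | (ages > age_range[1])).any():
        raise SurveyValidationError(f"age_years outside survey range {age_range}")


def read_persons(path: str | Path, age_range: tuple[int, int] = (4, 75)) -> pd.DataFrame:
    persons = _read_csv(path, PERSON_COLUMNS)
    persons["age_years"] = persons["age_years"].astype(int)
    validate_persons(persons, age_range)
    return persons


def validate_records(
    records: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    items: pd.DataFrame | None = None,
) -> None:
    g = pd.to_numeric(records["grams_per_day"], errors="coerce")
    if (~np.isfinite(g) | (g < 0)).any():
        raise SurveyValidationError("grams_per_day must be finite and >= 0")
    if persons is not None:
        unknown = set(records["person_id"]) - set(persons["person_id"])
        if unknown:
            raise SurveyValidationError(f"records reference unknown person_id(s): {sorted(unknown)[:10]}")
    if items is not None:
        unknown = set(records["food_code"]) - set(items["food_code"])
        if unknown:
            raise SurveyValidationError(f"records reference unknown food_code(s): {sorted(unknown)[:10]}")


def read_intake_records(
    path: str | Path,
    persons: pd.DataFrame | None = None,
    items: pd.DataFrame | None = None,
) -> pd.DataFrame:
    records = _read_csv(path, RECORD_COLUMNS)
    records["grams_per_day"] = records["grams_per_day"].astype(float)
    validate_records(records, persons, items)
    return records


# ---------------------------------------------------------------------------
# Per-person totals and stratified medians
# ---------------------------------------------------------------------------

def compute_person_group_totals(
    records: pd.DataFrame, items: pd.DataFrame, persons: pd.DataFrame
) -> pd.DataFrame:
    """Per-person, per-food-group intake totals.

    Returns a long DataFrame with one row for every (person, group) pair —
    persons with no record in a group get explicit zeros — and columns
    ``grams`` (g/day), ``energy_mj`` (MJ/day) and ``nutrient_ug`` (µg/day):

    * grams     = Σ grams_per_day over the group's items
    * energy_mj = Σ grams × energy_kj_per_100g / 100 / 1000
    * nutrient  = Σ grams × nutrient_ug_per_100g / 100
    """
    validate_records(records, persons, items)
    merged = records.merge(
        items[["food_code", "group_id", "energy_kj_per_100g", "nutrient_ug_per_100g"]],
        on="food_code", how="left",
    )
    merged["energy_mj"] = merged["grams_per_day"] * merged["energy_kj_per_100g"] * _KJ_PER_100G_TO_MJ_PER_G
    merged["nutrient_ug"] = merged["grams_per_day"] * merged["nutrient_ug_per_100g"] / 100.0
    agg = (
        merged.groupby(["person_id", "group_id"], sort=True)
        .agg(grams=("grams_per_day", "sum"), energy_mj=("energy_mj", "sum"), nutrient_ug=("nutrient_ug", "sum"))
    )
    # Dense (person × group) grid so non-consumers appear as explicit zeros.
    full = pd.MultiIndex.from_product(
        [sorted(persons["person_id"]), sorted(items["group_id"].unique())],
        names=["person_id", "group_id"],
    )
    return agg.reindex(full, fill_value=0.0).reset_index()


def person_totals(group_totals: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-group totals to one row per person (sum over groups)."""
    return (
        group_totals.groupby("person_id", sort=True)[["grams", "energy_mj", "nutrient_ug"]]
        .sum()
        .reset_index()
    )


def assign_strata(persons: pd.DataFrame, strata: Sequence[StratumDef]) -> pd.Series:
    """Map each person to the unique stratum containing them.

    Raises if any person matches zero or more than one stratum (the strata
    must partition the roster).
    """
    out = pd.Series(pd.NA, index=persons.index, dtype="object")
    for stratum in strata:
        mask = persons["sex"].isin(stratum.sexes) & persons["age_years"].between(
            stratum.age_min, stratum.age_max
        )
        clash = mask & out.notna()
        if clash.any():
            pid = persons.loc[clash, "person_id"].iloc[0]
            raise SurveyValidationError(
                f"person {pid!r} matches multiple strata (incl. {stratum.stratum_id!r})"
            )
        out[mask] = stratum.stratum_id
    if out.isna().any():
        pid = persons.loc[out.isna(), "person_id"].iloc[0]
        raise SurveyValidationError(f"person {pid!r} matches no stratum")
    out.index = persons["person_id"].values
    out.name = "stratum_id"
    return out


class StratumAggregates:
    """Per-stratum medians: everything the LP needs about the survey.

    ``strata``: one row per stratum — ``stratum_id, n_persons,
    median_total_energy_mj, median_background_nutrient_ug`` (B_s).

    ``groups``: one row per (stratum, group) — ``median_group_energy_mj``
    (E_{s,g}), ``median_group_grams``, ``median_group_nutrient_ug``.
    """

    STRATUM_COLS = ["stratum_id", "n_persons", "median_total_energy_mj", "median_background_nutrient_ug"]
    GROUP_COLS = ["stratum_id", "group_id", "median_group_energy_mj", "median_group_grams", "median_group_nutrient_ug"]

    def __init__(self, strata: pd.DataFrame, groups: pd.DataFrame):
        self.strata = strata.reset_index(drop=True)
        self.groups = groups.reset_index(drop=True)

    @property
    def stratum_ids(self) -> list[str]:
        return self.strata["stratum_id"].tolist()

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups["group_id"].unique())

    def group_energy_matrix(self, group_ids: Sequence[str], stratum_ids: Sequence[str] | None = None) -> np.ndarray:
        """E_{s,g} as an (n_strata × n_groups) array (MJ/day medians)."""
        sids = list(stratum_ids) if stratum_ids is not None else self.stratum_ids
        wide = self.groups.pivot(index="stratum_id", columns="group_id", values="median_group_energy_mj")
        return wide.reindex(index=sids, columns=list(group_ids)).to_numpy(dtype=float)

    def background(self, stratum_ids: Sequence[str] | None = None) -> np.ndarray:
        sids = list(stratum_ids) if stratum_ids is not None else self.stratum_ids
        s = self.strata.set_index("stratum_id")["median_background_nutrient_ug"]
        return s.reindex(sids).to_numpy(dtype=float)

    # -- CSV round trip (single long file; stratum-level values repeated) ----

    def to_csv(self, path: str | Path) -> None:
        long = self.groups.merge(self.strata, on="stratum_id")
        cols = self.STRATUM_COLS + self.GROUP_COLS[1:]
        long[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StratumAggregates":
        long = pd.read_csv(path, dtype={"stratum_id": str, "group_id": str})
        missing = [c for c in cls.STRATUM_COLS + cls.GROUP_COLS[1:] if c not in long.columns]
        if missing:
            raise SurveyValidationError(f"{path}: aggregates CSV missing columns {missing}")
        strata = long[cls.STRATUM_COLS].drop_duplicates("stratum_id")
        return cls(strata, long[cls.GROUP_COLS])


def _median(values: np.ndarray) -> float:
    # np.median already implements the mean-of-central-pair convention for
    # even n; routed through one place so the convention is pinned.
    return float(np.median(values))


def aggregate_strata(
    group_totals: pd.DataFrame,
    persons: pd.DataFrame,
    strata: Sequence[StratumDef],
) -> StratumAggregates:
    """Reduce person-level group totals to per-stratum medians.

    Medians are order statistics over the stratum's *persons* (zeros for
    non-consumers included), never over pooled records.  The background
    nutrient median B_s is the median of per-person total nutrient intake
    on the unfortified diet.
    """
    membership = assign_strata(persons, strata)
    totals = person_totals(group_totals)
    totals["stratum_id"] = totals["person_id"].map(membership)
    gt = group_totals.copy()
    gt["stratum_id"] = gt["person_id"].map(membership)

    stratum_rows = []
    for stratum in strata:
        sub = totals[totals["stratum_id"] == stratum.stratum_id]
        if sub.empty:
            raise SurveyValidationError(f"stratum {stratum.stratum_id!r} contains no persons")
        stratum_rows.append({
            "stratum_id": stratum.stratum_id,
            "n_persons": len(sub),
            "median_total_energy_mj": _median(sub["energy_mj"].to_numpy()),
            "median_background_nutrient_ug": _median(sub["nutrient_ug"].to_numpy()),
        })

    grp = (
        gt.groupby(["stratum_id", "group_id"], sort=True)
        .agg(
            median_group_energy_mj=("energy_mj", "median"),
            median_group_grams=("grams", "median"),
            median_group_nutrient_ug=("nutrient_ug", "median"),
        )
        .reset_index()
    )
    order = {s.stratum_id: i for i, s in enumerate(strata)}
    grp = grp.sort_values(["stratum_id", "group_id"], key=lambda c: c.map(order) if c.name == "stratum_id" else c)
    return StratumAggregates(pd.DataFrame(stratum_rows), grp)
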