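"""Synthetic dietary surveys with known structure.

Individual-level national dietary-survey records are typically restricted,
so every stage of the planner is exercised here on generated surveys that
emulate a 7-day-record survey of a Nordic population: ~4,000 persons aged
4–75 of both sexes, 17 food groups, right-skewed gram intakes with
non-consumers, plausible per-group energy densities and background
vitamin-D densities (fish, eggs and fats carrying most of the background).

The gram model per (person, group) is a zero-inflated log-normal: a
Bernoulli consumption gate with probability ``consumer_prob``, then
``LogNormal(meanlog + log(scale_stratum), sdlog)`` grams/day for
consumers, split across the group's items by Dirichlet weights.  The
median over *all* persons of a stratum (zeros included) has the closed
form exposed by :func:`analytic_group_median`, which the generator is
tested against.

Defaults are sized to the published survey margins (3,946 persons,
sex/age mix matching the published stratum counts) and land adult totals
near 10 MJ/day of energy and ~3 µg/day background vitamin D; child and
female strata scale down.  All randomness flows from one seed; a fixed
seed fixes the output byte-for-byte.

:func:`generate_known_answer_case` builds degenerate one-group surveys in
which every person is identical, so the LP optimum has the closed form
f* = 10·(RI − B)/E and the whole pipeline can be checked end-to-end
against a planted answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from .survey_data import StratumDef, default_strata

__all__ = [
    "GroupSpec",
    "StratumMix",
    "SurveySpec",
    "SyntheticSurvey",
    "default_survey_spec",
    "generate_survey",
    "write_survey",
    "analytic_group_median",
    "generate_known_answer_case",
]


class GroupSpec(BaseModel):
    group_id: str
    name: str
    fortifiable: bool = True
    consumer_prob: float = Field(ge=0, le=1)
    gram_median: float = Field(gt=0)      # exp(meanlog), adult-male baseline g/day
    gram_sdlog: float = Field(ge=0)
    energy_kj_per_100g: tuple[float, float]   # uniform range across items
    nutrient_ug_per_100g: tuple[float, float]
    n_items: int = 3


class StratumMix(BaseModel):
    sex: str
    age_min: int
    age_max: int
    proportion: float = Field(gt=0)
    intake_scale: float = Field(gt=0, default=1.0)  # multiplies gram medians


class SurveySpec(BaseModel):
    n_persons: int = Field(gt=0)
    mix: list[StratumMix]
    groups: list[GroupSpec] = Field(min_length=1)
    seed: int = 0

    @model_validator(mode="after")
    def _proportions(self) -> "SurveySpec":
        total = sum(m.proportion for m in self.mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix proportions must sum to 1, got {total}")
        return self


@dataclass
class SyntheticSurvey:
    persons: pd.DataFrame
    records: pd.DataFrame
    items: pd.DataFrame
    groups: pd.DataFrame
    spec: SurveySpec


# Adult-male baselines; energy densities kJ/100 g, vitamin D µg/100 g.
# Totals land near 10 MJ/day and ~3 µg/day background for adult men.
_DEFAULT_GROUPS: list[dict] = [
    dict(group_id="milk", name="Milk and milk products", consumer_prob=0.95, gram_median=250, gram_sdlog=0.9, energy_kj_per_100g=(150, 350), nutrient_ug_per_100g=(0.03, 0.10)),
    dict(group_id="cheese", name="Cheese and cheese products", consumer_prob=0.85, gram_median=30, gram_sdlog=0.8, energy_kj_per_100g=(1200, 1600), nutrient_ug_per_100g=(0.2, 0.5)),
    dict(group_id="icecream", name="Ice cream, fruit ice and other edible ices", consumer_prob=0.40, gram_median=20, gram_sdlog=0.9, energy_kj_per_100g=(700, 900), nutrient_ug_per_100g=(0.1, 0.3)),
    dict(group_id="cereals", name="Cereals and cereal products", consumer_prob=0.99, gram_median=200, gram_sdlog=0.5, energy_kj_per_100g=(900, 1500), nutrient_ug_per_100g=(0.0, 0.05)),
    dict(group_id="vegetables", name="Vegetables and vegetable products", consumer_prob=0.97, gram_median=150, gram_sdlog=0.7, energy_kj_per_100g=(100, 300), nutrient_ug_per_100g=(0.0, 0.02)),
    dict(group_id="fruit", name="Fruit and fruit products", consumer_prob=0.90, gram_median=150, gram_sdlog=0.8, energy_kj_per_100g=(150, 350), nutrient_ug_per_100g=(0.0, 0.0)),
    dict(group_id="meat", name="Meat and meat products", consumer_prob=0.95, gram_median=100, gram_sdlog=0.6, energy_kj_per_100g=(600, 1100), nutrient_ug_per_100g=(0.2, 0.7)),
    dict(group_id="fish", name="Fish and fish products", consumer_prob=0.70, gram_median=30, gram_sdlog=1.0, energy_kj_per_100g=(400, 900), nutrient_ug_per_100g=(2.0, 12.0)),
    dict(group_id="poultry", name="Poultry and poultry products", consumer_prob=0.60, gram_median=30, gram_sdlog=0.9, energy_kj_per_100g=(500, 800), nutrient_ug_per_100g=(0.1, 0.3)),
    dict(group_id="egg", name="Egg and egg products", consumer_prob=0.80, gram_median=25, gram_sdlog=0.8, energy_kj_per_100g=(550, 650), nutrient_ug_per_100g=(1.5, 2.5)),
    dict(group_id="fats", name="Fats, oils and their products", consumer_prob=0.95, gram_median=30, gram_sdlog=0.7, energy_kj_per_100g=(2500, 3300), nutrient_ug_per_100g=(0.5, 1.5)),
    dict(group_id="sugar", name="Sugar, honey and products thereof", consumer_prob=0.80, gram_median=30, gram_sdlog=0.9, energy_kj_per_100g=(1300, 1700), nutrient_ug_per_100g=(0.0, 0.0)),
    dict(group_id="beverages", name="Beverages", consumer_prob=0.95, gram_median=1500, gram_sdlog=0.6, energy_kj_per_100g=(50, 200), nutrient_ug_per_100g=(0.0, 0.0)),
    dict(group_id="spices", name="Spices and other ingredients", consumer_prob=0.90, gram_median=10, gram_sdlog=0.9, energy_kj_per_100g=(300, 1200), nutrient_ug_per_100g=(0.0, 0.1)),
    dict(group_id="other", name="Other foods", consumer_prob=0.50, gram_median=30, gram_sdlog=1.0, energy_kj_per_100g=(400, 1200), nutrient_ug_per_100g=(0.0, 0.2)),
    dict(group_id="potato", name="Potato and products thereof", consumer_prob=0.85, gram_median=100, gram_sdlog=0.8, energy_kj_per_100g=(300, 400), nutrient_ug_per_100g=(0.0, 0.0)),
    dict(group_id="juice", name="Juice", consumer_prob=0.50, gram_median=150, gram_sdlog=0.8, energy_kj_per_100g=(150, 200), nutrient_ug_per_100g=(0.0, 0.0)),
]

# Sex × six-age-band mix approximating the published stratum counts
# (n = 3,946; counts per four-band margin split across the finer bands),
# with intake scales shrinking child and female gram intakes.
_DEFAULT_MIX: list[dict] = [
    dict(sex="M", age_min=4, age_max=6, proportion=0.030, intake_scale=0.55),
    dict(sex="M", age_min=7, age_max=10, proportion=0.034, intake_scale=0.70),
    dict(sex="M", age_min=11, age_max=14, proportion=0.030, intake_scale=0.85),
    dict(sex="M", age_min=15, age_max=17, proportion=0.025, intake_scale=0.95),
    dict(sex="M", age_min=18, age_max=50, proportion=0.225, intake_scale=1.00),
    dict(sex="M", age_min=51, age_max=75, proportion=0.145, intake_scale=0.95),
    dict(sex="F", age_min=4, age_max=6, proportion=0.030, intake_scale=0.50),
    dict(sex="F", age_min=7, age_max=10, proportion=0.033, intake_scale=0.60),
    dict(sex="F", age_min=11, age_max=14, proportion=0.030, intake_scale=0.70),
    dict(sex="F", age_min=15, age_max=17, proportion=0.024, intake_scale=0.75),
    dict(sex="F", age_min=18, age_max=50, proportion=0.235, intake_scale=0.80),
    dict(sex="F", age_min=51, age_max=75, proportion=0.159, intake_scale=0.75),
]


def default_survey_spec(n_persons: int = 3946, seed: int = 0) -> SurveySpec:
    return SurveySpec(
        n_persons=n_persons,
        mix=[StratumMix(**m) for m in _DEFAULT_MIX],
        groups=[GroupSpec(**g) for g in _DEFAULT_GROUPS],
        seed=seed,
    )


def _mix_counts(spec: SurveySpec) -> list[int]:
    """Largest-remainder apportionment of n_persons over the mix cells."""
    raw = np.array([m.proportion for m in spec.mix]) * spec.n_persons
    counts = np.floor(raw).astype(int)
    remainder = spec.n_persons - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


def generate_survey(spec: SurveySpec) -> SyntheticSurvey:
    """Draw one survey from the spec.  Deterministic for a fixed seed."""
    if spec.n_persons <= 0 or not spec.groups:
        raise ValueError("degenerate spec: need persons and groups")
    rng = np.random.default_rng(spec.seed)

    # roster
    rows, scales = [], []
    counts = _mix_counts(spec)
    pid = 0
    for m, k in zip(spec.mix, counts):
        ages = rng.integers(m.age_min, m.age_max + 1, size=k)
        for a in ages:
            rows.append({"person_id": f"P{pid:05d}", "sex": m.sex, "age_years": int(a)})
            scales.append(m.intake_scale)
            pid += 1
    persons = pd.DataFrame(rows)
    scale = np.array(scales)

    # food-composition table
    item_rows, group_rows = [], []
    for g in spec.groups:
        group_rows.append({"group_id": g.group_id, "name": g.name, "fortifiable": g.fortifiable})
        energy = rng.uniform(*g.energy_kj_per_100g, size=g.n_items)
        lo, hi = g.nutrient_ug_per_100g
        nutrient = rng.uniform(lo, hi, size=g.n_items) if hi > lo else np.full(g.n_items, lo)
        for i in range(g.n_items):
            item_rows.append({
                "food_code": f"{g.group_id}_{i:02d}",
                "name": f"{g.name} item {i}",
                "group_id": g.group_id,
                "energy_kj_per_100g": round(float(energy[i]), 1),
                "nutrient_ug_per_100g": round(float(nutrient[i]), 4),
            })
    items = pd.DataFrame(item_rows)
    groups = pd.DataFrame(group_rows)

    # intake records: zero-inflated log-normal grams, Dirichlet item split
    n = len(persons)
    rec_frames = []
    for g in spec.groups:
        consumes = rng.random(n) < g.consumer_prob
        idx = np.flatnonzero(consumes)
        if idx.size == 0:
            continue
        meanlog = np.log(g.gram_median) + np.log(scale[idx])
        grams = np.exp(rng.normal(meanlog, g.gram_sdlog))
        weights = rng.dirichlet(np.ones(g.n_items), size=idx.size)
        alloc = grams[:, None] * weights  # (n_consumers, n_items)
        rec_frames.append(pd.DataFrame({
            "person_id": np.repeat(persons["person_id"].to_numpy()[idx], g.n_items),
            "food_code": np.tile([f"{g.group_id}_{i:02d}" for i in range(g.n_items)], idx.size),
            "grams_per_day": np.round(alloc.ravel(), 4),
        }))
    records = pd.concat(rec_frames, ignore_index=True)
    records = records[records["grams_per_day"] > 0].reset_index(drop=True)
    return SyntheticSurvey(persons=persons, records=records, items=items, groups=groups, spec=spec)


def write_survey(survey: SyntheticSurvey, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out / "persons.csv",
        "records": out / "records.csv",
        "food_table": out / "food_table.csv",
        "groups": out / "groups.csv",
    }
    survey.persons.to_csv(paths["persons"], index=False)
    survey.records.to_csv(paths["records"], index=False)
    survey.items.to_csv(paths["food_table"], index=False)
    survey.groups.to_csv(paths["groups"], index=False)
    return paths


def analytic_group_median(group: GroupSpec, intake_scale: float = 1.0) -> float:
    """Median gram intake over all persons (non-consumers as zeros) of a
    zero-inflated log-normal: 0 when consumer_prob ≤ 1/2, otherwise
    exp(meanlog)·exp(sdlog·Φ⁻¹(1 − 1/(2p)))."""
    p = group.consumer_prob
    if p <= 0.5:
        return 0.0
    z = norm.ppf(1.0 - 1.0 / (2.0 * p))
    return float(group.gram_median * intake_scale * np.exp(group.gram_sdlog * z))


def generate_known_answer_case(
    seed: int | None = None,
    ri_ug_per_day: float = 10.0,
    n_per_stratum: int = 20,
) -> tuple[SyntheticSurvey, dict]:
    """One-group survey with a planted closed-form LP optimum.

    Every person consumes the same single item, so all stratum medians
    coincide: E MJ/day of group energy and B µg/day of background
    nutrient.  The LP optimum for target RI is exactly

        f* = 10 · (RI − B) / E   [µg/10 MJ].

    ``seed=None`` gives the canonical case E=4 MJ, B=2 µg (f* = 20);
    an integer seed draws E ∈ U[2,6], B ∈ U[1, min(4, RI−1)].

    Returns the survey plus an ``expected`` dict with f*, the conversion
    factor k = 10·E/grams, the strata and targets used.
    """
    if seed is None:
        energy_mj, background_ug = 4.0, 2.0
    else:
        rng = np.random.default_rng(seed)
        energy_mj = float(rng.uniform(2.0, 6.0))
        background_ug = float(rng.uniform(1.0, min(4.0, ri_ug_per_day - 1.0)))

    energy_density = 1000.0  # kJ/100 g
    grams = energy_mj * 1e5 / energy_density           # grams × kJ/100g/1e5 = MJ
    nutrient_density = background_ug * 100.0 / grams   # grams × µg/100g/100 = µg

    items = pd.DataFrame([{
        "food_code": "carrier_00", "name": "carrier food", "group_id": "carrier",
        "energy_kj_per_100g": energy_density, "nutrient_ug_per_100g": nutrient_density,
    }])
    groups = pd.DataFrame([{"group_id": "carrier", "name": "carrier", "fortifiable": True}])
    strata = [
        StratumDef(stratum_id="M_4-75", sexes=("M",), age_min=4, age_max=75),
        StratumDef(stratum_id="F_4-75", sexes=("F",), age_min=4, age_max=75),
    ]
    rows = []
    for sex in ("M", "F"):
        for i in range(n_per_stratum):
            rows.append({"person_id": f"{sex}{i:03d}", "sex": sex, "age_years": 30})
    persons = pd.DataFrame(rows)
    records = pd.DataFrame({
        "person_id": persons["person_id"],
        "food_code": "carrier_00",
        "grams_per_day": grams,
    })
    spec = SurveySpec(
        n_persons=len(persons),
        mix=[StratumMix(sex="M", age_min=4, age_max=75, proportion=0.5),
             StratumMix(sex="F", age_min=4, age_max=75, proportion=0.5)],
        groups=[GroupSpec(group_id="carrier", name="carrier", consumer_prob=1.0,
                          gram_median=grams, gram_sdlog=0.0,
                          energy_kj_per_100g=(energy_density, energy_density),
                          nutrient_ug_per_100g=(nutrient_density, nutrient_density),
                          n_items=1)],
        seed=seed if seed is not None else 0,
    )
    survey = SyntheticSurvey(persons=persons, records=records, items=items, groups=groups, spec=spec)
    expected = {
        "f_star_ug_per_10mj": 10.0 * (ri_ug_per_day - background_ug) / energy_mj,
        "energy_mj": energy_mj,
        "background_ug": background_ug,
        "ri_ug_per_day": ri_ug_per_day,
        "k_ug_per_100g_per_10mj": 10.0 * energy_mj / grams,
        "strata": strata,
    }
    return survey, expected
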