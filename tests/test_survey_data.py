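"""Survey ingestion, per-person totals and stratified medians."""

import numpy as np
import pandas as pd
import pytest

import fortiplan as fp
from fortiplan.survey_data import SurveyValidationError, StratumDef
from fortiplan.synthetic import write_survey


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReaders:
    def test_valid_food_table_parses(self, tmp_path):
        p = _write(tmp_path, "ft.csv",
                   "food_code,name,group_id,energy_kj_per_100g,nutrient_ug_per_100g\n"
                   "0001,whole milk,milk,272,0.1\n0002,rye bread,cereals,950,0\n")
        items, groups = fp.read_food_table(p)
        assert len(items) == 2
        assert set(groups["group_id"]) == {"milk", "cereals"}

    def test_duplicate_food_code_names_the_code(self, tmp_path):
        p = _write(tmp_path, "ft.csv",
                   "food_code,name,group_id,energy_kj_per_100g,nutrient_ug_per_100g\n"
                   "0001,a,g,100,0\n0001,b,g,100,0\n")
        with pytest.raises(SurveyValidationError, match="0001"):
            fp.read_food_table(p)

    def test_negative_density_rejected(self, tmp_path):
        p = _write(tmp_path, "ft.csv",
                   "food_code,name,group_id,energy_kj_per_100g,nutrient_ug_per_100g\n"
                   "0001,a,g,-5,0\n")
        with pytest.raises(SurveyValidationError, match="energy_kj_per_100g"):
            fp.read_food_table(p)

    def test_negative_grams_rejected(self, tmp_path):
        p = _write(tmp_path, "r.csv", "person_id,food_code,grams_per_day\nP1,0001,-1\n")
        with pytest.raises(SurveyValidationError, match="grams_per_day"):
            fp.read_intake_records(p)

    def test_unknown_keys_listed(self, tmp_path):
        persons = pd.DataFrame({"person_id": ["P1"], "sex": ["M"], "age_years": [30]})
        p = _write(tmp_path, "r.csv", "person_id,food_code,grams_per_day\nP9,0001,10\n")
        with pytest.raises(SurveyValidationError, match="P9"):
            fp.read_intake_records(p, persons=persons)

    def test_synthetic_survey_round_trips(self, survey, tmp_path):
        """17-group generated survey loads, validates, and the food table
        survives a read→write→read cycle identically."""
        paths = write_survey(survey, tmp_path)
        items, groups = fp.read_food_table(paths["food_table"], paths["groups"])
        persons = fp.read_persons(paths["persons"])
        records = fp.read_intake_records(paths["records"], persons, items)
        assert len(persons) == len(survey.persons)
        assert len(records) == len(survey.records)
        items.to_csv(tmp_path / "ft2.csv", index=False)
        items2, _ = fp.read_food_table(tmp_path / "ft2.csv", paths["groups"])
        pd.testing.assert_frame_equal(items, items2)


class TestGroupTotals:
    def test_single_item_arithmetic(self):
        items = pd.DataFrame([{"food_code": "a", "name": "a", "group_id": "g",
                               "energy_kj_per_100g": 200.0, "nutrient_ug_per_100g": 0.5}])
        persons = pd.DataFrame([{"person_id": "P1", "sex": "M", "age_years": 30}])
        records = pd.DataFrame([{"person_id": "P1", "food_code": "a", "grams_per_day": 250.0}])
        out = fp.compute_person_group_totals(records, items, persons)
        row = out.iloc[0]
        assert row["energy_mj"] == pytest.approx(0.5)
        assert row["nutrient_ug"] == pytest.approx(1.25)

    def test_person_without_records_gets_zeros(self):
        items = pd.DataFrame([{"food_code": "a", "name": "a", "group_id": "g",
                               "energy_kj_per_100g": 200.0, "nutrient_ug_per_100g": 0.5}])
        persons = pd.DataFrame([{"person_id": "P1", "sex": "M", "age_years": 30},
                                {"person_id": "P2", "sex": "F", "age_years": 40}])
        records = pd.DataFrame([{"person_id": "P1", "food_code": "a", "grams_per_day": 100.0}])
        out = fp.compute_person_group_totals(records, items, persons)
        p2 = out[out["person_id"] == "P2"]
        assert len(p2) == 1
        assert (p2[["grams", "energy_mj", "nutrient_ug"]] == 0).all().all()

    def test_group_totals_conserve_person_totals(self, survey, totals):
        """Σ over groups of each quantity equals an independent record-level
        recomputation of the person total (1e-9 relative)."""
        summed = fp.person_totals(totals).set_index("person_id")
        merged = survey.records.merge(survey.items, on="food_code")
        direct_energy = (merged["grams_per_day"] * merged["energy_kj_per_100g"] / 1e5
                         ).groupby(merged["person_id"]).sum()
        direct_nutrient = (merged["grams_per_day"] * merged["nutrient_ug_per_100g"] / 100
                           ).groupby(merged["person_id"]).sum()
        np.testing.assert_allclose(summed["energy_mj"].reindex(direct_energy.index),
                                   direct_energy, rtol=1e-9)
        np.testing.assert_allclose(summed["nutrient_ug"].reindex(direct_nutrient.index),
                                   direct_nutrient, rtol=1e-9)


def _sort_median(values):
    """Independent order-statistic median: sort, pick middle (mean of the
    central pair for even n)."""
    v = sorted(values)
    n = len(v)
    return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2


class TestAggregation:
    def test_non_consumers_count_as_zeros(self):
        items = pd.DataFrame([{"food_code": "a", "name": "a", "group_id": "g",
                               "energy_kj_per_100g": 100.0, "nutrient_ug_per_100g": 0.0}])
        persons = pd.DataFrame({"person_id": ["P1", "P2", "P3"], "sex": "M", "age_years": 30})
        records = pd.DataFrame([
            {"person_id": "P2", "food_code": "a", "grams_per_day": 100.0},
            {"person_id": "P3", "food_code": "a", "grams_per_day": 200.0},
        ])
        strata = [StratumDef(stratum_id="all", sexes=("M", "F"), age_min=4, age_max=75)]
        totals = fp.compute_person_group_totals(records, items, persons)
        agg = fp.aggregate_strata(totals, persons, strata)
        assert agg.groups["median_group_grams"].iloc[0] == pytest.approx(100.0)

    def test_single_person_stratum_is_identity(self):
        items = pd.DataFrame([{"food_code": "a", "name": "a", "group_id": "g",
                               "energy_kj_per_100g": 400.0, "nutrient_ug_per_100g": 1.0}])
        persons = pd.DataFrame([{"person_id": "P1", "sex": "F", "age_years": 20}])
        records = pd.DataFrame([{"person_id": "P1", "food_code": "a", "grams_per_day": 500.0}])
        strata = [StratumDef(stratum_id="all", sexes=("M", "F"), age_min=4, age_max=75)]
        agg = fp.aggregate_strata(fp.compute_person_group_totals(records, items, persons),
                                  persons, strata)
        assert agg.strata["median_total_energy_mj"].iloc[0] == pytest.approx(2.0)
        assert agg.strata["median_background_nutrient_ug"].iloc[0] == pytest.approx(5.0)

    def test_every_aggregate_cell_matches_sort_based_oracle(self, survey, totals, strata, aggregates):
        membership = fp.assign_strata(survey.persons, strata)
        pt = fp.person_totals(totals).set_index("person_id")
        gt = totals.set_index("person_id")
        for stratum in strata:
            pids = membership.index[membership == stratum.stratum_id]
            row = aggregates.strata.set_index("stratum_id").loc[stratum.stratum_id]
            assert row["median_total_energy_mj"] == pytest.approx(
                _sort_median(pt.loc[pids, "energy_mj"]), rel=1e-12)
            assert row["median_background_nutrient_ug"] == pytest.approx(
                _sort_median(pt.loc[pids, "nutrient_ug"]), rel=1e-12)
        sub = aggregates.groups.set_index(["stratum_id", "group_id"])
        for gid in ["milk", "fish", "fats"]:
            for stratum in strata:
                pids = membership.index[membership == stratum.stratum_id]
                grams = gt.loc[pids].query("group_id == @gid")["grams"]
                assert sub.loc[(stratum.stratum_id, gid), "median_group_grams"] == pytest.approx(
                    _sort_median(grams), rel=1e-12)

    def test_record_order_is_irrelevant(self, survey, strata, aggregates):
        shuffled = survey.records.sample(frac=1.0, random_state=99).reset_index(drop=True)
        tot = fp.compute_person_group_totals(shuffled, survey.items, survey.persons)
        agg = fp.aggregate_strata(tot, survey.persons, strata)
        pd.testing.assert_frame_equal(agg.strata, aggregates.strata)
        pd.testing.assert_frame_equal(agg.groups.reset_index(drop=True),
                                      aggregates.groups.reset_index(drop=True))

    def test_empty_stratum_is_an_error(self):
        items = pd.DataFrame([{"food_code": "a", "name": "a", "group_id": "g",
                               "energy_kj_per_100g": 100.0, "nutrient_ug_per_100g": 0.0}])
        persons = pd.DataFrame([{"person_id": "P1", "sex": "M", "age_years": 30}])
        records = pd.DataFrame([{"person_id": "P1", "food_code": "a", "grams_per_day": 1.0}])
        strata = [StratumDef(stratum_id="kids", sexes=("M", "F"), age_min=4, age_max=17),
                  StratumDef(stratum_id="adults", sexes=("M", "F"), age_min=18, age_max=75)]
        with pytest.raises(SurveyValidationError, match="kids"):
            fp.aggregate_strata(fp.compute_person_group_totals(records, items, persons),
                                persons, strata)

    def test_aggregates_csv_round_trip(self, aggregates, tmp_path):
        p = tmp_path / "agg.csv"
        aggregates.to_csv(p)
        back = fp.StratumAggregates.from_csv(p)
        assert back.stratum_ids == aggregates.stratum_ids
        np.testing.assert_allclose(
            back.group_energy_matrix(aggregates.group_ids),
            aggregates.group_energy_matrix(aggregates.group_ids))
        np.testing.assert_allclose(back.background(), aggregates.background())
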