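import pandas as pd
import pytest

import fortiplan as fp
from fortiplan.synthetic import default_survey_spec, generate_survey


@pytest.fixture(scope="session")
def survey():
    """Default-sized synthetic survey (3,946 persons, 17 groups)."""
    return generate_survey(default_survey_spec(seed=1))


@pytest.fixture(scope="session")
def totals(survey):
    return fp.compute_person_group_totals(survey.records, survey.items, survey.persons)


@pytest.fixture(scope="session")
def strata():
    return fp.default_strata()


@pytest.fixture(scope="session")
def aggregates(totals, survey, strata):
    return fp.aggregate_strata(totals, survey.persons, strata)


@pytest.fixture(scope="session")
def targets(strata):
    return fp.default_targets(strata)


def toy_aggregates(energy, background, group_ids=None, stratum_ids=None):
    """Build StratumAggregates straight from an E_{s,g} matrix and B_s vector."""
    import numpy as np

    energy = np.atleast_2d(np.asarray(energy, dtype=float))
    n_s, n_g = energy.shape
    stratum_ids = stratum_ids or [f"s{i}" for i in range(n_s)]
    group_ids = group_ids or [f"g{j}" for j in range(n_g)]
    strata_df = pd.DataFrame({
        "stratum_id": stratum_ids,
        "n_persons": 10,
        "median_total_energy_mj": energy.sum(axis=1),
        "median_background_nutrient_ug": np.asarray(background, dtype=float),
    })
    rows = []
    for i, s in enumerate(stratum_ids):
        for j, g in enumerate(group_ids):
            rows.append({
                "stratum_id": s, "group_id": g,
                "median_group_energy_mj": energy[i, j],
                "median_group_grams": 100.0 * energy[i, j],
                "median_group_nutrient_ug": 0.0,
            })
    return fp.StratumAggregates(strata_df, pd.DataFrame(rows))


def toy_targets(stratum_ids, ri=10.0, ul=100.0):
    return fp.TargetSpec(targets={
        s: fp.StratumTarget(ri_ug_per_day=ri, ul_ug_per_day=ul) for s in stratum_ids
    })
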