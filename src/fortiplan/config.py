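"""Run configuration and the end-to-end pipeline.

A run is described by one YAML (or JSON) file: input paths, the stratum
partition, per-stratum RI/UL targets, a list of scenarios, an output
directory and a seed.  :func:`run_pipeline` executes the whole chain for
every scenario — aggregate, optimize, convert, fortify, evaluate — and
writes a scheme CSV/JSON per scenario, one comparison table, boxplot
statistics, and a manifest (config hash, seed, package and library
versions) so a run can be reproduced exactly.

Published aggregate medians can stand in for individual records: when the
config points at an ``aggregates`` CSV instead of persons/records,
``optimize`` and ``mincap`` still run (conversion and evaluation need the
individual-level files and are skipped).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .evaluation import boxplot_stats, evaluate_scenario, scenario_comparison_table, summarize_intakes
from .fortification import convert_scheme, fortify_food_table, group_energy_density
from .optimizer import (
    FortificationScheme,
    Scenario,
    StratumTarget,
    TargetSpec,
    build_lp,
    default_targets,
    find_min_cap,
    solve_scheme,
)
from .reference import ALL_GROUPS, FIVE_GROUPS, FOUR_GROUPS, SCENARIO_CAPS
from .survey_data import (
    DEFAULT_AGE_BANDS,
    REPORTING_AGE_BANDS,
    StratumAggregates,
    StratumDef,
    aggregate_strata,
    compute_person_group_totals,
    default_strata,
    person_totals,
    read_food_table,
    read_intake_records,
    read_persons,
)

__all__ = ["RunConfig", "load_config", "default_scenarios", "run_pipeline", "write_manifest"]


class RunConfig(BaseModel):
    food_table: str | None = None
    groups: str | None = None
    persons: str | None = None
    records: str | None = None
    aggregates: str | None = None
    strata: str | list[dict] = "default6"
    targets: dict[str, dict] | None = None
    ri_ug_per_day: float = 10.0
    scenarios: list[Scenario] = Field(default_factory=list)
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def stratum_defs(self) -> list[StratumDef]:
        if isinstance(self.strata, str):
            if self.strata == "default6":
                return default_strata(DEFAULT_AGE_BANDS)
            if self.strata == "default4":
                return default_strata(REPORTING_AGE_BANDS)
            if self.strata == "bysex":
                return default_strata([(4, 75)])
            raise ValueError(f"unknown strata preset {self.strata!r}")
        return [StratumDef(**d) for d in self.strata]

    def target_spec(self) -> TargetSpec:
        defs = self.stratum_defs()
        if self.targets is None:
            return default_targets(defs, ri_ug_per_day=self.ri_ug_per_day)
        return TargetSpec(targets={
            s: StratumTarget(ri_ug_per_day=v["ri"], ul_ug_per_day=v["ul"])
            for s, v in self.targets.items()
        })


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    names = [s["name"] for s in raw.get("scenarios", [])]
    if len(names) != len(set(names)):
        raise ValueError("scenario names must be unique")
    return RunConfig(**raw)


def default_scenarios(objective_mode: str = "sum_overshoot") -> list[Scenario]:
    """The eight published scenarios: caps 12–30 µg/10 MJ over the full
    group list, the five-group allow-list (with juice) or the four-group
    one (without)."""
    allow = {1: ALL_GROUPS, 2: ALL_GROUPS, 3: FIVE_GROUPS, 4: FOUR_GROUPS,
             5: FIVE_GROUPS, 6: FOUR_GROUPS, 7: FIVE_GROUPS, 8: FOUR_GROUPS}
    return [
        Scenario(name=f"scenario_{i}", cap_ug_per_10mj=SCENARIO_CAPS[i],
                 allowed_groups=list(allow[i]), objective_mode=objective_mode)
        for i in range(1, 9)
    ]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: Path, extra: dict[str, Any] | None = None) -> Path:
    import numpy, scipy  # versions recorded for reproducibility

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "fortiplan": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_scheme(scheme: FortificationScheme, stem: Path) -> None:
    scheme.to_frame().to_csv(stem.with_suffix(".csv"), index=False)
    stem.with_suffix(".json").write_text(json.dumps(scheme.to_dict(), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every configured scenario end to end.

    Returns a dict with the aggregates, per-scenario schemes and
    summaries, and the comparison table; artifacts land in
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    strata = config.stratum_defs()
    targets = config.target_spec()

    individual = config.persons is not None and config.records is not None and config.food_table is not None
    if individual:
        items, groups = read_food_table(config.food_table, config.groups)
        persons = read_persons(config.persons)
        records = read_intake_records(config.records, persons, items)
        totals = compute_person_group_totals(records, items, persons)
        aggregates = aggregate_strata(totals, persons, strata)
        density = group_energy_density(records, items)
        background = person_totals(totals).set_index("person_id")["nutrient_ug"]
        background_summary = summarize_intakes(background, persons, strata, targets)
    elif config.aggregates is not None:
        aggregates = StratumAggregates.from_csv(config.aggregates)
        density = background_summary = None
        items = persons = records = None
    else:
        raise ValueError("config needs persons+records+food_table, or an aggregates CSV")

    aggregates.to_csv(out / "aggregates.csv")
    schemes: dict[str, FortificationScheme] = {}
    summaries: dict[str, pd.DataFrame] = {}
    for scenario in config.scenarios:
        scheme = solve_scheme(build_lp(aggregates, scenario, targets))
        if scheme.feasible and individual:
            scheme = convert_scheme(scheme, density)
            fortified = fortify_food_table(items, scheme)
            fortified.to_csv(out / f"food_table_{scenario.name}.csv", index=False)
            summaries[scenario.name] = evaluate_scenario(records, persons, fortified, strata, targets)
            summaries[scenario.name].to_csv(out / f"summary_{scenario.name}.csv", index=False)
        write_scheme(scheme, out / f"scheme_{scenario.name}")
        schemes[scenario.name] = scheme

    comparison = None
    if individual and summaries:
        comparison = scenario_comparison_table(background_summary, summaries)
        comparison.to_csv(out / "comparison.csv", index=False)
        # plot-ready per-stratum boxplot statistics for each scenario
        box_rows = []
        fort_tables = {"background": items}
        for name in summaries:
            fort_tables[name] = pd.read_csv(out / f"food_table_{name}.csv")
        from .survey_data import assign_strata  # local to avoid cycle at import

        membership = assign_strata(persons, strata)
        for name, table in fort_tables.items():
            tots = person_totals(compute_person_group_totals(records, table, persons))
            tots = tots.set_index("person_id")["nutrient_ug"]
            for stratum in strata:
                vals = tots.reindex(membership.index[membership == stratum.stratum_id])
                box_rows.append({"scenario": name, "stratum_id": stratum.stratum_id, **boxplot_stats(vals)})
        pd.DataFrame(box_rows).to_csv(out / "boxplot_stats.csv", index=False)

    write_manifest(config, out, extra={"scenarios": [s.name for s in config.scenarios]})
    return {
        "aggregates": aggregates,
        "schemes": schemes,
        "summaries": summaries,
        "background_summary": background_summary,
        "comparison": comparison,
        "output_dir": out,
    }
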