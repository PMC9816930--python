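# fortiplan

Linear-programming planner for safe and adequate micronutrient food
fortification, driven by individual-level dietary-survey data.

Public-health agencies that consider mandatory or voluntary fortification
(the motivating case is vitamin D at Nordic latitudes) face a joint
adequacy/safety problem: levels must be high enough that every sex/age
subgroup's median intake reaches the Recommended Intake (RI), yet low
enough that nobody — including extreme consumers of the fortified foods —
risks exceeding the Tolerable Upper intake Level (UL). `fortiplan`
automates the search for such schemes from a national dietary survey and
a food-composition table, and verifies the result at the individual level.

## The model

Fortification levels are expressed per unit of food energy: `f_g` µg of
nutrient per 10 MJ of food group *g*'s energy, with a common cap
`0 ≤ f_g ≤ C`. Since recommended energy intake is roughly 10 MJ/day, the
cap guarantees by construction that even a consumer eating *only*
fortified foods gains at most `C` µg/day.

For each sex × age stratum *s*, let `B_s` be the stratum's median
background (unfortified) nutrient intake and `E_{s,g}` its median daily
energy from group *g* (both computed from the survey, with non-consumers
counted as zeros). The modelled post-fortification median intake is

    T_s = B_s + Σ_g f_g · E_{s,g} / 10     [µg/day]

and the planner solves the linear program

    minimize    Σ_s (T_s − RI_s)            (overshoot; minimax optional)
    subject to  T_s ≥ RI_s   for every stratum
                0 ≤ f_g ≤ C  for every allowed group

with HiGHS. Sweeping `C` upward locates the smallest cap at which the
program is feasible. Solved per-10 MJ levels are converted to practical
per-100 g levels through each group's population energy density
`k_g = 10 · (total MJ from g / total grams of g)`, the food-composition
table is rewritten, and every individual's intake is recomputed to check
medians against RI and 95th percentiles against UL.

Because individual records from the original survey are restricted, the
package ships a synthetic-survey generator (zero-inflated log-normal gram
intakes, realistic energy and vitamin-D densities, ~3,946 persons aged
4–75) plus planted-answer cases whose LP optimum has the closed form
`f* = 10·(RI − B)/E`, so the whole chain is testable end to end.

## Worked example

```sh
fortiplan simulate --out survey --seed 1          # synthetic survey, n = 3946
fortiplan aggregate --food-table survey/food_table.csv --groups survey/groups.csv \
    --persons survey/persons.csv --records survey/records.csv --out agg.csv
fortiplan mincap --aggregates agg.csv --out scheme
```

prints `19`: on this survey, 19 µg/10 MJ is the smallest common cap at
which every stratum's modelled median can reach the default RI of
10 µg/day when all 17 food groups may be fortified. The scheme
(`scheme.csv`) assigns most groups the full 19 µg/10 MJ — the binding
strata are young children, whose absolute food-group energies are small —
with per-100 g levels from the group energy densities, e.g. milk
19 µg/10 MJ → 0.489 µg/100 g, fats → 5.477 µg/100 g, potato only
8.36 µg/10 MJ (→ 0.292 µg/100 g). Converting, fortifying and re-evaluating:

```sh
fortiplan convert  --scheme scheme.json --food-table survey/food_table.csv \
    --records survey/records.csv --out scheme_conv
fortiplan fortify  --scheme scheme_conv.json --food-table survey/food_table.csv --out fortified.csv
fortiplan evaluate --food-table fortified.csv --persons survey/persons.csv \
    --records survey/records.csv --out summary.csv
```

yields, per stratum, `median (P5, P95)` µg/day with RI/UL flags — e.g.
girls 4–6 y rise from a background median of 1.6 to 11.8 (P5 8.1,
P95 17.7) µg/day: target reached, P95 far below the 50 µg/day child UL.
All twelve strata reach the target and none exceeds its UL.

`fortiplan run-all --config examples/config.yaml` executes eight bundled
reference scenarios (caps 12–30 µg/10 MJ over full and restricted food
group allow-lists) in one go, writing a scheme per scenario, a
background-vs-scenario comparison table, boxplot statistics and a
reproducibility manifest. The same pipeline is available as a library API
(`fortiplan.run_pipeline`), and `optimize`/`mincap` also accept an
aggregates CSV directly, so published stratum medians can be used when
individual records are unavailable.

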