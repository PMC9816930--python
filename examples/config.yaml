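# End-to-end run over the eight reference scenarios.
# Generate the synthetic survey first:
#   fortiplan simulate --out examples/survey --seed 1
# then:
#   fortiplan run-all --config examples/config.yaml
#
# Caps follow the published reference scenarios (12/25 µg/10 MJ with every
# group allowed; 20/25/30 over the restricted EU-fortifiable allow-lists).
# On synthetic surveys the restricted scenarios are typically infeasible at
# these caps (see docs/methods.md); their scheme files then record
# feasible: false, which is itself informative output.

food_table: examples/survey/food_table.csv
groups: examples/survey/groups.csv
persons: examples/survey/persons.csv
records: examples/survey/records.csv
strata: default6
output_dir: examples/out
seed: 1

scenarios:
  - name: scenario_1
    cap_ug_per_10mj: 12
    allowed_groups: [milk, cheese, icecream, cereals, vegetables, fruit, meat, fish, poultry, egg, fats, sugar, beverages, spices, other, potato, juice]
  - name: scenario_2
    cap_ug_per_10mj: 25
    allowed_groups: [milk, cheese, icecream, cereals, vegetables, fruit, meat, fish, poultry, egg, fats, sugar, beverages, spices, other, potato, juice]
  - name: scenario_3
    cap_ug_per_10mj: 20
    allowed_groups: [milk, cheese, cereals, fats, juice]
  - name: scenario_4
    cap_ug_per_10mj: 20
    allowed_groups: [milk, cheese, cereals, fats]
  - name: scenario_5
    cap_ug_per_10mj: 25
    allowed_groups: [milk, cheese, cereals, fats, juice]
  - name: scenario_6
    cap_ug_per_10mj: 25
    allowed_groups: [milk, cheese, cereals, fats]
  - name: scenario_7
    cap_ug_per_10mj: 30
    allowed_groups: [milk, cheese, cereals, fats, juice]
  - name: scenario_8
    cap_ug_per_10mj: 30
    allowed_groups: [milk, cheese, cereals, fats]
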