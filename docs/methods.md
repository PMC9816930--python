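# Methods

## Model and assumptions

The planner treats fortification as a stratum-median attainment problem.
A population is partitioned into sex × age strata (default: M/F × 4–6,
7–10, 11–14, 15–17, 18–50, 51–75 years; any partition of the survey age
range is accepted, and a coarser 4-band partition is provided for
reporting). For stratum *s* and food group *g* the survey contributes two
medians over **all** persons of the stratum, non-consumers included:
background nutrient intake `B_s` (µg/day) and group energy `E_{s,g}`
(MJ/day). Counting non-consumers as zeros is deliberate: excluding them
would inflate `E_{s,g}` and overstate what fortifying a group delivers.
Medians (mean-of-central-pair for even n) rather than means make the
aggregates robust to the energy mis-reporting endemic to dietary surveys,
so no mis-reporter screening is applied anywhere in the pipeline.

A level `f_g` (µg per 10 MJ of group energy) adds `f_g·E_{s,g}/10` µg/day
to stratum *s*'s modelled median. The LP minimizes total overshoot
`Σ_s (T_s − RI_s)` subject to hard attainment `T_s ≥ RI_s` and
`0 ≤ f_g ≤ C`. Two modelling choices deserve note:

* **Attainment is hard, overshoot is the objective.** With attainment as
  a constraint, "deviation from target" and "overshoot" coincide, and
  both the sum and minimax (`max_s` overshoot) objectives are exact
  linearizations of minimizing deviation; the sum is the default. Making
  attainment hard is also what gives the minimum-cap sweep its meaning:
  below the threshold cap the program is *infeasible*, not merely poor.
* **The cap is the safety argument.** Recommended energy intake is
  roughly 10 MJ/day, so `f_g ≤ C` for every group bounds any consumer's
  added intake by `C·(energy from fortified foods)/10 ≤ C` µg/day,
  independent of which foods they favour. The UL therefore does not
  appear in the LP at all; it is screened afterwards against each
  stratum's P95 from full individual recalculation.

LP optima need not be unique: groups with proportional energy profiles
across strata are interchangeable to the objective. The solver
configuration is pinned (HiGHS, sorted variable order), which makes runs
deterministic, but a different solver could return a different optimal
scheme with the same objective value; the feasibility threshold found by
the cap sweep is solver-independent. No lexicographic tie-break is added.
Levels are reported both continuous (authoritative) and nearest-integer.

## Unit conversion and table rewriting

Per-10 MJ levels become per-100 g levels through the group's
population-level energy density `ρ_g` = total MJ ÷ total grams over every
record of every person, i.e. `k_g = 10·ρ_g` µg/100 g per µg/10 MJ. This
group-average conversion is what keeps schemes implementable (one level
per group), at a known cost: within a group, items whose energy density
differs from the group average are dosed per gram as if they were
average, so individual added intakes deviate from exact per-10 MJ dosing
— upward for people favouring the group's low-energy-dense items. The
population *total* added nutrient is unaffected (both modes distribute
the same total, which the test suite checks), and an exact per-item mode
(`mode="per_item"`, each item dosed by its own energy density) is
provided; it is off by default. The per-person cap bound
`added ≤ C·E_fortified/10` is exact in per-item mode and approximate
under group-average conversion, which is why the safety-bound test and
acceptance metric use per-item dosing. Reported per-100 g levels are
rounded to 3 decimals; full precision is kept internally.

## Evaluation

Schemes are verified by rewriting the food-composition table and
recomputing every individual's intake, then summarizing each stratum:
median/P5/P95 by linear interpolation between closest ranks (the default
convention of mainstream numerical environments; stated because P5/P95
in ~100-person strata are sensitive to it), a notch
`median ± 1.57·IQR/√n` as the 95% CI of the median, `target_reached`
(median ≥ RI) and `ul_exceeded` (P95 > UL). Default targets: RI
10 µg/day in every stratum (configurable per stratum; published analyses
use 7.5 µg/day for some groups without specifying which), UL 50 µg/day
for strata entirely within ages 4–10 and 100 µg/day otherwise. The
comparison table and boxplot statistics (quartiles, 1.5·IQR whiskers,
notches) are exported as plain CSV; plotting is left to the caller.

## Synthetic surveys

The generator emulates a 7-day-record national survey: 3,946 persons by
default, sex/age mix matching published stratum margins, 17 food groups
with per-group consumption probability, log-normal gram intakes
(`LogNormal(log(median·scale_stratum), sdlog)` behind a Bernoulli
consumption gate), uniform per-item energy densities, and background
vitamin-D densities concentrated in fish, eggs and fats. Child and
female strata scale gram intakes down (scales 0.5–1.0). Defaults land
adult-male totals near 10 MJ/day and an all-ages background vitamin-D
median near 2.7 µg/day, in the range reported for Nordic populations.
All draws flow from a single seed; output is byte-reproducible.

What the generator does **not** emulate: day-to-day within-person
variance (records are pre-averaged intakes, as in the real input format),
correlations between food groups, recipe structure, secular trends, and
item-level nutrient correlations beyond the energy/vitamin-D densities.
Passing tests on synthetic surveys therefore certify the *machinery* —
aggregation, LP, conversion, evaluation — not the realism of any
particular fortification recommendation. On the default synthetic survey
the all-groups minimum cap is 19 µg/10 MJ and the restricted four/five
group scenarios become feasible only around 40 µg/10 MJ, both higher
than published values on real Danish data; the driver is the young-child
strata, whose group-median energies are smaller here than in the real
survey. Tests that need a feasible restricted scenario therefore use
caps at or above these synthetic thresholds.

Planted-answer cases make every person identical (one group, one item),
so all medians coincide and the LP optimum is `f* = 10·(RI − B)/E`
exactly; these are recovered through the full pipeline to 1e-6 µg/10 MJ.

## Numerical choices

* Attainment tolerance 1e-6 µg/day on `T_s ≥ RI_s` in feasibility checks.
* Min-cap search: integer caps from 10 in steps of 1 (the procedural
  definition); an equivalent bisection exploiting feasibility
  monotonicity is available but off by default.
* Grid oracle for cross-checking the LP: exhaustive search at 0.01
  µg/10 MJ resolution, ≤ 3 groups, vectorized and chunked; agreement is
  asserted within the objective's Lipschitz bound per grid step.
* Groups with zero recorded intake get `ρ_g = 0` with a warning and may
  not carry fortificant; allowed groups with zero median energy in every
  stratum trigger a warning (the variable cannot affect any constraint).
* Empty strata, duplicate keys, negative densities/grams and broken
  referential integrity are hard errors at ingestion.

## Problem sizes

The default test and acceptance runs use the full 3,946-person synthetic
survey for aggregation, evaluation and the safety bound; 500–600-person
surveys for pipeline determinism and CLI smoke tests; 20 random 2-group
instances for the LP-vs-grid comparison; and 10 seeded planted-answer
cases for closed-form recovery.

## Known limitations

Fortification is assumed to reach 100% of each group's items — no market
penetration below one. Single nutrient per run; no joint multi-nutrient
optimization. No mixed-integer variant (levels are continuous, with
integer rounding only for reporting). Supplement intake is outside the
model: background is dietary only. Habitual-intake (usual intake)
modelling of within-person variance is out of scope; percentiles are of
the observed person-mean intakes.
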