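"""Published reference fortification schemes for vitamin D in Denmark.

A published Danish analysis of survey-based vitamin D fortification
reports eight optimized scenarios, each listing the level assigned to
every food group both per 10 MJ and per 100 g.  Those printed levels are
carried here as reference data for cross-checking this package's unit
conversion: each printed (µg/10 MJ, µg/100 g) pair implies the food
group's population conversion factor k_g = per-100 g ÷ per-10 MJ, and a
factor derived from one scenario must reproduce the per-100 g cells of
the other scenarios of the same group.

Scenario caps (µg/10 MJ): 1→12 (the lowest cap at which the published
model is feasible with every group allowed), 2→25, 3→20, 4→20, 5→25,
6→25, 7→30, 8→30.  Scenarios 1–2 allow all groups; 3/5/7 allow milk,
cheese, cereals, fats and juice; 4/6/8 the same minus juice.

The scenario-1 milk pair (2 µg/10 MJ against 0.274 µg/100 g) is
internally inconsistent with milk's factor in every other scenario
(0.457/20 ≈ 0.0229 implies 0.274 ↔ 12, not 2) and is treated as a
misprint; milk is therefore excluded from conversion cross-checks.
"""

from __future__ import annotations

__all__ = [
    "SCENARIO_CAPS",
    "ALL_GROUPS",
    "FIVE_GROUPS",
    "FOUR_GROUPS",
    "PUBLISHED_LEVELS",
    "conversion_factor",
    "CONVERSION_CHECK_PAIRS",
]

SCENARIO_CAPS: dict[int, float] = {1: 12, 2: 25, 3: 20, 4: 20, 5: 25, 6: 25, 7: 30, 8: 30}

ALL_GROUPS = [
    "milk", "cheese", "icecream", "cereals", "vegetables", "fruit", "meat",
    "fish", "poultry", "egg", "fats", "sugar", "beverages", "spices",
    "other", "potato", "juice",
]
FIVE_GROUPS = ["milk", "cheese", "cereals", "fats", "juice"]
FOUR_GROUPS = ["milk", "cheese", "cereals", "fats"]

#: group_id -> scenario number -> (level µg/10 MJ, level µg/100 g)
PUBLISHED_LEVELS: dict[str, dict[int, tuple[float, float]]] = {
    "milk": {1: (2, 0.274), 2: (25, 0.571), 3: (20, 0.457), 4: (20, 0.457),
             5: (25, 0.571), 6: (25, 0.571), 7: (24, 0.548), 8: (25, 0.571)},
    "cheese": {1: (12, 1.464), 2: (0, 0.0), 3: (8, 0.976), 4: (16, 1.952),
               5: (3, 0.366), 6: (3, 0.366), 7: (0, 0.0), 8: (0, 0.0)},
    "icecream": {1: (12, 1.037), 2: (25, 2.161), 3: (0, 0.0), 4: (0, 0.0),
                 5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "cereals": {1: (12, 1.418), 2: (15, 1.773), 3: (20, 2.364), 4: (20, 2.364),
                5: (25, 2.955), 6: (25, 2.955), 7: (27, 3.191), 8: (28, 3.309)},
    "vegetables": {1: (12, 0.435), 2: (0, 0.0), 3: (0, 0.0), 4: (0, 0.0),
                   5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "fruit": {1: (12, 0.435), 2: (0, 0.0), 3: (0, 0.0), 4: (0, 0.0),
              5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "meat": {1: (12, 1.055), 2: (0, 0.0), 3: (0, 0.0), 4: (0, 0.0),
             5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "fish": {s: (0, 0.0) for s in range(1, 9)},
    "poultry": {1: (12, 0.733), 2: (25, 1.528), 3: (0, 0.0), 4: (0, 0.0),
                5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "egg": {1: (12, 0.716), 2: (0, 0.0), 3: (0, 0.0), 4: (0, 0.0),
            5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "fats": {1: (12, 3.508), 2: (0, 0.0), 3: (20, 5.847), 4: (20, 5.847),
             5: (4, 1.169), 6: (7, 2.047), 7: (0, 0.0), 8: (0, 0.0)},
    "sugar": {1: (12, 2.172), 2: (25, 4.525), 3: (0, 0.0), 4: (0, 0.0),
              5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "beverages": {s: (0, 0.0) for s in range(1, 9)},
    "spices": {1: (11, 0.091), 2: (19, 0.157), 3: (0, 0.0), 4: (0, 0.0),
               5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "other": {1: (12, 2.717), 2: (25, 5.660), 3: (0, 0.0), 4: (0, 0.0),
              5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "potato": {1: (12, 0.469), 2: (24, 0.938), 3: (0, 0.0), 4: (0, 0.0),
               5: (0, 0.0), 6: (0, 0.0), 7: (0, 0.0), 8: (0, 0.0)},
    "juice": {1: (12, 0.228), 2: (25, 0.476), 3: (19, 0.362), 4: (0, 0.0),
              5: (25, 0.476), 6: (0, 0.0), 7: (29, 0.552), 8: (0, 0.0)},
}


def conversion_factor(group_id: str, scenario: int) -> float:
    """k_g implied by one scenario's printed (per-10 MJ, per-100 g) pair."""
    per10mj, per100g = PUBLISHED_LEVELS[group_id][scenario]
    if per10mj == 0:
        raise ValueError(f"group {group_id!r} has level 0 in scenario {scenario}; factor undefined")
    return per100g / per10mj

#: Cross-check pairs (group, source scenario for k, target scenario):
#: k is derived from the largest printed per-100 g cell of the group to
#: minimize compounded rounding, then applied to the target's per-10 MJ
#: level; the result must match the target's printed per-100 g cell to
#: the printed precision (±0.001).
CONVERSION_CHECK_PAIRS: list[tuple[str, int, int]] = [
    ("cereals", 5, 3),
    ("fats", 3, 6),
    ("cheese", 4, 3),
    ("sugar", 2, 1),
    ("potato", 2, 1),
]
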