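"""Dietary scenario transformation by rule-based replacement.

A scenario disqualifies foods by category flag (meat for pescetarian; meat
and fish for the vegetarian and flexitarian scenarios; all animal categories
for vegan, except items whose only animal content is minor, such as cake)
and replaces each disqualified consumption event gram-for-gram with a
uniformly drawn alternative from the same food group.  The flexitarian
scenarios first select 40% or 80% of the disqualified events at random,
pooled across participants, then replace only those.

All randomness flows from one seeded generator per scenario run: the
flexitarian selection draw happens first, then one replacement draw per
affected event in dataset row order, so identical inputs and seed give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from plantshift.errors import UnmappedGroupError, ValidationError
from plantshift.food_composition import FoodDatabase, FoodItem, _read_table, _sep_for
from plantshift.protein_quality import ConsumptionEvent

#: Largest number of alternatives a food group may offer.
MAX_ALTERNATIVES = 12

SCENARIO_NAMES = (
    "original", "flexitarian40", "flexitarian80", "pescetarian", "vegetarian", "vegan",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Disqualification and replacement rules for one scenario."""

    name: str
    disqualifying_flags: frozenset[str] = frozenset()
    replacement_fraction: float = 1.0
    exempt_flags: frozenset[str] = frozenset()
    family: str | None = None  # replacement-table family: vegetarian or vegan
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.replacement_fraction <= 1.0:
            raise ValidationError(
                f"replacement_fraction {self.replacement_fraction} outside [0, 1]"
            )
        if self.name == "original" and self.disqualifying_flags:
            raise ValidationError("the original scenario disqualifies nothing")


def scenario_presets(
    seed: int = 0, flexitarian_includes_fish: bool = True
) -> dict[str, ScenarioSpec]:
    """The five named scenarios plus the untouched original diet.

    `flexitarian_includes_fish` controls whether the partial-replacement
    scenarios draw from meat and fish events (default) or meat only.
    """
    flex_flags = frozenset({"meat", "fish"} if flexitarian_includes_fish else {"meat"})
    return {
        "original": ScenarioSpec("original", seed=seed),
        "flexitarian40": ScenarioSpec(
            "flexitarian40", flex_flags, 0.40, family="vegetarian", seed=seed
        ),
        "flexitarian80": ScenarioSpec(
            "flexitarian80", flex_flags, 0.80, family="vegetarian", seed=seed
        ),
        "pescetarian": ScenarioSpec(
            "pescetarian", frozenset({"meat"}), 1.0, family="vegetarian", seed=seed
        ),
        "vegetarian": ScenarioSpec(
            "vegetarian", frozenset({"meat", "fish"}), 1.0, family="vegetarian", seed=seed
        ),
        "vegan": ScenarioSpec(
            "vegan",
            frozenset({"meat", "fish", "dairy", "egg", "cheese"}),
            1.0,
            exempt_flags=frozenset({"minor_animal_content"}),
            family="vegan",
            seed=seed,
        ),
    }


class ReplacementTable:
    """Alternatives per (scenario family, food group), at most 12 each."""

    def __init__(self, mapping: Mapping[tuple[str, str], Sequence[str]]):
        self._map: dict[tuple[str, str], tuple[str, ...]] = {}
        for key, alts in mapping.items():
            alts = tuple(str(a) for a in alts)
            if not 1 <= len(alts) <= MAX_ALTERNATIVES:
                raise ValidationError(
                    f"{key}: {len(alts)} alternatives, expected 1..{MAX_ALTERNATIVES}"
                )
            self._map[key] = alts

    def alternatives(self, family: str, food_group: str) -> tuple[str, ...]:
        try:
            return self._map[(family, food_group)]
        except KeyError:
            raise UnmappedGroupError(
                f"no {family} alternatives for food group {food_group!r}"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._map

    def items(self):
        return self._map.items()

    def validate_against(self, db: FoodDatabase, specs: Iterable[ScenarioSpec]) -> None:
        """Check alternatives exist in `db` and are themselves qualified."""
        by_family = {s.family: s for s in specs if s.family}
        for (family, group), alts in self._map.items():
            for alt in alts:
                item = db[alt]  # raises UnknownFoodError
                spec = by_family.get(family)
                if spec is not None and needs_replacement(item, spec):
                    raise ValidationError(
                        f"alternative {alt!r} for ({family}, {group}) is itself "
                        f"disqualified under the {spec.name} scenario"
                    )

    # -------------------------------------------------------------- I/O

    def save(self, path: str | Path) -> None:
        rows = [
            {"scenario_family": fam, "food_group": grp, "alternative_food_id": alt}
            for (fam, grp), alts in sorted(self._map.items())
            for alt in alts
        ]
        pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ReplacementTable":
        df = _read_table(path, ("scenario_family", "food_group", "alternative_food_id"))
        mapping: dict[tuple[str, str], list[str]] = {}
        for rec in df.to_dict("records"):
            key = (str(rec["scenario_family"]), str(rec["food_group"]))
            mapping.setdefault(key, []).append(str(rec["alternative_food_id"]))
        return cls(mapping)


@dataclass
class ReplacementLog:
    """Audit trail of every substitution performed in one scenario run."""

    scenario: str
    records: list[tuple[int, str, str, float]] = field(default_factory=list)
    # each record: (event row position, original food_id, new food_id, amount_g)

    @property
    def count(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["event_index", "original_food_id", "replacement_food_id", "amount_g"],
        )


def needs_replacement(item: FoodItem, spec: ScenarioSpec) -> bool:
    """True iff the item carries a disqualifying flag and no exempt flag."""
    if item.category_flags & spec.exempt_flags:
        return False
    return bool(item.category_flags & spec.disqualifying_flags)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_flexitarian_targets(
    disqualified_events: Sequence, fraction: float, rng: np.random.Generator
) -> list:
    """Uniform without-replacement subset of round_half_up(fraction x n) events.

    Events are pooled across participants; the draw is deterministic given
    the generator state.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction {fraction} outside [0, 1]")
    n = len(disqualified_events)
    k = round_half_up(fraction * n)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [disqualified_events[i] for i in idx]


def replace_event(
    event: ConsumptionEvent,
    item: FoodItem,
    table: ReplacementTable,
    rng: np.random.Generator,
    family: str = "vegetarian",
) -> ConsumptionEvent:
    """Swap the event's food for a uniformly drawn same-group alternative.

    The consumed amount is untouched (gram-for-gram substitution).
    """
    alts = table.alternatives(family, item.food_group)
    new_id = alts[int(rng.integers(len(alts)))]
    return ConsumptionEvent(
        participant_id=event.participant_id,
        day_index=event.day_index,
        occasion=event.occasion,
        food_id=new_id,
        amount_g=event.amount_g,
    )


def apply_scenario(
    consumption: pd.DataFrame,
    db: FoodDatabase,
    spec: ScenarioSpec,
    table: ReplacementTable | None,
) -> tuple[pd.DataFrame, ReplacementLog]:
    """Transform a consumption table into one scenario diet.

    Returns a new table of identical shape (same participants, days,
    occasions, event count and amounts; only food_id changes) and the
    replacement log.  A disqualified food whose group has no table entry is
    a hard error — silently keeping meat in a vegan diet would corrupt every
    downstream number.
    """
    log = ReplacementLog(scenario=spec.name)
    out = consumption.copy(deep=True)
    if not spec.disqualifying_flags:
        return out, log
    if table is None:
        raise ValidationError(f"scenario {spec.name} needs a replacement table")
    if spec.family is None:
        raise ValidationError(f"scenario {spec.name} has no replacement-table family")

    items = db.to_frame()
    flags = items["flags"].str.split(";").apply(
        lambda fs: frozenset(f for f in fs if f)
    )
    disq_item = flags.apply(
        lambda fs: bool(fs & spec.disqualifying_flags) and not (fs & spec.exempt_flags)
    )
    disq_ids = set(items.index[disq_item])
    mask = out["food_id"].isin(disq_ids).to_numpy()
    positions = np.flatnonzero(mask)

    rng = np.random.default_rng(spec.seed)
    if spec.replacement_fraction < 1.0:
        k = round_half_up(spec.replacement_fraction * len(positions))
        positions = np.sort(rng.choice(positions, size=k, replace=False))

    food_ids = out["food_id"].to_numpy(dtype=object).copy()
    amounts = out["amount_g"].to_numpy()
    groups = items["food_group"].to_dict()
    for pos in positions:
        old_id = food_ids[pos]
        alts = table.alternatives(spec.family, groups[old_id])
        new_id = alts[int(rng.integers(len(alts)))]
        log.records.append((int(pos), old_id, new_id, float(amounts[pos])))
        food_ids[pos] = new_id
    out["food_id"] = food_ids

    # purity check: no disqualified event may survive full replacement
    if spec.replacement_fraction == 1.0:
        leftover = out["food_id"].isin(disq_ids)
        if leftover.any():
            raise ValidationError(
                f"scenario {spec.name}: replacement alternatives are themselves "
                f"disqualified for {sorted(set(out['food_id'][leftover]))[:5]}"
            )
    return out, log


def plant_protein_share(consumption: pd.DataFrame, db: FoodDatabase) -> float:
    """Fraction of total (amino-acid-derived) protein that is plant-based."""
    items = db.to_frame()
    ev = consumption.merge(
        items[["protein_g_100g", "animal_protein_fraction"]],
        left_on="food_id", right_index=True, how="left", sort=False,
    )
    protein = ev["amount_g"].to_numpy() / 100.0 * ev["protein_g_100g"].to_numpy()
    total = protein.sum()
    if total == 0:
        raise ValidationError("plant-protein share undefined: zero total protein")
    plant = (protein * (1.0 - ev["animal_protein_fraction"].to_numpy())).sum()
    return float(plant / total)
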