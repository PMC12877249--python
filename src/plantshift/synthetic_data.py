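"""Synthetic survey-like populations, food databases and consumption data.

The generator emulates the structure the analysis assumes from a two-recall
national food consumption survey of older adults: two recall days of 7
eating occasions each, cereal-staple (lysine-poor) breakfasts and lunches,
meat-dominated dinners, roughly 60/40 animal/plant protein at baseline, and
lognormal between-person and day-to-day variation around per-sex protein
targets.  Every generated bundle passes the loaders' validation and carries
a ground-truth record (true variance components, true median intakes) so
parameter recovery can be scored.

Food classes are built so that protein-quality structure is known by
construction: animal items meet the reference pattern (similarity factor
exactly 1 as single-item meals), cereals are lysine-limited, legumes are
rich in lysine but limited in sulfur amino acids, and plant digestibility
(0.75-0.88) sits below animal digestibility (0.90-0.95).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from plantshift.errors import ValidationError
from plantshift.food_composition import (
    IAA_KEYS,
    AminoAcidVector,
    DigestibilityTable,
    FoodDatabase,
    FoodItem,
    who_2007_pattern,
)
from plantshift.protein_quality import MAIN_MEALS, OCCASIONS
from plantshift.scenario_engine import ReplacementTable

_SNACKS = tuple(o for o in OCCASIONS if o not in MAIN_MEALS)

# Per-class composition rules.  "ratios" are IAA contents relative to the
# scoring pattern (mg per g protein / pattern value); classes without an
# override use "default".  Density is AA-derived protein in g per 100 g.
_CLASS_SPECS: dict[str, dict] = {
    "meat": dict(flags={"meat"}, animal=(1.0, 1.0), density=(18.0, 24.0),
                 digest=(0.90, 0.95), kcal=(150.0, 250.0),
                 ratios={"default": (1.10, 1.40)}),
    "fish": dict(flags={"fish"}, animal=(1.0, 1.0), density=(16.0, 22.0),
                 digest=(0.90, 0.95), kcal=(100.0, 200.0),
                 ratios={"default": (1.10, 1.40)}),
    "dairy": dict(flags={"dairy"}, animal=(1.0, 1.0), density=(3.2, 3.8),
                  digest=(0.92, 0.95), kcal=(45.0, 70.0),
                  ratios={"default": (1.10, 1.40)}),
    "egg": dict(flags={"egg"}, animal=(1.0, 1.0), density=(11.0, 13.0),
                digest=(0.90, 0.95), kcal=(130.0, 160.0),
                ratios={"default": (1.10, 1.40)}),
    "cheese": dict(flags={"cheese"}, animal=(1.0, 1.0), density=(20.0, 26.0),
                   digest=(0.90, 0.95), kcal=(300.0, 400.0),
                   ratios={"default": (1.10, 1.40)}),
    "cereal": dict(flags=set(), animal=(0.0, 0.0), density=(8.0, 12.0),
                   digest=(0.78, 0.88), kcal=(220.0, 280.0),
                   ratios={"default": (1.00, 1.25), "lys": (0.55, 0.62)}),
    "legume": dict(flags=set(), animal=(0.0, 0.0), density=(6.0, 9.0),
                   digest=(0.75, 0.82), kcal=(90.0, 130.0),
                   ratios={"default": (1.00, 1.30), "lys": (1.25, 1.50),
                           "saa": (0.75, 0.85)}),
    "vegetable": dict(flags=set(), animal=(0.0, 0.0), density=(1.5, 3.0),
                      digest=(0.75, 0.85), kcal=(20.0, 40.0),
                      ratios={"default": (0.95, 1.20), "saa": (0.80, 0.95)}),
    "meat_substitute": dict(flags=set(), animal=(0.0, 0.0), density=(10.0, 15.0),
                            digest=(0.78, 0.85), kcal=(150.0, 250.0),
                            ratios={"default": (0.95, 1.20), "lys": (0.78, 0.88)}),
    "dairy_alternative": dict(flags=set(), animal=(0.0, 0.0), density=(2.5, 3.5),
                              digest=(0.80, 0.88), kcal=(35.0, 60.0),
                              ratios={"default": (1.00, 1.30), "saa": (0.80, 0.90)}),
    "sweet": dict(flags={"minor_animal_content"}, animal=(0.05, 0.15),
                  density=(4.0, 6.0), digest=(0.80, 0.88), kcal=(350.0, 480.0),
                  ratios={"default": (0.90, 1.20), "lys": (0.60, 0.80)}),
}

# Protein-share weights of the food classes at each occasion, chosen so the
# baseline reproduces the survey-like structure: ~55%/50% plant protein at
# breakfast/lunch (bread-dominated), ~25% at dinner (meat-dominated), and
# ~39% of daily protein plant-based overall.
_OCCASION_CLASS_WEIGHTS: dict[str, dict[str, float]] = {
    "breakfast": {"cereal": 0.50, "dairy": 0.30, "cheese": 0.14, "sweet": 0.06},
    "lunch": {"cereal": 0.42, "cheese": 0.20, "meat": 0.14, "egg": 0.08,
              "dairy": 0.05, "sweet": 0.05, "fish": 0.03, "legume": 0.03},
    "dinner": {"meat": 0.52, "fish": 0.13, "dairy": 0.10, "vegetable": 0.10,
               "cereal": 0.08, "legume": 0.07},
    "snack": {"dairy": 0.40, "sweet": 0.20, "cheese": 0.12, "cereal": 0.12,
              "vegetable": 0.10, "meat": 0.06},
}


def _log_sd(cv: float) -> float:
    """Log-scale SD of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic survey.

    Defaults encode the baseline the analysis expects: median daily protein
    82.5 g for men and 67.9 g for women (0.96 / 0.94 g per kg at median body
    weights of 86 / 72 kg), a ~61/39 animal/plant protein split, and
    moderate between-person (CV 0.20) and day-to-day (CV 0.25) variation.
    """

    n_participants: int = 600
    male_fraction: float = 0.51
    weight_median_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 86.0, "female": 72.0}
    )
    weight_log_sd: float = 0.11
    #: median protein target (g) per occasion; snacks share one target each
    occasion_protein_g: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "breakfast": {"male": 11.5, "female": 9.5},
            "lunch": {"male": 22.0, "female": 18.0},
            "dinner": {"male": 33.0, "female": 26.0},
            "snack": {"male": 4.0, "female": 3.6},
        }
    )
    between_person_cv: float = 0.20
    day_to_day_cv: float = 0.25
    #: probability a given snack occasion is habitually skipped
    snack_skip_prob: float = 0.20
    items_per_class: int = 6
    events_per_main_meal: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("need at least 2 participants")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValidationError("male_fraction outside [0, 1]")
        if not 0.0 <= self.snack_skip_prob < 1.0:
            raise ValidationError("snack_skip_prob outside [0, 1)")
        for cv in (self.between_person_cv, self.day_to_day_cv):
            if cv < 0:
                raise ValidationError("coefficients of variation must be >= 0")


@dataclass
class SyntheticBundle:
    """A complete generated dataset plus the ground truth that produced it."""

    food_db: FoodDatabase
    participants: pd.DataFrame
    consumption: pd.DataFrame
    replacement_table: ReplacementTable
    ground_truth: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.food_db.save(out / "composition.csv", out / "digestibility.csv")
        self.participants.to_csv(out / "participants.csv", index=False)
        self.consumption.to_csv(out / "consumption.csv", index=False)
        self.replacement_table.save(out / "replacements.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )


def generate_food_database(
    config: GeneratorConfig, rng: np.random.Generator
) -> FoodDatabase:
    """Generate class-structured food items and per-group digestibility."""
    pattern = who_2007_pattern()
    items: list[FoodItem] = []
    digestibility: dict[str, float] = {}
    for cls, spec in _CLASS_SPECS.items():
        digestibility[cls] = float(rng.uniform(*spec["digest"]))
        for i in range(config.items_per_class):
            density = float(rng.uniform(*spec["density"]))  # g protein / 100 g
            per_g = {}
            for k in IAA_KEYS:
                lo, hi = spec["ratios"].get(k, spec["ratios"]["default"])
                per_g[k] = float(rng.uniform(lo, hi)) * pattern[k]
            iaa_sum = sum(per_g.values())
            if iaa_sum >= 1000.0:
                raise ValidationError(
                    f"class {cls}: IAA content exceeds total protein"
                )  # pragma: no cover - impossible under packaged ranges
            profile = AminoAcidVector(
                **{f"{k}_mg": per_g[k] * density for k in IAA_KEYS},
                dispensable_aa_mg=(1000.0 - iaa_sum) * density,
            )
            items.append(
                FoodItem(
                    food_id=f"{cls}_{i:02d}",
                    name=f"synthetic {cls} {i}",
                    food_group=cls,
                    aa_profile=profile,
                    category_flags=frozenset(spec["flags"]),
                    animal_protein_fraction=float(rng.uniform(*spec["animal"])),
                    label_protein_g_per_100g=round(density * float(rng.uniform(1.05, 1.15)), 1),
                    kcal_per_100g=round(float(rng.uniform(*spec["kcal"])), 0),
                )
            )
    return FoodDatabase(items, DigestibilityTable(digestibility))


def generate_participants(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Participant table with sex, age, body weight and survey weight."""
    n = config.n_participants
    n_male = int(round(config.male_fraction * n))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    medians = np.array([config.weight_median_kg[s] for s in sex])
    weight = medians * np.exp(rng.normal(0.0, config.weight_log_sd, size=n))
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "sex": sex,
            "age": rng.integers(65, 80, size=n),
            "body_weight_kg": np.round(weight, 1),
            "survey_weight": np.round(rng.uniform(0.5, 1.5, size=n), 4),
        }
    )


def generate_consumption(
    config: GeneratorConfig,
    db: FoodDatabase,
    participants: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Two recall days of 7 occasions per participant, plus ground truth.

    Occasion protein targets are multiplied by a mean-median-one lognormal
    person effect and day effect; events realise the target exactly (amounts
    are protein target / item protein density), so daily total protein is
    lognormal by construction and the generating variance components are
    known.  Habitually skipped snack occasions are a per-participant trait,
    so zero day-to-day variation implies identical daily protein totals.
    """
    sb = _log_sd(config.between_person_cv)
    sw = _log_sd(config.day_to_day_cv)
    items = db.to_frame()
    class_ids = {
        cls: list(items.index[items["food_group"] == cls]) for cls in _CLASS_SPECS
    }
    density = items["protein_g_100g"].to_dict()

    occ_weights = {}
    for occ in OCCASIONS:
        key = occ if occ in _OCCASION_CLASS_WEIGHTS else "snack"
        w = _OCCASION_CLASS_WEIGHTS[key]
        occ_weights[occ] = (list(w.keys()), np.array(list(w.values())))

    records: list[tuple] = []
    for pid, p_sex in zip(participants["participant_id"], participants["sex"]):
        person = math.exp(rng.normal(0.0, sb))
        snacker = rng.random(len(_SNACKS)) >= config.snack_skip_prob
        for day in (1, 2):
            day_mult = math.exp(rng.normal(0.0, sw))
            for occ in OCCASIONS:
                if occ in _SNACKS:
                    if not snacker[_SNACKS.index(occ)]:
                        continue
                    base = config.occasion_protein_g["snack"][p_sex]
                    base /= 1.0 - config.snack_skip_prob
                    n_ev = 1
                else:
                    base = config.occasion_protein_g[occ][p_sex]
                    n_ev = config.events_per_main_meal
                target = base * person * day_mult
                shares = (
                    rng.dirichlet([2.0] * n_ev) if n_ev > 1 else np.array([1.0])
                )
                names, probs = occ_weights[occ]
                classes = rng.choice(len(names), size=n_ev, p=probs)
                for ci, share in zip(classes, shares):
                    ids = class_ids[names[ci]]
                    fid = ids[int(rng.integers(len(ids)))]
                    amount = target * share / density[fid] * 100.0
                    records.append((pid, day, occ, fid, round(float(amount), 2)))

    consumption = pd.DataFrame(
        records, columns=["participant_id", "day", "occasion", "food_id", "amount_g"]
    )
    base_daily = {
        s: (
            sum(config.occasion_protein_g[m][s] for m in MAIN_MEALS)
            + len(_SNACKS) * config.occasion_protein_g["snack"][s]
        )
        for s in ("male", "female")
    }
    ground_truth = {
        "sigma_between_log": sb,
        "sigma_within_log": sw,
        "target_median_daily_protein_g": base_daily,
        "target_median_daily_protein_per_kg": {
            s: base_daily[s] / config.weight_median_kg[s] for s in base_daily
        },
        "snack_skip_prob": config.snack_skip_prob,
    }
    return consumption, ground_truth


def generate_replacement_tables(db: FoodDatabase) -> ReplacementTable:
    """Replacement tables for both scenario families, built from the database.

    Vegetarian-family alternatives for meat and fish mix meat substitutes
    with dairy/egg/cheese and legumes; vegan alternatives are plant-only
    (meat substitutes, legumes, plant dairy alternatives).  Lists are capped
    at 12.
    """
    items = db.to_frame()

    def ids(cls: str) -> list[str]:
        out = list(items.index[items["food_group"] == cls])
        if not out:
            raise ValidationError(f"no qualified candidates in class {cls!r}")
        return out

    substitutes, legumes = ids("meat_substitute"), ids("legume")
    cheeses, eggs = ids("cheese"), ids("egg")
    dairy_alt = ids("dairy_alternative")

    veg_pool = (substitutes + cheeses[:3] + eggs[:3])[:12]
    vegan_pool = (substitutes + legumes)[:12]
    mapping = {
        ("vegetarian", "meat"): veg_pool,
        ("vegetarian", "fish"): veg_pool,
        ("vegan", "meat"): vegan_pool,
        ("vegan", "fish"): vegan_pool,
        ("vegan", "cheese"): vegan_pool,
        ("vegan", "egg"): vegan_pool,
        ("vegan", "dairy"): dairy_alt[:12],
    }
    return ReplacementTable(mapping)


def generate_bundle(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Generate a complete, validated bundle from one seeded RNG stream."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    db = generate_food_database(config, rng)
    participants = generate_participants(config, rng)
    consumption, ground_truth = generate_consumption(config, db, participants, rng)
    table = generate_replacement_tables(db)
    ground_truth["seed"] = config.seed
    ground_truth["n_participants"] = config.n_participants
    return SyntheticBundle(
        food_db=db,
        participants=participants,
        consumption=consumption,
        replacement_table=table,
        ground_truth=ground_truth,
    )
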