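"""Per-occasion protein quantity and PDCAAS-based quality scoring.

Protein availability is computed three ways for every participant-day:

* total protein — the consumed amino-acid mass summed over all foods;
* digestible protein — each food's amino acids multiplied by the faecal
  digestibility factor of its food group;
* utilizable protein — digestible protein multiplied by a per-meal-occasion
  similarity factor: the capped minimum, over the nine indispensable amino
  acids, of the meal's mg-per-g-protein content relative to the reference
  pattern.  Scoring happens within each of the 7 daily eating occasions
  (3 main meals, 4 in-between moments), because amino acids complement each
  other only when eaten within the same meal; daily utilizable protein is the
  sum over occasions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from plantshift.errors import FormatError, UnknownFoodError, ValidationError
from plantshift.food_composition import (
    AA_COLUMNS,
    IAA_KEYS,
    AminoAcidVector,
    FoodDatabase,
    ReferencePattern,
    _read_table,
)

#: The 7 recognised eating occasions of one recall day.
OCCASIONS: tuple[str, ...] = (
    "breakfast", "lunch", "dinner", "between1", "between2", "between3", "between4",
)

#: Occasions treated as main meals in reports.
MAIN_MEALS: tuple[str, ...] = ("breakfast", "lunch", "dinner")


@dataclass(frozen=True)
class ConsumptionEvent:
    """One food eaten by one participant on one day at one occasion."""

    participant_id: str
    day_index: int
    occasion: str
    food_id: str
    amount_g: float

    def __post_init__(self) -> None:
        if self.occasion not in OCCASIONS:
            raise ValidationError(
                f"unknown occasion {self.occasion!r}; expected one of {OCCASIONS}"
            )
        if self.amount_g < 0:
            raise ValidationError(f"negative amount_g {self.amount_g}")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    sex: str
    age_years: float
    body_weight_kg: float
    survey_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if not self.body_weight_kg > 0:
            raise ValidationError("body_weight_kg must be > 0")
        if self.survey_weight < 0:
            raise ValidationError("survey_weight must be >= 0")


@dataclass(frozen=True)
class OccasionProtein:
    occasion: str
    total_protein_g: float
    digestible_protein_g: float
    similarity_factor: float
    utilizable_protein_g: float


@dataclass(frozen=True)
class DailyProtein:
    participant_id: str
    day_index: int
    occasions: tuple[OccasionProtein, ...]
    total_protein_g: float
    digestible_protein_g: float
    utilizable_protein_g: float
    total_per_kg: float
    utilizable_per_kg: float


def occasion_amino_acids(
    events: Iterable[ConsumptionEvent], db: FoodDatabase, digested: bool
) -> AminoAcidVector:
    """Absolute amino-acid masses (mg) consumed at one occasion.

    Each event contributes amount_g/100 of its item's per-100 g profile,
    multiplied by the item's food-group digestibility factor when `digested`.
    An empty event list yields the zero vector.
    """
    acc = AminoAcidVector()
    for ev in events:
        item = db[ev.food_id]
        factor = ev.amount_g / 100.0
        if digested:
            factor *= db.digestibility[item.food_group]
        acc = acc + item.aa_profile.scaled(factor)
    return acc


def similarity_factor(
    occasion_aa: AminoAcidVector, pattern: ReferencePattern
) -> float:
    """Capped limiting-amino-acid score of one meal occasion, in (0, 1].

    The meal's amino acids per gram of meal protein are divided by the
    reference pattern; the minimum ratio over the nine IAAs, capped at 1, is
    the similarity factor.  A zero-protein occasion scores 1.0 by convention
    (utilizable protein is 0 either way, and the identity
    utilizable = factor x digestible then holds with both sides 0).
    """
    protein_g = occasion_aa.protein_g
    if protein_g == 0.0:
        return 1.0
    ratios = (
        (occasion_aa.iaa_mg(k) / protein_g) / pattern[k] for k in IAA_KEYS
    )
    return min(1.0, min(ratios))


def _score_occasion(
    events: Sequence[ConsumptionEvent], db: FoodDatabase, pattern: ReferencePattern,
    occasion: str,
) -> OccasionProtein:
    raw = occasion_amino_acids(events, db, digested=False)
    dig = occasion_amino_acids(events, db, digested=True)
    sf = similarity_factor(dig, pattern)
    return OccasionProtein(
        occasion=occasion,
        total_protein_g=raw.protein_g,
        digestible_protein_g=dig.protein_g,
        similarity_factor=sf,
        utilizable_protein_g=sf * dig.protein_g,
    )


def daily_protein(
    participant: Participant,
    events: Iterable[ConsumptionEvent],
    db: FoodDatabase,
    pattern: ReferencePattern,
) -> DailyProtein:
    """Score one participant-day: per-occasion records plus daily sums.

    Daily utilizable protein is the sum of the per-occasion utilizable
    values, not a whole-day rescoring — amino-acid complementation is only
    credited within a single occasion.
    """
    events = list(events)
    pids = {ev.participant_id for ev in events}
    if pids - {participant.participant_id}:
        raise ValidationError(
            f"events for {sorted(pids)} passed to daily_protein of "
            f"{participant.participant_id}"
        )
    days = {ev.day_index for ev in events}
    if len(days) > 1:
        raise ValidationError(f"events span multiple days: {sorted(days)}")
    day_index = days.pop() if days else 1

    per_occ = tuple(
        _score_occasion(
            [ev for ev in events if ev.occasion == occ], db, pattern, occ
        )
        for occ in OCCASIONS
    )
    total = sum(o.total_protein_g for o in per_occ)
    digestible = sum(o.digestible_protein_g for o in per_occ)
    utilizable = sum(o.utilizable_protein_g for o in per_occ)
    return DailyProtein(
        participant_id=participant.participant_id,
        day_index=day_index,
        occasions=per_occ,
        total_protein_g=total,
        digestible_protein_g=digestible,
        utilizable_protein_g=utilizable,
        total_per_kg=total / participant.body_weight_kg,
        utilizable_per_kg=utilizable / participant.body_weight_kg,
    )


# ----------------------------------------------------------------- frames

def score_consumption(
    consumption: pd.DataFrame,
    participants: pd.DataFrame,
    db: FoodDatabase,
    pattern: ReferencePattern,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised population scoring.

    Parameters
    ----------
    consumption
        Columns participant_id, day, occasion, food_id, amount_g.
    participants
        Columns participant_id, sex, age, body_weight_kg, survey_weight.

    Returns
    -------
    (occasion_df, daily_df)
        occasion_df: one row per participant x day x occasion with
        total/digestible/utilizable protein and the similarity factor;
        daily_df: one row per participant x day with daily sums, per-kg
        values and the participant attributes merged in.
    """
    unknown = set(consumption["food_id"]) - set(db.to_frame().index)
    if unknown:
        raise UnknownFoodError(
            f"unknown food_id(s) in consumption: {sorted(unknown)[:5]}"
        )
    items = db.to_frame()
    ev = consumption.merge(
        items[list(AA_COLUMNS) + ["digestibility"]],
        left_on="food_id", right_index=True, how="left", sort=False,
    )
    scale = ev["amount_g"].to_numpy() / 100.0
    aa_raw = ev[list(AA_COLUMNS)].to_numpy() * scale[:, None]
    aa_dig = aa_raw * ev["digestibility"].to_numpy()[:, None]

    keys = ev[["participant_id", "day", "occasion"]]
    raw_cols = pd.DataFrame(aa_raw, columns=[f"raw_{c}" for c in AA_COLUMNS],
                            index=ev.index)
    dig_cols = pd.DataFrame(aa_dig, columns=[f"dig_{c}" for c in AA_COLUMNS],
                            index=ev.index)
    grouped = (
        pd.concat([keys, raw_cols, dig_cols], axis=1)
        .groupby(["participant_id", "day", "occasion"], sort=False, observed=True)
        .sum()
    )

    dig_mat = grouped[[f"dig_{c}" for c in AA_COLUMNS]].to_numpy()
    total_g = grouped[[f"raw_{c}" for c in AA_COLUMNS]].to_numpy().sum(axis=1) / 1000.0
    dig_g = dig_mat.sum(axis=1) / 1000.0
    pattern_vec = np.array([pattern[k] for k in IAA_KEYS])
    # mg IAA per g meal protein, scored against the pattern; zero-protein
    # occasions get a dummy denominator and are forced to factor 1 below
    safe_g = np.where(dig_g == 0.0, 1.0, dig_g)
    ratios = dig_mat[:, : len(IAA_KEYS)] / safe_g[:, None] / pattern_vec
    sf = np.minimum(1.0, ratios.min(axis=1))
    sf = np.where(dig_g == 0.0, 1.0, sf)

    occasion_df = grouped.index.to_frame(index=False)
    occasion_df["total_protein_g"] = total_g
    occasion_df["digestible_protein_g"] = dig_g
    occasion_df["similarity_factor"] = sf
    occasion_df["utilizable_protein_g"] = sf * dig_g

    daily_df = (
        occasion_df.groupby(["participant_id", "day"], sort=False, observed=True)[
            ["total_protein_g", "digestible_protein_g", "utilizable_protein_g"]
        ]
        .sum()
        .reset_index()
        .merge(participants, on="participant_id", how="left", sort=False)
    )
    daily_df["total_per_kg"] = daily_df["total_protein_g"] / daily_df["body_weight_kg"]
    daily_df["utilizable_per_kg"] = (
        daily_df["utilizable_protein_g"] / daily_df["body_weight_kg"]
    )
    return occasion_df, daily_df


def load_consumption(path: str | Path) -> pd.DataFrame:
    """Load a consumption table (participant_id, day, occasion, food_id, amount_g)."""
    df = _read_table(path, ("participant_id", "day", "occasion", "food_id", "amount_g"))
    bad = set(df["occasion"]) - set(OCCASIONS)
    if bad:
        raise FormatError(f"{path}: unknown occasion label(s) {sorted(bad)}")
    if (df["amount_g"] < 0).any():
        raise ValidationError(f"{path}: negative amount_g present")
    df["participant_id"] = df["participant_id"].astype(str)
    df["food_id"] = df["food_id"].astype(str)
    return df


def load_participants(path: str | Path) -> pd.DataFrame:
    """Load a participant table (participant_id, sex, age, body_weight_kg, survey_weight)."""
    df = _read_table(
        path, ("participant_id", "sex", "age", "body_weight_kg", "survey_weight")
    )
    if (df["body_weight_kg"] <= 0).any():
        raise ValidationError(f"{path}: non-positive body weight present")
    if df["participant_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate participant_id")
    df["participant_id"] = df["participant_id"].astype(str)
    return df
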