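"""Food composition data model and I/O.

Protein arithmetic in this package is amino-acid based throughout: the total
protein of a food is the sum of its amino-acid masses (indispensable plus a
pooled dispensable remainder), never a nitrogen-times-6.25 conversion, because
nitrogen factors overestimate protein for most food groups.  Each food item
carries a full indispensable-amino-acid (IAA) profile per 100 g edible
portion, a food-group assignment that resolves to a faecal digestibility
factor, category flags driving scenario disqualification, and the fraction of
its protein that is animal-derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from plantshift.errors import (
    ConfigurationError,
    FormatError,
    UnknownFoodError,
    ValidationError,
)

#: The nine indispensable amino acids scored against the reference pattern.
#: Sulfur AAs (Met+Cys) and aromatic AAs (Phe+Tyr) are pooled, as is standard
#: in PDCAAS scoring.
IAA_KEYS: tuple[str, ...] = (
    "his", "ile", "leu", "lys", "saa", "aaa", "thr", "trp", "val",
)

#: Column order of amino-acid masses in composition files (mg per 100 g).
AA_COLUMNS: tuple[str, ...] = tuple(f"{k}_mg" for k in IAA_KEYS) + ("disp_aa_mg",)

#: Category flags recognised by the scenario engine.
CATEGORY_FLAGS: frozenset[str] = frozenset(
    {"meat", "fish", "dairy", "egg", "cheese", "minor_animal_content"}
)

_ANIMAL_PRIMARY = {"meat", "fish"}
_ANIMAL_SECONDARY = {"dairy", "egg", "cheese"}

_COMPOSITION_COLUMNS = (
    "food_id", "name", "food_group", *AA_COLUMNS,
    "flags", "animal_protein_fraction", "label_protein_g", "kcal",
)


@dataclass(frozen=True)
class AminoAcidVector:
    """Amino-acid masses in mg (per 100 g for a food, absolute for a meal).

    The nine IAA components are scored against the reference pattern; the
    pooled dispensable remainder only contributes to total protein.
    """

    his_mg: float = 0.0
    ile_mg: float = 0.0
    leu_mg: float = 0.0
    lys_mg: float = 0.0
    saa_mg: float = 0.0
    aaa_mg: float = 0.0
    thr_mg: float = 0.0
    trp_mg: float = 0.0
    val_mg: float = 0.0
    dispensable_aa_mg: float = 0.0

    def __post_init__(self) -> None:
        for key, value in self.as_dict().items():
            if value < 0 or math.isnan(value):
                raise ValidationError(f"negative or NaN amino-acid mass for {key}: {value}")

    def iaa_mg(self, key: str) -> float:
        return getattr(self, f"{key}_mg")

    def as_dict(self) -> dict[str, float]:
        d = {key: self.iaa_mg(key) for key in IAA_KEYS}
        d["dispensable"] = self.dispensable_aa_mg
        return d

    @property
    def total_mg(self) -> float:
        """Total amino-acid mass; protein in g is this / 1000."""
        return sum(self.as_dict().values())

    @property
    def protein_g(self) -> float:
        return self.total_mg / 1000.0

    def scaled(self, factor: float) -> "AminoAcidVector":
        return AminoAcidVector(
            **{f"{k}_mg": self.iaa_mg(k) * factor for k in IAA_KEYS},
            dispensable_aa_mg=self.dispensable_aa_mg * factor,
        )

    def __add__(self, other: "AminoAcidVector") -> "AminoAcidVector":
        return AminoAcidVector(
            **{f"{k}_mg": self.iaa_mg(k) + other.iaa_mg(k) for k in IAA_KEYS},
            dispensable_aa_mg=self.dispensable_aa_mg + other.dispensable_aa_mg,
        )


@dataclass(frozen=True)
class FoodItem:
    """One food of the composition database.

    `label_protein_g_per_100g` and `kcal_per_100g` are label metadata (the
    nitrogen-based values printed in food composition tables); they are never
    used in amino-acid arithmetic.
    """

    food_id: str
    name: str
    food_group: str
    aa_profile: AminoAcidVector
    category_flags: frozenset[str] = frozenset()
    animal_protein_fraction: float = 0.0
    label_protein_g_per_100g: float | None = None
    kcal_per_100g: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.category_flags) - CATEGORY_FLAGS
        if unknown:
            raise ValidationError(
                f"{self.food_id}: unknown category flags {sorted(unknown)}"
            )
        if self.category_flags & _ANIMAL_PRIMARY and self.category_flags & _ANIMAL_SECONDARY:
            raise ValidationError(
                f"{self.food_id}: flags {sorted(self.category_flags)} mix meat/fish "
                "with dairy/egg/cheese; composite items belong to their own group "
                "with a single flag set"
            )
        if not 0.0 <= self.animal_protein_fraction <= 1.0:
            raise ValidationError(
                f"{self.food_id}: animal_protein_fraction "
                f"{self.animal_protein_fraction} outside [0, 1]"
            )


def total_protein_per_100g(item: FoodItem) -> float:
    """Total protein in g per 100 g, as the sum of all amino-acid masses."""
    return item.aa_profile.protein_g


class DigestibilityTable:
    """Faecal protein digestibility factor per food group, each in (0, 1]."""

    def __init__(self, factors: Mapping[str, float]):
        for group, f in factors.items():
            if not 0.0 < f <= 1.0:
                raise ValidationError(
                    f"digestibility for group {group!r} is {f}, outside (0, 1]"
                )
        self._factors = dict(factors)

    def __getitem__(self, food_group: str) -> float:
        try:
            return self._factors[food_group]
        except KeyError:
            raise ValidationError(
                f"food group {food_group!r} has no digestibility factor"
            ) from None

    def __contains__(self, food_group: str) -> bool:
        return food_group in self._factors

    def __len__(self) -> int:
        return len(self._factors)

    def groups(self) -> set[str]:
        return set(self._factors)

    def as_dict(self) -> dict[str, float]:
        return dict(self._factors)


class ReferencePattern:
    """IAA requirement pattern in mg per g protein, covering all nine IAAs."""

    def __init__(self, requirements: Mapping[str, float]):
        missing = set(IAA_KEYS) - set(requirements)
        if missing:
            raise ConfigurationError(
                f"reference pattern missing IAA keys: {sorted(missing)}"
            )
        extra = set(requirements) - set(IAA_KEYS)
        if extra:
            raise ConfigurationError(
                f"reference pattern has unknown IAA keys: {sorted(extra)}"
            )
        for key, value in requirements.items():
            if not value > 0:
                raise ConfigurationError(
                    f"reference pattern value for {key} must be > 0, got {value}"
                )
        self._req = {k: float(requirements[k]) for k in IAA_KEYS}

    def __getitem__(self, iaa: str) -> float:
        return self._req[iaa]

    def as_dict(self) -> dict[str, float]:
        return dict(self._req)


class FoodDatabase:
    """Validated collection of FoodItem plus the attached digestibility table.

    Refuses items whose food group has no digestibility factor — incomplete
    items must be fixed or replaced upstream, never silently imputed.
    """

    def __init__(self, items: Iterable[FoodItem], digestibility: DigestibilityTable):
        self.digestibility = digestibility
        self._items: dict[str, FoodItem] = {}
        orphans: list[str] = []
        for item in items:
            if item.food_id in self._items:
                raise ValidationError(f"duplicate food_id {item.food_id!r}")
            if item.food_group not in digestibility:
                orphans.append(item.food_id)
            self._items[item.food_id] = item
        if orphans:
            raise ValidationError(
                "food groups without digestibility factor for items: "
                + ", ".join(sorted(orphans))
            )
        self._frame: pd.DataFrame | None = None

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._items[food_id]
        except KeyError:
            raise UnknownFoodError(f"unknown food_id {food_id!r}") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._items.values())

    def item_digestibility(self, food_id: str) -> float:
        return self.digestibility[self[food_id].food_group]

    def to_frame(self) -> pd.DataFrame:
        """Item attributes as a DataFrame indexed by food_id (cached).

        Columns: the AA masses (mg/100 g), digestibility, animal fraction,
        group, flags, protein_g_100g (AA-derived). Used by the vectorised
        scoring paths.
        """
        if self._frame is None:
            rows = []
            for it in self:
                row = {"food_id": it.food_id, "name": it.name,
                       "food_group": it.food_group}
                for k in IAA_KEYS:
                    row[f"{k}_mg"] = it.aa_profile.iaa_mg(k)
                row["disp_aa_mg"] = it.aa_profile.dispensable_aa_mg
                row["digestibility"] = self.digestibility[it.food_group]
                row["animal_protein_fraction"] = it.animal_protein_fraction
                row["flags"] = ";".join(sorted(it.category_flags))
                row["protein_g_100g"] = it.aa_profile.protein_g
                rows.append(row)
            self._frame = pd.DataFrame(rows).set_index("food_id")
        return self._frame

    # ------------------------------------------------------------------ I/O

    def save(self, composition_file: str | Path, digestibility_file: str | Path) -> None:
        """Write the database back to the delimited-text dialect it loads from."""
        comp = pd.DataFrame(
            [
                {
                    "food_id": it.food_id,
                    "name": it.name,
                    "food_group": it.food_group,
                    **{f"{k}_mg": it.aa_profile.iaa_mg(k) for k in IAA_KEYS},
                    "disp_aa_mg": it.aa_profile.dispensable_aa_mg,
                    "flags": ";".join(sorted(it.category_flags)),
                    "animal_protein_fraction": it.animal_protein_fraction,
                    "label_protein_g": it.label_protein_g_per_100g,
                    "kcal": it.kcal_per_100g,
                }
                for it in self
            ],
            columns=list(_COMPOSITION_COLUMNS),
        )
        # repr keeps full float precision so a save/load cycle is lossless
        comp.to_csv(composition_file, sep=_sep_for(composition_file), index=False,
                    float_format=lambda v: repr(float(v)))
        dig = pd.DataFrame(
            sorted(self.digestibility.as_dict().items()),
            columns=["food_group", "digestibility"],
        )
        dig.to_csv(digestibility_file, sep=_sep_for(digestibility_file), index=False,
                   float_format=lambda v: repr(float(v)))


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), comment="#",
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_flags(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(p for p in str(raw).split(";") if p)


def load_food_database(
    composition_file: str | Path, digestibility_file: str | Path
) -> FoodDatabase:
    """Load and validate a food database from delimited text files.

    The composition file has one row per food item with AA masses in mg per
    100 g; the digestibility file maps food groups to factors in (0, 1].
    Separator is tab for .tsv/.tab, comma otherwise.
    """
    dig_df = _read_table(digestibility_file, ("food_group", "digestibility"))
    digestibility = DigestibilityTable(
        dict(zip(dig_df["food_group"].astype(str), dig_df["digestibility"].astype(float)))
    )

    comp = _read_table(composition_file, _COMPOSITION_COLUMNS[:-2])  # metadata optional
    if comp.empty:
        raise ValidationError(f"{composition_file}: composition file has no items")

    items = []
    for rec in comp.to_dict("records"):
        aa_kwargs = {f"{k}_mg": float(rec[f"{k}_mg"]) for k in IAA_KEYS}
        try:
            profile = AminoAcidVector(**aa_kwargs, dispensable_aa_mg=float(rec["disp_aa_mg"]))
        except ValidationError as exc:
            raise ValidationError(f"{rec['food_id']}: {exc}") from None
        label = rec.get("label_protein_g")
        kcal = rec.get("kcal")
        items.append(
            FoodItem(
                food_id=str(rec["food_id"]),
                name=str(rec["name"]),
                food_group=str(rec["food_group"]),
                aa_profile=profile,
                category_flags=_parse_flags(rec.get("flags")),
                animal_protein_fraction=float(rec["animal_protein_fraction"]),
                label_protein_g_per_100g=None if pd.isna(label) else float(label),
                kcal_per_100g=None if pd.isna(kcal) else float(kcal),
            )
        )
    return FoodDatabase(items, digestibility)


def load_reference_pattern(path: str | Path) -> ReferencePattern:
    """Load an IAA scoring pattern (columns iaa, mg_per_g_protein)."""
    df = _read_table(path, ("iaa", "mg_per_g_protein"))
    return ReferencePattern(
        dict(zip(df["iaa"].astype(str), df["mg_per_g_protein"].astype(float)))
    )


def who_2007_pattern() -> ReferencePattern:
    """The packaged default scoring pattern (WHO/FAO/UNU 2007, adults).

    Loaded from the package data file so an alternative pattern can be swapped
    in via :func:`load_reference_pattern`.
    """
    ref = resources.files("plantshift.data").joinpath("who_2007_adult_pattern.csv")
    with resources.as_file(ref) as path:
        return load_reference_pattern(path)
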