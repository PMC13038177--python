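"""Typed long-format rating tables, schema validation, and participant cleaning.

All downstream analyses consume a :class:`RatingTable`: one row per
(perceiver, subject, trait) Likert rating on a 1-7 scale.  The subject is
either an individual face target (identified by an opaque id) or a social
category rated in the abstract.  Social categories are the six crossings of
target race (White, Black, East Asian) and target gender (female, male).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A row violates a value constraint (e.g. rating outside 1-7)."""


class ConfigurationError(ValueError):
    """An option was requested that the data cannot support."""


class Race(str, enum.Enum):
    WHITE = "White"
    BLACK = "Black"
    EAST_ASIAN = "East Asian"


class Gender(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


@dataclass(frozen=True, order=True)
class GroupKey:
    """One of the six target race x gender social categories."""

    race: Race
    gender: Gender

    def __str__(self) -> str:  # stable rendering, e.g. "East Asian female"
        return f"{self.race.value} {self.gender.value}"

    @classmethod
    def parse(cls, race: str, gender: str) -> "GroupKey":
        return cls(Race(race), Gender(gender))

    @classmethod
    def from_string(cls, s: str) -> "GroupKey":
        race_str, _, gender_str = s.rpartition(" ")
        return cls(Race(race_str), Gender(gender_str))


#: Canonical declared ordering of the six social categories.
ALL_GROUPS: tuple[GroupKey, ...] = tuple(
    GroupKey(race, gender)
    for race in (Race.WHITE, Race.BLACK, Race.EAST_ASIAN)
    for gender in (Gender.FEMALE, Gender.MALE)
)

#: The 14 traits rated in the large between-subjects face-impression study,
#: in alphabetical order (canonical lower-case form).
STUDY1_TRAITS: tuple[str, ...] = (
    "aggressive",
    "assertive",
    "attractive",
    "caring",
    "competent",
    "dominant",
    "friendly",
    "healthy",
    "intelligent",
    "physically strong",
    "smart",
    "trustworthy",
    "warm",
    "youthful",
)

#: The reduced 6-trait set used in the within-subjects study.
STUDY2_TRAITS: tuple[str, ...] = (
    "aggressive",
    "attractive",
    "friendly",
    "healthy",
    "intelligent",
    "physically strong",
)


class Design(str, enum.Enum):
    """Which study design produced the ratings.

    face_between
        Face ratings where each perceiver rates targets on a single trait
        (between-subjects trait assignment).
    group_abstract
        Abstract stereotype ratings of a social category, all traits per
        perceiver.
    face_within
        Face ratings where each perceiver rates every target on every trait.
    pairwise_stereotype
        Pairwise stereotype-likelihood ratings ("how likely is an
        aggressive X to be attractive?").
    """

    FACE_BETWEEN = "face_between"
    GROUP_ABSTRACT = "group_abstract"
    FACE_WITHIN = "face_within"
    PAIRWISE_STEREOTYPE = "pairwise_stereotype"


_BASE_COLUMNS = ["perceiver_id", "subject", "race", "gender", "trait", "rating"]
_PAIRWISE_COLUMNS = [
    "perceiver_id",
    "subject",
    "race",
    "gender",
    "trait_given",
    "trait_asked",
    "rating",
]
_OPTIONAL_COLUMNS = ["perceiver_race"]


def canonical_trait(name: str) -> str:
    """Canonical trait form: trimmed, lower-case."""
    return str(name).strip().lower()


@dataclass
class RatingTable:
    """Validated long-format rating data.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per rating.  Columns ``perceiver_id, subject, race, gender,
        trait, rating`` (plus ``trait_given``/``trait_asked`` instead of
        ``trait`` for the pairwise design, and optionally
        ``perceiver_race``).
    design : Design
    trait_set : tuple of str
        Declared ordered trait names (canonical form); the order fixes the
        canonical trait-pair ordering downstream.
    """

    df: pd.DataFrame
    design: Design
    trait_set: tuple[str, ...]
    #: integer 1-7 Likert contract; disable only for continuous synthetic
    #: latent-scale ratings used in recovery checks
    likert: bool = True

    def __post_init__(self) -> None:
        self.design = Design(self.design)
        self.trait_set = tuple(canonical_trait(t) for t in self.trait_set)
        if len(set(self.trait_set)) != len(self.trait_set):
            raise ValidationError("trait_set contains duplicate names")
        self.df = _validate_frame(self.df, self.design, self.trait_set, self.likert)

    # -- convenience -------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def perceivers(self) -> list[str]:
        return list(pd.unique(self.df["perceiver_id"]))

    def groups(self) -> list[GroupKey]:
        seen = self.df[["race", "gender"]].drop_duplicates()
        present = {GroupKey.parse(r, g) for r, g in seen.itertuples(index=False)}
        return [g for g in ALL_GROUPS if g in present]

    def group_mask(self, group: GroupKey) -> pd.Series:
        return (self.df["race"] == group.race.value) & (
            self.df["gender"] == group.gender.value
        )

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _validate_frame(
    df: pd.DataFrame, design: Design, trait_set: tuple[str, ...], likert: bool = True
) -> pd.DataFrame:
    required = (
        _PAIRWISE_COLUMNS if design is Design.PAIRWISE_STEREOTYPE else _BASE_COLUMNS
    )
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    keep = [c for c in required + _OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()

    ratings = pd.to_numeric(df["rating"], errors="coerce")
    if likert:
        bad = (
            ratings.isna()
            | (ratings != ratings.round())
            | (ratings < 1)
            | (ratings > 7)
        )
        if bad.any():
            idx = int(df.index[bad][0])
            raise ValidationError(
                f"rating outside 1-7 (or non-integer) at row {idx}: "
                f"{df['rating'].iloc[int(bad.to_numpy().argmax())]!r}"
            )
        df["rating"] = ratings.astype(int)
    else:
        if not np.isfinite(ratings.to_numpy(dtype=float)).all():
            raise ValidationError("non-numeric rating in continuous-scale table")
        df["rating"] = ratings.astype(float)

    try:
        for r, g in df[["race", "gender"]].drop_duplicates().itertuples(index=False):
            GroupKey.parse(r, g)
    except ValueError as exc:
        raise ValidationError(f"unknown race/gender label: {exc}") from exc

    trait_cols = (
        ["trait_given", "trait_asked"]
        if design is Design.PAIRWISE_STEREOTYPE
        else ["trait"]
    )
    declared = set(trait_set)
    for col in trait_cols:
        df[col] = df[col].map(canonical_trait)
        unknown = set(df[col]) - declared
        if unknown:
            raise ValidationError(
                f"traits not in declared trait set: {sorted(unknown)}"
            )
    if design is Design.PAIRWISE_STEREOTYPE:
        same = df["trait_given"] == df["trait_asked"]
        if same.any():
            raise ValidationError(
                f"trait_given equals trait_asked at row {int(df.index[same][0])}"
            )

    if design in (Design.FACE_WITHIN, Design.GROUP_ABSTRACT):
        dup = df.duplicated(subset=["perceiver_id", "subject", "trait"])
        if dup.any():
            raise ValidationError(
                "duplicate (perceiver, subject, trait) key at row "
                f"{int(df.index[dup][0])}"
            )
    return df.reset_index(drop=True)


def load_ratings(
    path: str | Path,
    design: Design | str,
    trait_set: Sequence[str],
) -> RatingTable:
    """Read a ratings CSV and return a validated :class:`RatingTable`.

    The file must be UTF-8, comma-separated, with a header row containing
    ``perceiver_id, subject, race, gender, trait, rating`` (``trait_given``
    and ``trait_asked`` replace ``trait`` for the pairwise design).  Row
    order is preserved.
    """
    df = pd.read_csv(path, dtype={"perceiver_id": str, "subject": str})
    return RatingTable(df=df, design=Design(design), trait_set=tuple(trait_set))


@dataclass
class CleaningReport:
    """Per-rule counts of removed perceivers.

    Counts are perceivers, not rows; each perceiver is counted once, under
    the first rule that removed them.
    """

    n_in: int
    n_removed_zero_variance: int = 0
    n_removed_optout: int = 0
    n_removed_race_filter: int = 0
    n_removed_custom: int = 0
    n_out: int = 0

    def __post_init__(self) -> None:
        expected = (
            self.n_in
            - self.n_removed_zero_variance
            - self.n_removed_optout
            - self.n_removed_race_filter
            - self.n_removed_custom
        )
        if self.n_out != expected or min(
            self.n_in,
            self.n_removed_zero_variance,
            self.n_removed_optout,
            self.n_removed_race_filter,
            self.n_removed_custom,
            self.n_out,
        ) < 0:
            raise ValidationError("cleaning report counts do not reconcile")


def clean_participants(
    table: RatingTable,
    drop_zero_variance: bool = True,
    optout_ids: Iterable[str] = (),
    perceiver_race_filter: Optional[Sequence[str]] = None,
    custom_predicate: Optional[Callable[[str, pd.DataFrame], bool]] = None,
) -> tuple[RatingTable, CleaningReport]:
    """Remove perceivers according to the study's cleaning rules.

    Rules apply in a fixed order, and a perceiver is counted under the first
    rule that removes them:

    1. ``drop_zero_variance`` -- perceivers whose ratings are all identical
       across every trait and subject ("no variation in their responses").
    2. ``optout_ids`` -- perceivers who asked that their data not be used.
    3. ``perceiver_race_filter`` -- keep only perceivers whose
       ``perceiver_race`` label is in the given list (exact match); requires
       a ``perceiver_race`` column.
    4. ``custom_predicate(perceiver_id, sub_df) -> bool`` -- pluggable hook
       (e.g. response-time rules); ``True`` removes the perceiver.

    Cleaning is idempotent: applying it twice with the same arguments equals
    applying it once.
    """
    df = table.df
    optout = {str(i) for i in optout_ids}
    if perceiver_race_filter is not None and "perceiver_race" not in df.columns:
        raise ConfigurationError(
            "perceiver_race_filter requested but table has no "
            "'perceiver_race' column"
        )
    keep_races = set(perceiver_race_filter) if perceiver_race_filter else None

    removed = {"zero_variance": 0, "optout": 0, "race": 0, "custom": 0}
    keep_ids: list[str] = []
    for pid, sub in df.groupby("perceiver_id", sort=False):
        if drop_zero_variance and sub["rating"].nunique() == 1:
            removed["zero_variance"] += 1
        elif pid in optout:
            removed["optout"] += 1
        elif keep_races is not None and not set(sub["perceiver_race"]) <= keep_races:
            removed["race"] += 1
        elif custom_predicate is not None and custom_predicate(str(pid), sub):
            removed["custom"] += 1
        else:
            keep_ids.append(pid)

    out_df = df[df["perceiver_id"].isin(keep_ids)].reset_index(drop=True)
    n_in = df["perceiver_id"].nunique()
    report = CleaningReport(
        n_in=n_in,
        n_removed_zero_variance=removed["zero_variance"],
        n_removed_optout=removed["optout"],
        n_removed_race_filter=removed["race"],
        n_removed_custom=removed["custom"],
        n_out=len(keep_ids),
    )
    cleaned = RatingTable(
        df=out_df,
        design=table.design,
        trait_set=table.trait_set,
        likert=table.likert,
    )
    return cleaned, report
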