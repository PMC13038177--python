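"""Per-group trait-pair correlation structure ("trait spaces").

A group's trait space is the k x k Pearson correlation matrix among trait
ratings, computed over a stated correlation unit:

``targets``
    across target-level mean ratings (between-subjects face ratings, where
    each perceiver contributed a single trait and correlations within a
    rater are impossible);
``perceivers``
    across participants' abstract ratings of the social category itself;
``within_perceiver_targets``
    across one perceiver's own targets of a group (within-subjects face
    ratings).

The matrix is then reduced to its strictly-upper-triangular trait-pair
vector (k(k-1)/2 entries), Fisher-z transformed, and the per-group vectors
are stacked into a single labeled column; optionally each trait pair is
mean-centered across groups so that only group-specific deviations remain.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ALL_GROUPS,
    Design,
    GroupKey,
    RatingTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    """Requested group or slice contains no data."""


class InsufficientDataError(ValueError):
    """Fewer than the minimum number of units to correlate."""


class IntegrityError(ValueError):
    """Structural inconsistency (asymmetry, duplicate labels...)."""


class StateError(ValueError):
    """Operation invalid for the object's current state (e.g. re-centering)."""


class Unit(str, enum.Enum):
    TARGETS = "targets"
    PERCEIVERS = "perceivers"
    WITHIN_PERCEIVER_TARGETS = "within_perceiver_targets"


class Scale(str, enum.Enum):
    R = "r"
    Z = "z"


MIN_UNITS = 3  # Pearson is degenerate below 3 complete observations


# ---------------------------------------------------------------------------
# Fisher transform


def fisher_z(r):
    """Fisher variance-stabilizing transform z = arctanh(r).

    Accepts scalars or arrays.  |r| = 1 is clamped to 1 - 1e-12 before the
    transform so that degenerate small-sample correlations stay finite;
    |r| > 1 raises.  NaN propagates.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
    clamped = np.clip(arr, -1 + 1e-12, 1 - 1e-12)
    out = np.arctanh(clamped)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def inverse_fisher_z(z):
    """Exact analytic inverse of :func:`fisher_z` (tanh)."""
    arr = np.asarray(z, dtype=float)
    out = np.tanh(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Containers


@dataclass
class TargetTraitMatrix:
    """Per-target mean ratings for one group (targets x traits).

    ``means`` holds NaN where a target was never rated on a trait; means lie
    in [1, 7] wherever defined and ``n_ratings`` counts contributing
    ratings per cell.
    """

    group: GroupKey
    targets: list[str]
    traits: list[str]
    means: pd.DataFrame  # index = targets, columns = traits
    n_ratings: pd.DataFrame


@dataclass
class TraitCorrelationMatrix:
    """Symmetric trait-pair Pearson correlation matrix for one group."""

    group: GroupKey
    traits: list[str]
    r: pd.DataFrame  # k x k, diagonal 1, NaN marks undefined pairs
    n_units: int
    unit: Unit
    scale: Scale = Scale.R


@dataclass
class TraitPairVector:
    """Upper-triangle trait-pair values for one group, canonical order."""

    group: GroupKey
    pairs: list[tuple[str, str]]
    values: np.ndarray
    scale: Scale

    def __len__(self) -> int:
        return len(self.pairs)


def canonical_pairs(traits: Sequence[str]) -> list[tuple[str, str]]:
    """Row-major upper-triangle ordering of unordered trait pairs."""
    return list(combinations(traits, 2))


@dataclass
class StackedSpace:
    """Concatenation of per-group trait-pair vectors into one labeled column.

    ``data`` columns: race, gender, trait_a, trait_b, value.  Row order is
    groups in declared order, pairs in canonical order within each group.
    """

    data: pd.DataFrame
    scale: Scale
    centered: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy()

    @property
    def row_labels(self) -> list[tuple[str, str, str, str]]:
        return list(
            self.data[["race", "gender", "trait_a", "trait_b"]].itertuples(
                index=False, name=None
            )
        )

    def __len__(self) -> int:
        return len(self.data)

    def groups(self) -> list[GroupKey]:
        seen = self.data[["race", "gender"]].drop_duplicates()
        return [GroupKey.parse(r, g) for r, g in seen.itertuples(index=False)]

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["scale"] = self.scale.value
        out["centered"] = self.centered
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "StackedSpace":
        df = pd.read_csv(path)
        required = {"race", "gender", "trait_a", "trait_b", "value", "scale", "centered"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"stacked-space CSV missing columns {sorted(missing)}")
        scale = Scale(df["scale"].iloc[0])
        centered = bool(df["centered"].iloc[0])
        return cls(
            data=df[["race", "gender", "trait_a", "trait_b", "value"]].copy(),
            scale=scale,
            centered=centered,
        )


# ---------------------------------------------------------------------------
# Operations


def target_trait_means(table: RatingTable, group: GroupKey) -> TargetTraitMatrix:
    """Aggregate between-subjects face ratings to target-level trait means.

    Cell (target, trait) is the unweighted arithmetic mean of all ratings of
    that target on that trait; never-rated cells are NaN, not 0.
    """
    if table.design is not Design.FACE_BETWEEN:
        raise ValidationError("target_trait_means requires a face_between table")
    sub = table.df[table.group_mask(group)]
    if sub.empty:
        raise EmptyInputError(f"no ratings for group {group}")
    means = sub.pivot_table(
        index="subject", columns="trait", values="rating", aggfunc="mean"
    )
    counts = sub.pivot_table(
        index="subject", columns="trait", values="rating", aggfunc="count"
    ).fillna(0).astype(int)
    traits = [t for t in table.trait_set if t in means.columns]
    means = means.reindex(columns=traits)
    counts = counts.reindex(columns=traits, fill_value=0)
    return TargetTraitMatrix(
        group=group,
        targets=list(means.index),
        traits=traits,
        means=means,
        n_ratings=counts,
    )


def _pairwise_corr(values: pd.DataFrame, group: GroupKey, unit: Unit) -> TraitCorrelationMatrix:
    """Pearson correlations over rows of a units x traits frame.

    Pairwise-complete over rows; a pair with < MIN_UNITS complete rows
    raises; a pair with zero variance in either trait is marked NaN.
    """
    traits = list(values.columns)
    k = len(traits)
    arr = values.to_numpy(dtype=float)
    r = np.eye(k)
    n_missing = 0
    for i, j in combinations(range(k), 2):
        cols = arr[:, [i, j]]
        ok = ~np.isnan(cols).any(axis=1)
        n = int(ok.sum())
        if n < MIN_UNITS:
            raise InsufficientDataError(
                f"pair ({traits[i]!r}, {traits[j]!r}) has {n} complete units "
                f"(< {MIN_UNITS}) in group {group}"
            )
        x, y = cols[ok, 0], cols[ok, 1]
        if x.std() == 0 or y.std() == 0:
            r[i, j] = r[j, i] = np.nan
            n_missing += 1
        else:
            r[i, j] = r[j, i] = np.corrcoef(x, y)[0, 1]
    if n_missing:
        logger.info(
            "group %s: %d trait pair(s) undefined (zero variance), marked missing",
            group,
            n_missing,
        )
    frame = pd.DataFrame(r, index=traits, columns=traits)
    return TraitCorrelationMatrix(
        group=group,
        traits=traits,
        r=frame,
        n_units=len(values),
        unit=unit,
    )


def trait_correlation_matrix(
    data: TargetTraitMatrix | RatingTable,
    unit: Unit | str,
    group: Optional[GroupKey] = None,
    perceiver_id: Optional[str] = None,
) -> TraitCorrelationMatrix:
    """Build a group's trait-pair Pearson correlation matrix.

    The correlation unit must match the design that produced the data:

    - ``unit=targets`` with a :class:`TargetTraitMatrix` — correlate across
      target means (between-subjects face ratings);
    - ``unit=perceivers`` with a ``group_abstract`` table and ``group`` —
      correlate across participants' abstract category ratings;
    - ``unit=within_perceiver_targets`` with a ``face_within`` table,
      ``group`` and ``perceiver_id`` — correlate across the perceiver's own
      targets within the group.
    """
    unit = Unit(unit)
    if unit is Unit.TARGETS:
        if not isinstance(data, TargetTraitMatrix):
            raise ValidationError("unit='targets' requires a TargetTraitMatrix")
        return _pairwise_corr(data.means, data.group, unit)

    if not isinstance(data, RatingTable):
        raise ValidationError(f"unit={unit.value!r} requires a RatingTable")
    if group is None:
        raise ValidationError("group is required for this unit")

    if unit is Unit.PERCEIVERS:
        if data.design is not Design.GROUP_ABSTRACT:
            raise ValidationError("unit='perceivers' requires a group_abstract table")
        sub = data.df[data.group_mask(group)]
        if sub.empty:
            raise EmptyInputError(f"no ratings for group {group}")
        wide = sub.pivot_table(
            index="perceiver_id", columns="trait", values="rating", aggfunc="mean"
        ).reindex(columns=[t for t in data.trait_set])
        return _pairwise_corr(wide, group, unit)

    # within_perceiver_targets
    if data.design is not Design.FACE_WITHIN:
        raise ValidationError(
            "unit='within_perceiver_targets' requires a face_within table"
        )
    if perceiver_id is None:
        raise ValidationError("perceiver_id is required for within-perceiver unit")
    sub = data.df[data.group_mask(group) & (data.df["perceiver_id"] == perceiver_id)]
    if sub.empty:
        raise EmptyInputError(f"no ratings for perceiver {perceiver_id}, group {group}")
    wide = sub.pivot_table(
        index="subject", columns="trait", values="rating", aggfunc="mean"
    ).reindex(columns=[t for t in data.trait_set])
    return _pairwise_corr(wide, group, Unit.WITHIN_PERCEIVER_TARGETS)


def vectorize_upper(m: TraitCorrelationMatrix, atol: float = 1e-10) -> TraitPairVector:
    """Strictly-upper-triangle entries of a symmetric matrix, canonical order."""
    arr = m.r.to_numpy(dtype=float)
    asym = np.nanmax(np.abs(arr - arr.T)) if arr.size else 0.0
    if asym > atol:
        raise IntegrityError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
    pairs = canonical_pairs(m.traits)
    iu = np.triu_indices(len(m.traits), k=1)
    return TraitPairVector(group=m.group, pairs=pairs, values=arr[iu], scale=m.scale)


def fisher_z_vector(v: TraitPairVector) -> TraitPairVector:
    """Fisher-z transform a trait-pair vector (r scale -> z scale)."""
    if v.scale is not Scale.R:
        raise StateError("vector already on z scale")
    return TraitPairVector(
        group=v.group, pairs=list(v.pairs), values=fisher_z(v.values), scale=Scale.Z
    )


def stack_groups(vectors: Sequence[TraitPairVector]) -> StackedSpace:
    """Concatenate per-group trait-pair vectors into a single stacked column."""
    if not vectors:
        raise EmptyInputError("no vectors to stack")
    ref_pairs = vectors[0].pairs
    scale = vectors[0].scale
    for v in vectors[1:]:
        if v.pairs != ref_pairs:
            diff = set(map(tuple, v.pairs)) ^ set(map(tuple, ref_pairs))
            raise IntegrityError(f"pair lists differ between groups: {sorted(diff)}")
        if v.scale is not scale:
            raise IntegrityError("mixed scales in stack")
    order = {g: i for i, g in enumerate(ALL_GROUPS)}
    vectors = sorted(vectors, key=lambda v: order.get(v.group, len(order)))
    frames = []
    for v in vectors:
        frames.append(
            pd.DataFrame(
                {
                    "race": v.group.race.value,
                    "gender": v.group.gender.value,
                    "trait_a": [a for a, _ in v.pairs],
                    "trait_b": [b for _, b in v.pairs],
                    "value": v.values,
                }
            )
        )
    return StackedSpace(data=pd.concat(frames, ignore_index=True), scale=scale)


def center_by_pair_mean(space: StackedSpace) -> StackedSpace:
    """Subtract each trait pair's mean value across groups (per-pair centering).

    Removes structure shared by all social categories, leaving only
    group-specific deviations.  Missing values are ignored in the pair mean.
    """
    if space.centered:
        raise StateError("space is already centered")
    df = space.data.copy()
    df["value"] = df["value"] - df.groupby(["trait_a", "trait_b"], sort=False)[
        "value"
    ].transform("mean")
    return StackedSpace(data=df, scale=space.scale, centered=True)


# ---------------------------------------------------------------------------
# Convenience pipelines


def face_space(
    table: RatingTable, groups: Sequence[GroupKey] = ALL_GROUPS, scale: Scale = Scale.Z
) -> StackedSpace:
    """Between-subjects face ratings -> stacked (optionally Fisher-z) space."""
    vectors = []
    for g in groups:
        ttm = target_trait_means(table, g)
        v = vectorize_upper(trait_correlation_matrix(ttm, Unit.TARGETS))
        vectors.append(fisher_z_vector(v) if scale is Scale.Z else v)
    return stack_groups(vectors)


def stereotype_space(
    table: RatingTable, groups: Sequence[GroupKey] = ALL_GROUPS, scale: Scale = Scale.Z
) -> StackedSpace:
    """Abstract category ratings -> stacked (optionally Fisher-z) space."""
    vectors = []
    for g in groups:
        v = vectorize_upper(
            trait_correlation_matrix(table, Unit.PERCEIVERS, group=g)
        )
        vectors.append(fisher_z_vector(v) if scale is Scale.Z else v)
    return stack_groups(vectors)
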