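"""Homogeneity of trait spaces across social categories.

The stacked trait-pair column is pivoted to a (trait pairs) x (groups)
table and analyzed with a 2 (target gender) x 3 (target race) fully
within-subjects ANOVA in which the trait pair is the repeated-measures
unit.  Because the cell entries are average trait-pair correlations, the
marginal means are interpretable as the overall homogeneity (average
interrelatedness) of each group's trait space.

Sphericity of the race factor and of the gender x race interaction is
checked with Mauchly's likelihood-ratio test, and Greenhouse-Geisser
epsilon (from the eigenvalues of the double-centered within-factor
covariance) is reported with corrected p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Gender, GroupKey, Race
from .trait_space import (
    IntegrityError,
    InsufficientDataError,
    Scale,
    StackedSpace,
    StateError,
    inverse_fisher_z,
)

logger = logging.getLogger(__name__)

GENDER_LEVELS = (Gender.FEMALE, Gender.MALE)
RACE_LEVELS = (Race.WHITE, Race.BLACK, Race.EAST_ASIAN)


@dataclass
class PairByGroupTable:
    """Trait pairs (rows) by social groups (columns) correlation table."""

    values: pd.DataFrame  # index: (trait_a, trait_b); columns: str(GroupKey)
    scale: Scale

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    def group_columns(self) -> list[GroupKey]:
        return [GroupKey.from_string(c) for c in self.values.columns]


def restructure_wide(space: StackedSpace) -> PairByGroupTable:
    """Lossless pivot of a stacked space to trait-pairs x groups."""
    if space.centered:
        raise StateError("restructure_wide expects an uncentered space")
    df = space.data
    dup = df.duplicated(subset=["race", "gender", "trait_a", "trait_b"])
    if dup.any():
        raise IntegrityError("duplicate (group, trait pair) rows in stack")
    col = df["race"].astype(str) + " " + df["gender"].astype(str)
    wide = df.assign(_group=col).pivot(
        index=["trait_a", "trait_b"], columns="_group", values="value"
    )
    # declared group order, then original pair order
    order = [
        str(GroupKey(r, g)) for g in GENDER_LEVELS for r in RACE_LEVELS
    ]
    wide = wide.reindex(columns=[c for c in order if c in wide.columns])
    pair_order = list(
        dict.fromkeys(zip(df["trait_a"], df["trait_b"]))
    )
    wide = wide.reindex(pd.MultiIndex.from_tuples(pair_order, names=["trait_a", "trait_b"]))
    return PairByGroupTable(values=wide, scale=space.scale)


def unpivot(table: PairByGroupTable) -> StackedSpace:
    """Inverse of :func:`restructure_wide` (order-normalized).

    Rows come back in declared group order with the table's own trait-pair
    order within each group.
    """
    from .data_model import ALL_GROUPS

    present = {GroupKey.from_string(c): c for c in table.values.columns}
    frames = []
    for g in ALL_GROUPS:
        if g not in present:
            continue
        col = table.values[present[g]]
        frames.append(
            pd.DataFrame(
                {
                    "race": g.race.value,
                    "gender": g.gender.value,
                    "trait_a": [a for a, _ in col.index],
                    "trait_b": [b for _, b in col.index],
                    "value": col.to_numpy(),
                }
            )
        )
    return StackedSpace(data=pd.concat(frames, ignore_index=True), scale=table.scale)


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class EffectResult:
    ss: float
    ss_error: float
    df_num: float
    df_den: float
    ms: float
    ms_error: float
    F: float
    p: float
    partial_eta_sq: float
    gg_epsilon: Optional[float] = None
    p_gg_corrected: Optional[float] = None
    mauchly_W: Optional[float] = None
    mauchly_chi2: Optional[float] = None
    mauchly_df: Optional[int] = None
    mauchly_p: Optional[float] = None


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]  # keys: gender, race, gender_x_race
    n_subjects: int
    n_dropped_incomplete: int
    ss_subject: float
    ss_total: float
    scale: Scale
    emm: Optional[pd.DataFrame] = None

    def ss_reconciles(self, rtol: float = 1e-8) -> bool:
        parts = self.ss_subject + sum(
            e.ss + e.ss_error for e in self.effects.values()
        )
        return abs(parts - self.ss_total) <= rtol * max(self.ss_total, 1.0)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _mauchly_gg(d: np.ndarray) -> tuple[float, float, int, float, float]:
    """Mauchly's W, chi-square approximation, and GG epsilon.

    ``d`` is the n x m matrix of orthonormal within-factor contrast scores;
    sphericity means its covariance is proportional to the identity.
    """
    n, m = d.shape
    s = np.cov(d, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0, None)
    mean_eig = eig.mean()
    with np.errstate(divide="ignore"):
        logW = float(np.sum(np.log(eig[eig > 0])) - m * np.log(mean_eig))
    W = float(np.exp(logW)) if np.isfinite(logW) else 0.0
    f = 1 - (2 * m * m + m + 2) / (6.0 * m * (n - 1))
    chi2 = -(n - 1) * f * logW if np.isfinite(logW) else np.inf
    df = m * (m + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    gg = float(eig.sum() ** 2 / (m * np.sum(eig**2))) if np.sum(eig**2) > 0 else 1.0
    return W, float(chi2), df, p, gg


def _complete_wide(
    table: PairByGroupTable, min_rows: int = 3
) -> tuple[np.ndarray, int]:
    cols = [str(GroupKey(r, g)) for g in GENDER_LEVELS for r in RACE_LEVELS]
    missing_cols = [c for c in cols if c not in table.values.columns]
    if missing_cols:
        raise InsufficientDataError(f"missing group columns: {missing_cols}")
    wide = table.values[cols]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("listwise-deleted %d incomplete trait-pair rows", n_dropped)
    if len(complete) < min_rows:
        raise InsufficientDataError(
            f"only {len(complete)} complete trait-pair rows (< {min_rows})"
        )
    # reshape to (subjects, gender, race) following the column order above
    y = complete.to_numpy(dtype=float).reshape(len(complete), 2, 3)
    return y, n_dropped


def rm_anova_2x3(table: PairByGroupTable) -> AnovaResult:
    """2 (gender) x 3 (race) within-subjects ANOVA over trait pairs.

    Sums of squares use the standard fully-within partition with the trait
    pair as the blocking unit; each effect is tested against its own
    subject-by-effect interaction error term.  Partial eta squared is
    SS_effect / (SS_effect + SS_error_effect).  Greenhouse-Geisser
    corrected p-values accompany the race and interaction effects.
    """
    y, n_dropped = _complete_wide(table)
    n, a, b = y.shape
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    A = y.mean(axis=(0, 2))  # gender means
    B = y.mean(axis=(0, 1))  # race means
    AB = y.mean(axis=0)
    SA = y.mean(axis=2)  # subject x gender
    SB = y.mean(axis=1)  # subject x race

    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(a * b * ((subj - grand) ** 2).sum())
    ss_A = float(n * b * ((A - grand) ** 2).sum())
    ss_B = float(n * a * ((B - grand) ** 2).sum())
    ss_AB = float(n * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum())
    ss_errA = float(
        b * ((SA - subj[:, None] - A[None, :] + grand) ** 2).sum()
    )
    ss_errB = float(
        a * ((SB - subj[:, None] - B[None, :] + grand) ** 2).sum()
    )
    ss_errAB = ss_total - ss_subj - ss_A - ss_B - ss_AB - ss_errA - ss_errB

    tiny = 1e-12 * max(ss_total, 1.0)  # floating-point zero for degenerate data

    def effect(ss, ss_err, df1, df2) -> EffectResult:
        ss = 0.0 if ss < tiny else ss
        ss_err = 0.0 if ss_err < tiny else ss_err
        ms, ms_e = ss / df1, ss_err / df2
        F = ms / ms_e if ms_e > 0 else 0.0
        p = float(stats.f.sf(F, df1, df2)) if ms_e > 0 else 1.0
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return EffectResult(
            ss=ss, ss_error=ss_err, df_num=df1, df_den=df2,
            ms=ms, ms_error=ms_e, F=F, p=p, partial_eta_sq=eta,
        )

    res_gender = effect(ss_A, ss_errA, a - 1, (a - 1) * (n - 1))
    res_gender.gg_epsilon = 1.0  # two levels: sphericity holds trivially
    res_gender.p_gg_corrected = res_gender.p

    res_race = effect(ss_B, ss_errB, b - 1, (b - 1) * (n - 1))
    cb = _orthonormal_contrasts(b)
    d_race = SB @ cb.T
    W, chi2, dfm, pm, gg = _mauchly_gg(d_race)
    res_race.mauchly_W, res_race.mauchly_chi2 = W, chi2
    res_race.mauchly_df, res_race.mauchly_p = dfm, pm
    res_race.gg_epsilon = gg
    res_race.p_gg_corrected = float(
        stats.f.sf(res_race.F, gg * res_race.df_num, gg * res_race.df_den)
    )

    res_int = effect(
        ss_AB, ss_errAB, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)
    )
    ca = _orthonormal_contrasts(a)
    c_int = np.kron(ca, cb)  # contrasts over the flattened gender x race cells
    d_int = y.reshape(n, a * b) @ c_int.T
    W, chi2, dfm, pm, gg = _mauchly_gg(d_int)
    res_int.mauchly_W, res_int.mauchly_chi2 = W, chi2
    res_int.mauchly_df, res_int.mauchly_p = dfm, pm
    res_int.gg_epsilon = gg
    res_int.p_gg_corrected = float(
        stats.f.sf(res_int.F, gg * res_int.df_num, gg * res_int.df_den)
    )

    result = AnovaResult(
        effects={"gender": res_gender, "race": res_race, "gender_x_race": res_int},
        n_subjects=n,
        n_dropped_incomplete=n_dropped,
        ss_subject=ss_subj,
        ss_total=ss_total,
        scale=table.scale,
    )
    result.emm = marginal_means(table)
    return result


def marginal_means(
    table: PairByGroupTable, back_transform: Optional[bool] = None
) -> pd.DataFrame:
    """Estimated marginal means per gender, race, and gender x race cell.

    Means and their CIs are computed on the analysis scale; when the table
    is on the Fisher-z scale (and ``back_transform`` is not disabled) they
    are additionally reported back-transformed to the correlation scale in
    the ``mean_r`` / ``ci_low_r`` / ``ci_high_r`` columns.  The SE of each
    margin comes from the between-trait-pair variability of that margin's
    per-pair mean (the within-subject error model at that margin).
    """
    y, _ = _complete_wide(table, min_rows=2)
    n = y.shape[0]
    if back_transform is None:
        back_transform = table.scale is Scale.Z
    tcrit = stats.t.ppf(0.975, n - 1)
    rows = []

    def add(margin: str, level: str, per_subject: np.ndarray) -> None:
        m = float(per_subject.mean())
        se = float(per_subject.std(ddof=1) / np.sqrt(n))
        lo, hi = m - tcrit * se, m + tcrit * se
        row = {
            "margin": margin, "level": level, "mean": m, "se": se,
            "ci_low": lo, "ci_high": hi, "n": n,
        }
        if back_transform:
            row["mean_r"] = inverse_fisher_z(m)
            row["ci_low_r"] = inverse_fisher_z(lo)
            row["ci_high_r"] = inverse_fisher_z(hi)
        rows.append(row)

    for j, g in enumerate(GENDER_LEVELS):
        add("gender", g.value, y[:, j, :].mean(axis=1))
    for k, r in enumerate(RACE_LEVELS):
        add("race", r.value, y[:, :, k].mean(axis=1))
    for j, g in enumerate(GENDER_LEVELS):
        for k, r in enumerate(RACE_LEVELS):
            add("cell", f"{r.value} {g.value}", y[:, j, k])
    return pd.DataFrame(rows)
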