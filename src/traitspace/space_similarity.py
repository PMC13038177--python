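"""Similarity of two stacked trait spaces: centered Spearman correlation.

The headline statistic: after removing each trait pair's mean value across
the six social categories from both the face-trait stack and the
group-stereotype stack independently, the Spearman rank correlation between
the two 546-row columns measures how far group-specific shifts in
stereotype structure track group-specific shifts in face-impression
structure.  Spearman is used because the values being correlated are
themselves (Fisher-z) correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trait_space import StackedSpace, Scale, StateError, center_by_pair_mean
from .trait_space import IntegrityError

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 9  # exact permutation p-value up to this many rows


class InputError(ValueError):
    pass


@dataclass
class SimilarityResult:
    """Spearman comparison of two aligned stacked spaces."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n_rows: int
    method: str  # "bootstrap" | "fisher_approx"
    n_resamples: int
    seed: Optional[int]
    n_dropped_missing: int

    def to_dict(self) -> dict:
        return asdict(self)


def _rankdata(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use average-rank tie handling; rho is the Pearson correlation of
    the ranks.  For n <= 9 the p-value is an exact permutation p (all n!
    orderings); otherwise the t-distribution approximation is used.
    Missing values are removed pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InputError(f"need >= 3 paired values, got {n}")
    rx, ry = _rankdata(x), _rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_P_MAX_N:
        # exact: enumerate all orderings of one rank vector
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        num = pc @ rxc
        denom = math.sqrt((rxc @ rxc)) * np.sqrt((pc * pc).sum(axis=1))
        null = num / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _aligned_values(
    face: StackedSpace, stereo: StackedSpace
) -> tuple[np.ndarray, np.ndarray]:
    if face.row_labels != stereo.row_labels:
        a, b = set(face.row_labels), set(stereo.row_labels)
        raise IntegrityError(
            f"row labels differ between spaces; symmetric difference size "
            f"{len(a ^ b)}"
        )
    return face.values, stereo.values


def compare_spaces(
    face: StackedSpace,
    stereo: StackedSpace,
    center: bool = True,
    ci_method: str = "bootstrap",
    n_resamples: int = 10_000,
    seed: Optional[int] = None,
) -> SimilarityResult:
    """Centered Spearman comparison of two stacked spaces.

    When ``center`` is set, each space is independently centered by its own
    per-trait-pair mean across groups before correlating.  The 95% CI is a
    seeded percentile bootstrap over rows by default; ``fisher_approx``
    selects the Bonett-Wright normal approximation
    (SE = sqrt((1 + rho^2/2)/(n-3)) on the arctanh scale) instead.
    """
    if face.scale is not Scale.Z or stereo.scale is not Scale.Z:
        raise StateError("compare_spaces expects both spaces on the z scale")
    if center:
        if face.centered or stereo.centered:
            raise StateError("center requested but input is already centered")
        face = center_by_pair_mean(face)
        stereo = center_by_pair_mean(stereo)
    x, y = _aligned_values(face, stereo)
    ok = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing values", n_dropped)
    xs, ys = x[ok], y[ok]
    rho, p = spearman_rho(xs, ys)
    n = len(xs)

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_resamples, n))
        boots = np.empty(n_resamples)
        for b in range(n_resamples):
            i = idx[b]
            rx, ry = _rankdata(xs[i]), _rankdata(ys[i])
            if rx.std() == 0 or ry.std() == 0:
                boots[b] = np.nan
            else:
                boots[b] = np.corrcoef(rx, ry)[0, 1]
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        n_res = n_resamples
    elif ci_method == "fisher_approx":
        se = math.sqrt((1 + rho * rho / 2) / (n - 3))
        zr = math.atanh(max(min(rho, 1 - 1e-12), -1 + 1e-12))
        lo, hi = math.tanh(zr - 1.959964 * se), math.tanh(zr + 1.959964 * se)
        n_res = 0
    else:
        raise InputError(f"unknown ci_method {ci_method!r}")

    return SimilarityResult(
        rho=rho,
        p_value=p,
        ci_low=float(lo),
        ci_high=float(hi),
        n_rows=n,
        method=ci_method,
        n_resamples=n_res,
        seed=seed,
        n_dropped_missing=n_dropped,
    )


@dataclass
class PermutationNull:
    null: np.ndarray
    envelope_low: float
    envelope_high: float
    observed: float
    p_value: float
    n_perm: int
    seed: Optional[int]


def permutation_null(
    face: StackedSpace,
    stereo: StackedSpace,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> PermutationNull:
    """Empirical null for the centered statistic by within-pair group shuffles.

    The stereotype stack's group labels are permuted independently within
    each trait pair, breaking any group-specific alignment while preserving
    each pair's value set; the centered Spearman rho is recomputed each
    time.  Returns the null draws, its two-sided (alpha) envelope, and a
    permutation p-value for the observed statistic.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; envelope will be coarse", n_perm)
    if face.centered or stereo.centered:
        raise StateError("permutation_null expects uncentered inputs")
    obs = compare_spaces(
        face, stereo, center=True, ci_method="fisher_approx", seed=seed
    ).rho

    fc = center_by_pair_mean(face)
    sc = center_by_pair_mean(stereo)
    x, y = _aligned_values(fc, sc)
    df = sc.data
    pair_codes = pd.factorize(
        df["trait_a"].astype(str) + "\x00" + df["trait_b"].astype(str)
    )[0]
    n_pairs = pair_codes.max() + 1
    pair_rows = [np.flatnonzero(pair_codes == k) for k in range(n_pairs)]

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    yp = y.copy()
    for b in range(n_perm):
        for rows in pair_rows:
            yp[rows] = y[rng.permutation(rows)]
        ok = ~(np.isnan(x) | np.isnan(yp))
        rx, ry = _rankdata(x[ok]), _rankdata(yp[ok])
        null[b] = np.corrcoef(rx, ry)[0, 1]
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (1 + n_perm))
    return PermutationNull(
        null=null,
        envelope_low=float(lo),
        envelope_high=float(hi),
        observed=float(obs),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
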