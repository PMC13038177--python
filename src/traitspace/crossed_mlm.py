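"""Cross-classified multilevel analysis of within-perceiver trait spaces.

Each observation is one perceiver's Fisher-z trait-pair correlation from
face ratings of one social group (the outcome ``y``), joined with that
perceiver's pairwise stereotype-likelihood rating for the same group and
trait pair (the predictor ``x``).  Observations are cross-classified:
simultaneously clustered by perceiver and by trait pair, which are not
nested in one another.

Model (full):

    Level 1:  y_ijk = b0_jk + b1_jk * x_cwc_ijk + r_ijk
    Level 2:  b0_jk = g000 + g010 * xbar_j + u0_j + u00_k
              b1_jk = g100 + u1_j

where ``x_cwc`` is the stereotype rating centered within perceiver *j*,
``xbar_j`` is perceiver *j*'s mean stereotype rating (grand-mean centered
before entry), ``u0_j`` / ``u00_k`` are crossed random intercepts for
perceiver and trait pair, and ``u1_j`` is a perceiver random slope.  All
random effects are mutually independent; estimation is REML.

The null (intercept-only) model partitions outcome variance into perceiver,
trait-pair (and, for the stereotype outcome, perceiver-by-pair interaction)
components, summarized as intraclass correlations.  The full model's
explained variance is decomposed into fixed within, fixed between, random
slope, random intercept, and residual shares following the integrated R²
framework for mixed models, with both crossed intercept variances entering
the intercept share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._reml import ConvergenceError, RandomComponent, fit_reml
from .data_model import Design, GroupKey, RatingTable, ValidationError
from .trait_space import canonical_pairs, fisher_z

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054


@dataclass
class MLMDataset:
    """One row per (perceiver, group, trait pair).

    Columns: ``perceiver_id, race, gender, trait_a, trait_b, y, x_raw,
    x_cwc, x_pmean``.  ``y`` is the within-perceiver Fisher-z face-rating
    correlation; ``x_raw`` the perceiver's stereotype-likelihood rating
    (averaged over the two question directions); ``x_cwc`` is ``x_raw``
    centered on the perceiver's own mean ``x_pmean``.
    """

    df: pd.DataFrame
    n_perceivers: int
    n_pairs: int
    n_groups: int
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def subset(self, groups: Sequence[GroupKey]) -> "MLMDataset":
        keys = {(g.race.value, g.gender.value) for g in groups}
        mask = [
            (r, g) in keys
            for r, g in zip(self.df["race"], self.df["gender"])
        ]
        sub = self.df[np.asarray(mask)].reset_index(drop=True)
        return MLMDataset(
            df=sub,
            n_perceivers=sub["perceiver_id"].nunique(),
            n_pairs=sub.groupby(["trait_a", "trait_b"]).ngroups,
            n_groups=sub["race"].nunique(),
            n_dropped=self.n_dropped,
        )


def build_mlm_dataset(
    face: RatingTable,
    pairwise: RatingTable,
    min_targets: int = 3,
) -> MLMDataset:
    """Join within-perceiver face-space correlations with stereotype ratings.

    For every perceiver and race group (target gender is fixed within
    perceiver), the trait-pair Pearson correlations across that perceiver's
    own targets are Fisher-z transformed to give ``y``; the perceiver's
    pairwise likelihood ratings give ``x_raw`` (two question directions
    averaged).  Rows whose correlation is undefined (zero-variance trait in
    the cell, or fewer than ``min_targets`` targets) are excluded with a
    logged count.  ``x_cwc``/``x_pmean`` are computed per perceiver over
    that perceiver's retained rows.
    """
    if face.design is not Design.FACE_WITHIN:
        raise ValidationError("face table must use the face_within design")
    if pairwise.design is not Design.PAIRWISE_STEREOTYPE:
        raise ValidationError("pairwise table must use the pairwise_stereotype design")
    traits = [t for t in face.trait_set]
    pairs = canonical_pairs(traits)
    order = {t: i for i, t in enumerate(traits)}

    # stereotype likelihoods: average the two directions per unordered pair,
    # orienting each pair by the declared trait order
    pw = pairwise.df.copy()
    gi = pw["trait_given"].map(order)
    ai = pw["trait_asked"].map(order)
    first = gi <= ai
    pw["trait_a"] = pw["trait_given"].where(first, pw["trait_asked"])
    pw["trait_b"] = pw["trait_asked"].where(first, pw["trait_given"])
    x_tab = (
        pw.groupby(["perceiver_id", "race", "gender", "trait_a", "trait_b"])[
            "rating"
        ]
        .mean()
        .rename("x_raw")
    )

    rows = []
    n_dropped = 0
    iu = np.triu_indices(len(traits), k=1)
    for (pid, race, gender), sub in face.df.groupby(
        ["perceiver_id", "race", "gender"], sort=False
    ):
        wide = sub.pivot_table(
            index="subject", columns="trait", values="rating", aggfunc="mean"
        ).reindex(columns=traits)
        arr = wide.to_numpy(dtype=float)
        if arr.shape[0] < min_targets or np.isnan(arr).any():
            n_dropped += len(pairs)
            continue
        sd = arr.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(arr, rowvar=False)
        for (i, j) in zip(*iu):
            a, b = traits[i], traits[j]
            if sd[i] == 0 or sd[j] == 0 or not np.isfinite(r[i, j]):
                n_dropped += 1
                continue
            rows.append((pid, race, gender, a, b, fisher_z(r[i, j])))

    df = pd.DataFrame(
        rows, columns=["perceiver_id", "race", "gender", "trait_a", "trait_b", "y"]
    )
    df = df.join(
        x_tab, on=["perceiver_id", "race", "gender", "trait_a", "trait_b"]
    )
    n_missing_x = int(df["x_raw"].isna().sum())
    if n_missing_x:
        logger.info("dropping %d rows without a stereotype rating", n_missing_x)
        n_dropped += n_missing_x
        df = df.dropna(subset=["x_raw"]).reset_index(drop=True)
    if n_dropped:
        logger.info("excluded %d rows while building the dataset", n_dropped)

    df["x_pmean"] = df.groupby("perceiver_id")["x_raw"].transform("mean")
    df["x_cwc"] = df["x_raw"] - df["x_pmean"]

    # groups are the race levels each perceiver rated (target gender is
    # fixed within perceiver, so race x gender cells would double-count)
    return MLMDataset(
        df=df,
        n_perceivers=df["perceiver_id"].nunique(),
        n_pairs=df.groupby(["trait_a", "trait_b"]).ngroups,
        n_groups=df["race"].nunique(),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Variance components / null model


@dataclass
class VarianceComponents:
    var_perceiver_intercept: float
    var_pair_intercept: float
    var_residual: float
    var_perceiver_slope: float = 0.0
    var_interaction: Optional[float] = None
    icc_perceiver: float = 0.0
    icc_pair: float = 0.0
    icc_interaction: Optional[float] = None
    boundary: dict = field(default_factory=dict)
    loglik: float = float("nan")
    n_obs: int = 0

    def total_variance(self) -> float:
        return (
            self.var_perceiver_intercept
            + self.var_pair_intercept
            + (self.var_interaction or 0.0)
            + self.var_residual
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _codes(series: pd.Series) -> tuple[np.ndarray, int]:
    codes, levels = pd.factorize(series, sort=True)
    return codes.astype(np.int64), len(levels)


def fit_null_crossclassified(
    dataset: MLMDataset, outcome: str = "y"
) -> VarianceComponents:
    """Intercept-only cross-classified variance decomposition (REML).

    Random intercepts for perceiver and trait pair; for the stereotype
    outcome (``outcome='x_raw'``) a perceiver-by-pair interaction component
    is added, since each perceiver rates each pair once per group so the
    interaction is identified from the group replicates.  ICCs are each
    component's share of total outcome variance.
    """
    df = dataset.df
    if dataset.n_perceivers < 10 or dataset.n_pairs < 5:
        raise ValidationError(
            "null model needs >= 10 perceivers and >= 5 trait pairs"
        )
    if outcome not in ("y", "x_raw"):
        raise ValidationError(f"unknown outcome {outcome!r}")
    y = df[outcome].to_numpy(dtype=float)
    X = np.ones((len(df), 1))
    p_codes, n_p = _codes(df["perceiver_id"])
    pair_key = df["trait_a"] + "\x00" + df["trait_b"]
    k_codes, n_k = _codes(pair_key)
    comps = [
        RandomComponent("perceiver", p_codes, n_p),
        RandomComponent("pair", k_codes, n_k),
    ]
    if outcome == "x_raw":
        i_codes, n_i = _codes(
            df["perceiver_id"] + "\x00" + pair_key
        )
        comps.append(RandomComponent("interaction", i_codes, n_i))
    res = fit_reml(y, X, comps)
    var_p = res.variances["perceiver"]
    var_k = res.variances["pair"]
    var_i = res.variances.get("interaction")
    total = var_p + var_k + (var_i or 0.0) + res.sigma2
    return VarianceComponents(
        var_perceiver_intercept=var_p,
        var_pair_intercept=var_k,
        var_residual=res.sigma2,
        var_interaction=var_i,
        icc_perceiver=var_p / total,
        icc_pair=var_k / total,
        icc_interaction=(var_i / total) if var_i is not None else None,
        boundary=dict(res.boundary),
        loglik=res.loglik,
        n_obs=res.n_obs,
    )


# ---------------------------------------------------------------------------
# Full model


@dataclass
class FixedEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def _fixed(est: float, se: float) -> FixedEffect:
    from scipy import stats

    z = est / se if se > 0 else float("inf")
    return FixedEffect(
        estimate=float(est),
        se=float(se),
        ci_low=float(est - _Z975 * se),
        ci_high=float(est + _Z975 * se),
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
    )


@dataclass
class MLMFit:
    gamma_000: FixedEffect
    gamma_010: FixedEffect
    gamma_100: FixedEffect
    std_beta: float
    components: VarianceComponents
    converged: bool
    loglik: float
    n_obs: int
    slope_dropped: bool = False  # singular slope variance refit flag

    def to_dict(self) -> dict:
        return {
            "gamma_000": asdict(self.gamma_000),
            "gamma_010": asdict(self.gamma_010),
            "gamma_100": asdict(self.gamma_100),
            "std_beta": self.std_beta,
            "components": self.components.to_dict(),
            "converged": self.converged,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "slope_dropped": self.slope_dropped,
        }


def fit_full(
    dataset: MLMDataset,
    subset_groups: Optional[Sequence[GroupKey]] = None,
    random_slope: bool = True,
) -> MLMFit:
    """Fit the full cross-classified model by REML.

    Fixed effects: intercept (g000), grand-mean-centered perceiver mean
    stereotype rating (g010), and the within-perceiver centered stereotype
    rating (g100).  Random: crossed intercepts for perceiver and trait
    pair, plus an independent perceiver random slope on ``x_cwc``.  A
    singular slope component (variance estimated on the zero boundary) is
    refit without the slope and flagged via ``slope_dropped``.
    """
    data = dataset.subset(subset_groups) if subset_groups else dataset
    df = data.df
    y = df["y"].to_numpy(dtype=float)
    x_cwc = df["x_cwc"].to_numpy(dtype=float)
    x_pm = df["x_pmean"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), x_pm - x_pm.mean(), x_cwc])
    p_codes, n_p = _codes(df["perceiver_id"])
    k_codes, n_k = _codes(df["trait_a"] + "\x00" + df["trait_b"])
    comps = [
        RandomComponent("perceiver", p_codes, n_p),
        RandomComponent("pair", k_codes, n_k),
    ]
    if random_slope:
        comps.append(
            RandomComponent("slope", p_codes, n_p, covariate=x_cwc)
        )
    try:
        res = fit_reml(y, X, comps)
    except ConvergenceError:
        if not random_slope:
            raise
        logger.warning("full model failed with random slope; refitting without")
        return _as_fit(dataset, df, y, x_cwc, None, slope_dropped=True)

    slope_dropped = False
    if random_slope and res.boundary.get("slope", False):
        logger.info("random-slope variance on the zero boundary; refit without")
        res = fit_reml(y, X, comps[:2])
        slope_dropped = True
    return _as_fit(dataset, df, y, x_cwc, res, slope_dropped=slope_dropped)


def _as_fit(dataset, df, y, x_cwc, res, slope_dropped: bool) -> MLMFit:
    if res is None:
        X = np.column_stack(
            [np.ones(len(df)), df["x_pmean"] - df["x_pmean"].mean(), x_cwc]
        )
        p_codes, n_p = _codes(df["perceiver_id"])
        k_codes, n_k = _codes(df["trait_a"] + "\x00" + df["trait_b"])
        res = fit_reml(
            y,
            X,
            [
                RandomComponent("perceiver", p_codes, n_p),
                RandomComponent("pair", k_codes, n_k),
            ],
        )
    var_slope = res.variances.get("slope", 0.0)
    components = VarianceComponents(
        var_perceiver_intercept=res.variances["perceiver"],
        var_pair_intercept=res.variances["pair"],
        var_residual=res.sigma2,
        var_perceiver_slope=var_slope,
        boundary=dict(res.boundary),
        loglik=res.loglik,
        n_obs=res.n_obs,
    )
    sd_y = float(np.std(y))
    sd_x = float(np.std(x_cwc))
    g100 = res.beta[2]
    return MLMFit(
        gamma_000=_fixed(res.beta[0], res.se_beta[0]),
        gamma_010=_fixed(res.beta[1], res.se_beta[1]),
        gamma_100=_fixed(g100, res.se_beta[2]),
        std_beta=float(g100 * sd_x / sd_y) if sd_y > 0 else float("nan"),
        components=components,
        converged=res.converged,
        loglik=res.loglik,
        n_obs=res.n_obs,
        slope_dropped=slope_dropped,
    )


# ---------------------------------------------------------------------------
# R^2 decomposition


@dataclass
class R2Decomposition:
    """Model-implied outcome-variance shares (sum to 1).

    ``r2_f1_within``: fixed Level-1 effect (within-perceiver stereotype
    deviations via g100); ``r2_f2_between``: fixed Level-2 effect
    (perceiver mean stereotype via g010); ``r2_v_slope``: perceiver random
    slope variation; ``r2_m_intercepts``: both crossed random intercepts;
    ``r2_residual``: remainder.
    """

    r2_f1_within: float
    r2_f2_between: float
    r2_v_slope: float
    r2_m_intercepts: float
    r2_residual: float
    total_variance: float

    def to_dict(self) -> dict:
        return asdict(self)

    def shares(self) -> np.ndarray:
        return np.array(
            [
                self.r2_f1_within,
                self.r2_f2_between,
                self.r2_v_slope,
                self.r2_m_intercepts,
                self.r2_residual,
            ]
        )


def r2_decomposition(fit: MLMFit, dataset: MLMDataset) -> R2Decomposition:
    """Integrated R² partition adapted to the cross-classified structure.

    The model-implied total variance is

        g100^2 var(x_cwc) + g010^2 var(x_pmean)          (fixed f1 + f2)
        + tau_slope E[x_cwc^2]                           (random slope, v)
        + tau_perceiver + tau_pair                       (intercepts, m)
        + sigma^2                                        (residual)

    with predictor moments taken over the analysis rows; each term divided
    by the total gives its variance share.  Both crossed intercept
    variances enter the ``m`` partition.
    """
    if not fit.converged:
        raise ConvergenceError("refusing to decompose a non-converged fit")
    df = dataset.df
    x_cwc = df["x_cwc"].to_numpy(dtype=float)
    x_pm = df["x_pmean"].to_numpy(dtype=float)
    c = fit.components
    f1 = fit.gamma_100.estimate ** 2 * float(np.var(x_cwc))
    f2 = fit.gamma_010.estimate ** 2 * float(np.var(x_pm))
    v = c.var_perceiver_slope * float(np.mean(x_cwc**2))
    m = c.var_perceiver_intercept + c.var_pair_intercept
    resid = c.var_residual
    total = f1 + f2 + v + m + resid
    return R2Decomposition(
        r2_f1_within=f1 / total,
        r2_f2_between=f2 / total,
        r2_v_slope=v / total,
        r2_m_intercepts=m / total,
        r2_residual=resid / total,
        total_variance=total,
    )
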