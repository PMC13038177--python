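import numpy as np
import pandas as pd
import pytest

import traitspace as ts
from traitspace._reml import RandomComponent, fit_reml
from traitspace.crossed_mlm import MLMDataset, build_mlm_dataset
from traitspace.data_model import Design, GroupKey, Race, Gender, ValidationError


class TestBuildDataset:
    def test_one_perceiver_complete_gives_45_rows(self):
        cfg = ts.SimulationConfig.study2(seed=2, n_perceivers=1)
        study = ts.simulate_study2(cfg)
        ds = build_mlm_dataset(study.face_ratings, study.pairwise_ratings)
        assert ds.n_rows == 45  # 15 pairs x 3 race groups
        assert ds.n_pairs == 15 and ds.n_groups == 3

    def test_cwc_centering_identities(self, small_study2_dataset):
        df = small_study2_dataset.df
        assert np.allclose(df["x_cwc"], df["x_raw"] - df["x_pmean"], atol=1e-10)
        sums = df.groupby("perceiver_id")["x_cwc"].sum()
        assert np.allclose(sums, 0.0, atol=1e-9)

    def test_constant_stereotype_rater_has_zero_cwc(self):
        cfg = ts.SimulationConfig.study2(seed=4, n_perceivers=2)
        study = ts.simulate_study2(cfg)
        pw = study.pairwise_ratings.df.copy()
        pid = pw["perceiver_id"].iloc[0]
        pw.loc[pw["perceiver_id"] == pid, "rating"] = 4
        pairwise = ts.RatingTable(
            df=pw, design=Design.PAIRWISE_STEREOTYPE, trait_set=ts.STUDY2_TRAITS
        )
        ds = build_mlm_dataset(study.face_ratings, pairwise)
        assert np.allclose(
            ds.df.loc[ds.df["perceiver_id"] == pid, "x_cwc"], 0.0, atol=1e-12
        )

    def test_zero_variance_trait_cell_excluded_with_count(self):
        cfg = ts.SimulationConfig.study2(seed=5, n_perceivers=2)
        study = ts.simulate_study2(cfg)
        face = study.face_ratings.df.copy()
        pid = face["perceiver_id"].iloc[0]
        sel = (face["perceiver_id"] == pid) & (face["race"] == "White") & (
            face["trait"] == "attractive"
        )
        face.loc[sel, "rating"] = 4
        table = ts.RatingTable(
            df=face, design=Design.FACE_WITHIN, trait_set=ts.STUDY2_TRAITS
        )
        ds = build_mlm_dataset(table, study.pairwise_ratings)
        # 5 pairs involving 'attractive' dropped for that perceiver-group
        assert ds.n_dropped == 5
        assert ds.n_rows == 2 * 45 - 5

    def test_wrong_designs_rejected(self, small_study2):
        with pytest.raises(ValidationError):
            build_mlm_dataset(
                small_study2.pairwise_ratings, small_study2.pairwise_ratings
            )

    def test_y_matches_directly_computed_correlation(self, small_study2):
        ds = build_mlm_dataset(
            small_study2.face_ratings, small_study2.pairwise_ratings
        )
        row = ds.df.iloc[10]
        group = GroupKey.parse(row["race"], row["gender"])
        m = ts.trait_correlation_matrix(
            small_study2.face_ratings,
            ts.Unit.WITHIN_PERCEIVER_TARGETS,
            group=group,
            perceiver_id=row["perceiver_id"],
        )
        expected = ts.fisher_z(m.r.loc[row["trait_a"], row["trait_b"]])
        assert row["y"] == pytest.approx(expected, abs=1e-10)


class TestREMLEngine:
    def test_matches_closed_form_balanced_two_way_anova(self):
        # 4 perceivers x 3 pairs, one observation per cell, intercept only:
        # REML equals the classic two-way random-effects moment estimators
        rng = np.random.default_rng(12)
        a, b = 4, 3
        Y = (
            1.5
            + rng.normal(0, 1.2, a)[:, None]
            + rng.normal(0, 1.0, b)[None, :]
            + rng.normal(0, 0.5, (a, b))
        )
        ybar, ra, cb = Y.mean(), Y.mean(axis=1), Y.mean(axis=0)
        msa = b * ((ra - ybar) ** 2).sum() / (a - 1)
        msb = a * ((cb - ybar) ** 2).sum() / (b - 1)
        mse = ((Y - ra[:, None] - cb[None, :] + ybar) ** 2).sum() / ((a - 1) * (b - 1))
        rows = [(i, j, Y[i, j]) for i in range(a) for j in range(b)]
        df = pd.DataFrame(rows, columns=["i", "j", "y"])
        res = fit_reml(
            df["y"].to_numpy(),
            np.ones((len(df), 1)),
            [
                RandomComponent("perceiver", df["i"].to_numpy(), a),
                RandomComponent("pair", df["j"].to_numpy(), b),
            ],
        )
        assert res.variances["perceiver"] == pytest.approx((msa - mse) / b, abs=1e-6)
        assert res.variances["pair"] == pytest.approx((msb - mse) / a, abs=1e-6)
        assert res.sigma2 == pytest.approx(mse, abs=1e-6)

    def test_matches_statsmodels_mixedlm_crossed(self):
        import statsmodels.api as sm

        ds = ts.simulate_crossed_outcome(
            20, 6, n_groups=3, var_perceiver=0.8, var_pair=0.5,
            var_residual=1.0, seed=3,
        )
        df = ds.df.assign(g=1)
        pc, pl = pd.factorize(df["perceiver_id"])
        kc, kl = pd.factorize(df["trait_a"])
        mine = fit_reml(
            df["y"].to_numpy(),
            np.ones((len(df), 1)),
            [
                RandomComponent("p", pc, len(pl)),
                RandomComponent("k", kc, len(kl)),
            ],
        )
        theirs = sm.MixedLM.from_formula(
            "y ~ 1",
            groups="g",
            vc_formula={"p": "0 + C(perceiver_id)", "k": "0 + C(trait_a)"},
            data=df,
        ).fit(reml=True)
        assert mine.variances["p"] == pytest.approx(theirs.vcomp[1], rel=1e-3)
        assert mine.variances["k"] == pytest.approx(theirs.vcomp[0], rel=1e-3)
        assert mine.sigma2 == pytest.approx(theirs.scale, rel=1e-4)
        assert mine.beta[0] == pytest.approx(theirs.fe_params.iloc[0], abs=1e-6)
        assert mine.se_beta[0] == pytest.approx(theirs.bse_fe.iloc[0], rel=1e-4)
        assert mine.loglik == pytest.approx(theirs.llf, abs=1e-4)


class TestNullModel:
    def test_planted_variances_recovered_as_iccs(self):
        ds = ts.simulate_crossed_outcome(
            200, 15, n_groups=3, var_perceiver=1.0, var_pair=1.0,
            var_residual=2.0, seed=42,
        )
        comp = ts.fit_null_crossclassified(ds, outcome="y")
        assert comp.icc_perceiver == pytest.approx(0.25, abs=0.05)
        assert comp.icc_pair == pytest.approx(0.25, abs=0.05)

    def test_no_clustering_gives_near_zero_iccs(self):
        ds = ts.simulate_crossed_outcome(
            60, 10, n_groups=3, var_perceiver=0.0, var_pair=0.0,
            var_residual=1.0, seed=8,
        )
        comp = ts.fit_null_crossclassified(ds, outcome="y")
        assert comp.icc_perceiver < 0.02
        assert comp.icc_pair < 0.02

    def test_icc_shares_sum_to_one(self, small_study2_dataset):
        comp = ts.fit_null_crossclassified(small_study2_dataset, outcome="y")
        total_share = (
            comp.icc_perceiver
            + comp.icc_pair
            + comp.var_residual / comp.total_variance()
        )
        assert total_share == pytest.approx(1.0, abs=1e-6)

    def test_interaction_component_for_stereotype_outcome(self):
        ds = ts.simulate_crossed_outcome(
            60, 10, n_groups=3, var_perceiver=0.5, var_pair=0.5,
            var_interaction=0.5, var_residual=1.0, seed=10,
        )
        comp = ts.fit_null_crossclassified(ds, outcome="x_raw")
        assert comp.var_interaction is not None
        assert comp.icc_interaction == pytest.approx(0.5 / 2.5, abs=0.08)

    def test_icc_invariant_to_shift_and_scale(self, small_study2_dataset):
        base = ts.fit_null_crossclassified(small_study2_dataset, outcome="y")
        shifted = MLMDataset(
            df=small_study2_dataset.df.assign(
                y=lambda d: 3.0 + 2.0 * d["y"]
            ),
            n_perceivers=small_study2_dataset.n_perceivers,
            n_pairs=small_study2_dataset.n_pairs,
            n_groups=small_study2_dataset.n_groups,
        )
        other = ts.fit_null_crossclassified(shifted, outcome="y")
        assert other.icc_perceiver == pytest.approx(base.icc_perceiver, abs=1e-4)
        assert other.icc_pair == pytest.approx(base.icc_pair, abs=1e-4)
        assert other.var_residual == pytest.approx(4 * base.var_residual, rel=1e-3)

    def test_minimum_size_guard(self):
        ds = ts.simulate_crossed_outcome(5, 3, seed=0)
        with pytest.raises(ValidationError):
            ts.fit_null_crossclassified(ds)


class TestFullModel:
    def test_planted_slope_recovered_single_study(self, small_study2_dataset):
        fit = ts.fit_full(small_study2_dataset)
        assert fit.converged
        # planted 0.05 at 30 perceivers: generous single-study window
        assert fit.gamma_100.estimate == pytest.approx(0.05, abs=0.03)
        assert fit.gamma_100.ci_low <= fit.gamma_100.estimate <= fit.gamma_100.ci_high

    def test_std_beta_consistent_with_slope(self, small_study2_dataset):
        fit = ts.fit_full(small_study2_dataset)
        df = small_study2_dataset.df
        expected = fit.gamma_100.estimate * df["x_cwc"].std(ddof=0) / df["y"].std(ddof=0)
        assert fit.std_beta == pytest.approx(expected, rel=1e-9)

    def test_group_subset_refit(self, small_study2_dataset):
        groups = [
            GroupKey(Race.WHITE, Gender.FEMALE),
            GroupKey(Race.WHITE, Gender.MALE),
        ]
        sub = small_study2_dataset.subset(groups)
        assert set(sub.df["race"]) == {"White"}
        fit = ts.fit_full(small_study2_dataset, subset_groups=groups)
        assert fit.n_obs == len(sub.df)

    def test_consistency_error_shrinks_with_sample_size(self):
        # median |estimate - planted| should drop from small to large n
        errs = {}
        for n in (20, 80):
            e = []
            for seed in range(3):
                cfg = ts.SimulationConfig.study2(
                    seed=300 + seed, n_perceivers=n, slope_gamma=0.06
                )
                st = ts.simulate_study2(cfg)
                d = build_mlm_dataset(st.face_ratings, st.pairwise_ratings)
                f = ts.fit_full(d)
                e.append(abs(f.gamma_100.estimate - 0.06))
            errs[n] = float(np.median(e))
        assert errs[80] < errs[20] + 0.01


class TestR2Decomposition:
    def test_partitions_sum_to_one(self, small_study2_dataset):
        fit = ts.fit_full(small_study2_dataset)
        r2 = ts.r2_decomposition(fit, small_study2_dataset)
        assert r2.shares().sum() == pytest.approx(1.0, abs=1e-9)
        assert (r2.shares() >= 0).all()

    def test_zero_slope_zero_variance_gives_zero_partitions(
        self, small_study2_dataset
    ):
        fit = ts.fit_full(small_study2_dataset)
        import dataclasses

        zeroed = dataclasses.replace(
            fit,
            gamma_100=dataclasses.replace(fit.gamma_100, estimate=0.0),
            components=dataclasses.replace(
                fit.components, var_perceiver_slope=0.0
            ),
        )
        r2 = ts.r2_decomposition(zeroed, small_study2_dataset)
        assert r2.r2_f1_within == 0.0
        assert r2.r2_v_slope == 0.0
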