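import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import traitspace as ts
from traitspace.data_model import Design, GroupKey, Race, Gender
from traitspace.trait_space import (
    EmptyInputError,
    InsufficientDataError,
    IntegrityError,
    Scale,
    StateError,
    TraitCorrelationMatrix,
    Unit,
    canonical_pairs,
    fisher_z_vector,
)

WM = GroupKey(Race.WHITE, Gender.MALE)


def _face_table(records):
    return ts.RatingTable(
        df=pd.DataFrame(
            records,
            columns=["perceiver_id", "subject", "race", "gender", "trait", "rating"],
        ),
        design=Design.FACE_BETWEEN,
        trait_set=("warm", "dominant"),
    )


class TestTargetTraitMeans:
    def test_mean_of_two_ratings(self):
        table = _face_table(
            [
                ("a", "t1", "White", "male", "warm", 3),
                ("b", "t1", "White", "male", "warm", 5),
            ]
        )
        ttm = ts.target_trait_means(table, WM)
        assert ttm.means.loc["t1", "warm"] == 4.0
        assert ttm.n_ratings.loc["t1", "warm"] == 2

    def test_unrated_cell_is_missing_not_zero(self):
        table = _face_table(
            [
                ("a", "t1", "White", "male", "warm", 3),
                ("a", "t2", "White", "male", "dominant", 2),
            ]
        )
        ttm = ts.target_trait_means(table, WM)
        assert np.isnan(ttm.means.loc["t1", "dominant"])
        assert ttm.n_ratings.loc["t1", "dominant"] == 0

    def test_absent_group_raises(self):
        table = _face_table([("a", "t1", "White", "male", "warm", 3)])
        with pytest.raises(EmptyInputError):
            ts.target_trait_means(table, GroupKey(Race.BLACK, Gender.FEMALE))

    def test_recovers_generator_latent_means(self, small_study1):
        # target-level means should sit near 4 + latent within sampling error
        cfg = small_study1.truth["config"]
        g = cfg.groups[0]
        ttm = ts.target_trait_means(small_study1.face_ratings, g)
        diffs = (ttm.means - 4.0).to_numpy()
        # latents are standard normal; means of a few noisy Likert ratings
        assert np.nanmean(np.abs(diffs)) < 1.5


def _corr_from_columns(cols: dict) -> TraitCorrelationMatrix:
    df = pd.DataFrame(cols)
    from traitspace.trait_space import _pairwise_corr

    return _pairwise_corr(df, WM, Unit.TARGETS)


class TestTraitCorrelationMatrix:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),  # hand-computed Pearson
        ],
    )
    def test_pearson_oracle_values(self, x, y, expected):
        m = _corr_from_columns({"a": x, "b": y})
        assert m.r.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_units_raises_naming_pair(self):
        with pytest.raises(InsufficientDataError, match="'a'.*'b'"):
            _corr_from_columns({"a": [1, 2], "b": [2, 1]})

    def test_zero_variance_pair_marked_missing(self):
        m = _corr_from_columns({"a": [4, 4, 4], "b": [1, 2, 3]})
        assert np.isnan(m.r.loc["a", "b"])
        assert m.r.loc["a", "a"] == 1.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        m1 = _corr_from_columns({"a": x, "b": y})
        m2 = _corr_from_columns({"a": 2.5 * x + 7, "b": 0.3 * y - 2})
        assert m1.r.loc["a", "b"] == pytest.approx(m2.r.loc["a", "b"], abs=1e-12)

    def test_unit_routing_perceivers(self, small_study1):
        table = small_study1.abstract_ratings
        g = small_study1.truth["config"].groups[0]
        m = ts.trait_correlation_matrix(table, Unit.PERCEIVERS, group=g)
        assert m.unit is Unit.PERCEIVERS
        assert m.n_units == table.df["perceiver_id"].nunique()
        assert np.allclose(np.diag(m.r), 1.0)


class TestFisherZ:
    def test_zero_fixed_point(self):
        assert ts.fisher_z(0.0) == 0.0

    def test_half_log_three(self):
        assert ts.fisher_z(0.5) == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert ts.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_inverse_identity(self):
        assert ts.inverse_fisher_z(ts.fisher_z(0.3)) == pytest.approx(0.3, abs=1e-12)

    def test_unit_correlation_clamped_finite(self):
        assert np.isfinite(ts.fisher_z(1.0))
        assert np.isfinite(ts.fisher_z(-1.0))

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            ts.fisher_z(1.5)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, r):
        assert ts.inverse_fisher_z(ts.fisher_z(r)) == pytest.approx(r, abs=1e-9)


def _symmetric_matrix(k: int, seed: int = 0) -> TraitCorrelationMatrix:
    rng = np.random.default_rng(seed)
    a = rng.uniform(-0.8, 0.8, size=(k, k))
    r = (a + a.T) / 2
    np.fill_diagonal(r, 1.0)
    traits = [f"tr{i:02d}" for i in range(k)]
    return TraitCorrelationMatrix(
        group=WM, traits=traits, r=pd.DataFrame(r, index=traits, columns=traits),
        n_units=10, unit=Unit.TARGETS,
    )


class TestVectorizeAndStack:
    @pytest.mark.parametrize("k, expected", [(14, 91), (2, 1), (6, 15)])
    def test_upper_triangle_length(self, k, expected):
        v = ts.vectorize_upper(_symmetric_matrix(k))
        assert len(v) == expected
        assert len(v.pairs) == len(set(v.pairs))

    def test_asymmetric_matrix_rejected(self):
        m = _symmetric_matrix(4)
        m.r.iloc[0, 1] += 0.01
        with pytest.raises(IntegrityError):
            ts.vectorize_upper(m)

    def test_reconstruction_round_trip(self):
        m = _symmetric_matrix(6, seed=2)
        v = ts.vectorize_upper(m)
        rebuilt = np.eye(6)
        iu = np.triu_indices(6, 1)
        rebuilt[iu] = v.values
        rebuilt = rebuilt + np.triu(rebuilt, 1).T
        assert np.allclose(rebuilt, m.r.to_numpy())

    def test_stack_six_91_vectors_gives_546_rows(self):
        vectors = [
            ts.TraitPairVector(
                group=g, pairs=canonical_pairs([f"tr{i}" for i in range(14)]),
                values=np.zeros(91), scale=Scale.R,
            )
            for g in ts.ALL_GROUPS
        ]
        space = ts.stack_groups(vectors)
        assert len(space) == 546

    def test_stack_three_15_vectors_gives_45_rows(self):
        vectors = [
            ts.TraitPairVector(
                group=g, pairs=canonical_pairs(list(ts.STUDY2_TRAITS)),
                values=np.zeros(15), scale=Scale.Z,
            )
            for g in ts.ALL_GROUPS[:3]
        ]
        assert len(ts.stack_groups(vectors)) == 45

    def test_single_vector_stack_keeps_labels(self):
        v = ts.TraitPairVector(
            group=WM, pairs=[("a", "b")], values=np.array([0.4]), scale=Scale.R
        )
        space = ts.stack_groups([v])
        assert space.row_labels == [("White", "male", "a", "b")]
        assert space.values[0] == 0.4

    def test_mismatched_pair_lists_rejected(self):
        v1 = ts.TraitPairVector(
            group=WM, pairs=[("a", "b")], values=np.array([0.1]), scale=Scale.R
        )
        v2 = ts.TraitPairVector(
            group=GroupKey(Race.BLACK, Gender.MALE), pairs=[("a", "c")],
            values=np.array([0.1]), scale=Scale.R,
        )
        with pytest.raises(IntegrityError):
            ts.stack_groups([v1, v2])

    def test_csv_round_trip(self, tmp_path, study1_spaces):
        fs, _ = study1_spaces
        path = tmp_path / "space.csv"
        fs.write_csv(path)
        again = ts.StackedSpace.read_csv(path)
        assert again.scale is fs.scale and again.centered == fs.centered
        assert np.allclose(again.values, fs.values)
        assert again.row_labels == fs.row_labels


class TestCentering:
    def _space(self, per_group_values):
        vectors = []
        for g, vals in zip(ts.ALL_GROUPS, per_group_values):
            vectors.append(
                ts.TraitPairVector(
                    group=g, pairs=[("a", "b")], values=np.array([vals]),
                    scale=Scale.Z,
                )
            )
        return ts.stack_groups(vectors)

    def test_constant_pair_centered_to_zero(self):
        space = self._space([0.3] * 6)
        centered = ts.center_by_pair_mean(space)
        assert np.allclose(centered.values, 0.0)

    def test_hand_arithmetic(self):
        space = self._space([0.2, 0.4, 0.6, 0.2, 0.4, 0.6])
        centered = ts.center_by_pair_mean(space)
        assert np.allclose(
            centered.values, [-0.2, 0.0, 0.2, -0.2, 0.0, 0.2], atol=1e-12
        )

    def test_per_pair_mean_zero_after_centering(self, study1_spaces):
        fs, _ = study1_spaces
        centered = ts.center_by_pair_mean(fs)
        means = centered.data.groupby(["trait_a", "trait_b"])["value"].mean()
        assert np.allclose(means.to_numpy(), 0.0, atol=1e-12)

    def test_double_centering_rejected(self, study1_spaces):
        fs, _ = study1_spaces
        centered = ts.center_by_pair_mean(fs)
        with pytest.raises(StateError):
            ts.center_by_pair_mean(centered)


class TestFullPipeline:
    def test_fourteen_trait_six_group_stack_is_546_deterministic(self):
        cfg = ts.SimulationConfig.study1(
            seed=11, n_perceivers=40, n_targets_per_group=25,
            targets_per_perceiver=10,
        )
        study = ts.simulate_study1(cfg)
        fs = ts.face_space(study.face_ratings)
        assert len(fs) == 546
        labels = fs.row_labels
        # deterministic order: groups in declared order, 91 pairs per group
        assert labels == sorted(
            labels,
            key=lambda t: ([str(g) for g in ts.ALL_GROUPS].index(f"{t[0]} {t[1]}")),
        )
        fs2 = ts.face_space(ts.simulate_study1(cfg).face_ratings)
        assert np.array_equal(fs.values, fs2.values)
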