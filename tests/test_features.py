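import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import motorsig as ms
from motorsig.errors import (
    ConflictingLabelError,
    ConstantColumnError,
    TaskSkippedError,
    TimestampOrderError,
)
from motorsig.features import ALL_FEATURES, KINEMATIC_FEATURES

import _oracles
from conftest import DT, make_traj


class TestStepKinematics:
    def test_unit_steps_at_40hz(self):
        kin = ms.step_kinematics(make_traj([(0, 0), (1, 0), (2, 0)]))
        np.testing.assert_allclose(kin.speed, [40.0, 40.0])
        np.testing.assert_allclose(kin.acceleration, [0.0])
        np.testing.assert_allclose(kin.directional_change, [0.0])

    def test_345_step(self):
        kin = ms.step_kinematics(make_traj([(0, 0), (3, 4)]))
        np.testing.assert_allclose(kin.speed, [200.0])

    def test_stationary_step_speed_zero_heading_propagates(self):
        kin = ms.step_kinematics(make_traj([(0, 0), (0, 1), (0, 1), (1, 1)]))
        assert kin.speed[1] == 0.0
        # the zero-length step keeps the previous (upward) heading
        assert kin.heading[1] == kin.heading[0]
        assert kin.directional_change[0] == 0.0

    def test_duplicate_timestamp_raises(self):
        traj = make_traj([(0, 0), (1, 0), (2, 0)], t=[0.0, 0.025, 0.025])
        with pytest.raises(TimestampOrderError):
            ms.step_kinematics(traj)

    def test_series_length_invariants(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            traj = make_traj(rng.uniform(0, 100, (n, 2)))
            kin = ms.step_kinematics(traj)
            assert len(kin.speed) == n - 1
            assert len(kin.acceleration) == n - 2
            assert len(kin.directional_change) == n - 2
            assert np.all(kin.speed >= 0)
            assert kin.path_length >= kin.net_displacement >= 0


class TestStraightness:
    def test_collinear_path(self):
        assert ms.straightness_index(make_traj([(0, 0), (1, 0), (5, 0)])) == 1.0

    def test_right_angle(self):
        sth = ms.straightness_index(make_traj([(0, 0), (1, 0), (1, 1)]))
        assert sth == pytest.approx(math.sqrt(2.0) / 2.0, abs=1e-12)

    def test_closed_loop(self):
        sth = ms.straightness_index(
            make_traj([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        )
        assert sth == 0.0

    def test_zero_path_undefined(self):
        assert ms.straightness_index(make_traj([(3, 3), (3, 3)])) is None


class TestDirectionalChange:
    def test_straight_path(self):
        assert ms.directional_change_stats(
            make_traj([(0, 0), (1, 0), (2, 0), (3, 0)])
        ) == (0.0, 0.0)

    def test_single_right_turn_at_40hz(self):
        mean_dc, _sd = ms.directional_change_stats(make_traj([(0, 0), (1, 0), (1, 1)]))
        assert mean_dc == pytest.approx((math.pi / 2.0) / DT, rel=1e-12)
        assert mean_dc == pytest.approx(62.83185, abs=1e-4)

    def test_full_reversal_wraps_to_pi(self):
        mean_dc, _sd = ms.directional_change_stats(make_traj([(0, 0), (1, 0), (0, 0)]))
        assert mean_dc == pytest.approx(math.pi / DT, rel=1e-12)
        assert mean_dc == pytest.approx(125.66371, abs=1e-4)

    def test_never_exceeds_pi_over_dt(self, rng):
        for _ in range(50):
            traj = make_traj(rng.uniform(0, 10, (8, 2)))
            mean_dc, _ = ms.directional_change_stats(traj)
            dc = ms.step_kinematics(traj).directional_change
            assert np.all(dc <= math.pi / DT + 1e-9)

    def test_two_points_undefined(self):
        assert ms.directional_change_stats(make_traj([(0, 0), (1, 0)])) is None


def random_bouts(rng, n_trajs=None):
    """Random micro-bouts, each with enough points to define every feature."""
    if n_trajs is None:
        n_trajs = int(rng.integers(1, 4))
    bouts = []
    for _ in range(n_trajs):
        n = int(rng.integers(4, 9))
        t = np.cumsum(rng.uniform(0.01, 0.06, n))
        x = rng.uniform(0, 1280, n)
        y = rng.uniform(0, 800, n)
        bouts.append((t, x, y))
    return bouts


def featurize_bouts(bouts):
    trajs = [
        ms.Trajectory(t=t, x=x, y=y, subject_id="S", group="TD",
                      subtest_id=1, item_id=1)
        for t, x, y in bouts
    ]
    return ms.featurize_task(trajs, subtest_id=1, label="TD", subject_id="S")


class TestOracleEquivalence:
    def test_features_match_bruteforce_on_1000_random_trajectories(self, rng):
        total_trajs = 0
        while total_trajs < 1000:
            bouts = random_bouts(rng)
            total_trajs += len(bouts)
            got = featurize_bouts(bouts).kinematics
            want = _oracles.oracle_task_features(
                [(list(t), list(x), list(y)) for t, x, y in bouts]
            )
            for f in KINEMATIC_FEATURES:
                assert math.isclose(got[f], want[f], rel_tol=1e-9, abs_tol=1e-9), f

    def test_step_series_match_bruteforce(self, rng):
        for _ in range(200):
            ((t, x, y),) = random_bouts(rng, n_trajs=1)
            kin = ms.step_kinematics(
                ms.Trajectory(t=t, x=x, y=y)
            )
            want = _oracles.oracle_step_series(list(t), list(x), list(y))
            np.testing.assert_allclose(kin.speed, want["speed"], rtol=1e-9)
            np.testing.assert_allclose(kin.acceleration, want["acceleration"],
                                       rtol=1e-9)
            np.testing.assert_allclose(kin.directional_change, want["dc"],
                                       rtol=1e-9, atol=1e-9)


class TestEquivariance:
    @given(st.floats(0.1, 50.0), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, c, seed):
        """Coordinates x c: speeds/accelerations/lengths scale, STH/DC fixed."""
        rng = np.random.default_rng(seed)
        bouts = random_bouts(rng)
        base = featurize_bouts(bouts).kinematics
        scaled = featurize_bouts([(t, c * x, c * y) for t, x, y in bouts]).kinematics
        for f in ("MeanSpeed", "MaxSpeed", "MinSpeed", "sdSpeed",
                  "MeanAcceleration", "MaxAcceleration", "MinAcceleration",
                  "sdAcceleration", "MeanLength"):
            assert scaled[f] == pytest.approx(c * base[f], rel=1e-9)
        for f in ("STH", "DC", "sdDC"):
            assert scaled[f] == pytest.approx(base[f], rel=1e-9, abs=1e-12)

    @given(st.floats(0.1, 50.0), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_time_rescaling(self, c, seed):
        """Timestamps x c: speed and DC / c, acceleration / c^2, STH/length fixed."""
        rng = np.random.default_rng(seed)
        bouts = random_bouts(rng)
        base = featurize_bouts(bouts).kinematics
        rescaled = featurize_bouts([(c * t, x, y) for t, x, y in bouts]).kinematics
        for f in ("MeanSpeed", "MaxSpeed", "MinSpeed", "sdSpeed", "DC", "sdDC"):
            assert rescaled[f] == pytest.approx(base[f] / c, rel=1e-9)
        for f in ("MeanAcceleration", "MaxAcceleration", "MinAcceleration",
                  "sdAcceleration"):
            assert rescaled[f] == pytest.approx(base[f] / c ** 2, rel=1e-9)
        for f in ("STH", "MeanLength"):
            assert rescaled[f] == pytest.approx(base[f], rel=1e-9)


class TestFeaturizeTask:
    def test_single_straight_constant_speed_trajectory(self):
        traj = make_traj([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)])
        v = ms.featurize_task([traj], subtest_id=2, label="TD", subject_id="S")
        k = v.kinematics
        assert k["MeanSpeed"] == pytest.approx(40.0, rel=1e-12)
        assert k["MaxSpeed"] == pytest.approx(k["MeanSpeed"], rel=1e-12)
        assert k["MinSpeed"] == pytest.approx(k["MeanSpeed"], rel=1e-12)
        assert k["sdSpeed"] == pytest.approx(0.0, abs=1e-9)
        assert k["STH"] == 1.0
        assert k["DC"] == k["sdDC"] == 0.0
        assert k["MeanLength"] == 4.0

    def test_mean_length_averages_path_lengths(self):
        t1 = make_traj([(0, 0), (1, 0), (2, 0)])          # length 2
        t2 = make_traj([(0, 0), (2, 0), (4, 0)])          # length 4
        v = ms.featurize_task([t1, t2], subtest_id=1, label="TD")
        assert v.kinematics["MeanLength"] == 3.0

    def test_exactly_12_kinematic_entries(self):
        traj = make_traj([(0, 0), (1, 0), (2, 1), (3, 1)])
        v = ms.featurize_task([traj], subtest_id=1, label="ASD")
        assert len(v.kinematics) == 12
        assert set(v.kinematics) == set(KINEMATIC_FEATURES)

    def test_peak_aggregation_mean_of_per_bout_extrema(self):
        fast = make_traj([(0, 0), (2, 0), (4, 0)])   # speed 80
        slow = make_traj([(0, 0), (1, 0), (2, 0)])   # speed 40
        v = ms.featurize_task([fast, slow], subtest_id=1, label="TD")
        assert v.kinematics["MaxSpeed"] == pytest.approx((80.0 + 40.0) / 2.0)
        assert v.kinematics["MinSpeed"] == pytest.approx((80.0 + 40.0) / 2.0)
        assert v.kinematics["MeanSpeed"] == pytest.approx(60.0)

    def test_undefined_features_excluded_not_zero_filled(self):
        # 2-point bouts define speed but not DC; DC comes from the long bout only
        short = make_traj([(0, 0), (1, 0)])
        turn = make_traj([(0, 0), (1, 0), (1, 1), (2, 1)])
        v = ms.featurize_task([short, turn, short], subtest_id=1, label="TD")
        want_dc = np.mean(ms.step_kinematics(turn).directional_change)
        assert v.kinematics["DC"] == pytest.approx(want_dc)

    def test_no_trajectories_raises(self):
        with pytest.raises(TaskSkippedError):
            ms.featurize_task([], subtest_id=1, label="TD")

    def test_only_undefined_dc_raises(self):
        short = make_traj([(0, 0), (1, 0)])
        with pytest.raises(TaskSkippedError):
            ms.featurize_task([short, short], subtest_id=1, label="TD")

    def test_ordering_invariant_on_generated_data(self, default_table):
        table, _ = default_table
        df = table.df
        assert (df["MinSpeed"] <= df["MeanSpeed"] + 1e-12).all()
        assert (df["MeanSpeed"] <= df["MaxSpeed"] + 1e-12).all()
        assert (df["MinAcceleration"] <= df["MeanAcceleration"] + 1e-12).all()
        assert (df["MeanAcceleration"] <= df["MaxAcceleration"] + 1e-12).all()
        assert df["STH"].between(0.0, 1.0).all()


class TestAssembleDataset:
    def test_default_cohort_1500_rows(self, default_table):
        table, _ = default_table
        assert len(table) == 1500

    def test_17_feature_columns(self, default_table):
        table, _ = default_table
        assert table.X.shape[1] == 17
        assert list(table.df.columns[:17]) == list(ALL_FEATURES)

    def test_indicator_one_hot(self, default_table):
        table, _ = default_table
        ind = table.df[list(ms.INDICATOR_FEATURES)].to_numpy()
        np.testing.assert_array_equal(ind.sum(axis=1), np.ones(len(table)))
        assert set(np.unique(ind)) == {0.0, 1.0}

    def test_single_vector(self):
        traj = make_traj([(0, 0), (1, 0), (2, 1), (3, 1)])
        v = ms.featurize_task([traj], subtest_id=3, label="ASD", subject_id="a")
        table = ms.assemble_dataset([v])
        assert len(table) == 1
        assert table.df["task_CA"].iloc[0] == 1.0
        assert table.df[list(ms.INDICATOR_FEATURES)].iloc[0].sum() == 1.0

    def test_conflicting_labels_rejected(self):
        traj = make_traj([(0, 0), (1, 0), (2, 1), (3, 1)])
        v1 = ms.featurize_task([traj], subtest_id=1, label="ASD", subject_id="a")
        v2 = ms.featurize_task([traj], subtest_id=2, label="TD", subject_id="a")
        with pytest.raises(ConflictingLabelError):
            ms.assemble_dataset([v1, v2])


class TestStandardize:
    def make_table(self, col):
        rows = []
        rng = np.random.default_rng(0)
        for i, v in enumerate(col):
            row = {f: rng.normal() for f in KINEMATIC_FEATURES}
            row["MeanSpeed"] = float(v)
            for j, ind in enumerate(ms.INDICATOR_FEATURES):
                row[ind] = 1.0 if j == 0 else 0.0
            row["label"] = "TD"
            row["subject_id"] = f"s{i}"
            rows.append(row)
        return ms.FeatureTable(pd.DataFrame(rows))

    def test_123_column(self):
        table = self.make_table([1.0, 2.0, 3.0])
        out, params = ms.standardize(table, "fit")
        np.testing.assert_allclose(out.df["MeanSpeed"], [-1.0, 0.0, 1.0])
        i = KINEMATIC_FEATURES.index("MeanSpeed")
        assert params.mean[i] == 2.0 and params.sd[i] == 1.0  # sample SD

    def test_fitted_columns_zero_mean_unit_sd(self, default_table):
        table, _ = default_table
        out, _ = ms.standardize(table, "fit")
        kin = out.df[list(KINEMATIC_FEATURES)]
        np.testing.assert_allclose(kin.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(kin.std(ddof=1), 1.0, atol=1e-12)

    def test_indicators_untouched(self, default_table):
        table, _ = default_table
        out, _ = ms.standardize(table, "fit")
        pd.testing.assert_frame_equal(
            out.df[list(ms.INDICATOR_FEATURES)],
            table.df[list(ms.INDICATOR_FEATURES)],
        )

    def test_constant_column_raises(self):
        table = self.make_table([5.0, 5.0, 5.0])
        with pytest.raises(ConstantColumnError, match="MeanSpeed"):
            ms.standardize(table, "fit")

    def test_params_reusable_on_heldout(self):
        table = self.make_table([1.0, 2.0, 3.0, 4.0])
        _, params = ms.standardize(table, "fit")
        other = self.make_table([10.0])
        out, params2 = ms.standardize(other, params)
        assert params2 is params
        i = "MeanSpeed"
        mean, sd = 2.5, np.std([1, 2, 3, 4], ddof=1)
        assert out.df[i].iloc[0] == pytest.approx((10.0 - mean) / sd)
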