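"""Trajectory reshaping, speeds, seed selection, PCA projection, hulls."""

import numpy as np
import pytest

from actspace import (FormatError, SampleStore, TrajectorySet, differentiate,
                      filter_by_delta, fit_pc_per_timestep, hull_area,
                      max_abs_speed, occupancy_summary, project,
                      reshape_to_trajectories, seeded_reduction_ratio,
                      select_seeds)


def make_ts(data, muscles=None):
    data = np.asarray(data, dtype=float)
    muscles = muscles or tuple(f"m{i + 1}" for i in range(data.shape[2]))
    return TrajectorySet(data=data, muscle_names=muscles,
                         times=tuple(range(data.shape[1])))


class TestReshape:
    def test_49_columns_become_7x7_grid(self, unseeded_store_012):
        ts = reshape_to_trajectories(unseeded_store_012)
        assert ts.data.shape == (unseeded_store_012.n_samples, 7, 7)

    def test_label_driven_not_positional(self):
        labels = (("a", 0), ("b", 0), ("a", 1), ("b", 1))
        samples = np.array([[1.0, 2.0, 3.0, 4.0]])
        ts1 = reshape_to_trajectories(SampleStore(samples, labels))
        perm = [2, 0, 3, 1]
        ts2 = reshape_to_trajectories(
            SampleStore(samples[:, perm], tuple(labels[i] for i in perm)))
        np.testing.assert_array_equal(ts1.data, ts2.data)

    def test_incomplete_grid_lists_missing_labels(self):
        labels = (("a", 0), ("b", 0), ("a", 1))
        with pytest.raises(FormatError, match=r"\('b', 1\)"):
            reshape_to_trajectories(SampleStore(np.zeros((2, 3)), labels))


class TestSpeeds:
    def test_constant_trajectory_has_zero_speed(self):
        ts = make_ts(np.full((3, 5, 2), 0.4))
        assert np.all(differentiate(ts).data == 0.0)

    def test_linear_ramp_speed(self):
        ramp = np.linspace(0.0, 0.6, 7)  # 6 intervals of 0.1
        ts = make_ts(ramp[None, :, None])
        np.testing.assert_allclose(differentiate(ts).data, 0.1, atol=1e-12)

    def test_single_step_by_definition(self):
        ts = make_ts(np.array([[[0.2], [0.32]]]))
        assert differentiate(ts).data[0, 0, 0] == pytest.approx(0.12)

    def test_max_abs_speed(self):
        ss = differentiate(make_ts(np.array([[[0.0], [0.1], [-0.2], [0.0]]])))
        # speeds 0.1, -0.3, 0.2
        assert max_abs_speed(ss)[0, 0] == pytest.approx(0.3)

    def test_max_abs_speed_zero_for_constant(self):
        ss = differentiate(make_ts(np.full((2, 4, 3), 0.7)))
        assert np.all(max_abs_speed(ss) == 0.0)


class TestFilterAndSeeds:
    @pytest.fixture
    def known_maxima_ts(self):
        # five 1-muscle trajectories with max |speed| 0.05/0.10/0.12/0.20/0.50
        rows = [np.cumsum([0.2, m, -m, m]) for m in
                (0.05, 0.10, 0.12, 0.20, 0.50)]
        return make_ts(np.array(rows)[:, :, None])

    def test_filter_keeps_known_count(self, known_maxima_ts):
        assert filter_by_delta(known_maxima_ts, 0.12).n_traj == 3

    def test_filter_delta_one_keeps_everything(self, known_maxima_ts):
        assert filter_by_delta(known_maxima_ts, 1.0).n_traj == 5

    def test_filter_delta_zero_keeps_only_constant(self, known_maxima_ts):
        const = make_ts(np.full((2, 4, 1), 0.3))
        assert filter_by_delta(const, 0.0).n_traj == 2
        assert filter_by_delta(known_maxima_ts, 0.0).n_traj == 0

    def test_select_all_seeds_returns_first_slices(self, known_maxima_ts):
        seeds = select_seeds(known_maxima_ts, 5, rng_seed=0)
        got = sorted(float(s.activation[0]) for s in seeds)
        assert got == pytest.approx([0.2] * 5)

    def test_select_seeds_deterministic(self, known_maxima_ts):
        s1 = select_seeds(known_maxima_ts, 3, rng_seed=9)
        s2 = select_seeds(known_maxima_ts, 3, rng_seed=9)
        assert all(np.array_equal(a.activation, b.activation)
                   for a, b in zip(s1, s2))

    def test_too_many_seeds_rejected(self, known_maxima_ts):
        with pytest.raises(ValueError):
            select_seeds(known_maxima_ts, 6, rng_seed=0)

    def test_selected_seeds_are_first_moment_feasible(
            self, unseeded_store_012, synth_model, synth_seq):
        ts = reshape_to_trajectories(unseeded_store_012)
        for seed in select_seeds(filter_by_delta(ts, 0.12), 5, rng_seed=1):
            resid = np.abs(synth_model.values @ seed.activation - synth_seq[0])
            assert resid.max() <= 1e-6 * (1 + np.abs(synth_seq[0]).max())


class TestPCA:
    def test_planar_data_fully_explained(self):
        rng = np.random.default_rng(0)
        basis = np.array([[1.0, 0, 0, 1.0], [0, 1.0, -1.0, 0]]) / np.sqrt(2)
        coords = rng.uniform(-0.2, 0.2, size=(50, 2))
        X = 0.5 + coords @ basis
        ts = make_ts(X[:, None, :].repeat(2, axis=1))
        model = fit_pc_per_timestep(ts)[0]
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert model.n_informative == 2

    def test_duplicated_dataset_gives_identical_model(self, unseeded_store_012):
        ts = reshape_to_trajectories(unseeded_store_012)
        doubled = make_ts(np.concatenate([ts.data, ts.data]),
                          muscles=ts.muscle_names)
        m1 = fit_pc_per_timestep(ts)[2]
        m2 = fit_pc_per_timestep(doubled)[2]
        np.testing.assert_allclose(m1.mean, m2.mean, atol=1e-12)
        np.testing.assert_allclose(m1.components, m2.components, atol=1e-9)

    def test_toy_segment_single_informative_direction(self, segment_spec):
        from actspace import ChainConfig, hit_and_run
        store = hit_and_run(segment_spec, ChainConfig(n_samples=500, rng_seed=8))
        ts = make_ts(store.samples[:, None, :], muscles=("m1", "m2"))
        model = fit_pc_per_timestep(ts)[0]
        assert model.n_informative == 1
        expected = np.array([1.0, -1.0]) / np.sqrt(2)
        np.testing.assert_allclose(np.abs(model.components[0]),
                                   np.abs(expected), atol=1e-9)
        # sign convention: largest-magnitude loading is positive
        assert model.components[0][np.argmax(np.abs(model.components[0]))] > 0

    def test_projection_of_center_is_origin(self, unseeded_store_012):
        ts = reshape_to_trajectories(unseeded_store_012)
        models = fit_pc_per_timestep(ts)
        np.testing.assert_allclose(project(models[1].mean, models, 1),
                                   [[0.0, 0.0]], atol=1e-9)

    def test_projection_preserves_in_plane_distances(self, unseeded_store_012):
        ts = reshape_to_trajectories(unseeded_store_012)
        models = fit_pc_per_timestep(ts)
        m = models[3]
        rng = np.random.default_rng(1)
        coords = rng.standard_normal((10, 2))
        pts = m.mean + coords @ m.components
        proj = project(pts, models, 3)
        d_in = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        d_out = np.linalg.norm(proj[:, None] - proj[None, :], axis=-1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)

    def test_out_of_range_slice_rejected(self, unseeded_store_012):
        ts = reshape_to_trajectories(unseeded_store_012)
        models = fit_pc_per_timestep(ts)
        with pytest.raises(IndexError):
            project(ts, models, 99)

    def test_too_few_trajectories_rejected(self):
        ts = make_ts(np.zeros((3, 2, 7)))
        with pytest.raises(ValueError):
            fit_pc_per_timestep(ts)


class TestHulls:
    def test_unit_square_corners(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert hull_area(pts) == pytest.approx(1.0)

    def test_right_triangle(self):
        assert hull_area([(0, 0), (1, 0), (0, 1)]) == pytest.approx(0.5)

    def test_collinear_points_flagged_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert hull_area([(0, 0), (0.5, 0.5), (1, 1)]) == 0.0

    def test_too_few_points_flagged_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert hull_area([(0, 0), (1, 1)]) == 0.0

    def test_identical_sets_give_unit_ratio(self):
        pts = [(0, 0), (2, 0), (2, 1), (0, 1)]
        assert seeded_reduction_ratio(pts, pts) == pytest.approx(1.0)

    def test_degenerate_outer_hull_rejected(self):
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ValueError, match="degenerate"):
                seeded_reduction_ratio([(0, 0), (1, 0), (0, 1)],
                                       [(0, 0), (1, 1)])

    def test_ratio_invariant_to_plane_rotation_and_sign(self):
        rng = np.random.default_rng(2)
        inner = rng.uniform(0.2, 0.4, size=(40, 2))
        outer = rng.uniform(0.0, 1.0, size=(80, 2))
        base = seeded_reduction_ratio(inner, outer)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert seeded_reduction_ratio(inner @ R.T, outer @ R.T) == \
            pytest.approx(base, rel=1e-9)
        flip = np.diag([1.0, -1.0])
        assert seeded_reduction_ratio(inner @ flip, outer @ flip) == \
            pytest.approx(base, rel=1e-9)


class TestOccupancy:
    def test_constant_trajectories_have_zero_width(self):
        ts = make_ts(np.full((4, 5, 2), 0.25))
        table = occupancy_summary(ts)
        assert np.all(table["act_min"] == table["act_max"])
        assert np.all(table["max_abs_speed"] == 0.0)

    def test_quartiles_match_hand_computation(self):
        # one muscle visiting 1..8 across two trajectories of four steps
        data = np.array([[[1], [2], [3], [4]], [[5], [6], [7], [8]]],
                        dtype=float) / 8.0
        table = occupancy_summary(ts := make_ts(data))
        # linear-interpolation quartiles of {1..8}/8
        assert table["act_q25"].iloc[0] == pytest.approx(2.75 / 8)
        assert table["act_median"].iloc[0] == pytest.approx(4.5 / 8)
        assert table["act_q75"].iloc[0] == pytest.approx(6.25 / 8)
        assert ts.n_muscles == 1

    def test_speed_maxima_shrink_with_tighter_rate_limit(
            self, synth_model, synth_seq):
        from actspace import (ChainConfig, build_trajectory_polytope,
                              hit_and_run, reshape_to_trajectories)
        maxima = {}
        for delta in (0.5, 0.12):
            spec = build_trajectory_polytope(synth_model, synth_seq, delta)
            store = hit_and_run(spec, ChainConfig(n_samples=300, burn_in=400,
                                                  thin=3, rng_seed=12))
            table = occupancy_summary(reshape_to_trajectories(store))
            maxima[delta] = table["max_abs_speed"].to_numpy()
        assert np.all(maxima[0.12] <= maxima[0.5] + 1e-9)
        assert np.all(maxima[0.12] <= 0.12 + 1e-9)
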