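import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from lymphwalk import simulator
from lymphwalk.simulator import (EfficiencyResult, TargetSet, WalkerSpec,
                                 compare_models, efficiency_experiment,
                                 generate_walker_track,
                                 generate_walker_tracks, hopkins_3d,
                                 place_targets, run_search)

from conftest import make_track, straight_track

BOX = (400.0, 315.0, 50.0)


class TestPlaceTargets:
    def test_default_density_gives_200_targets(self, rng):
        ts = place_targets(BOX, cluster_radius=10.0, rng=rng)
        assert ts.n == 200  # round(3.17e-5 * 6.3e6)

    def test_points_inside_box(self, rng):
        for radius in (None, 10.0, 40.0):
            ts = place_targets(BOX, cluster_radius=radius, rng=rng)
            assert np.all(ts.points >= 0) and np.all(ts.points <= BOX)

    def test_zero_targets_error(self, rng):
        with pytest.raises(ValueError):
            place_targets((1.0, 1.0, 1.0), rng=rng)

    def test_bad_radius_error(self, rng):
        with pytest.raises(ValueError):
            place_targets(BOX, cluster_radius=-5.0, rng=rng)


class TestHopkins:
    def test_uniform_points_near_half(self, rng):
        vals = [hopkins_3d(rng.uniform(0, 1, (200, 3)) * BOX, BOX,
                           m=20, reps=100, rng=rng) for _ in range(10)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_coincident_points_zero(self, rng):
        pts = np.tile([[200.0, 150.0, 25.0]], (50, 1))
        assert hopkins_3d(pts, BOX, m=10, reps=20, rng=rng) == pytest.approx(0.0)

    def test_clustered_below_uniform(self, rng):
        clustered = place_targets(BOX, cluster_radius=10.0, rng=1).points
        uniform = place_targets(BOX, cluster_radius=None, rng=2).points
        h_c = hopkins_3d(clustered, BOX, reps=100, rng=3)
        h_u = hopkins_3d(uniform, BOX, reps=100, rng=4)
        assert h_c < h_u - 0.1

    def test_matches_exhaustive_nearest_neighbour_oracle(self):
        # replicate the internal sampling stream and recompute u, w by
        # brute-force double loops
        pts = np.random.default_rng(0).uniform(0, 1, (20, 3)) * BOX
        m, seed = 7, 42
        got = hopkins_3d(pts, BOX, m=m, reps=1, rng=seed)
        r = np.random.default_rng(seed)
        probes = np.zeros(3) + r.uniform(size=(m, 3)) * np.asarray(BOX)
        u = [min(np.linalg.norm(p - q) for q in pts) for p in probes]
        idx = r.choice(len(pts), size=m, replace=False)
        w = [min(np.linalg.norm(pts[i] - pts[j]) for j in range(len(pts))
                 if j != i) for i in idx]
        assert got == pytest.approx(sum(w) / (sum(u) + sum(w)), rel=1e-12)

    def test_m_validation(self):
        pts = np.random.default_rng(0).uniform(0, 1, (20, 3)) * BOX
        with pytest.raises(ValueError):
            hopkins_3d(pts, BOX, m=3)
        with pytest.raises(ValueError):
            hopkins_3d(pts, BOX, m=30)


class TestWalkers:
    def test_unknown_model_error(self):
        with pytest.raises(ValueError):
            generate_walker_tracks("run_and_tumble", 1, BOX, 15.0, 10)

    def test_deterministic_given_seed(self):
        kw = dict(speed_params={"mu": -2.5, "sigma": 0.9},
                  angle_params={"shape": 2.0, "scale": 20.0})
        a = generate_walker_tracks("logmcrw", 5, BOX, 15.0, 20, rng=77, **kw)
        b = generate_walker_tracks("logmcrw", 5, BOX, 15.0, 20, rng=77, **kw)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.xyz, tb.xyz)

    @pytest.mark.parametrize("model,kw", [
        ("brownian", {"speed_params": {"a": 0.1}}),
        ("lognormal", {"speed_params": {"mu": -2.5, "sigma": 0.9}}),
        ("crw", {"speed_params": {"mu": 0.13, "sigma": 0.08},
                 "angle_params": {"shape": 2.0, "scale": 20.0}}),
        ("powerlaw", {"step_params": {"mu": 2.0, "x_min": 5.0,
                                      "mean_speed": 0.13}}),
    ])
    def test_confined_to_box(self, model, kw):
        tracks = generate_walker_tracks(model, 20, BOX, 15.0, 30, rng=5, **kw)
        for tr in tracks:
            assert np.all(tr.xyz >= -1e-9)
            assert np.all(tr.xyz <= np.asarray(BOX) + 1e-9)
            assert tr.n_positions == 31

    def test_bootstrap_single_speed_pool(self):
        pool = (np.full(50, 0.1), np.random.default_rng(0).uniform(0, 60, 50))
        tr = generate_walker_track(
            WalkerSpec(model="bootstrap", pool=pool), BOX, 15.0, 300.0, rng=1)
        step_norms = np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1)
        np.testing.assert_allclose(step_norms, 0.1 * 15.0, rtol=1e-9)

    def test_distance_budget_stops_walker(self):
        spec = WalkerSpec(model="brownian", speed_params={"a": 0.1},
                          distance_budget=5.0)
        tr = generate_walker_track(spec, BOX, 15.0, 600.0, rng=2)
        assert tr.path_length <= 5.0 + 0.1 * 15.0 * 4  # a few frames overshoot

    def test_global_budget_caps_cohort(self):
        tracks = generate_walker_tracks(
            "brownian", 10, BOX, 15.0, 40, speed_params={"a": 0.1},
            global_budget=100.0, rng=3)
        total = sum(tr.path_length for tr in tracks)
        assert total <= 100.0 + 10 * 0.3 * 15.0  # one frame of overshoot


def segment_point_distance_oracle(a, b, p):
    f = lambda t: np.linalg.norm(a + t * (b - a) - p)
    res = minimize_scalar(f, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    return min(f(0.0), f(1.0), res.fun)


class TestRunSearch:
    def test_single_target_near_straight_path(self):
        # 10-minute track passes 5 um from the target
        tr = straight_track(n=41, speed=0.2, dt=15.0)  # 600 s
        targets = TargetSet(np.array([[60.0, 5.0, 0.0]]), None, 1, 0.0)
        res = run_search([tr], targets)
        assert (res.unique_contacts, res.total_contacts) == (1, 1)
        assert res.efficiency_unique == pytest.approx(0.1)

    def test_no_target_in_radius(self):
        tr = straight_track(n=10, speed=0.2)
        targets = TargetSet(np.array([[0.0, 50.0, 0.0]]), None, 1, 0.0)
        res = run_search([tr], targets)
        assert res.unique_contacts == res.total_contacts == 0

    def test_reentry_counted_in_total_not_unique(self):
        xs = [-30, -15, -5, -15, -30, -15, -5]
        xyz = np.column_stack([xs, np.zeros(7), np.zeros(7)])
        tr = make_track(xyz)
        targets = TargetSet(np.array([[0.0, 0.0, 0.0]]), None, 1, 0.0)
        res = run_search([tr], targets)
        assert res.unique_contacts == 1
        assert res.total_contacts == 2

    def test_zero_searcher_time_error(self):
        tr = straight_track(n=2)
        targets = TargetSet(np.zeros((1, 3)), None, 1, 0.0)
        with pytest.raises(ValueError):
            run_search([tr], targets, searcher_time_min=0.0)

    def test_contact_matrix_matches_numeric_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            tr = make_track(rng.uniform(0, 100, (n, 3)))
            pts = rng.uniform(0, 100, (int(rng.integers(1, 15)), 3))
            radius = float(rng.uniform(5, 30))
            got = simulator._segment_contacts(tr, pts, radius)
            for s in range(n - 1):
                for t in range(len(pts)):
                    d = segment_point_distance_oracle(tr.xyz[s], tr.xyz[s + 1],
                                                      pts[t])
                    if abs(d - radius) > 1e-6:  # skip knife-edge cases
                        assert got[s, t] == (d <= radius)


class TestCompareModels:
    def test_identical_distributions(self, rng):
        samples = [rng.gamma(2, 1, 200) for _ in range(5)]
        out = compare_models(samples, [s.copy() for s in samples])
        assert abs(out["pct_change_median"]) < 1e-9
        assert out["p_all"] >= 0.05

    def test_shifted_distribution_detected(self, rng):
        ref = [rng.gamma(2, 1, 1000) for _ in range(5)]
        model = [1.5 * r for r in ref]
        out = compare_models(model, ref)
        assert out["pct_change_median"] == pytest.approx(50.0, abs=5.0)
        assert out["p_all"] < 1e-3

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            compare_models([[]], [[1.0, 2.0]])


class TestEfficiencyExperiment:
    def test_observed_reference_and_schema(self, filtered_field, walker_params):
        table = efficiency_experiment(
            filtered_field, models=("brownian",), cluster_radii=(10.0,),
            replicates=4, reps=2, params=walker_params, rng=0)
        assert set(table.columns) == {"field", "model", "radius", "rep",
                                      "replicate", "efficiency_unique",
                                      "efficiency_total"}
        assert set(table.model) == {"observed", "brownian"}
        obs = table[table.model == "observed"]
        out = compare_models(
            [g.efficiency_unique.to_numpy() for _, g in obs.groupby("rep")],
            [g.efficiency_unique.to_numpy() for _, g in obs.groupby("rep")])
        assert out["pct_change_median"] == pytest.approx(0.0)

    def test_unique_never_exceeds_total(self, filtered_field, walker_params):
        table = efficiency_experiment(
            filtered_field, models=("logmcrw",), cluster_radii=(10.0,),
            replicates=4, reps=2, params=walker_params, rng=1)
        assert np.all(table.efficiency_total >= table.efficiency_unique - 1e-12)

    def test_contacts_monotone_in_detection_radius(self, filtered_field, rng):
        targets = place_targets(filtered_field.bbox, cluster_radius=10.0,
                                rng=rng)
        res = [run_search(filtered_field.tracks, targets, detection_radius=r)
               for r in (5.0, 10.0, 20.0)]
        uniq = [r.unique_contacts for r in res]
        tot = [r.total_contacts for r in res]
        assert uniq == sorted(uniq)
        assert tot == sorted(tot)
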