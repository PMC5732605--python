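"""Stationary-point criteria, Methods A and B, theorem check, clusters."""

import numpy as np
import pytest

import tcnet as tc

CFS = tc.CombinationFunctionSpec


@pytest.mark.parametrize(
    "agg,value,expected",
    [(0.6, 0.2, "increasing"), (0.2, 0.2, "stationary"), (0.1, 0.2, "decreasing")],
)
def test_classify_step(agg, value, expected):
    assert tc.classify_step(agg, value) == expected


def synthetic_trajectory(times, series):
    cols = tuple(series)
    data = np.column_stack([series[c] for c in cols])
    return tc.Trajectory(times=np.asarray(times), columns=cols, data=data)


class TestDetectStationaryPoints:
    def test_monotone_trace_has_no_extrema(self):
        t = np.linspace(0, 10, 101)
        traj = synthetic_trajectory(t, {"Y": 1 - np.exp(-t)})
        records = tc.detect_stationary_points(traj, "Y", slope_tol=1e-6)
        assert not [r for r in records if r.kind in ("maximum", "minimum")]

    def test_oscillation_alternates_maxima_and_minima(self):
        t = np.linspace(0, 4 * np.pi, 800)
        traj = synthetic_trajectory(t, {"Y": 0.5 + 0.4 * np.sin(t)})
        records = [
            r for r in tc.detect_stationary_points(traj, "Y", slope_tol=0.0)
            if r.kind in ("maximum", "minimum")
        ]
        kinds = [r.kind for r in records]
        assert kinds == ["maximum", "minimum", "maximum", "minimum"]
        peaks = [r.time for r in records if r.kind == "maximum"]
        assert peaks == pytest.approx([np.pi / 2, np.pi * 5 / 2], abs=0.05)
        assert [r.value for r in records if r.kind == "maximum"] == pytest.approx([0.9, 0.9], abs=1e-3)

    def test_constant_trace_is_one_plateau(self):
        t = np.linspace(0, 5, 51)
        traj = synthetic_trajectory(t, {"Y": np.full_like(t, 0.3)})
        records = tc.detect_stationary_points(traj, "Y", slope_tol=1e-9)
        assert len(records) == 1
        assert records[0].kind == "plateau"
        assert records[0].time == t[-1]  # spans the whole range, recorded at its end


class TestMethodA:
    def converged_run(self):
        net = tc.NetworkSpec(
            states=[
                tc.StateConfig("X", clamped=True),
                tc.StateConfig("Y", speed=0.8, combiner=CFS("ssum", {"lam": 2.0})),
                tc.StateConfig("Z", speed=0.5, combiner=CFS("sum")),
            ],
            connections=[
                tc.Connection("X", "Y", 1.0),
                tc.Connection("Z", "Y", 1.0),
                tc.Connection("Y", "Z", 0.6),
            ],
        )
        traj = tc.simulate(
            net, {"X": 0.8, "Y": 0.1, "Z": 0.1},
            tc.SimulationSettings(dt=0.01, t_end=70.0, record_stride=10),
        )
        return net, traj

    def test_correct_integration_passes(self):
        net, traj = self.converged_run()
        report = tc.verify_method_A(traj, net, tolerance=0.05)
        assert report.passed and not report.failures
        plateaus = [r for r in report.records if r.kind == "plateau"]
        assert {r.state for r in plateaus} == {"Y", "Z"}
        # at the true equilibrium the residual is far below the 0.05 tolerance
        assert all(r.residual < 1e-6 for r in plateaus)

    def test_injected_offset_fault_is_caught(self):
        net, traj = self.converged_run()
        data = traj.data.copy()
        data[:, traj.index_of("Y")] += 0.2
        corrupted = tc.Trajectory(traj.times, traj.columns, data)
        report = tc.verify_method_A(corrupted, net, tolerance=0.05)
        assert not report.passed
        assert any(r.state == "Y" for r in report.failures)

    def test_damped_oscillation_peaks_pass(self):
        """Peaks and dips are stationary points; substitution holds there too."""
        net = tc.NetworkSpec(
            states=[
                tc.StateConfig("U", speed=1.0, combiner=CFS("sum")),
                tc.StateConfig("V", speed=1.0, combiner=CFS("sum")),
            ],
            connections=[
                tc.Connection("V", "U", -1.0),
                tc.Connection("U", "U", 0.9),
                tc.Connection("U", "V", 1.0),
                tc.Connection("V", "V", 0.9),
            ],
        )
        traj = tc.simulate(
            net, {"U": 0.8, "V": 0.2},
            tc.SimulationSettings(dt=0.005, t_end=25.0, clip_unit_interval=False),
        )
        report = tc.verify_method_A(traj, net, tolerance=0.05, slope_tol=1e-7)
        extrema = [r for r in report.records if r.kind in ("maximum", "minimum")]
        assert len(extrema) >= 4  # several peaks and dips of the spiral
        assert report.passed

    def test_state_mismatch_rejected(self):
        net, traj = self.converged_run()
        renamed = tc.Trajectory(traj.times, ("X", "Y", "Q"), traj.data)
        with pytest.raises(tc.InputMismatchError):
            tc.verify_method_A(renamed, net)


class TestMethodB:
    def brute_force_mbm(self, w0, eta=0.3, dt=0.001, t_end=80.0):
        """Independent oracle: integrate the k+1 averaging equations directly."""
        w = np.asarray(w0, dtype=float)
        k = w.size - 1
        for _ in range(int(t_end / dt)):
            peer_mean = (w.sum() - w) / k
            w = w + eta * (peer_mean - w) * dt
        return w

    def test_linear_solve_matches_brute_force(self):
        predicted = tc.solve_equilibrium_linear_mbm(2, [0.2, 0.5, 0.8])
        assert predicted == pytest.approx([0.5, 0.5, 0.5], abs=1e-12)
        oracle = self.brute_force_mbm([0.2, 0.5, 0.8])
        assert predicted == pytest.approx(oracle, abs=1e-6)

    def test_two_weight_system_averages(self):
        predicted = tc.solve_equilibrium_linear_mbm(1, [0.2, 0.6])
        assert predicted == pytest.approx([0.4, 0.4], abs=1e-12)

    def test_equal_weights_are_already_the_solution(self):
        assert tc.solve_equilibrium_linear_mbm(3, [0.7] * 4) == pytest.approx([0.7] * 4)

    def test_input_length_checked(self):
        with pytest.raises(tc.UsageError):
            tc.solve_equilibrium_linear_mbm(2, [0.2, 0.5])


class TestSymmetricFixedPoint:
    def test_scaled_sum_is_the_identity_map(self):
        with pytest.raises(tc.IdentityMapError):
            tc.solve_symmetric_fixed_point(CFS("ssum", {"lam": 3.0}), k=3)

    def test_unique_logistic_fixed_point(self):
        fn = CFS("alogistic", {"sigma": 3.0, "tau": 0.5})
        assert tc.count_fixed_point_sign_changes(fn, k=3, grid_points=10_000) == 1
        w = tc.solve_symmetric_fixed_point(fn, k=3)
        assert abs(tc.evaluate(fn, [w] * 3) - w) < 1e-10

    def test_bistable_logistic_reports_multiple_crossings(self):
        # steep sigmoid with a high threshold: 0, an unstable interior point
        # and a high stable point all solve w = c(w, w, w)
        fn = CFS("alogistic", {"sigma": 5.0, "tau": 1.0})
        assert tc.count_fixed_point_sign_changes(fn, k=3, grid_points=10_000) == 2

    def test_saturated_threshold_pins_zero(self):
        fn = CFS("alogistic", {"sigma": 3.0, "tau": 3.0})
        assert tc.solve_symmetric_fixed_point(fn, k=2) == 0.0

    def test_no_fixed_point_reported(self):
        # c(w) = w + 0.1 stays strictly above the diagonal on all of [0, 1]
        with pytest.raises(tc.NoFixedPointError):
            tc.solve_symmetric_fixed_point(lambda v: v[0] + 0.1, k=1)


def test_mbm_logistic_response_is_non_increasing():
    from tcnet.analysis import mbm_logistic_response

    v = np.linspace(0, 1, 500)
    for sigma, kappa, mu, nu in [(3, 0.5, 0.1, 1.2), (8, 2.0, 0.05, 1.01), (1, 0.01, 0.5, 2.0)]:
        f = mbm_logistic_response(v, sigma, kappa, mu, nu)
        assert np.all(np.diff(f) <= 0)


class TestHomophilyStationaryClassification:
    @pytest.mark.parametrize(
        "omega,va,vb,expected",
        [
            (0.0, 0.3, 0.9, "ZERO"),
            (1.0, 0.3, 0.9, "ONE"),
            (0.4, 0.5, 0.525, "THRESHOLD_DIFF"),
            (0.4, 0.5, 0.9, "NOT_STATIONARY"),
        ],
    )
    def test_three_types(self, omega, va, vb, expected):
        assert tc.classify_homophily_stationary(omega, va, vb, 0.025, tol=1e-12) == expected

    def test_boundary_precedence_over_threshold(self):
        # both conditions hold; the weight-boundary label is the informative one
        assert tc.classify_homophily_stationary(0.0, 0.5, 0.525, 0.025) == "ZERO"

    def test_exhaustive_and_exclusive_at_zero_tolerance(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            omega, va, vb = rng.uniform(0, 1, 3)
            label = tc.classify_homophily_stationary(omega, va, vb, 0.025, tol=0.0)
            stationary = omega in (0.0, 1.0) or abs(va - vb) == 0.025
            assert (label != "NOT_STATIONARY") == stationary


class TestTheorem:
    def test_scaled_sum_consensus(self):
        fn = CFS("ssum", {"lam": 3.0})
        report = tc.check_equal_equilibrium_theorem(fn, n=4, trials=3, seed=1, t_end=40.0)
        assert not report.skipped
        assert report.passed
        assert all(s < 1e-3 for s in report.spreads)

    def test_asymmetric_combiner_skipped_with_reason(self):
        fn = CFS("sisum", {"lam": 3.0, "mu": {(0, 1): 0.5}})
        report = tc.check_equal_equilibrium_theorem(fn, n=4, trials=3, seed=1)
        assert report.skipped
        assert "precondition failed" in report.reason


class TestClusters:
    def block_weights(self):
        groups = [["a", "b", "c"], ["d", "e"], ["f"]]
        members = [s for g in groups for s in g]
        of = {s: i for i, g in enumerate(groups) for s in g}
        return {
            (x, y): 1.0 if of[x] == of[y] else 0.0
            for x in members for y in members if x != y
        }

    def test_block_matrix_recovers_groups(self):
        part = tc.extract_clusters(self.block_weights())
        assert sorted(sorted(c) for c in part.clusters) == [["a", "b", "c"], ["d", "e"], ["f"]]
        assert part.intra_min == 1.0
        assert part.inter_max == 0.0

    def test_all_strong_weights_single_cluster(self):
        w = {(a, b): 1.0 for a in "xyz" for b in "xyz" if a != b}
        part = tc.extract_clusters(w)
        assert len(part.clusters) == 1
        assert part.inter_max is None

    def test_threshold_tie_connects(self):
        w = {("a", "b"): 0.5, ("b", "a"): 0.1}
        part = tc.extract_clusters(w, threshold=0.5)
        assert len(part.clusters) == 1  # symmetrised by max; ties connect

    def test_permutation_equivariance(self):
        w = self.block_weights()
        mapping = {s: s.upper() for s in "abcdef"}
        relabeled = {(mapping[a], mapping[b]): v for (a, b), v in w.items()}
        p1 = tc.extract_clusters(w)
        p2 = tc.extract_clusters(relabeled)
        assert sorted(sorted(mapping[s] for s in c) for c in p1.clusters) == sorted(
            sorted(c) for c in p2.clusters
        )


def test_weights_at_parses_omega_columns(clamped_pair_homophily):
    rnet, init = clamped_pair_homophily(0.3, 0.3)
    traj = tc.simulate(rnet, init, tc.SimulationSettings(dt=0.01, t_end=1.0))
    w = tc.weights_at(traj, 0.0)
    assert w == {("A", "B"): 0.5}
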