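"""Aggregate model: multi-arm adjustment, pooling, incidence, hat matrix."""

import numpy as np
import pytest

from evidenceflow.model import AggregateEdge, ModelSpec, Trial, TrialContrast
from evidenceflow.nma_core import (
    adjust_multiarm,
    build_network,
    hat_matrix,
    incidence_matrix,
    network_estimates,
    network_from_weights,
    pool_direct,
)

from conftest import small_synthetic_network


def make_trial(study, entries):
    return Trial(study, [TrialContrast(study, a, b, y, se) for a, b, y, se in entries])


class TestAdjustMultiarm:
    def test_two_arm_weight_is_inverse_total_variance(self):
        trial = make_trial("s", [(1, 2, 0.3, 0.5)])
        adjust_multiarm(trial, ModelSpec(tau2=0.0))
        assert trial.adjusted_weights[(1, 2)] == pytest.approx(4.0, abs=0)

        trial = make_trial("s", [(1, 2, 0.3, 0.5)])
        adjust_multiarm(trial, ModelSpec(tau2=0.75))
        assert trial.adjusted_weights[(1, 2)] == pytest.approx(1.0, abs=0)

    def test_symmetric_three_arm(self):
        """Equal pairwise variances v give adjusted weights 2/(3v).

        Independent derivation: with equal arm variances v/2 the arm-level
        information matrix is D - d d^T / s (d the arm precisions), whose
        off-diagonals are -2/(3v); equivalently the adjusted variance is
        1.5 v, the classic sqrt(1.5) standard-error inflation.
        """
        v = 0.7
        trial = make_trial("s", [(1, 2, 0.0, np.sqrt(v)), (1, 3, 0.0, np.sqrt(v)), (2, 3, 0.0, np.sqrt(v))])
        adjust_multiarm(trial)
        for w in trial.adjusted_weights.values():
            assert w == pytest.approx(2.0 / (3.0 * v), rel=1e-12)

    @pytest.mark.parametrize(
        "pairwise_var",
        [
            (1.0, 1.0, 4.0),  # degenerate: implies a negative arm variance
            (1.0, 1.0, 1.5),
            (0.5, 1.2, 0.9),
        ],
    )
    def test_matches_centered_variance_oracle(self, pairwise_var):
        """Adjusted weights equal the negated off-diagonals of pinv(-0.5 C V C)."""
        v12, v13, v23 = pairwise_var
        trial = make_trial(
            "s",
            [(1, 2, 0.0, np.sqrt(v12)), (1, 3, 0.0, np.sqrt(v13)), (2, 3, 0.0, np.sqrt(v23))],
        )
        adjust_multiarm(trial)
        variance = np.array([[0, v12, v13], [v12, 0, v23], [v13, 0 * v23, 0]], dtype=float)
        variance[2, 1] = v23
        centering = np.eye(3) - np.ones((3, 3)) / 3
        lap = np.linalg.pinv(-0.5 * centering @ variance @ centering)
        expected = {(1, 2): -lap[0, 1], (1, 3): -lap[0, 2], (2, 3): -lap[1, 2]}
        for pair, w in trial.adjusted_weights.items():
            assert w == pytest.approx(max(expected[pair], 0.0), abs=1e-10)

    def test_heterogeneity_added_before_adjustment(self):
        """tau2 must enter the pairwise variances, not the adjusted weights."""
        v, tau2 = 0.7, 0.3
        trial = make_trial(
            "s", [(1, 2, 0.0, np.sqrt(v)), (1, 3, 0.0, np.sqrt(v)), (2, 3, 0.0, np.sqrt(v))]
        )
        adjust_multiarm(trial, ModelSpec(tau2=tau2))
        for w in trial.adjusted_weights.values():
            assert w == pytest.approx(2.0 / (3.0 * (v + tau2)), rel=1e-12)

    def test_incomplete_multiarm_raises(self):
        trial = make_trial("s", [(1, 2, 0.0, 1.0), (1, 3, 0.0, 1.0), (1, 4, 0.0, 1.0)])
        with pytest.raises(ValueError, match="incomplete multi-arm"):
            adjust_multiarm(trial)

    def test_inadmissible_variance_pattern_raises(self):
        # a 4-arm pattern whose conversion yields clearly negative weights
        variances = {(1, 2): 3.221, (1, 3): 1.422, (1, 4): 0.301, (2, 3): 0.181, (2, 4): 4.085, (3, 4): 4.573}
        trial = make_trial("s", [(a, b, 0.0, np.sqrt(v)) for (a, b), v in variances.items()])
        with pytest.raises(ValueError, match="inadmissible variance pattern"):
            adjust_multiarm(trial)


class TestPoolDirect:
    def test_single_two_arm_trial(self):
        net = pool_direct([make_trial("s", [(1, 2, 0.3, 1.0)])])
        assert net.n_edges == 1
        assert net.edges[0].weight == pytest.approx(1.0)
        assert net.edges[0].direct_estimate == pytest.approx(0.3)

    def test_weighted_mean_over_trials(self):
        trials = [
            make_trial("s1", [(1, 2, 0.0, 1 / np.sqrt(2))]),  # w = 2
            make_trial("s2", [(1, 2, 1.0, 1 / np.sqrt(3))]),  # w = 3
        ]
        net = pool_direct(trials)
        assert net.edges[0].weight == pytest.approx(5.0)
        assert net.edges[0].direct_estimate == pytest.approx(0.6)

    def test_fig2_weights(self, fig2):
        assert fig2.comparisons == [(1, 2), (1, 3), (1, 5), (2, 3), (2, 4), (3, 5), (4, 5)]
        assert np.allclose(fig2.weights, [1, 3, 4, 6, 5, 2, 7])

    def test_disconnected_network_names_components(self):
        trials = [make_trial("s1", [(1, 2, 0.0, 1.0)]), make_trial("s2", [(3, 4, 0.0, 1.0)])]
        with pytest.raises(ValueError, match=r"disconnected.*\[1, 2\].*\[3, 4\]"):
            pool_direct(trials)

    def test_reversed_effect_orientation_pools_consistently(self):
        """A contrast entered as (2, 1, -y) pools like (1, 2, +y)."""
        net_fwd = pool_direct([make_trial("s", [(1, 2, 0.4, 1.0)])])
        net_rev = pool_direct([make_trial("s", [(2, 1, -0.4, 1.0)])])
        assert net_fwd.edges[0].direct_estimate == pytest.approx(net_rev.edges[0].direct_estimate)


class TestIncidence:
    def test_fig2_matches_printed_matrix(self, fig2):
        expected = np.array(
            [
                [1, -1, 0, 0, 0],
                [1, 0, -1, 0, 0],
                [1, 0, 0, 0, -1],
                [0, 1, -1, 0, 0],
                [0, 1, 0, -1, 0],
                [0, 0, 1, 0, -1],
                [0, 0, 0, 1, -1],
            ],
            dtype=float,
        )
        assert np.array_equal(incidence_matrix(fig2), expected)

    def test_single_edge(self):
        net = network_from_weights({(1, 2): 2.0})
        assert np.array_equal(incidence_matrix(net), [[1.0, -1.0]])

    def test_orientation_flip_changes_signs_not_flows(self):
        """Reversing one edge's orientation flips its H row/column signs consistently."""
        weights = {(1, 2): 1.0, (1, 3): 2.0, (2, 3): 3.0}
        net = network_from_weights(weights)
        edges_flipped = [
            AggregateEdge(2, 1, 1.0, 0.0),  # non-canonical orientation for edge 1-2
            AggregateEdge(1, 3, 2.0, 0.0),
            AggregateEdge(2, 3, 3.0, 0.0),
        ]
        net_flipped = build_network([1, 2, 3], edges_flipped)
        h = hat_matrix(net).values
        h_flipped = hat_matrix(net_flipped).values
        flip = np.diag([-1.0, 1.0, 1.0])
        assert np.allclose(h_flipped, flip @ h @ flip, atol=1e-12)


class TestHatMatrix:
    def test_single_edge_is_identity(self):
        net = network_from_weights({(1, 2): 5.0})
        assert np.allclose(hat_matrix(net).values, [[1.0]])

    def test_two_path_triangle_series_parallel(self):
        """Equal-weight triangle: direct edge carries 2/3, the detour 1/3 each."""
        net = network_from_weights({("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        hat = hat_matrix(net)
        row = hat.row("a", "b")
        by_pair = dict(zip(hat.comparisons, row))
        assert by_pair[("a", "b")] == pytest.approx(2 / 3, abs=1e-12)
        assert by_pair[("a", "c")] == pytest.approx(1 / 3, abs=1e-12)
        assert by_pair[("b", "c")] == pytest.approx(-1 / 3, abs=1e-12)  # flow c->b

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_idempotent_on_synthetic_networks(self, seed):
        net = small_synthetic_network(seed)
        h = hat_matrix(net).values
        assert np.max(np.abs(h @ h - h)) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_moore_penrose_identities(self, seed):
        net = small_synthetic_network(seed)
        lap, pinv = net.laplacian, net.laplacian_pinv
        assert np.max(np.abs(lap @ pinv @ lap - lap)) < 1e-10
        assert np.max(np.abs(pinv @ lap @ pinv - pinv)) < 1e-10
        assert np.max(np.abs((lap @ pinv) - (lap @ pinv).T)) < 1e-10
        assert np.max(np.abs((pinv @ lap) - (pinv @ lap).T)) < 1e-10


class TestNetworkEstimates:
    def test_single_edge_passthrough(self):
        net = network_from_weights({(1, 2): 2.0}, {(1, 2): 0.7})
        hat = hat_matrix(net)
        assert network_estimates(hat, [0.7]) == pytest.approx([0.7])

    def test_consistent_directs_are_fixed_points(self, fig2, fig2_hat):
        rng = np.random.default_rng(7)
        potentials = rng.normal(size=fig2.n_treatments)
        consistent = -fig2.incidence @ potentials  # effect of b relative to a
        assert np.allclose(network_estimates(fig2_hat, consistent), consistent, atol=1e-12)

    def test_matches_weighted_least_squares_oracle(self, fig2, fig2_hat):
        """Inconsistent directs: H theta equals the WLS solution B L+ B' W theta."""
        rng = np.random.default_rng(11)
        direct = rng.normal(size=fig2.n_edges)
        estimates = network_estimates(fig2_hat, direct)
        b, w = fig2.incidence, fig2.weight_diag
        solution = np.linalg.pinv(b.T @ w @ b) @ b.T @ w @ direct
        assert np.allclose(estimates, b @ solution, atol=1e-10)


class TestMultiArmEquivalence:
    def test_resistance_distance_reproduces_pairwise_variance(self):
        """The adjusted subgraph's effective resistances equal the trial's variances.

        Arm-based variances guarantee an admissible pattern; the equivalent
        two-arm network must then assign each comparison a network variance
        (resistance distance) equal to the original pairwise variance.
        """
        rng = np.random.default_rng(3)
        arm_var = rng.uniform(0.1, 1.0, size=4)
        arms = [1, 2, 3, 4]
        entries = []
        for i in range(4):
            for j in range(i + 1, 4):
                entries.append((arms[i], arms[j], 0.0, np.sqrt(arm_var[i] + arm_var[j])))
        trial = make_trial("s", entries)
        net = pool_direct([trial])
        for i in range(4):
            for j in range(i + 1, 4):
                e_ij = np.zeros(4)
                e_ij[i], e_ij[j] = 1.0, -1.0
                resistance = e_ij @ net.laplacian_pinv @ e_ij
                assert resistance == pytest.approx(arm_var[i] + arm_var[j], abs=1e-8)

    def test_network_estimates_match_one_step_gls(self, synthetic_trials):
        """Two-step aggregate estimates equal one-step GLS with the full
        within-trial covariance (arm variances recovered from the pairwise
        standard errors of each multi-arm trial)."""
        import scipy.linalg as sla

        trials, _ = synthetic_trials
        net = pool_direct(trials)
        index = {t: i for i, t in enumerate(net.treatments)}

        def arm_variances(trial):
            arms = trial.treatments
            pair_var = {c.pair: c.se**2 for c in trial.contrasts}

            def v(x, y):
                return pair_var.get((x, y), pair_var.get((y, x)))

            out = {}
            for x in arms:
                y, z = [t for t in arms if t != x][:2]
                out[x] = (v(x, y) + v(x, z) - v(y, z)) / 2
            return out

        design, observed, blocks = [], [], []
        for trial in trials:
            q = len(trial.contrasts)
            x = np.zeros((q, len(net.treatments)))
            y = np.zeros(q)
            cov = np.zeros((q, q))
            arm_var = arm_variances(trial) if trial.n_arms >= 3 else None
            for i, ci in enumerate(trial.contrasts):
                x[i, index[ci.treat_b]] = 1.0
                x[i, index[ci.treat_a]] = -1.0
                y[i] = ci.effect
                for j, cj in enumerate(trial.contrasts):
                    if arm_var is None:
                        cov[i, j] = ci.se**2 if i == j else 0.0
                    else:
                        c = 0.0
                        for arm, sign in ((ci.treat_a, -1), (ci.treat_b, 1)):
                            for arm2, sign2 in ((cj.treat_a, -1), (cj.treat_b, 1)):
                                if arm == arm2:
                                    c += sign * sign2 * arm_var[arm]
                        cov[i, j] = c
            design.append(x)
            observed.append(y)
            blocks.append(cov)

        x_all = np.vstack(design)
        y_all = np.concatenate(observed)
        cov_pinv = np.linalg.pinv(sla.block_diag(*blocks))
        mu = np.linalg.pinv(x_all.T @ cov_pinv @ x_all) @ x_all.T @ cov_pinv @ y_all
        gls = np.array([mu[index[e.treat_b]] - mu[index[e.treat_a]] for e in net.edges])

        hat = hat_matrix(net)
        assert np.max(np.abs(hat.values @ net.direct_estimates - gls)) < 1e-8
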