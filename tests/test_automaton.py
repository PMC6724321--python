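"""State encoding, transition estimation, maximum-likelihood cycle
extraction and Markov-chain simulation."""

import numpy as np
import pytest

from marimo_machines.automaton import (
    MISSING,
    StateSymbol,
    TransitionMatrix,
    encode_states,
    estimate_transitions,
    max_likelihood_cycle,
    oscillation_metrics,
    simulate_automaton,
)

S00, S01, S10, S11 = (
    StateSymbol.S00,
    StateSymbol.S01,
    StateSymbol.S10,
    StateSymbol.S11,
)

IDEAL = np.array(
    [
        [0, 1, 0, 0],
        [0, 0, 0, 1],
        [1, 0, 0, 0],
        [0, 0, 1, 0],
    ],
    dtype=float,
)


class TestEncode:
    def test_protocol_bit_assignment(self):
        # left low / right high -> 01; both high -> 11
        sym = encode_states([0.0, 0.3], [0.3, 0.3], up_threshold=0.15)
        assert list(sym) == [S01, S11]

    def test_threshold_is_closed_upper(self):
        sym = encode_states([0.15], [0.1], up_threshold=0.15)
        assert sym[0] == S10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_states([0.1, 0.2], [0.1])

    def test_missing_samples_marked(self):
        sym = encode_states([0.1, np.nan], [0.1, 0.2])
        assert sym[1] == MISSING

    def test_invariant_to_monotone_rescaling(self):
        left = np.array([0.01, 0.05, 0.20, 0.29])
        right = np.array([0.25, 0.02, 0.16, 0.03])
        base = encode_states(left, right, up_threshold=0.15)

        def rescale(x):  # monotone, fixes the threshold crossing
            return 0.15 + np.sign(x - 0.15) * np.abs(x - 0.15) ** 1.3

        rescaled = encode_states(rescale(left), rescale(right), up_threshold=0.15)
        assert list(base) == list(rescaled)


class TestEstimate:
    def test_brute_force_counts_on_short_series(self):
        sym = [S00, S01, S11, S10, S00, S01]
        m = estimate_transitions(sym)
        assert m.probabilities[S00, S01] == 1.0
        assert m.probabilities[S01, S11] == 1.0
        assert m.probabilities[S11, S10] == 1.0
        assert m.probabilities[S10, S00] == 1.0
        assert m.counts[S00, S01] == 2  # 01's last visit has no successor
        assert m.counts.sum() == 5

    def test_constant_series_self_loop(self):
        m = estimate_transitions([S00] * 10)
        assert m.probabilities[S00, S00] == 1.0
        assert not m.observed[S01]
        assert np.isnan(m.probabilities[S01]).all()

    def test_observed_rows_sum_to_one(self, rng):
        sym = rng.integers(0, 4, size=500)
        m = estimate_transitions(sym)
        sums = m.probabilities[m.observed].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_pairs_with_missing_samples_skipped(self):
        sym = [S00, MISSING, S01, S01]
        m = estimate_transitions(sym)
        assert m.counts.sum() == 1
        assert m.counts[S01, S01] == 1

    @pytest.mark.parametrize("series", [[], [S00]])
    def test_too_short_series_rejected(self, series):
        with pytest.raises(ValueError):
            estimate_transitions(series)

    def test_lag_two_skips_alternate_samples(self):
        sym = [S00, S01, S11, S10, S00, S01, S11]
        m = estimate_transitions(sym, lag=2)
        assert m.probabilities[S00, S11] == 1.0
        assert m.probabilities[S11, S00] == 1.0


class TestMaxLikelihoodCycle:
    def test_ideal_oscillator_matrix(self):
        m = TransitionMatrix(IDEAL, counts=(IDEAL * 10).astype(int))
        cyc = max_likelihood_cycle(m)
        assert cyc.labels == ["00", "01", "11", "10"]
        assert cyc.is_cycle
        assert cyc.edge_probabilities == [1.0, 1.0, 1.0, 1.0]

    def test_identity_matrix_is_trivial_self_loop(self):
        eye = np.eye(4)
        m = TransitionMatrix(eye, counts=(eye * 5).astype(int))
        cyc = max_likelihood_cycle(m)
        assert cyc.labels == ["00"]
        assert cyc.is_cycle

    def test_tied_argmax_prefers_lowest_state(self):
        p = np.full((4, 4), 0.25)
        m = TransitionMatrix(p, counts=np.ones((4, 4), dtype=int))
        cyc = max_likelihood_cycle(m)
        assert cyc.labels == ["00"]  # 00 -> 00 on a four-way tie

    def test_unobserved_row_is_explicit_dead_end(self):
        p = np.full((4, 4), np.nan)
        p[0] = [0.0, 1.0, 0.0, 0.0]
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 3
        cyc = max_likelihood_cycle(TransitionMatrix(p, counts=counts))
        assert cyc.dead_end
        assert not cyc.is_cycle
        assert cyc.labels == ["00", "01"]

    @pytest.mark.parametrize(
        "perm", [(1, 0, 3, 2), (1, 2, 3, 0), (3, 2, 1, 0), (0, 1, 2, 3)]
    )
    def test_permutation_matrix_returns_orbit_of_start(self, perm):
        p = np.zeros((4, 4))
        for i, j in enumerate(perm):
            p[i, j] = 1.0
        m = TransitionMatrix(p, counts=(p * 7).astype(int))
        cyc = max_likelihood_cycle(m, start=S00)
        # orbit of 00 under the permutation
        orbit = [0]
        while True:
            nxt = perm[orbit[-1]]
            if nxt == 0:
                break
            orbit.append(nxt)
        assert [int(s) for s in cyc.states] == orbit
        assert cyc.is_cycle


class TestSimulate:
    def test_deterministic_cycle_reproduced_exactly(self):
        sym = simulate_automaton(IDEAL, 8, seed=0)
        assert list(sym) == [S00, S01, S11, S10] * 2

    def test_same_seed_same_series(self):
        p = np.full((4, 4), 0.25)
        a = simulate_automaton(p, 200, seed=5)
        b = simulate_automaton(p, 200, seed=5)
        assert np.array_equal(a, b)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError):
            simulate_automaton(bad, 10, seed=0)

    def test_estimation_recovers_generating_matrix(self, rng):
        # law of large numbers: re-estimating from a long simulated chain
        # recovers the matrix to within 0.05 per entry
        for _ in range(3):
            p = rng.dirichlet(np.ones(4), size=4)
            sym = simulate_automaton(p, 10_000, seed=int(rng.integers(2**31)))
            est = estimate_transitions(sym)
            assert np.nanmax(np.abs(est.probabilities - p)) <= 0.05


class TestMetrics:
    def test_perfect_cycle_period_and_occupancy(self):
        sym = [S00, S01, S11, S10] * 5
        m = oscillation_metrics(sym)
        assert m.period_samples == pytest.approx(4.0)
        assert np.allclose(m.occupancy, 0.25)

    def test_constant_series_period_undefined(self):
        m = oscillation_metrics([S11] * 20)
        assert m.period_samples is None
        assert m.occupancy[S11] == 1.0

    def test_noisy_cycle_period_within_ten_percent(self, rng):
        # known period 20 samples, 5% symbol noise
        period = 20
        base = np.array(
            [S00] * 5 + [S01] * 5 + [S11] * 5 + [S10] * 5, dtype=int
        )
        sym = np.tile(base, 50)
        noise = rng.random(len(sym)) < 0.05
        sym[noise] = rng.integers(0, 4, size=noise.sum())
        m = oscillation_metrics(sym)
        assert m.period_samples == pytest.approx(period, rel=0.10)

    def test_metrics_accept_trajectory_input(self):
        from marimo_machines.fixtures import (
            SyntheticTrajectoryParams,
            synth_oscillator_trajectory,
        )

        traj = synth_oscillator_trajectory(
            SyntheticTrajectoryParams(duration_h=16.0)
        )
        m = oscillation_metrics(traj)
        # 2 h period sampled four times per period
        assert m.period_samples == pytest.approx(4.0)
        assert m.transition_counts is not None
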