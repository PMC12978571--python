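"""Markov-chain state dynamics: transition estimation, stationary
distributions, occupancy contrasts, block entropy and bootstrap
comparisons."""

import numpy as np
import pytest

from loomdyn import dynamics as dy


class TestEstimate:
    def test_constant_sequence_self_transition(self):
        m = dy.estimate_transitions([np.zeros(4, dtype=int)])
        assert m.P[0, 0] == 1.0
        assert m.counts[0, 0] == 3

    def test_deterministic_alternation(self):
        m = dy.estimate_transitions([np.array([0, 1, 0, 1, 0])])
        assert m.P[0, 1] == 1.0
        assert m.P[1, 0] == 1.0

    def test_unvisited_state_flagged(self):
        m = dy.estimate_transitions([np.array([0, 1, 0, 1])])
        assert set(m.unobserved_rows) == set(range(2, 8))

    def test_no_cross_subject_transitions(self):
        # last state of subject 1 never linked to first state of subject 2
        m = dy.estimate_transitions([np.array([0, 0]), np.array([1, 1])])
        assert m.counts[0, 1] == 0 and m.counts[1, 0] == 0

    def test_consistency_on_simulated_chain(self, rng):
        P = np.array([[0.7, 0.3], [0.2, 0.8]])
        cum = np.cumsum(P, axis=1)
        seq = np.zeros(10_000, dtype=int)
        for i in range(1, len(seq)):
            seq[i] = np.searchsorted(cum[seq[i - 1]], rng.random())
        m = dy.estimate_transitions([seq], n_states=2)
        assert np.max(np.abs(m.P - P)) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="length"):
            dy.estimate_transitions([np.array([3])])


class TestStationary:
    def test_uniform_matrix(self):
        pi = dy.stationary_distribution(np.full((8, 8), 1 / 8))
        np.testing.assert_allclose(pi, 1 / 8, atol=1e-12)

    def test_two_state_hand_solution(self):
        # pi P = pi solved by hand: pi = (5/6, 1/6)
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        pi = dy.stationary_distribution(P)
        np.testing.assert_allclose(pi, [5 / 6, 1 / 6], atol=1e-12)
        # cross-check by power iteration
        q = np.array([0.5, 0.5])
        for _ in range(200):
            q = q @ P
        np.testing.assert_allclose(pi, q, atol=1e-10)

    def test_identity_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-unique"):
            dy.stationary_distribution(np.eye(8))

    def test_fixed_point_property(self):
        from loomdyn.config import default_transition_matrices
        for P in default_transition_matrices().values():
            pi = dy.stationary_distribution(P)
            np.testing.assert_allclose(pi @ P, pi, atol=1e-9)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_empirical_occupancy(self, rng):
        from loomdyn.config import default_transition_matrices
        P = default_transition_matrices()["PLC"]
        cum = np.cumsum(P, axis=1)
        seq = np.zeros(100_000, dtype=int)
        for i in range(1, len(seq)):
            seq[i] = np.searchsorted(cum[seq[i - 1]], rng.random())
        occ = np.bincount(seq, minlength=8) / len(seq)
        pi = dy.stationary_distribution(P)
        assert 0.5 * np.abs(occ - pi).sum() < 0.02  # total variation


class TestOccupancyContrast:
    def test_hand_computed_table(self):
        out = dy.occupancy_contrast(np.array([[30, 10], [10, 30]]))
        assert out["chi2"] == pytest.approx(20.0, abs=1e-12)
        assert out["df"] == 1
        assert out["residuals_z"][0, 0] == pytest.approx(4.472, abs=1e-3)

    def test_independence_table_zero(self):
        out = dy.occupancy_contrast(np.array([[20., 40.], [10., 20.]]))
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out["residuals_z"], 0.0, atol=1e-12)

    def test_three_by_eight_df(self, rng):
        table = rng.integers(20, 60, (3, 8))
        assert dy.occupancy_contrast(table)["df"] == 14

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dy.occupancy_contrast(np.array([[0, 0], [5, 5]]))


class TestEntropy:
    def test_constant_sequence_zero_bits(self):
        assert dy.sequence_entropy([np.zeros(100, dtype=int)]) == 0.0

    def test_alternation_one_bit(self):
        # blocks ABA and BAB, equiprobable
        seq = np.array([0, 1] * 500)
        assert dy.sequence_entropy([seq], block_len=3) == pytest.approx(1.0)

    def test_iid_uniform_approaches_nine_bits(self, rng):
        seq = rng.integers(0, 8, 100_000)
        h = dy.sequence_entropy([seq], block_len=3)
        assert h == pytest.approx(9.0, abs=0.05)

    def test_entropy_increases_with_dispersion(self, rng):
        def simulate(P, n=20_000):
            cum = np.cumsum(P, axis=1)
            seq = np.zeros(n, dtype=int)
            for i in range(1, n):
                seq[i] = np.searchsorted(cum[seq[i - 1]], rng.random())
            return seq

        diag = 0.7 * np.eye(8) + 0.3 / 7 * (1 - np.eye(8))
        uniform = np.full((8, 8), 1 / 8)
        h_diag = dy.sequence_entropy([simulate(diag)])
        h_unif = dy.sequence_entropy([simulate(uniform)])
        assert h_diag < h_unif

    def test_bounds(self, rng):
        for k in (1, 2, 3):
            seq = rng.integers(0, 8, 5000)
            h = dy.sequence_entropy([seq], block_len=k)
            assert 0.0 <= h <= k * 3.0 + 1e-9

    def test_invalid_block_length(self):
        with pytest.raises(ValueError):
            dy.sequence_entropy([np.zeros(10, dtype=int)], block_len=0)


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        seqs = [np.array([0, 0, 1, 1])] * 6
        lo, hi = dy.bootstrap_cis(seqs, statistic=lambda s: np.array([1.0]),
                                  n_boot=50)
        assert lo[0] == hi[0] == 1.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(0)
        seqs = [rng.integers(0, 8, 60) for _ in range(10)]
        a = dy.bootstrap_cis(seqs, n_boot=100, seed=42)
        b = dy.bootstrap_cis(seqs, n_boot=100, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        seqs = [rng.integers(0, 8, 200) for _ in range(20)]
        m = dy.estimate_transitions(seqs)
        lo, hi = dy.bootstrap_cis(seqs, n_boot=200, seed=3)
        ok = ~np.isnan(lo)
        assert (lo[ok] <= m.P[ok] + 1e-9).mean() > 0.95
        assert (hi[ok] >= m.P[ok] - 1e-9).mean() > 0.95


class TestCompareGroups:
    def test_self_difference_exactly_zero(self):
        rng = np.random.default_rng(2)
        seqs = [rng.integers(0, 8, 100) for _ in range(8)]
        out = dy.compare_groups(seqs, seqs, n_boot=50, seed=1)
        assert (out["diff"] == 0).all()

    def test_antisymmetry_of_point_difference(self):
        rng = np.random.default_rng(3)
        a = [rng.integers(0, 8, 100) for _ in range(8)]
        b = [rng.integers(0, 8, 100) for _ in range(8)]
        ab = dy.compare_groups(a, b, n_boot=20, seed=1)
        ba = dy.compare_groups(b, a, n_boot=20, seed=1)
        np.testing.assert_allclose(ab["diff"], -ba["diff"], atol=1e-12)

    def test_identical_groups_near_nominal_rate(self):
        rng = np.random.default_rng(4)
        gen = lambda: [rng.integers(0, 8, 150) for _ in range(15)]
        out = dy.compare_groups(gen(), gen(), n_boot=200, seed=5)
        assert out["significant"].mean() < 0.15

    def test_large_injected_difference_detected(self):
        # group A strongly self-transitions in state 0; group B uniform
        rng = np.random.default_rng(6)

        def chain(P, n, count):
            cum = np.cumsum(P, axis=1)
            seqs = []
            for _ in range(count):
                s = np.zeros(n, dtype=int)
                for i in range(1, n):
                    s[i] = np.searchsorted(cum[s[i - 1]], rng.random())
                seqs.append(s)
            return seqs

        Pa = np.full((8, 8), 1 / 8)
        Pa[0] = 0.05
        Pa[0, 0] = 0.65  # +0.525 vs uniform
        Pb = np.full((8, 8), 1 / 8)
        a = chain(Pa, 140, 20)
        b = chain(Pb, 140, 20)
        out = dy.compare_groups(a, b, n_boot=300, seed=7)
        cell = out[(out["from"] == "E1") & (out["to"] == "E1")].iloc[0]
        assert cell["significant"]
        assert cell["diff"] > 0.3


class TestWithinGroup:
    def test_uniform_chain_no_flags_no_attractors(self):
        rng = np.random.default_rng(8)
        seqs = [rng.integers(0, 8, 300) for _ in range(20)]
        m = dy.estimate_transitions(seqs)
        out = dy.within_group_significant_transitions(m)
        assert out["attractors"] == []
        assert not out["significant"].any()

    def test_diagonal_dominant_all_attractors(self):
        P = 0.6 * np.eye(8) + 0.4 / 7 * (1 - np.eye(8))
        m = dy.TransitionModel(counts=P * 1000, P=P)
        out = dy.within_group_significant_transitions(m)
        assert len(out["attractors"]) == 8

    def test_constructed_selective_inflow_to_e1_flagged(self):
        # E3 and E4 feed E1 far above the column margin; residuals vs
        # independence single out exactly those pathways
        counts = np.full((8, 8), 20.0)
        counts[2, 0] = 120.0
        counts[3, 0] = 120.0
        m = dy.TransitionModel(counts=counts,
                               P=counts / counts.sum(1, keepdims=True))
        out = dy.within_group_significant_transitions(m)
        sig = out["significant"]
        assert sig[2, 0] and sig[3, 0]
        z = out["residuals_z"]
        assert z[2, 0] > 1.96 and z[3, 0] > 1.96


class TestEntropyContrast:
    def test_identical_groups_difference_covers_zero(self):
        rng = np.random.default_rng(9)
        seqs = [rng.integers(0, 8, 150) for _ in range(12)]
        out = dy.entropy_contrast({"a": seqs, "b": list(seqs)},
                                  n_boot=200, seed=1)
        d = out[out["kind"] == "difference"].iloc[0]
        assert d["ci_low"] <= 0 <= d["ci_high"]

    def test_dispersion_ordering_detected(self):
        rng = np.random.default_rng(10)

        def chain(P, n, count):
            cum = np.cumsum(P, axis=1)
            out = []
            for _ in range(count):
                s = np.zeros(n, dtype=int)
                for i in range(1, n):
                    s[i] = np.searchsorted(cum[s[i - 1]], rng.random())
                out.append(s)
            return out

        conc = 0.75 * np.eye(8) + 0.25 / 7 * (1 - np.eye(8))
        unif = np.full((8, 8), 1 / 8)
        out = dy.entropy_contrast({"conc": chain(conc, 150, 15),
                                   "unif": chain(unif, 150, 15)},
                                  n_boot=100, seed=2)
        g = out[out["kind"] == "group"].set_index("a")
        assert g.loc["unif", "value"] > g.loc["conc", "value"]
        d = out[out["kind"] == "difference"].iloc[0]
        assert d["ci_high"] < 0  # conc - unif decisively negative

    def test_group_value_within_its_ci(self):
        rng = np.random.default_rng(11)
        seqs = [rng.integers(0, 8, 150) for _ in range(12)]
        out = dy.entropy_contrast({"a": seqs, "b": seqs}, n_boot=200, seed=3)
        for _, row in out[out["kind"] == "group"].iterrows():
            assert row["ci_low"] <= row["value"] + 0.1
            assert row["ci_high"] >= row["value"] - 0.1
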