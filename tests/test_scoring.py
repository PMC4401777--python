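from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from loregic import (
    INCONSISTENT,
    Triplet,
    TripletCounts,
    complement_gate,
    consistency_score,
    enumerate_gates,
    gate_by_alias,
    match_counts,
    match_gate,
    permutation_score,
    score_all_gates,
    symmetric_partner,
    tabulate_counts,
)
from conftest import random_counts


class TestTabulation:
    def test_worked_example_counts(self, fig2_vectors):
        c = tabulate_counts(*fig2_vectors)
        assert c.m_i == (5, 5, 5, 5)
        assert c.n1_i == (0, 1, 0, 4)
        assert c.m == 20

    def test_all_zero_vectors(self):
        c = tabulate_counts([0, 0, 0], [0, 0, 0], [0, 0, 0])
        assert c.m_i == (3, 0, 0, 0)
        assert c.n1_i == (0, 0, 0, 0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        x, y, z = rng.integers(0, 2, size=(3, 30))
        perm = rng.permutation(30)
        assert tabulate_counts(x, y, z) == tabulate_counts(x[perm], y[perm], z[perm])

    def test_missing_samples_dropped(self):
        c = tabulate_counts([0, 1, np.nan], [0, 1, 1], [0, np.nan, 1])
        assert c.m == 1  # only the first sample is complete...
        # sample 2 has missing z, sample 3 missing x
        assert c.m_i == (1, 0, 0, 0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            tabulate_counts([0, 1], [0], [1, 0])

    def test_non_binary_errors(self):
        with pytest.raises(ValueError, match="non-binary"):
            tabulate_counts([0, 2], [0, 1], [1, 0])


class TestConsistencyScore:
    def test_worked_example_score(self, fig2_vectors, and_gate):
        c = tabulate_counts(*fig2_vectors)
        score = consistency_score(c, and_gate)
        assert score == Fraction(6, 7) * Fraction(5, 7) * Fraction(6, 7) * Fraction(5, 7)
        assert score == Fraction(900, 2401)
        assert round(float(score), 2) == 0.37

    def test_succession_probability_components(self, fig2_vectors, and_gate):
        c = tabulate_counts(*fig2_vectors)
        n = c.n_for_gate(and_gate)
        s = [Fraction(1 + n[i], 2 + c.m_i[i]) for i in range(4)]
        assert s[0] == Fraction(6, 7)
        assert s[1] == Fraction(5, 7)

    def test_empty_data_scores_one_sixteenth_for_every_gate(self):
        c = TripletCounts((0, 0, 0, 0), (0, 0, 0, 0))
        for g in enumerate_gates():
            assert consistency_score(c, g) == Fraction(1, 16)
        m = match_counts(c)
        assert not m.consistent
        assert m.gate_label == INCONSISTENT
        assert m.score == Fraction(1, 16)

    def test_score_complement_identity(self):
        # s_i of a gate and of its complement sum to 1 at every combination
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = random_counts(rng)
            for g in enumerate_gates():
                comp = complement_gate(g)
                for i in range(4):
                    s_g = Fraction(1 + c.n_for_gate(g)[i], 2 + c.m_i[i])
                    s_c = Fraction(1 + c.n_for_gate(comp)[i], 2 + c.m_i[i])
                    assert s_g + s_c == 1

    def test_score_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            c = random_counts(rng)
            lo = np.prod([Fraction(1, 2 + m) for m in c.m_i])
            hi = np.prod([Fraction(1 + m, 2 + m) for m in c.m_i])
            for s in score_all_gates(c):
                assert lo <= s <= hi


class TestMatchGate:
    def test_worked_example_matches_and(self, fig2_vectors, and_gate):
        m = match_gate(*fig2_vectors)
        assert m.best_gate is and_gate
        assert m.score == Fraction(900, 2401)

    def test_empty_input_combination_ties(self):
        # no (1,1) samples: gates differing only at v4 tie -> inconsistent
        x = [0, 0, 1, 1, 0, 0, 1, 1]
        y = [0, 0, 0, 0, 1, 1, 0, 0]
        z = [0, 0, 0, 0, 1, 1, 0, 0]
        m = match_gate(x, y, z)
        assert not m.consistent
        top = max(m.per_gate_scores)
        assert sum(1 for s in m.per_gate_scores if s == top) >= 2

    def test_exact_half_split_ties(self):
        # at (0,1) exactly half the targets are 1: both outputs score equally
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        y = [1, 1, 1, 1, 1, 1, 0, 0]
        z = [0, 0, 1, 1, 1, 1, 0, 0]
        assert not match_gate(x, y, z).consistent

    def test_argmax_equals_per_combination_majority_vote(self):
        # brute-force oracle: best gate takes the majority target output at
        # each input combination; any per-combination tie ties the maximum
        from loregic.gates import gate_by_outputs

        rng = np.random.default_rng(3)
        for _ in range(300):
            c = random_counts(rng)
            scores = score_all_gates(c)
            top = max(scores)
            tied = [i for i, s in enumerate(scores) if s == top]
            bin_tie = any(2 * n == m for n, m in zip(c.n1_i, c.m_i))
            if bin_tie:
                assert len(tied) > 1
                assert not match_counts(c).consistent
            else:
                majority = tuple(int(2 * n > m) for n, m in zip(c.n1_i, c.m_i))
                assert len(tied) == 1
                assert match_counts(c).best_gate is gate_by_outputs(majority)

    def test_swapping_inputs_maps_to_symmetric_partner(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x, y, z = rng.integers(0, 2, size=(3, 25))
            m1 = match_gate(x, y, z)
            m2 = match_gate(y, x, z)
            assert m1.score == m2.score
            if m1.consistent:
                assert m2.best_gate is symmetric_partner(m1.best_gate)
            else:
                assert not m2.consistent

    def test_min_score_threshold_branch(self):
        x = [0, 1, 0, 1]
        y = [0, 0, 1, 1]
        z = [0, 0, 0, 1]
        assert match_gate(x, y, z).consistent
        assert not match_gate(x, y, z, min_score=Fraction(99, 100)).consistent


class TestPermutationScore:
    @staticmethod
    def _binmat(rows: dict) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index", dtype=float)

    def test_identical_pool_scores_one(self, fig2_vectors, and_gate):
        x, y, z = fig2_vectors
        rows = {"RF1": x, "RF2": y, "T": z}
        rows.update({f"copy{i}": z for i in range(5)})  # pool = exact copies
        p = permutation_score(
            Triplet("RF1", "RF2", "T"), and_gate, self._binmat(rows), M=50, seed=0
        )
        assert p == 1.0

    def test_seed_reproducibility(self, fig2_vectors, and_gate):
        rng = np.random.default_rng(9)
        x, y, z = fig2_vectors
        rows = {"RF1": x, "RF2": y, "T": z}
        rows.update(
            {f"g{i}": rng.integers(0, 2, size=20) for i in range(30)}
        )
        binmat = self._binmat(rows)
        t = Triplet("RF1", "RF2", "T")
        p1 = permutation_score(t, and_gate, binmat, M=100, seed=7)
        p2 = permutation_score(t, and_gate, binmat, M=100, seed=7)
        assert p1 == p2

    def test_planted_gate_scores_low_against_noise_pool(self, and_gate):
        # a genuine AND triplet is rarely reproduced by independent genes
        rng = np.random.default_rng(17)
        n = 100
        x = rng.integers(0, 2, size=n)
        y = rng.integers(0, 2, size=n)
        z = (x & y).astype(float)
        flip = rng.random(n) < 0.02
        z = np.where(flip, 1 - z, z)
        rows = {"RF1": x, "RF2": y, "T": z}
        rows.update({f"g{i}": rng.integers(0, 2, size=n) for i in range(500)})
        assert match_gate(x, y, z).best_gate is and_gate
        p = permutation_score(
            Triplet("RF1", "RF2", "T"), and_gate, self._binmat(rows), M=1000, seed=3
        )
        assert p < 0.1

    def test_invalid_arguments(self, fig2_vectors, and_gate):
        x, y, z = fig2_vectors
        binmat = self._binmat({"RF1": x, "RF2": y, "T": z})
        t = Triplet("RF1", "RF2", "T")
        with pytest.raises(ValueError, match="M must be positive"):
            permutation_score(t, and_gate, binmat, M=0)
        with pytest.raises(ValueError, match="empty replacement pool"):
            permutation_score(t, and_gate, binmat, M=10)
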