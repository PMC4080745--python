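import math
from itertools import product

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from spacedwords import (
    DistanceMatrix,
    SequenceRecord,
    count_spaced_words,
    euclidean_distance,
    js_distance,
    kl_divergence,
    pairwise_matrix_multi,
    pairwise_matrix_single,
    parse_pattern,
    profile_distance,
    profile_sequences,
    sample_pattern_set,
)
from spacedwords._kernels import euclidean_sparse, js_sparse

from conftest import random_dna


def sparse_random(rng, size, universe=500):
    keys = np.sort(rng.choice(universe, size=size, replace=False)).astype(np.uint64)
    weights = rng.integers(1, 50, size=size).astype(float)
    return keys, weights / weights.sum()


class TestKL:
    def test_identical_is_zero(self):
        p = {1: 0.25, 2: 0.75}
        assert kl_divergence(p, p) == 0.0

    def test_single_term_one_bit(self):
        assert kl_divergence({1: 1.0}, {1: 0.5, 2: 0.5}) == pytest.approx(1.0)

    def test_support_violation(self):
        with pytest.raises(ValueError, match="support"):
            kl_divergence({1: 0.5, 2: 0.5}, {1: 1.0})

    def test_zero_terms_skipped(self):
        assert kl_divergence({1: 1.0, 2: 0.0}, {1: 1.0}) == 0.0

    def test_against_dense_evaluation(self, rng):
        kp, fp = sparse_random(rng, 40)
        kq, fq = sparse_random(rng, 50)
        p = dict(zip(kp.tolist(), fp))
        q = dict(zip(kq.tolist(), fq))
        m = {k: (p.get(k, 0) + q.get(k, 0)) / 2 for k in set(p) | set(q)}
        dense = sum(
            pv * math.log2(pv / m[k]) for k, pv in p.items() if pv > 0
        )
        assert kl_divergence(p, m) == pytest.approx(dense, abs=1e-12)


class TestJS:
    def test_identical_zero_and_symmetry(self, rng):
        kp, fp = sparse_random(rng, 30)
        p = dict(zip(kp.tolist(), fp))
        assert js_distance(p, p) == 0.0
        kq, fq = sparse_random(rng, 30)
        q = dict(zip(kq.tolist(), fq))
        assert js_distance(p, q) == pytest.approx(js_distance(q, p))

    def test_disjoint_supports_one_bit(self):
        assert js_distance({1: 1.0}, {2: 1.0}) == pytest.approx(1.0)
        assert js_distance({1: 0.5, 2: 0.5}, {3: 0.25, 4: 0.75}) == pytest.approx(1.0)

    def test_half_half_vs_point_mass(self):
        # hand evaluation: M=(3/4,1/4); JS = 0.5*0.20752 + 0.5*0.41504
        assert js_distance({1: 0.5, 2: 0.5}, {1: 1.0}) == pytest.approx(0.31128, abs=1e-5)

    def test_bounded_zero_one(self, rng):
        for _ in range(20):
            kp, fp = sparse_random(rng, 20)
            kq, fq = sparse_random(rng, 25)
            d = js_distance(dict(zip(kp.tolist(), fp)), dict(zip(kq.tolist(), fq)))
            assert 0.0 <= d <= 1.0

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            js_distance({1: 0.7}, {1: 1.0})

    def test_empty_profiles(self):
        assert js_distance({}, {}) == 0.0
        with pytest.raises(ValueError):
            js_distance({}, {1: 1.0})

    def test_sqrt_option(self):
        d = js_distance({1: 0.5, 2: 0.5}, {1: 1.0})
        assert js_distance({1: 0.5, 2: 0.5}, {1: 1.0}, sqrt=True) == pytest.approx(
            math.sqrt(d)
        )

    def test_matches_scipy(self, rng):
        kp, fp = sparse_random(rng, 40)
        kq, fq = sparse_random(rng, 30)
        p = dict(zip(kp.tolist(), fp))
        q = dict(zip(kq.tolist(), fq))
        keys = sorted(set(p) | set(q))
        dense_p = np.array([p.get(k, 0.0) for k in keys])
        dense_q = np.array([q.get(k, 0.0) for k in keys])
        expected = jensenshannon(dense_p, dense_q, base=2) ** 2
        assert js_distance(p, q) == pytest.approx(expected, abs=1e-10)


class TestEuclidean:
    def test_identical_zero(self, rng):
        kp, fp = sparse_random(rng, 30)
        p = dict(zip(kp.tolist(), fp))
        assert euclidean_distance(p, p) == 0.0

    def test_disjoint_unit_vectors(self):
        assert euclidean_distance({1: 1.0}, {2: 1.0}) == pytest.approx(math.sqrt(2))

    def test_against_dense(self, rng):
        kp, fp = sparse_random(rng, 35)
        kq, fq = sparse_random(rng, 20)
        p = dict(zip(kp.tolist(), fp))
        q = dict(zip(kq.tolist(), fq))
        keys = sorted(set(p) | set(q))
        dense = np.linalg.norm(
            np.array([p.get(k, 0.0) for k in keys]) - np.array([q.get(k, 0.0) for k in keys])
        )
        assert euclidean_distance(p, q) == pytest.approx(dense, abs=1e-12)


class TestKernels:
    """The compiled merge kernels must agree with the dict reference."""

    @pytest.mark.parametrize("trial", range(5))
    def test_js_kernel_matches_reference(self, rng, trial):
        kp, fp = sparse_random(rng, 40 + trial)
        kq, fq = sparse_random(rng, 60 - trial)
        ref = js_distance(dict(zip(kp.tolist(), fp)), dict(zip(kq.tolist(), fq)))
        assert js_sparse(kp, fp, kq, fq) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_euclidean_kernel_matches_reference(self, rng, trial):
        kp, fp = sparse_random(rng, 30 + trial)
        kq, fq = sparse_random(rng, 45 - trial)
        ref = euclidean_distance(dict(zip(kp.tolist(), fp)), dict(zip(kq.tolist(), fq)))
        assert euclidean_sparse(kp, fp, kq, fq) == pytest.approx(ref, abs=1e-12)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="unique"):
            DistanceMatrix(("a", "a"), np.zeros((2, 2)))

    def test_lookup(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 2.5], [2.5, 0.0]]))
        assert dm["a", "b"] == 2.5


class TestPairwiseMatrices:
    def _profiles(self, rtab, rng, n_seq=4, masks=("11",)):
        seqs = [SequenceRecord(f"s{i}", random_dna(rng, 300)) for i in range(n_seq)]
        pats = [parse_pattern(m) for m in masks]
        return seqs, profile_sequences(seqs, pats, rtab)

    def test_duplicated_sequence_gives_zero(self, rtab, rng):
        s = random_dna(rng, 200)
        seqs = [SequenceRecord("a", s), SequenceRecord("b", s)]
        grid = profile_sequences(seqs, [parse_pattern("1011")], rtab)
        dm = pairwise_matrix_single(grid[0], ["a", "b"])
        assert dm.values[0, 1] == 0.0

    def test_matches_dense_bruteforce_small_k(self, rtab, rng):
        """Sparse evaluation equals a dense vector over all |alphabet|^k words."""
        seqs, grid = self._profiles(rtab, rng, n_seq=3, masks=("101",))
        dm = pairwise_matrix_single(grid[0], [s.id for s in seqs], metric="js")
        # dense oracle over all 16 two-letter match words
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            dense = []
            for seq in (seqs[i], seqs[j]):
                counts = {}
                for a in range(len(seq.residues) - 2):
                    w = seq.residues[a] + seq.residues[a + 2]
                    counts[w] = counts.get(w, 0) + 1
                total = sum(counts.values())
                dense.append(
                    np.array(
                        [counts.get(x + y, 0) / total for x, y in product("ACGT", "ACGT")]
                    )
                )
            expected = jensenshannon(dense[0], dense[1], base=2) ** 2
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_multi_is_elementwise_mean(self, rtab, rng):
        seqs, grid = self._profiles(rtab, rng, n_seq=4, masks=("1011", "11001", "101"))
        labels = [s.id for s in seqs]
        multi = pairwise_matrix_multi(grid, labels)
        singles = [pairwise_matrix_single(row, labels).values for row in grid]
        assert np.allclose(multi.values, np.mean(singles, axis=0), atol=1e-12)

    def test_single_pattern_multi_reduces_to_single(self, rtab, rng):
        seqs, grid = self._profiles(rtab, rng, masks=("1101",))
        labels = [s.id for s in seqs]
        multi = pairwise_matrix_multi(grid, labels)
        single = pairwise_matrix_single(grid[0], labels)
        assert np.allclose(multi.values, single.values)

    def test_repeated_pattern_average_is_identity(self, rtab, rng):
        seqs, grid = self._profiles(rtab, rng, masks=("1101", "1101x".replace("x", "")))
        labels = [s.id for s in seqs]
        # same pattern twice: average of equal terms
        multi = pairwise_matrix_multi([grid[0], grid[0]], labels)
        single = pairwise_matrix_single(grid[0], labels)
        assert np.allclose(multi.values, single.values)

    def test_incomplete_grid_rejected(self, rtab, rng):
        seqs, grid = self._profiles(rtab, rng, masks=("11", "101"))
        with pytest.raises(ValueError, match="incomplete"):
            pairwise_matrix_multi([grid[0], grid[1][:2]], [s.id for s in seqs])

    def test_empty_vs_nonempty_profile_rejected(self, rtab):
        short = SequenceRecord("a", "AC")
        long = SequenceRecord("b", "ACGTACGT")
        grid = profile_sequences([short, long], [parse_pattern("10101")], rtab)
        with pytest.raises(ValueError, match="empty"):
            pairwise_matrix_single(grid[0], ["a", "b"])
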