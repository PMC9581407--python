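"""Candidate filtering, pooling (vs. brute-force clustering), downsampling."""

import numpy as np
import pytest

import chromloop as cl
from chromloop.caller import CandidateLoop


def _cands(triples, chrom="chr1"):
    return [CandidateLoop(chrom, i, j, p, v) for i, j, p, v in triples]


def _brute_pool(cands, radius):
    """Connected components under Chebyshev <= radius + argmax, by brute force."""
    n = len(cands)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = cands[a], cands[b]
            if ca.chrom == cb.chrom and max(abs(ca.i - cb.i), abs(ca.j - cb.j)) <= radius:
                parent[find(a)] = find(b)
    comps = {}
    for k in range(n):
        comps.setdefault(find(k), []).append(cands[k])
    out = [min(m, key=lambda c: (-c.probability, -c.raw_value, c.i, c.j))
           for m in comps.values()]
    return sorted(out, key=lambda c: (c.chrom, c.i, c.j))


class TestFrequencyFilter:
    def test_example(self):
        cands = _cands([(0, 10, 0.5, 1), (0, 20, 0.5, 2), (0, 30, 0.5, 3), (0, 40, 0.5, 4)])
        kept = cl.filter_by_frequency(cands)
        assert sorted(c.raw_value for c in kept) == [3, 4]

    def test_all_equal_empty(self):
        cands = _cands([(0, 10, 0.5, 2), (0, 20, 0.5, 2)])
        assert cl.filter_by_frequency(cands) == []

    def test_empty(self):
        assert cl.filter_by_frequency([]) == []

    def test_brute_force(self, rng):
        cands = _cands([(int(i), int(i) + 5, 0.5, float(v))
                        for i, v in zip(range(300), rng.integers(1, 50, 300))])
        kept = cl.filter_by_frequency(cands)
        mean = np.mean([c.raw_value for c in cands])
        expected = [c for c in cands if c.raw_value > mean]
        assert kept == expected

    def test_per_chromosome_means(self):
        a = _cands([(0, 10, 0.5, 1), (0, 20, 0.5, 3)], "chr1")   # mean 2
        b = _cands([(0, 10, 0.5, 10), (0, 20, 0.5, 30)], "chr2")  # mean 20
        kept = cl.filter_by_frequency(a + b)
        assert {(c.chrom, c.raw_value) for c in kept} == {("chr1", 3), ("chr2", 30)}


class TestProbabilityFilter:
    def test_threshold_zero_identity(self, rng):
        cands = _cands([(i, i + 5, float(p), 1) for i, p in enumerate(rng.random(50))])
        assert cl.filter_by_probability(cands, 0.0) == cands

    def test_threshold_one_empty(self, rng):
        cands = _cands([(i, i + 5, float(p) * 0.99, 1) for i, p in enumerate(rng.random(50))])
        assert cl.filter_by_probability(cands, 1.0) == []

    def test_brute_force(self, rng):
        cands = _cands([(i, i + 5, float(p), 1) for i, p in enumerate(rng.random(100))])
        kept = cl.filter_by_probability(cands, 0.5)
        assert kept == [c for c in cands if c.probability >= 0.5]


class TestPoolCandidates:
    def test_singleton(self):
        c = _cands([(5, 50, 0.9, 2.0)])
        assert cl.pool_candidates(c, 2) == c

    def test_separated_pair_kept(self):
        c = _cands([(5, 50, 0.9, 2.0), (8, 53, 0.8, 1.0)])  # Chebyshev 3 > radius 2
        assert len(cl.pool_candidates(c, 2)) == 2

    def test_adjacent_pair_pooled_by_probability(self):
        c = _cands([(5, 50, 0.7, 9.0), (6, 51, 0.9, 1.0)])
        (rep,) = cl.pool_candidates(c, 2)
        assert (rep.i, rep.j) == (6, 51)

    def test_tie_breaks(self):
        c = _cands([(5, 50, 0.9, 1.0), (6, 51, 0.9, 2.0)])
        (rep,) = cl.pool_candidates(c, 2)
        assert rep.raw_value == 2.0
        c = _cands([(6, 51, 0.9, 2.0), (5, 50, 0.9, 2.0)])
        (rep,) = cl.pool_candidates(c, 2)
        assert (rep.i, rep.j) == (5, 50)

    @pytest.mark.parametrize("trial", range(8))
    def test_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 60))
        cands = _cands([
            (int(i), int(i) + int(d), float(np.round(p, 3)), float(v))
            for i, d, p, v in zip(rng.integers(0, 60, n), rng.integers(3, 40, n),
                                  rng.random(n), rng.integers(1, 9, n))
        ])
        # dedupe identical pixels to respect candidate uniqueness
        seen, uniq = set(), []
        for c in cands:
            if (c.i, c.j) not in seen:
                seen.add((c.i, c.j))
                uniq.append(c)
        radius = int(rng.integers(1, 4))
        assert cl.pool_candidates(uniq, radius) == _brute_pool(uniq, radius)

    def test_idempotent(self, rng):
        cands = _cands([(int(i), int(i + d), float(p), 1.0) for i, d, p in
                        zip(rng.integers(0, 100, 40), rng.integers(3, 30, 40),
                            rng.random(40))])
        once = cl.pool_candidates(cands, 2)
        assert cl.pool_candidates(once, 2) == once

    def test_representatives_separated(self, rng):
        cands = _cands([(int(i), int(i + d), float(p), 1.0) for i, d, p in
                        zip(rng.integers(0, 50, 60), rng.integers(3, 20, 60),
                            rng.random(60))])
        seen, uniq = set(), []
        for c in cands:
            if (c.i, c.j) not in seen:
                seen.add((c.i, c.j))
                uniq.append(c)
        reps = cl.pool_candidates(uniq, 2)
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                assert max(abs(reps[a].i - reps[b].i), abs(reps[a].j - reps[b].j)) > 2


class TestDownsample:
    def _map(self, rng, n=300):
        i = rng.integers(0, n - 30, 500)
        d = rng.integers(1, 30, 500)
        m = cl.ContactMap.from_entries("chr1", 10000, n, i, i + d,
                                       rng.integers(1, 20, 500).astype(float))
        return m

    def test_fraction_one_identity(self, rng):
        m = self._map(rng)
        out = cl.downsample(m, 1.0, seed=1)
        np.testing.assert_array_equal(out.bin1, m.bin1)
        np.testing.assert_allclose(out.value, m.value)

    def test_fraction_zero_empty(self, rng):
        m = self._map(rng)
        assert len(cl.downsample(m, 0.0, seed=1)) == 0

    def test_binomial_moments(self, rng):
        m = self._map(rng)
        total = m.total()
        out = cl.downsample(m, 0.5, seed=7)
        assert abs(out.total() - total / 2) < 4 * np.sqrt(total * 0.25)

    def test_expected_linear_in_fraction(self, rng):
        m = self._map(rng)
        total = m.total()
        for frac in (0.3, 0.6, 0.9):
            draws = [cl.downsample(m, frac, seed=s).total() for s in range(20)]
            expected = frac * total
            assert abs(np.mean(draws) - expected) < 4 * np.sqrt(total * frac * (1 - frac) / 20)

    def test_non_integer_rejected(self):
        m = cl.ContactMap("chr1", 10000, 10, [0], [5], [1.5])
        with pytest.raises(ValueError, match="integer"):
            cl.downsample(m, 0.5, seed=0)

    def test_deterministic(self, rng):
        m = self._map(rng)
        a = cl.downsample(m, 0.5, seed=3)
        b = cl.downsample(m, 0.5, seed=3)
        np.testing.assert_array_equal(a.bin1, b.bin1)
        np.testing.assert_allclose(a.value, b.value)


class TestScoreAndCall:
    def test_empty_distance_range(self, trained, study):
        m = study["maps"]["chr3"]
        t = study["tracks"]["chr3"]
        assert cl.score_chromosome(trained, m, t, min_dist=330, max_dist=340) == []

    def test_candidate_enumeration(self, trained, study):
        m = study["maps"]["chr3"]
        t = study["tracks"]["chr3"]
        lo, hi, half = 100, 120, 11
        cands = cl.score_chromosome(trained, m, t, min_dist=lo, max_dist=hi)
        d = m.distance
        expected = int(np.sum(
            (d >= lo) & (d <= hi)
            & (m.bin1 >= half) & (m.bin2 + half < m.n_bins)
        ))
        assert len(cands) == expected

    def test_planted_pixels_score_higher(self, trained, study, scored_test_chrom):
        cands, _ = scored_test_chrom
        truth = {(t.bin1, t.bin2) for t in study["truth"]["chr3"]}
        probs_t = [c.probability for c in cands if (c.i, c.j) in truth]
        probs_b = [c.probability for c in cands if (c.i, c.j) not in truth]
        assert np.mean(probs_t) > np.mean(probs_b)

    def test_pipeline_monotonicity(self, trained, study, scored_test_chrom):
        cands, after_freq = scored_test_chrom
        after_prob = cl.filter_by_probability(after_freq, 0.5)
        pooled = cl.pool_candidates(after_prob, 2)
        assert len(pooled) <= len(after_prob) <= len(after_freq) <= len(cands)
        pixel_set = {(c.i, c.j) for c in cands}
        assert all((c.i, c.j) in pixel_set for c in pooled)
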