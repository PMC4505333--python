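import numpy as np
import pytest

from sigmatch.distance import (
    DistanceMatrix,
    combine_scores,
    combined_es,
    distance_from_scores,
    distance_matrix,
    enrichment_score,
    extract_signature,
    prl_distance,
)
from sigmatch.prl import ProbeRankList

from helpers import naive_enrichment_score, naive_running_sums, random_prl


class TestExtractSignature:
    def test_top_and_bottom_slices(self):
        prl = ProbeRankList([f"P{i}" for i in range(1, 11)])
        sig = extract_signature(prl, 2)
        assert sig.up_set == {"P1", "P2"}
        assert sig.down_set == {"P9", "P10"}

    def test_half_universe_partitions(self, rng):
        prl = random_prl(20, rng)
        sig = extract_signature(prl, 10)
        assert sig.up_set | sig.down_set == prl.universe
        assert not sig.up_set & sig.down_set

    def test_default_size_on_platform_scale_universe(self, rng):
        """n = 250 against a 22,215-probe universe (the GPL96 probe count)."""
        prl = random_prl(22215, rng)
        sig = extract_signature(prl)
        assert len(sig.up_set) == len(sig.down_set) == 250
        assert not sig.up_set & sig.down_set

    def test_oversized_signature_rejected(self, rng):
        with pytest.raises(ValueError, match="2n"):
            extract_signature(random_prl(10, rng), 6)


class TestEnrichmentScore:
    def test_top_block_scores_one(self, rng):
        ref = random_prl(50, rng)
        assert enrichment_score(ref.ordering[:10], ref) == 1.0

    def test_bottom_block_scores_minus_one(self, rng):
        ref = random_prl(50, rng)
        assert enrichment_score(ref.ordering[-10:], ref) == -1.0

    def test_hand_enumerated_running_sum(self):
        # N=5, n=2, hits at ranks 1 and 3: sums 1/2, 1/6, 2/3, 1/3, 0
        ref = ProbeRankList(["A", "B", "C", "D", "E"])
        assert enrichment_score({"A", "C"}, ref) == pytest.approx(2 / 3, abs=1e-12)

    def test_matches_membership_loop_oracle(self, rng):
        for _ in range(50):
            N = int(rng.integers(10, 400))
            n = int(rng.integers(1, N // 2 + 1))
            ref = random_prl(N, np.random.default_rng(rng.integers(2**31)))
            gene_set = set(rng.choice(ref.ordering, size=n, replace=False).tolist())
            fast = enrichment_score(gene_set, ref)
            assert fast == pytest.approx(naive_enrichment_score(gene_set, ref), abs=1e-12)
            assert -1.0 <= fast <= 1.0

    def test_running_sum_returns_to_zero(self, rng):
        ref = random_prl(200, rng)
        gene_set = set(rng.choice(ref.ordering, size=40, replace=False).tolist())
        assert naive_running_sums(gene_set, ref)[-1] == pytest.approx(0.0, abs=1e-9)

    def test_unknown_probe_rejected(self, rng):
        with pytest.raises(KeyError):
            enrichment_score({"missing"}, random_prl(10, rng))

    def test_degenerate_set_sizes_rejected(self, rng):
        ref = random_prl(10, rng)
        with pytest.raises(ValueError):
            enrichment_score(set(), ref)
        with pytest.raises(ValueError):
            enrichment_score(set(ref.ordering.tolist()), ref)


class TestCombinedScores:
    def test_self_signature_perfect_enrichment(self, rng):
        ref = random_prl(40, rng)
        res = combined_es(extract_signature(ref, 8), ref)
        assert res.es_up == 1.0 and res.es_down == -1.0 and res.combined == 1.0

    def test_reverse_signature_perfect_anticorrelation(self, rng):
        ref = random_prl(40, rng)
        res = combined_es(extract_signature(ref, 8), ref.reverse())
        assert res.combined == -1.0

    def test_two_sided_combination_rule(self):
        assert combine_scores(0.0557, -0.0706) == pytest.approx(0.06315, abs=1e-12)

    def test_random_signature_combined_es_centred_on_zero(self, rng):
        """Mean combined ES of unrelated signature/reference pairs is ~0."""
        vals = []
        for _ in range(200):
            seeds = rng.integers(2**31, size=2)
            sig = extract_signature(random_prl(1000, np.random.default_rng(seeds[0])), 100)
            ref = random_prl(1000, np.random.default_rng(seeds[1]))
            vals.append(combined_es(sig, ref).combined)
        assert abs(float(np.mean(vals))) < 0.05


class TestPrlDistance:
    def test_self_distance_zero(self, rng):
        a = random_prl(60, rng)
        assert prl_distance(a, a, 10) == 0.0

    def test_reversal_distance_two(self, rng):
        a = random_prl(60, rng)
        assert prl_distance(a, a.reverse(), 10) == 2.0

    def test_distance_from_directional_scores(self):
        assert distance_from_scores(0.06315, 0.15345) == pytest.approx(0.8917, abs=1e-12)

    def test_universe_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="universe"):
            prl_distance(random_prl(20, rng), random_prl(21, rng), 5)


class TestDistanceMatrix:
    def test_identical_pair_off_diagonal_zero(self, rng):
        a = random_prl(40, rng)
        b = ProbeRankList(a.ordering.copy())
        dm = distance_matrix({"x": a, "y": b}, n=8)
        assert dm[("x", "y")] == 0.0

    def test_reversal_pair_off_diagonal_two(self, rng):
        a = random_prl(40, rng)
        dm = distance_matrix({"x": a, "y": a.reverse()}, n=8)
        assert dm[("x", "y")] == 2.0

    def test_matches_pairwise_recomputation(self, rng):
        prls = {f"c{i}": random_prl(100, np.random.default_rng(i)) for i in range(5)}
        dm = distance_matrix(prls, n=10)
        for i, li in enumerate(dm.labels):
            for j, lj in enumerate(dm.labels):
                expected = 0.0 if i == j else prl_distance(prls[li], prls[lj], 10)
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_array_equal(dm.values, dm.values.T)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))

    def test_out_of_range_values_rejected(self):
        v = np.array([[0.0, 2.5], [2.5, 0.0]])
        with pytest.raises(ValueError, match="\\[0, 2\\]"):
            DistanceMatrix(["a", "b"], v)
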