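import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmatch.prl import ProbeRankList, build_prl, primary_threshold

# frozen hand-worked fixtures: (control, experiment, probe ids, expected ordering)
#
# fixture 1 — pooled values {40,20,10,5,10,10,10,10}, lower quartile 10,
# secondary 1; clamped ratios (4, 2, 1, 1); the ratio-1 block re-clamps the
# original values at 1 giving sub-ratios (1, 0.5), so P3 precedes P4.
FIXTURE_UNIFORM_CONTROL = (
    [10.0, 10.0, 10.0, 10.0],
    [40.0, 20.0, 10.0, 5.0],
    ["P1", "P2", "P3", "P4"],
    ["P1", "P2", "P3", "P4"],
)
# fixture 2 — pooled sorted {1,2,2,5,8,10,50,100}, lower quartile 2,
# secondary 0.2; clamped ratios (0.5, 1, 2, 0.25); P2's sub-ratio stays 1.
FIXTURE_MIXED = (
    [10.0, 2.0, 50.0, 8.0],
    [5.0, 2.0, 100.0, 1.0],
    ["P1", "P2", "P3", "P4"],
    ["P3", "P2", "P1", "P4"],
)


class TestPrimaryThreshold:
    def test_pooled_lower_quartile_interpolated(self):
        t = primary_threshold([1, 2, 3, 4], [5, 6, 7, 8])
        assert t.primary == pytest.approx(2.75, abs=1e-12)
        assert t.secondary == pytest.approx(0.275, abs=1e-12)

    def test_constant_vector_quartile_is_constant(self):
        t = primary_threshold([3.0] * 6, [3.0] * 6)
        assert t.primary == 3.0 and t.secondary == 0.3

    def test_four_pooled_values_interpolate_between_order_statistics(self):
        t = primary_threshold([10, 20], [30, 40])
        assert t.primary == pytest.approx(17.5, abs=1e-12)

    def test_non_positive_value_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            primary_threshold([1, 2, 3, -1], [1, 2, 3, 4])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            primary_threshold([1, 2, 3], [1, 2, 3, 4])


class TestBuildPrl:
    @pytest.mark.parametrize(
        "ctrl,exp,ids,expected", [FIXTURE_UNIFORM_CONTROL, FIXTURE_MIXED]
    )
    def test_frozen_fixture_permutations(self, ctrl, exp, ids, expected):
        prl = build_prl(exp, ctrl, ids)
        assert prl.ordering.tolist() == expected

    def test_identical_samples_fall_back_to_lexicographic_order(self):
        vals = [7.0, 3.0, 9.0, 1.0]
        prl = build_prl(vals, vals, ["PB", "PD", "PA", "PC"])
        assert prl.ordering.tolist() == ["PA", "PB", "PC", "PD"]

    @pytest.mark.parametrize("c", [0.1, 17.3])
    def test_scale_invariance(self, c, rng):
        exp = rng.lognormal(6, 1, 200)
        ctl = rng.lognormal(6, 1, 200)
        ids = [f"P{i:03d}" for i in range(200)]
        assert build_prl(c * exp, c * ctl, ids) == build_prl(exp, ctl, ids)

    @pytest.mark.parametrize(
        "ctrl,exp,ids,expected", [FIXTURE_UNIFORM_CONTROL, FIXTURE_MIXED]
    )
    def test_scale_invariance_on_fixtures(self, ctrl, exp, ids, expected):
        for c in (0.1, 17.3):
            scaled = build_prl(np.multiply(exp, c), np.multiply(ctrl, c), ids)
            assert scaled.ordering.tolist() == expected

    def test_clamped_ratios_non_increasing_along_ranking(self, rng):
        """Order consistency: higher clamped ratio always ranks higher."""
        exp = rng.lognormal(6, 1, 500)
        ctl = rng.lognormal(6, 1, 500)
        ids = np.array([f"P{i:03d}" for i in range(500)])
        prl = build_prl(exp, ctl, ids)
        thr = primary_threshold(exp, ctl)
        ratio = np.maximum(exp, thr.primary) / np.maximum(ctl, thr.primary)
        by_id = dict(zip(ids, ratio))
        along = np.array([by_id[p] for p in prl.ordering])
        assert (np.diff(along) <= 0).all()

    def test_deterministic_across_calls(self, rng):
        exp = rng.lognormal(6, 1, 100)
        ctl = rng.lognormal(6, 1, 100)
        ids = [f"P{i}" for i in range(100)]
        assert build_prl(exp, ctl, ids) == build_prl(exp, ctl, ids)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            build_prl([1, 2, 3], [1, 2, 3], ["A", "B", "C"])

    def test_non_positive_value_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_prl([1, 2, 3, 0], [1, 2, 3, 4], list("ABCD"))

    @given(
        values=st.lists(
            st.tuples(
                st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False),
                st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False),
            ),
            min_size=4,
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_output_is_strict_permutation(self, values):
        exp = [v[0] for v in values]
        ctl = [v[1] for v in values]
        ids = [f"P{i:03d}" for i in range(len(values))]
        prl = build_prl(exp, ctl, ids)
        assert sorted(prl.ordering.tolist()) == sorted(ids)
        assert len(prl) == len(ids)


class TestProbeRankList:
    def test_rank_lookup_and_reverse(self):
        prl = ProbeRankList(["B", "A", "C"])
        assert prl.rank_of("B") == 1 and prl.rank_of("C") == 3
        assert prl.reverse().ordering.tolist() == ["C", "A", "B"]

    def test_duplicate_probe_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ProbeRankList(["A", "A", "B"])

    def test_unknown_probe_lookup_raises(self):
        with pytest.raises(KeyError):
            ProbeRankList(["A", "B"]).ranks_of(["Z"])
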