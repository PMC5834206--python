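"""Scoring layer: rankit transform, S-score arithmetic, significance calls,
differential construction, per-query tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emapnet import (
    ColonyPlateSet,
    EmapValidationError,
    InteractionMatrix,
    call_significant,
    compute_differential,
    compute_sscores,
    rankit_normalize,
    tally_by_query,
    variance_floor_weight,
)


class TestRankit:
    def test_single_value_maps_to_zero(self):
        assert rankit_normalize([17.3]) == pytest.approx([0.0])

    def test_three_distinct_values(self):
        # Phi^-1 of (1/6, 1/2, 5/6)
        out = rankit_normalize([10.0, 30.0, 20.0])
        np.testing.assert_allclose(out, [-0.9674, 0.9674, 0.0], atol=5e-5)

    def test_ties_get_mean_rank(self):
        out = rankit_normalize([1.0, 1.0, 2.0])
        expected = stats.norm.ppf((np.array([1.5, 1.5, 3.0]) - 0.5) / 3)
        np.testing.assert_allclose(out, expected)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            rankit_normalize([1.0, np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2,
                    max_size=40, unique=True))
    def test_antisymmetric_under_order_reversal(self, values):
        forward = rankit_normalize(values)
        reversed_ = rankit_normalize([-v for v in values])
        np.testing.assert_allclose(reversed_, -forward, atol=1e-12)

    def test_monotone_in_rank_and_centered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=101)
        out = rankit_normalize(x)
        assert (np.diff(out[np.argsort(x)]) > 0).all()
        assert abs(out.mean()) < 1e-12


def _single_pair_plates(observed, e_query, n_replicates=4):
    c0 = 1000.0
    sizes = np.array(observed).reshape(1, 1, 1, n_replicates) * c0
    return ColonyPlateSet(
        queries=["Q"], tests=["T"], conditions=["u"], sizes=sizes,
        n_replicates=n_replicates,
        single_fitness={("Q", "u"): e_query, ("T", "u"): 1.0},
    ), c0


class TestSScore:
    def test_hand_computed_four_replicate_example(self):
        """S = (0.5 - 0.8) / sqrt(0.0016667/4) with a zero variance floor."""
        plates, c0 = _single_pair_plates([0.5, 0.55, 0.45, 0.5], e_query=0.8)
        m = compute_sscores(plates, "u", c0=c0, variance_floor=0.0, center=False)
        s2 = np.var([0.5, 0.55, 0.45, 0.5], ddof=1)
        expected = (0.5 - 0.8) / np.sqrt(s2 / 4)
        assert m.scores[0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(-14.6969, abs=1e-4)

    def test_observed_equal_expected_scores_zero(self):
        plates, c0 = _single_pair_plates([0.8, 0.8, 0.8, 0.8], e_query=0.8)
        m = compute_sscores(plates, "u", c0=c0, center=False)
        assert m.scores[0, 0] == 0.0
        assert not m.mask[0, 0]

    def test_pairs_with_too_few_replicates_masked_with_warning(self, caplog):
        sizes = np.array([800.0, 820.0, 790.0, 810.0]).reshape(1, 1, 1, 4)
        sizes = np.repeat(sizes, 2, axis=1)
        sizes[0, 1, 0, 1:] = np.nan  # one replicate only
        plates = ColonyPlateSet(
            queries=["Q"], tests=["T1", "T2"], conditions=["u"], sizes=sizes,
            n_replicates=4,
            single_fitness={("Q", "u"): 1.0, ("T1", "u"): 1.0, ("T2", "u"): 1.0},
        )
        with caplog.at_level("WARNING"):
            m = compute_sscores(plates, "u", c0=1000.0)
        assert m.mask[0, 1] and not m.mask[0, 0]
        assert any("masked" in r.message for r in caplog.records)

    def test_zero_reference_size_rejected(self):
        plates, _ = _single_pair_plates([0.5, 0.6, 0.7, 0.8], e_query=1.0)
        with pytest.raises(EmapValidationError):
            compute_sscores(plates, "u", c0=0.0)

    def test_variance_floor_weight_calibrates_unit_variance(self):
        """Monte Carlo check of the floor solver: with the calibrated floor,
        null scores Z/sqrt((X + c*q)) have variance ~ 1."""
        n = 4
        c = variance_floor_weight(n)
        rng = np.random.default_rng(0)
        x = rng.chisquare(n - 1, 400_000) / (n - 1)
        q = np.median(x)
        z = rng.standard_normal(x.size)
        s = z / np.sqrt(x + c * q)
        assert s.var() == pytest.approx(1.0, abs=0.02)


class TestCalls:
    @pytest.mark.parametrize(
        "score,mode,expected",
        [
            (2.0, "static", 1), (1.99, "static", 0),
            (-2.5, "static", -1), (-2.4, "static", 0),
            (3.0, "differential", 1), (2.99, "differential", 0),
            (-3.0, "differential", -1), (-2.99, "differential", 0),
        ],
    )
    def test_threshold_boundaries_inclusive(self, score, mode, expected):
        thresholds = (2.0, -2.5) if mode == "static" else (3.0, -3.0)
        m = InteractionMatrix(
            queries=["Q"], tests=["T"], condition="u",
            scores=np.array([[score]]), mask=np.zeros((1, 1), bool),
            thresholds=thresholds,
        )
        assert call_significant(m, mode=mode).calls[0, 0] == expected

    def test_masked_pairs_never_called(self, tiny_matrix):
        tiny_matrix.scores[1, 1] = 99.0
        calls = call_significant(tiny_matrix, "static")
        assert calls.calls[1, 1] == 0

    def test_counts_monotone_in_cutoff_magnitude(self):
        rng = np.random.default_rng(2)
        m = InteractionMatrix(
            queries=[f"q{i}" for i in range(5)], tests=[f"t{j}" for j in range(50)],
            condition="u", scores=rng.normal(0, 2, (5, 50)),
            mask=np.zeros((5, 50), bool),
        )
        counts = [
            call_significant(m, "static", thresholds=(c, -c)).n_significant()
            for c in (1.0, 1.5, 2.0, 2.5, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)


def _matrix(scores, condition="u", mask=None):
    scores = np.asarray(scores, dtype=float)
    return InteractionMatrix(
        queries=[f"q{i}" for i in range(scores.shape[0])],
        tests=[f"t{j}" for j in range(scores.shape[1])],
        condition=condition,
        scores=scores,
        mask=np.zeros(scores.shape, bool) if mask is None else mask,
    )


class TestDifferential:
    def test_self_difference_is_identically_zero(self):
        rng = np.random.default_rng(3)
        x = _matrix(rng.normal(0, 1, (6, 80)))
        d = compute_differential(x, x)
        assert np.abs(d.scores).max() == 0.0

    def test_antisymmetric_under_argument_swap(self):
        rng = np.random.default_rng(4)
        a = _matrix(rng.normal(0, 1, (6, 80)), "t")
        b = _matrix(rng.normal(0, 1, (6, 80)), "u")
        d_ab = compute_differential(a, b)
        d_ba = compute_differential(b, a)
        np.testing.assert_allclose(d_ab.scores, -d_ba.scores, atol=1e-12)
        assert d_ab.sigma_delta == pytest.approx(d_ba.sigma_delta)

    def test_mad_scale_estimate_is_consistent(self):
        """Delta ~ N(0, 2) at 1e5 pairs: recorded sigma_delta estimates 2."""
        rng = np.random.default_rng(5)
        delta = rng.normal(0, 2.0, (100, 1000))
        d = compute_differential(_matrix(delta, "t"), _matrix(np.zeros_like(delta), "u"))
        assert 1.9 <= d.sigma_delta <= 2.1

    def test_mask_union_propagates(self):
        mask_a = np.zeros((2, 3), bool); mask_a[0, 0] = True
        mask_b = np.zeros((2, 3), bool); mask_b[1, 2] = True
        a = _matrix(np.ones((2, 3)), "t", mask_a)
        b = _matrix(np.zeros((2, 3)), "u", mask_b)
        d = compute_differential(a, b)
        assert d.mask[0, 0] and d.mask[1, 2] and d.mask.sum() == 2

    def test_axis_mismatch_lists_symmetric_difference(self):
        a = _matrix(np.ones((2, 3)), "t")
        b = InteractionMatrix(
            queries=["q0", "qX"], tests=a.tests, condition="u",
            scores=np.zeros((2, 3)), mask=np.zeros((2, 3), bool),
        )
        with pytest.raises(EmapValidationError, match="qX"):
            compute_differential(a, b)


class TestTally:
    def test_hand_built_counts(self):
        scores = np.zeros((3, 4))
        scores[0, 0] = 2.5   # positive for q0
        scores[0, 1] = 3.0   # positive for q0
        scores[0, 2] = -2.6  # negative for q0
        calls = call_significant(_matrix(scores), "static")
        tally = tally_by_query(calls)
        assert tally.counts("q0") == (2, 1)
        assert tally.counts("q1") == (0, 0)

    def test_no_calls_all_zero(self):
        calls = call_significant(_matrix(np.zeros((3, 4))), "static")
        tally = tally_by_query(calls)
        assert (tally.table[["n_positive", "n_negative"]].to_numpy() == 0).all()

    def test_hub_query_has_max_rankit(self):
        """A query with 10x interaction density tops the rankit-normalized tally."""
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, (54, 300))
        hub = rng.random(300) < 0.30
        scores[7, hub] = 5.0  # dense hub row
        others = rng.random((54, 300)) < 0.03
        others[7] = False
        scores[others] = 5.0
        calls = call_significant(_matrix(scores), "static")
        tally = tally_by_query(calls, normalize=True)
        table = tally.table
        assert table.loc[table["rankit"].idxmax(), "query"] == "q7"
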