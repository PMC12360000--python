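import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ranksum_p_exact
from teepi.config import Config
from teepi.effect_calling import (
    DEPLETION,
    ENRICHMENT,
    EXCLUDED,
    HIGHER,
    LOWER,
    MIX,
    NA,
    NONE,
    PairCall,
    classify_pair,
    combine_marks,
    consensus_call,
    percent_change,
    spread_extent,
    window_test,
)
from teepi.signal_windows import WindowProfile

CFG = Config(n_windows_per_side=5)


def _profile(window_values, strain="A", n_windows=5, bins=100):
    """Profile with every window filled at the given constant or array."""
    def side():
        return np.stack(
            [np.broadcast_to(np.asarray(window_values[i], float), (bins,)).copy()
             for i in range(n_windows)]
        )
    return WindowProfile("te1", strain, "head", "H3K9me3", side(), side())


def _noisy_profile(rng, mult=None, strain="A", n_windows=5, bins=100, sd=0.2):
    base = rng.lognormal(0, sd, (2, n_windows, bins))
    if mult is not None:
        base *= np.asarray(mult, float)[None, :, None]
    return WindowProfile("te1", strain, "head", "H3K9me3", base[0], base[1])


class TestWindowTest:
    def test_identical_vectors_give_p_one(self):
        x = np.full(100, 2.0)
        res = window_test(x, x, CFG)
        assert res.p_value == 1.0 and res.direction == NONE

    def test_complete_separation_is_overwhelming(self):
        x = np.linspace(10, 11, 100)
        y = np.linspace(1, 2, 100)
        res = window_test(x, y, CFG)
        assert res.p_value < 1e-30 and res.direction == HIGHER

    def test_too_few_bins_is_missing(self):
        rng = np.random.default_rng(0)
        res = window_test(rng.normal(size=40), rng.normal(size=100), CFG)
        assert res.missing

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_matches_exact_enumeration_for_small_groups(self, data):
        n = data.draw(st.integers(2, 8))
        m = data.draw(st.integers(2, 8))
        vals = data.draw(
            st.lists(st.integers(0, 1000), min_size=n + m, max_size=n + m,
                     unique=True)
        )
        x, y = np.array(vals[:n], float), np.array(vals[n:], float)
        cfg = Config(min_bins_per_window=2)
        assert window_test(x, y, cfg).p_value == pytest.approx(
            ranksum_p_exact(x, y), abs=1e-12
        )

    def test_asymptotic_matches_scipy_for_large_groups(self, rng):
        from scipy import stats

        x, y = rng.lognormal(0, 0.2, 100), rng.lognormal(0.1, 0.2, 100)
        res = window_test(x, y, CFG)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-9)


class TestPercentChange:
    def test_doubling_is_plus_hundred(self):
        assert percent_change(_profile([2.0] * 5), _profile([1.0] * 5), CFG) == 100.0

    def test_quarter_drop_is_minus_twentyfive(self):
        assert percent_change(_profile([0.75] * 5), _profile([1.0] * 5), CFG) == -25.0

    def test_zero_denominator_is_undefined(self):
        assert np.isnan(percent_change(_profile([2.0] * 5), _profile([0.0] * 5), CFG))


class TestSpreadExtent:
    def test_min_rule_uses_window_closer_to_te(self):
        s = spread_extent(
            np.array([1, 1, 1, 0, 0], bool), [HIGHER] * 5,
            np.array([1, 1, 0, 0, 0], bool), [HIGHER] * 5,
            HIGHER,
        )
        assert s == 2

    def test_all_windows_significant_gives_full_span(self):
        s = spread_extent(
            np.ones(5, bool), [HIGHER] * 5, np.ones(5, bool), [HIGHER] * 5, HIGHER
        )
        assert s == 5

    def test_innermost_not_significant_gives_zero(self):
        s = spread_extent(
            np.ones(5, bool), [HIGHER] * 5,
            np.array([0, 1, 1, 1, 1], bool), [NONE, *[HIGHER] * 4],
            HIGHER,
        )
        assert s == 0

    def test_direction_change_breaks_the_run(self):
        s = spread_extent(
            np.ones(5, bool), [HIGHER, HIGHER, LOWER, HIGHER, HIGHER],
            np.ones(5, bool), [HIGHER] * 5,
            HIGHER,
        )
        assert s == 2


class TestClassifyPair:
    def test_planted_enrichment_detected_with_spread(self, rng):
        mult = [1.5, 1.5, 1.5, 1.0, 1.0]
        pos = _noisy_profile(rng, mult)
        neg = _noisy_profile(rng, None, strain="B")
        pc = classify_pair("te1", pos, neg, CFG)
        assert pc.effect == ENRICHMENT
        assert pc.spread_kb == 3.0
        assert pc.percentage == pytest.approx(50, abs=10)

    def test_no_difference_is_none_with_zero_spread(self, rng):
        pc = classify_pair(
            "te1", _noisy_profile(rng), _noisy_profile(rng, strain="B"), CFG
        )
        assert pc.effect in (NONE, NA)  # null data is almost always "none"
        if pc.effect == NONE:
            assert pc.spread_kb == 0.0

    def test_contradictory_sides_are_na(self, rng):
        pos = _noisy_profile(rng)
        pos.left *= 1.8  # left higher ...
        pos.right *= 0.4  # ... right lower
        pc = classify_pair("te1", pos, _noisy_profile(rng, strain="B"), CFG)
        assert pc.effect == NA

    def test_missing_innermost_window_is_na(self, rng):
        pos = _noisy_profile(rng)
        pos.left[0] = np.nan
        pc = classify_pair("te1", pos, _noisy_profile(rng, strain="B"), CFG)
        assert pc.effect == NA

    def test_label_swap_flips_class_and_sign(self, rng):
        mult = [1.6, 1.6, 1.0, 1.0, 1.0]
        pos = _noisy_profile(rng, mult)
        neg = _noisy_profile(rng, None, strain="B")
        fwd = classify_pair("te1", pos, neg, CFG)
        rev = classify_pair("te1", neg, pos, CFG)
        assert fwd.effect == ENRICHMENT and rev.effect == DEPLETION
        assert fwd.percentage > 0 > rev.percentage

    def test_null_pair_call_rate_is_calibrated(self, rng):
        # both innermost windows significant in the same direction happens
        # with probability about alpha^2 / 2 under the null
        n_pairs, hits = 400, 0
        for _ in range(n_pairs):
            pc = classify_pair(
                "te1", _noisy_profile(rng), _noisy_profile(rng, strain="B"), CFG
            )
            if pc.effect in (ENRICHMENT, DEPLETION):
                hits += 1
        alpha = CFG.alpha
        bound = 2 * alpha**2 + 3 * np.sqrt(2 * alpha**2 / n_pairs)
        assert hits / n_pairs <= bound


def _pair(effect, pct=50.0, spread=3.0):
    return PairCall("te1", "A", "B", "head", "H3K9me3", effect, pct, spread)


class TestConsensus:
    def test_unanimous_pairs_agree(self):
        ec = consensus_call([_pair(ENRICHMENT)] * 4, CFG)
        assert ec.effect == ENRICHMENT and ec.n_concordant == 4
        assert ec.percentage == 50.0 and ec.spread_kb == 3.0

    def test_one_deviating_pair_allowed(self):
        ec = consensus_call([_pair(ENRICHMENT)] * 3 + [_pair(NONE, np.nan, 0.0)], CFG)
        assert ec.effect == ENRICHMENT

    def test_one_na_pair_allowed(self):
        ec = consensus_call([_pair(ENRICHMENT)] * 3 + [_pair(NA, np.nan, np.nan)], CFG)
        assert ec.effect == ENRICHMENT

    def test_two_against_two_excluded(self):
        ec = consensus_call([_pair(ENRICHMENT)] * 2 + [_pair(DEPLETION, -30.0)] * 2,
                            CFG)
        assert ec.effect == EXCLUDED

    def test_two_deviations_excluded(self):
        ec = consensus_call(
            [_pair(ENRICHMENT)] * 3 + [_pair(NONE, np.nan, 0.0)] * 2, CFG
        )
        assert ec.effect == EXCLUDED

    def test_all_na_excluded(self):
        ec = consensus_call([_pair(NA, np.nan, np.nan)] * 3, CFG)
        assert ec.effect == EXCLUDED

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            consensus_call([], CFG)

    def test_reported_stats_average_concordant_pairs(self):
        ec = consensus_call(
            [_pair(ENRICHMENT, 40.0, 2.0), _pair(ENRICHMENT, 60.0, 4.0)], CFG
        )
        assert ec.percentage == 50.0 and ec.spread_kb == 3.0

    def test_consensus_class_always_among_pair_classes(self, rng):
        import itertools

        options = [ENRICHMENT, DEPLETION, NONE, NA]
        for combo in itertools.product(options, repeat=3):
            pairs = [_pair(c, 50.0 if c == ENRICHMENT else -50.0) for c in combo]
            ec = consensus_call(pairs, CFG)
            assert ec.effect in set(combo) | {EXCLUDED}


class TestCombineMarks:
    def _call(self, mark, effect):
        from teepi.effect_calling import EffectCall

        return EffectCall("te1", "head", mark, effect, 50.0, 3.0, 4, 4)

    @pytest.mark.parametrize(
        "k9,k27,expected",
        [
            (ENRICHMENT, ENRICHMENT, "bivalent"),
            (DEPLETION, DEPLETION, "bivalent"),
            (ENRICHMENT, DEPLETION, MIX),
            (ENRICHMENT, NONE, "H3K9me3-only"),
            (NONE, NONE, NONE),
        ],
    )
    def test_combined_class(self, k9, k27, expected):
        combined = combine_marks(
            {"H3K9me3": self._call("H3K9me3", k9), "H3K27ac": self._call("H3K27ac", k27)}
        )
        assert combined == expected
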