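import itertools

import numpy as np
import pytest

from baciveg import baci
from baciveg.baci import (
    Category,
    CompositionSummary,
    PADroppedError,
    classify_after,
    classify_change,
    compare_pair,
    composition,
    ternary_export,
)
from baciveg.config import AnalysisConfig

SIGNS = (-0.003, 0.0, 0.004)


def expected_category(a: float, b: float) -> Category:
    if a > 0 and b > 0:
        return Category.POSITIVE
    if a < 0 and b < 0:
        return Category.NEGATIVE
    return Category.UNCLEAR  # mixed signs and any zero


class TestConditionTruthTable:
    @pytest.mark.parametrize("sb,sd", list(itertools.product(SIGNS, SIGNS)))
    def test_all_nine_sign_combinations(self, sb, sd):
        assert classify_after(sb, sd) == expected_category(sb, sd)

    def test_examples(self):
        assert classify_after(0.004, 0.002) == Category.POSITIVE  # improve
        assert classify_after(-0.003, -0.001) == Category.NEGATIVE  # decline
        assert classify_after(0.004, -0.001) == Category.UNCLEAR

    def test_missing_slope_is_insufficient(self):
        assert classify_after(np.nan, 0.1) == Category.INSUFFICIENT
        assert classify_after(0.1, np.nan) == Category.INSUFFICIENT


class TestChangeTruthTable:
    @pytest.mark.parametrize("db,dd", list(itertools.product(SIGNS, SIGNS)))
    def test_all_nine_difference_sign_combinations(self, db, dd):
        # build before/after slopes realizing the target differences
        got = classify_change(0.001, 0.001 + db, -0.002, -0.002 + dd)
        assert got == expected_category(db, dd)

    def test_examples(self):
        assert classify_change(0.001, 0.003, 0.001, 0.002) == Category.POSITIVE
        assert classify_change(0.002, 0.001, 0.002, 0.000) == Category.NEGATIVE
        assert classify_change(0.002, 0.001, 0.000, 0.001) == Category.UNCLEAR

    def test_any_missing_slope_is_insufficient(self):
        assert classify_change(np.nan, 0.1, 0.1, 0.2) == Category.INSUFFICIENT


class TestComposition:
    def test_partition_and_percentages(self):
        cats = np.zeros((10, 10), dtype=np.uint8)
        cats.ravel()[:50] = Category.POSITIVE
        cats.ravel()[50:80] = Category.NEGATIVE
        cats.ravel()[80:] = Category.UNCLEAR
        summary = composition(cats, np.ones((10, 10), bool), "PA1")
        assert summary.percent == {
            "improve": 50.0,
            "decline": 30.0,
            "unclear": 20.0,
            "insufficient": 0.0,
        }
        assert sum(summary.percent.values()) == pytest.approx(100.0)

    def test_single_category(self):
        cats = np.full((5, 5), Category.NEGATIVE, dtype=np.uint8)
        summary = composition(cats, np.ones((5, 5), bool), mode="before-after")
        assert summary.percent["harmed"] == 100.0

    def test_mask_restricts_to_pa(self):
        cats = np.full((4, 4), Category.POSITIVE, dtype=np.uint8)
        cats[:, 2:] = Category.NEGATIVE
        mask = np.zeros((4, 4), bool)
        mask[:, :2] = True
        assert composition(cats, mask).percent["improve"] == 100.0

    def test_dropped_pa_refuses(self):
        with pytest.raises(PADroppedError):
            composition(np.zeros((2, 2)), np.ones((2, 2), bool), sufficient=False)

    def test_percentages_always_sum_to_100(self):
        rng = np.random.default_rng(5)
        cats = rng.integers(0, 4, size=(20, 20)).astype(np.uint8)
        mask = rng.random((20, 20)) < 0.6
        summary = composition(cats, mask)
        assert sum(summary.percent.values()) == pytest.approx(100.0, abs=1e-9)


def summary_of(pa_id, improve, decline, unclear=None, insufficient=0.0,
               mode="after-only"):
    labels = ("improve", "decline") if mode == "after-only" else ("helped", "harmed")
    if unclear is None:
        unclear = 100.0 - improve - decline - insufficient
    return CompositionSummary(
        pa_id=pa_id,
        mode=mode,
        percent={
            labels[0]: improve,
            labels[1]: decline,
            "unclear": unclear,
            "insufficient": insufficient,
        },
    )


class TestComparePair:
    def test_better_and_substantial(self):
        c = compare_pair(summary_of("TR", 40, 30), summary_of("W", 20, 50))
        assert (c.verdict, c.substantial) == ("better", True)

    def test_worse_and_substantial(self):
        c = compare_pair(summary_of("TR", 20, 50), summary_of("W", 40, 30))
        assert (c.verdict, c.substantial) == ("worse", True)

    def test_ambiguous_when_both_greater(self):
        c = compare_pair(summary_of("TR", 40, 50, 10), summary_of("W", 20, 30, 50))
        assert c.verdict == "ambiguous"

    def test_substantial_threshold_is_inclusive_15(self):
        c = compare_pair(summary_of("TR", 40, 30), summary_of("W", 25, 31))
        assert c.substantial  # improvement differs by exactly 15
        c2 = compare_pair(summary_of("TR", 40, 30), summary_of("W", 26, 31))
        assert not c2.substantial

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.dirichlet([1, 1, 1]) * 100
            b = rng.dirichlet([1, 1, 1]) * 100
            s1 = summary_of("TR", a[0], a[1], a[2])
            s2 = summary_of("W", b[0], b[1], b[2])
            fwd = compare_pair(s1, s2)
            rev = compare_pair(s2, s1)
            flip = {"better": "worse", "worse": "better", "ambiguous": "ambiguous"}
            assert rev.verdict == flip[fwd.verdict]
            assert rev.substantial == fwd.substantial

    def test_mode_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            compare_pair(
                summary_of("TR", 40, 30),
                summary_of("W", 20, 50, mode="before-after"),
            )


class TestTernaryExport:
    def test_simple_normalization(self):
        df = ternary_export([summary_of("A", 50, 30, 20)])
        assert df.iloc[0][["improve", "decline", "unclear"]].tolist() == (
            pytest.approx([0.5, 0.3, 0.2])
        )

    def test_insufficient_share_renormalized(self):
        df = ternary_export([summary_of("A", 45, 27, 18, insufficient=10.0)])
        row = df.iloc[0]
        assert row["improve"] == pytest.approx(0.5)
        assert row["improve"] + row["decline"] + row["unclear"] == pytest.approx(1.0)

    def test_empty_list(self):
        assert ternary_export([]).empty
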