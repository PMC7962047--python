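"""Allele classification, mode estimation, consensus and PCR sizing."""

import numpy as np
import pytest

from repeatlens.alleles import (
    NO_INTERRUPTION,
    classify_reads,
    estimate_modes,
    interruption_consensus,
    pcr_size_to_units,
    pct_expanded,
    refined_modes,
    summarize,
)
from repeatlens.decompose import decompose
from repeatlens.patterns import expand_pattern, parse_pattern
from repeatlens.simulate import corrupt


def _calls(unit_counts):
    return [decompose("CTG" * int(u), read_id=str(i)) for i, u in enumerate(unit_counts)]


def _pattern_calls(pattern_text, n, copies, start_id=0):
    tract = expand_pattern(parse_pattern(pattern_text, n_value=n))
    return [decompose(tract, read_id=str(start_id + i)) for i in range(copies)]


class TestClassification:
    @pytest.mark.parametrize(
        "below, at_or_above, expected_pct",
        [
            (724, 9276, 93),
            (1670, 8329, 83),
            (627, 9372, 94),
            (750, 9250, 93),  # 92.5 rounds half away from zero
        ],
    )
    def test_percent_expanded_rounding(self, below, at_or_above, expected_pct):
        assert pct_expanded(below, at_or_above) == expected_pct

    def test_partition_at_fifty_units(self):
        calls = _calls([10, 49, 50, 51, 400])
        normal, expanded = classify_reads(calls)
        assert [c.total_units for c in normal] == [10, 49]
        assert [c.total_units for c in expanded] == [50, 51, 400]

    def test_all_normal_reads_give_zero_percent(self):
        normal, expanded = classify_reads(_calls([37] * 20))
        assert pct_expanded(len(normal), len(expanded)) == 0


class TestModes:
    def test_point_allele_is_exact(self):
        (m,) = estimate_modes([37] * 10)
        assert m.mode_units == 37

    def test_fewer_than_ten_counts_fall_back_to_empirical(self):
        (m,) = estimate_modes([5, 5, 5, 80])
        assert m.mode_units == 5

    def test_bimodal_mixture_recovered_within_five_units(self):
        rng = np.random.default_rng(0)
        comp = rng.random(4000) < 0.5
        draws = np.where(
            comp,
            rng.lognormal(np.log(173) + 0.05**2, 0.05, 4000),
            rng.lognormal(np.log(215) + 0.05**2, 0.05, 4000),
        )
        modes = estimate_modes(np.rint(draws))
        assert len(modes) == 2
        assert abs(modes[0].mode_units - 173) <= 5
        assert abs(modes[1].mode_units - 215) <= 5

    def test_unimodal_distribution_keeps_single_mode(self):
        rng = np.random.default_rng(1)
        draws = np.rint(rng.lognormal(np.log(447) + 0.25**2, 0.25, 2000))
        assert len(estimate_modes(draws)) == 1

    def test_refined_modes_on_two_point_sample(self):
        counts = [16] * 40 + [37] * 60
        assert [m.mode_units for m in refined_modes(counts)] == [16, 37]

    def test_refined_mode_tracks_lognormal_density_mode(self):
        rng = np.random.default_rng(2)
        draws = np.rint(rng.lognormal(np.log(1156) + 0.15**2, 0.15, 2000))
        (m,) = refined_modes(draws)
        assert abs(m.mode_units - 1156) <= 10


class TestInterruptionConsensus:
    def test_e3_reads_at_qv20_give_six_ccg(self):
        rng = np.random.default_rng(5)
        tract = expand_pattern(
            parse_pattern(
                "(CTG)n(CCGCTG)2(CTG)3(CCGCTG)2(CTG)5(CCGCTG)(CTG)7(CCGCTG)(CTG)11",
                n_value=140,
            )
        )
        calls = []
        for i in range(400):
            seq, _, _ = corrupt(tract, 0.99, rng)
            calls.append(decompose(seq, read_id=str(i)))
        text, dist = interruption_consensus(calls)
        assert text == "6x CCG"
        assert dist["CCG"].most_common(1)[0][0] == 6

    def test_pure_reads_report_no_interruption(self):
        rng = np.random.default_rng(6)
        tract = "CTG" * 447
        calls = [decompose(corrupt(tract, 0.99, rng)[0]) for _ in range(300)]
        assert interruption_consensus(calls)[0] == NO_INTERRUPTION

    def test_sixty_forty_split_reports_range(self):
        calls = _pattern_calls("(CTG)100(CCG)1(CTG)5(CCG)1(CTG)10", None, 60)
        calls += _pattern_calls(
            "(CTG)100(CCG)1(CTG)5(CCG)1(CTG)5(CCG)1(CTG)4", None, 40, start_id=60
        )
        assert interruption_consensus(calls)[0] == "2–3x CCG"

    def test_needs_at_least_one_call(self):
        with pytest.raises(ValueError):
            interruption_consensus([])


class TestSummarize:
    def test_error_free_two_normal_alleles(self):
        calls = _calls([16] * 40 + [37] * 60)
        summary = summarize("G", calls)
        assert summary.reads_at_or_above_threshold == 0
        assert summary.pct_expanded == 0
        assert summary.normal_modes == [16, 37]
        assert summary.expanded_modes == []
        assert summary.max_units is None
        assert summary.interruption_consensus == NO_INTERRUPTION

    def test_expanded_summary_fields(self):
        rng = np.random.default_rng(8)
        counts = np.rint(rng.lognormal(np.log(292) + 0.1**2, 0.1, 500)).astype(int)
        calls = _calls([5] * 50 + list(counts))
        summary = summarize("B2-like", calls)
        assert summary.reads_analyzed == 550
        assert summary.reads_below_threshold == 50
        assert summary.pct_expanded == 91  # 500/550 -> 90.9
        assert abs(summary.expanded_modes[0] - 292) <= 10
        assert summary.max_units == max(counts)


class TestPcrSizing:
    @pytest.mark.parametrize(
        "product, units_int",
        [(472, 37), (1150, 263), (364, 1)],
    )
    def test_unit_conversion(self, product, units_int):
        decimal, integer = pcr_size_to_units(product)
        assert integer == units_int
        assert decimal == pytest.approx((product - 361) / 3, abs=0.05)

    def test_product_within_flanks_raises(self):
        with pytest.raises(ValueError):
            pcr_size_to_units(361)
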