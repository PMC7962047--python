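"""Synthetic read generation: mosaicism sampling, amplicon layout, errors."""

import numpy as np
import pandas as pd
import pytest

from repeatlens.alleles import refined_modes
from repeatlens.decompose import decompose
from repeatlens.patterns import expand_pattern, parse_pattern
from repeatlens.prep import extract_tract
from repeatlens.simulate import (
    BARCODES,
    BUFFER,
    FLANK_TOTAL_BP,
    AlleleSpec,
    Mosaicism,
    ReadRecord,
    SampleSheet,
    SimulationError,
    build_amplicon,
    corrupt,
    example_samples,
    reference_flanks,
    revcomp,
    sample_unit_counts,
    write_run,
)


def _sheet(alleles=()):
    return SampleSheet("S1", "BC1018_Forward", BARCODES["BC1018_Forward"], alleles=alleles)


def _spec(pattern_text, mosaicism, n=None, fraction=1.0):
    return AlleleSpec(parse_pattern(pattern_text, n_value=n), mosaicism, fraction)


class TestSampleUnitCounts:
    def test_point_distribution(self):
        spec = _spec("(CTG)37", Mosaicism.point(37))
        assert list(sample_unit_counts(spec, 5, 0)) == [37] * 5

    def test_reproducible_for_fixed_seed(self):
        spec = _spec("(CTG)n", Mosaicism.lognormal(447, 0.25), n=440)
        a = sample_unit_counts(spec, 100, 7)
        b = sample_unit_counts(spec, 100, 7)
        assert np.array_equal(a, b)

    def test_lognormal_mode_recovery(self):
        # the distribution is parameterised by its density mode; the refined
        # mode estimator recovers it from 2000 draws
        spec = _spec("(CTG)n", Mosaicism.lognormal(447, 0.25), n=440)
        counts = sample_unit_counts(spec, 2000, 7)
        (mode,) = refined_modes(counts)
        assert abs(mode.mode_units - 447) <= 10

    def test_mixture_shows_both_components(self):
        spec = _spec(
            "(CTG)n",
            Mosaicism.mixture([(173, 0.05, 0.5), (215, 0.05, 0.5)]),
            n=170,
        )
        counts = sample_unit_counts(spec, 4000, 7)
        modes = [m.mode_units for m in refined_modes(counts)]
        assert len(modes) == 2
        assert abs(modes[0] - 173) <= 5 and abs(modes[1] - 215) <= 5

    def test_counts_never_drop_below_fixed_structure(self):
        spec = _spec("(CTG)n(CCGCTG)(CTG)11", Mosaicism.lognormal(20, 0.5), n=100)
        counts = sample_unit_counts(spec, 500, 0)
        assert counts.min() >= 14  # 13 fixed units + at least 1 in the long run

    def test_invalid_parameters_raise(self):
        with pytest.raises(SimulationError):
            Mosaicism.mixture([(100, 0.1, 0.6), (200, 0.1, 0.6)]).validate()


class TestBuildAmplicon:
    def test_layout_lengths(self):
        seq = build_amplicon(37, parse_pattern("(CTG)6(CCGCTG)13(CTG)5"), _sheet())
        # buffer+barcode on each end plus 361 bp of flanks plus the tract
        assert len(seq) == 2 * (len(BUFFER) + 16) + FLANK_TOTAL_BP + 111

    def test_tract_matches_expansion_when_count_equals_total(self):
        p = parse_pattern("(CTG)6(CCGCTG)13(CTG)5")
        seq = build_amplicon(37, p, _sheet())
        assert expand_pattern(p) in seq

    def test_rescaling_preserves_fixed_three_prime_block(self, fixture_map):
        fx = fixture_map["E3"]
        seq = build_amplicon(180, fx.pattern, _sheet())
        flank5, flank3 = reference_flanks()
        tract = seq.split(flank5)[1].split(flank3)[0]
        assert len(tract) == 3 * 180
        # the fixed 3' block (38 units after the long run) is untouched
        fixed_3p = expand_pattern(fx.pattern)[3 * 140 :]
        assert tract.endswith(fixed_3p)

    def test_unit_count_below_fixed_units_raises(self, fixture_map):
        with pytest.raises(SimulationError):
            build_amplicon(10, fixture_map["E3"].pattern, _sheet())


class TestCorrupt:
    def test_perfect_quality_is_identity(self):
        seq = "ACGT" * 200
        out, passes, rq = corrupt(seq, 1.0, 0)
        assert out == seq and rq == 1.0 and passes >= 1

    def test_error_count_matches_binomial_expectation(self):
        seq = "CTG" * 1000  # 3000 nt
        n, p = 3000, 0.01
        sigma = (n * p * (1 - p)) ** 0.5
        for seed in range(10):
            _, _, rq = corrupt(seq, 0.99, seed)
            events = round((1 - rq) * n)
            assert abs(events - n * p) <= 4 * sigma

    def test_quality_one_percent_is_qv20(self):
        # QV = -10 log10(error): QV20 <-> accuracy 0.99
        assert round(-10 * np.log10(1 - 0.99)) == 20


class TestWriteRun:
    def _samples(self):
        return [
            SampleSheet(
                "A",
                "BC1018_Forward",
                BARCODES["BC1018_Forward"],
                alleles=(_spec("(CTG)30", Mosaicism.point(30)),),
            ),
            SampleSheet(
                "B",
                "BC1019_Forward",
                BARCODES["BC1019_Forward"],
                alleles=(_spec("(CTG)80", Mosaicism.point(80)),),
            ),
        ]

    def test_record_and_truth_counts(self, tmp_path):
        run = write_run(
            self._samples(), 100, 5, tmp_path / "r.fastq", tmp_path / "t.tsv"
        )
        assert run.n_reads == 200
        assert sum(1 for line in open(run.fastq_path) if line.startswith("@")) >= 200
        assert len(pd.read_csv(run.truth_path, sep="\t")) == 200

    def test_byte_identical_for_fixed_seed(self, tmp_path):
        for d in ("x", "y"):
            (tmp_path / d).mkdir()
            write_run(
                self._samples(), 40, 9, tmp_path / d / "r.fastq", tmp_path / d / "t.tsv"
            )
        assert (tmp_path / "x/r.fastq").read_bytes() == (tmp_path / "y/r.fastq").read_bytes()
        assert (tmp_path / "x/t.tsv").read_bytes() == (tmp_path / "y/t.tsv").read_bytes()

    def test_truth_recoverable_from_error_free_reads(self, tmp_path):
        samples = example_samples()
        run = write_run(
            samples, 30, 2, tmp_path / "r.fastq", tmp_path / "t.tsv", target_quality=1.0
        )
        from repeatlens.io import read_fastq

        truth = pd.read_csv(run.truth_path, sep="\t").set_index("read_id")
        sheets = {s.sample_id: s for s in samples}
        for read in read_fastq(run.fastq_path):
            sample = truth.loc[read.read_id, "sample"]
            tract = extract_tract(read, sheets[sample]).tract
            call = decompose(tract)
            assert call.total_units == truth.loc[read.read_id, "true_unit_count"]
            assert call.noise_units == 0

    def test_mixture_fractions_within_two_percent(self, tmp_path):
        samples = [
            SampleSheet(
                "M",
                "BC1018_Forward",
                BARCODES["BC1018_Forward"],
                alleles=(
                    _spec("(CTG)5", Mosaicism.point(5), fraction=0.3),
                    _spec("(CTG)60", Mosaicism.point(60), fraction=0.7),
                ),
            )
        ]
        run = write_run(
            samples, 10_000, 4, tmp_path / "r.fastq", tmp_path / "t.tsv", target_quality=1.0
        )
        truth = pd.read_csv(run.truth_path, sep="\t")
        share = (truth["true_unit_count"] == 60).mean()
        assert abs(share - 0.7) <= 0.02


def test_revcomp_involution():
    seq = "GGTAGTCACGTGCTCACTGTG"
    assert revcomp(revcomp(seq)) == seq
    assert revcomp("ACGT") == "ACGT"
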