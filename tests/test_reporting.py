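"""Figures, pipeline orchestration and output determinism."""

import numpy as np
import pandas as pd
import pytest
import yaml

from repeatlens.decompose import decompose
from repeatlens.io import read_table
from repeatlens.patterns import expand_pattern, parse_pattern
from repeatlens.pipeline import PipelineError, load_config, run_pipeline
from repeatlens.plots import MOTIF_COLORS, distribution_plot, waterfall, waterfall_segments


def _demo_config(tmp_path, out_name="out", reads=60, target_quality=1.0, seed=5):
    cfg = {
        "out_dir": str(tmp_path / out_name),
        "seed": seed,
        "simulate": {"reads_per_sample": reads, "target_quality": target_quality},
        "samples": [
            {
                "sample_id": "E3-like",
                "barcode_name": "BC1020_Forward",
                "alleles": [
                    {
                        "pattern": "(CTG)31",
                        "fraction": 0.1,
                        "mosaicism": {"family": "point", "location": 31},
                    },
                    {
                        "pattern": "(CTG)n(CCGCTG)2(CTG)3(CCGCTG)2(CTG)5(CCGCTG)(CTG)7(CCGCTG)(CTG)11",
                        "n": 140,
                        "fraction": 0.9,
                        "mosaicism": {
                            "family": "mixture",
                            "components": [
                                {"mode": 173, "sigma": 0.05, "weight": 0.5},
                                {"mode": 215, "sigma": 0.05, "weight": 0.5},
                            ],
                        },
                    },
                ],
            },
            {
                "sample_id": "pure",
                "barcode_name": "BC1018_Forward",
                "alleles": [
                    {
                        "pattern": "(CTG)n",
                        "n": 100,
                        "fraction": 1.0,
                        "mosaicism": {"family": "lognormal", "mode": 100, "sigma": 0.05},
                    }
                ],
            },
        ],
    }
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestWaterfall:
    def test_segments_sorted_and_colored_by_motif(self, fixture_map):
        tract = expand_pattern(fixture_map["E3"].pattern)
        calls = [decompose(tract, read_id=f"r{i}") for i in range(20)]
        calls.append(decompose("CTG" * 60, read_id="short"))
        rows = waterfall_segments(calls)
        assert rows[0][0] == "short"  # ascending by total units
        for read_id, segments in rows[1:]:
            ccg = [s for s in segments if s[2] == "CCG"]
            assert len(ccg) == 6
            total = 3 * fixture_map["E3"].pattern.total_units
            assert all(x >= 2 * total / 3 for x, _, _ in ccg)  # 3' third

    def test_single_pure_read_is_one_blue_bar(self):
        rows = waterfall_segments([decompose("CTG" * 40, read_id="r")])
        assert rows == [("r", [(0, 120, "CTG")])]
        assert MOTIF_COLORS["CTG"] == "#1f77b4"

    def test_waterfall_writes_figure(self, tmp_path):
        calls = [decompose("CTG" * (30 + i), read_id=str(i)) for i in range(5)]
        out = tmp_path / "wf.png"
        waterfall(calls, out)
        assert out.stat().st_size > 0


class TestDistributionPlot:
    def test_axis_label_names_ctg_repeats(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = np.rint(rng.normal(100, 5, 200))
        fig = distribution_plot(counts, tmp_path / "d.png")
        assert fig.axes[0].get_xlabel() == "number of CTG repeats"

    def test_needs_ten_counts(self):
        with pytest.raises(ValueError):
            distribution_plot([1, 2, 3])


class TestRunPipeline:
    def test_error_free_run_recovers_truth_exactly(self, tmp_path):
        cfg = load_config(_demo_config(tmp_path))
        out = run_pipeline(cfg)
        calls = read_table(out / "calls.tsv").set_index("read_id")
        truth = pd.read_csv(out / "truth.tsv", sep="\t").set_index("read_id")
        assert len(calls) == len(truth)
        for read_id, row in calls.iterrows():
            assert row["total_units"] == truth.loc[read_id, "true_unit_count"]
            assert row["sample"] == truth.loc[read_id, "sample"]
        summary = read_table(out / "summary.tsv").set_index("sample")
        assert summary.loc["E3-like", "interruption_consensus"] == "6x CCG"
        assert summary.loc["pure", "interruption_consensus"] == "No obvious interruption"
        tracts = (out / "tracts_pure.fastq").read_text().splitlines()
        assert len(tracts) == 4 * int(summary.loc["pure", "reads_analyzed"])

    def test_rerun_with_same_seed_is_identical(self, tmp_path):
        a = run_pipeline(load_config(_demo_config(tmp_path, "out_a", reads=40)))
        b = run_pipeline(load_config(_demo_config(tmp_path, "out_b", reads=40)))
        for name in ("summary.tsv", "calls.tsv", "prep_report.tsv"):
            # first line is the provenance header, whose config hash covers
            # the differing output paths; the content below must be identical
            body_a = (a / name).read_text().splitlines()[1:]
            body_b = (b / name).read_text().splitlines()[1:]
            assert body_a == body_b

    def test_missing_input_fails_before_compute(self, tmp_path):
        cfg_path = _demo_config(tmp_path)
        raw = yaml.safe_load(cfg_path.read_text())
        del raw["simulate"]
        raw["input_fastq"] = str(tmp_path / "absent.fastq")
        cfg_path.write_text(yaml.safe_dump(raw))
        with pytest.raises(PipelineError):
            run_pipeline(load_config(cfg_path))

    def test_manifest_records_seed_and_config(self, tmp_path):
        out = run_pipeline(load_config(_demo_config(tmp_path, "out_m", reads=20)))
        manifest = yaml.safe_load((out / "manifest.yaml").read_text())
        assert manifest["seed"] == 5
        assert manifest["config_hash"]
        header = (out / "summary.tsv").read_text().splitlines()[0]
        assert header.startswith("# repeatlens") and manifest["config_hash"] in header
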