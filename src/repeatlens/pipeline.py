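"""Run orchestration: simulate -> prep -> decompose -> call -> report.

A run is driven by one YAML configuration naming the input FASTQ (or a
simulation block that generates it), the sample sheet, thresholds and the
output directory.  Outputs are tab-separated tables (per-read calls, prep
report, per-sample summary), optional figures, a machine-readable manifest
(version, seed, config echo and hash) and a run log.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alleles import EXPANSION_THRESHOLD, summarize
from .decompose import DecomposerConfig, decompose
from .io import config_hash, read_fastq, write_table, write_tract_fastq
from .patterns import parse_pattern
from .plots import distribution_plot, waterfall
from .prep import PrepConfig, cap_reads, demultiplex, extract_tract, filter_reads
from .simulate import (
    BARCODES,
    AlleleSpec,
    Mosaicism,
    QualityModel,
    SampleSheet,
    write_run,
)

log = logging.getLogger("repeatlens")


class PipelineError(RuntimeError):
    pass


@dataclass
class SimulateBlock:
    reads_per_sample: int = 2000
    target_quality: float | None = None
    quality: QualityModel = field(default_factory=QualityModel)


@dataclass
class RunConfig:
    out_dir: Path
    samples: list[SampleSheet]
    input_fastq: Path | None = None
    simulate: SimulateBlock | None = None
    prep: PrepConfig = field(default_factory=PrepConfig)
    decomposer: DecomposerConfig = field(default_factory=DecomposerConfig)
    expansion_threshold: int = EXPANSION_THRESHOLD
    make_plots: bool = True
    seed: int = 0
    raw: dict = field(default_factory=dict)  # config echo for the manifest


def _mosaicism_from_dict(d: dict) -> Mosaicism:
    family = d.get("family", "point")
    if family == "point":
        return Mosaicism.point(int(d["location"]))
    if family == "lognormal":
        return Mosaicism.lognormal(float(d["mode"]), float(d["sigma"]))
    if family == "mixture":
        return Mosaicism.mixture(
            [(c["mode"], c["sigma"], c["weight"]) for c in d["components"]]
        )
    raise PipelineError(f"unknown mosaicism family {family!r}")


def _sheet_from_dict(d: dict) -> SampleSheet:
    alleles = []
    for a in d.get("alleles", []):
        pattern = parse_pattern(a["pattern"], n_value=a.get("n"), label=a.get("name", ""))
        alleles.append(
            AlleleSpec(
                base_pattern=pattern,
                mosaicism=_mosaicism_from_dict(a.get("mosaicism", {"family": "point", "location": pattern.total_units})),
                fraction=float(a.get("fraction", 1.0)),
                name=a.get("name", ""),
            )
        )
    barcode = d.get("barcode") or BARCODES[d["barcode_name"]]
    return SampleSheet(
        sample_id=str(d["sample_id"]),
        barcode_name=d.get("barcode_name", ""),
        barcode=barcode,
        alleles=tuple(alleles),
    )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    samples = [_sheet_from_dict(d) for d in raw.get("samples", [])]
    if not samples:
        raise PipelineError("configuration defines no samples")
    sim = None
    if "simulate" in raw:
        s = raw["simulate"] or {}
        sim = SimulateBlock(
            reads_per_sample=int(s.get("reads_per_sample", 2000)),
            target_quality=s.get("target_quality"),
            quality=QualityModel(**s.get("quality", {})),
        )
    prep = PrepConfig(**raw.get("prep", {}))
    dec_raw = dict(raw.get("decomposer", {}))
    if "motif_alphabet" in dec_raw:
        dec_raw["motif_alphabet"] = tuple(dec_raw["motif_alphabet"])
    decomposer = DecomposerConfig(**dec_raw)
    input_fastq = raw.get("input_fastq")
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        samples=samples,
        input_fastq=Path(input_fastq) if input_fastq else None,
        simulate=sim,
        prep=prep,
        decomposer=decomposer,
        expansion_threshold=int(raw.get("expansion_threshold", EXPANSION_THRESHOLD)),
        make_plots=bool(raw.get("make_plots", True)),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Raises PipelineError naming the failing stage.  Fixed config and seed
    give identical tables across reruns.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    cfg_hash = config_hash(config.raw) if config.raw else config_hash({"seed": config.seed})
    log.info("repeatlens %s starting; seed=%d config=%s", __version__, config.seed, cfg_hash)

    stage = "configure"
    try:
        fastq = config.input_fastq
        if fastq is None:
            if config.simulate is None:
                raise PipelineError("no input FASTQ and no simulate block")
            stage = "simulate"
            fastq = out / "simulated.fastq"
            write_run(
                config.samples,
                config.simulate.reads_per_sample,
                seed=config.seed,
                out_fastq=fastq,
                out_truth=out / "truth.tsv",
                target_quality=config.simulate.target_quality,
                quality_model=config.simulate.quality,
            )
            log.info("simulated %d samples into %s", len(config.samples), fastq)
        elif not fastq.exists():
            raise PipelineError(f"input FASTQ {fastq} does not exist")

        stage = "prep"
        reads = read_fastq(fastq)
        passing = filter_reads(reads, config.prep)
        assigned, unassigned = demultiplex(passing, config.samples, config.prep)
        log.info(
            "%d reads; %d pass filter; %d unassigned", len(reads), len(passing), len(unassigned)
        )

        from .prep import PrepReport

        report = PrepReport(
            total_reads=len(reads),
            reads_passing_filter=len(passing),
            unassigned=len(unassigned),
        )

        stage = "decompose"
        summaries = []
        all_calls = []
        for sheet in config.samples:
            sample_reads = assigned[sheet.sample_id]
            results = [extract_tract(r, sheet, config.prep) for r in sample_reads]
            on_target = [t for t in results if t.on_target]
            full = [t for t in results if t.full_length]
            report.add_sample(sheet.sample_id, len(sample_reads), len(on_target), len(full))
            analyzed = cap_reads(full, config.prep.analysis_cap, config.prep.subsample_seed)
            write_tract_fastq(
                out / f"tracts_{sheet.sample_id}.fastq",
                ((t.read_id, t.tract) for t in analyzed),
            )
            calls = [decompose(t.tract, config.decomposer, read_id=t.read_id) for t in analyzed]
            stage = "call"
            per_sample = report.per_sample[sheet.sample_id]
            summary = summarize(
                sheet.sample_id,
                calls,
                threshold=config.expansion_threshold,
                total_ccs_reads=len(sample_reads),
                pct_on_target=per_sample["pct_on_target"],
                pct_full_length=per_sample["pct_full_length"],
            )
            summaries.append(summary)
            for c in calls:
                all_calls.append(
                    {
                        "read_id": c.read_id,
                        "sample": sheet.sample_id,
                        "total_units": c.total_units,
                        "noise_units": c.noise_units,
                        "frame_offset": c.frame_offset,
                        "ccg_units": c.inventory.count("CCG"),
                        "cag_units": c.inventory.count("CAG"),
                        "ctc_units": c.inventory.count("CTC"),
                        "allele_class": "expanded"
                        if c.total_units >= config.expansion_threshold
                        else "normal",
                    }
                )
            if config.make_plots and calls:
                stage = "report"
                waterfall(calls, out / f"waterfall_{sheet.sample_id}.png", title=sheet.sample_id)
                counts = [c.total_units for c in calls]
                if len(counts) >= 10:
                    distribution_plot(
                        counts, out / f"distribution_{sheet.sample_id}.png", title=sheet.sample_id
                    )
            stage = "decompose"

        stage = "report"
        write_table(report.to_frame(), out / "prep_report.tsv", cfg_hash)
        write_table(pd.DataFrame(all_calls), out / "calls.tsv", cfg_hash)
        write_table(pd.DataFrame([s.to_row() for s in summaries]), out / "summary.tsv", cfg_hash)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": cfg_hash,
            "config": config.raw,
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        log.info("run complete: %s", out)
        return out
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
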