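"""Read preprocessing: filtering, demultiplexing and tract extraction.

Functional stand-in for the vendor consensus pipeline on a single-locus
amplicon: consensus reads are filtered on pass count and mean accuracy,
assigned to samples by edit distance over the buffer+barcode prefix (both
orientations), and the repeat tract is cut out by anchoring the 20-nt flank
segments adjacent to the tract.  Alignment to a reference genome is
unnecessary in amplicon context — flank anchoring is equivalent and
dependency-free.

Anchors are matched with a Hamming mismatch budget (no indels): an indel
inside an anchor demotes the read to not-full-length rather than shifting
the tract boundary.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .simulate import ReadRecord, SampleSheet, reference_flanks, revcomp

ANCHOR_LEN = 20


class PrepConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PrepConfig:
    min_passes: int = 3
    min_read_quality: float = 0.99  # QV20: 1 - 10^(-20/10)
    max_barcode_edits: int = 2
    anchor_max_mismatches: int = 3
    analysis_cap: int = 10_000
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if self.analysis_cap < 1:
            raise PrepConfigError("analysis_cap must be >= 1")
        if min(self.min_passes, self.max_barcode_edits, self.anchor_max_mismatches) < 0:
            raise PrepConfigError("thresholds must be >= 0")


@dataclass
class TractResult:
    read_id: str
    tract: str | None
    on_target: bool
    full_length: bool
    orientation: str = "+"


@dataclass
class PrepReport:
    """Run-level accounting in the shape of a per-sample summary table."""

    total_reads: int = 0
    reads_passing_filter: int = 0
    unassigned: int = 0
    per_sample: dict[str, dict] = field(default_factory=dict)

    def add_sample(self, sample_id: str, demuxed: int, on_target: int, full_length: int) -> None:
        pct_on = 100.0 * on_target / demuxed if demuxed else 0.0
        pct_full = 100.0 * full_length / on_target if on_target else 0.0
        self.per_sample[sample_id] = {
            "demuxed_reads": demuxed,
            "on_target_reads": on_target,
            "full_length_reads": full_length,
            "pct_on_target": pct_on,
            "pct_full_length": pct_full,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": k, **v} for k, v in sorted(self.per_sample.items())]
        return pd.DataFrame(rows)


def filter_reads(reads: list[ReadRecord], config: PrepConfig | None = None) -> list[ReadRecord]:
    """Retain reads with pass_count >= min_passes and read_quality >= minimum.

    Reads missing either metadatum are rejected (there is nothing to test).
    """
    config = config or PrepConfig()
    kept = []
    for r in reads:
        if r.pass_count is None or r.read_quality is None:
            continue
        if r.pass_count >= config.min_passes and r.read_quality >= config.min_read_quality:
            kept.append(r)
    return kept


def demultiplex(
    reads: list[ReadRecord],
    sheets: list[SampleSheet],
    config: PrepConfig | None = None,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to samples by minimal-edit buffer+barcode prefix match.

    Both orientations are checked; a read whose minimal distance exceeds the
    edit budget, or is attained by more than one sample, goes to the
    unassigned bin.
    """
    config = config or PrepConfig()
    barcodes = [s.barcode for s in sheets]
    if len(set(barcodes)) != len(barcodes):
        raise PrepConfigError("duplicate barcodes across sample sheets")

    assigned: dict[str, list[ReadRecord]] = {s.sample_id: [] for s in sheets}
    unassigned: list[ReadRecord] = []
    for read in reads:
        rc = revcomp(read.sequence)
        best: list[tuple[int, str]] = []
        for sheet in sheets:
            window = len(sheet.prefix) + config.max_barcode_edits + 2
            d = min(
                edlib.align(sheet.prefix, read.sequence[:window], mode="SHW", task="distance")["editDistance"],
                edlib.align(sheet.prefix, rc[:window], mode="SHW", task="distance")["editDistance"],
            )
            best.append((d, sheet.sample_id))
        best.sort()
        d0, sample = best[0]
        ambiguous = len(best) > 1 and best[1][0] == d0
        if d0 <= config.max_barcode_edits and not ambiguous:
            assigned[sample].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


def _find_anchor(seq_arr: np.ndarray, anchor: np.ndarray, max_mismatches: int, last: bool) -> int | None:
    if len(seq_arr) < len(anchor):
        return None
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, len(anchor))
    mismatches = (windows != anchor).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    if len(hits) == 0:
        return None
    return int(hits[-1] if last else hits[0])


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def extract_tract(
    read: ReadRecord,
    sheet: SampleSheet,
    config: PrepConfig | None = None,
) -> TractResult:
    """Locate the flank anchors and cut out the repeat tract.

    The anchors are the 20 nt of flank immediately 5' and 3' of the tract.
    on_target means at least one anchor was found (either orientation);
    full_length means both were, in which case the tract is the sequence
    strictly between the inner flank boundaries, reported on the strand
    where the repeat reads as CTG units.
    """
    config = config or PrepConfig()
    flank5, flank3 = reference_flanks()
    left = _seq_to_arr(flank5[-ANCHOR_LEN:])
    right = _seq_to_arr(flank3[:ANCHOR_LEN])

    best: TractResult | None = None
    for orientation in ("+", "-"):
        seq = read.sequence if orientation == "+" else revcomp(read.sequence)
        arr = _seq_to_arr(seq)
        i = _find_anchor(arr, left, config.anchor_max_mismatches, last=False)
        j = _find_anchor(arr, right, config.anchor_max_mismatches, last=True)
        found = (i is not None) + (j is not None)
        full = i is not None and j is not None and i + ANCHOR_LEN <= j
        tract = seq[i + ANCHOR_LEN : j] if full else None
        result = TractResult(read.read_id, tract, found > 0, bool(full), orientation)
        if best is None or (result.full_length, result.on_target) > (
            best.full_length,
            best.on_target,
        ):
            best = result
        if best.full_length:
            break
    assert best is not None
    return best


def cap_reads(reads: list, analysis_cap: int, subsample_seed: int = 0) -> list:
    """Seeded uniform subsample to the analysis cap, preserving input order."""
    if len(reads) <= analysis_cap:
        return list(reads)
    rng = np.random.default_rng(subsample_seed)
    idx = np.sort(rng.choice(len(reads), size=analysis_cap, replace=False))
    return [reads[i] for i in idx]
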