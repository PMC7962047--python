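"""Synthetic barcoded amplicon consensus reads with known truth.

Emulates a multiplexed single-locus amplicon run on a long-read instrument:
each sample carries a normal and an expanded allele, the expanded allele's
per-molecule repeat length is drawn from a mosaicism distribution (point,
discretised lognormal parameterised by its mode, or a two-component
mixture), and reads are corrupted by a quality-parameterised error process
(QV20 corresponds to a per-base error rate of 1e-2, split
substitution:insertion:deletion = 2:1:1).

The amplicon layout mirrors a barcoded PCR across the repeat:

    buffer + barcode + [5' flank ...] + repeat tract + [... 3' flank]
        + revcomp(buffer + barcode + reverse primer)

where the two flanks total 361 bp including the two 20-nt primer sites, so
that repeat units = (product length - 361) / 3 holds for the unbarcoded
product.  The flank interiors are synthetic random-but-fixed sequence (the
real flanking sequence is not bundled); everything downstream anchors on
them through the same configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .patterns import CTG, RepeatPattern, canonical_string, parse_pattern

# Primer pair flanking the repeat (ST300F / ST300R).
FORWARD_PRIMER = "GAACTGTCTTCGACTCCGGG"
REVERSE_PRIMER = "GCACTTTGCGAACCAACGAT"
#: 5-nt buffer preceding every barcode on both amplicon ends.
BUFFER = "GGTAG"
#: Total 5' + 3' flanking sequence around the tract, primer sites included.
FLANK_TOTAL_BP = 361

#: 16-nt forward barcodes used for multiplexing (name -> sequence).
BARCODES = {
    "BC1012_Forward": "ACACTAGATCGCGTGT",
    "BC1013_Forward": "CTCTCGCATACGCGAG",
    "BC1014_Forward": "CTCACTACGCGCGCGT",
    "BC1015_Forward": "CGCATGACACGTGTGT",
    "BC1016_Forward": "CATAGAGAGATAGTAT",
    "BC1017_Forward": "CACACGCGCGCTATAT",
    "BC1018_Forward": "TCACGTGCTCACTGTG",
    "BC1019_Forward": "ACACACTCTATCAGAT",
    "BC1020_Forward": "CACGACACGACGATGT",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.array(list("ACGT"))
_FLANK_SEED = 104729  # arbitrary fixed seed: every run shares one synthetic locus


class SimulationError(ValueError):
    """Raised for inconsistent simulation parameters."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


@lru_cache(maxsize=1)
def reference_flanks() -> tuple[str, str]:
    """Fixed synthetic 5'/3' flanks totalling FLANK_TOTAL_BP.

    The 5' flank starts with the forward primer site; the 3' flank ends with
    the reverse complement of the reverse primer site.
    """
    rng = np.random.default_rng(_FLANK_SEED)
    inner5 = _random_bases(rng, 161)
    inner3 = _random_bases(rng, 160)
    flank5 = FORWARD_PRIMER + inner5
    flank3 = inner3 + revcomp(REVERSE_PRIMER)
    assert len(flank5) + len(flank3) == FLANK_TOTAL_BP
    return flank5, flank3


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Mosaicism model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mosaicism:
    """Distribution of per-molecule total repeat-unit counts.

    ``lognormal`` is parameterised by the *mode* of the continuous density
    (mu = ln(mode) + sigma^2) so that configured and recovered modes are
    directly comparable.  ``mixture`` holds (mode, sigma, weight) components.
    """

    family: str  # "point" | "lognormal" | "mixture"
    location: float = 0.0
    sigma: float = 0.0
    components: tuple[tuple[float, float, float], ...] = ()

    @classmethod
    def point(cls, units: int) -> "Mosaicism":
        return cls("point", location=float(units))

    @classmethod
    def lognormal(cls, mode: float, sigma: float) -> "Mosaicism":
        return cls("lognormal", location=float(mode), sigma=float(sigma))

    @classmethod
    def mixture(cls, components) -> "Mosaicism":
        comps = tuple((float(m), float(s), float(w)) for m, s, w in components)
        return cls("mixture", components=comps)

    def validate(self) -> None:
        if self.family == "point":
            if self.location < 1:
                raise SimulationError("point location must be >= 1 unit")
        elif self.family == "lognormal":
            if self.location < 1 or self.sigma <= 0:
                raise SimulationError("lognormal needs mode >= 1 and sigma > 0")
        elif self.family == "mixture":
            if not self.components:
                raise SimulationError("mixture needs >= 1 component")
            w = sum(c[2] for c in self.components)
            if not math.isclose(w, 1.0, abs_tol=1e-6):
                raise SimulationError("mixture weights must sum to 1")
        else:
            raise SimulationError(f"unknown mosaicism family {self.family!r}")


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a sample: base structure, mosaicism and molecular share."""

    base_pattern: RepeatPattern
    mosaicism: Mosaicism
    fraction: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise SimulationError("allele fraction must lie in (0, 1]")
        self.mosaicism.validate()


@dataclass
class SampleSheet:
    """Barcode/primer bookkeeping for one multiplexed sample."""

    sample_id: str
    barcode_name: str
    barcode: str
    buffer: str = BUFFER
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    alleles: tuple[AlleleSpec, ...] = ()

    def __post_init__(self) -> None:
        if len(self.barcode) != 16:
            raise SimulationError(f"barcode must be 16 nt, got {len(self.barcode)}")
        if self.alleles:
            total = sum(a.fraction for a in self.alleles)
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise SimulationError("allele fractions must sum to 1")

    @property
    def prefix(self) -> str:
        return self.buffer + self.barcode


@dataclass
class ReadRecord:
    """One consensus read; truth fields are set only for simulated reads."""

    read_id: str
    sequence: str
    pass_count: int | None = None
    read_quality: float | None = None
    true_sample: str | None = None
    true_allele: str | None = None
    true_unit_count: int | None = None


# ---------------------------------------------------------------------------
# Sampling and read construction
# ---------------------------------------------------------------------------


def _fixed_units(pattern: RepeatPattern) -> tuple[int, int]:
    """(index of the rescalable CTG run, units held fixed by everything else).

    The rescalable run is the largest CTG run (ties toward 5'); interruption
    runs and the remaining CTG blocks are held intact during rescaling.
    """
    ctg_runs = [(i, r.count) for i, r in enumerate(pattern.runs) if r.motif == CTG]
    if not ctg_runs:
        raise SimulationError("pattern has no CTG run to rescale")
    idx = max(ctg_runs, key=lambda t: t[1])[0]
    fixed = pattern.total_units - pattern.runs[idx].count
    return idx, fixed


def rescale_pattern(pattern: RepeatPattern, unit_count: int) -> RepeatPattern:
    """Pattern with its main CTG run resized so totals reach ``unit_count``."""
    idx, fixed = _fixed_units(pattern)
    new_count = unit_count - fixed
    if new_count < 1:
        raise SimulationError(
            f"unit count {unit_count} cannot hold the pattern's {fixed} fixed units"
        )
    runs = list(pattern.runs)
    runs[idx] = type(runs[idx])(CTG, new_count)
    return RepeatPattern(tuple(runs), label=pattern.label)


def sample_unit_counts(spec: AlleleSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` per-molecule total unit counts for an allele (ints >= 1)."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = _as_rng(seed)
    m = spec.mosaicism
    if m.family == "point":
        draws = np.full(n, m.location)
    elif m.family == "lognormal":
        mu = math.log(m.location) + m.sigma**2
        draws = rng.lognormal(mu, m.sigma, size=n)
    else:  # mixture
        weights = [c[2] for c in m.components]
        comp = rng.choice(len(m.components), size=n, p=weights)
        draws = np.empty(n)
        for k, (mode, sigma, _) in enumerate(m.components):
            mask = comp == k
            mu = math.log(mode) + sigma**2
            draws[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    counts = np.rint(draws).astype(int)
    _, fixed = _fixed_units(spec.base_pattern)
    return np.clip(counts, max(1, fixed + 1), None)


def build_amplicon(
    unit_count: int,
    base_pattern: RepeatPattern,
    sheet: SampleSheet,
    flank_total_bp: int = FLANK_TOTAL_BP,
) -> str:
    """Forward-strand amplicon sequence for one molecule."""
    flank5, flank3 = reference_flanks()
    if len(flank5) + len(flank3) != flank_total_bp:
        raise SimulationError("flank_total_bp does not match the configured flanks")
    tract = "".join(
        r.motif * r.count for r in rescale_pattern(base_pattern, unit_count).runs
    )
    tail = revcomp(sheet.buffer + sheet.barcode)
    return sheet.prefix + flank5 + tract + flank3 + tail


def corrupt(sequence: str, target_quality: float, seed) -> tuple[str, int, float]:
    """Apply the error process; returns (sequence, pass_count, read_quality).

    Each base errs with probability 1 - target_quality; error types are
    substitution/insertion/deletion at 2:1:1.  read_quality is the realised
    identity estimate (1 - events/length); pass_count is a shifted Poisson
    (mean 8, minimum 1).
    """
    if not 0 < target_quality <= 1:
        raise SimulationError("target_quality must lie in (0, 1]")
    rng = _as_rng(seed)
    n = len(sequence)
    rate = 1.0 - target_quality
    if rate == 0.0:
        out = sequence
        events = 0
    else:
        idxs = np.nonzero(rng.random(n) < rate)[0]
        kinds = rng.choice(3, size=len(idxs), p=[0.5, 0.25, 0.25])
        picks = rng.integers(0, 3, size=len(idxs))  # substitution alternatives
        ins = rng.choice(_BASES, size=len(idxs)) if len(idxs) else np.array([])
        parts: list[str] = []
        prev = 0
        for i, kind, pick, ib in zip(idxs, kinds, picks, ins):
            parts.append(sequence[prev:i])
            base = sequence[i]
            if kind == 0:  # substitution
                alternatives = [b for b in "ACGT" if b != base]
                parts.append(alternatives[pick])
            elif kind == 1:  # insertion after the base
                parts.append(base + str(ib))
            # kind == 2: deletion, emit nothing
            prev = i + 1
        parts.append(sequence[prev:])
        out = "".join(parts)
        events = len(idxs)
    read_quality = 1.0 - events / n if n else 1.0
    pass_count = int(1 + rng.poisson(7))
    return out, pass_count, max(0.0, read_quality)


@dataclass(frozen=True)
class QualityModel:
    """Per-read target accuracy drawn on a Phred scale (QV ~ N(mean, sd))."""

    mean_qv: float = 27.0
    sd_qv: float = 3.0
    min_qv: float = 12.0
    max_qv: float = 45.0

    def draw(self, rng: np.random.Generator) -> float:
        qv = float(np.clip(rng.normal(self.mean_qv, self.sd_qv), self.min_qv, self.max_qv))
        return 1.0 - 10 ** (-qv / 10.0)


def _phred_char(read_quality: float) -> str:
    err = max(1.0 - read_quality, 1e-6)
    q = min(60, int(round(-10 * math.log10(err))))
    return chr(33 + q)


@dataclass
class SimulatedRun:
    fastq_path: Path
    truth_path: Path
    n_reads: int


def write_run(
    samples: list[SampleSheet],
    reads_per_sample: int,
    seed: int,
    out_fastq: str | Path,
    out_truth: str | Path,
    target_quality: float | None = None,
    quality_model: QualityModel | None = None,
) -> SimulatedRun:
    """Write a multiplexed FASTQ plus a truth table for ``samples``.

    The FASTQ description carries ``np=<passes> rq=<read quality>``; per-base
    quality characters are constant and consistent with rq.  About half the
    reads are emitted reverse-complemented.  Fixed (samples, seed) give
    byte-identical outputs.
    """
    rng = _as_rng(seed)
    quality_model = quality_model or QualityModel()
    out_fastq = Path(out_fastq)
    out_truth = Path(out_truth)
    truth_rows = []
    n_total = 0
    with open(out_fastq, "w") as fq:
        for sheet in samples:
            if not sheet.alleles:
                raise SimulationError(f"sample {sheet.sample_id} has no alleles")
            fractions = [a.fraction for a in sheet.alleles]
            for i in range(reads_per_sample):
                allele = sheet.alleles[int(rng.choice(len(sheet.alleles), p=fractions))]
                units = int(sample_unit_counts(allele, 1, rng)[0])
                amplicon = build_amplicon(units, allele.base_pattern, sheet)
                tq = target_quality if target_quality is not None else quality_model.draw(rng)
                seq, passes, rq = corrupt(amplicon, tq, rng)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                read_id = f"{sheet.sample_id}_{i:06d}"
                fq.write(f"@{read_id} np={passes} rq={rq:.4f}\n{seq}\n+\n")
                fq.write(_phred_char(rq) * len(seq) + "\n")
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample": sheet.sample_id,
                        "allele": allele.name or canonical_string(allele.base_pattern),
                        "true_unit_count": units,
                        "true_pattern": canonical_string(
                            rescale_pattern(allele.base_pattern, units)
                        ),
                    }
                )
                n_total += 1
    truth = pd.DataFrame(truth_rows)
    if truth["read_id"].duplicated().any():
        raise SimulationError("duplicate read ids in truth table")
    truth.to_csv(out_truth, sep="\t", index=False)
    return SimulatedRun(out_fastq, out_truth, n_total)


# ---------------------------------------------------------------------------
# Example study configuration
# ---------------------------------------------------------------------------


def example_samples() -> list[SampleSheet]:
    """Three-sample study emulating a family with a de novo interruption.

    One parent-like sample with a pure unimodal expansion (mode 447), one
    with a 3'-interrupted expansion (mode 383, 2x CCG) and one fetal-like
    sample with a bimodal 173/215 distribution carrying 6x CCG.  Spreads
    derive from the mode-to-maximum ratios typical of blood mosaicism.
    """
    e1 = parse_pattern("(CTG)n", n_value=440, label="E1-exp")
    e21 = parse_pattern("(CTG)n(CCGCTG)(CTG)7(CCGCTG)(CTG)11", n_value=350, label="E2.1-exp")
    e3 = parse_pattern(
        "(CTG)n(CCGCTG)2(CTG)3(CCGCTG)2(CTG)5(CCGCTG)(CTG)7(CCGCTG)(CTG)11",
        n_value=140,
        label="E3-exp",
    )
    normal = lambda u: AlleleSpec(  # noqa: E731
        parse_pattern(f"(CTG){u}"), Mosaicism.point(u), fraction=0.06, name=f"normal-{u}"
    )
    return [
        SampleSheet(
            "E1",
            "BC1018_Forward",
            BARCODES["BC1018_Forward"],
            alleles=(
                normal(5),
                AlleleSpec(e1, Mosaicism.lognormal(447, 0.25), fraction=0.94, name="expanded"),
            ),
        ),
        SampleSheet(
            "E2.1",
            "BC1019_Forward",
            BARCODES["BC1019_Forward"],
            alleles=(
                normal(13),
                AlleleSpec(e21, Mosaicism.lognormal(383, 0.20), fraction=0.94, name="expanded"),
            ),
        ),
        SampleSheet(
            "E3",
            "BC1020_Forward",
            BARCODES["BC1020_Forward"],
            alleles=(
                normal(31),
                AlleleSpec(
                    e3,
                    Mosaicism.mixture([(173, 0.05, 0.5), (215, 0.05, 0.5)]),
                    fraction=0.94,
                    name="expanded",
                ),
            ),
        ),
    ]
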