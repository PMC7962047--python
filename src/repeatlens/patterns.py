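"""Run-length representation of triplet-repeat alleles.

The CTG tract in the *DMPK* 3'-UTR is conventionally written as a
concatenation of parenthesised motif groups, e.g. ``(CTG)6(CCGCTG)13(CTG)5``
for a 37-unit allele whose middle is an alternating CCG/CTG hexamer block.
This module provides the parser for that notation, the canonical renderer
(including the hexamer collapse rule), expansion to nucleotides, and the
interruption inventory that the allele reports are built on.

Coordinates are repeat *units* (one unit = one 3-nt motif).  A pattern is an
ordered run-length encoding: adjacent runs always carry different motifs, so
equality of run tuples is a well-defined identity for allele structure.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path
from typing import Iterable, Sequence

CTG = "CTG"
CCG = "CCG"
CAG = "CAG"
CTC = "CTC"

#: Sentinel motif for units the decomposer could not assign to the alphabet.
OTHER = "OTHER"

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_MOTIF_RE = re.compile(r"^[ACGT]{3}$")
_GROUP_RE = re.compile(r"\(([ACGTacgt]+)\)(\d+|n)?")


class PatternError(ValueError):
    """Raised for malformed pattern strings or invalid run structures."""


@dataclass(frozen=True)
class MotifRun:
    """``count`` consecutive occurrences of a 3-nt ``motif``."""

    motif: str
    count: int

    def __post_init__(self) -> None:
        if self.motif != OTHER and not _MOTIF_RE.match(self.motif):
            raise PatternError(f"motif must be a 3-letter ACGT string, got {self.motif!r}")
        if self.count < 1:
            raise PatternError(f"run count must be >= 1, got {self.count}")


def merge_runs(units: Iterable[str]) -> tuple[MotifRun, ...]:
    """Run-length encode a unit sequence, merging equal adjacent motifs."""
    return tuple(MotifRun(m, sum(1 for _ in g)) for m, g in groupby(units))


@dataclass(frozen=True)
class RepeatPattern:
    """Ordered run-length encoding of a repeat tract.

    ``label`` is a free-text sample/allele identifier and is ignored by
    equality checks on structure (compare ``.runs`` directly for those).
    """

    runs: tuple[MotifRun, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "runs", tuple(self.runs))
        for a, b in zip(self.runs, self.runs[1:]):
            if a.motif == b.motif:
                raise PatternError(f"adjacent runs share motif {a.motif}; merge them first")

    @property
    def total_units(self) -> int:
        return sum(r.count for r in self.runs)

    def units(self) -> list[str]:
        """Flat unit-by-unit motif list, 5' to 3'."""
        out: list[str] = []
        for r in self.runs:
            out.extend([r.motif] * r.count)
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return canonical_string(self)


def pattern_from_units(units: Sequence[str], label: str = "") -> RepeatPattern:
    return RepeatPattern(merge_runs(units), label=label)


def parse_pattern(text: str, n_value: int | None = None, label: str = "") -> RepeatPattern:
    """Parse a pattern string in the parenthesised-group notation.

    Groups are ``(MOTIFS)k`` where the group content length is a multiple of
    3 and ``k`` is a positive integer, the literal ``n`` (replaced by
    ``n_value``), or absent (meaning 1).  Hexamer and longer groups are
    unrolled into triplet runs; adjacent equal-motif runs are merged.
    """
    s = text.strip()
    units: list[str] = []
    pos = 0
    for m in _GROUP_RE.finditer(s):
        if m.start() != pos:
            raise PatternError(f"malformed pattern near {s[pos:m.start() + 1]!r}")
        content = m.group(1).upper()
        if len(content) % 3 != 0:
            raise PatternError(f"group ({content}) content length is not a multiple of 3")
        mult = m.group(2)
        if mult is None:
            count = 1
        elif mult == "n":
            if n_value is None:
                raise PatternError(f"group ({content})n requires an n_value")
            count = int(n_value)
        else:
            count = int(mult)
        if count < 1:
            raise PatternError(f"non-positive multiplier in group ({content}){mult}")
        motifs = [content[i : i + 3] for i in range(0, len(content), 3)]
        for _ in range(count):
            units.extend(motifs)
        pos = m.end()
    if pos != len(s):
        raise PatternError(f"malformed pattern near {s[pos:pos + 8]!r}")
    return pattern_from_units(units, label=label)


def expand_pattern(pattern: RepeatPattern) -> str:
    """Concatenate the pattern's motifs into a nucleotide string."""
    parts = []
    for r in pattern.runs:
        if r.motif == OTHER:
            raise PatternError("cannot expand a pattern containing OTHER units")
        parts.append(r.motif * r.count)
    return "".join(parts)


def canonical_string(pattern: RepeatPattern) -> str:
    """Render a pattern in the field's notation, collapsing hexamer blocks.

    Maximal blocks of alternating single-unit CCG,CTG pairs (starting with
    CCG) render as ``(CCGCTG)k`` — ``(CCGCTG)`` when k is 1.  A CTG run of
    count > 1 may donate its first unit to complete the final pair; the rest
    renders as ``(CTG)c-1`` after the block.  A CCG run of count >= 2 never
    collapses.  All other runs render ``(MOTIF)count``.

    ``parse_pattern(canonical_string(p))`` reproduces ``p.runs`` exactly.
    """
    runs = pattern.runs
    out: list[str] = []
    i = 0
    while i < len(runs):
        r = runs[i]
        if r.motif == OTHER:
            raise PatternError("cannot render a pattern containing OTHER units")
        if r.motif == CCG and r.count == 1 and i + 1 < len(runs) and runs[i + 1].motif == CTG:
            k = 0
            leftover = 0
            j = i
            while (
                j + 1 < len(runs)
                and runs[j].motif == CCG
                and runs[j].count == 1
                and runs[j + 1].motif == CTG
            ):
                k += 1
                if runs[j + 1].count == 1:
                    j += 2
                else:
                    leftover = runs[j + 1].count - 1
                    j += 2
                    break
            out.append("(CCGCTG)" if k == 1 else f"(CCGCTG){k}")
            if leftover:
                out.append(f"(CTG){leftover}")
            i = j
        else:
            out.append(f"({r.motif}){r.count}")
            i += 1
    return "".join(out)


@dataclass(frozen=True)
class Interruption:
    """One non-CTG unit inside the tract, located in unit coordinates."""

    motif: str
    position: int  # 0-based unit index from the 5' end
    dist_5p: int
    dist_3p: int
    end_class: str  # FIVE_PRIME or THREE_PRIME


@dataclass(frozen=True)
class InterruptionInventory:
    """Per-motif interruption unit counts plus per-unit localisation.

    ``counts`` covers every non-CTG alphabet motif in the tract; OTHER units
    (decomposition noise) are tallied separately so that
    ``ctg_units + sum(counts.values()) + other_units == total_units``.
    """

    total_units: int
    ctg_units: int
    other_units: int
    counts: dict[str, int] = field(default_factory=dict)
    interruptions: tuple[Interruption, ...] = ()

    def count(self, motif: str) -> int:
        return self.counts.get(motif, 0)


def inventory_from_units(units: Sequence[str]) -> InterruptionInventory:
    total = len(units)
    counts: Counter[str] = Counter()
    other = 0
    interruptions: list[Interruption] = []
    for idx, u in enumerate(units):
        if u == CTG:
            continue
        if u == OTHER:
            other += 1
            continue
        counts[u] += 1
        d5 = idx
        d3 = total - 1 - idx
        end = FIVE_PRIME if d5 < d3 else THREE_PRIME  # tie goes 3'
        interruptions.append(Interruption(u, idx, d5, d3, end))
    ctg = total - other - sum(counts.values())
    return InterruptionInventory(
        total_units=total,
        ctg_units=ctg,
        other_units=other,
        counts=dict(counts),
        interruptions=tuple(interruptions),
    )


def inventory(pattern: RepeatPattern) -> InterruptionInventory:
    """Interruption inventory of a pattern (counts, 5'/3' localisation)."""
    return inventory_from_units(pattern.units())


# ---------------------------------------------------------------------------
# Bundled fixture table: literature interruption patterns with fixed n-values.
# ---------------------------------------------------------------------------

_FIXTURE_PATH = Path(__file__).parent / "data" / "interrupted_allele_fixtures.tsv"


@dataclass(frozen=True)
class AlleleFixture:
    label: str
    pattern_text: str
    n_value: int | None
    expected_total_units: int
    expected_interruptions: dict[str, int]
    localization: str
    pattern: RepeatPattern

    @property
    def is_pure(self) -> bool:
        return not self.expected_interruptions


def load_fixtures(path: str | Path | None = None) -> list[AlleleFixture]:
    """Load the bundled allele fixture table (label, pattern, n, expectations)."""
    path = Path(path) if path is not None else _FIXTURE_PATH
    fixtures: list[AlleleFixture] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            n_value = int(row["n_value"]) if row["n_value"] not in ("", "-") else None
            expected: dict[str, int] = {}
            if row["expected_interruptions"] not in ("", "-"):
                for part in row["expected_interruptions"].split(";"):
                    motif, k = part.split(":")
                    expected[motif.strip()] = int(k)
            pattern = parse_pattern(row["pattern"], n_value=n_value, label=row["label"])
            fixtures.append(
                AlleleFixture(
                    label=row["label"],
                    pattern_text=row["pattern"],
                    n_value=n_value,
                    expected_total_units=int(row["expected_total_units"]),
                    expected_interruptions=expected,
                    localization=row.get("localization", ""),
                    pattern=pattern,
                )
            )
    return fixtures


def fixture(label: str, path: str | Path | None = None) -> AlleleFixture:
    for fx in load_fixtures(path):
        if fx.label == label:
            return fx
    raise KeyError(f"no fixture labelled {label!r}")
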