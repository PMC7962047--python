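"""DM1-locus haplotype calling from the seven flanking polymorphisms.

Most European DM1 expansions — pure and interrupted — sit on a shared
marker combination ("haplotype A") over seven polymorphisms flanking the
repeat, including the intronic *Alu* insertion.  Genotypes are unphased, so
the call is compatibility-based: a sample is labelled "A" when every marker
carries at least one haplotype-A allele, "non-A" when any marker carries
none, and "ambiguous" when the panel is incomplete.  True phased
haplotyping is out of scope; heterozygous compatibility is a documented
limitation of the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

#: Panel order follows the locus layout, 5' to 3'.
MARKER_PANEL = (
    "RS2070736",
    "RS572634",
    "RS1799894",
    "RS4646995",  # Alu element insertion/deletion
    "RS16939",
    "RS527221",
    "RS915915",
)

HAPLOTYPE_A = {
    "RS2070736": "T",
    "RS572634": "T",
    "RS1799894": "T",
    "RS4646995": "Ins",
    "RS16939": "G",
    "RS527221": "C",
    "RS915915": "T",
}


class GenotypeError(ValueError):
    pass


def _normalise_allele(allele: str) -> str:
    a = str(allele).strip()
    if a.lower() in ("ins", "insertion"):
        return "Ins"
    if a.lower() in ("del", "deletion"):
        return "Del"
    return a.upper()


@dataclass(frozen=True)
class MarkerGenotype:
    marker: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        marker = self.marker.upper()
        if marker not in MARKER_PANEL:
            raise GenotypeError(f"unknown marker {self.marker!r}")
        object.__setattr__(self, "marker", marker)
        object.__setattr__(
            self, "alleles", tuple(_normalise_allele(a) for a in self.alleles)
        )


@dataclass(frozen=True)
class HaplotypeCall:
    label: str  # "A" | "non-A" | "ambiguous"
    matched_markers: int
    missing_markers: tuple[str, ...] = ()


def call_haplotype(genotypes: Iterable[MarkerGenotype]) -> HaplotypeCall:
    """Compatibility call against the haplotype-A reference alleles.

    Order-independent in the input; duplicate markers are rejected.
    ``matched_markers`` counts markers with at least one matching allele.
    """
    seen: dict[str, MarkerGenotype] = {}
    for g in genotypes:
        if g.marker in seen:
            raise GenotypeError(f"marker {g.marker} supplied twice")
        seen[g.marker] = g
    missing = tuple(m for m in MARKER_PANEL if m not in seen)
    matched = sum(
        1 for m, g in seen.items() if HAPLOTYPE_A[m] in g.alleles
    )
    if missing:
        return HaplotypeCall("ambiguous", matched, missing)
    if matched == len(MARKER_PANEL):
        return HaplotypeCall("A", matched)
    return HaplotypeCall("non-A", matched)


def genotypes_from_mapping(mapping: Mapping[str, tuple[str, str]]) -> list[MarkerGenotype]:
    return [MarkerGenotype(m, tuple(a)) for m, a in mapping.items()]


def call_sample_table(frame: pd.DataFrame, sample: str) -> HaplotypeCall:
    """Call one sample from a long genotype table (sample, marker, alleles)."""
    rows = frame[frame["sample"] == sample]
    if rows.empty:
        raise GenotypeError(f"sample {sample!r} not present in the genotype table")
    genotypes = [
        MarkerGenotype(r.marker, (r.allele1, r.allele2)) for r in rows.itertuples()
    ]
    return call_haplotype(genotypes)
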