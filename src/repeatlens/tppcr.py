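"""In-silico triplet-primed PCR (TP-PCR) traces and interruption gaps.

TP-PCR primes within the repeat with a primer whose repeat-complementary
portion spans several CTG units, producing a ladder of fragments — one peak
per eligible annealing position.  An interruption breaks every annealing
window that covers it, so interruptions near the assayed end appear as gaps
in the ladder.  The model here is positional only: annealing requires
``anneal_units`` consecutive CTG units, peak intensity decays exponentially
with fragment length (a qualitative stand-in for amplification efficiency),
and gap positions — not intensities — are the meaningful output.

Unit coordinates are 1-based and counted from the assayed end (the 3' end
by default, matching the 3' TP-PCR design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .patterns import CTG, OTHER, RepeatPattern

ANNEAL_UNITS = 5
#: Fixed fragment-length contribution of the locus-specific primer side (bp).
FLANK_OFFSET_BP = 60
DECAY_RATE = 0.002  # per bp

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"


@dataclass
class TppcrTrace:
    """Simulated electropherogram: (length, intensity) peaks plus gaps.

    ``gaps`` are maximal unit intervals (inclusive, 1-based from the assayed
    end) that contain no annealing site but are flanked by sites.
    """

    peaks: list[tuple[float, float]] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)
    orientation: str = THREE_PRIME


def _oriented_units(pattern: RepeatPattern, orientation: str) -> list[str]:
    units = pattern.units()
    if any(u == OTHER for u in units):
        raise ValueError("TP-PCR simulation needs a fully decomposed pattern")
    if orientation == THREE_PRIME:
        units.reverse()
    elif orientation != FIVE_PRIME:
        raise ValueError(f"unknown orientation {orientation!r}")
    return units


def annealing_sites(
    pattern: RepeatPattern,
    anneal_units: int = ANNEAL_UNITS,
    orientation: str = FIVE_PRIME,
) -> list[int]:
    """1-based unit positions where ``anneal_units`` consecutive CTGs begin.

    Interruption units break window eligibility.  With the default 5'
    orientation, positions count from the 5' end of the tract as written.
    """
    units = _oriented_units(pattern, orientation)
    sites = []
    run = 0
    for i, u in enumerate(units):
        run = run + 1 if u == CTG else 0
        if run >= anneal_units:
            sites.append(i - anneal_units + 2)  # window start, 1-based
    return sites


def interruption_clusters(
    pattern: RepeatPattern,
    min_separation: int = ANNEAL_UNITS,
    orientation: str = FIVE_PRIME,
) -> list[tuple[int, int]]:
    """Maximal interruption groups, merging neighbours closer than a window.

    Two interruptions separated by fewer than ``min_separation`` CTG units
    cannot re-establish an annealing site between them, so they act as one
    gap-inducing cluster.  Returns (first, last) 1-based unit positions.
    """
    units = _oriented_units(pattern, orientation)
    positions = [i + 1 for i, u in enumerate(units) if u != CTG]
    clusters: list[tuple[int, int]] = []
    for p in positions:
        if clusters and p - clusters[-1][1] - 1 < min_separation:
            clusters[-1] = (clusters[-1][0], p)
        else:
            clusters.append((p, p))
    return clusters


def simulate_trace(
    pattern: RepeatPattern,
    anneal_units: int = ANNEAL_UNITS,
    decay_rate: float = DECAY_RATE,
    flank_offset_bp: int = FLANK_OFFSET_BP,
    orientation: str = THREE_PRIME,
    base_intensity: float = 1000.0,
) -> TppcrTrace:
    """One peak per annealing site; gaps where interruptions kill the ladder.

    Fragment length for a site at unit position q (from the assayed end) is
    ``3 * (q + anneal_units - 1) + flank_offset_bp``; intensity decays
    exponentially with length.  Peaks are sorted by ascending length.
    """
    sites = annealing_sites(pattern, anneal_units, orientation)
    peaks = []
    for q in sites:
        length = 3.0 * (q + anneal_units - 1) + flank_offset_bp
        peaks.append((length, base_intensity * math.exp(-decay_rate * length)))
    peaks.sort()
    gaps = []
    for a, b in zip(sites, sites[1:]):
        if b - a > 1:
            gaps.append((a + 1, b - 1))
    return TppcrTrace(peaks=peaks, gaps=gaps, orientation=orientation)


def mixed_trace(
    patterns_and_fractions: list[tuple[RepeatPattern, float]],
    **kwargs,
) -> TppcrTrace:
    """Fraction-weighted sum of per-allele traces (gaps are per-allele unions)."""
    combined: dict[float, float] = {}
    gaps: list[tuple[int, int]] = []
    orientation = kwargs.get("orientation", THREE_PRIME)
    for pattern, fraction in patterns_and_fractions:
        trace = simulate_trace(pattern, **kwargs)
        for length, intensity in trace.peaks:
            combined[length] = combined.get(length, 0.0) + fraction * intensity
        gaps.extend(g for g in trace.gaps if g not in gaps)
    peaks = sorted(combined.items())
    return TppcrTrace(peaks=[(l, i) for l, i in peaks], gaps=sorted(gaps), orientation=orientation)
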