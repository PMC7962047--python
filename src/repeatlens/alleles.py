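"""Allele classification, mode estimation and per-sample summaries.

Reads are partitioned into normal and expanded alleles at a unit-count
threshold (50 units for the DM1 locus: the classic boundary between normal/
intermediate alleles and disease-range expansions).  Somatic mosaicism is
summarised by the mode(s) of the per-read repeat-length distribution — a
Gaussian KDE with Silverman bandwidth, keeping up to two sufficiently
prominent maxima, which captures both unimodal expansions and the bimodal
distributions seen in early embryonic instability — together with the
maximum observed expansion and a majority-vote interruption consensus.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .decompose import RepeatCall
from .patterns import THREE_PRIME

EXPANSION_THRESHOLD = 50
NO_INTERRUPTION = "No obvious interruption"


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ModeEstimate:
    mode_units: int
    density_height: float
    prominence: float


@dataclass
class SampleSummary:
    """Per-sample statistics in the shape of the study's summary table."""

    sample_id: str
    total_ccs_reads: int | None = None
    pct_on_target: float | None = None
    pct_full_length: float | None = None
    reads_analyzed: int = 0
    reads_below_threshold: int = 0
    reads_at_or_above_threshold: int = 0
    pct_expanded: int = 0
    normal_modes: list[int] = field(default_factory=list)
    expanded_modes: list[int] = field(default_factory=list)
    max_units: int | None = None
    interruption_consensus: str = NO_INTERRUPTION

    def to_row(self) -> dict:
        return {
            "sample": self.sample_id,
            "total_ccs_reads": self.total_ccs_reads,
            "pct_on_target": self.pct_on_target,
            "pct_full_length": self.pct_full_length,
            "reads_analyzed": self.reads_analyzed,
            "reads_below_threshold": self.reads_below_threshold,
            "reads_at_or_above_threshold": self.reads_at_or_above_threshold,
            "pct_expanded": self.pct_expanded,
            "normal_modes": ",".join(map(str, self.normal_modes)),
            "expanded_modes": ",".join(map(str, self.expanded_modes)),
            "max_units": self.max_units,
            "interruption_consensus": self.interruption_consensus,
        }


def classify_reads(
    calls: list[RepeatCall], threshold: int = EXPANSION_THRESHOLD
) -> tuple[list[RepeatCall], list[RepeatCall]]:
    """Strict partition into (< threshold, >= threshold) unit counts."""
    normal = [c for c in calls if c.total_units < threshold]
    expanded = [c for c in calls if c.total_units >= threshold]
    return normal, expanded


def pct_expanded(below: int, at_or_above: int) -> int:
    """Integer percent of expanded reads, half away from zero."""
    total = below + at_or_above
    if total == 0:
        return 0
    return round_half_up(100.0 * at_or_above / total)


def estimate_modes(
    unit_counts,
    bandwidth_rule: str = "silverman",
    max_modes: int = 2,
    prominence_fraction: float = 0.05,
) -> list[ModeEstimate]:
    """Mode(s) of a repeat-length distribution via Gaussian KDE.

    Local maxima with prominence below ``prominence_fraction`` of the global
    maximum are discarded; the ``max_modes`` highest survivors are returned
    sorted by position.  Fewer than 10 counts (or a degenerate, zero-spread
    sample) fall back to the empirical mode.
    """
    counts = np.asarray(unit_counts, dtype=float)
    if counts.size == 0:
        return []
    if counts.size < 10 or np.ptp(counts) == 0:
        values, freq = np.unique(counts, return_counts=True)
        best = values[np.argmax(freq)]
        return [ModeEstimate(int(round(best)), float(freq.max()), float(freq.max()))]

    kde = gaussian_kde(counts, bw_method=bandwidth_rule)
    h = float(kde.factor * counts.std(ddof=1))
    lo, hi = counts.min() - 3 * h, counts.max() + 3 * h
    grid = np.linspace(lo, hi, max(2048, int((hi - lo) * 4)))
    density = kde(grid)
    peaks, props = find_peaks(density, prominence=prominence_fraction * density.max())
    if len(peaks) == 0:
        i = int(np.argmax(density))
        return [ModeEstimate(int(round(grid[i])), float(density[i]), float(density[i]))]
    order = np.argsort(density[peaks])[::-1][:max_modes]
    chosen = sorted(
        (int(peaks[k]), float(props["prominences"][k])) for k in order
    )
    return [
        ModeEstimate(int(round(grid[i])), float(density[i]), prom) for i, prom in chosen
    ]


def refined_modes(
    unit_counts,
    bandwidth_rule: str = "silverman",
    max_modes: int = 2,
    prominence_fraction: float = 0.05,
) -> list[ModeEstimate]:
    """KDE-located modes refined by a lognormal-mixture fit.

    The KDE argmax of a broad repeat-length distribution carries sampling
    jitter of many units, so the KDE here only counts the modes and seeds
    them; each is then refined by fitting a Gaussian mixture to log unit
    counts (one component per retained peak) and reporting each component's
    density mode exp(mu - sigma^2).  Degenerate samples fall back to the
    KDE/empirical estimate unchanged.
    """
    counts = np.asarray(unit_counts, dtype=float)
    kde_modes = estimate_modes(counts, bandwidth_rule, max_modes, prominence_fraction)
    if counts.size < 10 or np.ptp(counts) == 0 or not kde_modes:
        return kde_modes
    from sklearn.mixture import GaussianMixture

    means_init = np.log([max(m.mode_units, 1) for m in kde_modes]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=len(kde_modes), means_init=means_init, n_init=1, random_state=0
    )
    gm.fit(np.log(np.maximum(counts, 1.0)).reshape(-1, 1))
    refined = sorted(
        float(np.exp(mu - s2))
        for mu, s2 in zip(gm.means_[:, 0], gm.covariances_[:, 0, 0])
    )
    return [
        ModeEstimate(int(round(x)), m.density_height, m.prominence)
        for x, m in zip(refined, kde_modes)
    ]


def _supported_positions(
    per_read: list[list[tuple[str, int]]],
    n_reads: int,
    min_support: float,
    tolerance: int,
) -> list[tuple[str, int]]:
    """Anchored interruption positions recurring across reads.

    A candidate (end, distance) is supported when at least ``min_support``
    of reads carry an interruption of the motif within ``tolerance`` units
    of it; accepted windows are greedily non-overlapping, highest support
    first.  Error-induced interruptions are uniform along the tract and
    never reach the support threshold, while true interruptions sit at a
    fixed distance from their nearer end (the far end absorbs the mosaic
    length variation).
    """
    coverage: Counter[tuple[str, int]] = Counter()
    for units in per_read:
        covered = set()
        for end, dist in units:
            for d in range(dist - tolerance, dist + tolerance + 1):
                covered.add((end, d))
        coverage.update(covered)
    threshold = min_support * n_reads
    candidates = sorted(
        (c for c, k in coverage.items() if k >= threshold),
        key=lambda c: (-coverage[c], c[0], c[1]),
    )
    accepted: list[tuple[str, int]] = []
    for end, dist in candidates:
        if all(e != end or abs(d - dist) > 2 * tolerance for e, d in accepted):
            accepted.append((end, dist))
    return accepted


def interruption_consensus(
    calls: list[RepeatCall],
    motifs: tuple[str, ...] = ("CCG", "CAG", "CTC"),
    min_support: float = 0.25,
    position_tolerance: int = 2,
) -> tuple[str, dict[str, Counter]]:
    """Majority interruption count per motif across expanded reads.

    Only position-consistent interruptions are counted: an interruption
    contributes when its distance from the nearer tract end recurs (within
    ``position_tolerance`` units) in at least ``min_support`` of reads,
    which suppresses isolated sequencing-error artefacts.  Formats
    ``kx CCG``; when the two most frequent counts each exceed 25% of reads
    the range form ``k1–k2x CCG`` is used.  A majority count of zero for
    every motif yields the no-interruption phrase.  The per-read
    distribution of (position-filtered) counts per motif is returned
    alongside.
    """
    if not calls:
        raise ValueError("interruption consensus needs at least one call")
    distributions: dict[str, Counter] = {}
    parts: list[str] = []
    n = len(calls)
    for motif in motifs:
        per_read: list[list[tuple[str, int]]] = []
        for c in calls:
            units = [
                (
                    i.end_class,
                    i.dist_3p if i.end_class == THREE_PRIME else i.dist_5p,
                )
                for i in c.inventory.interruptions
                if i.motif == motif
            ]
            per_read.append(units)
        accepted = _supported_positions(per_read, n, min_support, position_tolerance)
        counter = Counter(
            sum(
                1
                for end, dist in units
                if any(e == end and abs(d - dist) <= position_tolerance for e, d in accepted)
            )
            for units in per_read
        )
        distributions[motif] = counter
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        majority = ranked[0][0]
        if len(ranked) > 1:
            k1, f1 = ranked[0]
            k2, f2 = ranked[1]
            if f1 > 0.25 * n and f2 > 0.25 * n and not (k1 == 0 or k2 == 0):
                lo, hi = sorted((k1, k2))
                parts.append(f"{lo}–{hi}x {motif}")
                continue
        if majority > 0:
            parts.append(f"{majority}x {motif}")
    text = ", ".join(parts) if parts else NO_INTERRUPTION
    return text, distributions


def summarize(
    sample_id: str,
    calls: list[RepeatCall],
    threshold: int = EXPANSION_THRESHOLD,
    total_ccs_reads: int | None = None,
    pct_on_target: float | None = None,
    pct_full_length: float | None = None,
) -> SampleSummary:
    """Populate the per-sample summary from decomposed calls."""
    normal, expanded = classify_reads(calls, threshold)
    summary = SampleSummary(
        sample_id=sample_id,
        total_ccs_reads=total_ccs_reads,
        pct_on_target=pct_on_target,
        pct_full_length=pct_full_length,
        reads_analyzed=len(calls),
        reads_below_threshold=len(normal),
        reads_at_or_above_threshold=len(expanded),
        pct_expanded=pct_expanded(len(normal), len(expanded)),
    )
    if normal:
        summary.normal_modes = [
            m.mode_units for m in refined_modes([c.total_units for c in normal])
        ]
    if expanded:
        summary.expanded_modes = [
            m.mode_units for m in refined_modes([c.total_units for c in expanded])
        ]
        summary.max_units = max(c.total_units for c in expanded)
        summary.interruption_consensus = interruption_consensus(expanded)[0]
    return summary


def pcr_size_to_units(product_bp: float, flank_bp: int = 361) -> tuple[float, int]:
    """Repeat units implied by a PCR product length.

    Units = (product - flank_bp) / 3, the flanks being the 5' + 3' sequence
    around the tract in the sizing amplicon.  Returns (one-decimal value,
    rounded integer).
    """
    if product_bp <= flank_bp:
        raise ValueError(f"product of {product_bp} bp is within the {flank_bp} bp flanks")
    units = (product_bp - flank_bp) / 3.0
    return round(units, 1), round_half_up(units)
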