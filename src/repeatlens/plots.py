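"""Waterfall and repeat-length distribution figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .alleles import estimate_modes
from .decompose import RepeatCall
from .patterns import OTHER

#: Motif colour map: CTG blue, CCG orange, CAG purple, CTC green, noise grey.
MOTIF_COLORS = {
    "CTG": "#1f77b4",
    "CCG": "#ff7f0e",
    "CAG": "#9467bd",
    "CTC": "#2ca02c",
    OTHER: "#bbbbbb",
}


def waterfall_segments(calls: list[RepeatCall]) -> list[tuple[str, list[tuple[int, int, str]]]]:
    """Deterministic plot geometry: per read, (x bp, width bp, motif) segments.

    Reads sort by ascending total_units, ties by read_id.  Every unit spans
    3 bp on the x axis (OTHER units included, so bars reflect total length).
    """
    ordered = sorted(calls, key=lambda c: (c.total_units, c.read_id))
    rows = []
    for call in ordered:
        segments = []
        x = 0
        for run in call.runs:
            width = 3 * run.count
            segments.append((x, width, run.motif))
            x += width
        rows.append((call.read_id, segments))
    return rows


def waterfall(calls: list[RepeatCall], path: str | Path | None = None, title: str = ""):
    """One horizontal bar per read, motif-coloured along the tract."""
    if not calls:
        raise ValueError("waterfall needs at least one call")
    rows = waterfall_segments(calls)
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.02 * len(rows) + 1)))
    quads: dict[str, list] = {}
    for y, (_, segments) in enumerate(rows):
        for x, width, motif in segments:
            quads.setdefault(motif, []).append(
                [(x, y), (x + width, y), (x + width, y + 0.9), (x, y + 0.9)]
            )
    from matplotlib.collections import PolyCollection

    for motif, verts in quads.items():
        ax.add_collection(
            PolyCollection(verts, facecolors=MOTIF_COLORS.get(motif, "#999999"))
        )
    ax.autoscale_view()
    ax.set_xlabel("repeat tract length (bp)")
    ax.set_ylabel("CCS reads")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def distribution_plot(
    unit_counts,
    path: str | Path | None = None,
    title: str = "",
    annotate_modes: bool = True,
):
    """Histogram of per-read unit counts with an overlaid KDE and modes."""
    counts = np.asarray(unit_counts)
    if counts.size < 10:
        raise ValueError("distribution plot needs at least 10 counts")
    fig, ax = plt.subplots(figsize=(8, 4))
    bin_edges = np.arange(counts.min() - 0.5, counts.max() + 1.5)
    if len(bin_edges) > 400:
        bin_edges = np.linspace(counts.min() - 0.5, counts.max() + 0.5, 401)
    binwidth = bin_edges[1] - bin_edges[0]
    ax.hist(counts, bins=bin_edges, color="#9fb8cc", label="CCS reads")
    modes = estimate_modes(counts)
    if np.ptp(counts) > 0:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(counts.astype(float), bw_method="silverman")
        grid = np.linspace(counts.min(), counts.max(), 1024)
        density = kde(grid) * counts.size * binwidth  # scale to histogram counts
        ax.plot(grid, density, color="grey", label="kernel density estimate")
    if annotate_modes:
        for m in modes:
            ax.axvline(m.mode_units, color="#444444", linestyle="--", linewidth=0.8)
            ax.annotate(str(m.mode_units), (m.mode_units, ax.get_ylim()[1] * 0.95))
    ax.set_xlabel("number of CTG repeats")
    ax.set_ylabel("number of CCS reads")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def trace_plot(trace, path: str | Path | None = None, title: str = ""):
    """Stem plot of a simulated TP-PCR trace (length vs intensity)."""
    fig, ax = plt.subplots(figsize=(8, 3))
    if trace.peaks:
        lengths, intensities = zip(*trace.peaks)
        ax.vlines(lengths, 0, intensities, color="#1f77b4", linewidth=1)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("intensity of fluorescence (arbitrary unit)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
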