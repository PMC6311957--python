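"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each statistic by direct enumeration (double loops over
peaks and genes) so the vectorised implementations can be checked against a
path that shares no code with them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cochip.core import FactorTrack, GeneModel, GenomicInterval, Peak


def make_peak(chrom, start, end, signal=1.0, summit=None, name="."):
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        signal_value=signal,
        summit_offset=summit,
        name=name,
    )


def make_track(intervals, factor="F", cell="C", chrom="chr1", signals=None,
               factor_class="TF"):
    """Track from a list of (start, end) pairs on one chromosome."""
    if signals is None:
        signals = [1.0] * len(intervals)
    peaks = [
        make_peak(chrom, s, e, signal=g, name=f"{factor}_{i}")
        for i, ((s, e), g) in enumerate(zip(intervals, signals))
    ]
    return FactorTrack(factor_name=factor, cell_line=cell, peaks=peaks,
                       factor_class=factor_class)


def random_track(rng, n_peaks, factor="F", cell="C", chrom="chr1",
                 span=1_000_000, width_lo=50, width_hi=2000):
    starts = rng.integers(0, span, size=n_peaks)
    widths = rng.integers(width_lo, width_hi, size=n_peaks)
    peaks = [
        make_peak(chrom, int(s), int(s + w), signal=float(rng.uniform(0.5, 10)))
        for s, w in zip(starts, widths)
    ]
    return FactorTrack(factor_name=factor, cell_line=cell, peaks=peaks)


# ------------------------------------------------------------------ oracles


def oracle_peaks_overlap(p: Peak, q: Peak) -> bool:
    """Direct strict-inequality evaluation of the center-distance predicate."""
    if p.chrom != q.chrom:
        return False
    return abs(p.center - q.center) < (p.width + q.width) / 2


def oracle_overlap_ratio(track_a: FactorTrack, track_b: FactorTrack) -> float:
    """O(N^2) all-pairs evaluation of R_o with matched-peak counting."""
    hits_a = sum(
        any(oracle_peaks_overlap(p, q) for q in track_b.peaks)
        for p in track_a.peaks
    )
    hits_b = sum(
        any(oracle_peaks_overlap(q, p) for p in track_a.peaks)
        for q in track_b.peaks
    )
    return (hits_a + hits_b) / (track_a.n_peaks + track_b.n_peaks)


def oracle_bin_matrix(track, genes, half_window=20000, bin_size=200):
    """O(peaks x genes) double-loop bin assignment."""
    n_bins = 2 * half_window // bin_size
    counts = np.zeros((len(genes), n_bins), dtype=int)
    for gi, gene in enumerate(genes):
        for p in track.peaks:
            if p.chrom != gene.chrom:
                continue
            offset = p.center - gene.tss
            if gene.strand == "-":
                offset = -offset
            if -half_window <= offset < half_window:
                counts[gi, (offset + half_window) // bin_size] += 1
    return counts


def oracle_tfas(track, gene, d0=2000.0, half_window=20000):
    """Per-peak loop evaluation of the distance-decay sum."""
    total = 0.0
    for p in track.peaks:
        if p.chrom != gene.chrom:
            continue
        offset = p.center - gene.tss
        if gene.strand == "-":
            offset = -offset
        if -half_window <= offset < half_window:
            total += p.signal_value * np.exp(-abs(offset) / d0)
    return total


def oracle_filter_genes(genes, half_window=20000):
    """All-pairs closed-window intersection test."""
    kept = []
    for i, g in enumerate(genes):
        clash = any(
            j != i and h.chrom == g.chrom and abs(h.tss - g.tss) <= 2 * half_window
            for j, h in enumerate(genes)
        )
        if not clash:
            kept.append(g)
    return kept


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genes():
    return [
        GeneModel("g1", "chr1", 100_000, "+"),
        GeneModel("g2", "chr1", 200_000, "-"),
        GeneModel("g3", "chr2", 150_000, "+"),
    ]
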