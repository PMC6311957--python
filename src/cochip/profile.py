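"""TSS-centered peak binning, per-bin signal intensity, and the
cross-cell-line dynamics indices.

A 40 kb window flanking each TSS (20 kb up, 20 kb down by default) is split
into 200 bins of 200 bp. Peak centers are counted per (gene, bin); the
per-bin signal intensity over n genes is

    S_j = (10^3 / n) * sum_i N_ij

The total signal ratio between two cell lines, f = sum_j S_j^(1) / sum_j
S_j^(2), and the normalised difference D_signal = (f - 1) / (f + 1) classify
each factor as enriched in one cell line or unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import FactorTrack, GeneModel

__all__ = [
    "BinMatrix",
    "SignalProfile",
    "FactorDynamics",
    "LABEL_FIRST_RICH",
    "LABEL_SECOND_RICH",
    "LABEL_UNBIASED",
    "LABEL_UNCLASSIFIED",
    "bin_peaks",
    "signal_intensity",
    "dynamics_indices",
    "peak_count_difference",
]

# Three-way factor classification labels. The first/second cell line of a
# comparison is GM12878/K562 in the reference analysis, hence the names.
LABEL_FIRST_RICH = "GM12878_rich_factor"
LABEL_SECOND_RICH = "K562_rich_factor"
LABEL_UNBIASED = "unbiased_factor"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass
class BinMatrix:
    """Per-gene, per-bin peak-center counts for one factor in one cell line."""

    factor_name: str
    cell_line: str
    counts: np.ndarray  # shape (n_genes, n_bins), nonnegative ints
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class SignalProfile:
    """Aggregated per-bin signal intensity S_j = (10^3/n) sum_i N_ij."""

    factor_name: str
    cell_line: str
    s: np.ndarray  # shape (n_bins,)
    n_genes: int

    @property
    def total(self) -> float:
        return float(self.s.sum())


@dataclass
class FactorDynamics:
    """Cross-cell-line dynamics of one factor: ratio f, D_signal, label."""

    factor_name: str
    f: float  # ratio of total signal, first/second cell line; may be +inf
    d_signal: float  # (f - 1) / (f + 1), in [-1, 1]
    label: str
    peak_count_diff: Optional[float] = None  # |a - b| / (a + b)


def bin_peaks(
    track: FactorTrack,
    genes: list[GeneModel],
    half_window: int = 20000,
    bin_size: int = 200,
    use_summit: bool = False,
) -> BinMatrix:
    """Count peak centers per TSS-relative bin for every gene.

    The oriented offset of a peak center c from gene i is (c - tss) for '+'
    genes and (tss - c) for '-' genes, so bin 1 is always the most upstream
    bin. A peak is assigned to bin j (1-based) iff

        -half_window <= offset < half_window,
        j = floor((offset + half_window) / bin_size) + 1.

    A peak center may fall in the windows of several genes and then counts
    toward each.
    """
    if half_window <= 0 or bin_size <= 0:
        raise ValueError("half_window and bin_size must be positive")
    if half_window % bin_size != 0:
        raise ValueError(
            f"half_window ({half_window}) must be divisible by "
            f"bin_size ({bin_size})"
        )
    n_bins = 2 * half_window // bin_size
    counts = np.zeros((len(genes), n_bins), dtype=np.int64)

    # per-chromosome sorted center arrays
    if use_summit:
        groups: dict[str, list[int]] = {}
        for p in track.peaks:
            groups.setdefault(p.chrom, []).append(p.point(use_summit=True))
        chrom_centers = {
            chrom: np.sort(np.asarray(v, dtype=np.int64))
            for chrom, v in groups.items()
        }
    else:
        chrom_centers = {
            chrom: arrs[0] for chrom, arrs in track.by_chrom().items()
        }

    for gi, gene in enumerate(genes):
        centers = chrom_centers.get(gene.chrom)
        if centers is None or centers.size == 0:
            continue
        if gene.strand == "+":
            # centers in [tss - hw, tss + hw)
            lo = np.searchsorted(centers, gene.tss - half_window, side="left")
            hi = np.searchsorted(centers, gene.tss + half_window, side="left")
            offsets = centers[lo:hi] - gene.tss
        else:
            # offset = tss - c in [-hw, hw)  <=>  c in (tss - hw, tss + hw]
            lo = np.searchsorted(centers, gene.tss - half_window, side="right")
            hi = np.searchsorted(centers, gene.tss + half_window, side="right")
            offsets = gene.tss - centers[lo:hi]
        if offsets.size == 0:
            continue
        bins = (offsets + half_window) // bin_size
        counts[gi] += np.bincount(bins, minlength=n_bins)

    return BinMatrix(
        factor_name=track.factor_name,
        cell_line=track.cell_line,
        counts=counts,
        gene_ids=[g.gene_id for g in genes],
    )


def signal_intensity(bins: BinMatrix) -> SignalProfile:
    """Per-bin signal intensity S_j = (10^3 / n) * column sum of counts."""
    n = bins.n_genes
    if n < 1:
        raise ValueError("signal intensity requires at least one gene")
    s = (1000.0 / n) * bins.counts.sum(axis=0)
    return SignalProfile(
        factor_name=bins.factor_name,
        cell_line=bins.cell_line,
        s=s.astype(float),
        n_genes=n,
    )


def classify_dynamics(f: float, d_signal: float) -> str:
    """Three-way factor classification from (f, D_signal).

    Enriched in the first cell line: f > 1.5 and D_signal > 0.2.
    Enriched in the second:          f < 0.6 and D_signal < -0.25.
    Unbiased: 0.6 < f < 1.5 and -0.25 < D_signal < 0.2.
    The three boxes do not tile the plane; anything else is unclassified.
    """
    if f > 1.5 and d_signal > 0.2:
        return LABEL_FIRST_RICH
    if f < 0.6 and d_signal < -0.25:
        return LABEL_SECOND_RICH
    if 0.6 < f < 1.5 and -0.25 < d_signal < 0.2:
        return LABEL_UNBIASED
    return LABEL_UNCLASSIFIED


def dynamics_indices(
    profile_1: SignalProfile,
    profile_2: SignalProfile,
    peak_counts: Optional[tuple[int, int]] = None,
) -> FactorDynamics:
    """Compute f, D_signal and the three-way label for one factor.

    ``profile_1``/``profile_2`` are the factor's signal profiles in the two
    cell lines (first = the f numerator). Optional raw peak totals (a, b)
    fill in the |a-b|/(a+b) peak-count difference.
    """
    if profile_1.factor_name != profile_2.factor_name:
        raise ValueError(
            f"profiles are for different factors: "
            f"{profile_1.factor_name!r} vs {profile_2.factor_name!r}"
        )
    if profile_1.s.shape != profile_2.s.shape:
        raise ValueError("profiles have different bin counts")
    t1, t2 = profile_1.total, profile_2.total
    if t1 == 0 and t2 == 0:
        raise ValueError(
            f"both cell-line totals are zero for {profile_1.factor_name!r}; "
            "dynamics undefined"
        )
    if t2 == 0:
        f = float("inf")
        d = 1.0
    else:
        f = t1 / t2
        d = (t1 - t2) / (t1 + t2)
    pcd = None
    if peak_counts is not None:
        pcd = peak_count_difference(*peak_counts)
    return FactorDynamics(
        factor_name=profile_1.factor_name,
        f=f,
        d_signal=d,
        label=classify_dynamics(f, d),
        peak_count_diff=pcd,
    )


def peak_count_difference(a: int, b: int) -> float:
    """Normalised peak-count difference |a - b| / (a + b) in [0, 1]."""
    if a < 0 or b < 0:
        raise ValueError("peak counts must be nonnegative")
    if a + b == 0:
        raise ValueError("peak count difference undefined for a = b = 0")
    return abs(a - b) / (a + b)
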