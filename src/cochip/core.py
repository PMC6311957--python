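"""Core domain types: genomic intervals, ChIP-seq peaks, tracks, and genes.

Coordinates are 0-based, half-open (BED convention) throughout. A peak's
center is the interval midpoint ``floor((start + end) / 2)``: the working
assumption is that the midpoint of a signal peak marks the factor-DNA
interaction site. The narrowPeak summit offset is parsed and stored but only
used when explicitly requested (``use_summit``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "FactorTrack",
    "GeneModel",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."  # '+', '-', or '.' for unknown

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq peak: an interval plus an enrichment value.

    ``signal_value`` is the track's enrichment score (narrowPeak/broadPeak
    column 7). ``summit_offset`` is the point-source offset from ``start``
    (narrowPeak column 10); ``None`` means absent (-1 in the file).
    """

    interval: GenomicInterval
    signal_value: float = 0.0
    summit_offset: Optional[int] = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValueError(
                f"signal_value must be >= 0, got {self.signal_value}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def center(self) -> int:
        """Midpoint of the interval, floor((start + end) / 2)."""
        return (self.interval.start + self.interval.end) // 2

    @property
    def summit(self) -> Optional[int]:
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset

    def point(self, use_summit: bool = False) -> int:
        """Representative binding position: midpoint, or summit if asked."""
        if use_summit and self.summit_offset is not None:
            return self.summit
        return self.center


@dataclass
class FactorTrack:
    """All peaks of one factor (TF or HM) in one cell line.

    Peaks are kept sorted by (chrom, start). Numpy views of centers and
    widths per chromosome are cached lazily for the vectorised overlap and
    binning code paths.
    """

    factor_name: str
    cell_line: str
    peaks: list[Peak]
    factor_class: str = "TF"  # 'TF' or 'HM'

    _chrom_arrays: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.factor_name:
            raise ValueError("factor_name must be nonempty")
        if self.factor_class not in ("TF", "HM"):
            raise ValueError(f"factor_class must be TF or HM, got {self.factor_class!r}")
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))
        self._chrom_arrays = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterable[Peak]:
        return iter(self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def chromosomes(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    def by_chrom(self) -> dict:
        """Per-chromosome arrays sorted by peak center.

        Returns {chrom: (centers, widths, signals)} with centers ascending.
        """
        if self._chrom_arrays is None:
            out = {}
            groups: dict[str, list[Peak]] = {}
            for p in self.peaks:
                groups.setdefault(p.chrom, []).append(p)
            for chrom, plist in groups.items():
                centers = np.array([p.center for p in plist], dtype=np.int64)
                widths = np.array([p.width for p in plist], dtype=np.int64)
                signals = np.array([p.signal_value for p in plist], dtype=float)
                order = np.argsort(centers, kind="stable")
                out[chrom] = (centers[order], widths[order], signals[order])
            self._chrom_arrays = out
        return self._chrom_arrays


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript anchor: id, chromosome, TSS position and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
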