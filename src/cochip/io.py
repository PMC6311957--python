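"""Readers and writers for ENCODE peak formats, gene annotations and
expression tables, plus the TSS-window gene filter.

All readers transparently accept gzip-compressed files (by ``.gz`` suffix).
Formats are the plain-text ENCODE standards: narrowPeak (BED6+4), broadPeak
(BED6+3), BED6 or 4-column TSV gene annotations, and a 2-column
``gene_id<TAB>fpkm`` expression table. Parse errors name the offending line.
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path
from typing import Optional, Union

from .core import FactorTrack, GeneModel, GenomicInterval, Peak

__all__ = [
    "ParseError",
    "read_narrowpeak",
    "read_broadpeak",
    "write_narrowpeak",
    "write_broadpeak",
    "read_gene_annotation",
    "write_gene_annotation",
    "filter_nonoverlapping_genes",
    "read_expression",
    "write_expression",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed record in an input file; message names file and line."""


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_int(value: str, what: str, path: PathLike, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-integer {what}: {value!r}"
        ) from None


def _parse_float(value: str, what: str, path: PathLike, lineno: int) -> float:
    try:
        x = float(value)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric {what}: {value!r}"
        ) from None
    if math.isnan(x):
        raise ParseError(f"{path}:{lineno}: NaN {what}")
    return x


def _read_peak_file(
    path: PathLike,
    n_columns: int,
    with_summit: bool,
    factor_name: Optional[str],
    cell_line: str,
    factor_class: str,
    rename_chroms: Optional[dict] = None,
) -> FactorTrack:
    peaks = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_columns} tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            if rename_chroms:
                chrom = rename_chroms.get(chrom, chrom)
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            strand = fields[5] if fields[5] in ("+", "-") else "."
            signal = _parse_float(fields[6], "signalValue", path, lineno)
            summit: Optional[int] = None
            if with_summit:
                s = _parse_int(fields[9], "summit offset", path, lineno)
                if s >= 0:
                    summit = s
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    signal_value=signal,
                    summit_offset=summit,
                    name=fields[3],
                )
            )
    name = factor_name if factor_name is not None else Path(path).name.split(".")[0]
    return FactorTrack(
        factor_name=name,
        cell_line=cell_line,
        peaks=peaks,
        factor_class=factor_class,
    )


def read_narrowpeak(
    path: PathLike,
    factor_name: Optional[str] = None,
    cell_line: str = "",
    rename_chroms: Optional[dict] = None,
) -> FactorTrack:
    """Read an ENCODE narrowPeak (BED6+4) file into a sorted FactorTrack.

    signalValue comes from column 7; the summit offset from column 10
    (-1 in the file means absent). An empty file yields an empty track.
    """
    return _read_peak_file(
        path, 10, True, factor_name, cell_line, "TF", rename_chroms
    )


def read_broadpeak(
    path: PathLike,
    factor_name: Optional[str] = None,
    cell_line: str = "",
    rename_chroms: Optional[dict] = None,
) -> FactorTrack:
    """Read an ENCODE broadPeak (BED6+3) file; no summit column exists."""
    return _read_peak_file(
        path, 9, False, factor_name, cell_line, "HM", rename_chroms
    )


def _format_peak(p: Peak, with_summit: bool) -> str:
    base = (
        f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.interval.strand}"
        f"\t{p.signal_value:.17g}\t-1\t-1"
    )
    if with_summit:
        summit = -1 if p.summit_offset is None else p.summit_offset
        base += f"\t{summit}"
    return base


def write_narrowpeak(track: FactorTrack, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for p in track.peaks:
            fh.write(_format_peak(p, with_summit=True) + "\n")


def write_broadpeak(track: FactorTrack, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for p in track.peaks:
            fh.write(_format_peak(p, with_summit=False) + "\n")


def read_gene_annotation(
    path: PathLike,
    dialect: str = "bed",
    rename_chroms: Optional[dict] = None,
) -> list[GeneModel]:
    """Read a gene/transcript annotation.

    dialect="bed": BED6; TSS = start for '+' records, end-1 for '-'.
    dialect="tsv": 4 columns gene_id, chrom, tss, strand.
    Duplicate gene_ids and unknown strand symbols are rejected.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 6:
                    raise ParseError(
                        f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}"
                    )
                chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
                start = _parse_int(start_s, "start", path, lineno)
                end = _parse_int(end_s, "end", path, lineno)
                if strand == "+":
                    tss = start
                elif strand == "-":
                    tss = end - 1
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unknown strand {strand!r}"
                    )
            else:
                if len(fields) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: TSV annotation needs 4 columns, "
                        f"got {len(fields)}"
                    )
                gene_id, chrom, tss_s, strand = fields
                if strand not in ("+", "-"):
                    raise ParseError(
                        f"{path}:{lineno}: unknown strand {strand!r}"
                    )
                tss = _parse_int(tss_s, "tss", path, lineno)
            if rename_chroms:
                chrom = rename_chroms.get(chrom, chrom)
            if gene_id in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                )
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, chrom, tss, strand))
    return genes


def write_gene_annotation(genes: list[GeneModel], path: PathLike) -> None:
    """Write genes as the 4-column TSV dialect (gene_id, chrom, tss, strand)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def filter_nonoverlapping_genes(
    genes: list[GeneModel], half_window: int = 20000
) -> list[GeneModel]:
    """Keep genes whose +/- half_window TSS windows touch no other gene's.

    Two genes conflict iff they are on the same chromosome and their closed
    windows [tss - half_window, tss + half_window] intersect, i.e.
    |tss_i - tss_j| <= 2 * half_window. Input order is preserved; the
    operation is idempotent.
    """
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append((g.tss, idx))
    drop: set[int] = set()
    for positions in by_chrom.values():
        positions.sort()
        for (tss_a, ia), (tss_b, ib) in zip(positions, positions[1:]):
            if tss_b - tss_a <= 2 * half_window:
                drop.add(ia)
                drop.add(ib)
    return [g for idx, g in enumerate(genes) if idx not in drop]


def read_expression(path: PathLike) -> dict[str, float]:
    """Read a 2-column TSV gene_id -> FPKM table; FPKM must be >= 0."""
    table: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            gene_id, fpkm_s = fields
            fpkm = _parse_float(fpkm_s, "FPKM", path, lineno)
            if fpkm < 0:
                raise ParseError(
                    f"{path}:{lineno}: negative FPKM {fpkm} for {gene_id!r}"
                )
            if gene_id in table:
                raise ParseError(
                    f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                )
            table[gene_id] = fpkm
    return table


def write_expression(table: dict[str, float], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for gene_id in table:
            fh.write(f"{gene_id}\t{table[gene_id]:.10g}\n")
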