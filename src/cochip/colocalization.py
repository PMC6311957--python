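"""Pairwise and groupwise peak co-localization statistics.

Two peaks co-localize when their centers are closer than the mean of their
widths: |S1 - S2| < (L1 + L2) / 2, a strict inequality evaluated in integer
arithmetic (touching half-widths do NOT overlap). On top of that predicate:

* overlap ratio  R_o = 2n / (N1 + N2) with n = (#A-peaks hit + #B-peaks hit)/2,
  so R_o is symmetric, lies in [0, 1] and equals 1 for a track against itself;
* relative variation  I_RV = (R_1 - R_2) / (R_1 + R_2 + alpha), alpha = 0.001,
  with mu +/- 2*sigma outlier flagging across all pairs;
* average overlap ratio  R_av = (1/m) sum_i x_i / N, where x_i counts the
  other factors having at least one peak overlapping peak i;
* k-clique mining of the thresholded co-localization graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import FactorTrack, GenomicInterval, Peak

__all__ = [
    "PairOverlap",
    "PairDynamics",
    "AverageOverlap",
    "EmptyRestrictionError",
    "peaks_overlap",
    "overlap_hits",
    "overlap_ratio",
    "overlap_ratio_in_regions",
    "relative_variation",
    "outlier_pairs",
    "average_overlap_ratio",
    "mine_combinations",
]

ALPHA = 0.001


class EmptyRestrictionError(ValueError):
    """Region restriction removed every peak of both tracks."""


@dataclass
class PairOverlap:
    factor_a: str
    factor_b: str
    n_overlap: float  # matched-peak count; may be half-integral
    n_a: int
    n_b: int
    r_o: float

    def __post_init__(self) -> None:
        pass


@dataclass
class PairDynamics:
    factor_a: str
    factor_b: str
    r_1: float  # R_o in the first cell line (R_G in the reference analysis)
    r_2: float  # R_o in the second cell line (R_K)
    i_rv: float
    is_outlier: bool = False


@dataclass
class AverageOverlap:
    factor_name: str
    x: np.ndarray  # per-peak counts of overlapping other factors
    n_others: int
    r_av: float

    @property
    def m(self) -> int:
        return int(self.x.size)


def peaks_overlap(p: Peak, q: Peak) -> bool:
    """Strict center-distance predicate |S1 - S2| < (L1 + L2) / 2.

    Evaluated as 2|S1 - S2| < L1 + L2 in exact integers. Peaks on different
    chromosomes never overlap (returns False, not an error).
    """
    if p.chrom != q.chrom:
        return False
    return 2 * abs(p.center - q.center) < p.width + q.width


def _hit_mask(track_a: FactorTrack, track_b: FactorTrack) -> np.ndarray:
    """Boolean mask over track_a's center-sorted per-chrom peaks: does each
    peak of A overlap at least one peak of B?

    Works on the "stretched" intervals (2c - w, 2c + w): the strict predicate
    2|cA - cB| < wA + wB holds iff those open intervals intersect. For each
    query, B intervals are sorted by left endpoint; a prefix maximum of right
    endpoints gives an O(log N) existence test.
    """
    masks = []
    b_chrom = track_b.by_chrom()
    for chrom in sorted(track_a.by_chrom()):
        ca, wa, _ = track_a.by_chrom()[chrom]
        if chrom not in b_chrom:
            masks.append(np.zeros(ca.size, dtype=bool))
            continue
        cb, wb, _ = b_chrom[chrom]
        lb = 2 * cb - wb
        rb = 2 * cb + wb
        order = np.argsort(lb, kind="stable")
        lb_sorted = lb[order]
        prefmax_rb = np.maximum.accumulate(rb[order])
        la = 2 * ca - wa
        ra = 2 * ca + wa
        idx = np.searchsorted(lb_sorted, ra, side="left")  # count of lB < rA
        hit = np.zeros(ca.size, dtype=bool)
        nz = idx > 0
        hit[nz] = prefmax_rb[idx[nz] - 1] > la[nz]
        masks.append(hit)
    if not masks:
        return np.zeros(0, dtype=bool)
    return np.concatenate(masks)


def overlap_hits(track_a: FactorTrack, track_b: FactorTrack) -> int:
    """Number of peaks of A overlapping at least one peak of B."""
    return int(_hit_mask(track_a, track_b).sum())


def _pair_event_count(track_a: FactorTrack, track_b: FactorTrack) -> int:
    """Number of overlapping (A-peak, B-peak) ordered pairs."""
    total = 0
    b_chrom = track_b.by_chrom()
    for chrom, (ca, wa, _) in track_a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        cb, wb, _ = b_chrom[chrom]
        lb = np.sort(2 * cb - wb)
        rb = np.sort(2 * cb + wb)
        la = 2 * ca - wa
        ra = 2 * ca + wa
        # overlap iff lB < rA and rB > lA; intervals with rB <= lA are a
        # subset of those with lB < rA, so the difference counts overlaps
        n_left = np.searchsorted(lb, ra, side="left")
        n_disjoint = np.searchsorted(rb, la, side="right")
        total += int((n_left - n_disjoint).sum())
    return total


def overlap_ratio(
    track_a: FactorTrack,
    track_b: FactorTrack,
    count_mode: str = "matched",
) -> PairOverlap:
    """Genome-wide co-localization degree R_o = 2n / (N1 + N2).

    count_mode="matched" (default): n = (#A-peaks overlapping B +
    #B-peaks overlapping A) / 2, which keeps R_o in [0, 1] and makes a track
    against itself score exactly 1. count_mode="pairs" counts overlap events
    instead and can exceed 1; it exists for sensitivity analysis only.
    """
    n_a, n_b = track_a.n_peaks, track_b.n_peaks
    if n_a + n_b == 0:
        raise ValueError(
            f"overlap ratio undefined: both {track_a.factor_name!r} and "
            f"{track_b.factor_name!r} are empty"
        )
    if count_mode == "matched":
        hits_a = overlap_hits(track_a, track_b)
        hits_b = overlap_hits(track_b, track_a)
        n = (hits_a + hits_b) / 2
    elif count_mode == "pairs":
        n = _pair_event_count(track_a, track_b)
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    return PairOverlap(
        factor_a=track_a.factor_name,
        factor_b=track_b.factor_name,
        n_overlap=n,
        n_a=n_a,
        n_b=n_b,
        r_o=2 * n / (n_a + n_b),
    )


def _merge_regions(regions: list[GenomicInterval]) -> dict[str, np.ndarray]:
    """Sort and merge regions per chromosome -> {chrom: (k, 2) array}."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def _restrict(track: FactorTrack, merged: dict[str, np.ndarray]) -> FactorTrack:
    kept = []
    for p in track.peaks:
        spans = merged.get(p.chrom)
        if spans is None:
            continue
        i = np.searchsorted(spans[:, 0], p.center, side="right") - 1
        if i >= 0 and p.center < spans[i, 1]:
            kept.append(p)
    return FactorTrack(
        factor_name=track.factor_name,
        cell_line=track.cell_line,
        peaks=kept,
        factor_class=track.factor_class,
    )


def overlap_ratio_in_regions(
    track_a: FactorTrack,
    track_b: FactorTrack,
    regions: list[GenomicInterval],
    count_mode: str = "matched",
) -> PairOverlap:
    """R_o restricted to peaks whose centers fall inside the given regions
    (e.g. enhancers). Regions are merged first; half-open membership
    start <= center < end."""
    merged = _merge_regions(regions)
    ra = _restrict(track_a, merged)
    rb = _restrict(track_b, merged)
    if ra.n_peaks + rb.n_peaks == 0:
        raise EmptyRestrictionError(
            f"no peaks of {track_a.factor_name!r}/{track_b.factor_name!r} "
            "remain inside the given regions"
        )
    return overlap_ratio(ra, rb, count_mode=count_mode)


def relative_variation(r_1: float, r_2: float, alpha: float = ALPHA) -> float:
    """Relative variation index (R_1 - R_2) / (R_1 + R_2 + alpha).

    alpha (default 0.001) guards the zero denominator when both ratios are 0.
    Antisymmetric under swapping the cell lines.
    """
    if not (0 <= r_1 <= 1 and 0 <= r_2 <= 1):
        raise ValueError("overlap ratios must lie in [0, 1]")
    return (r_1 - r_2) / (r_1 + r_2 + alpha)


def outlier_pairs(all_pairs: list[PairDynamics]) -> list[PairDynamics]:
    """Flag pairs whose I_RV falls outside mu +/- 2*sigma (population sd).

    Mutates and returns the input list. With sigma = 0 nothing is flagged.
    """
    if len(all_pairs) < 2:
        raise ValueError("outlier detection needs at least two pairs")
    values = np.array([p.i_rv for p in all_pairs], dtype=float)
    mu = values.mean()
    sigma = values.std()  # population (ddof=0)
    for p in all_pairs:
        p.is_outlier = bool(sigma > 0 and abs(p.i_rv - mu) > 2 * sigma)
    return all_pairs


def average_overlap_ratio(
    track: FactorTrack, others: list[FactorTrack]
) -> AverageOverlap:
    """Average overlap ratio R_av = (1/m) sum_i x_i / N.

    x_i counts the distinct other FACTORS (not peaks) having at least one
    peak overlapping the i-th peak of ``track``; N = number of other factors.
    """
    if not others:
        raise ValueError("average overlap ratio needs at least one other factor")
    m = track.n_peaks
    if m == 0:
        raise ValueError(f"track {track.factor_name!r} has no peaks")
    x = np.zeros(m, dtype=np.int64)
    for other in others:
        x += _hit_mask(track, other).astype(np.int64)
    n_others = len(others)
    return AverageOverlap(
        factor_name=track.factor_name,
        x=x,
        n_others=n_others,
        r_av=float(x.mean() / n_others),
    )


def mine_combinations(
    pair_table: list[PairOverlap], k: int = 3, threshold: float = 0.6
) -> list[tuple[tuple[str, ...], float]]:
    """All k-sets of factors whose pairwise R_o all exceed ``threshold``.

    Edges are pairs with r_o > threshold (strict, 'more than 60%'). Returns
    [(sorted factor k-tuple, min edge weight)] sorted by min edge weight
    descending, ties by factor names.
    """
    weights: dict[frozenset, float] = {}
    factors: set[str] = set()
    for po in pair_table:
        if po.factor_a == po.factor_b:
            continue
        factors.update((po.factor_a, po.factor_b))
        weights[frozenset((po.factor_a, po.factor_b))] = po.r_o
    results = []
    for combo in itertools.combinations(sorted(factors), k):
        edge_ws = []
        ok = True
        for a, b in itertools.combinations(combo, 2):
            w = weights.get(frozenset((a, b)))
            if w is None or w <= threshold:
                ok = False
                break
            edge_ws.append(w)
        if ok:
            results.append((combo, min(edge_ws)))
    results.sort(key=lambda item: (-item[1], item[0]))
    return results
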