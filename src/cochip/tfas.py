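"""TF/HM association strength (TFAS), its pairwise correlation, and the
thresholded co-binding network.

The association strength of factor j on gene i sums the factor's peak
intensities weighted by exponential decay with distance from the TSS:

    A_ij = sum_k g_k * exp(-d_k / d0)

over peaks whose center lies in the gene's TSS window (+/- 20 kb by
default, half-open, oriented like the binning window), with decay length
d0 = 2 kb. Columns of the resulting genes x factors matrix are correlated
(Pearson) to score the interaction tendency of factor pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import FactorTrack, GeneModel
from .colocalization import PairDynamics
from .profile import FactorDynamics

__all__ = [
    "TFASConfig",
    "TFASMatrix",
    "PairCorrelation",
    "InteractionNetwork",
    "NetworkEdge",
    "tfas",
    "tfas_matrix",
    "pair_pcc",
    "build_network",
]


@dataclass(frozen=True)
class TFASConfig:
    """Decay length d0 and TSS window half-width, both in bp."""

    d0: float = 2000.0
    half_window: int = 20000
    use_summit: bool = False

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if self.half_window <= 0:
            raise ValueError(f"half_window must be > 0, got {self.half_window}")


@dataclass
class TFASMatrix:
    """Genes x factors association-strength matrix."""

    genes: list[str]
    factors: list[str]
    a: np.ndarray  # shape (n_genes, n_factors), nonnegative

    def column(self, factor: str) -> np.ndarray:
        return self.a[:, self.factors.index(factor)]

    def select(self, factors: list[str]) -> np.ndarray:
        idx = [self.factors.index(f) for f in factors]
        return self.a[:, idx]


@dataclass
class PairCorrelation:
    factor_x: str
    factor_y: str
    pcc: float  # NaN flags an undefined (constant-column) correlation


@dataclass(frozen=True)
class NetworkEdge:
    factor_a: str
    factor_b: str
    weight: float
    specificity: str  # GM12878_specific | K562_specific | unbiased


@dataclass
class InteractionNetwork:
    """Factor co-binding network: nodes carry the dynamics label, edges the
    cell-line specificity class derived from I_RV outlier status."""

    nodes: dict[str, str]  # factor -> dynamics label
    edges: list[NetworkEdge]


def _window_offsets(
    track: FactorTrack, gene: GeneModel, config: TFASConfig
) -> np.ndarray:
    """Absolute TSS distances of the track's peak points inside the gene's
    half-open, strand-oriented window; parallel array of signals attached."""
    chrom_arrays = track.by_chrom().get(gene.chrom)
    if chrom_arrays is None:
        return np.zeros(0), np.zeros(0)
    centers, _, signals = chrom_arrays
    if config.use_summit:
        pts, sigs = [], []
        for p in track.peaks:
            if p.chrom == gene.chrom:
                pts.append(p.point(use_summit=True))
                sigs.append(p.signal_value)
        pts = np.asarray(pts, dtype=np.int64)
        sigs = np.asarray(sigs, dtype=float)
        order = np.argsort(pts, kind="stable")
        centers, signals = pts[order], sigs[order]
    hw = config.half_window
    if gene.strand == "+":
        lo = np.searchsorted(centers, gene.tss - hw, side="left")
        hi = np.searchsorted(centers, gene.tss + hw, side="left")
    else:
        lo = np.searchsorted(centers, gene.tss - hw, side="right")
        hi = np.searchsorted(centers, gene.tss + hw, side="right")
    d = np.abs(centers[lo:hi] - gene.tss)
    return d, signals[lo:hi]


def tfas(track: FactorTrack, gene: GeneModel, config: TFASConfig = TFASConfig()) -> float:
    """Association strength A_ij = sum_k g_k exp(-d_k / d0) of one factor on
    one gene; 0.0 when no peak lies in the window."""
    d, g = _window_offsets(track, gene, config)
    if d.size == 0:
        return 0.0
    return float(np.sum(g * np.exp(-d / config.d0)))


def tfas_matrix(
    tracks: list[FactorTrack],
    genes: list[GeneModel],
    config: TFASConfig = TFASConfig(),
) -> TFASMatrix:
    """Complete genes x factors TFAS matrix with deterministic ordering
    (genes and factors in the order given)."""
    a = np.zeros((len(genes), len(tracks)), dtype=float)
    for j, track in enumerate(tracks):
        for i, gene in enumerate(genes):
            d, g = _window_offsets(track, gene, config)
            if d.size:
                a[i, j] = np.sum(g * np.exp(-d / config.d0))
    return TFASMatrix(
        genes=[g.gene_id for g in genes],
        factors=[t.factor_name for t in tracks],
        a=a,
    )


def pair_pcc(
    x_col: np.ndarray,
    y_col: np.ndarray,
    factor_x: str = "x",
    factor_y: str = "y",
) -> PairCorrelation:
    """Pearson correlation of two factors' TFAS columns.

    A constant column makes the correlation undefined; it is returned as NaN
    rather than raised, so callers can filter flagged pairs.
    """
    x = np.asarray(x_col, dtype=float)
    y = np.asarray(y_col, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("Pearson correlation needs n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(np.dot(xc, xc)) * float(np.dot(yc, yc)))
    if denom == 0.0:
        pcc = float("nan")
    else:
        pcc = float(np.dot(xc, yc) / denom)
        pcc = max(-1.0, min(1.0, pcc))
    return PairCorrelation(factor_x=factor_x, factor_y=factor_y, pcc=pcc)


def build_network(
    pair_pcc_table: list[PairCorrelation],
    pair_overlap_dynamics: list[PairDynamics],
    factor_dynamics: list[FactorDynamics],
    weight_threshold: float = 0.6,
    weight: str = "r_o",
) -> InteractionNetwork:
    """Thresholded factor interaction network.

    Edge weight is either the pair's best overlap ratio across the two cell
    lines (weight="r_o", default) or its TFAS Pearson correlation
    (weight="pcc"); edges require weight > weight_threshold. Edge
    specificity: an I_RV outlier pair is specific to the cell line where it
    overlaps more (sign of I_RV); other pairs are unbiased.
    """
    labels = {fd.factor_name: fd.label for fd in factor_dynamics}
    dyn = {
        frozenset((pd.factor_a, pd.factor_b)): pd
        for pd in pair_overlap_dynamics
    }
    pcc = {
        frozenset((pc.factor_x, pc.factor_y)): pc.pcc
        for pc in pair_pcc_table
    }
    for key in set(dyn) | set(pcc):
        for f in key:
            if f not in labels:
                raise ValueError(f"factor {f!r} missing from factor dynamics")

    edges = []
    for key, pd in sorted(dyn.items(), key=lambda kv: tuple(sorted(kv[0]))):
        if weight == "r_o":
            w = max(pd.r_1, pd.r_2)
        elif weight == "pcc":
            w = pcc.get(key, float("nan"))
        else:
            raise ValueError(f"unknown edge weight {weight!r}")
        if not (w > weight_threshold):  # NaN-safe
            continue
        if pd.is_outlier and pd.i_rv > 0:
            spec = "GM12878_specific"
        elif pd.is_outlier and pd.i_rv < 0:
            spec = "K562_specific"
        else:
            spec = "unbiased"
        a, b = sorted((pd.factor_a, pd.factor_b))
        edges.append(NetworkEdge(a, b, float(w), spec))
    return InteractionNetwork(nodes=dict(labels), edges=edges)
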