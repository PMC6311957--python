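"""Synthetic ChIP-seq / RNA-seq data with planted, recoverable structure.

The generator emulates the statistical features the pipeline's indices
measure, without any sequence content:

* gene annotations whose TSS windows never overlap (so the annotation filter
  keeps everything unless deliberately misconfigured);
* per-factor, per-cell-line peak tracks with controllable peak count, width
  distribution (lognormal, narrow for TFs, broad for HMs) and a fraction of
  peaks placed within +/- 2 kb of a TSS;
* planted pairwise co-localization: for a pair (A, B, co_rate) a fraction
  co_rate of A's peaks receives a coupled B peak strictly inside the overlap
  predicate, while B's remaining peaks are rejection-sampled away from every
  A peak, so the recovered overlap ratio estimates co_rate;
* planted cell-line enrichment: a factor with ratio f_true gets TSS-proximal
  placement probabilities 2*t*f/(1+f) and 2*t/(1+f) in the two cell lines
  (t = tss_enrichment), making the expected proximal peak-count ratio f_true;
* an FPKM table where expression is exp(beta * mean driver TFAS + noise),
  a noisy monotone function of the designated driver factors' association
  strength.

Identical config + seed produces byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import FactorTrack, GeneModel, GenomicInterval, Peak
from .io import (
    write_broadpeak,
    write_expression,
    write_gene_annotation,
    write_narrowpeak,
)
from .tfas import TFASConfig, TFASMatrix, tfas_matrix

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_expression",
    "write_dataset",
]

TSS_PROXIMAL_BP = 2000  # 'TSS-proximal' means within +/- this of a TSS
MIN_PEAK_WIDTH = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-cell-line dataset."""

    n_genes: int = 500
    chrom_length: int = 50_000_000
    chrom_name: str = "chr1"
    n_factors: int = 6
    n_hms: int = 0
    peaks_per_factor: int = 2000
    peak_width_mean: float = 300.0
    peak_width_sd: float = 150.0
    hm_width_mean: float = 1500.0
    hm_width_sd: float = 750.0
    tss_enrichment: float = 0.5
    signal_mean: float = 5.0
    cell_lines: tuple[str, ...] = ("cellA", "cellB")
    # (factor_a, factor_b, co_rate): plant co-localization of B onto A
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    # factor -> f_true: ratio of cell-line-1 to cell-line-2 proximal signal
    planted_enrichment: dict = field(default_factory=dict)
    driver_factors: tuple[str, ...] = ()
    beta: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def factor_names(self) -> list[str]:
        tfs = [f"TF{i + 1:02d}" for i in range(self.n_factors)]
        hms = [f"HM{i + 1:02d}" for i in range(self.n_hms)]
        return tfs + hms

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_factors + self.n_hms < 1:
            raise ValueError("need at least one gene and one factor")
        if self.peaks_per_factor < 1:
            raise ValueError("peaks_per_factor must be >= 1")
        if not (0 <= self.tss_enrichment <= 1):
            raise ValueError("tss_enrichment must be in [0, 1]")
        if len(self.cell_lines) < 1:
            raise ValueError("need at least one cell line")
        names = set(self.factor_names())
        coupled = set()
        for a, b, co_rate in self.planted_pairs:
            if a not in names or b not in names:
                raise ValueError(f"planted pair ({a}, {b}) names unknown factors")
            if a == b:
                raise ValueError("planted pair must involve two distinct factors")
            if not (0 <= co_rate <= 1):
                raise ValueError(f"co_rate must be in [0, 1], got {co_rate}")
            if b in coupled:
                raise ValueError(
                    f"factor {b!r} is the coupled member of more than one pair"
                )
            coupled.add(b)
        for f_name, f_true in self.planted_enrichment.items():
            if f_name not in names:
                raise ValueError(f"planted_enrichment names unknown factor {f_name!r}")
            if f_true <= 0:
                raise ValueError(f"f_true must be > 0, got {f_true}")
            if f_name in coupled:
                raise ValueError(
                    f"factor {f_name!r} cannot carry planted enrichment and be "
                    "the coupled member of a planted pair"
                )
        for d in self.driver_factors:
            if d not in names:
                raise ValueError(f"driver factor {d!r} is not a simulated factor")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # feasibility: genes must fit with non-overlapping +/- 20 kb windows
        spacing = self.chrom_length // (self.n_genes + 1)
        if spacing < 2 * 20000 + 2:
            raise ValueError(
                f"chrom_length {self.chrom_length} too short for {self.n_genes} "
                "genes with non-overlapping 20 kb TSS windows"
            )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with given mean and sd."""
    if mean <= 0:
        raise ValueError("width mean must be > 0")
    if sd <= 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _proximal_probability(
    config: SimulationConfig, factor: str, cell_index: int
) -> float:
    t = config.tss_enrichment
    f_true = config.planted_enrichment.get(factor)
    if f_true is None or cell_index > 1:
        return t
    p = 2 * t * f_true / (1 + f_true) if cell_index == 0 else 2 * t / (1 + f_true)
    if p > 1:
        raise ValueError(
            f"planted enrichment f_true={f_true} for {factor!r} needs proximal "
            f"probability {p:.3f} > 1; lower tss_enrichment or f_true"
        )
    return p


def _draw_widths(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    mu, sigma = _lognormal_params(mean, sd)
    w = rng.lognormal(mu, sigma, size=n)
    return np.maximum(np.rint(w).astype(np.int64), MIN_PEAK_WIDTH)


def _make_peaks(
    factor: str,
    centers: np.ndarray,
    widths: np.ndarray,
    signals: np.ndarray,
    chrom: str,
) -> list[Peak]:
    peaks = []
    for i, (c, w, g) in enumerate(zip(centers, widths, signals)):
        start = int(max(0, c - w // 2))
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, start + int(w), "."),
                signal_value=float(g),
                summit_offset=int(w) // 2,
                name=f"{factor}_{i + 1}",
            )
        )
    return peaks


def _base_track(
    config: SimulationConfig,
    rng: np.random.Generator,
    factor: str,
    cell_line: str,
    cell_index: int,
    tss_positions: np.ndarray,
) -> FactorTrack:
    n = config.peaks_per_factor
    is_hm = factor.startswith("HM")
    wm, ws = (
        (config.hm_width_mean, config.hm_width_sd)
        if is_hm
        else (config.peak_width_mean, config.peak_width_sd)
    )
    widths = _draw_widths(rng, n, wm, ws)
    signals = rng.lognormal(*_lognormal_params(config.signal_mean, config.signal_mean / 2), size=n)
    p = _proximal_probability(config, factor, cell_index)
    proximal = rng.random(n) < p
    centers = np.empty(n, dtype=np.int64)
    margin = int(widths.max()) + 1
    n_prox = int(proximal.sum())
    if n_prox:
        gene_idx = rng.integers(0, tss_positions.size, size=n_prox)
        offsets = rng.integers(-TSS_PROXIMAL_BP, TSS_PROXIMAL_BP + 1, size=n_prox)
        centers[proximal] = tss_positions[gene_idx] + offsets
    n_bg = n - n_prox
    if n_bg:
        centers[~proximal] = rng.integers(
            margin, config.chrom_length - margin, size=n_bg
        )
    centers = np.clip(centers, margin, config.chrom_length - margin)
    return FactorTrack(
        factor_name=factor,
        cell_line=cell_line,
        peaks=_make_peaks(factor, centers, widths, signals, config.chrom_name),
        factor_class="HM" if is_hm else "TF",
    )


def _coupled_track(
    config: SimulationConfig,
    rng: np.random.Generator,
    factor_b: str,
    track_a: FactorTrack,
    co_rate: float,
    cell_line: str,
) -> FactorTrack:
    """Rebuild B's peaks coupled to A: co_rate of A's peaks get a B peak
    strictly inside the overlap predicate; the rest are placed so that no
    accidental overlap with any A peak is possible."""
    a_centers = np.array([p.center for p in track_a.peaks], dtype=np.int64)
    a_widths = np.array([p.width for p in track_a.peaks], dtype=np.int64)
    order = np.argsort(a_centers, kind="stable")
    a_centers_sorted = a_centers[order]
    max_wa = int(a_widths.max()) if a_widths.size else 0
    is_hm = factor_b.startswith("HM")
    wm, ws = (
        (config.hm_width_mean, config.hm_width_sd)
        if is_hm
        else (config.peak_width_mean, config.peak_width_sd)
    )
    n = track_a.n_peaks
    widths = _draw_widths(rng, n, wm, ws)
    signals = rng.lognormal(
        *_lognormal_params(config.signal_mean, config.signal_mean / 2), size=n
    )
    coupled = rng.random(n) < co_rate
    centers = np.empty(n, dtype=np.int64)
    margin = int(widths.max()) + max_wa + 2
    for i in range(n):
        w_b = int(widths[i])
        if coupled[i]:
            max_off = (int(a_widths[i]) + w_b) // 2 - 1
            off = int(rng.integers(-max_off, max_off + 1)) if max_off > 0 else 0
            centers[i] = a_centers[i] + off
        else:
            # keep strictly clear of every A peak: distance to the nearest A
            # center must exceed (max_wa + w_b) / 2
            min_gap = (max_wa + w_b) // 2 + 1
            for _attempt in range(1000):
                c = int(rng.integers(margin, config.chrom_length - margin))
                j = np.searchsorted(a_centers_sorted, c)
                near = min(
                    abs(c - a_centers_sorted[j - 1]) if j > 0 else np.iinfo(np.int64).max,
                    abs(a_centers_sorted[j] - c) if j < a_centers_sorted.size else np.iinfo(np.int64).max,
                )
                if near >= min_gap:
                    centers[i] = c
                    break
            else:
                raise ValueError(
                    "could not place an uncoupled peak away from the partner "
                    "track; chromosome too crowded for the planted pair"
                )
    # only uncoupled centers are clipped: moving a coupled peak would break
    # its planted overlap
    centers[~coupled] = np.clip(
        centers[~coupled], margin, config.chrom_length - margin
    )
    return FactorTrack(
        factor_name=factor_b,
        cell_line=cell_line,
        peaks=_make_peaks(factor_b, centers, widths, signals, config.chrom_name),
        factor_class="HM" if is_hm else "TF",
    )


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, dict[str, FactorTrack]]]:
    """Generate the gene annotation and all peak tracks.

    Returns (genes, {cell_line: {factor_name: FactorTrack}}). Gene TSSs sit
    on a jittered grid spaced > 2 x 20 kb + 1 apart so the non-overlap filter
    keeps all of them; strands are random.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    spacing = config.chrom_length // (config.n_genes + 1)
    slack = max(0, (spacing - (2 * 20000 + 2)) // 2)
    jitter_bound = min(2000, slack)
    base = (np.arange(config.n_genes, dtype=np.int64) + 1) * spacing
    if jitter_bound > 0:
        base = base + rng.integers(-jitter_bound, jitter_bound + 1, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = [
        GeneModel(f"gene{i + 1:05d}", config.chrom_name, int(t), str(s))
        for i, (t, s) in enumerate(zip(base, strands))
    ]
    tss_positions = np.asarray([g.tss for g in genes], dtype=np.int64)

    tracks: dict[str, dict[str, FactorTrack]] = {}
    for ci, cell in enumerate(config.cell_lines):
        cell_tracks: dict[str, FactorTrack] = {}
        for factor in config.factor_names():
            cell_tracks[factor] = _base_track(
                config, rng, factor, cell, ci, tss_positions
            )
        for factor_a, factor_b, co_rate in config.planted_pairs:
            cell_tracks[factor_b] = _coupled_track(
                config, rng, factor_b, cell_tracks[factor_a], co_rate, cell
            )
        tracks[cell] = cell_tracks
    return genes, tracks


def simulate_expression(
    genes: Sequence[GeneModel],
    tfas: TFASMatrix,
    driver_factors: Sequence[str],
    noise_sd: float,
    seed: int,
    beta: float = 1.0,
) -> dict[str, float]:
    """FPKM_i = exp(beta * mean driver TFAS_i + eps_i), eps ~ N(0, noise_sd).

    The exp link keeps FPKM strictly positive and makes expression a noisy
    monotone function of the drivers' association strength.
    """
    gene_ids = [g.gene_id for g in genes]
    missing = set(gene_ids) - set(tfas.genes)
    if missing:
        raise ValueError(f"TFAS matrix does not cover all genes, e.g. {sorted(missing)[:3]}")
    for d in driver_factors:
        if d not in tfas.factors:
            raise ValueError(f"unknown driver factor {d!r}")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rng = np.random.default_rng(seed)
    row = {g: i for i, g in enumerate(tfas.genes)}
    rows = np.array([row[g] for g in gene_ids])
    if driver_factors:
        score = tfas.select(list(driver_factors))[rows].mean(axis=1)
    else:
        score = np.zeros(len(gene_ids))
    eps = rng.normal(0.0, noise_sd, size=len(gene_ids)) if noise_sd > 0 else 0.0
    fpkm = np.exp(beta * score + eps)
    return {g: float(v) for g, v in zip(gene_ids, fpkm)}


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Simulate a full dataset and write it in the formats the readers accept.

    Layout: <outdir>/genes.tsv, <outdir>/<cell>/<factor>.narrowPeak (TFs) or
    .broadPeak (HMs), <outdir>/expression_<cell>.tsv. Returns a manifest of
    the written paths. Deterministic: same config + seed, same bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, tracks = simulate_genome(config)
    genes_path = outdir / "genes.tsv"
    write_gene_annotation(genes, genes_path)
    manifest = {"genes": str(genes_path), "peaks": {}, "expression": {}}
    tfas_cfg = TFASConfig()
    for ci, cell in enumerate(config.cell_lines):
        cell_dir = outdir / cell
        cell_dir.mkdir(exist_ok=True)
        paths = {}
        for factor, track in tracks[cell].items():
            if track.factor_class == "HM":
                path = cell_dir / f"{factor}.broadPeak"
                write_broadpeak(track, path)
            else:
                path = cell_dir / f"{factor}.narrowPeak"
                write_narrowpeak(track, path)
            paths[factor] = str(path)
        manifest["peaks"][cell] = paths
        ordered = [tracks[cell][f] for f in config.factor_names()]
        mat = tfas_matrix(ordered, genes, tfas_cfg)
        expr = simulate_expression(
            genes,
            mat,
            config.driver_factors,
            config.noise_sd,
            seed=config.seed + 1000 + ci,
            beta=config.beta,
        )
        expr_path = outdir / f"expression_{cell}.tsv"
        write_expression(expr, expr_path)
        manifest["expression"][cell] = str(expr_path)
    return manifest
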