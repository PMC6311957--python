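"""End-to-end orchestration: ingest -> filter -> profile -> colocalize ->
TFAS -> network -> predict -> report.

Stages write plain TSV intermediates into the output directory and record
them, with sha256 content hashes, in ``MANIFEST.json``. A resumed run reloads
hash-matching stage outputs instead of recomputing them. All randomness flows
from the config seed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocalization import (
    PairDynamics,
    PairOverlap,
    average_overlap_ratio,
    mine_combinations,
    outlier_pairs,
    overlap_ratio,
    relative_variation,
)
from .core import FactorTrack
from .expression import (
    prediction_difference,
    correlate_dynamics,
    quartile_labels,
    svm_scan,
)
from .io import (
    filter_nonoverlapping_genes,
    read_broadpeak,
    read_expression,
    read_gene_annotation,
    read_narrowpeak,
)
from .profile import FactorDynamics, bin_peaks, signal_intensity, dynamics_indices
from .tfas import (
    PairCorrelation,
    TFASConfig,
    TFASMatrix,
    build_network,
    pair_pcc,
    tfas_matrix,
)

logger = logging.getLogger("cochip")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location of one pipeline run.

    Parameter defaults are the analysis constants: 20 kb TSS half-window,
    200 bp bins, 2 kb TFAS decay length.
    """

    cell_lines: list[str]
    peak_dirs: dict  # cell line -> directory of *.narrowPeak / *.broadPeak
    annotation: str
    expression: dict  # cell line -> 2-column TSV path
    out_dir: str
    annotation_dialect: str = "tsv"
    half_window: int = 20000
    bin_size: int = 200
    d0: float = 2000.0
    count_mode: str = "matched"
    alpha: float = 0.001
    network_threshold: float = 0.6
    network_weight: str = "r_o"
    clique_k: int = 3
    clique_threshold: float = 0.6
    svm_folds: int = 5
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    svm_gamma: str = "auto"
    use_summit: bool = False
    rename_chroms: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class RunReport:
    stage_counts: dict
    files: dict  # name -> path
    timings: dict  # stage -> seconds
    config_echo: dict
    version: str
    skipped_stages: list
    correlation_d_acc_d_signal: Optional[float] = None


def validate_config(config: PipelineConfig) -> list[str]:
    """Non-raising config validation; returns a list of diagnostics."""
    diags: list[str] = []
    if config.half_window <= 0 or config.bin_size <= 0:
        diags.append("half_window and bin_size must be positive")
    elif config.half_window % config.bin_size != 0:
        diags.append(
            f"half_window ({config.half_window}) is not divisible by "
            f"bin_size ({config.bin_size})"
        )
    if config.d0 <= 0:
        diags.append(f"d0 must be > 0, got {config.d0}")
    if config.count_mode not in ("matched", "pairs"):
        diags.append(f"unknown count_mode {config.count_mode!r}")
    if not Path(config.annotation).exists():
        diags.append(f"annotation file missing: {config.annotation}")
    for cell in config.cell_lines:
        d = config.peak_dirs.get(cell)
        if d is None or not Path(d).is_dir():
            diags.append(f"peak directory missing for cell line {cell!r}: {d}")
        e = config.expression.get(cell)
        if e is None or not Path(e).exists():
            diags.append(f"expression table missing for cell line {cell!r}: {e}")
    # factor-class collisions: the same factor must have one format everywhere
    classes: dict[str, str] = {}
    for cell in config.cell_lines:
        d = config.peak_dirs.get(cell)
        if d is None or not Path(d).is_dir():
            continue
        for path in sorted(Path(d).iterdir()):
            if path.suffix == ".narrowPeak":
                fc = "TF"
            elif path.suffix == ".broadPeak":
                fc = "HM"
            else:
                continue
            name = path.stem
            if classes.setdefault(name, fc) != fc:
                diags.append(
                    f"factor {name!r} appears as both narrowPeak and broadPeak "
                    "across cell lines"
                )
    return diags


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "MANIFEST.json"
        self.data = {"complete": False, "files": {}}
        if self.path.exists():
            try:
                self.data = json.loads(self.path.read_text())
            except (json.JSONDecodeError, OSError):
                pass

    def record(self, name: str, path: Path) -> None:
        self.data["files"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }
        self.flush()

    def matches(self, name: str) -> bool:
        entry = self.data["files"].get(name)
        if entry is None:
            return False
        p = Path(entry["path"])
        return p.exists() and _sha256(p) == entry["sha256"]

    def flush(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _read_tracks(config: PipelineConfig, cell: str) -> dict[str, FactorTrack]:
    tracks: dict[str, FactorTrack] = {}
    for path in sorted(Path(config.peak_dirs[cell]).iterdir()):
        if path.suffix == ".narrowPeak":
            track = read_narrowpeak(
                path, cell_line=cell, rename_chroms=config.rename_chroms
            )
        elif path.suffix == ".broadPeak":
            track = read_broadpeak(
                path, cell_line=cell, rename_chroms=config.rename_chroms
            )
        else:
            continue
        tracks[track.factor_name] = track
    return tracks


# ---------------------------------------------------------------- stage I/O


def _write_dynamics(dyn: list[FactorDynamics], path: Path) -> None:
    rows = [
        {
            "factor": d.factor_name,
            "f": d.f,
            "d_signal": d.d_signal,
            "label": d.label,
            "peak_count_diff": d.peak_count_diff,
        }
        for d in dyn
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _load_dynamics(path: Path) -> list[FactorDynamics]:
    df = pd.read_csv(path, sep="\t")
    return [
        FactorDynamics(
            factor_name=r.factor,
            f=float(r.f),
            d_signal=float(r.d_signal),
            label=r.label,
            peak_count_diff=None if pd.isna(r.peak_count_diff) else float(r.peak_count_diff),
        )
        for r in df.itertuples()
    ]


def _write_pairs(pairs: list[PairDynamics], path: Path) -> None:
    rows = [
        {
            "factor_a": p.factor_a,
            "factor_b": p.factor_b,
            "r_1": p.r_1,
            "r_2": p.r_2,
            "i_rv": p.i_rv,
            "outlier": int(p.is_outlier),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _load_pairs(path: Path) -> list[PairDynamics]:
    df = pd.read_csv(path, sep="\t")
    return [
        PairDynamics(
            factor_a=r.factor_a,
            factor_b=r.factor_b,
            r_1=float(r.r_1),
            r_2=float(r.r_2),
            i_rv=float(r.i_rv),
            is_outlier=bool(r.outlier),
        )
        for r in df.itertuples()
    ]


def _write_tfas(mat: TFASMatrix, path: Path) -> None:
    pd.DataFrame(mat.a, index=mat.genes, columns=mat.factors).to_csv(
        path, sep="\t", index_label="gene_id", float_format="%.10g"
    )


def _load_tfas(path: Path) -> TFASMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return TFASMatrix(
        genes=[str(g) for g in df.index],
        factors=[str(c) for c in df.columns],
        a=df.to_numpy(dtype=float),
    )


def _write_pcc(pccs: list[PairCorrelation], path: Path) -> None:
    rows = [
        {"factor_x": p.factor_x, "factor_y": p.factor_y, "pcc": p.pcc}
        for p in pccs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _load_pcc(path: Path) -> list[PairCorrelation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PairCorrelation(r.factor_x, r.factor_y, float(r.pcc))
        for r in df.itertuples()
    ]


# -------------------------------------------------------------- the pipeline


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunReport:
    """Execute all stages in dependency order and write every result table.

    With resume=True, stages whose recorded outputs still hash-match the
    manifest are reloaded from their TSVs instead of recomputed. A stage
    failure raises StageError naming the stage; partial outputs stay on disk
    with the manifest marked incomplete.
    """
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid config:\n" + "\n".join(f"- {d}" for d in diags))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    manifest.data["complete"] = False
    manifest.data["config"] = {
        k: (dict(v) if isinstance(v, dict) else v)
        for k, v in asdict(config).items()
    }
    manifest.flush()

    counts: dict = {}
    timings: dict = {}
    skipped: list[str] = []
    files: dict = {}
    stage = "ingest"
    try:
        # ---------------------------------------------------------- ingest
        t0 = time.perf_counter()
        genes = read_gene_annotation(
            config.annotation,
            dialect=config.annotation_dialect,
            rename_chroms=config.rename_chroms,
        )
        kept = filter_nonoverlapping_genes(genes, config.half_window)
        tracks = {cell: _read_tracks(config, cell) for cell in config.cell_lines}
        factors = sorted(
            set.intersection(*(set(t) for t in tracks.values()))
        )
        if not factors:
            raise ValueError("no factor is present in every cell line")
        counts["genes_total"] = len(genes)
        counts["genes_kept"] = len(kept)
        counts["factors"] = len(factors)
        counts["peaks"] = {
            cell: {f: tracks[cell][f].n_peaks for f in factors}
            for cell in config.cell_lines
        }
        timings["ingest"] = time.perf_counter() - t0
        logger.info(
            "ingest: %d/%d genes kept, %d shared factors",
            len(kept), len(genes), len(factors),
        )
        cell_1 = config.cell_lines[0]
        cell_2 = config.cell_lines[1] if len(config.cell_lines) > 1 else None

        # --------------------------------------------------------- profile
        stage = "profile"
        t0 = time.perf_counter()
        dyn_path = out / "factor_dynamics.tsv"
        profile_paths = {
            cell: out / f"signal_profiles_{cell}.tsv" for cell in config.cell_lines
        }
        if resume and cell_2 and manifest.matches("factor_dynamics"):
            dynamics = _load_dynamics(dyn_path)
            logger.info("profile: reloaded %d factor dynamics", len(dynamics))
        else:
            profiles: dict[str, dict[str, object]] = {}
            for cell in config.cell_lines:
                rows = {}
                for f in factors:
                    bm = bin_peaks(
                        tracks[cell][f], kept, config.half_window,
                        config.bin_size, use_summit=config.use_summit,
                    )
                    rows[f] = signal_intensity(bm)
                profiles[cell] = rows
                df = pd.DataFrame(
                    {f: rows[f].s for f in factors},
                ).T
                df.columns = [f"bin{j + 1}" for j in range(df.shape[1])]
                df.to_csv(profile_paths[cell], sep="\t", index_label="factor")
                manifest.record(f"signal_profiles_{cell}", profile_paths[cell])
            dynamics = []
            if cell_2:
                for f in factors:
                    dynamics.append(
                        dynamics_indices(
                            profiles[cell_1][f],
                            profiles[cell_2][f],
                            peak_counts=(
                                tracks[cell_1][f].n_peaks,
                                tracks[cell_2][f].n_peaks,
                            ),
                        )
                    )
                _write_dynamics(dynamics, dyn_path)
                manifest.record("factor_dynamics", dyn_path)
            else:
                skipped.append("dynamics (single cell line)")
                logger.warning("profile: single cell line, no dynamics indices")
        for cell in config.cell_lines:
            files[f"signal_profiles_{cell}"] = str(profile_paths[cell])
        if cell_2:
            files["factor_dynamics"] = str(dyn_path)
        counts["dynamics"] = len(dynamics) if cell_2 else 0
        timings["profile"] = time.perf_counter() - t0

        # ----------------------------------------------------------- coloc
        stage = "colocalization"
        t0 = time.perf_counter()
        tf_factors = [f for f in factors if tracks[cell_1][f].factor_class == "TF"]
        pair_dyn: list[PairDynamics] = []
        pairs_path = out / "pairs.tsv"
        rav_path = out / "rav.tsv"
        if len(tf_factors) < 2 or not cell_2:
            skipped.append("colocalization")
            logger.warning(
                "colocalization skipped: needs >= 2 TF tracks in two cell lines"
            )
        elif resume and manifest.matches("pairs") and manifest.matches("rav"):
            pair_dyn = _load_pairs(pairs_path)
            logger.info("colocalization: reloaded %d pairs", len(pair_dyn))
        else:
            per_cell_ro: dict[str, dict[frozenset, float]] = {}
            for cell in (cell_1, cell_2):
                ros = {}
                for a, b in itertools.combinations(tf_factors, 2):
                    po = overlap_ratio(
                        tracks[cell][a], tracks[cell][b], config.count_mode
                    )
                    ros[frozenset((a, b))] = po.r_o
                per_cell_ro[cell] = ros
            for a, b in itertools.combinations(tf_factors, 2):
                key = frozenset((a, b))
                r1 = per_cell_ro[cell_1][key]
                r2 = per_cell_ro[cell_2][key]
                pair_dyn.append(
                    PairDynamics(
                        factor_a=a, factor_b=b, r_1=r1, r_2=r2,
                        i_rv=relative_variation(r1, r2, config.alpha),
                    )
                )
            if len(pair_dyn) >= 2:
                outlier_pairs(pair_dyn)
            _write_pairs(pair_dyn, pairs_path)
            manifest.record("pairs", pairs_path)
            # average overlap ratio of every factor vs the other factors
            rav_rows = []
            for cell in (cell_1, cell_2):
                for f in factors:
                    others = [tracks[cell][g] for g in factors if g != f]
                    if not others or tracks[cell][f].n_peaks == 0:
                        continue
                    ao = average_overlap_ratio(tracks[cell][f], others)
                    rav_rows.append(
                        {"cell_line": cell, "factor": f, "r_av": ao.r_av}
                    )
            pd.DataFrame(rav_rows).to_csv(rav_path, sep="\t", index=False)
            manifest.record("rav", rav_path)
            # k-clique combinations per cell line
            for cell in (cell_1, cell_2):
                table = [
                    PairOverlap(a, b, 0.0, 0, 0, per_cell_ro[cell][frozenset((a, b))])
                    for a, b in itertools.combinations(tf_factors, 2)
                ]
                cliques = mine_combinations(
                    table, k=config.clique_k, threshold=config.clique_threshold
                )
                cpath = out / f"combinations_{cell}.tsv"
                pd.DataFrame(
                    [
                        {"factors": "+".join(c), "min_r_o": w}
                        for c, w in cliques
                    ]
                ).to_csv(cpath, sep="\t", index=False)
                manifest.record(f"combinations_{cell}", cpath)
                files[f"combinations_{cell}"] = str(cpath)
        if pair_dyn:
            files["pairs"] = str(pairs_path)
            files["rav"] = str(rav_path)
        counts["tf_pairs"] = len(pair_dyn)
        counts["outlier_pairs"] = sum(p.is_outlier for p in pair_dyn)
        timings["colocalization"] = time.perf_counter() - t0

        # ------------------------------------------------------------ tfas
        stage = "tfas"
        t0 = time.perf_counter()
        tfas_cfg = TFASConfig(
            d0=config.d0, half_window=config.half_window,
            use_summit=config.use_summit,
        )
        tfas_mats: dict[str, TFASMatrix] = {}
        pcc_tables: dict[str, list[PairCorrelation]] = {}
        for cell in config.cell_lines:
            tpath = out / f"tfas_{cell}.tsv"
            ppath = out / f"pcc_{cell}.tsv"
            if resume and manifest.matches(f"tfas_{cell}") and manifest.matches(f"pcc_{cell}"):
                tfas_mats[cell] = _load_tfas(tpath)
                pcc_tables[cell] = _load_pcc(ppath)
            else:
                mat = tfas_matrix(
                    [tracks[cell][f] for f in factors], kept, tfas_cfg
                )
                tfas_mats[cell] = mat
                _write_tfas(mat, tpath)
                manifest.record(f"tfas_{cell}", tpath)
                pccs = [
                    pair_pcc(mat.column(a), mat.column(b), a, b)
                    for a, b in itertools.combinations(factors, 2)
                ]
                pcc_tables[cell] = pccs
                _write_pcc(pccs, ppath)
                manifest.record(f"pcc_{cell}", ppath)
            files[f"tfas_{cell}"] = str(tpath)
            files[f"pcc_{cell}"] = str(ppath)
        timings["tfas"] = time.perf_counter() - t0

        # --------------------------------------------------------- network
        stage = "network"
        t0 = time.perf_counter()
        if pair_dyn and cell_2:
            net = build_network(
                pcc_tables[cell_1],
                pair_dyn,
                dynamics,
                weight_threshold=config.network_threshold,
                weight=config.network_weight,
            )
            npath = out / "network_edges.tsv"
            pd.DataFrame(
                [
                    {
                        "factor_a": e.factor_a,
                        "factor_b": e.factor_b,
                        "weight": e.weight,
                        "specificity": e.specificity,
                        "label_a": net.nodes[e.factor_a],
                        "label_b": net.nodes[e.factor_b],
                    }
                    for e in net.edges
                ]
            ).to_csv(npath, sep="\t", index=False)
            manifest.record("network_edges", npath)
            files["network_edges"] = str(npath)
            counts["network_edges"] = len(net.edges)
        else:
            skipped.append("network")
            logger.warning("network skipped: no pair table available")
        timings["network"] = time.perf_counter() - t0

        # --------------------------------------------------------- predict
        stage = "predict"
        t0 = time.perf_counter()
        metrics_rows = []
        acc: dict[str, dict[str, float]] = {}
        for cell in config.cell_lines:
            expr = read_expression(config.expression[cell])
            expr = {g: v for g, v in expr.items() if g in set(tfas_mats[cell].genes)}
            labels = quartile_labels(expr)
            feature_sets = [(f,) for f in factors] + [tuple(factors)]
            res = svm_scan(
                tfas_mats[cell], labels, feature_sets,
                folds=config.svm_folds, seed=config.seed,
                c=config.svm_c, kernel=config.svm_kernel,
                gamma=config.svm_gamma,
            )
            acc[cell] = {}
            for feats, m in res.items():
                name = "+".join(feats) if len(feats) < len(factors) else "ALL"
                metrics_rows.append(
                    {
                        "cell_line": cell, "features": name,
                        "sn": m.sn, "sp": m.sp, "acc": m.acc,
                    }
                )
                if len(feats) == 1:
                    acc[cell][feats[0]] = m.acc
        mpath = out / "prediction_metrics.tsv"
        pd.DataFrame(metrics_rows).to_csv(mpath, sep="\t", index=False)
        manifest.record("prediction_metrics", mpath)
        files["prediction_metrics"] = str(mpath)
        corr = None
        if cell_2:
            comparisons = [
                prediction_difference(acc[cell_1][f], acc[cell_2][f], f)
                for f in factors
            ]
            dpath = out / "d_acc.tsv"
            pd.DataFrame(
                [
                    {
                        "factor": pc.factor_name, "acc_1": pc.acc_1,
                        "acc_2": pc.acc_2, "d_acc": pc.d_acc,
                    }
                    for pc in comparisons
                ]
            ).to_csv(dpath, sep="\t", index=False)
            manifest.record("d_acc", dpath)
            files["d_acc"] = str(dpath)
            if len(factors) >= 3:
                d_signal_by_factor = {d.factor_name: d.d_signal for d in dynamics}
                corr = correlate_dynamics(
                    [pc.d_acc for pc in comparisons],
                    [d_signal_by_factor[pc.factor_name] for pc in comparisons],
                )
                counts["pcc_d_acc_d_signal"] = corr
        timings["predict"] = time.perf_counter() - t0
    except Exception as exc:
        manifest.flush()
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.data["complete"] = True
    manifest.flush()
    files["manifest"] = str(manifest.path)
    return RunReport(
        stage_counts=counts,
        files=files,
        timings=timings,
        config_echo=asdict(config),
        version=__version__,
        skipped_stages=skipped,
        correlation_d_acc_d_signal=corr,
    )
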