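"""The synthetic-data generator: determinism, planted structure recovery,
and config validation."""

import filecmp
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from cochip.colocalization import overlap_ratio
from cochip.io import (
    filter_nonoverlapping_genes,
    read_broadpeak,
    read_expression,
    read_gene_annotation,
    read_narrowpeak,
)
from cochip.profile import (
    LABEL_FIRST_RICH,
    LABEL_SECOND_RICH,
    bin_peaks,
    dynamics_indices,
    signal_intensity,
)
from cochip.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genome,
    write_dataset,
)
from cochip.tfas import tfas_matrix


SMALL = SimulationConfig(
    n_genes=60,
    chrom_length=6_000_000,
    n_factors=3,
    n_hms=1,
    peaks_per_factor=300,
    seed=11,
)


class TestGenomeStructure:
    def test_gene_windows_never_overlap(self):
        genes, _ = simulate_genome(SMALL)
        assert filter_nonoverlapping_genes(genes) == genes

    def test_counts_and_names(self):
        genes, tracks = simulate_genome(SMALL)
        assert len(genes) == 60
        for cell in SMALL.cell_lines:
            assert set(tracks[cell]) == {"TF01", "TF02", "TF03", "HM01"}
            for track in tracks[cell].values():
                assert track.n_peaks == 300

    def test_peaks_stay_on_the_chromosome(self):
        _, tracks = simulate_genome(SMALL)
        for cell_tracks in tracks.values():
            for track in cell_tracks.values():
                for p in track.peaks:
                    assert 0 <= p.start < p.end <= SMALL.chrom_length

    def test_hm_peaks_are_systematically_wider(self):
        _, tracks = simulate_genome(SMALL)
        tf_w = np.mean([p.width for p in tracks["cellA"]["TF01"].peaks])
        hm_w = np.mean([p.width for p in tracks["cellA"]["HM01"].peaks])
        assert hm_w > 2 * tf_w

    def test_same_seed_same_genome(self):
        g1, t1 = simulate_genome(SMALL)
        g2, t2 = simulate_genome(SMALL)
        assert g1 == g2
        assert t1["cellA"]["TF01"].peaks == t2["cellA"]["TF01"].peaks

    def test_different_seed_different_genome(self):
        _, t1 = simulate_genome(SMALL)
        _, t2 = simulate_genome(replace(SMALL, seed=12))
        assert t1["cellA"]["TF01"].peaks != t2["cellA"]["TF01"].peaks


class TestPlantedColocalization:
    @staticmethod
    def coloc_config(co_rate, seed=0):
        # tss_enrichment=0 so TSS clustering cannot create accidental overlap
        return SimulationConfig(
            n_genes=50,
            chrom_length=5_000_000,
            n_factors=2,
            peaks_per_factor=400,
            tss_enrichment=0.0,
            planted_pairs=(("TF01", "TF02", co_rate),),
            seed=seed,
        )

    def test_co_rate_zero_gives_exactly_zero_overlap(self):
        _, tracks = simulate_genome(self.coloc_config(0.0))
        po = overlap_ratio(tracks["cellA"]["TF01"], tracks["cellA"]["TF02"])
        assert po.r_o == 0.0

    def test_co_rate_one_gives_exactly_full_overlap(self):
        _, tracks = simulate_genome(self.coloc_config(1.0))
        po = overlap_ratio(tracks["cellA"]["TF01"], tracks["cellA"]["TF02"])
        assert po.r_o == 1.0

    def test_co_rate_half_is_recovered_in_expectation(self):
        ratios = [
            overlap_ratio(
                t["cellA"]["TF01"], t["cellA"]["TF02"]
            ).r_o
            for _, t in (
                simulate_genome(self.coloc_config(0.5, seed=s)) for s in range(8)
            )
        ]
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)


class TestPlantedEnrichment:
    @staticmethod
    def measured_dynamics(f_true, seed=0):
        # sparse genome so uniform background peaks inside the TSS windows
        # cannot dilute the planted proximal ratio toward 1
        config = SimulationConfig(
            n_genes=150,
            chrom_length=60_000_000,
            n_factors=1,
            peaks_per_factor=3000,
            tss_enrichment=0.5,
            planted_enrichment={"TF01": f_true},
            seed=seed,
        )
        genes, tracks = simulate_genome(config)
        p1 = signal_intensity(bin_peaks(tracks["cellA"]["TF01"], genes))
        p2 = signal_intensity(bin_peaks(tracks["cellB"]["TF01"], genes))
        return dynamics_indices(p1, p2)

    def test_strong_first_cell_enrichment_classified(self):
        d = self.measured_dynamics(4.0)
        assert d.label == LABEL_FIRST_RICH

    def test_strong_second_cell_enrichment_classified(self):
        d = self.measured_dynamics(0.25)
        assert d.label == LABEL_SECOND_RICH

    def test_balanced_factor_near_unity_ratio(self):
        d = self.measured_dynamics(1.0)
        assert d.f == pytest.approx(1.0, abs=0.25)

    def test_infeasible_enrichment_probability_rejected(self):
        config = SimulationConfig(
            tss_enrichment=0.9, planted_enrichment={"TF01": 10.0}
        )
        with pytest.raises(ValueError, match="probability"):
            simulate_genome(config)


class TestExpression:
    def test_noise_free_expression_is_monotone_in_driver_tfas(self):
        genes, tracks = simulate_genome(SMALL)
        mat = tfas_matrix(list(tracks["cellA"].values()), genes)
        expr = simulate_expression(genes, mat, ("TF01",), noise_sd=0.0, seed=0)
        score = mat.column("TF01")
        fpkm = np.array([expr[g.gene_id] for g in genes])
        order = np.argsort(score)
        assert np.all(np.diff(fpkm[order]) >= 0)

    def test_unknown_driver_rejected(self):
        genes, tracks = simulate_genome(SMALL)
        mat = tfas_matrix(list(tracks["cellA"].values()), genes)
        with pytest.raises(ValueError, match="driver"):
            simulate_expression(genes, mat, ("TF99",), 0.5, seed=0)

    def test_matrix_must_cover_all_genes(self):
        genes, tracks = simulate_genome(SMALL)
        mat = tfas_matrix(list(tracks["cellA"].values()), genes[:-1])
        with pytest.raises(ValueError, match="cover"):
            simulate_expression(genes, mat, (), 0.5, seed=0)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(n_genes=0), "at least one gene"),
            (dict(peaks_per_factor=0), "peaks_per_factor"),
            (dict(tss_enrichment=1.5), "tss_enrichment"),
            (dict(cell_lines=()), "cell line"),
            (dict(planted_pairs=(("TF01", "TFxx", 0.5),)), "unknown"),
            (dict(planted_pairs=(("TF01", "TF01", 0.5),)), "distinct"),
            (dict(planted_pairs=(("TF01", "TF02", 1.5),)), "co_rate"),
            (
                dict(
                    planted_pairs=(
                        ("TF01", "TF03", 0.5),
                        ("TF02", "TF03", 0.5),
                    )
                ),
                "more than one",
            ),
            (dict(planted_enrichment={"TFxx": 2.0}), "unknown"),
            (dict(planted_enrichment={"TF01": 0.0}), "f_true"),
            (
                dict(
                    planted_pairs=(("TF01", "TF02", 0.5),),
                    planted_enrichment={"TF02": 2.0},
                ),
                "coupled",
            ),
            (dict(driver_factors=("TFxx",)), "driver"),
            (dict(noise_sd=-0.1), "noise_sd"),
            (dict(n_genes=5000, chrom_length=1_000_000), "too short"),
        ],
    )
    def test_bad_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            SimulationConfig(**kwargs).validate()


class TestWriteDataset:
    def test_files_round_trip_through_the_readers(self, tmp_path):
        manifest = write_dataset(SMALL, tmp_path)
        genes = read_gene_annotation(manifest["genes"], dialect="tsv")
        assert len(genes) == SMALL.n_genes
        for cell in SMALL.cell_lines:
            for factor, path in manifest["peaks"][cell].items():
                reader = read_broadpeak if factor.startswith("HM") else read_narrowpeak
                track = reader(path, factor_name=factor, cell_line=cell)
                assert track.n_peaks == SMALL.peaks_per_factor
            expr = read_expression(manifest["expression"][cell])
            assert set(expr) == {g.gene_id for g in genes}

    def test_byte_identical_reruns(self, tmp_path):
        m1 = write_dataset(SMALL, tmp_path / "run1")
        m2 = write_dataset(SMALL, tmp_path / "run2")
        files1 = sorted(p for p in Path(tmp_path / "run1").rglob("*") if p.is_file())
        files2 = sorted(p for p in Path(tmp_path / "run2").rglob("*") if p.is_file())
        assert [p.relative_to(tmp_path / "run1") for p in files1] == [
            p.relative_to(tmp_path / "run2") for p in files2
        ]
        for a, b in zip(files1, files2):
            assert filecmp.cmp(a, b, shallow=False), a.name

    def test_expression_differs_between_cell_lines(self, tmp_path):
        manifest = write_dataset(SMALL, tmp_path)
        ea = read_expression(manifest["expression"]["cellA"])
        eb = read_expression(manifest["expression"]["cellB"])
        assert ea != eb
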