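"""The synthetic-data generator: determinism, planted structure, and
lossless round trips of every emitted file."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from arsig.cistrome import GenomeAnnotation, PeakSet, partition_peak_sets
from arsig.diffexpr import read_counts, read_design
from arsig.enrichment import read_gmt, read_motif_table, read_regulator_network
from arsig.simulate import (
    SimConfig,
    SyntheticTruth,
    generate_cohort,
    generate_condition_peaks,
    generate_counts,
    generate_genome_annotation,
    generate_motif_tables,
    simulate_all,
)
from arsig.survival import logrank_test, read_clinical, stratify_by_score


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_peaks_near_tss": 1.5},
            {"censor_rate": -0.1},
            {"nb_dispersion": 0.0},
            {"n_genes": -1},
            {"frac_de_A_unique": 0.5, "frac_de_B_unique": 0.4, "frac_de_common": 0.3},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestAnnotation:
    def test_zero_genes_gives_empty_annotation(self):
        ann = generate_genome_annotation(SimConfig(n_genes=0))
        assert len(ann) == 0

    def test_determinism_under_fixed_seed(self, small_cfg):
        a1 = generate_genome_annotation(small_cfg)
        a2 = generate_genome_annotation(small_cfg)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)

    def test_bounds_and_uniqueness(self):
        cfg = SimConfig(seed=5, n_genes=100, n_chroms=2, chrom_length=1_000_000)
        ann = generate_genome_annotation(cfg)
        assert len(ann) == 100
        assert set(ann.genes["chrom"]) == {"chr1", "chr2"}
        assert ann.genes["tss"].between(0, cfg.chrom_length - 1).all()
        assert not ann.genes.duplicated(["chrom", "tss"]).any()

    def test_too_small_chromosome_refused(self):
        with pytest.raises(ValueError, match="chrom_length"):
            generate_genome_annotation(
                SimConfig(n_genes=100, n_chroms=1, chrom_length=50))


class TestConditionPeaks:
    def test_no_unique_peaks_makes_sets_identical(self):
        cfg = SimConfig(seed=9, n_genes=200, n_chroms=2, chrom_length=3_000_000,
                        n_peaks_common=40, n_peaks_unique_A=0, n_peaks_unique_B=0)
        ann = generate_genome_annotation(cfg)
        a, b, _ = generate_condition_peaks(cfg, ann)
        assert [i for i in a] == [i for i in b]

    def test_planted_venn_counts_recovered_exactly(self):
        cfg = SimConfig(seed=11, n_genes=200, n_chroms=2, chrom_length=3_000_000,
                        n_peaks_common=100, n_peaks_unique_A=50, n_peaks_unique_B=30)
        ann = generate_genome_annotation(cfg)
        a, b, _ = generate_condition_peaks(cfg, ann)
        part = partition_peak_sets(a, b)
        assert part.counts == {
            "common_a": 100, "common_b": 100, "unique_a": 50, "unique_b": 30}

    def test_all_near_fraction_puts_every_peak_at_a_tss(self):
        cfg = SimConfig(seed=13, n_genes=200, n_chroms=2, chrom_length=3_000_000,
                        n_peaks_common=30, n_peaks_unique_A=20, n_peaks_unique_B=20,
                        frac_peaks_near_tss=1.0)
        ann = generate_genome_annotation(cfg)
        a, b, _ = generate_condition_peaks(cfg, ann)
        tss = ann.genes["tss"].to_numpy()
        chroms = ann.genes["chrom"].to_numpy()
        for peaks in (a, b):
            for iv in peaks:
                dists = np.abs(tss[chroms == iv.chrom] - iv.midpoint)
                assert dists.min() <= cfg.tss_window

    def test_truth_invariants(self, small_world):
        truth = small_world["truth"]
        classes = [truth.planted_unique_genes_A, truth.planted_unique_genes_B,
                   truth.planted_common_genes]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not classes[i] & classes[j]
        planted = set().union(*classes)
        assert truth.planted_direct_targets <= planted
        assert truth.planted_up_genes | truth.planted_down_genes == planted


class TestCounts:
    def test_determinism(self, small_world):
        w = small_world
        c2, d2 = generate_counts(w["cfg"], w["ann"], w["truth"])
        pd.testing.assert_frame_equal(w["counts"], c2)
        pd.testing.assert_series_equal(w["design"], d2)

    def test_four_groups_with_requested_sizes(self, small_world):
        design = small_world["design"]
        assert design.value_counts().to_dict() == {
            g: small_world["cfg"].n_samples_per_group
            for g in ("vehicle", "A", "B", "AB")}

    def test_planted_fold_change_shows_in_group_means(self, small_world):
        w = small_world
        counts, design = w["counts"], w["design"]
        veh = counts.loc[:, design == "vehicle"].mean(axis=1)
        grp_a = counts.loc[:, design == "A"].mean(axis=1)
        planted_up_a = sorted(
            (w["truth"].planted_unique_genes_A | w["truth"].planted_common_genes)
            & w["truth"].planted_up_genes)
        ratios = (grp_a[planted_up_a] + 0.5) / (veh[planted_up_a] + 0.5)
        # planted log2fc=2 -> point ratio 4; NB sampling spread at n=5
        assert 2.5 <= ratios.median() <= 6.5
        assert (ratios > 1.5).mean() >= 0.95

    def test_unplanted_genes_have_no_shift(self, small_world):
        w = small_world
        counts, design = w["counts"], w["design"]
        planted = (w["truth"].planted_unique_genes_A
                   | w["truth"].planted_unique_genes_B
                   | w["truth"].planted_common_genes)
        nulls = [g for g in counts.index if g not in planted]
        veh = counts.loc[nulls, design == "vehicle"].mean(axis=1)
        grp = counts.loc[nulls, design == "A"].mean(axis=1)
        ratio = ((grp + 0.5) / (veh + 0.5)).median()
        assert 0.8 <= ratio <= 1.25


class TestMotifsAndNetwork:
    def test_motif_tables_deterministic_and_shared_universe(self, small_cfg):
        a1, b1, p1 = generate_motif_tables(small_cfg)
        a2, b2, p2 = generate_motif_tables(small_cfg)
        pd.testing.assert_series_equal(a1, a2)
        pd.testing.assert_series_equal(b1, b2)
        assert p1 == p2
        assert list(a1.index) == list(b1.index)

    def test_no_shift_means_symmetric_tables(self):
        cfg = SimConfig(seed=2, n_motifs=50, n_shifted_motifs=0)
        a, b, planted = generate_motif_tables(cfg)
        assert planted == []
        # rank differences sum to zero by construction; mean shift is zero
        assert abs((a - b).mean()) < 0.2


class TestCohort:
    def test_high_score_group_has_worse_survival(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, hazard_beta=1.0, n_cohort_samples=200)
        expr, clinical = generate_cohort(cfg, [f"SG{i}" for i in range(30)])
        score = expr.iloc[:30].mean(axis=0)
        cohort = clinical.join(score.rename("score"))
        strat = stratify_by_score(cohort, 0.25)
        res = logrank_test(strat[strat["stratum"] == "high"],
                           strat[strat["stratum"] == "low"])
        assert res["p"] < 0.05

    def test_full_censoring_breaks_logrank_with_clear_message(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, censor_rate=1.0)
        expr, clinical = generate_cohort(cfg, ["SG1", "SG2"])
        assert (clinical["event"] == 0).all()
        c = clinical.assign(score=expr.iloc[:2].mean(axis=0))
        with pytest.raises(ValueError, match="no events"):
            logrank_test(c.iloc[:40], c.iloc[40:])

    def test_empty_signature_refused(self, small_cfg):
        with pytest.raises(ValueError, match="empty"):
            generate_cohort(small_cfg, [])


class TestRoundTripsAndDeterminism:
    def test_simulate_all_round_trips_and_byte_identical(self, small_cfg, tmp_path):
        p1 = simulate_all(small_cfg, tmp_path / "r1")
        p2 = simulate_all(small_cfg, tmp_path / "r2")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

        ann = GenomeAnnotation.from_tsv(p1["annotation"])
        assert len(ann) == small_cfg.n_genes
        peaks_a = PeakSet.from_bed(p1["peaks_a"])
        assert len(peaks_a) == small_cfg.n_peaks_common + small_cfg.n_peaks_unique_A
        counts = read_counts(p1["counts"])
        design = read_design(p1["design"])
        assert list(counts.columns) == list(design.index)
        read_motif_table(p1["motifs_a"])
        net = read_regulator_network(p1["network"])
        assert set(net.columns) == {"regulator", "target"}
        assert "EZH2_REGULATED" in read_gmt(p1["ezh2_regulated"])
        clinical = read_clinical(p1["clinical"])
        assert len(clinical) == small_cfg.n_cohort_samples
        truth = SyntheticTruth.from_json(p1["truth"])
        assert truth.planted_unique_genes_A
        assert truth.peak_labels
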