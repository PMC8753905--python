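"""Synthetic-data generator: planted TADs, contact model, gene model, catalog."""

import numpy as np
import pandas as pd
import pytest

from tadrisk.catalog import _in_union, classify_positions
from tadrisk.simulate import (SimConfig, plant_tads, simulate_catalog,
                              simulate_contact_matrix, simulate_gene_model,
                              simulate_study)


class TestPlantTads:
    def test_forced_single_tad(self):
        truth = plant_tads({"chr1": 10}, (10, 10), seed=0)
        assert truth.planted_tads["chr1"].tolist() == [[0, 10]]

    def test_remainder_absorbed_into_last_tad(self):
        truth = plant_tads({"chr1": 10}, (3, 3), seed=0)
        assert truth.planted_tads["chr1"].tolist() == [[0, 3], [3, 6], [6, 10]]

    def test_500_bin_partition_tiles_exactly_within_size_bounds(self):
        lo, hi = 5, 50
        truth = plant_tads({"chr1": 500}, (lo, hi), seed=123)
        tads = truth.planted_tads["chr1"]
        assert tads[0, 0] == 0 and tads[-1, 1] == 500
        assert (tads[1:, 0] == tads[:-1, 1]).all()  # exact tiling
        sizes = tads[:, 1] - tads[:, 0]
        # the final TAD may have absorbed a remainder < lo
        assert (sizes >= lo).all() and (sizes <= hi + lo - 1).all()

    def test_too_short_chromosome_errors(self):
        with pytest.raises(ValueError):
            plant_tads({"chr1": 4}, (5, 10), seed=0)

    def test_deterministic_given_seed(self):
        a = plant_tads({"chr1": 300, "chr2": 200}, (5, 30), seed=9)
        b = plant_tads({"chr1": 300, "chr2": 200}, (5, 30), seed=9)
        for chrom in a.planted_tads:
            assert np.array_equal(a.planted_tads[chrom], b.planted_tads[chrom])

    def test_tads_tile_around_gap_runs(self):
        truth = plant_tads({"chr1": 50}, (5, 10), seed=1,
                           gap_bins={"chr1": [20, 21]})
        covered = np.zeros(50, dtype=bool)
        for s, e in truth.planted_tads["chr1"]:
            assert not (s <= 20 < e) and not (s <= 21 < e)
            covered[s:e] = True
        assert covered.sum() == 48


class TestContactMatrix:
    def test_symmetric_nonnegative_zero_diagonal_and_gaps(self):
        cfg = SimConfig(seed=5, n_chromosomes=1, bins_per_chromosome=60,
                        tad_size_range=(5, 15), gap_bins={"chr1": [10, 11]})
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 5, gap_bins=cfg.gap_bins)
        m = simulate_contact_matrix(truth, cfg, 6)
        assert np.array_equal(m.counts, m.counts.T)
        assert (m.counts >= 0).all()
        assert (np.diag(m.counts) == 0).all()
        assert (m.counts[[10, 11], :] == 0).all()

    def test_decay_only_mean_when_b_is_one(self):
        # B=1: expectation depends only on distance, E = A * (1 + d)^-alpha
        cfg = SimConfig(seed=0, n_chromosomes=1, bins_per_chromosome=400,
                        tad_size_range=(10, 20), baseline_intensity=8.0,
                        decay_exponent=1.0, within_tad_factor=1.0)
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 0)
        vals = {1: [], 4: []}
        for rep in range(5):
            m = simulate_contact_matrix(truth, cfg, 100 + rep)
            for d in vals:
                vals[d].extend(np.diagonal(m.counts, d))
        for d, v in vals.items():
            expected = 8.0 / (1 + d)
            se = np.std(v) / np.sqrt(len(v))
            assert abs(np.mean(v) - expected) < 4 * se + 1e-9

    def test_plugin_expectation_within_and_across_tads(self):
        # A=8, alpha=1, B=4: adjacent within-TAD E = 8/2*4 = 16, across = 4
        cfg = SimConfig(seed=0, n_chromosomes=1, bins_per_chromosome=505,
                        tad_size_range=(5, 5), baseline_intensity=8.0,
                        decay_exponent=1.0, within_tad_factor=4.0)
        truth = plant_tads(cfg.layout, (5, 5), 0)
        tad_id = np.full(505, -1)
        for t, (s, e) in enumerate(truth.planted_tads["chr1"]):
            tad_id[s:e] = t
        within, across = [], []
        for rep in range(25):
            m = simulate_contact_matrix(truth, cfg, 200 + rep)
            d1 = np.diagonal(m.counts, 1)
            same = tad_id[:-1] == tad_id[1:]
            within.extend(d1[same])
            across.extend(d1[~same])
        assert len(within) >= 10_000
        assert np.mean(within) == pytest.approx(16.0, abs=0.2)
        assert np.mean(across) == pytest.approx(4.0, abs=0.3)

    def test_invalid_intensity_errors(self):
        with pytest.raises(ValueError):
            SimConfig(baseline_intensity=0.0)
        with pytest.raises(ValueError):
            SimConfig(decay_exponent=-1.0)

    def test_bit_reproducible(self):
        cfg = SimConfig(seed=4, n_chromosomes=1, bins_per_chromosome=80,
                        tad_size_range=(5, 20))
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 4)
        a = simulate_contact_matrix(truth, cfg, 11)
        b = simulate_contact_matrix(truth, cfg, 11)
        assert np.array_equal(a.counts, b.counts)


class TestGeneModel:
    def test_zero_density_empty_model(self):
        gm = simulate_gene_model({"chr1": 1_000_000}, seed=0, gene_fraction=0.0)
        assert gm.genes.empty
        cats = classify_positions(np.array(["chr1"] * 3),
                                  np.array([10, 500_000, 999_999]), gm)
        assert (cats == "intergenic").all()

    def test_containment_classification(self):
        gm = simulate_gene_model({"chr1": 10_000}, seed=0, gene_fraction=0.0)
        gm.genes = pd.DataFrame([("chr1", 1000, 5000)],
                                columns=["chrom", "start", "end"])
        gm.exons = pd.DataFrame([("chr1", 1000, 1500)],
                                columns=["chrom", "start", "end"])
        cats = classify_positions(np.array(["chr1"] * 3),
                                  np.array([1200, 3000, 9000]), gm)
        assert cats.tolist() == ["exonic", "intronic", "intergenic"]

    def test_exon_fraction_matches_configuration(self):
        gm = simulate_gene_model({"chr1": 5_000_000}, seed=2,
                                 gene_fraction=0.6, exon_fraction_of_gene=0.0833)
        gene_bp = (gm.genes["end"] - gm.genes["start"]).sum()
        exon_bp = (gm.exons["end"] - gm.exons["start"]).sum()
        assert exon_bp / gene_bp == pytest.approx(0.0833, rel=0.10)

    def test_exons_nested_in_genes(self):
        gm = simulate_gene_model({"chr1": 2_000_000}, seed=3)
        genes = gm.genes.sort_values("start")
        for ex in gm.exons.itertuples():
            hit = genes[(genes["start"] <= ex.start) & (genes["end"] >= ex.end)]
            assert len(hit) == 1


class TestCatalog:
    def _truth_and_config(self, **kw):
        cfg = SimConfig(seed=0, n_chromosomes=1, bins_per_chromosome=1000,
                        tad_size_range=(20, 60), n_cancers=0, n_noncancers=1,
                        frac_enriched_noncancers=1.0, snp_sharing_prob=0.0, **kw)
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 0)
        return truth, cfg

    def test_rho_one_puts_all_snps_in_borders(self):
        truth, cfg = self._truth_and_config(border_placement_prob=1.0,
                                            snps_per_disease=20.0)
        df = simulate_catalog(truth, cfg, seed=7)
        inb = _in_union(df["chrom"].to_numpy(), df["pos"].to_numpy() - 1,
                        truth.planted_border_union)
        assert inb.all()

    def test_border_hit_expectation_binomial_oracle(self):
        # E[q] = Q * (rho + (1 - rho) * border_fraction)
        truth, cfg = self._truth_and_config(border_placement_prob=0.5,
                                            snps_per_disease=40.0)
        frac = truth.border_union_bp / cfg.genome_bp
        expected = 40.0 * (0.5 + 0.5 * frac)
        qs = []
        for seed in range(300):
            df = simulate_catalog(truth, cfg, seed)
            inb = _in_union(df["chrom"].to_numpy(), df["pos"].to_numpy() - 1,
                            truth.planted_border_union)
            qs.append(inb.sum())
        se = np.std(qs) / np.sqrt(len(qs))
        assert abs(np.mean(qs) - expected) < 3 * se + 0.05 * expected

    def test_positions_deduplicated_per_disease(self):
        cfg = SimConfig(seed=0, n_chromosomes=1, bins_per_chromosome=200,
                        n_cancers=5, n_noncancers=5, snp_sharing_prob=0.5)
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 0)
        df = simulate_catalog(truth, cfg, seed=3)
        assert not df.duplicated(subset=["efoId", "snpId"]).any()

    def test_enrichment_requested_without_borders_errors(self):
        cfg = SimConfig(seed=0, n_chromosomes=1, bins_per_chromosome=100,
                        tad_size_range=(5, 10), n_noncancers=2,
                        frac_enriched_noncancers=1.0, border_placement_prob=0.5)
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 0)
        truth.planted_border_union = {"chr1": np.empty((0, 2), dtype=np.int64)}
        with pytest.raises(ValueError):
            simulate_catalog(truth, cfg, seed=0)


class TestStudy:
    def test_category_fractions_converge_to_configuration(self):
        cfg = SimConfig(seed=3, n_chromosomes=4, bins_per_chromosome=1000,
                        n_cancers=50, n_noncancers=200, snp_sharing_prob=0.0)
        _, _, cat = simulate_study(cfg)
        frac = cat["category"].value_counts(normalize=True)
        assert len(cat) > 10_000
        assert frac["intergenic"] == pytest.approx(0.40, abs=0.02)
        assert frac["exonic"] == pytest.approx(0.05, abs=0.02)

    def test_study_is_bit_reproducible(self):
        cfg = SimConfig(seed=8, n_chromosomes=1, bins_per_chromosome=120,
                        tad_size_range=(5, 20), n_cancers=3, n_noncancers=5)
        t1, m1, c1 = simulate_study(cfg)
        t2, m2, c2 = simulate_study(cfg)
        assert c1.equals(c2)
        assert np.array_equal(m1["chr1"].counts, m2["chr1"].counts)
        assert t1.enriched_disease_ids == t2.enriched_disease_ids
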