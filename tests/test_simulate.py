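"""Tests for the synthetic-data generators: determinism, truth labels and
agreement with the generating models' closed forms."""

import numpy as np
import pandas as pd
import pytest

from gistkit.founder import FounderModelParams, founder_threshold
from gistkit.screen import screen_panel, sites_from_frame
from gistkit.simulate import (
    SimulationConfig,
    simulate_loh_genome,
    simulate_methylation,
    simulate_screen_panel,
    simulate_variant_table,
    simulate_zf_protein,
)
from gistkit import io as gio


class TestDeterminism:
    def test_identical_seeds_identical_outputs(self):
        config = SimulationConfig(seed=42, n_founder=50, n_subclonal=50, n_germline_het=50)
        pd.testing.assert_frame_equal(
            simulate_variant_table(config), simulate_variant_table(config)
        )
        a_snps, a_truth = simulate_loh_genome(config)
        b_snps, b_truth = simulate_loh_genome(config)
        pd.testing.assert_frame_equal(a_snps, b_snps)
        pd.testing.assert_frame_equal(a_truth, b_truth)
        pd.testing.assert_frame_equal(
            simulate_methylation(config)[0], simulate_methylation(config)[0]
        )
        assert simulate_zf_protein(config) == simulate_zf_protein(config)

    def test_different_seeds_differ(self):
        a = simulate_variant_table(SimulationConfig(seed=1))
        b = simulate_variant_table(SimulationConfig(seed=2))
        assert not a.equals(b)


class TestVariantTable:
    def test_truth_labels_match_generating_model(self):
        config = SimulationConfig(seed=3, n_founder=100, n_subclonal=100, n_germline_het=100)
        table = simulate_variant_table(config)
        somatic = table[table["truth"] != "germline"]
        assert (somatic["control_alt_count"] == 0).all()
        germline = table[table["truth"] == "germline"]
        control_baf = germline["control_alt_count"] / germline["control_depth"]
        assert abs(control_baf.mean() - 0.5) < 0.03
        assert (
            table["tumour_alt_fwd"] + table["tumour_alt_rev"]
            <= table["tumour_depth"]
        ).all()

    def test_no_founders_requested(self):
        table = simulate_variant_table(SimulationConfig(seed=4, n_founder=0))
        assert "founder" not in set(table["truth"])

    def test_pure_tumour_high_depth_fractions_near_half(self):
        config = SimulationConfig(
            seed=5, purity=1.0, n_founder=200, n_subclonal=0,
            n_germline_het=0, depth_mean=1000,
        )
        table = simulate_variant_table(config)
        frac = (
            table["tumour_alt_fwd"] + table["tumour_alt_rev"]
        ) / table["tumour_depth"]
        assert abs(frac.mean() - 0.5) < 0.01
        assert frac.std() < 0.03

    def test_founder_inclusion_at_design_level(self):
        """Most simulated founders clear the 95%-inclusion threshold."""
        config = SimulationConfig(seed=6, n_founder=2000, n_subclonal=0, n_germline_het=0)
        table = simulate_variant_table(config)
        params = FounderModelParams(purity=config.purity)
        alt = table["tumour_alt_fwd"] + table["tumour_alt_rev"]
        passed = [
            a >= founder_threshold(n, params)
            for a, n in zip(alt, table["tumour_depth"])
        ]
        assert np.mean(passed) >= 0.94


class TestLohGenome:
    def test_truth_marks_exactly_the_planted_arm(self):
        _, truth = simulate_loh_genome(SimulationConfig(seed=7))
        assert truth.loc[truth["loh"], ["chrom", "arm"]].values.tolist() == [["14", "q"]]

    def test_vanishing_purity_means_no_shift_and_no_call(self):
        from gistkit.loh import arm_summaries

        snps, _ = simulate_loh_genome(
            SimulationConfig(seed=8, purity=1e-9, loh_arm="14q", depth_mean=100)
        )
        baf = snps["tumour_alt"] / snps["tumour_depth"]
        assert abs(baf.mean() - 0.5) < 0.01
        assert not arm_summaries(snps).loh_call.any()


class TestScreenPanelSim:
    def test_zero_maf_zero_carriers(self):
        config = SimulationConfig(seed=9, panel=((0.0, False),) * 5)
        panel, _ = simulate_screen_panel(config)
        assert (panel["carriers"] == 0).all()

    def test_enriched_site_detected_others_quiet(self):
        """Power at the planted site (MAF inflated 8x) and control of the
        per-site false-positive rate over seeded replicates."""
        n_reps = 500
        flagged = None
        for i in range(n_reps):
            panel, truth = simulate_screen_panel(SimulationConfig(seed=i))
            results, _ = screen_panel(sites_from_frame(panel))
            sig = results["significant"].fillna(False).to_numpy(dtype=bool)
            flagged = sig.astype(int) if flagged is None else flagged + sig
        rates = flagged / n_reps
        enriched_idx = 0  # first panel site carries the planted enrichment
        assert rates[enriched_idx] >= 0.5
        # null sites: at most alpha plus a 3-sigma Monte-Carlo margin
        margin = 3 * (0.05 * 0.95 / n_reps) ** 0.5
        assert (rates[1:] <= 0.05 + margin).all()


class TestRoundTrips:
    def test_snp_table_round_trip(self, tmp_path):
        snps, _ = simulate_loh_genome(SimulationConfig(seed=10, snps_per_arm=50))
        path = tmp_path / "snps.tsv"
        gio.write_snp_tsv(snps, path)
        pd.testing.assert_frame_equal(gio.read_snp_tsv(path), snps)

    def test_methylation_matrix_round_trip(self, tmp_path):
        matrix, _ = simulate_methylation(
            SimulationConfig(seed=11, meth_informative=20, meth_background=30)
        )
        path = tmp_path / "meth.tsv"
        gio.write_matrix_tsv(matrix, path)
        back = gio.read_matrix_tsv(path)
        pd.testing.assert_frame_equal(back, matrix, check_names=False)

    def test_methylation_values_in_unit_interval(self):
        matrix, _ = simulate_methylation(SimulationConfig(seed=12))
        assert (matrix.values >= 0).all() and (matrix.values <= 1).all()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(purity=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(depth_model="gamma")
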