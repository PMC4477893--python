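"""Tests for methylation normalization, variance filtering and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from gistkit.methylome import (
    ProbeReference,
    cluster_samples,
    correlation_distance_matrix,
    normalize_matrix,
    normalize_probe,
    variance_filter,
)
from gistkit.simulate import SimulationConfig, simulate_methylation

REF = ProbeReference("cg0001", ref_low=200.0, ref_high=1200.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [(200.0, 0.0), (1200.0, 1.0), (700.0, 0.5), (0.0, 0.0), (5000.0, 1.0)],
    )
    def test_anchors_midpoint_and_clipping(self, raw, expected):
        assert normalize_probe(raw, REF) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        raw=st.floats(0.0, 5000.0),
        scale=st.floats(0.1, 100.0),
    )
    def test_scale_invariant_and_monotone(self, raw, scale):
        scaled_ref = ProbeReference("cg0001", REF.ref_low * scale, REF.ref_high * scale)
        assert normalize_probe(raw * scale, scaled_ref) == pytest.approx(
            normalize_probe(raw, REF), abs=1e-9
        )
        assert normalize_probe(raw + 10.0, REF) >= normalize_probe(raw, REF)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            ProbeReference("cg0001", 10.0, 10.0)

    def test_matrix_normalization(self):
        raw = pd.DataFrame(
            {"s1": [200.0, 0.0], "s2": [1200.0, 50.0]}, index=["p1", "p2"]
        )
        refs = pd.DataFrame(
            {"ref_low": [200.0, 0.0], "ref_high": [1200.0, 100.0]},
            index=["p1", "p2"],
        )
        out = normalize_matrix(raw, refs)
        assert out.loc["p1"].tolist() == [0.0, 1.0]
        assert out.loc["p2"].tolist() == [0.0, 0.5]

    def test_missing_reference_rejected(self):
        raw = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        refs = pd.DataFrame({"ref_low": [], "ref_high": []})
        with pytest.raises(ValueError, match="p1"):
            normalize_matrix(raw, refs)


class TestVarianceFilter:
    def test_constant_probe_excluded(self):
        matrix = pd.DataFrame({"a": [0.5, 0.0], "b": [0.5, 1.0]}, index=["flat", "var"])
        kept = variance_filter(matrix, threshold=0.1)
        assert list(kept) == ["var"]  # variance of {0,1} is 0.5 with ddof=1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            variance_filter(pd.DataFrame({"only": [0.1, 0.2]}))

    def test_exactly_planted_probes_retained(self):
        """300 high-variance probes planted among 10000 background probes
        are recovered exactly at the 0.1 cutoff."""
        config = SimulationConfig(
            seed=21,
            meth_informative=300,
            meth_background=10000,
            meth_group_means=(0.9, 0.1),
        )
        matrix, _ = simulate_methylation(config)
        kept = variance_filter(matrix, threshold=0.1)
        assert sorted(kept) == sorted(matrix.index[:300])


class TestClustering:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, 50)
        matrix = pd.DataFrame(
            {"a": base, "b": base, "c": rng.uniform(0, 1, 50)}
        )
        result = cluster_samples(matrix)
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_samples_maximally_distant(self):
        x = np.linspace(0, 1, 20)
        matrix = pd.DataFrame({"a": x, "b": 1 - x})
        d = correlation_distance_matrix(matrix)
        assert d[0] == pytest.approx(2.0)

    def test_two_group_recovery(self):
        matrix, truth = simulate_methylation(SimulationConfig(seed=13))
        informative = matrix.loc[matrix.index.str.startswith("inf")]
        labels = cluster_samples(informative).cut(2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_merge_heights_non_decreasing(self):
        matrix, _ = simulate_methylation(SimulationConfig(seed=14))
        Z = cluster_samples(matrix).linkage
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_invariant_under_sample_reordering(self):
        matrix, _ = simulate_methylation(SimulationConfig(seed=15))
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.columns)
        a = cluster_samples(matrix)
        b = cluster_samples(matrix[perm])
        coph_a = a.cophenetic_matrix()
        coph_b = b.cophenetic_matrix().loc[coph_a.index, coph_a.columns]
        pd.testing.assert_frame_equal(coph_a, coph_b)

    def test_zero_variance_sample_named(self):
        matrix = pd.DataFrame({"ok": [0.1, 0.9], "flat": [0.5, 0.5]})
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(matrix)

    def test_newick_contains_all_leaves(self):
        matrix, _ = simulate_methylation(
            SimulationConfig(seed=16, meth_group_sizes=(3, 3), meth_background=50)
        )
        result = cluster_samples(matrix)
        newick = result.to_newick()
        for sample in matrix.columns:
            assert sample in newick
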