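"""Rank-variance CNV detection: transform, outliers, merging, copy number."""

import numpy as np
import pandas as pd
import pytest

from poolcoev.cnv import (
    CoverageMatrix,
    NoVarianceError,
    call_cnvs,
    contig_copy_number,
    detect_outlier_positions,
    estimate_copy_number,
    merge_adjacent,
    rank_transform,
    rank_variance,
)


class TestRankTransform:
    def test_definition(self, coverage_matrix_factory):
        m = coverage_matrix_factory(np.array([[10], [20], [30]]))
        ranks = rank_transform(m)
        assert ranks["s0"].tolist() == [1 / 3, 2 / 3, 1.0]

    def test_all_equal_tie_average(self, coverage_matrix_factory):
        n = 7
        m = coverage_matrix_factory(np.full((n, 1), 42))
        assert np.allclose(rank_transform(m)["s0"], (n + 1) / (2 * n))

    def test_brute_force_comparison_oracle(self, coverage_matrix_factory):
        """Normalized fractional rank equals 1 + #smaller + (#equal-1)/2,
        all over n, computed by the O(n^2) counting loop."""
        rng = np.random.default_rng(2)
        depths = rng.integers(0, 20, size=(60, 3))
        ranks = rank_transform(coverage_matrix_factory(depths))
        n = depths.shape[0]
        for j in range(3):
            col = depths[:, j]
            for i in range(n):
                expected = (1 + np.sum(col < col[i]) + (np.sum(col == col[i]) - 1) / 2) / n
                assert ranks.iloc[i, j] == pytest.approx(expected)


class TestRankVariance:
    def test_identical_samples_zero(self, coverage_matrix_factory):
        depths = np.tile(np.arange(50)[:, None], (1, 4))
        v = rank_variance(rank_transform(coverage_matrix_factory(depths)))
        assert np.allclose(v, 0.0)

    def test_hand_computed_value(self):
        ranks = pd.DataFrame({"a": [0.1], "b": [0.9]})
        assert rank_variance(ranks).iloc[0] == pytest.approx(0.32)

    def test_single_sample_rejected(self):
        with pytest.raises(NoVarianceError):
            rank_variance(pd.DataFrame({"a": [0.1, 0.2]}))

    def test_monotone_depth_invariance(self, coverage_matrix_factory):
        """The whole statistic is rank-based: any per-sample strictly
        monotone transform of the depths leaves the variances unchanged."""
        rng = np.random.default_rng(4)
        depths = rng.poisson(50, size=(200, 4))
        v1 = rank_variance(rank_transform(coverage_matrix_factory(depths)))
        transformed = np.column_stack(
            [10 * depths[:, 0], depths[:, 1] ** 3, 7 + depths[:, 2], np.exp(depths[:, 3] / 20.0)]
        )
        v2 = rank_variance(rank_transform(coverage_matrix_factory(transformed)))
        assert np.allclose(v1, v2)


class TestOutlierDetection:
    def test_all_equal_no_outliers(self):
        assert detect_outlier_positions(np.full(500, 0.01)).size == 0

    def test_planted_outlier_recovery(self):
        """10,000 N(0.01, 0.001^2) draws plus 20 planted values at 0.05:
        every planted position is flagged on every seed, and false flags
        stay within the rho-controlled expected-count budget (at rho=1 the
        threshold sits near 3.7 sigma for N=10,000, so ~1 null exceedance
        per run is the rule's own expectation, not an error)."""
        false_flags = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            v = rng.normal(0.01, 0.001, size=10_000)
            planted = rng.choice(10_000, size=20, replace=False)
            v[planted] = 0.05
            flagged = set(detect_outlier_positions(v))
            assert set(planted) <= flagged
            false_flags.append(len(flagged - set(planted)))
        assert np.mean(false_flags) <= 2.0

    def test_null_calibration_normal(self):
        """On truly normal data the expected-count rule is calibrated:
        mean false positives over 50 seeds within 2*rho."""
        counts = [
            detect_outlier_positions(
                np.random.default_rng(seed).normal(0.01, 0.001, 10_000)
            ).size
            for seed in range(50)
        ]
        assert np.mean(counts) <= 2.0

    def test_left_tail_ignored(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0.01, 0.001, size=5_000)
        v[100] = -0.05  # extreme low variance is not a CNV signature
        assert 100 not in detect_outlier_positions(v)


class TestMergeAdjacent:
    def test_gaps_below_100_merge(self):
        regions = merge_adjacent([("c1", 1000), ("c1", 1050), ("c1", 1120)])
        assert regions == [("c1", 1000, 1121)]

    def test_gap_of_exactly_100_splits(self):
        regions = merge_adjacent([("c1", 1000), ("c1", 1100)])
        assert regions == [("c1", 1000, 1001), ("c1", 1100, 1101)]

    def test_contigs_never_merge(self):
        regions = merge_adjacent([("c1", 10), ("c2", 15)])
        assert len(regions) == 2

    def test_brute_force_union_oracle(self):
        """Random position sets: merged regions equal an O(n^2) union-find
        over the pairwise closer-than-100 relation (transitive closure)."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = sorted(rng.choice(5_000, size=40, replace=False))
            items = [("c1", int(p)) for p in pos]
            got = merge_adjacent(items)
            # union-find oracle
            parent = list(range(len(pos)))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    if abs(pos[i] - pos[j]) < 100:
                        parent[find(j)] = find(i)
            groups = {}
            for i, p in enumerate(pos):
                groups.setdefault(find(i), []).append(p)
            expected = sorted(
                ("c1", min(g), max(g) + 1) for g in groups.values()
            )
            assert sorted(got) == expected


class TestCopyNumber:
    def test_ratio_definition(self, coverage_matrix_factory):
        depths = np.full((1000, 2), 100)
        depths[100:200] = 200
        m = coverage_matrix_factory(depths)
        cn = estimate_copy_number(("c1", 100, 200), m)
        assert cn == {"s0": 2.0, "s1": 2.0}

    def test_null_interval_near_one(self, coverage_matrix_factory):
        rng = np.random.default_rng(12)
        m = coverage_matrix_factory(rng.poisson(100, size=(5_000, 3)))
        cn = estimate_copy_number(("c1", 2_000, 2_500), m)
        for v in cn.values():
            assert v == pytest.approx(1.0, abs=0.1)

    def test_planted_partial_duplication(self, coverage_matrix_factory):
        """CN=2 at carrier frequency 0.5 shifts coverage by 1.5x."""
        rng = np.random.default_rng(13)
        depths = rng.poisson(100, size=(10_000, 3)).astype(float)
        depths[4_000:4_600] = rng.poisson(150, size=(600, 3))
        cn = estimate_copy_number(("c1", 4_000, 4_600), coverage_matrix_factory(depths))
        for v in cn.values():
            assert v == pytest.approx(1.5, abs=0.1)

    def test_contig_copy_number_plasmid(self):
        rng = np.random.default_rng(14)
        chrom = rng.poisson(100, size=(8_000, 2))
        plasmid = rng.poisson(500, size=(2_000, 2))
        idx = pd.MultiIndex.from_tuples(
            [("chr", i) for i in range(8_000)] + [("pls", i) for i in range(2_000)],
            names=["contig", "position"],
        )
        m = CoverageMatrix(
            depths=pd.DataFrame(np.vstack([chrom, plasmid]), index=idx, columns=["s0", "s1"]),
            roles={"chr": "chromosomal", "pls": "plasmid"},
        )
        out = contig_copy_number(m, seed=5)
        pls = out[out["contig"] == "pls"]
        assert np.allclose(pls["ratio"], 5.0, atol=0.2)
        chrom_rows = out[out["contig"] == "chr"]
        assert np.allclose(chrom_rows["ratio"], 1.0, atol=0.05)

    def test_contig_variance_deterministic(self, coverage_matrix_factory):
        rng = np.random.default_rng(15)
        m = coverage_matrix_factory(rng.poisson(80, size=(3_000, 2)))
        a = contig_copy_number(m, seed=7)
        b = contig_copy_number(m, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestEndToEnd:
    def test_monotone_invariance_of_calls(self, coverage_matrix_factory):
        rng = np.random.default_rng(16)
        depths = rng.poisson(100, size=(3_000, 4)).astype(float)
        depths[1_000:1_300, :2] *= 2  # CNV in half the samples
        m1 = coverage_matrix_factory(depths)
        m2 = coverage_matrix_factory(
            np.column_stack([depths[:, 0] * 3, depths[:, 1] + 5,
                             depths[:, 2] ** 2, depths[:, 3]])
        )
        c1 = [(c.contig, c.start, c.end) for c in call_cnvs(m1)]
        c2 = [(c.contig, c.start, c.end) for c in call_cnvs(m2)]
        assert c1 == c2
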