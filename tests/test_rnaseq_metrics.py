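"""Depletion metrics, TPM, consistency statistics and ordination."""

import numpy as np
import pytest

import ribodeplete as rd
from ribodeplete.rnaseq_metrics import MetricsError, ReadClassification


def profile(sample_id, counts, lengths=None):
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths if lengths is not None else [100] * len(counts))
    return rd.ExpressionProfile(
        sample_id=sample_id,
        feature_ids=[f"g{i}" for i in range(len(counts))],
        counts=counts,
        lengths=lengths,
    )


class TestReadLevelMetrics:
    def test_rrna_fraction(self):
        cls = ReadClassification(n_rrna=940, n_genome_mapped=60, n_unmapped=0, n_cds=50)
        assert rd.rrna_fraction(cls) == pytest.approx(94.0)

    def test_zero_rrna(self):
        cls = ReadClassification(n_rrna=0, n_genome_mapped=10, n_unmapped=0, n_cds=0)
        assert rd.rrna_fraction(cls) == 0.0

    def test_zero_mapped_is_error(self):
        cls = ReadClassification(n_rrna=0, n_genome_mapped=0, n_unmapped=5, n_cds=0)
        with pytest.raises(MetricsError):
            rd.rrna_fraction(cls)

    @pytest.mark.parametrize(
        "before,after,expected",
        [(50.0, 50.0, 1.0), (94.0, 26.5, 12.25), (90.0, 0.0, 10.0)],
    )
    def test_fold_enrichment(self, before, after, expected):
        assert rd.fold_enrichment(before, after) == pytest.approx(expected)

    def test_fold_enrichment_undefined_at_total_rrna(self):
        with pytest.raises(MetricsError):
            rd.fold_enrichment(100.0, 50.0)

    def test_fold_enrichment_decreasing_in_p_after(self):
        values = [rd.fold_enrichment(90.0, p) for p in (10.0, 30.0, 60.0, 89.0)]
        assert values == sorted(values, reverse=True)

    def test_mappability_stats(self):
        cls = ReadClassification(n_rrna=0, n_genome_mapped=80, n_unmapped=20, n_cds=60)
        assert rd.mappability_stats(cls) == (pytest.approx(80.0), pytest.approx(75.0))

    def test_mappability_all_mapped_all_cds(self):
        cls = ReadClassification(n_rrna=10, n_genome_mapped=50, n_unmapped=0, n_cds=50)
        assert rd.mappability_stats(cls) == (pytest.approx(100.0), pytest.approx(100.0))


def aln(read_id, ref, pos, length, multi=False):
    return rd.ReadAlignmentRecord(read_id=read_id, ref_id=ref, pos=pos,
                                  aln_len=length, multi_mapped=multi)


class TestCdsCounts:
    FEATURES = [
        rd.CdsFeature("c", 101, 200, "+", "g1"),
        rd.CdsFeature("c", 201, 300, "-", "g2"),
    ]

    def test_read_inside_cds_counts(self):
        counts = rd.cds_counts([aln("r1", "c", 120, 30)], self.FEATURES)
        assert counts == {"g1": 1, "g2": 0}

    def test_multi_mapped_excluded(self):
        counts = rd.cds_counts([aln("r1", "c", 120, 30, multi=True)], self.FEATURES)
        assert counts == {"g1": 0, "g2": 0}

    def test_straddling_read_ambiguous(self):
        counts = rd.cds_counts([aln("r1", "c", 190, 30)], self.FEATURES)
        assert counts == {"g1": 0, "g2": 0}

    def test_one_bp_overlap_counts(self):
        counts = rd.cds_counts([aln("r1", "c", 71, 31)], self.FEATURES)
        assert counts == {"g1": 1, "g2": 0}

    def test_read_outside_all_cds(self):
        counts = rd.cds_counts([aln("r1", "c", 1, 50)], self.FEATURES)
        assert counts == {"g1": 0, "g2": 0}


class TestTpm:
    def test_single_cds(self):
        assert rd.tpm([7], [100])[0] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths(self):
        assert rd.tpm([5, 5], [100, 100]) == pytest.approx([5e5, 5e5])

    def test_length_normalization(self):
        out = rd.tpm([10, 20], [100, 400])
        assert out == pytest.approx([666666.6667, 333333.3333], abs=0.01)

    def test_all_zero_counts(self):
        assert rd.tpm([0, 0, 0], [10, 20, 30]) == pytest.approx([0, 0, 0])

    def test_sums_to_one_million(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 500, size=50)
            if counts.sum() == 0:
                continue
            lengths = rng.integers(100, 5000, size=50)
            assert rd.tpm(counts, lengths).sum() == pytest.approx(1e6, abs=1e-3)


def spearman_oracle(x, y):
    """Brute-force Spearman: average ranks computed by sorting, then the
    Pearson formula on the ranks."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for idx in order[i : j + 1]:
                ranks[idx] = mean_rank
            i = j + 1
        return np.array(ranks)

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestConsistency:
    def test_identical_profiles(self):
        a = profile("a", [10, 5, 80, 3, 40])
        b = profile("b", [10, 5, 80, 3, 40])
        rep = rd.consistency(a, b)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rs == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mwu_effect_size == pytest.approx(0.0)
        assert all(qa == pytest.approx(qb) for qa, qb in rep.qq_pairs)

    def test_tpm_scale_invariance(self):
        a = profile("a", [10, 5, 80, 3, 40])
        b = profile("b", [20, 10, 160, 6, 80])  # 2x counts -> identical TPM
        rep = rd.consistency(a, b)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mwu_effect_size == pytest.approx(0.0)

    def test_complete_separation_effect_size(self):
        a = profile("a", [1000, 2000, 4000], lengths=[100, 100, 100])
        b = profile("b", [1, 2, 4], lengths=[100, 100, 100])
        # TPM renormalizes, so force separation via raw tpm vectors
        a.tpm = np.array([1e5, 2e5, 3e5])
        b.tpm = np.array([1.0, 2.0, 3.0])
        rep = rd.consistency(a, b)
        assert abs(rep.mwu_effect_size) == pytest.approx(1.0)

    def test_r_squared_is_square_of_pearson(self, rng):
        a = profile("a", rng.integers(0, 300, size=40))
        b = profile("b", rng.integers(0, 300, size=40))
        rep = rd.consistency(a, b)
        assert rep.r_squared == pytest.approx(rep.pearson_r**2)

    def test_spearman_matches_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            a, b = profile("a", x), profile("b", y)
            rep = rd.consistency(a, b)
            expected = spearman_oracle(np.log10(a.tpm + 0.1), np.log10(b.tpm + 0.1))
            assert rep.spearman_rs == pytest.approx(expected, abs=1e-12)

    def test_too_few_cds_rejected(self):
        with pytest.raises(MetricsError):
            rd.consistency(profile("a", [1, 2]), profile("b", [2, 1]))

    def test_mismatched_universe_rejected(self):
        a, b = profile("a", [1, 2, 3]), profile("b", [1, 2, 3, 4])
        with pytest.raises(MetricsError):
            rd.consistency(a, b)


class TestMdsOrdination:
    def test_three_points_reproduce_distances(self, rng):
        profiles = [profile(f"s{i}", rng.integers(1, 500, size=30)) for i in range(3)]
        res = rd.mds_ordination(profiles)
        for i in range(3):
            for j in range(3):
                emb = np.linalg.norm(res.coordinates[i] - res.coordinates[j])
                assert emb == pytest.approx(res.distances[i, j], abs=1e-9)

    def test_distance_formula_bounds(self):
        # rs=1 -> d=0; rs=0 -> d=sqrt(2); rs=-1 -> d=2
        for rs, d in [(1.0, 0.0), (0.0, np.sqrt(2)), (-1.0, 2.0)]:
            assert np.sqrt(2 - 2 * rs) == pytest.approx(d, abs=1e-5)

    def test_distance_matrix_properties(self, rng):
        profiles = [profile(f"s{i}", rng.integers(1, 500, size=25)) for i in range(5)]
        res = rd.mds_ordination(profiles)
        assert np.allclose(res.distances, res.distances.T)
        assert np.allclose(np.diag(res.distances), 0.0)
        assert res.distances.max() <= 2.0 + 1e-12

    def test_sign_canonicalization(self, rng):
        profiles = [profile(f"s{i}", rng.integers(1, 500, size=25)) for i in range(4)]
        res = rd.mds_ordination(profiles)
        for axis in range(res.n_dims):
            pivot = next(i for i in range(4) if abs(res.coordinates[i, axis]) > 1e-12)
            assert res.coordinates[pivot, axis] >= 0

    def test_too_few_profiles_rejected(self, rng):
        with pytest.raises(MetricsError):
            rd.mds_ordination([profile("a", [1, 2, 3]), profile("b", [3, 2, 1])])


class TestPerTileDepletionEfficiency:
    def test_pseudocount_arithmetic(self):
        folds = rd.per_tile_depletion_efficiency(
            [100] * 50, [5] * 50, 1.0, 1.0, [(0, 50)])
        assert folds == [pytest.approx(100.5 / 5.5)]

    def test_identical_samples_fold_one(self):
        folds = rd.per_tile_depletion_efficiency(
            [7] * 100, [7] * 100, 10.0, 10.0, [(0, 50), (50, 100)])
        assert folds == [pytest.approx(1.0), pytest.approx(1.0)]

    def test_zero_depleted_coverage_finite(self):
        folds = rd.per_tile_depletion_efficiency(
            [50] * 40, [0] * 40, 1.0, 1.0, [(0, 40)])
        assert np.isfinite(folds[0]) and folds[0] == pytest.approx(50.5 / 0.5)

    def test_normalization_totals(self):
        # norm ratio scales the fold change
        folds = rd.per_tile_depletion_efficiency(
            [10] * 20, [10] * 20, 100.0, 50.0, [(0, 20)])
        assert folds == [pytest.approx(0.5)]

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError):
            rd.per_tile_depletion_efficiency([1] * 10, [1] * 9, 1.0, 1.0, [(0, 5)])


class TestDualPathClassification:
    def test_truth_and_sam_paths_agree_exactly(self, toy_organism, toy_library, tmp_path):
        cfg = rd.CommunityConfig(n_fragments=4000, seed=31)
        frags = rd.simulate_pool(cfg, toy_organism)
        survivors, truth = rd.apply_depletion(
            frags, toy_library, {p.probe_id: 0.0 for p in toy_library.probes},
            rd.DepletionModel(p_max=0.977), seed=32)
        paths = rd.emit_reads(survivors, truth, tmp_path / "dual",
                              organism=toy_organism, write_sam=True)
        cls_truth = rd.classify_truth(truth)
        records = rd.read_sam(paths["sam"])
        rrna_ids = {toy_organism.rrna_16s.id, toy_organism.rrna_23s.id}
        cls_sam = rd.classify_sam(records, rrna_ids, toy_organism.cds_features)
        assert rd.rrna_fraction(cls_sam) == rd.rrna_fraction(cls_truth)
        assert cls_sam.n_rrna == cls_truth.n_rrna
        assert cls_sam.n_genome_mapped == cls_truth.n_genome_mapped
        assert rd.mappability_stats(cls_sam) == rd.mappability_stats(cls_truth)
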