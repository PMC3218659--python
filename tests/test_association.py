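import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ldsplit import (
    EstimatorConfig,
    Hotspot,
    ScanConfig,
    association_p,
    call_hotspots,
    candidate_snps,
    delta_rho,
    estimate_rates,
    grubbs_outliers,
    maf_bin_stats,
    normality_gate,
    null_scan,
    pair_distances,
    permutation_null,
    qvalues,
    random_split,
    retest_without_outliers,
    scan,
    side_scores,
    split_by_allele,
    standardize,
)
from ldsplit.association import MafBinStats, PermutationNull, SideScoreTable, SplitTest

from conftest import make_panel


def fake_hotspot(start, end, center=None):
    return Hotspot(
        peak_center=center if center is not None else (start + end) / 2,
        start=start,
        end=end,
        strength=1.0,
        avg_rate_cm_mb=5.0,
    )


class TestSplitByAllele:
    def test_sperm_typing_sizes(self, rng):
        col = np.zeros(180, dtype=np.uint8)
        col[rng.choice(180, 63, replace=False)] = 1  # 63 T vs 117 C
        other = (rng.random(180) < 0.5).astype(np.uint8)
        p = make_panel(np.stack([col, other], axis=1))
        p0, p1 = split_by_allele(p, 0)
        assert (p0.n_chromosomes, p1.n_chromosomes) == (117, 63)

    def test_singleton_split(self):
        col = np.zeros(10, dtype=np.uint8)
        col[3] = 1
        p = make_panel(np.stack([col, 1 - col], axis=1))
        p0, p1 = split_by_allele(p, 0)
        assert (p0.n_chromosomes, p1.n_chromosomes) == (9, 1)

    def test_partition_preserves_rows(self, rng):
        mat = (rng.random((16, 4)) < 0.5).astype(np.uint8)
        mat[0, 0], mat[1, 0] = 0, 1
        p = make_panel(mat)
        p0, p1 = split_by_allele(p, 0)
        combined = sorted(
            map(tuple, np.vstack([p0.haplotypes, p1.haplotypes]).tolist())
        )
        assert combined == sorted(map(tuple, mat.tolist()))

    def test_monomorphic_errors(self):
        p = make_panel(np.zeros((6, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="monomorphic"):
            split_by_allele(p, 0)


class TestDeltaRho:
    @pytest.mark.parametrize(
        "r0,r1,expected", [(2, 2, 0.0), (3, 1, 0.5), (0, 5, -1.0), (0, 0, 0.0)]
    )
    def test_examples(self, r0, r1, expected):
        assert delta_rho(r0, r1) == pytest.approx(expected)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            delta_rho(-1, 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        assert delta_rho(a, b) == pytest.approx(-delta_rho(b, a))
        assert abs(delta_rho(a, b)) <= 1.0


class TestCandidateSnps:
    def build(self):
        g = np.random.default_rng(0)
        n = 20
        mat = np.zeros((n, 7), dtype=np.uint8)
        # MAFs: 0.5, 0.25, 0.4, 0.5, 0.3, 0.5, 0.1
        for j, k in enumerate([10, 5, 8, 10, 6, 10, 2]):
            mat[g.choice(n, k, replace=False), j] = 1
        pos = [1000, 2000, 3000, 4000, 5000, 6000, 7000]
        return make_panel(mat, positions=pos)

    def test_maf_filter(self):
        p = self.build()
        hs = fake_hotspot(2500.0, 5500.0)
        cands = candidate_snps(p, hs, maf_min=0.3, span_snps=200)
        assert 1 not in cands  # MAF 0.25
        assert 6 not in cands  # MAF 0.1
        assert 2 in cands and 4 in cands

    def test_span_limit(self):
        p = self.build()
        hs = fake_hotspot(2500.0, 4500.0)
        cands = candidate_snps(p, hs, maf_min=0.0, span_snps=1)
        # inside: snps 2,3; one beyond each boundary: snps 1 and 4
        assert cands == [1, 2, 3, 4]


class TestRandomSplit:
    def test_minimum_fraction(self):
        p = make_panel((np.arange(180 * 2).reshape(180, 2) % 2).astype(np.uint8))
        for seed in range(5):
            r0, r1 = random_split(p, 0.3, seed)
            assert min(len(r0), len(r1)) >= 54

    def test_seed_reproducible(self):
        p = make_panel((np.arange(40).reshape(20, 2) % 2).astype(np.uint8))
        a = random_split(p, 0.3, 7)
        b = random_split(p, 0.3, 7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_infeasible_fraction(self):
        p = make_panel((np.arange(40).reshape(20, 2) % 2).astype(np.uint8))
        with pytest.raises(ValueError, match="infeasible"):
            random_split(p, 0.6, 0)

    def test_keep_pairs_moves_homologs_together(self):
        p = make_panel((np.arange(40).reshape(20, 2) % 2).astype(np.uint8))
        r0, r1 = random_split(p, 0.3, 3, sizes=(10, 10), keep_pairs=True)
        for side in (r0, r1):
            for i in side:
                mate = i + 1 if i % 2 == 0 else i - 1
                assert mate in side


class TestAssociationP:
    def test_observed_exceeds_all(self):
        assert association_p(5.0, np.linspace(-1, 1, 200)) == 0.0

    def test_observed_zero_symmetric_null(self):
        null = np.concatenate([np.linspace(0.1, 1, 100), -np.linspace(0.1, 1, 100)])
        assert association_p(0.0, null) == 1.0

    def test_mixed_matches_count(self, rng):
        null = rng.normal(size=200)
        obs = 0.7
        expected = np.sum(np.abs(null) > abs(obs)) / 200
        assert association_p(obs, null) == pytest.approx(expected)

    def test_pseudo_count_correction(self):
        assert association_p(5.0, np.zeros(199), pseudo_count=True) == pytest.approx(
            1 / 200
        )


class TestMafBinStats:
    def test_constant_bin(self):
        s = MafBinStats(20).fit([0.4, 0.4, 0.4], [0.3, 0.3, 0.3])
        mean, sd = s.lookup(0.4)
        assert mean == pytest.approx(0.3) and sd == 0.0

    def test_two_value_bin(self):
        s = MafBinStats(20).fit([0.35, 0.35], [0.1, 0.3])
        mean, sd = s.lookup(0.35)
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.1414, abs=1e-4)

    def test_matches_groupby_oracle(self, rng):
        n = 40
        mafs = rng.integers(12, 21, size=60) / n
        deltas = rng.normal(size=60)
        s = MafBinStats(n).fit(mafs, deltas)
        import pandas as pd

        df = pd.DataFrame({"bin": np.round(mafs * n).astype(int), "d": deltas})
        for b, grp in df.groupby("bin"):
            if len(grp) >= 2:
                mean, sd = s.lookup(b / n)
                # bin may have been merged; only unmerged bins must match
                if s._bin_of[b] == b:
                    assert mean == pytest.approx(grp.d.mean())
                    assert sd == pytest.approx(grp.d.std(ddof=1))

    def test_sparse_bin_merged(self):
        s = MafBinStats(20).fit([0.30, 0.40, 0.40], [5.0, 0.1, 0.2])
        # the singleton 0.30 bin merges into the 0.40 bin
        assert s.merged_bins
        mean, _ = s.lookup(0.30)
        assert mean == pytest.approx(np.mean([5.0, 0.1, 0.2]))


class TestStandardize:
    def test_examples(self):
        s = MafBinStats(20).fit([0.4] * 3, [0.0, 0.1, 0.2])
        mean, sd = s.lookup(0.4)
        assert standardize(mean, 0.4, s) == 0.0
        s2 = MafBinStats(20)
        s2._stats = {8: (0.1, 0.2, 5)}
        s2._bin_of = {8: 8}
        assert standardize(0.5, 0.4, s2) == pytest.approx(2.0)

    def test_studentization(self, rng):
        vals = rng.normal(size=30)
        mafs = [0.4] * 30
        s = MafBinStats(20).fit(mafs, vals)
        zs = [standardize(v, 0.4, s) for v in vals]
        assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)
        assert np.std(zs, ddof=1) == pytest.approx(1.0)

    def test_zero_sd_errors(self):
        s = MafBinStats(20).fit([0.4] * 3, [0.3] * 3)
        with pytest.raises(ValueError, match="SD"):
            standardize(0.5, 0.4, s)


class TestQvalues:
    def test_all_ones(self):
        assert np.allclose(qvalues([1.0] * 8), 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    def test_monotone_in_p(self, ps):
        q = qvalues(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all()

    def test_storey_ten_value_oracle(self):
        p = np.array([0.01, 0.02, 0.9, 0.04, 0.5, 0.6, 0.03, 0.8, 0.7, 0.05])
        # direct evaluation of the Storey formula at lambda = 0.5
        m = len(p)
        pi0 = min(1.0, np.sum(p > 0.5) / (0.5 * m))
        order = np.argsort(p)
        expected = np.empty(m)
        prev = np.inf
        for rank in range(m, 0, -1):
            j = order[rank - 1]
            val = min(prev, pi0 * m * p[j] / rank)
            expected[j] = val
            prev = val
        assert np.allclose(qvalues(p), expected)


class TestSideScores:
    def null_with(self, deltas, membership):
        deltas = np.asarray(deltas, float)
        membership = np.asarray(membership, np.uint8)
        sizes = np.stack(
            [(membership == 0).sum(axis=1), (membership == 1).sum(axis=1)], axis=1
        )
        return PermutationNull(
            fake_hotspot(0.0, 10.0), deltas, membership, sizes, shapiro_p=1.0
        )

    def test_always_hot_side(self):
        # chromosome 0 on side 0 both times; side 0 hotter both times
        null = self.null_with([0.1, 0.2], [[0, 1, 1, 0], [0, 0, 1, 1]])
        t = side_scores(null, ["a", "b", "c", "d"])
        assert t.scores["a"] == pytest.approx(0.3)

    def test_always_cold_side(self):
        null = self.null_with([0.1, 0.2], [[1, 0, 0, 1], [1, 1, 0, 0]])
        t = side_scores(null, ["a", "b", "c", "d"])
        assert t.scores["a"] == pytest.approx(-0.3)

    def test_even_split_scores_sum_to_zero(self, rng):
        n, n_perm = 12, 25
        membership = np.zeros((n_perm, n), dtype=np.uint8)
        for i in range(n_perm):
            membership[i, rng.choice(n, n // 2, replace=False)] = 1
        deltas = rng.normal(size=n_perm)
        t = side_scores(self.null_with(deltas, membership), [str(i) for i in range(n)])
        assert sum(t.scores.values()) == pytest.approx(0.0, abs=1e-9)


class TestGrubbs:
    def test_single_gross_outlier(self):
        scores = {str(i): 0.0 for i in range(19)}
        scores["x"] = 10.0
        out = grubbs_outliers(SideScoreTable(scores), 0.1)
        assert out and out[0][0] == "x"

    def test_no_variance_no_outliers(self):
        scores = {str(i): 1.0 for i in range(10)}
        assert grubbs_outliers(SideScoreTable(scores), 0.1) == []

    def test_needs_seven(self):
        with pytest.raises(ValueError):
            grubbs_outliers(SideScoreTable({str(i): float(i) for i in range(5)}), 0.1)

    def test_statistic_matches_hand_formula(self):
        vals = [1.2, 0.9, 1.1, 1.0, 0.95, 1.05, 1.0, 0.98, 1.02, 1.3, 0.9, 4.0]
        n = len(vals)
        arr = np.array(vals)
        G = np.max(np.abs(arr - arr.mean())) / arr.std(ddof=1)
        t = np.sqrt(n * (n - 2) * G**2 / ((n - 1) ** 2 - n * G**2))
        p_expected = min(1.0, 2 * n * sps.t.sf(t, n - 2))
        table = SideScoreTable({str(i): v for i, v in enumerate(vals)})
        out = grubbs_outliers(table, p_threshold=max(p_expected * 2, 1e-12))
        assert out[0][0] == "11"
        assert out[0][1] == pytest.approx(p_expected)


class TestNormalityGate:
    def make_null(self, shapiro_p, n=200):
        return PermutationNull(
            fake_hotspot(0.0, 10.0),
            np.zeros(n),
            np.zeros((n, 4), dtype=np.uint8),
            np.tile([2, 2], (n, 1)),
            shapiro_p=shapiro_p,
        )

    def test_threshold(self):
        assert not normality_gate(self.make_null(0.03))
        assert normality_gate(self.make_null(0.06))

    def test_requires_three(self):
        with pytest.raises(ValueError):
            normality_gate(self.make_null(0.5, n=2))


class TestPairDistances:
    def panel(self):
        pos = [1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000, 9000]
        g = np.random.default_rng(1)
        return make_panel((g.random((10, 9)) < 0.5).astype(np.uint8), positions=pos)

    def test_inside_zero(self):
        p = self.panel()
        hs = fake_hotspot(4000.0, 6000.0, center=5000.0)
        assert pair_distances(p, hs, 4) == (0.0, 0)

    def test_left_right_counts(self):
        p = self.panel()
        hs = fake_hotspot(4000.0, 6000.0, center=5000.0)
        # snp 0 at 1000: left, SNPs at 2000,3000 strictly between it and 4000
        assert pair_distances(p, hs, 0) == (-4000.0, 2)
        # snp 8 at 9000: right, SNPs at 7000,8000 between 6000 and 9000
        assert pair_distances(p, hs, 8) == (4000.0, 2)

    def test_symmetric_absolute_distance(self):
        p = self.panel()
        hs = fake_hotspot(4000.0, 6000.0, center=5000.0)
        d_left, _ = pair_distances(p, hs, 1)
        d_right, _ = pair_distances(p, hs, 7)
        assert abs(d_left) == abs(d_right)


class TestPermutationMachinery:
    def test_cardinality(self, sim_sample, fast_estimator):
        _, sample = sim_sample
        hs = fake_hotspot(95_000.0, 105_000.0, center=100_000.0)
        null = permutation_null(
            sample.panel, hs, fast_estimator, n_perm=6, rng=0, sizes=(19, 31)
        )
        assert null.n_perm == 6
        assert null.membership.shape == (6, sample.panel.n_chromosomes)
        assert ((null.sizes == (19, 31)) | (null.sizes == (31, 19))).all()

    def test_duplicated_haplotypes_give_zero_deltas(self, fast_estimator):
        row = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1], dtype=np.uint8)
        p = make_panel(np.tile(row, (24, 1)))
        hs = fake_hotspot(2000.0, 6000.0)
        null = permutation_null(p, hs, fast_estimator, n_perm=5, rng=1, sizes=(10, 14))
        assert np.allclose(null.deltas, 0.0)


class TestScan:
    def test_reproducible_bit_for_bit(self, sim_sample, fast_estimator):
        cfg, sample = sim_sample
        hs = call_hotspots(
            estimate_rates(sample.panel, fast_estimator), Ne=cfg.pop_size
        )
        sc = ScanConfig(n_perm=12)
        snps = candidate_snps(sample.panel, hs[0])[:3]
        a = scan(sample.panel, hs, fast_estimator, sc, rng=5, snp_subset=snps)
        b = scan(sample.panel, hs, fast_estimator, sc, rng=5, snp_subset=snps)
        assert [(t.snp, t.p_value, t.q_value, t.z) for t in a] == [
            (t.snp, t.p_value, t.q_value, t.z) for t in b
        ]

    def test_gated_hotspot_contributes_no_tests(self, sim_sample, fast_estimator):
        _, sample = sim_sample
        hs = fake_hotspot(95_000.0, 105_000.0, center=100_000.0)
        sc = ScanConfig(n_perm=12, shapiro_alpha=1.0)  # everything fails the gate
        tests = scan(sample.panel, [hs], fast_estimator, sc, rng=2)
        assert tests == []

    def test_null_scan_matches_sizes_and_count(self, sim_sample, fast_estimator):
        cfg, sample = sim_sample
        hs = call_hotspots(
            estimate_rates(sample.panel, fast_estimator), Ne=cfg.pop_size
        )
        sc = ScanConfig(n_perm=12)
        snps = candidate_snps(sample.panel, hs[0])[:3]
        tests = scan(sample.panel, hs, fast_estimator, sc, rng=5, snp_subset=snps)
        assert tests, "scan produced no tests"
        pseudo = null_scan(sample.panel, tests, fast_estimator, sc, rng=6)
        assert len(pseudo) == len(tests)
        for t, pt in zip(tests, pseudo):
            assert (pt.n0, pt.n1) == (t.n0, t.n1)

    def test_retest_with_empty_outliers_is_identity(
        self, sim_sample, fast_estimator
    ):
        cfg, sample = sim_sample
        hs = call_hotspots(
            estimate_rates(sample.panel, fast_estimator), Ne=cfg.pop_size
        )
        sc = ScanConfig(n_perm=12)
        snp = candidate_snps(sample.panel, hs[0])[0]
        direct = scan(
            sample.panel, [hs[0]], fast_estimator, sc, rng=9, snp_subset=[snp]
        )
        re = retest_without_outliers(
            sample.panel, hs[0], snp, [], fast_estimator, sc, rng=9
        )
        assert direct
        assert re.p_value == direct[0].p_value
        assert re.delta_rho == direct[0].delta_rho

    def test_retest_rejects_infeasible_removal(self, sim_sample, fast_estimator):
        cfg, sample = sim_sample
        hs = call_hotspots(
            estimate_rates(sample.panel, fast_estimator), Ne=cfg.pop_size
        )
        snp = candidate_snps(sample.panel, hs[0])[0]
        col = sample.panel.haplotypes[:, snp]
        minority = 0 if col.sum() > len(col) / 2 else 1
        drop = [
            cid
            for cid, a in zip(sample.panel.chromosome_ids, col)
            if a == minority
        ][:12]
        with pytest.raises(ValueError):
            retest_without_outliers(
                sample.panel, hs[0], snp, drop, fast_estimator, ScanConfig(n_perm=6),
                rng=0,
            )
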