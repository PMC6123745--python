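import numpy as np
import pytest

from mustat import (
    Dataset,
    InputError,
    PatternPool,
    ScanConfig,
    compute_mu,
    compute_mu_ld,
    compute_mu_sfs,
    compute_mu_var,
    relocate_tail,
    scan_incremental,
    scan_naive,
    window_location,
)
from mustat.snp_core import SNPChunk, build_chunk

from conftest import make_random_dataset


def assert_scans_equal(a, b):
    assert len(a) == len(b)
    for x, y in zip(a, b):
        assert x.position == y.position
        assert x.window_first_bp == y.window_first_bp
        assert x.window_last_bp == y.window_last_bp
        for attr in ("mu_var", "mu_sfs", "mu_ld", "mu"):
            assert getattr(x, attr) == pytest.approx(getattr(y, attr), rel=1e-9)


class TestFactors:
    @pytest.mark.parametrize(
        "first,last,d_ln,w,expected",
        [
            (1, 100, 100, 10, 0.099),
            (1, 101, 100, 10, 0.1),  # span equals the region: 1 / W_sz
            (2500, 3500, 100_000, 50, 2.0e-4),
        ],
    )
    def test_mu_var(self, first, last, d_ln, w, expected):
        assert compute_mu_var(first, last, d_ln, w) == pytest.approx(expected)

    def test_mu_var_rejects_bad_inputs(self):
        with pytest.raises(InputError):
            compute_mu_var(1, 10, 0, 10)
        with pytest.raises(InputError):
            compute_mu_var(10, 1, 100, 10)

    def test_mu_sfs_counts_singletons_and_high_frequency(self):
        counts = [1, 1, 1, 19, 19, 5, 6, 7, 8, 9]  # 3 singletons, 2 at S-1
        assert compute_mu_sfs(counts, 20) == pytest.approx(0.5)

    def test_mu_sfs_zero_without_edge_counts(self):
        assert compute_mu_sfs([5, 6, 7, 8], 20) == 0.0

    def test_mu_sfs_saturates_at_one(self):
        assert compute_mu_sfs([1] * 8, 20) == 1.0

    def test_mu_sfs_rejects_monomorphic_counts(self):
        with pytest.raises(InputError):
            compute_mu_sfs([0, 3], 20)
        with pytest.raises(InputError):
            compute_mu_sfs([3, 20], 20)

    def test_mu_ld_worked_example(self):
        """Pattern layout with n_SL=3, n_PL=2, n_SR=2, n_PR=1, P_Lsz=3,
        P_Rsz=2 gives (3*2 + 2*1)/(3*2) = 8/6."""
        left = [0, 1, 1, 2]  # patterns {0,1,2}; 0 and 1 absent from the right
        right = [2, 3, 3, 2]  # patterns {2,3}; only 3 absent from the left
        assert compute_mu_ld(left, right) == pytest.approx(8 / 6)

    def test_mu_ld_zero_when_all_patterns_shared(self):
        assert compute_mu_ld([0, 1, 0], [1, 0, 1]) == 0.0

    def test_mu_ld_private_pattern_per_half(self):
        # two copies of A vs two copies of B: (2*1 + 2*1)/(1*1) = 4
        assert compute_mu_ld([7, 7], [9, 9]) == pytest.approx(4.0)

    def test_mu_ld_rejects_empty_half(self):
        with pytest.raises(InputError):
            compute_mu_ld([], [1])

    def test_mu_composite_product(self):
        assert compute_mu(2.0e-4, 0.5, 8 / 6, 100_000, k=1.0) == pytest.approx(
            13.333, abs=1e-3
        )

    def test_mu_zero_factor_annihilates(self):
        assert compute_mu(0.0, 0.5, 2.0, 100_000) == 0.0

    def test_mu_k_zero_ignores_variation_factor(self):
        assert compute_mu(1e-4, 0.5, 2.0, 100_000, k=0.0) == pytest.approx(
            100_000 * 0.5 * 2.0
        )

    @pytest.mark.parametrize(
        "first,last,expected", [(100, 200, 150.0), (77, 77, 77.0), (1, 2, 1.5)]
    )
    def test_window_location_midpoint(self, first, last, expected):
        assert window_location(first, last) == expected


class TestScanConfig:
    def test_odd_window_rejected(self):
        with pytest.raises(InputError):
            ScanConfig(window_size=49)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ScanConfig(k=1.5)


class TestScanNaive:
    def test_score_count_law(self, rng):
        for s, d, w in [(8, 10, 10), (8, 100, 10), (20, 57, 4), (6, 230, 50)]:
            ds = make_random_dataset(rng, s, d)
            scores = scan_naive(ds, ScanConfig(window_size=w))
            assert len(scores) == max(0, ds.snp_count - w + 1)

    def test_exactly_one_window_when_sizes_match(self, rng):
        ds = make_random_dataset(rng, 8, 40)
        w = ds.snp_count if ds.snp_count % 2 == 0 else ds.snp_count - 1
        scores = scan_naive(
            Dataset(ds.genotypes[:w], ds.locations[:w], ds.region_length),
            ScanConfig(window_size=w),
        )
        assert len(scores) == 1

    def test_insufficient_snps_warns_and_returns_empty(self, rng):
        ds = make_random_dataset(rng, 8, 5)
        with pytest.warns(UserWarning):
            scores = scan_naive(ds, ScanConfig(window_size=10))
        assert scores == []

    def test_monomorphic_input_rejected(self):
        geno = np.zeros((4, 6), dtype=np.uint8)
        geno[1:, 0] = 1
        ds = Dataset(geno, [1, 2, 3, 4], 10)
        with pytest.raises(InputError):
            scan_naive(ds, ScanConfig(window_size=2))

    def test_masked_windows_flagged_but_counted(self, rng):
        ds = make_random_dataset(rng, 10, 100)
        cfg = ScanConfig(window_size=10, mask=[(1, ds.region_length)])
        scores = scan_naive(ds, cfg)
        assert len(scores) == ds.snp_count - 10 + 1
        assert all(sc.masked for sc in scores)


class TestIncrementalEqualsNaive:
    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        s = int(rng.integers(4, 33))
        w = int(rng.choice([4, 10, 26]))
        d = int(rng.integers(w, 600))
        ds = make_random_dataset(rng, s, d)
        cfg = ScanConfig(window_size=w)
        chunk = int(rng.choice([w, w + 3, 5 * w, 10**6]))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            naive = scan_naive(ds, cfg)
            incremental = scan_incremental(ds, cfg, max_chunk_snps=chunk)
        assert_scans_equal(naive, incremental)

    def test_multi_chunk_equals_single_chunk(self):
        rng = np.random.default_rng(99)
        ds = make_random_dataset(rng, 20, 500)
        cfg = ScanConfig(window_size=50)
        single = scan_incremental(ds, cfg)
        multi = scan_incremental(ds, cfg, max_chunk_snps=64)
        assert_scans_equal(single, multi)

    def test_pool_budget_forces_chunking(self):
        """A tiny pool budget triggers pool-full flushes without changing the
        output, and bounds the resident SNP storage."""
        from mustat import ChunkedScanner

        rng = np.random.default_rng(7)
        ds = make_random_dataset(rng, 8, 400, pattern_reuse=1.0)
        cfg = ScanConfig(window_size=10)
        budget = 12  # 12 patterns at 1 byte each (packed: ceil(8/8))
        scanner = ChunkedScanner(8, ds.region_length, cfg, pool_budget=budget)
        out = []
        counts = ds.derived_counts
        for i in range(ds.snp_count):
            out.extend(
                scanner.push(ds.genotypes[i], int(ds.locations[i]), int(counts[i]))
            )
        out.extend(scanner.finish())
        assert scanner.chunks_flushed > 0
        assert_scans_equal(scan_naive(ds, cfg), out)

    def test_duplicate_columns_at_same_position(self):
        geno = np.tile(np.array([0, 1, 1, 0], dtype=np.uint8), (6, 1))
        geno[3] = [1, 0, 0, 1]
        ds = Dataset(geno, [5, 5, 5, 7, 7, 9], 20)
        cfg = ScanConfig(window_size=4)
        assert_scans_equal(scan_naive(ds, cfg), scan_incremental(ds, cfg))


class TestRelocateTail:
    def _chunk_with_patterns(self, ids, pool_s=6):
        pool = PatternPool(pool_s)
        vecs = {}
        mapped = []
        for i in ids:
            if i not in vecs:
                v = np.zeros(pool_s, dtype=np.uint8)
                v[i % pool_s] = 1
                vecs[i] = v
            mapped.append(pool.match_or_insert(vecs[i])[0])
        n = len(ids)
        chunk = SNPChunk(mapped, np.arange(1, n + 1), np.ones(n, dtype=np.int64))
        return chunk, pool

    def test_tail_pool_holds_exactly_tail_patterns(self):
        # 20 SNPs, window 10 -> tail of 9; tail uses 4 distinct patterns
        ids = [0, 1, 2, 3, 4] * 2 + [5, 0, 5, 0, 1, 1, 0, 5, 2]
        chunk, pool = self._chunk_with_patterns(ids, pool_s=8)
        new_chunk, new_pool = relocate_tail(chunk, pool, window_size=10)
        assert len(new_chunk) == 9
        assert len(new_pool) == 4  # {5, 0, 1, 2}
        # content preserved under the re-mapping
        old_tail = [pool.pattern(int(i)).tobytes() for i in chunk.pattern_ids[-9:]]
        new_tail = [new_pool.pattern(int(i)).tobytes() for i in new_chunk.pattern_ids]
        assert old_tail == new_tail

    def test_minimal_window_keeps_one_snp(self):
        chunk, pool = self._chunk_with_patterns([0, 1, 2])
        new_chunk, new_pool = relocate_tail(chunk, pool, window_size=2)
        assert len(new_chunk) == 1
        assert len(new_pool) == 1

    def test_short_chunk_fully_retained(self):
        chunk, pool = self._chunk_with_patterns([0, 1, 2])
        new_chunk, new_pool = relocate_tail(chunk, pool, window_size=4)
        assert len(new_chunk) == 3
        assert new_chunk.pattern_ids.tolist() == [0, 1, 2]


class TestInvariants:
    def test_region_length_cancels_for_k1(self, rng):
        """For k = 1 the region length cancels between the composite score and
        the diversity factor: doubling D_ln leaves every mu unchanged."""
        ds = make_random_dataset(rng, 16, 200, region_length=5000)
        doubled = Dataset(ds.genotypes, ds.locations, 2 * ds.region_length)
        a = scan_naive(ds, ScanConfig(window_size=20, k=1.0))
        b = scan_naive(doubled, ScanConfig(window_size=20, k=1.0))
        assert [x.position for x in a] == [x.position for x in b]
        assert [x.mu for x in a] == pytest.approx([x.mu for x in b], rel=1e-12)

    def test_sample_permutation_invariance(self, rng):
        ds = make_random_dataset(rng, 14, 150)
        perm = rng.permutation(ds.sample_count)
        permuted = Dataset(ds.genotypes[:, perm], ds.locations, ds.region_length)
        a = scan_naive(ds, ScanConfig(window_size=10))
        b = scan_naive(permuted, ScanConfig(window_size=10))
        assert [x.mu for x in a] == [x.mu for x in b]

    def test_factor_bounds(self, rng):
        w = 10
        for seed in range(5):
            ds = make_random_dataset(np.random.default_rng(seed), 10, 150)
            for sc in scan_naive(ds, ScanConfig(window_size=w)):
                assert 0.0 <= sc.mu_sfs <= 1.0
                assert sc.mu_var >= 0.0
                assert 0.0 <= sc.mu_ld <= 2 * (w // 2) * (w // 2)
                assert np.isfinite(sc.mu) and sc.mu >= 0.0
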