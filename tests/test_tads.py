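"""TAD caller: insulation signal, gap detection, boundary calls, borders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadrisk.simulate import SimConfig, plant_tads, simulate_contact_matrix
from tadrisk.tads import (ContactMatrix, TAD, TADCallConfig,
                          border_genome_fraction, call_tads,
                          call_tads_multi_k, compute_bin_signal, detect_gaps,
                          extract_borders, merge_intervals, _local_minima)


def brute_force_signal(c: np.ndarray, k: int, b: int) -> float:
    n = c.shape[0]
    vals = [c[i, j]
            for i in range(max(0, b - k), b)
            for j in range(b, min(n, b + k))]
    return float(np.mean(vals))


class TestSignal:
    def test_constant_matrix_gives_constant_signal(self):
        c = np.full((8, 8), 3.0)
        cm = ContactMatrix("chr1", 10_000, c)
        sig = compute_bin_signal(cm, 2)
        assert np.allclose(sig[1:], 3.0)

    def test_k1_is_single_adjacent_entry(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 20, (6, 6)).astype(float)
        c = (c + c.T) / 2
        cm = ContactMatrix("chr1", 10_000, c)
        sig = compute_bin_signal(cm, 1)
        for b in range(1, 6):
            assert sig[b] == c[b - 1, b]

    def test_four_bin_worked_example(self):
        c = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], float)
        sig = compute_bin_signal(ContactMatrix("chr1", 10_000, c), 2)
        assert sig[2] == pytest.approx(3.5)  # mean(2, 3, 4, 5)

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_matches_brute_force_submatrix_mean(self, k):
        rng = np.random.default_rng(42)
        c = rng.poisson(6, (15, 15)).astype(float)
        c = c + c.T
        cm = ContactMatrix("chr1", 10_000, c)
        sig = compute_bin_signal(cm, k)
        for b in range(1, 15):
            assert sig[b] == pytest.approx(brute_force_signal(c, k, b))

    def test_k_too_large_errors(self):
        cm = ContactMatrix("chr1", 10_000, np.ones((4, 4)))
        with pytest.raises(ValueError):
            compute_bin_signal(cm, 4)

    def test_chromosome_relabeling_is_equivariant(self, two_block_matrix):
        other = ContactMatrix("chrX", two_block_matrix.bin_size,
                              two_block_matrix.counts)
        s1 = compute_bin_signal(two_block_matrix, 2)
        s2 = compute_bin_signal(other, 2)
        assert np.array_equal(s1, s2, equal_nan=True)


class TestGaps:
    def test_all_positive_no_gaps(self):
        c = np.full((5, 5), 4.0)
        assert not detect_gaps(ContactMatrix("chr1", 10_000, c)).any()

    def test_zero_row_is_gap(self):
        c = np.full((5, 5), 4.0)
        c[2, :] = 0.0
        c[:, 2] = 0.0
        gaps = detect_gaps(ContactMatrix("chr1", 10_000, c))
        assert gaps.tolist() == [False, False, True, False, False]

    def test_threshold_arithmetic(self):
        # off-diagonal row sums (100, 100, 3, 100); 3 < 0.05 * median(=100)
        c = np.array([
            [0, 49.5, 1, 49.5],
            [49.5, 0, 1, 49.5],
            [1, 1, 0, 1],
            [49.5, 49.5, 1, 0],
        ])
        gaps = detect_gaps(ContactMatrix("chr1", 10_000, c), gap_zero_fraction=0.05)
        assert gaps.tolist() == [False, False, True, False]

    def test_idempotent_on_masked_matrix(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(10, (30, 30)).astype(float)
        c = c + c.T
        c[5, :] = 0.0
        c[:, 5] = 0.0
        cm = ContactMatrix("chr1", 10_000, c)
        gaps = detect_gaps(cm)
        masked = c.copy()
        masked[gaps, :] = 0.0
        masked[:, gaps] = 0.0
        again = detect_gaps(ContactMatrix("chr1", 10_000, masked))
        assert np.array_equal(gaps, again)

    def test_all_gap_chromosome_errors(self):
        with pytest.raises(ValueError):
            detect_gaps(ContactMatrix("chr1", 10_000, np.zeros((4, 4))))

    def test_adding_contacts_to_gap_bin_never_creates_gaps(self):
        rng = np.random.default_rng(2)
        c = rng.poisson(20, (40, 40)).astype(float)
        c = c + c.T
        c[7, :] = 0.0
        c[:, 7] = 0.0
        cm = ContactMatrix("chr1", 10_000, c)
        before = detect_gaps(cm)
        filled = c.copy()
        filled[7, :] = 20.0
        filled[:, 7] = 20.0
        np.fill_diagonal(filled, 0.0)
        after = detect_gaps(ContactMatrix("chr1", 10_000, filled))
        assert not after[7]
        assert not (after & ~before).any()


class TestCallTads:
    def test_uniform_matrix_single_tad(self):
        cm = ContactMatrix("chr1", 10_000, np.full((10, 10), 2.0))
        tads = call_tads(cm, TADCallConfig(k=3, statistical_filter=False))
        assert [(t.start_bin, t.end_bin) for t in tads] == [(0, 10)]

    def test_two_block_matrix(self, two_block_matrix):
        tads = call_tads(two_block_matrix,
                         TADCallConfig(k=2, statistical_filter=False))
        assert [(t.start_bin, t.end_bin) for t in tads] == [(0, 3), (3, 6)]
        # the hand-derived insulation profile behind the call
        sig = compute_bin_signal(two_block_matrix, 2)
        assert np.allclose(sig[1:], [5, 3, 1, 3, 5])

    def test_plateau_minimum_reports_leftmost(self):
        sig = np.array([np.nan, 5.0, 1.0, 1.0, 5.0, 6.0])
        assert _local_minima(sig, 0, 6) == [2]

    def test_no_tad_spans_a_gap_run(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(seed=3, n_chromosomes=1, bins_per_chromosome=100,
                        tad_size_range=(5, 20),
                        gap_bins={"chr1": [40, 41, 42]})
        truth = plant_tads(cfg.layout, cfg.tad_size_range, 3,
                           gap_bins=cfg.gap_bins)
        m = simulate_contact_matrix(truth, cfg, 30)
        tads = call_tads(m, TADCallConfig(k=4))
        for t in tads:
            assert not (t.start_bin < 41 < t.end_bin)

    def test_multi_k_matches_single_calls_and_is_deterministic(self, two_block_matrix):
        cfg = TADCallConfig(k_range=(2,), statistical_filter=False)
        multi = call_tads_multi_k(two_block_matrix, cfg)
        assert set(multi) == {2}
        single = call_tads(
            two_block_matrix,
            TADCallConfig(k=2, statistical_filter=False,
                          gap_zero_fraction=cfg.gap_zero_fraction),
        )
        assert multi[2] == single
        again = call_tads_multi_k(two_block_matrix, cfg)
        assert multi == again

    @staticmethod
    def _nested_matrix(seed, n=300, big=30, sub=10, A=10.0, alpha=1.0,
                       B_big=2.0, B_sub=2.5):
        """Two-level domain hierarchy: 30-bin blocks split into 10-bin
        sub-domains, the regime where window size determines which level
        the caller resolves."""
        rng = np.random.default_rng(seed)
        idx = np.arange(n)
        d = np.abs(np.subtract.outer(idx, idx)).astype(float)
        lam = A * (1 + d) ** (-alpha)
        lam *= np.where(idx[:, None] // big == idx[None, :] // big, B_big, 1.0)
        lam *= np.where(idx[:, None] // sub == idx[None, :] // sub, B_sub, 1.0)
        iu = np.triu_indices(n, 1)
        c = np.zeros((n, n))
        c[iu] = rng.poisson(lam[iu])
        return ContactMatrix("chr1", 10_000, c + c.T)

    def test_smaller_k_resolves_substructure_into_more_tads(self):
        # small windows extract sub-domains, large windows only the outer
        # blocks, so #TADs(k=3) >= #TADs(k=15) in nearly every seed
        wins = 0
        for seed in range(10):
            calls = call_tads_multi_k(self._nested_matrix(seed),
                                      TADCallConfig(k_range=(3, 15)))
            if len(calls[3]) >= len(calls[15]):
                wins += 1
        assert wins >= 8


class TestBorders:
    def test_long_tad_two_20kb_borders(self):
        tads = [TAD("chr1", 10, 30, 5)]  # [100000, 300000) bp
        bs = extract_borders(tads, border_bp=20_000, bin_size=10_000)
        ivals = sorted(map(tuple, bs.intervals[["start", "end"]].to_numpy()))
        assert ivals == [(100_000, 120_000), (280_000, 300_000)]
        assert bs.union_bp == 40_000

    def test_40kb_tad_tiles_exactly(self):
        bs = extract_borders([TAD("chr1", 0, 4, 5)], 20_000, 10_000)
        assert bs.union_bp == 40_000
        assert merge_intervals(bs.intervals[["start", "end"]].to_numpy()).tolist() \
            == [[0, 40_000]]

    def test_30kb_tad_clipped_at_midpoint(self):
        bs = extract_borders([TAD("chr1", 0, 3, 5)], 20_000, 10_000)
        ivals = sorted(map(tuple, bs.intervals[["start", "end"]].to_numpy()))
        assert ivals == [(0, 15_000), (15_000, 30_000)]
        assert bs.union_bp == 30_000

    def test_empty_tadset_empty_borderset(self):
        bs = extract_borders([], 20_000, 10_000)
        assert bs.intervals.empty and bs.union_bp == 0

    def test_borders_lie_inside_parent_tad(self):
        rng = np.random.default_rng(7)
        tads, pos = [], 0
        for _ in range(20):
            size = int(rng.integers(2, 12))
            tads.append(TAD("chr1", pos, pos + size, 5))
            pos += size
        bs = extract_borders(tads, 20_000, 10_000)
        for row in bs.intervals.itertuples():
            assert row.tad_start <= row.start < row.end <= row.tad_end
            assert row.end - row.start <= 20_000

    def test_idempotent_on_same_tads(self):
        tads = [TAD("chr1", 0, 10, 4), TAD("chr1", 10, 13, 4)]
        a = extract_borders(tads, 20_000, 10_000)
        b = extract_borders(tads, 20_000, 10_000)
        assert a.intervals.equals(b.intervals)

    def test_genome_fraction_worked_examples(self):
        one = extract_borders([TAD("chr1", 0, 10, 3)], 20_000, 10_000)
        assert border_genome_fraction(one, 100_000) == pytest.approx(0.40)
        two = extract_borders(
            [TAD("chr1", 0, 10, 3), TAD("chr1", 50, 60, 3)], 20_000, 10_000
        )
        assert border_genome_fraction(two, 1_000_000) == pytest.approx(0.08)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=1, max_size=20))
    def test_union_never_exceeds_interval_sum(self, pairs):
        iv = np.array([[s, s + w] for s, w in pairs])
        merged = merge_intervals(iv)
        assert (merged[:, 1] > merged[:, 0]).all()
        assert (merged[1:, 0] > merged[:-1, 1]).all() or len(merged) == 1
        assert (merged[:, 1] - merged[:, 0]).sum() <= (iv[:, 1] - iv[:, 0]).sum()
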