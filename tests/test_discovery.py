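import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chromotif.discovery import (
    KmerMotifDiscovery,
    count_occurrences,
    discover,
    enumerate_kmers,
    occurrence_rate,
    paired_t_test,
    write_results_tsv,
)

from conftest import make_pair, planted_pairs, random_dna


def brute_force_count(kmer: str, seq: str) -> int:
    """Independent all-offsets oracle for sliding-window counting."""
    k = len(kmer)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == kmer)


class TestEnumerateKmers:
    def test_single_base(self):
        assert list(enumerate_kmers(1, 1)) == ["A", "C", "G", "T"]

    def test_dimers(self):
        dimers = list(enumerate_kmers(2, 2))
        assert len(dimers) == 16
        assert dimers[0] == "AA" and dimers[-1] == "TT"

    def test_counts_and_uniqueness(self):
        kmers = list(enumerate_kmers(2, 4))
        assert len(kmers) == 16 + 64 + 256
        assert len(set(kmers)) == len(kmers)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            list(enumerate_kmers(3, 2))


class TestCountOccurrences:
    @pytest.mark.parametrize(
        "kmer,seq,expected",
        [
            ("CTC", "CTCTC", 2),   # overlapping hits at offsets 0 and 2
            ("AAA", "CCCCCCC", 0),
            ("AAA", "AAAA", 2),
            ("ACGT", "ACG", 0),    # k-mer longer than the window
            ("ctc", "CTCTC", 2),   # case-insensitive
            ("AN", "AANAA", 0),    # N never matches
        ],
    )
    def test_examples(self, kmer, seq, expected):
        assert count_occurrences(kmer, seq) == expected

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(1, 10), st.integers(0))
    def test_matches_brute_force_oracle(self, k, seed):
        rng = np.random.default_rng(seed % 2**31)
        window = random_dna(rng, 41)
        kmer = random_dna(rng, k)
        assert count_occurrences(kmer, window) == brute_force_count(kmer, window)


class TestPairedTTest:
    def test_worked_example_vectors(self):
        t, p = paired_t_test([2, 2, 0], [1, 0, 0])
        assert t == pytest.approx(math.sqrt(3), rel=1e-12)
        assert p == pytest.approx(0.2254, abs=2e-4)

    def test_identical_vectors(self):
        assert paired_t_test([3, 1, 4], [3, 1, 4]) == (0.0, 1.0)

    def test_swap_negates_t(self):
        t1, p1 = paired_t_test([2, 2, 0], [1, 0, 0])
        t2, p2 = paired_t_test([1, 0, 0], [2, 2, 0])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_nonzero_mean(self):
        t, p = paired_t_test([2, 3, 4], [1, 2, 3])
        assert t == math.inf and p == 0.0
        t, p = paired_t_test([1, 2, 3], [2, 3, 4])
        assert t == -math.inf and p == 0.0

    @pytest.mark.parametrize("x,y", [([1], [2]), ([1, 2], [1, 2, 3])])
    def test_invalid_inputs(self, x, y):
        with pytest.raises(ValueError):
            paired_t_test(x, y)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0), st.integers(3, 30))
    def test_matches_scipy(self, seed, n):
        rng = np.random.default_rng(seed % 2**31)
        x = rng.integers(0, 6, size=n)
        y = rng.integers(0, 6, size=n)
        if np.all(x - y == (x - y)[0]):
            return  # degenerate case covered above; scipy returns nan
        t_ref, p_ref = sps.ttest_rel(x, y)
        t, p = paired_t_test(x, y)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)


class TestOccurrenceRate:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 2, 0], 2 / 3), ([0, 0, 0, 0], 0.0), ([1, 5, 2], 1.0)],
    )
    def test_examples(self, counts, expected):
        assert occurrence_rate(counts) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            occurrence_rate([])


class TestDiscover:
    def test_planted_motif_separates(self, rng):
        pairs = planted_pairs(rng, n_pairs=12, motif="CACGTG")
        results = discover(pairs, kmin=6, kmax=6)
        by_kmer = {r.kmer: r for r in results}
        assert "CACGTG" in by_kmer
        r = by_kmer["CACGTG"]
        assert r.rate_accessible == 1.0
        assert r.p_value < 0.01
        assert r.t_stat < 0  # enriched on the accessible allele
        assert r.antisense == "CACGTG"  # palindromic

    def test_degenerate_variance_convention_selected(self):
        # constant difference d = [1,1,1]: sd 0, nonzero mean -> p = 0
        pairs = [
            make_pair("CTCAAAA", "AAAAAAA", pos=1000 + i) for i in range(3)
        ]
        results = discover(pairs, kmin=3, kmax=3)
        r = {x.kmer: x for x in results}["CTC"]
        assert r.p_value == 0.0 and r.t_stat == math.inf

    def test_rate_filter_excludes_rare_kmer(self, rng):
        # a k-mer present once among 300 windows: rate 1/300 < 1% fails even at p ~ 0
        est = KmerMotifDiscovery(kmin=6, kmax=6, keep_all=True)
        windows = [random_dna(rng, 41) for _ in range(300)]
        pairs = [
            make_pair(w, w[:20] + ("A" if w[20] != "A" else "C") + w[21:], pos=10**6 + i)
            for i, w in enumerate(windows)
        ]
        est.fit(pairs)
        for r in est.all_results_:
            if max(r.rate_accessible, r.rate_inaccessible) <= est.rate_min:
                assert r not in est.results_

    def test_results_sorted_by_p_then_kmer(self, rng):
        pairs = planted_pairs(rng, n_pairs=10)
        results = discover(pairs, kmin=6, kmax=7, p_max=1.1, rate_min=0.0)
        keys = [(r.p_value, r.kmer) for r in results]
        assert keys == sorted(keys)

    def test_vectorized_stats_match_scalar_oracles(self, rng):
        """Dual route: the batched sparse-table statistics must equal
        per-k-mer counting plus the scalar paired t-test."""
        pairs = planted_pairs(rng, n_pairs=8, motif="CAC", flank=6)
        est = KmerMotifDiscovery(kmin=2, kmax=3, keep_all=True).fit(pairs)
        assert est.all_results_  # every observed candidate is present
        for r in est.all_results_:
            ci = tuple(count_occurrences(r.kmer, p.seq_inaccessible) for p in pairs)
            ca = tuple(count_occurrences(r.kmer, p.seq_accessible) for p in pairs)
            assert r.counts_inaccessible == ci
            assert r.counts_accessible == ca
            t, p = paired_t_test(ci, ca)
            assert r.t_stat == pytest.approx(t, rel=1e-9) or (
                math.isinf(t) and r.t_stat == t
            )
            assert r.p_value == pytest.approx(p, abs=1e-12)
            assert r.rate_inaccessible == pytest.approx(occurrence_rate(ci))
            assert r.rate_accessible == pytest.approx(occurrence_rate(ca))

    def test_label_swap_negates_t_and_keeps_selection(self, rng):
        pairs = planted_pairs(rng, n_pairs=10)
        swapped = []
        for p in pairs:
            swapped.append(
                make_pair(p.seq_accessible, p.seq_inaccessible, pos=p.snp.pos)
            )
        a = KmerMotifDiscovery(kmin=6, kmax=6, keep_all=True).fit(pairs)
        b = KmerMotifDiscovery(kmin=6, kmax=6, keep_all=True).fit(swapped)
        ra = {r.kmer: r for r in a.all_results_}
        rb = {r.kmer: r for r in b.all_results_}
        assert set(ra) == set(rb)
        for kmer in ra:
            assert rb[kmer].t_stat == pytest.approx(-ra[kmer].t_stat) or (
                math.isinf(ra[kmer].t_stat) and rb[kmer].t_stat == -ra[kmer].t_stat
            )
            assert rb[kmer].p_value == pytest.approx(ra[kmer].p_value, abs=1e-12)
        assert {r.kmer for r in a.results_} == {r.kmer for r in b.results_}

    def test_needs_two_pairs(self, rng):
        with pytest.raises(ValueError):
            discover(planted_pairs(rng, n_pairs=1))

    def test_write_results_tsv(self, rng, tmp_path):
        import pandas as pd

        pairs = planted_pairs(rng, n_pairs=10)
        results = discover(pairs, kmin=6, kmax=6)
        out = tmp_path / "motifs.tsv"
        write_results_tsv(results, out, "genome-wide")
        df = pd.read_csv(out, sep="\t")
        assert list(df["kmer"]) == [r.kmer for r in results]
        assert (df["bh_fdr"] >= df["p_value"] - 1e-12).all()
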