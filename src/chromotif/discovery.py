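"""Exhaustive k-mer chromatin-motif discovery over DCSR pairs.

Every DNA word of length 6-10 (1,396,736 candidates) is a motif candidate.
For each candidate we count overlapping sliding-window occurrences in the
inaccessible and accessible window of every DCSR pair, giving two paired
frequency vectors, and run a paired t-test between them. A candidate is
reported as a chromatin motif when its two-sided p-value is < 0.01 and it
occurs in more than 1% of either the accessible or the inaccessible windows.

Counting is forward-strand only on each stored window; the reverse
complement is reported as metadata (palindromes such as CACGTG are their own
antisense and would double-count under strand merging). Candidates that
never occur in any window have identically zero vectors (t = 0, p = 1) and
can never pass the occurrence-rate filter, so the implementation only
materialises statistics for k-mers observed at least once.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from chromotif.dcsr import DCSRPair
from chromotif.diploid_io import reverse_complement

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class KmerResult:
    """Discovery statistics for one k-mer candidate.

    ``counts_inaccessible[i]`` and ``counts_accessible[i]`` are the
    sliding-window hit counts in the i-th DCSR pair; the paired t-test is on
    their difference (inaccessible minus accessible), so positive ``t_stat``
    means the motif is more frequent on the inaccessible allele.
    """

    kmer: str
    antisense: str
    counts_inaccessible: tuple[int, ...]
    counts_accessible: tuple[int, ...]
    t_stat: float
    p_value: float
    rate_inaccessible: float
    rate_accessible: float
    n_pairs: int


def enumerate_kmers(kmin: int, kmax: int) -> Iterator[str]:
    """Yield every DNA word of each length in [kmin, kmax], lexicographically."""
    if not 1 <= kmin <= kmax:
        raise ValueError(f"need 1 <= kmin <= kmax, got ({kmin}, {kmax})")
    for k in range(kmin, kmax + 1):
        for letters in itertools.product(_ALPHABET, repeat=k):
            yield "".join(letters)


def count_occurrences(kmer: str, window_seq: str) -> int:
    """Number of (possibly overlapping) exact occurrences of ``kmer`` in
    ``window_seq``. Matching is case-insensitive; N never matches. A k-mer
    longer than the window has zero occurrences."""
    kmer = kmer.upper()
    seq = window_seq.upper()
    if "N" in kmer:
        return 0
    n = 0
    i = seq.find(kmer)
    while i != -1:
        n += 1
        i = seq.find(kmer, i + 1)
    return n


def paired_t_test(x: Sequence[int], y: Sequence[int]) -> tuple[float, float]:
    """Paired t-test on the differences d = x - y.

    t = mean(d) / (sd(d)/sqrt(n)) with the sample standard deviation (n-1
    denominator); the two-sided p-value comes from Student's t with n-1
    degrees of freedom. Degenerate conventions: when sd(d) == 0, the result
    is (0, 1) if mean(d) == 0 and (signed infinity, 0) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got n={n}")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def occurrence_rate(counts: Sequence[int]) -> float:
    """Fraction of windows containing at least one occurrence."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("occurrence_rate needs a non-empty vector")
    return float((counts >= 1).sum() / counts.size)


def _sparse_counts(
    windows: Sequence[str], kmin: int, kmax: int
) -> dict[str, dict[int, int]]:
    """One pass over all windows building kmer -> {window index: hits}."""
    table: dict[str, dict[int, int]] = {}
    for i, seq in enumerate(windows):
        L = len(seq)
        for k in range(kmin, min(kmax, L) + 1):
            for off in range(L - k + 1):
                sub = seq[off : off + k]
                if "N" in sub:
                    continue
                table.setdefault(sub, {}).setdefault(i, 0)
                table[sub][i] += 1
    return table


class KmerMotifDiscovery(BaseEstimator):
    """Exhaustive 6-10mer differential-occurrence testing over DCSR pairs.

    Parameters
    ----------
    kmin, kmax : candidate lengths, inclusive (defaults 6 and 10).
    p_max : strict two-sided p-value cutoff for selection (default 0.01).
    rate_min : strict occurrence-rate cutoff; a candidate is kept when
        max(rate_accessible, rate_inaccessible) > rate_min (default 0.01).
    keep_all : also retain statistics for every observed candidate
        (``all_results_``), not just the selected motifs.

    Attributes
    ----------
    results_ : selected motifs sorted by ascending p-value, ties broken
        lexicographically by k-mer.
    all_results_ : every observed candidate (same ordering) when
        ``keep_all`` is set.
    n_pairs_ : number of DCSR pairs tested.
    n_candidates_observed_ : number of distinct candidates with >= 1 hit.
    """

    def __init__(
        self,
        kmin: int = 6,
        kmax: int = 10,
        p_max: float = 0.01,
        rate_min: float = 0.01,
        keep_all: bool = False,
    ):
        self.kmin = kmin
        self.kmax = kmax
        self.p_max = p_max
        self.rate_min = rate_min
        self.keep_all = keep_all

    def fit(self, pairs: Sequence[DCSRPair]) -> "KmerMotifDiscovery":
        if not 1 <= self.kmin <= self.kmax:
            raise ValueError(f"need 1 <= kmin <= kmax, got ({self.kmin}, {self.kmax})")
        n = len(pairs)
        if n < 2:
            raise ValueError("discovery needs at least 2 DCSR pairs")

        inacc = [p.seq_inaccessible for p in pairs]
        acc = [p.seq_accessible for p in pairs]
        t_in = _sparse_counts(inacc, self.kmin, self.kmax)
        t_ac = _sparse_counts(acc, self.kmin, self.kmax)

        kmers = sorted(set(t_in) | set(t_ac))
        m = len(kmers)
        sum_d = np.zeros(m)
        sum_d2 = np.zeros(m)
        hit_in = np.zeros(m, dtype=np.int64)
        hit_ac = np.zeros(m, dtype=np.int64)

        sparse: list[dict[int, tuple[int, int]]] = []
        for j, kmer in enumerate(kmers):
            ci = t_in.get(kmer, {})
            ca = t_ac.get(kmer, {})
            merged: dict[int, tuple[int, int]] = {}
            for i, c in ci.items():
                merged[i] = (c, 0)
            for i, c in ca.items():
                prev = merged.get(i, (0, 0))
                merged[i] = (prev[0], c)
            sparse.append(merged)
            hit_in[j] = len(ci)
            hit_ac[j] = len(ca)
            for c_in, c_ac in merged.values():
                d = c_in - c_ac
                sum_d[j] += d
                sum_d2[j] += d * d

        # paired t from sparse aggregates: zero differences contribute nothing
        mean = sum_d / n
        var = (sum_d2 - sum_d**2 / n) / (n - 1)
        var = np.maximum(var, 0.0)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / math.sqrt(n))
        degenerate = sd == 0.0
        t[degenerate & (mean == 0.0)] = 0.0
        t[degenerate & (mean > 0.0)] = np.inf
        t[degenerate & (mean < 0.0)] = -np.inf
        p = np.where(degenerate, np.where(mean == 0.0, 1.0, 0.0),
                     2.0 * sps.t.sf(np.abs(np.where(degenerate, 0.0, t)), df=n - 1))

        rate_in = hit_in / n
        rate_ac = hit_ac / n

        def build(j: int) -> KmerResult:
            ci = np.zeros(n, dtype=int)
            ca = np.zeros(n, dtype=int)
            for i, (a, b) in sparse[j].items():
                ci[i], ca[i] = a, b
            return KmerResult(
                kmer=kmers[j],
                antisense=reverse_complement(kmers[j]),
                counts_inaccessible=tuple(ci.tolist()),
                counts_accessible=tuple(ca.tolist()),
                t_stat=float(t[j]),
                p_value=float(p[j]),
                rate_inaccessible=float(rate_in[j]),
                rate_accessible=float(rate_ac[j]),
                n_pairs=n,
            )

        order = sorted(range(m), key=lambda j: (p[j], kmers[j]))
        selected = [
            j
            for j in order
            if p[j] < self.p_max and max(rate_in[j], rate_ac[j]) > self.rate_min
        ]
        self.results_ = [build(j) for j in selected]
        self.all_results_ = [build(j) for j in order] if self.keep_all else None
        self.n_pairs_ = n
        self.n_candidates_observed_ = m
        logger.info(
            "discovery: %d pairs, %d observed candidates, %d selected motifs",
            n, m, len(self.results_),
        )
        return self


def discover(
    pairs: Sequence[DCSRPair],
    kmin: int = 6,
    kmax: int = 10,
    p_max: float = 0.01,
    rate_min: float = 0.01,
) -> list[KmerResult]:
    """Functional wrapper over :class:`KmerMotifDiscovery`."""
    est = KmerMotifDiscovery(kmin=kmin, kmax=kmax, p_max=p_max, rate_min=rate_min)
    return est.fit(pairs).results_


def write_results_tsv(
    results: Sequence[KmerResult], path: str | Path, region_scope: str = "genome-wide"
) -> None:
    """TSV of discovery results; a Benjamini-Hochberg column is included for
    information only (selection uses raw p-values)."""
    df = pd.DataFrame(
        [
            (
                r.kmer, r.antisense, r.p_value, r.t_stat,
                r.rate_inaccessible, r.rate_accessible, r.n_pairs, region_scope,
            )
            for r in results
        ],
        columns=[
            "kmer", "antisense", "p_value", "t_stat",
            "rate_inaccessible", "rate_accessible", "n_pairs", "region_scope",
        ],
    )
    if len(df):
        m = len(df)
        order = np.argsort(df["p_value"].to_numpy(), kind="stable")
        bh = np.empty(m)
        ranked = df["p_value"].to_numpy()[order] * m / (np.arange(m) + 1)
        bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        df["bh_fdr"] = np.minimum(bh, 1.0)
    else:
        df["bh_fdr"] = pd.Series(dtype=float)
    df.to_csv(path, sep="\t", index=False)
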