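"""Shared statistical kernels: Pearson chi-squared on 2x2 tables and the
DCSR-versus-peak association table."""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from chromotif.dcsr import DCSRPair


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class PeakCall:
    """A called peak interval, labelled allele-specific or not."""

    chrom: str
    start: int
    end: int
    allele_specific: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")


def chi2_test(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 degree of freedom, upper-tail
    p-value, with no continuity correction.

    A zero row or column margin makes the expected counts degenerate and
    raises a ValueError naming the offending margin.
    """
    arr = table.as_array()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if rows[0] == 0 or rows[1] == 0:
        raise ValueError(f"zero row margin (row {1 if rows[0] == 0 else 2})")
    if cols[0] == 0 or cols[1] == 0:
        raise ValueError(f"zero column margin (column {1 if cols[0] == 0 else 2})")
    chi2, p, _dof, _exp = chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def load_peaks(bed_path: str | Path) -> list[PeakCall]:
    """Read peaks from BED; the 4th column (name) tags allele specificity —
    any of {allele_specific, AS, 1, true} (case-insensitive) marks a peak as
    allele-specific."""
    truthy = {"allele_specific", "as", "1", "true", "yes"}
    peaks = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            label = f[3].lower() if len(f) > 3 else ""
            peaks.append(PeakCall(f[0], int(f[1]), int(f[2]), label in truthy))
    return peaks


def peak_association(
    pairs: Sequence[DCSRPair], peaks: Sequence[PeakCall]
) -> ContingencyTable2x2:
    """Cross-classify DCSR and NDCSR windows by the allele specificity of
    overlapping peaks.

    A window overlapping at least one peak (>= 1 shared base) is classified
    allele-specific when any overlapping peak carries the flag (allele-
    specific precedence); windows overlapping no peak are excluded. Returns
    the table (DCSR allele-specific, DCSR non-specific; NDCSR allele-
    specific, NDCSR non-specific).
    """
    by_chrom: dict[str, list[PeakCall]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    starts: dict[str, list[int]] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.start)
        starts[chrom] = [p.start for p in by_chrom[chrom]]

    counts = {("DCSR", True): 0, ("DCSR", False): 0,
              ("NDCSR", True): 0, ("NDCSR", False): 0}
    for pair in pairs:
        chrom, w_start, w_end = pair.interval
        chrom_peaks = by_chrom.get(chrom)
        if not chrom_peaks:
            continue
        # peaks starting before the window end are overlap candidates
        hi = bisect.bisect_left(starts[chrom], w_end)
        overlapping = [p for p in chrom_peaks[:hi] if p.end > w_start]
        if not overlapping:
            continue
        allele_specific = any(p.allele_specific for p in overlapping)
        counts[(pair.kind, allele_specific)] += 1

    return ContingencyTable2x2(
        a=counts[("DCSR", True)],
        b=counts[("DCSR", False)],
        c=counts[("NDCSR", True)],
        d=counts[("NDCSR", False)],
    )
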