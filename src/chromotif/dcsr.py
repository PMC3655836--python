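"""Calling differential chromatin-state region (DCSR) pairs.

A DCSR pair is the +/- ``flank`` (default 20) base window around a
heterozygous SNP whose two alleles show imbalanced FAIRE-seq depth: fold
change strictly > 2 with the greater depth >= 10. Balanced control pairs
(NDCSRs: fold < 1.5, greater depth >= 5) are called by the same machinery.
The higher-depth allele's window is the accessible chromatin sequence, the
lower-depth allele's the inaccessible one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from chromotif.allele_depth import AlleleDepthRecord
from chromotif.diploid_io import (
    GeneModel,
    HetSNP,
    WindowRejected,
    classify_region,
    extract_allele_window,
)

logger = logging.getLogger(__name__)

PairKind = Literal["DCSR", "NDCSR"]

# Printed thresholds: DCSR fold change > 2 with greater depth >= 10;
# NDCSR fold change < 1.5 with greater depth >= 5.
DCSR_FOLD_MIN = 2.0
DCSR_DEPTH_MIN = 10
NDCSR_FOLD_MAX = 1.5
NDCSR_DEPTH_MIN = 5


@dataclass(frozen=True)
class DCSRPair:
    """An accessible/inaccessible window pair around one het SNP."""

    snp: HetSNP
    seq_accessible: str
    seq_inaccessible: str
    accessible_allele: Literal["paternal", "maternal"]
    depth_high: int
    depth_low: int
    fold_change: float
    region: str
    kind: PairKind
    flagged_nearby_variant: bool = False

    def __post_init__(self) -> None:
        if self.depth_high < self.depth_low:
            raise ValueError("depth_high must be >= depth_low")
        if len(self.seq_accessible) != len(self.seq_inaccessible):
            raise ValueError("window pair must have equal lengths")

    @property
    def interval(self) -> tuple[str, int, int]:
        """0-based half-open genomic interval of the window."""
        flank = len(self.seq_accessible) // 2
        return (self.snp.chrom, self.snp.pos0 - flank, self.snp.pos0 + flank + 1)


def _fold_change(high: int, low: int) -> float:
    # zero depth on the low allele is maximal imbalance
    return math.inf if low == 0 else high / low


class DCSRCaller(BaseEstimator):
    """Call DCSR (or NDCSR control) pairs from allele depth records.

    Parameters
    ----------
    mode : "DCSR" or "NDCSR"
        DCSR: fold change > ``dcsr_fold`` and greater depth >= ``dcsr_depth``.
        NDCSR: fold change < ``ndcsr_fold`` and greater depth >= ``ndcsr_depth``.
        Fold thresholds are strict; depth floors inclusive. Equal depths
        (fold 1.0) qualify only in NDCSR mode.
    flank : half-window size in bases; windows span ``2*flank + 1``.

    Attributes
    ----------
    pairs_ : list of DCSRPair for qualifying SNPs, in input order.
    n_input_ / n_called_ / n_edge_ / n_with_n_ : bookkeeping counts.
    """

    def __init__(
        self,
        mode: PairKind = "DCSR",
        flank: int = 20,
        dcsr_fold: float = DCSR_FOLD_MIN,
        dcsr_depth: int = DCSR_DEPTH_MIN,
        ndcsr_fold: float = NDCSR_FOLD_MAX,
        ndcsr_depth: int = NDCSR_DEPTH_MIN,
        promoter_up: int = 2000,
        drop_n_windows: bool = True,
    ):
        self.mode = mode
        self.flank = flank
        self.dcsr_fold = dcsr_fold
        self.dcsr_depth = dcsr_depth
        self.ndcsr_fold = ndcsr_fold
        self.ndcsr_depth = ndcsr_depth
        self.promoter_up = promoter_up
        self.drop_n_windows = drop_n_windows

    def _qualifies(self, high: int, low: int) -> bool:
        fold = _fold_change(high, low)
        if self.mode == "DCSR":
            return fold > self.dcsr_fold and high >= self.dcsr_depth
        if self.mode == "NDCSR":
            return fold < self.ndcsr_fold and high >= self.ndcsr_depth
        raise ValueError(f"mode must be DCSR or NDCSR, got {self.mode!r}")

    def fit(
        self,
        depths: Sequence[AlleleDepthRecord],
        genome: Mapping[str, str],
        genes: Sequence[GeneModel] = (),
    ) -> "DCSRCaller":
        all_snps = [d.snp for d in depths]
        snps_by_chrom: dict[str, list[HetSNP]] = {}
        for s in all_snps:
            snps_by_chrom.setdefault(s.chrom, []).append(s)

        pairs: list[DCSRPair] = []
        n_edge = n_with_n = 0
        for rec in depths:
            hi, lo = rec.depth_paternal, rec.depth_maternal
            accessible = "paternal"
            if rec.depth_maternal > rec.depth_paternal:
                hi, lo = rec.depth_maternal, rec.depth_paternal
                accessible = "maternal"
            if not self._qualifies(hi, lo):
                continue
            snp = rec.snp
            if snp.chrom not in genome:
                raise KeyError(f"chromosome {snp.chrom!r} not in genome")
            try:
                pat, mat = extract_allele_window(
                    genome[snp.chrom],
                    snp,
                    flank=self.flank,
                    nearby_variants=snps_by_chrom[snp.chrom],
                )
            except WindowRejected:
                n_edge += 1
                continue
            if self.drop_n_windows and ("N" in pat.seq or "N" in mat.seq):
                n_with_n += 1
                continue
            acc_win, inacc_win = (pat, mat) if accessible == "paternal" else (mat, pat)
            pairs.append(
                DCSRPair(
                    snp=snp,
                    seq_accessible=acc_win.seq,
                    seq_inaccessible=inacc_win.seq,
                    accessible_allele=accessible,
                    depth_high=hi,
                    depth_low=lo,
                    fold_change=_fold_change(hi, lo),
                    region=classify_region(snp, genes, self.promoter_up),
                    kind=self.mode,
                    flagged_nearby_variant=pat.has_nearby_variant,
                )
            )
        self.pairs_ = pairs
        self.n_input_ = len(depths)
        self.n_called_ = len(pairs)
        self.n_edge_ = n_edge
        self.n_with_n_ = n_with_n
        logger.info(
            "%s calling: %d/%d SNPs qualified (%d edge-rejected, %d N-dropped)",
            self.mode, self.n_called_, self.n_input_, n_edge, n_with_n,
        )
        return self


def call_pairs(
    depths: Sequence[AlleleDepthRecord],
    mode: PairKind,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel] = (),
    flank: int = 20,
    promoter_up: int = 2000,
) -> list[DCSRPair]:
    """Functional wrapper over :class:`DCSRCaller`."""
    caller = DCSRCaller(mode=mode, flank=flank, promoter_up=promoter_up)
    return caller.fit(depths, genome, genes).pairs_


def partition_by_region(pairs: Sequence[DCSRPair]) -> dict[str, list[DCSRPair]]:
    """Split pairs by region class; "genome-wide" holds every pair."""
    out: dict[str, list[DCSRPair]] = {
        "genome-wide": list(pairs),
        "promoter": [],
        "genic": [],
        "intergenic": [],
    }
    for p in pairs:
        out[p.region].append(p)
    return out


_PAIR_COLUMNS = [
    "chrom", "start", "end", "pos", "allele_pat", "allele_mat",
    "accessible_allele", "depth_high", "depth_low", "fold_change",
    "region", "kind", "flagged_nearby_variant",
    "seq_accessible", "seq_inaccessible",
]


def write_pairs_tsv(pairs: Sequence[DCSRPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        chrom, start, end = p.interval
        rows.append(
            (
                chrom, start, end, p.snp.pos,
                p.snp.allele_paternal, p.snp.allele_maternal,
                p.accessible_allele, p.depth_high, p.depth_low,
                "inf" if math.isinf(p.fold_change) else f"{p.fold_change:.6g}",
                p.region, p.kind, int(p.flagged_nearby_variant),
                p.seq_accessible, p.seq_inaccessible,
            )
        )
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[DCSRPair]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pairs = []
    for r in df.itertuples():
        pairs.append(
            DCSRPair(
                snp=HetSNP(r.chrom, int(r.pos), r.allele_pat, r.allele_mat),
                seq_accessible=r.seq_accessible,
                seq_inaccessible=r.seq_inaccessible,
                accessible_allele=r.accessible_allele,
                depth_high=int(r.depth_high),
                depth_low=int(r.depth_low),
                fold_change=float(r.fold_change),
                region=r.region,
                kind=r.kind,
                flagged_nearby_variant=bool(r.flagged_nearby_variant),
            )
        )
    return pairs


def write_pairs_fasta(pairs: Sequence[DCSRPair], path: str | Path) -> None:
    """Paired FASTA of accessible/inaccessible windows with structured
    headers ``chrom:pos:allele:role``."""
    with open(path, "w") as fh:
        for p in pairs:
            inacc = "maternal" if p.accessible_allele == "paternal" else "paternal"
            fh.write(f">{p.snp.chrom}:{p.snp.pos}:{p.accessible_allele}:accessible\n")
            fh.write(p.seq_accessible + "\n")
            fh.write(f">{p.snp.chrom}:{p.snp.pos}:{inacc}:inaccessible\n")
            fh.write(p.seq_inaccessible + "\n")
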