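"""Per-allele FAIRE-seq read depth at heterozygous SNPs.

The primary input path is a precomputed tab-separated depth table (the
upstream diploid-genome alignment is out of scope); the alignment mode is a
convenience that approximates it by counting the read base at each SNP on a
haploid reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from chromotif.diploid_io import HetSNP

logger = logging.getLogger(__name__)

_DEPTH_COLUMNS = ["chrom", "pos", "allele_pat", "allele_mat", "depth_pat", "depth_mat"]


@dataclass(frozen=True)
class AlleleDepthRecord:
    """Read depth observed on each haplotype at one heterozygous SNP."""

    snp: HetSNP
    depth_paternal: int
    depth_maternal: int

    def __post_init__(self) -> None:
        if self.depth_paternal < 0 or self.depth_maternal < 0:
            raise ValueError("depths must be non-negative")


def load_depth_table(tsv_path: str | Path) -> list[AlleleDepthRecord]:
    """Read a depth table with columns chrom, pos, allele_pat, allele_mat,
    depth_pat, depth_mat (tab-separated, header required)."""
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype={"chrom": str})
    missing = set(_DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate (chrom, pos) row: {row.chrom}:{row.pos}")
    if (df["depth_pat"] < 0).any() or (df["depth_mat"] < 0).any():
        raise ValueError("negative depth in depth table")
    return [
        AlleleDepthRecord(
            HetSNP(r.chrom, int(r.pos), r.allele_pat, r.allele_mat),
            int(r.depth_pat),
            int(r.depth_mat),
        )
        for r in df.itertuples()
    ]


def write_depth_table(records: Sequence[AlleleDepthRecord], tsv_path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                r.snp.chrom,
                r.snp.pos,
                r.snp.allele_paternal,
                r.snp.allele_maternal,
                r.depth_paternal,
                r.depth_maternal,
            )
            for r in records
        ],
        columns=_DEPTH_COLUMNS,
    )
    df.to_csv(tsv_path, sep="\t", index=False)


def _read_mismatches(read, exclude_ref_pos: int) -> int:
    """Count mismatches of an aligned read to the reference, excluding one
    reference column (the focal SNP). Requires the MD tag."""
    n = 0
    for _qpos, rpos, ref_base in read.get_aligned_pairs(matches_only=True, with_seq=True):
        if rpos == exclude_ref_pos:
            continue
        if ref_base is not None and ref_base.islower():
            n += 1
    return n


def depth_from_alignments(
    alignment_path: str | Path,
    snps: Sequence[HetSNP],
    require_perfect: bool = False,
    min_mapq: int = 0,
    dedup: bool = False,
) -> list[AlleleDepthRecord]:
    """Count, for each SNP, reads whose base at the SNP matches the paternal
    or maternal allele.

    Reads carrying any other base, or a deletion/refskip at the position, are
    ignored. With ``require_perfect`` a read is counted only when it has no
    mismatch to the reference outside the focal SNP column (needs MD tags,
    mirroring a zero-mismatch diploid alignment). ``dedup`` drops
    duplicate-flagged reads; ``min_mapq`` drops low-mapping-quality reads.

    BAM/CRAM input must be indexed; plain SAM is streamed in one pass.
    """
    import pysam

    alignment_path = Path(alignment_path)
    if not alignment_path.exists():
        raise FileNotFoundError(f"alignment file not found: {alignment_path}")

    is_sam = alignment_path.suffix.lower() == ".sam"
    mode = "r" if is_sam else "rb"
    af = pysam.AlignmentFile(str(alignment_path), mode)
    if not is_sam and not af.has_index():
        raise ValueError(
            f"{alignment_path} has no index; run `samtools index` first"
        )

    by_chrom: dict[str, list[HetSNP]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)

    counts: dict[tuple[str, int], list[int]] = {
        (s.chrom, s.pos0): [0, 0] for s in snps
    }

    def tally(read, snp: HetSNP) -> None:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return
        if read.mapping_quality < min_mapq:
            return
        if dedup and read.is_duplicate:
            return
        pos0 = snp.pos0
        base = None
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos == pos0:
                base = read.query_sequence[qpos].upper()
                break
        if base is None:
            return  # deletion, refskip or no overlap at the SNP column
        if require_perfect and _read_mismatches(read, pos0) > 0:
            return
        if base == snp.allele_paternal:
            counts[(snp.chrom, pos0)][0] += 1
        elif base == snp.allele_maternal:
            counts[(snp.chrom, pos0)][1] += 1

    if is_sam:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            for snp in by_chrom.get(read.reference_name, ()):
                if read.reference_start <= snp.pos0 < read.reference_end:
                    tally(read, snp)
    else:
        for snp in snps:
            for read in af.fetch(snp.chrom, snp.pos0, snp.pos0 + 1):
                tally(read, snp)
    af.close()

    return [
        AlleleDepthRecord(s, *counts[(s.chrom, s.pos0)]) for s in snps
    ]
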