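"""Phased-variant, sequence and annotation I/O plus allele-aware windowing.

All internal coordinates are 0-based half-open; VCF positions are converted
on read. Haplotype 1 of a phased genotype ``a|b`` is treated as paternal and
haplotype 2 as maternal by convention (configurable via ``haplotype_order``),
matching diploid-genome pipelines where parental origin is fixed by trio
phasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_WINDOW_ALPHABET = frozenset("ACGTN")

RegionClass = Literal["promoter", "genic", "intergenic"]


@dataclass(frozen=True)
class HetSNP:
    """A phased heterozygous single-base variant.

    ``pos`` is the 1-based genomic position as printed in a VCF; use
    ``pos0`` for 0-based arithmetic.
    """

    chrom: str
    pos: int
    allele_paternal: str
    allele_maternal: str
    phased: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("allele_paternal", "allele_maternal"):
            a = getattr(self, name)
            if len(a) != 1 or a not in _BASES:
                raise ValueError(f"{name} must be a single base A/C/G/T, got {a!r}")
        if self.allele_paternal == self.allele_maternal:
            raise ValueError("alleles must differ (heterozygous)")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class SequenceWindow:
    """A haplotype-resolved sequence window around a focal SNP."""

    chrom: str
    start: int
    end: int
    seq: str
    allele_origin: Literal["paternal", "maternal"]
    has_nearby_variant: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError("seq length must equal end - start")
        if not set(self.seq) <= _WINDOW_ALPHABET:
            bad = set(self.seq) - _WINDOW_ALPHABET
            raise ValueError(f"seq contains invalid characters: {sorted(bad)}")


@dataclass(frozen=True)
class GeneModel:
    """Transcript bounds used for promoter/genic stratification."""

    chrom: str
    tx_start: int
    tx_end: int
    strand: Literal["+", "-"]
    gene_id: str

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class WindowRejected(Exception):
    """Raised when a window cannot be built; carries a status string."""

    def __init__(self, status: str, message: str):
        self.status = status
        super().__init__(message)


def load_het_snps(
    vcf_path: str | Path,
    haplotype_order: tuple[str, str] = ("paternal", "maternal"),
) -> list[HetSNP]:
    """Read phased, biallelic, single-base heterozygous SNPs from a VCF.

    The first phased haplotype maps to ``haplotype_order[0]`` and the second
    to ``haplotype_order[1]``. Unphased heterozygous records are skipped with
    a logged warning; homozygous, multi-allelic and indel records are
    silently excluded.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(f"VCF not found: {vcf_path}")
    if haplotype_order not in (("paternal", "maternal"), ("maternal", "paternal")):
        raise ValueError("haplotype_order must be a permutation of paternal/maternal")

    snps: list[HetSNP] = []
    n_unphased = 0
    for var in VCF(str(vcf_path)):
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            continue  # indel or symbolic allele
        gt = var.genotypes[0]  # [hap1, hap2, phased]
        a, b, phased = gt[0], gt[1], bool(gt[2])
        if a < 0 or b < 0 or a == b:
            continue  # missing or homozygous
        if not phased:
            n_unphased += 1
            continue
        alleles = (ref, alt)
        first, second = alleles[a], alleles[b]
        if haplotype_order[0] == "paternal":
            pat, mat = first, second
        else:
            pat, mat = second, first
        snps.append(HetSNP(var.CHROM, var.POS, pat, mat, phased=True))
    if n_unphased:
        logger.warning("skipped %d unphased heterozygous records", n_unphased)
    return snps


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a FASTA into a chrom -> uppercase sequence mapping."""
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA not found: {fasta_path}")
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not genome:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return genome


def reverse_complement(seq: str) -> str:
    """Uppercase reverse complement over the A/C/G/T/N alphabet."""
    seq = seq.upper()
    if not set(seq) <= _WINDOW_ALPHABET:
        bad = set(seq) - _WINDOW_ALPHABET
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def extract_allele_window(
    ref_seq: str,
    snp: HetSNP,
    flank: int = 20,
    nearby_variants: Sequence[HetSNP] = (),
) -> tuple[SequenceWindow, SequenceWindow]:
    """Build the paternal and maternal sequence windows around a het SNP.

    Each window spans ``2*flank + 1`` bases with the focal allele substituted
    at index ``flank``. Every other phased variant from ``nearby_variants``
    that falls inside the window is substituted on its own haplotype, and the
    windows are flagged when at least one such substitution happened.

    Raises :class:`WindowRejected` with status ``"edge"`` when the SNP sits
    closer than ``flank`` to a sequence end (the window is never truncated).
    """
    if flank < 1:
        raise ValueError(f"flank must be >= 1, got {flank}")
    center = snp.pos0
    start, end = center - flank, center + flank + 1
    if start < 0 or end > len(ref_seq):
        raise WindowRejected(
            "edge", f"{snp.chrom}:{snp.pos} closer than {flank} bases to sequence end"
        )

    pat = list(ref_seq[start:end].upper())
    mat = pat.copy()
    pat[flank] = snp.allele_paternal
    mat[flank] = snp.allele_maternal

    flagged = False
    for other in nearby_variants:
        if other.chrom != snp.chrom or other.pos0 == center:
            continue
        off = other.pos0 - start
        if 0 <= off < len(pat):
            pat[off] = other.allele_paternal
            mat[off] = other.allele_maternal
            flagged = True

    mk = lambda seq, origin: SequenceWindow(
        snp.chrom, start, end, "".join(seq), origin, has_nearby_variant=flagged
    )
    return mk(pat, "paternal"), mk(mat, "maternal")


def load_genes(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED6 or GTF (transcript/gene features).

    ``fmt`` is inferred from the suffix when not given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
        return [
            GeneModel(r.chrom, int(r.start), int(r.end), r.strand, r.name)
            for r in df.itertuples()
        ]
    if fmt == "gtf":
        genes: list[GeneModel] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] not in ("gene", "transcript"):
                    continue
                attrs = f[8]
                gene_id = "unknown"
                for token in attrs.split(";"):
                    token = token.strip()
                    if token.startswith("gene_id"):
                        gene_id = token.split(None, 1)[1].strip('" ')
                        break
                # GTF is 1-based inclusive
                genes.append(GeneModel(f[0], int(f[3]) - 1, int(f[4]), f[6], gene_id))
        return genes
    raise ValueError(f"unknown gene annotation format: {fmt!r}")


def classify_region(
    snp: HetSNP, genes: Sequence[GeneModel], promoter_up: int = 2000
) -> RegionClass:
    """Assign a SNP to promoter, genic or intergenic (in that precedence).

    The promoter is the strand-aware upstream interval ``[TSS - promoter_up,
    TSS)`` of any gene; genic is any position inside ``[tx_start, tx_end)``.
    """
    pos = snp.pos0
    in_gene = False
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        if g.strand == "+":
            promo = (g.tx_start - promoter_up, g.tx_start)
        else:
            promo = (g.tx_end, g.tx_end + promoter_up)
        if promo[0] <= pos < promo[1]:
            return "promoter"
        if g.tx_start <= pos < g.tx_end:
            in_gene = True
    return "genic" if in_gene else "intergenic"
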