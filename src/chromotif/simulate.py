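"""Fully synthetic inputs for the allele-specific accessibility pipeline.

The generator emits a small diploid-like world: random chromosomes, phased
heterozygous SNPs, and per-allele read depths drawn from a negative binomial
(the standard overdispersed model for sequencing coverage). At a configurable
fraction of SNPs a motif is planted so that one haplotype's allele completes
it across the SNP while the other allele breaks it, and the motif-intact
allele's depth mean is multiplied by ``effect_fold`` — the causal structure
the discovery method is designed to detect. The planted motif spans the SNP
at a uniformly random in-motif offset so discovery cannot exploit a fixed
phase.

All randomness flows from a single seed; two runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """World definition for one synthetic dataset.

    Depth is negative-binomial with mean ``base_depth_mean`` and dispersion
    ``depth_dispersion`` (the NB size parameter r; variance = mu + mu^2/r).
    ``effect_fold`` multiplies the depth mean of the motif-intact allele at
    planted SNPs. Defaults give moderately overdispersed FAIRE-like coverage
    in which strong allelic imbalance also arises occasionally by chance.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 60_000
    n_het_snps: int = 1_000
    planted_motif: str = "CACGTG"
    planted_fraction: float = 0.0
    base_depth_mean: float = 20.0
    depth_dispersion: float = 2.0
    effect_fold: float = 1.0
    gc_content: float = 0.41
    flank: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.effect_fold < 1.0:
            raise ValueError("effect_fold must be >= 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if len(self.planted_motif) > 2 * self.flank + 1:
            raise ValueError("planted motif longer than the analysis window")
        if set(self.planted_motif) - set("ACGT"):
            raise ValueError("planted motif must be over A/C/G/T")


def _nb_draw(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def simulate_dataset(
    config: SimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write reference FASTA, phased VCF, depth TSV and a truth manifest.

    Returns a mapping with keys ``fasta``, ``vcf``, ``depth``, ``truth``.
    The truth manifest records, per SNP, whether the motif was planted, the
    intact haplotype, the in-motif offset of the SNP, and whether the SNP is
    expected to be DCSR-eligible were the realized depths thresholded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    motif = config.planted_motif.upper()
    L = len(motif)
    flank = config.flank

    gc = config.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    chroms: dict[str, np.ndarray] = {}
    for c in range(config.n_chrom):
        chroms[f"chr{c + 1}"] = rng.choice(4, size=config.chrom_len, p=base_probs)

    # SNP positions: evenly allocated across chromosomes, spaced far enough
    # apart that windows never contain a second variant.
    spacing = 2 * flank + 2 + L
    per_chrom = int(np.ceil(config.n_het_snps / config.n_chrom))
    snp_sites: list[tuple[str, int]] = []  # (chrom, 0-based pos)
    for name in chroms:
        lo, hi = flank + L, config.chrom_len - flank - L
        n_slots = (hi - lo) // spacing
        take = min(per_chrom, n_slots)
        slots = rng.choice(n_slots, size=take, replace=False)
        slots.sort()
        for s in slots:
            snp_sites.append((name, lo + int(s) * spacing + int(rng.integers(L))))
    snp_sites = snp_sites[: config.n_het_snps]
    if len(snp_sites) < config.n_het_snps:
        raise ValueError("chromosomes too short for the requested SNP count")

    n = len(snp_sites)
    planted = rng.random(n) < config.planted_fraction

    rows = []  # per-SNP record dicts
    for i, (chrom, pos0) in enumerate(snp_sites):
        seq = chroms[chrom]
        if planted[i]:
            offset = int(rng.integers(L))  # SNP sits at motif[offset]
            start = pos0 - offset
            # write the motif into the reference around the SNP
            for j, b in enumerate(motif):
                seq[start + j] = "ACGT".index(b)
            intact_base = motif[offset]
            broken_base = _other_base(rng, intact_base)
            intact_hap = "paternal" if rng.random() < 0.5 else "maternal"
            if intact_hap == "paternal":
                pat, mat = intact_base, broken_base
            else:
                pat, mat = broken_base, intact_base
            mean_pat = config.base_depth_mean * (
                config.effect_fold if intact_hap == "paternal" else 1.0
            )
            mean_mat = config.base_depth_mean * (
                config.effect_fold if intact_hap == "maternal" else 1.0
            )
        else:
            offset = -1
            intact_hap = "none"
            ref_base = "ACGT"[seq[pos0]]
            pat = ref_base if rng.random() < 0.5 else _other_base(rng, ref_base)
            mat = _other_base(rng, pat)
            mean_pat = mean_mat = config.base_depth_mean
        d_pat = int(_nb_draw(rng, mean_pat, config.depth_dispersion, 1)[0])
        d_mat = int(_nb_draw(rng, mean_mat, config.depth_dispersion, 1)[0])
        rows.append(
            dict(
                chrom=chrom, pos=pos0 + 1, allele_pat=pat, allele_mat=mat,
                depth_pat=d_pat, depth_mat=d_mat, planted=int(planted[i]),
                intact_hap=intact_hap, motif_offset=offset,
            )
        )

    fasta_path = out_dir / "genome.fa"
    vcf_path = out_dir / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=chromotif-simulate seed={config.seed}\n")
        for name in chroms:
            fh.write(f"##contig=<ID={name},length={config.chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in sorted(rows, key=lambda r: (r["chrom"], r["pos"])):
            chrom_arr = chroms[r["chrom"]]
            ref = "ACGT"[chrom_arr[r["pos"] - 1]]
            pat, mat = r["allele_pat"], r["allele_mat"]
            # REF must be one of the two alleles for a clean biallelic record
            if ref == pat:
                alt, gt = mat, "0|1"
            elif ref == mat:
                alt, gt = pat, "1|0"
            else:  # neither allele matches the reference draw: use pat as REF
                ref, alt, gt = pat, mat, "0|1"
                # patch the genome so windows are consistent with the VCF REF
                chrom_arr[r["pos"] - 1] = "ACGT".index(pat)
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n"
            )

    # the FASTA is written after the VCF pass so REF patching is reflected
    with open(fasta_path, "w") as fh:
        for name, arr in chroms.items():
            fh.write(f">{name}\n")
            s = "".join(_BASES[arr])
            for k in range(0, len(s), 80):
                fh.write(s[k : k + 80] + "\n")

    depth_path = out_dir / "depth.tsv"
    depth_df = pd.DataFrame(rows)[
        ["chrom", "pos", "allele_pat", "allele_mat", "depth_pat", "depth_mat"]
    ]
    with open(depth_path, "w") as fh:
        fh.write(f"# chromotif-simulate seed={config.seed}\n")
        depth_df.to_csv(fh, sep="\t", index=False)

    truth_path = out_dir / "truth.tsv"
    truth = pd.DataFrame(rows)
    hi = truth[["depth_pat", "depth_mat"]].max(axis=1)
    lo = truth[["depth_pat", "depth_mat"]].min(axis=1)
    fold = np.where(lo == 0, np.inf, hi / np.where(lo == 0, 1, lo))
    truth["dcsr_eligible"] = ((fold > 2.0) & (hi >= 10)).astype(int)
    with open(truth_path, "w") as fh:
        fh.write(f"# chromotif-simulate seed={config.seed}\n")
        truth.to_csv(fh, sep="\t", index=False)

    return {"fasta": fasta_path, "vcf": vcf_path, "depth": depth_path, "truth": truth_path}


def simulate_peaks(
    intervals: Sequence[tuple[str, int, int, str]],
    out_path: str | Path,
    seed: int = 0,
    p_peak: float = 0.5,
    p_allele_specific: tuple[float, float] = (0.46, 0.26),
) -> Path:
    """Write a BED of labelled peak calls covering a subset of windows.

    ``intervals`` are (chrom, start, end, kind) with kind DCSR or NDCSR.
    Each window receives a covering peak with probability ``p_peak``; the
    peak is labelled allele-specific with the first probability for DCSR
    windows and the second for NDCSR windows (defaults near the proportions
    reported for allele-specific binding at differential regions).
    """
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write(f"# chromotif-simulate peaks seed={seed}\n")
        for chrom, start, end, kind in intervals:
            if rng.random() >= p_peak:
                continue
            p_as = p_allele_specific[0] if kind == "DCSR" else p_allele_specific[1]
            label = "allele_specific" if rng.random() < p_as else "other"
            # small pad keeps each peak local to its window: simulated SNPs
            # can sit close enough that a wide peak would span two windows
            pad = int(rng.integers(0, 4))
            fh.write(f"{chrom}\t{max(0, start - pad)}\t{end + pad}\t{label}\n")
    return out_path


DEFAULT_TF_SPECS: tuple[tuple[str, str, float], ...] = (
    # (tf_name, site sequence, FPKM): exercises the annotation path,
    # the FPKM < 1 expression filter, and the >30-base length filter.
    ("MAXFIX", "CACGTG", 12.0),
    ("USF1FIX", "TCACGTGA", 8.5),
    ("SILENTTF", "GGGTTTCAC", 0.2),
    ("LONGTF", "A" * 35, 5.0),
    ("RXRFIX", "CTCCTGACCT", 3.1),
)


def simulate_tfbs_fixture(
    tf_specs: Sequence[tuple[str, str, float]] = DEFAULT_TF_SPECS,
    out_dir: str | Path = ".",
) -> dict[str, Path]:
    """Write a small TFBS FASTA and expression TSV fixture.

    The default specs include one unexpressed factor (FPKM 0.2) and one
    35-base site so both annotation filters are exercised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "tfbs.fa"
    expr_path = out_dir / "expression.tsv"
    with open(fasta_path, "w") as fh:
        for tf, site, _fpkm in tf_specs:
            fh.write(f">{tf}|fixture\n{site}\n")
    pd.DataFrame(
        [(tf, fpkm) for tf, _site, fpkm in tf_specs], columns=["tf_name", "fpkm"]
    ).to_csv(expr_path, sep="\t", index=False)
    return {"tfbs": fasta_path, "expression": expr_path}
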