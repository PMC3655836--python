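"""Annotation of chromatin motifs against TFBS sequence collections.

A significant k-mer is aligned (both strands, local alignment) against every
binding-site sequence of length <= 30 in the database; the best hit per
source with E-value <= 10 and homology > 0.8 annotates the motif with that
transcription factor. Homology is alignment identities divided by k-mer
length, which makes the 80% rule meaningful for short queries (>= 5 of 6
matching bases for a 6-mer). Unexpressed factors (FPKM < 1) are removed when
an expression table is supplied.

The E-value for such ultra-short queries is implementation-defined; we use a
Karlin-Altschul estimate with ungapped +1/-2 nucleotide parameters
(lambda = 1.33, K = 0.621). E <= 10 is a permissive gate; homology is the
operative filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO
from sklearn.base import BaseEstimator

from chromotif.diploid_io import reverse_complement
from chromotif.discovery import KmerResult
from chromotif.stats import ContingencyTable2x2, chi2_test

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for ungapped +1/-2 nucleotide scoring
_KA_LAMBDA = 1.33
_KA_K = 0.621
_SEARCH_SPACE = 1_000.0  # nominal database length for one site comparison


@dataclass(frozen=True)
class TFBSRecord:
    """One transcription-factor binding-site sequence."""

    tf_name: str
    site_seq: str
    source: str = "custom"

    def __post_init__(self) -> None:
        if len(self.site_seq) < 4:
            raise ValueError("site_seq must be at least 4 bases")


@dataclass(frozen=True)
class MotifAnnotation:
    """A retained k-mer -> transcription factor assignment."""

    kmer: str
    tf_name: str
    source: str
    e_value: float
    homology: float
    expressed: bool = True


def load_tfbs(path: str | Path, max_len: int = 30) -> list[TFBSRecord]:
    """Load a TFBS database from FASTA (headers ``TFNAME|source``) or a
    two/three-column TSV (tf_name, site_seq[, source]).

    Sites longer than ``max_len`` are dropped (long sequences may contain
    several distinct binding sites); duplicate (tf, seq) records are
    deduplicated.
    """
    path = Path(path)
    records: list[TFBSRecord] = []
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            tf = parts[0]
            source = parts[1] if len(parts) > 1 else "custom"
            records.append(TFBSRecord(tf, str(rec.seq).upper(), source))
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        if "source" not in df.columns:
            df["source"] = "custom"
        for r in df.itertuples():
            records.append(TFBSRecord(r.tf_name, r.site_seq.upper(), r.source))
    if not records:
        raise ValueError(f"empty TFBS database: {path}")
    n_long = sum(1 for r in records if len(r.site_seq) > max_len)
    if n_long:
        logger.info("dropped %d TFBS sequences longer than %d bases", n_long, max_len)
    kept = [r for r in records if len(r.site_seq) <= max_len]
    seen: set[tuple[str, str]] = set()
    out = []
    for r in kept:
        key = (r.tf_name, r.site_seq)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def load_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (tf_name, fpkm) into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["tf_name"], df["fpkm"].astype(float)))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -2.5
    return aligner


def _identities(alignment) -> int:
    n = 0
    for (qs, qe), (ts, te) in zip(alignment.aligned[0], alignment.aligned[1]):
        for i in range(qe - qs):
            if alignment.query[ts + i] == alignment.target[qs + i]:
                n += 1
    return n


def align_motif(
    kmer: str, site: TFBSRecord, evalue_max: float = 10.0
) -> tuple[float, float] | None:
    """Best local alignment of a k-mer (either strand) against one site.

    Returns ``(e_value, homology)`` or None when the E-value exceeds
    ``evalue_max``. Homology is identities / len(kmer).
    """
    aligner = _make_aligner()
    best_score = -math.inf
    best_identities = 0
    for query in (kmer.upper(), reverse_complement(kmer)):
        alns = aligner.align(site.site_seq, query)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if aln.score > best_score:
            best_score = aln.score
            best_identities = _identities(aln)
    if best_score <= 0:
        return None
    e_value = _KA_K * len(kmer) * _SEARCH_SPACE * math.exp(-_KA_LAMBDA * best_score)
    if e_value > evalue_max:
        return None
    homology = best_identities / len(kmer)
    return e_value, homology


class MotifAnnotator(BaseEstimator):
    """Annotate k-mers with transcription factors by TFBS alignment.

    Parameters
    ----------
    homology_min : strict lower bound on identities / k-mer length (0.8).
    evalue_max : inclusive E-value gate (10).
    fpkm_min : factors with expression below this are removed (1.0).

    Attributes (after ``fit``)
    ----------
    db_ : loaded/validated binding-site records.
    expression_ : TF -> FPKM mapping, or None when not supplied.
    """

    def __init__(
        self,
        homology_min: float = 0.8,
        evalue_max: float = 10.0,
        fpkm_min: float = 1.0,
    ):
        self.homology_min = homology_min
        self.evalue_max = evalue_max
        self.fpkm_min = fpkm_min

    def fit(
        self,
        db: Sequence[TFBSRecord],
        expression: Mapping[str, float] | None = None,
    ) -> "MotifAnnotator":
        self.db_ = list(db)
        self.expression_ = dict(expression) if expression is not None else None
        if self.expression_ is None:
            logger.warning("no expression table supplied; FPKM filter skipped")
        return self

    def annotate(self, kmers: Sequence[str]) -> list[MotifAnnotation]:
        """Best qualifying alignment per (k-mer, source); expression-filtered."""
        annotations: list[MotifAnnotation] = []
        for kmer in kmers:
            best: dict[str, tuple[float, float, str]] = {}  # source -> (E, hom, tf)
            for site in self.db_:
                hit = align_motif(kmer, site, evalue_max=self.evalue_max)
                if hit is None:
                    continue
                e_value, homology = hit
                if homology <= self.homology_min:
                    continue
                cur = best.get(site.source)
                if cur is None or e_value < cur[0]:
                    best[site.source] = (e_value, homology, site.tf_name)
            for source, (e_value, homology, tf) in best.items():
                if self.expression_ is not None:
                    fpkm = self.expression_.get(tf)
                    if fpkm is not None and fpkm < self.fpkm_min:
                        continue
                annotations.append(
                    MotifAnnotation(kmer, tf, source, e_value, homology, True)
                )
        n_annotated = len({a.kmer for a in annotations})
        if kmers:
            logger.info(
                "annotated %d/%d motifs (%.1f%%)",
                n_annotated, len(kmers), 100.0 * n_annotated / len(kmers),
            )
        return annotations


def annotate_all(
    results: Sequence[KmerResult],
    db: Sequence[TFBSRecord],
    expression: Mapping[str, float] | None = None,
    fpkm_min: float = 1.0,
    homology_min: float = 0.8,
    evalue_max: float = 10.0,
) -> list[MotifAnnotation]:
    """Functional wrapper over :class:`MotifAnnotator`."""
    annotator = MotifAnnotator(
        homology_min=homology_min, evalue_max=evalue_max, fpkm_min=fpkm_min
    )
    annotator.fit(db, expression)
    return annotator.annotate([r.kmer for r in results])


def chromatin_go_enrichment(
    top_a: Sequence[Sequence[str]],
    top_b: Sequence[Sequence[str]],
    chromatin_tf_set: Sequence[str],
) -> tuple[ContingencyTable2x2, float, float]:
    """Chi-squared enrichment of chromatin-specific annotation between two
    motif lists.

    ``top_a`` and ``top_b`` are lists of per-motif annotated TF-name lists
    (e.g. the top 100 DCSR and NDCSR motifs); a motif counts as
    chromatin-specific when any of its factors belongs to
    ``chromatin_tf_set`` (a flat TF-name list resolved upstream from GO
    terms such as chromatin remodeling, histone modification and chromatin
    DNA binding). Returns the 2x2 table, chi-squared statistic and p-value.
    """
    if not top_a or not top_b:
        raise ValueError("both motif lists must be non-empty")
    tf_set = set(chromatin_tf_set)

    def split(motifs: Sequence[Sequence[str]]) -> tuple[int, int]:
        pos = sum(1 for tfs in motifs if set(tfs) & tf_set)
        return pos, len(motifs) - pos

    a, b = split(top_a)
    c, d = split(top_b)
    table = ContingencyTable2x2(a, b, c, d)
    chi2, p = chi2_test(table)
    return table, chi2, p
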