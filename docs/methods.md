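# Methods

## Model and procedure

### Allele-resolved accessibility at heterozygous SNPs

FAIRE-seq enriches nucleosome-depleted DNA, so local read depth is a proxy
for chromatin accessibility. At a phased heterozygous SNP the reads covering
the position split into paternal and maternal counts `(d_P, d_M)`. The
method treats a strong imbalance as evidence that the two alleles sit in
different chromatin states and asks which sequence differences between the
two allelic windows co-occur with that state difference across the genome.

A **DCSR pair** (differential chromatin-state region) is called at a SNP
when

    max(d_P, d_M) / min(d_P, d_M) > 2   and   max(d_P, d_M) >= 10,

with the convention that a zero minority depth gives infinite fold change
(qualifies when the majority depth passes the floor). The pair consists of
the two 41-base haplotype windows (±20 around the SNP, the focal allele
substituted at index 20, and any other phased variant inside the window
substituted on its own haplotype and flagged). The higher-depth allele's
window is labelled *accessible*, the other *inaccessible*. **NDCSR** control
pairs use fold < 1.5 and majority depth ≥ 5; the fold conditions are
mutually exclusive, so the two sets are disjoint by construction. Fold
thresholds are strict and depth floors inclusive, exactly as printed in the
thresholds table (`chromotif.cli.RunConfig`).

Windows that would run past a chromosome end are rejected, never truncated;
windows containing N after substitution are dropped before counting, because
k-mer matching is exact.

Region stratification assigns each SNP the first matching class of
promoter ≻ genic ≻ intergenic, where the promoter is the strand-aware
upstream interval `[TSS − 2000, TSS)` of any transcript and genic is any
`[tx_start, tx_end)`. Strand-aware promoters are a design choice (the
biologically standard reading); the precedence rule resolves overlapping
annotations deterministically.

### Differential k-mer testing

Every DNA word of length 6–10 — Σ₆¹⁰ 4ᵏ = 1,396,736 candidates — is counted
in both windows of every pair with an overlapping sliding window
(case-insensitive exact match; N never matches). For candidate `w` this
gives paired vectors `x` (inaccessible) and `y` (accessible) of per-window
hit counts. The statistic is the paired t-test on `d = x − y`:

    t = mean(d) / (sd(d) / sqrt(n)),    sd with the n−1 denominator,

two-sided p from Student's t with n−1 degrees of freedom. Degenerate cases
are fixed by convention: `sd(d) = 0` with zero mean gives `(t, p) = (0, 1)`;
with nonzero mean, `(±∞, 0)`. Two-sided testing is deliberate — motifs
enriched on either allele are of interest (both directions occur in
practice, and the sign of `t` reports the direction: positive means
enriched on the inaccessible allele).

A candidate is reported as a **chromatin motif** when `p < 0.01` (strict,
raw — no multiple-testing correction, matching the selection rule the
method was defined with; a Benjamini–Hochberg column is emitted in the
output TSV for information only) and its **occurrence rate** — the fraction
of windows in a group containing ≥ 1 hit — exceeds 1% in either group
(strict). Output is sorted by ascending p, ties broken lexicographically for
reproducibility. Counting is forward-strand only on each stored window; the
reverse complement is reported as metadata. Merging strands would
double-count palindromes (CACGTG is its own antisense).

**Implementation.** Testing ~1.4 M candidates against thousands of pairs
does not iterate candidates × windows. One pass over the windows builds a
sparse table `kmer → {pair index: hits}` (a 41-base window contributes at
most 36+35+34+33+32 = 170 k-mer instances), and per-candidate aggregates
Σd, Σd² and per-side hit counts give t, p and both rates vectorised over
all observed candidates. Candidates never observed have identically zero
vectors (t = 0, p = 1, rates 0) and cannot pass the rate filter, so only
observed candidates are materialised. A test asserts the batched statistics
equal the scalar per-k-mer routines exactly.

### Annotation

Significant k-mers are aligned against a user-supplied TFBS collection
(FASTA `>TFNAME|source` or TSV). Sites longer than 30 bases are dropped at
load (long sequences may contain several distinct sites). Alignment is
local, both strands, Biopython `PairwiseAligner` with match +1, mismatch −2,
gaps −2.5 — parameters suited to 6–10 base queries. **Homology** is
identities divided by k-mer length (not alignment length), which makes the
80% rule meaningful for a 6-mer (≥ 5 of 6 bases). The E-value uses the
Karlin–Altschul formula with ungapped +1/−2 nucleotide parameters
(λ = 1.33, K = 0.621) over a nominal 1 kb search space; any E-value
definition for such short queries is somewhat arbitrary, so E ≤ 10 is a
permissive gate and homology > 0.8 is the operative filter. The best
qualifying hit per source annotates the motif; factors with FPKM < 1 in the
expression table are removed (motifs bound only by unexpressed factors
revert to unannotated). Annotation is strand-symmetric by construction.

Consensus-logo match scores are out of scope (no published algorithm);
logo-based collections should be supplied as plain site sequences.

### Validation statistics

Both validation tests are Pearson chi-squared on 2×2 tables with 1 degree
of freedom and **no continuity correction** — the published p-value for the
peak-association table (31, 36; 21, 61) is 0.008, which only the
uncorrected statistic (χ² = 6.93, p = 0.0085) reproduces; Yates' correction
would give ≈ 0.015. Zero row/column margins raise an error naming the
degenerate margin.

* **Annotation enrichment**: motifs of the DCSR and control lists are each
  tagged by whether any annotated factor belongs to a user-supplied
  chromatin-related TF set (resolved upstream from GO terms such as
  chromatin remodeling, histone modification and chromatin DNA binding; GO
  resolution is an input, not computed here).
* **Peak association**: each DCSR/NDCSR window overlapping ≥ 1 labelled
  peak (≥ 1 shared base; configurable) is classified by the overlapping
  peaks' allele-specificity, with allele-specific taking precedence when
  both types overlap — a documented choice, since the original treatment is
  unstated. Windows overlapping no peak are excluded.

## Synthetic data generator

`simulate_dataset` emits the exact formats the pipeline consumes (FASTA,
phased VCF 4.2, depth TSV, truth manifest; `simulate_peaks` adds labelled
BED peaks and `simulate_tfbs_fixture` a TFBS database with one unexpressed
factor and one over-length site).

* **Sequence**: i.i.d. bases at GC 0.41 (human-like), default two 60 kb
  chromosomes.
* **SNPs**: placed on a jittered grid with spacing > 41 bases so no window
  contains a second variant (the adjacent-variant code path is exercised by
  hand-built unit fixtures instead).
* **Depth**: negative binomial with mean 20 and dispersion r = 2
  (variance = μ + μ²/r), the standard overdispersed model for sequencing
  coverage. The heavy tail means strong allelic imbalance also arises by
  chance, which is what makes null DCSR calling and the control analyses
  possible.
* **Planted effect**: at a `planted_fraction` of SNPs the planted motif is
  written into the reference spanning the SNP at a uniformly random
  in-motif offset; one haplotype's allele completes the motif, the other
  breaks it, and the intact allele's depth mean is multiplied by
  `effect_fold`. The truth manifest records the planted positions, intact
  haplotype, offset and realized DCSR eligibility.
* Non-planted SNP depths are exchangeable between alleles; with
  `effect_fold = 1` the paternal−maternal depth difference is symmetric
  about zero (tested by a sign test).

What the generator does **not** emulate: mappability and allelic mapping
bias, correlated coverage along the genome, linkage between nearby SNPs,
indels, read-level artifacts, and realistic motif composition of the
background sequence. A green recovery test therefore establishes that the
statistical machinery detects a planted allele-linked depth effect of the
stated size — not that real FAIRE-seq preprocessing (upstream of this
package) is handled.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| flank | 20 | windows of 2·20+1 = 41 bases |
| dcsr_fold / dcsr_depth | 2 / 10 | DCSR: fold > 2, majority depth ≥ 10 |
| ndcsr_fold / ndcsr_depth | 1.5 / 5 | control pairs |
| kmin–kmax | 6–10 | candidate lengths |
| p_max / rate_min | 0.01 / 0.01 | selection: p < 1%, rate > 1% |
| homology_min / evalue_max | 0.8 / 10 | annotation filters |
| fpkm_min | 1 | expression filter |
| promoter_up | 2000 | promoter = [TSS−2000, TSS) |

## Known limitations

* **The paired t-test is conservative at small pair counts.** Because the
  two windows of a pair differ at (usually) a single base, a k-mer's paired
  differences are a few ±1 entries among mostly zeros. With 500 pairs the
  median number of nonzero differences for a rate-passing 6-mer is ~2–8,
  and |t| can only reach the 1% critical value when ≥ 7 nonzero differences
  share a sign — so the null fraction of p < 0.01 is far below 0.01
  (measured ≈ 0.000–0.001 at 500 pairs, 0.007 at ~2,000, and 0.0102 at
  ~8,000 pairs, where the normal approximation finally holds). At
  genome-wide pair counts the test is approximately calibrated; at small n
  it loses power but does not inflate false positives. The acceptance suite
  asserts calibration at the scaled-down 500-pair size and that check
  fails for this structural reason; it is kept red deliberately.
* Raw p < 0.01 over ~1.4 M candidates implies many false discoveries under
  the null; the BH column is provided for users who want FDR control.
* Overlapping DCSR windows (two qualifying SNPs < 41 bp apart) are both
  retained and flagged, not merged.
* The E-value for 6–10 base queries is heuristic (see Annotation); results
  should be read through the homology filter.
* Reads spanning several het SNPs are tallied per SNP independently in the
  alignment-based depth mode; conflicting assignments are not reconciled.
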