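# Methods

This note documents the models and procedures implemented in `slsplice`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinate and window conventions

All genomic coordinates are 0-based, half-open, reported on the plus strand;
sequence windows are computed on the transcribed strand. A trans-splice
acceptor coordinate is the first exonic base in transcript orientation (for
minus-strand genes, the highest genomic coordinate of the first exon; the
template-strand AG then sits at the two positions just above it).

Windows around an anchor are half-open offset ranges `(start, end)` with
offset 0 = the anchor base. Splice-site notation maps onto this with "+1" at
offset 0 and "−1" at offset −1, so:

| window (splice-site notation) | internal offsets | length |
|---|---|---|
| trans-acceptor motif −10..+2 | (−10, 2) | 12 |
| acceptor 3'SS −6..+1 | (−6, 1) | 7 |
| donor 5'SS −3..+6 | (−3, 6) | 9 |
| Kozak −3..−1 | (−3, 0) | 3 |
| read-classification −14..+10 | inclusive offsets −14..+10 | 25 positions |

## Long-read site discovery

A trans-spliced long read retains a 3'-anchored SL remnant as a 5'
soft-clip. For each mapped read, candidate acceptors are genomic positions
immediately 3' of a template-strand AG within ±10 nt of the aligned 5' end
(two-sided: soft-clip boundary errors shift the aligned end in either
direction). For each candidate × leader pair an *expected reference* is
built (leader + 24 nt of exon-side genomic sequence, truncated at contig
ends) and aligned against the read's 5' query (last ≤ 28 nt of soft-clip +
first 24 aligned nt) with affine-gap Smith–Waterman. Default scores are
match +2, mismatch −2, gap open −4, gap extend −1 — deliberately stringent
so short remnants only score well against the right leader; a gap of length
k costs open + (k−1)·extend. Ties between pairs break to the higher JAD,
then SL1 before SL2, making output deterministic.

The **junction alignment distance** is the minimum, over the leader and
exon flanks, of the number of error-free match columns between the junction
and the first mismatch, gap, or alignment end. An error-free flank
contributes its full aligned length: the definition's "first alignment
error" treats the alignment end as a cap, not an error. A junction outside
the aligned reference span scores 0.

Sites whose best read has JAD **> 8** train the outron PSSM; final retention
requires JAD **≥ 8**. The two cutoffs are deliberately distinct (and both
configurable): the training set is meant to be high-confidence, the final
filter inclusive at the boundary.

The outron PSSM covers −10..+2 (the *C. elegans* UUUCAG/R acceptor element
with its extended polypyrimidine tract), uses pseudocount 1 and genome-wide
mononucleotide background frequencies, and scores in log2 odds; ambiguous
bases contribute 0. The score threshold is chosen by scoring **all possible
trans-splice sites** — every AG-preceded position on both strands (evenly
subsampled above 200 000) — flagging those that are JAD-passing candidates,
and taking the interior decile boundary of the score distribution that
maximises the Pearson χ² of the (score ≥ boundary) × (flag) table.
Degenerate tables score 0 and ties return the lowest boundary. Scoring the
genome-wide background rather than only observed candidates is what makes
decile boundaries meaningful: candidate sites alone are motif-enriched, and
their deciles would cut into true sites.

## Short-read site discovery

Leader trimming is anchored: a read prefix of length k matches a leader's
3' suffix of length k when the Hamming distance divided by k is ≤ 0.09,
with k ≥ 7. The longest passing k wins (ties: fewer errors, then SL1).
Because remnants are 3'-anchored suffixes, a full-length remnant with two
substitutions (rate 2/22 = 0.0909) cannot rescue itself at shorter k — the
read prefix then corresponds to the leader's 5' portion, not its 3' suffix.
Reads shorter than 15 nt after trimming are discarded. Indels are not
modelled in trimming (the synthetic error model is substitution-only); a
mismatch-only error count is the matching convention.

Candidate positions need more than 10 trimmed-read 5' ends. Positions whose
upstream genomic sequence equals the (modal) trimmed leader sequence are
genomic false positives — the "remnant" was never a leader — and are removed
both from PSSM training and from the final site set. Surviving candidates
train the PSSM; the threshold is selected exactly as in the long-read path
with "is a surviving high-confidence candidate" as the pass flag (the
short-read path has no JAD; this is the analogous high-confidence
indicator). Positions with ≥ 2 trimmed reads and a score above threshold
are retained. Merging with long-read sites is a union on (chrom, position,
strand) with summed support and support-weighted SL-class majority (ties
prefer SL1).

## Differential trans-splicing

Reads are classified per site: aligned 5' end within −14..+10 →
trans-spliced; earlier than −14 **and** first downstream intron junction
identical to the modal junction of that site's trans-spliced reads →
retained outron; anything else is excluded with a reason
(internal_truncation / junction_mismatch) tallied in a QC table. The
junction condition removes degraded or mis-spliced fragments from the
retention count. The modal junction is computed per replicate; introns whose
acceptor end abuts the site itself (cis-splicing into the trans-splice
acceptor) count as upstream, so cis-spliced retained outrons classify as
retained.

Replicate counts are aggregated per genotype before the main test (the
pooled test equals the test of the aggregated 2×2 by construction). Sites
need ≥ 10 reads per genotype. The G-test (G = 2·Σ O·ln(O/E), df from the
table shape, chi-square upper tail; empty rows/columns dropped, fully
degenerate tables return G = 0, p = 1) gives the raw p-value; sites with
p < 0.05 get per-genotype replicate-homogeneity G-tests; BH adjustment runs
over **all tested sites**. A site is significant at FDR < 0.05 and
|ΔPSI| ≥ 0.03 (fraction scale) provided neither genotype fails homogeneity
at p < 0.05 — homogeneity failures are excluded from the significant set
but remain flagged in the output. A single informative replicate leaves the
homogeneity test undefined (NaN) and the site passes by default.

Significant sites are classified in order: **CSRO** if ≥ 2 retained-class
reads carry an intron ending exactly at the site and the exon carrying the
cis donor has no annotated SL site; **ALT3TSS** if an annotated SL site
downstream on the same first exon has a larger |ΔPSI|; otherwise **RO**.
Gene assignment resolves multi-gene overlaps to the gene with the nearest
annotated 5' exon boundary, ties going to both genes.

## Motif statistics and effect sizes

Motif matrices are per-position base probabilities with raw counts retained.
The motif G-test sums per-position 2×4 G statistics and degrees of freedom
(a pooled whole-window alternative exists as an option); it is invariant to
position permutation and zero for identical matrices. Consensus-distance
classes use IUPAC R = {A, G}: U2AF65 = Hamming(−6..−4, UUU), U2AF35 =
Hamming(−3..+1, CAGR), U5 = Hamming(−2..−1, AG), U6 = Hamming(+3..+5, RAG).

The per-(position, base) effect size compares the ΔPSI distributions of
with-base vs without-base sites. The named paired-rank test does not apply
to two independent groups, so the two-sample rank-sum (Mann–Whitney) test is
used; "difference between the distributions" is implemented as the median
difference (mean available as an option). The statistic is sign × −log10(p)
with p floored at 1e-300 and significance at p < 0.01; the sign is negative
when significantly changed sites are proportionally more common in the
with-base group (the base sensitises the site to the mutation). Pairs with
fewer than two sites in either group are omitted. Genome frequencies for
plotting sizes default to the observed with-base fraction when no external
table is given.

Alternative splice-site distances are signed in transcript orientation
(negative = alternative upstream of canonical); identical pairs are excluded
and logged, cross-contig pairs are rejected.

## Outron uORFs and Kozak scoring

For RO events the outron 5' end is estimated as the 5'-most retained-read
end among supporting long reads — a lower bound on the true transcription
start, since long reads are 5'-truncated. CSRO regions use the cis-spliced
exonic sequence. Every ATG upstream of the canonical start is reported with
in_frame ⇔ (canonical offset − ATG offset) mod 3 = 0; alternative cis-spliced
isoforms are analysed as separate regions. The Kozak PSSM is strictly −3..−1
(the scored context; wider windows are only ever visualised), trained on all
annotated start-codon contexts with pseudocount 1; candidates without a full
3-nt context are unscored. The best in-frame candidate per region is the
highest Kozak score, ties broken to the most upstream ATG
(scanning-model plausibility, deterministic output).

## Synthetic data generator

The generator defines the study conditions. Each gene carries a 40-nt
flank, an outron of 50–150 nt (uniform), a 120-nt first exon, a 60-nt
intron and an 80-nt second exon, alternating strands to exercise
strand-handling everywhere. Planted acceptors are immediately 3' of an exact
AG with a noisy extended UUUCAG/R context (T at 90% per polypyrimidine
position, C at 95%); donors get GT with an AG|GTAAGT-like context; each gene
has an annotated ATG at exon-1 offset 45 with an AAA-enriched Kozak
context. CSRO genes plant a cis donor 10 nt into the outron whose intron
ends at the acceptor; ALT3TSS genes plant a second acceptor 36 nt into
exon 1.

Long reads per (genotype, replicate) draw a category per read: trans-spliced
with the site's configured proportion (wild type 0.9, mutant 0.5 by
default; ALT3TSS genes redistribute towards the alternative acceptor in the
mutant: wt (0.90, 0.02), mut (0.30, 0.55) for primary/alt), otherwise
retained (CSRO genes cis-splice 80% of retained reads). Trans reads carry a
leader 3' suffix of 10–22 nt as soft-clip; retained reads start ≥ 15 nt
upstream of the acceptor; all reads get uniform substitution errors and a
geometric 5' truncation (success 0.5, mean 1 nt — a stand-in, since the
real truncation process of direct RNA reads is not distributionally
characterised). Ground-truth labels are assigned from the *realised* 5'
structure, so truncated reads that no longer carry their class's signature
are labelled internal_truncation; reads of genes without a planted site are
labelled "unspliced" (an extra label outside the four event-linked ones).
Alignments are synthesised directly from ground truth with correct
soft-clips, CIGAR junctions and strands — no external aligner, so the
records exercise exactly the features the pipeline consumes.

Short reads are 75-nt forward reads beginning with a 0–22 nt leader suffix;
the emitted post-trim SAM reflects ground-truth trimming (remnants ≥ 7 nt
removed, shorter remnants left as soft-clips, as a spliced aligner would
report them). A planted intergenic decoy locus carries an exact SL1 3'
10-mer followed by genomic sequence and 15 reads, providing a true false
positive for the genomic-leader filter. A count-level simulator (binomial
per-replicate draws) serves the statistical calibrations, and a ΔPSI-table
simulator plants per-(position, base) shifts on donor-like 5'SS windows
with Gaussian noise (significance flag at |ΔPSI| > 2·SD).

What the generator does **not** emulate: indel or homopolymer error
profiles, coverage and expression variation between genes, squiggle-level
artefacts, overlapping genes, alternative TSSs, and trans-splicing at
non-AG acceptors. Passing tests therefore demonstrate correctness of the
method's logic under its stated read model, not robustness to every real
ONT/Illumina artefact.

## Problem sizes and numerical choices

The shipped analyses and checks use deliberately desk-scale conditions:
discovery recovery at 100 genes / 60 sites / 50 reads per gene with 1%
substitution errors; type-I calibration at 300 null sites × 20 seeded runs
(2 genotypes × 3 replicates × 50 reads); power at 200 sites of PSI 0.9 vs
0.5; effect-size recovery at 500 sites × 100 runs with a +4A shift of 0.3
(SD 0.1). All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical configs and seeds give byte-identical
output files. Probability floors (1e-300), pseudocounts (1), and the
G-statistic's clamp at 0 on homogeneous tables are the only numerical
guards; no iterative optimisation is involved anywhere.

## Known limitations

* The homogeneity QC removes ~5–10% of genuinely changed sites at the
  shipped replicate depths (chance replicate heterogeneity); they remain in
  the output flagged, only the significance call is withheld.
* Decile-based thresholding cannot place a boundary above the 90th
  percentile of the background score distribution; with very weak outron
  motifs, true sites below that boundary are lost.
* The CSRO rule's "annotated SL site on the donor exon" check is only as
  good as the annotation's `sl_sites` attribute.
* PSI makes no coverage-bias or length-normalisation corrections; it is a
  read-count proportion.
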