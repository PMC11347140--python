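"""Trans-splice site discovery from long-read and short-read data.

Long-read path: for each read, candidate acceptors are AG dinucleotides near
the aligned 5' end; each (candidate, leader) pair defines an expected
reference (leader + downstream genomic exon sequence) that is locally aligned
against the read's 5' end (soft-clip tail + first aligned bases).  The best
pair per read is retained with its junction alignment distance (JAD).  Sites
whose best read has JAD above the training cutoff seed an outron-motif PSSM;
a score threshold is chosen by maximising the Pearson Chi-square statistic of
JAD pass/fail against score >= threshold over the score deciles; final sites
must pass both the JAD and the PSSM filters.

Short-read path: SL 3' suffixes are trimmed from read 5' ends
(minimum overlap, maximum error rate, minimum remaining length); positions
supported by trimmed-read 5' ends become candidates, positions whose upstream
genomic sequence equals the trimmed leader (false positives) are removed, and
the surviving candidates train the same PSSM/threshold machinery.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .align import LocalAlignment, ScoringScheme, junction_alignment_distance, local_align
from .io import AlignmentRecord
from .pssm import Pssm, mononucleotide_background
from .seq import revcomp, window_sequence
from .stats import pearson_chi2

logger = logging.getLogger(__name__)

DEFAULT_PSSM_WINDOW = (-10, 2)  # acceptor motif -10..+2 in splice-site notation
SL_CLASS_ORDER = ("SL1", "SL2")


@dataclass(frozen=True)
class SpliceLeader:
    name: str
    sl_class: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq or not set(seq) <= set("ACGT"):
            raise ValueError(f"leader {self.name}: bad sequence")
        if self.sl_class not in SL_CLASS_ORDER:
            raise ValueError(f"leader {self.name}: sl_class must be SL1 or SL2")


@dataclass(frozen=True)
class CandidateAcceptor:
    chrom: str
    position: int  # 0-based coordinate of the first exonic base
    strand: str
    source_read: str = ""


@dataclass
class TransSpliceSite:
    chrom: str
    position: int
    strand: str
    sl_class: str
    n_supporting_reads: int
    best_alignment_score: int
    best_jad: int
    pssm_score: float
    source: str  # long_read / short_read / merged

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass
class ReadSiteSupport:
    """Best (candidate, leader) assignment for one read."""

    read_name: str
    candidate: CandidateAcceptor
    leader: SpliceLeader
    score: int
    jad: int


@dataclass
class TrimRecord:
    read_name: str
    trimmed_sequence: str
    sl_class: str

    @property
    def trimmed_length(self) -> int:
        return len(self.trimmed_sequence)


# ---------------------------------------------------------------------------
# long-read path

def find_candidate_acceptors(
    read: AlignmentRecord,
    genome: Mapping[str, str],
    search_radius: int = 10,
) -> List[CandidateAcceptor]:
    """AG-preceded positions within `search_radius` of the aligned 5' end.

    The AG is read on the template strand; candidate positions are first-exon
    base coordinates.  The search is two-sided (soft-clip mis-assignment can
    shift the aligned end either way).
    """
    seq = str(genome[read.chrom])
    out: List[CandidateAcceptor] = []
    for pos in range(read.five_prime_pos - search_radius, read.five_prime_pos + search_radius + 1):
        if read.strand == "+":
            if pos - 2 >= 0 and pos < len(seq) and seq[pos - 2 : pos].upper() == "AG":
                out.append(CandidateAcceptor(read.chrom, pos, "+", read.query_name))
        else:
            if pos >= 0 and pos + 3 <= len(seq) and seq[pos + 1 : pos + 3].upper() == "CT":
                out.append(CandidateAcceptor(read.chrom, pos, "-", read.query_name))
    return out


def build_expected_reference(
    leader: SpliceLeader,
    genome: Mapping[str, str],
    site: CandidateAcceptor,
    genomic_ext: int = 24,
) -> str:
    """Leader sequence + downstream exon-side genomic sequence (strand-corrected).

    The genomic extension is truncated at the contig end.
    """
    seq = str(genome[site.chrom])
    if site.strand == "+":
        exon = seq[site.position : site.position + genomic_ext]
    else:
        lo = max(site.position - genomic_ext + 1, 0)
        exon = revcomp(seq[lo : site.position + 1])
    return leader.sequence + exon.upper()


def read_query_window(read: AlignmentRecord, aligned_ext: int = 24, clip_ext: int = 28) -> str:
    """5'-end query: last <= `clip_ext` nt of the 5' soft-clip + first
    <= `aligned_ext` nt of the aligned read sequence (read orientation)."""
    if not read.usable:
        raise ValueError(
            f"read {read.query_name}: alignment record lacks sequence or is 5' hard-clipped; "
            "supply sequence-bearing alignments"
        )
    clip = read.softclip5[-clip_ext:] if read.softclip5 else ""
    return (clip + read.aligned_seq[:aligned_ext]).upper()


def assign_read_best_site(
    read: AlignmentRecord,
    candidates: Sequence[CandidateAcceptor],
    leaders: Sequence[SpliceLeader],
    genome: Mapping[str, str],
    scoring: Optional[ScoringScheme] = None,
    genomic_ext: int = 24,
    aligned_ext: int = 24,
    clip_ext: int = 28,
) -> Optional[ReadSiteSupport]:
    """Best (candidate, leader) pair by alignment score; ties break to the
    higher JAD, then SL1 before SL2.  Returns None if every score is 0."""
    if scoring is None:
        scoring = ScoringScheme()
    query = read_query_window(read, aligned_ext=aligned_ext, clip_ext=clip_ext)
    best: Optional[ReadSiteSupport] = None
    for cand in candidates:
        for leader in leaders:
            ref = build_expected_reference(leader, genome, cand, genomic_ext=genomic_ext)
            aln = local_align(query, ref, scoring)
            if aln.score <= 0:
                continue
            jad = junction_alignment_distance(aln, len(leader.sequence))
            rank = (aln.score, jad, -SL_CLASS_ORDER.index(leader.sl_class))
            if best is None or rank > (best.score, best.jad, -SL_CLASS_ORDER.index(best.leader.sl_class)):
                best = ReadSiteSupport(read.query_name, cand, leader, aln.score, jad)
    return best


def enumerate_ag_positions(genome: Mapping[str, str], limit: int = 200_000) -> List[Tuple[str, int, str]]:
    """All possible trans-splice sites: AG-preceded positions on both strands.

    Evenly subsampled above `limit` to keep decile estimation cheap on large
    contigs.
    """
    out: List[Tuple[str, int, str]] = []
    for chrom, raw in genome.items():
        seq = str(raw).upper()
        idx = seq.find("AG")
        while idx != -1:
            out.append((chrom, idx + 2, "+"))
            idx = seq.find("AG", idx + 1)
        idx = seq.find("CT")
        while idx != -1:
            if idx >= 1:
                out.append((chrom, idx - 1, "-"))
            idx = seq.find("CT", idx + 1)
    if len(out) > limit:
        stride = len(out) // limit + 1
        out = out[::stride]
    return out


def select_pssm_threshold(scores: Sequence[float], jad_pass: Sequence[bool]) -> float:
    """Score threshold maximising the Pearson Chi-square of (score >= t) x pass.

    Candidate thresholds are the 9 interior deciles of the score distribution;
    degenerate 2x2 tables score 0; ties return the lowest boundary.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(jad_pass, dtype=bool)
    if scores.size == 0 or scores.size != flags.size:
        raise ValueError("need matched, nonempty score/flag vectors")
    boundaries = np.quantile(scores, np.arange(1, 10) / 10.0)
    best_t, best_chi2 = float(boundaries[0]), -1.0
    for t in boundaries:
        hi = scores >= t
        table = [
            [int(np.sum(hi & flags)), int(np.sum(hi & ~flags))],
            [int(np.sum(~hi & flags)), int(np.sum(~hi & ~flags))],
        ]
        c2 = pearson_chi2(table)
        if c2 > best_chi2:
            best_chi2, best_t = c2, float(t)
    return best_t


def _majority_class(votes: Counter) -> str:
    best = max(votes.items(), key=lambda kv: (kv[1], -SL_CLASS_ORDER.index(kv[0])))
    return best[0]


def build_outron_pssm(
    site_keys: Iterable[Tuple[str, int, str]],
    genome: Mapping[str, str],
    window: Tuple[int, int] = DEFAULT_PSSM_WINDOW,
    pseudocount: float = 1.0,
    background: Optional[Mapping[str, float]] = None,
) -> Pssm:
    """Outron-motif PSSM from (chrom, position, strand) site keys."""
    if background is None:
        background = mononucleotide_background(genome)
    seqs = []
    for chrom, pos, strand in site_keys:
        s = window_sequence(genome, chrom, pos, strand, window)
        if s is not None and "N" not in s:
            seqs.append(s)
    if not seqs:
        raise ValueError("no usable site windows to train the outron PSSM")
    return Pssm.from_sequences(seqs, window=window, background=background, pseudocount=pseudocount)


def score_site(
    pssm: Pssm, genome: Mapping[str, str], chrom: str, pos: int, strand: str
) -> Optional[float]:
    """PSSM log-odds of the site's window sequence; None if off-contig."""
    s = window_sequence(genome, chrom, pos, strand, pssm.window)
    if s is None:
        return None
    return pssm.score(s)


def call_long_read_sites(
    reads: Iterable[AlignmentRecord],
    genome: Mapping[str, str],
    leaders: Sequence[SpliceLeader],
    scoring: Optional[ScoringScheme] = None,
    search_radius: int = 10,
    jad_train_cutoff: int = 8,  # strict > for PSSM training sites
    jad_final_cutoff: int = 8,  # >= for final retention
    pssm_window: Tuple[int, int] = DEFAULT_PSSM_WINDOW,
    pseudocount: float = 1.0,
) -> Tuple[List[TransSpliceSite], Dict[str, ReadSiteSupport]]:
    """Full long-read pipeline; returns retained sites and per-read assignments."""
    if scoring is None:
        scoring = ScoringScheme()
    assignments: Dict[str, ReadSiteSupport] = {}
    n_reads = n_unusable = n_no_candidate = n_unassigned = 0
    for read in reads:
        n_reads += 1
        if not read.usable:
            n_unusable += 1
            continue
        candidates = find_candidate_acceptors(read, genome, search_radius)
        if not candidates:
            n_no_candidate += 1
            continue
        best = assign_read_best_site(read, candidates, leaders, genome, scoring)
        if best is None:
            n_unassigned += 1
            continue
        assignments[read.query_name] = best
    logger.info(
        "long-read discovery: %d reads, %d unusable, %d without AG candidates, %d unassigned",
        n_reads, n_unusable, n_no_candidate, n_unassigned,
    )

    by_site: Dict[Tuple[str, int, str], List[ReadSiteSupport]] = defaultdict(list)
    for sup in assignments.values():
        by_site[(sup.candidate.chrom, sup.candidate.position, sup.candidate.strand)].append(sup)
    if not by_site:
        logger.warning("long-read discovery: no candidate sites")
        return [], assignments

    keys = sorted(by_site)
    best_jad = {k: max(s.jad for s in by_site[k]) for k in keys}
    train_keys = [k for k in keys if best_jad[k] > jad_train_cutoff]
    if not train_keys:
        logger.warning("long-read discovery: no high-scoring sites (JAD > %d)", jad_train_cutoff)
        return [], assignments
    pssm = build_outron_pssm(train_keys, genome, window=pssm_window, pseudocount=pseudocount)

    # threshold over *all possible* sites (every AG genome-wide), flagged by
    # whether the position is a high-scoring (JAD-passing) candidate
    train_set = set(train_keys)
    all_scored = [
        (k, s)
        for k in enumerate_ag_positions(genome)
        if (s := score_site(pssm, genome, *k)) is not None
    ]
    threshold = select_pssm_threshold(
        [s for _, s in all_scored], [k in train_set for k, _ in all_scored]
    )
    logger.info(
        "long-read discovery: %d candidate sites, %d PSSM-training sites, "
        "%d possible sites scored, score threshold %.3f",
        len(keys), len(train_keys), len(all_scored), threshold,
    )

    sites: List[TransSpliceSite] = []
    scored = [(k, s) for k in keys if (s := score_site(pssm, genome, *k)) is not None]
    for k, score in scored:
        if best_jad[k] < jad_final_cutoff or score <= threshold:
            continue
        sups = by_site[k]
        votes = Counter(s.leader.sl_class for s in sups)
        sites.append(
            TransSpliceSite(
                chrom=k[0], position=k[1], strand=k[2],
                sl_class=_majority_class(votes),
                n_supporting_reads=len(sups),
                best_alignment_score=max(s.score for s in sups),
                best_jad=best_jad[k],
                pssm_score=score,
                source="long_read",
            )
        )
    logger.info("long-read discovery: retained %d sites", len(sites))
    return sites, assignments


# ---------------------------------------------------------------------------
# short-read path

def trim_sl_short_reads(
    reads: Iterable[Tuple[str, str]],
    leaders: Sequence[SpliceLeader],
    min_overlap: int = 7,
    max_error_rate: float = 0.09,
    min_length: int = 15,
) -> Tuple[List[Tuple[str, str]], Dict[str, TrimRecord]]:
    """Remove the best-matching SL 3' suffix from read 5' ends.

    A leader suffix of length k (k >= `min_overlap`) matches when its Hamming
    distance to the read prefix, divided by k, is <= `max_error_rate`.  The
    longest match wins (ties: fewer errors, then SL1 before SL2).  Reads
    shorter than `min_length` after trimming are discarded.
    Returns (surviving reads, trim records by read name).
    """
    trimmed_reads: List[Tuple[str, str]] = []
    records: Dict[str, TrimRecord] = {}
    n_in = n_trimmed = n_discarded = 0
    for name, seq in reads:
        n_in += 1
        su = seq.upper()
        best: Optional[Tuple[int, int, SpliceLeader]] = None  # (k, errors, leader)
        for leader in leaders:
            ls = leader.sequence
            for k in range(min(len(ls), len(su)), min_overlap - 1, -1):
                errors = sum(a != b for a, b in zip(su[:k], ls[-k:]))
                if errors / k <= max_error_rate:
                    cand = (k, errors, leader)
                    if best is None or (cand[0], -cand[1], -SL_CLASS_ORDER.index(leader.sl_class)) > (
                        best[0], -best[1], -SL_CLASS_ORDER.index(best[2].sl_class)
                    ):
                        best = cand
                    break  # longer k failed already; shorter k cannot beat this leader's k
        if best is None:
            trimmed_reads.append((name, seq))
            continue
        k, _errors, leader = best
        remainder = seq[k:]
        if len(remainder) < min_length:
            n_discarded += 1
            continue
        n_trimmed += 1
        trimmed_reads.append((name, remainder))
        records[name] = TrimRecord(read_name=name, trimmed_sequence=su[:k], sl_class=leader.sl_class)
    logger.info(
        "SL trimming: %d reads in, %d trimmed, %d discarded (< %d nt after trimming)",
        n_in, n_trimmed, n_discarded, min_length,
    )
    return trimmed_reads, records


def _upstream_genomic(genome: Mapping[str, str], chrom: str, pos: int, strand: str, length: int) -> Optional[str]:
    return window_sequence(genome, chrom, pos, strand, (-length, 0))


def call_short_read_sites(
    alignments: Iterable[AlignmentRecord],
    trim_records: Mapping[str, TrimRecord],
    genome: Mapping[str, str],
    min_candidate_reads: int = 10,
    min_support: int = 2,
    pssm_window: Tuple[int, int] = DEFAULT_PSSM_WINDOW,
    pseudocount: float = 1.0,
) -> List[TransSpliceSite]:
    """Short-read pipeline over post-trim alignments + trim records.

    Candidates need more than `min_candidate_reads` trimmed-read 5' ends;
    positions whose upstream genomic sequence equals the trimmed leader
    sequence are removed as false positives (and excluded from output);
    surviving candidates train the outron PSSM, whose threshold then filters
    all positions with >= `min_support` trimmed reads.
    """
    by_pos: Dict[Tuple[str, int, str], List[TrimRecord]] = defaultdict(list)
    n_aln = 0
    for rec in alignments:
        n_aln += 1
        tr = trim_records.get(rec.query_name)
        if tr is None:
            continue
        by_pos[(rec.chrom, rec.five_prime_pos, rec.strand)].append(tr)
    if not by_pos:
        logger.warning("short-read discovery: no trimmed-read positions")
        return []

    keys = sorted(by_pos)
    candidates = [k for k in keys if len(by_pos[k]) > min_candidate_reads]
    false_positive: set = set()
    for k in keys:
        trims = by_pos[k]
        common = Counter(t.trimmed_sequence for t in trims).most_common(1)[0][0]
        upstream = _upstream_genomic(genome, k[0], k[1], k[2], len(common))
        if upstream is not None and upstream == common:
            false_positive.add(k)
    high_conf = [k for k in candidates if k not in false_positive]
    logger.info(
        "short-read discovery: %d alignments, %d positions, %d candidates, %d genomic-leader false positives, %d high-confidence",
        n_aln, len(keys), len(candidates), len(false_positive), len(high_conf),
    )
    if not high_conf:
        logger.warning("short-read discovery: no high-confidence candidates")
        return []

    pssm = build_outron_pssm(high_conf, genome, window=pssm_window, pseudocount=pseudocount)
    high_set = set(high_conf)
    all_scored = [
        (k, s)
        for k in enumerate_ag_positions(genome)
        if (s := score_site(pssm, genome, *k)) is not None
    ]
    threshold = select_pssm_threshold(
        [s for _, s in all_scored], [k in high_set for k, _ in all_scored]
    )
    supported = [k for k in keys if len(by_pos[k]) >= min_support]
    scored = [(k, s) for k in supported if (s := score_site(pssm, genome, *k)) is not None]

    sites: List[TransSpliceSite] = []
    for k, score in scored:
        if k in false_positive or score <= threshold:
            continue
        trims = by_pos[k]
        votes = Counter(t.sl_class for t in trims)
        sites.append(
            TransSpliceSite(
                chrom=k[0], position=k[1], strand=k[2],
                sl_class=_majority_class(votes),
                n_supporting_reads=len(trims),
                best_alignment_score=0,
                best_jad=0,
                pssm_score=score,
                source="short_read",
            )
        )
    logger.info("short-read discovery: retained %d sites (threshold %.3f)", len(sites), threshold)
    return sites


# ---------------------------------------------------------------------------
# merging

def merge_site_sets(
    long_sites: Sequence[TransSpliceSite], short_sites: Sequence[TransSpliceSite]
) -> List[TransSpliceSite]:
    """Non-redundant union keyed on (chrom, position, strand).

    Support counts are summed; SL class is decided by support-weighted
    majority (ties prefer SL1); sites present in both inputs get
    source="merged".
    """
    merged: Dict[Tuple[str, int, str], TransSpliceSite] = {}
    for site in list(long_sites) + list(short_sites):
        key = site.key
        if key not in merged:
            merged[key] = replace(site)
            continue
        cur = merged[key]
        votes = Counter({cur.sl_class: cur.n_supporting_reads})
        votes[site.sl_class] += site.n_supporting_reads
        merged[key] = TransSpliceSite(
            chrom=cur.chrom, position=cur.position, strand=cur.strand,
            sl_class=_majority_class(votes),
            n_supporting_reads=cur.n_supporting_reads + site.n_supporting_reads,
            best_alignment_score=max(cur.best_alignment_score, site.best_alignment_score),
            best_jad=max(cur.best_jad, site.best_jad),
            pssm_score=max(cur.pssm_score, site.pssm_score),
            source="merged" if cur.source != site.source else cur.source,
        )
    return [merged[k] for k in sorted(merged)]
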