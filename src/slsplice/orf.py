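"""Upstream start codons in retained outrons and Kozak context scoring.

When trans-splicing fails, the outron stays on the mature transcript and can
contribute upstream ATGs.  This module classifies reading-frame changes,
finds every ATG upstream of the canonical start in an outron region (after
any cis-splicing, i.e. on the supplied exonic sequence), flags each by the
mod-3 rule against the canonical start, scores the -3..-1 Kozak context with
a PSSM trained on annotated start codons, and picks the best in-frame
candidate per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .pssm import Pssm
from .seq import window_sequence

logger = logging.getLogger(__name__)

KOZAK_WINDOW = (-3, 0)  # positions -3..-1 relative to the A of ATG

IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"


def frame_class(length_change: int) -> str:
    """in_frame iff the inclusion/exclusion length is a multiple of 3 nt."""
    return IN_FRAME if abs(int(length_change)) % 3 == 0 else OUT_OF_FRAME


@dataclass
class StartCodonCandidate:
    offset: int  # transcript offset of the A of ATG within the region
    in_frame: bool  # relative to the canonical start
    kozak_score: Optional[float] = None


@dataclass
class OutronRegion:
    """Exonic sequence from the (estimated) outron 5' end to the canonical start.

    For plain retained outrons the 5' end is estimated from the most extended
    supporting long read; for cis-spliced retained outrons the cis-spliced
    isoform sequence is supplied directly.  `canonical_start` is the offset of
    the canonical ATG, i.e. usually len(sequence) when the sequence ends just
    before it.
    """

    name: str
    sequence: str
    canonical_start: int
    event_class: str = "RO"

    def __post_init__(self) -> None:
        if self.canonical_start > len(self.sequence):
            raise ValueError(f"region {self.name}: canonical start beyond sequence end")


def find_upstream_starts(region: OutronRegion) -> List[StartCodonCandidate]:
    """All ATGs upstream of the canonical start, flagged by the mod-3 rule.

    Alternative isoforms of the same outron (from cis-splicing) are handled
    by calling this once per isoform region.
    """
    seq = region.sequence.upper()
    out: List[StartCodonCandidate] = []
    pos = seq.find("ATG")
    while 0 <= pos < region.canonical_start:
        out.append(
            StartCodonCandidate(
                offset=pos, in_frame=(region.canonical_start - pos) % 3 == 0
            )
        )
        pos = seq.find("ATG", pos + 1)
    return out


def build_kozak_pssm(
    contexts: Iterable[str],
    background: Optional[Mapping[str, float]] = None,
    pseudocount: float = 1.0,
) -> Pssm:
    """Kozak PSSM from -3..-1 contexts of annotated start codons.

    Contexts shorter than 3 nt (starts at the transcript 5' edge) are
    skipped and logged.
    """
    kept, skipped = [], 0
    for c in contexts:
        if len(c) == 3:
            kept.append(c)
        else:
            skipped += 1
    if skipped:
        logger.info("Kozak PSSM: skipped %d truncated contexts", skipped)
    if not kept:
        raise ValueError("no usable Kozak contexts")
    return Pssm.from_sequences(kept, window=KOZAK_WINDOW, background=background, pseudocount=pseudocount)


def kozak_contexts_from_annotation(genome, annotation) -> List[str]:
    """-3..-1 contexts of every annotated start codon (transcribed strand)."""
    out = []
    for gene in annotation.genes.values():
        if gene.start_codon is None:
            continue
        ctx = window_sequence(genome, gene.chrom, gene.start_codon, gene.strand, KOZAK_WINDOW)
        if ctx is not None:
            out.append(ctx)
    return out


def score_candidates(region: OutronRegion, candidates: Sequence[StartCodonCandidate], pssm: Pssm) -> None:
    """Attach Kozak scores in place; candidates without a full -3 context get None."""
    for cand in candidates:
        if cand.offset >= 3:
            cand.kozak_score = pssm.score(region.sequence[cand.offset - 3 : cand.offset])
        else:
            cand.kozak_score = None


def select_best_start(candidates: Sequence[StartCodonCandidate]) -> Optional[StartCodonCandidate]:
    """Highest-Kozak-score in-frame candidate; ties break to the most upstream.

    Returns None when no in-frame candidate has a score.
    """
    scored = [c for c in candidates if c.in_frame and c.kozak_score is not None]
    if not scored:
        return None
    return max(scored, key=lambda c: (c.kozak_score, -c.offset))


def analyse_regions(regions: Sequence[OutronRegion], pssm: Optional[Pssm] = None) -> pd.DataFrame:
    """Per-region uORF summary: candidate counts, frames, best Kozak start."""
    rows = []
    for region in regions:
        cands = find_upstream_starts(region)
        if pssm is not None:
            score_candidates(region, cands, pssm)
        best = select_best_start(cands) if pssm is not None else None
        rows.append(
            {
                "region": region.name,
                "event_class": region.event_class,
                "n_starts": len(cands),
                "n_in_frame": sum(c.in_frame for c in cands),
                "has_start": len(cands) > 0,
                "has_in_frame_start": any(c.in_frame for c in cands),
                "best_start_offset": best.offset if best else pd.NA,
                "best_kozak_score": best.kozak_score if best else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def class_summary(per_region: pd.DataFrame) -> pd.DataFrame:
    """Fractions of regions with (in-frame) upstream starts per event class."""
    out = (
        per_region.groupby("event_class")
        .agg(
            n_regions=("region", "count"),
            frac_with_start=("has_start", "mean"),
            frac_with_in_frame_start=("has_in_frame_start", "mean"),
        )
        .reset_index()
    )
    return out
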