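"""Local pairwise alignment and the junction alignment distance (JAD).

Trans-spliced reads carry a partially degraded spliced-leader (SL) remnant at
their 5' end, emitted by aligners as a soft-clip.  To decide whether a read
supports a candidate trans-splice acceptor, the remnant-plus-exon portion of
the read is locally aligned against an *expected reference* built by
concatenating the SL sequence with the genomic exon sequence downstream of the
acceptor.  The quality of the alignment across the leader/exon junction is
summarised by the junction alignment distance: the minimum distance, in
reference columns, from the junction to the first alignment error on either
side.  A high JAD means the alignment matches cleanly on both sides of the
junction and is therefore strong evidence for trans-splicing at that acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

__all__ = [
    "ScoringScheme",
    "AlignedColumn",
    "LocalAlignment",
    "local_align",
    "junction_alignment_distance",
]

# column kinds
MATCH = "match"
MISMATCH = "mismatch"
GAP_QUERY = "gap_query"  # reference base consumed, gap in the query (deletion)
GAP_REF = "gap_ref"      # query base consumed, gap in the reference (insertion)

_REF_CONSUMING = (MATCH, MISMATCH, GAP_QUERY)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap local alignment scores.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Defaults are
    deliberately stringent (match +2, mismatch -2) so that short SL remnants
    only score well against the correct leader/acceptor combination.
    """

    match: int = 2
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


@dataclass(frozen=True)
class AlignedColumn:
    """One traceback column: query index, reference index, and its kind.

    For gap columns the index on the gapped side is the index of the *next*
    base on that side (the column does not consume it).
    """

    query_index: int
    ref_index: int
    kind: str

    @property
    def is_error(self) -> bool:
        return self.kind != MATCH


@dataclass
class LocalAlignment:
    """Optimal local alignment with full traceback.

    ``query_span``/``ref_span`` are 0-based half-open intervals of the aligned
    portions.  An empty alignment has score 0 and no columns.
    """

    score: int
    columns: List[AlignedColumn] = field(default_factory=list)
    query_span: Tuple[int, int] = (0, 0)
    ref_span: Tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def is_empty(self) -> bool:
        return not self.columns


def local_align(query: str, reference: str, scoring: Optional[ScoringScheme] = None) -> LocalAlignment:
    """Smith-Waterman local alignment with affine gaps (Gotoh) and traceback.

    Returns the optimal-scoring local alignment of `query` vs `reference`
    under `scoring`.  Ties are broken towards the cell reached first in
    row-major order and, within a cell, diagonal > gap-in-query > gap-in-ref,
    which keeps output deterministic.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if not query or not reference:
        raise ValueError("local_align requires nonempty sequences")

    n, m = len(query), len(reference)
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend

    NEG = float("-inf")
    # H/E/F matrices with traceback pointers.  E: gap in query (moves j),
    # F: gap in ref (moves i).
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    # pointers: Hp in {0 stop, 1 diag, 2 E, 3 F}; Ep/Fp True if extending
    Hp = [[0] * (m + 1) for _ in range(n + 1)]
    Ep = [[False] * (m + 1) for _ in range(n + 1)]
    Fp = [[False] * (m + 1) for _ in range(n + 1)]

    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        for j in range(1, m + 1):
            e_open = Hi[j - 1] + go
            e_ext = Ei[j - 1] + ge
            e = e_open if e_open >= e_ext else e_ext
            Ei[j] = e
            Ep[i][j] = e_ext > e_open

            f_open = Hi1[j] + go
            f_ext = F[i - 1][j] + ge
            f = f_open if f_open >= f_ext else f_ext
            F[i][j] = f
            Fp[i][j] = f_ext > f_open

            diag = Hi1[j - 1] + (ma if qc == reference[j - 1] else mi)
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if e > h:
                h, p = e, 2
            if f > h:
                h, p = f, 3
            Hi[j] = h
            Hp[i][j] = p
            if h > best:
                best, bi, bj = h, i, j

    if best == 0:
        return LocalAlignment(score=0)

    # traceback from (bi, bj) in state H
    cols: List[AlignedColumn] = []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            p = Hp[i][j]
            if p == 0:
                break
            if p == 1:
                kind = MATCH if query[i - 1] == reference[j - 1] else MISMATCH
                cols.append(AlignedColumn(i - 1, j - 1, kind))
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append(AlignedColumn(i, j - 1, GAP_QUERY))
            ext = Ep[i][j]
            j -= 1
            state = "E" if ext else "H"
        else:  # F
            cols.append(AlignedColumn(i - 1, j, GAP_REF))
            ext = Fp[i][j]
            i -= 1
            state = "F" if ext else "H"

    cols.reverse()
    return LocalAlignment(score=best, columns=cols, query_span=(i, bi), ref_span=(j, bj))


def junction_alignment_distance(aln: LocalAlignment, junction: int) -> int:
    """Minimum distance (reference columns) from `junction` to the first error.

    `junction` is the boundary index in the reference between the leader part
    (reference[:junction]) and the genomic part (reference[junction:]).  Each
    flank contributes the number of error-free match columns between the
    junction and its first mismatch, gap, or the alignment end; an error-free
    flank therefore contributes its full aligned length.  If the junction lies
    outside the aligned reference span the distance is 0.
    """
    if aln.is_empty:
        return 0
    rstart, rend = aln.ref_span
    if junction <= rstart or junction >= rend:
        return 0

    # split columns at the junction: first column whose reference side has
    # reached the genomic part.  Gap-in-reference columns sit between reference
    # positions and belong to whichever side they are emitted on.
    split = len(aln.columns)
    ref_pos = rstart
    for idx, col in enumerate(aln.columns):
        if ref_pos >= junction:
            split = idx
            break
        if col.kind in _REF_CONSUMING:
            ref_pos += 1
    else:
        split = len(aln.columns)

    left = 0
    for col in reversed(aln.columns[:split]):
        if col.kind == MATCH:
            left += 1
        else:
            break
    right = 0
    for col in aln.columns[split:]:
        if col.kind == MATCH:
            right += 1
        else:
            break
    return min(left, right)
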