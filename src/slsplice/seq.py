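"""Small sequence utilities shared across modules.

Coordinate conventions (package-wide):

* all genomic coordinates are 0-based, half-open, on the plus strand;
* an acceptor (trans-splice site) coordinate is the first exonic base in
  transcript orientation — for minus-strand genes this is the *highest*
  genomic coordinate of the exon;
* windows around an anchor are half-open offset ranges ``(start, end)`` on
  the transcribed strand with offset 0 = the anchor base (see `slsplice.pssm`).
"""

from __future__ import annotations

from typing import Mapping, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def window_sequence(
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    strand: str,
    window: Tuple[int, int],
) -> str | None:
    """Transcribed-strand sequence of `window` anchored at `pos`.

    Offset 0 maps to the base at `pos` (plus strand) or at `pos` read on the
    minus strand; positive offsets run downstream in transcript orientation.
    Returns None when the window runs off the contig.
    """
    seq = str(genome[chrom])
    w0, w1 = window
    if strand == "+":
        lo, hi = pos + w0, pos + w1
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi].upper()
    elif strand == "-":
        lo, hi = pos - w1 + 1, pos - w0 + 1
        if lo < 0 or hi > len(seq):
            return None
        return revcomp(seq[lo:hi]).upper()
    raise ValueError(f"bad strand {strand!r}")


def has_acceptor_ag(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> bool:
    """True if the 2 bases immediately 5' of `pos` on the template strand are AG."""
    context = window_sequence(genome, chrom, pos, strand, (-2, 0))
    return context == "AG"


def iupac_hamming(seq: str, consensus: str) -> int:
    """Hamming distance where consensus R matches A or G; other codes literal ACGT."""
    if len(seq) != len(consensus):
        raise ValueError("length mismatch")
    d = 0
    for b, c in zip(seq.upper(), consensus.upper()):
        if c == "R":
            if b not in "AG":
                d += 1
        elif c in "ACGT":
            if b != c:
                d += 1
        else:
            raise ValueError(f"unsupported consensus code {c!r}")
    return d
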