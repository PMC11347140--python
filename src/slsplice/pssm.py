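"""Position-specific scoring matrices (log-odds over background).

Used twice in the pipeline: for the outron motif upstream of trans-splice
acceptors (the C. elegans polypyrimidine/acceptor element, UUUCAG/R on the
RNA) and for Kozak contexts (-3..-1) around annotated start codons.

Window convention (used package-wide): a window is a half-open offset range
``(start, end)`` relative to an anchor coordinate, where offset 0 is the
anchor base itself (first exonic base for acceptors, first intronic base for
donors, the A of ATG for starts).  Biological "+1" is offset 0; biological
"-1" is offset -1.  So the acceptor motif written -10..+2 in splice-site
notation is the window (-10, 2) and covers 12 bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

BASES = "ACGT"
UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}


@dataclass
class Pssm:
    window: Tuple[int, int]
    scores: Dict[int, Dict[str, float]]  # offset -> base -> log2 odds
    pseudocount: float
    background: Mapping[str, float]

    @property
    def length(self) -> int:
        return self.window[1] - self.window[0]

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        window: Tuple[int, int],
        background: Mapping[str, float] | None = None,
        pseudocount: float = 1.0,
    ) -> "Pssm":
        """Build a log2-odds matrix from aligned window sequences.

        Per position p and base b the score is
        ``log2(((count + pseudocount) / (total + 4 * pseudocount)) / background[b])``.
        """
        if background is None:
            background = UNIFORM_BACKGROUND
        tot_bg = sum(background[b] for b in BASES)
        if abs(tot_bg - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        seqs = [s.upper() for s in sequences]
        if not seqs:
            raise ValueError("cannot build a PSSM from an empty sequence set")
        length = window[1] - window[0]
        for s in seqs:
            if len(s) != length:
                raise ValueError(f"sequence length {len(s)} != window length {length}")

        scores: Dict[int, Dict[str, float]] = {}
        for i, offset in enumerate(range(window[0], window[1])):
            counts = {b: 0 for b in BASES}
            total = 0
            for s in seqs:
                b = s[i]
                if b in counts:
                    counts[b] += 1
                    total += 1
            denom = total + 4.0 * pseudocount
            scores[offset] = {
                b: math.log2(((counts[b] + pseudocount) / denom) / background[b])
                for b in BASES
            }
        return cls(window=window, scores=scores, pseudocount=pseudocount, background=dict(background))

    def score(self, sequence: str) -> float:
        """Sum of per-position log-odds; ambiguous bases (N) contribute 0."""
        sequence = sequence.upper()
        if len(sequence) != self.length:
            raise ValueError(f"sequence length {len(sequence)} != window length {self.length}")
        total = 0.0
        for offset, base in zip(range(self.window[0], self.window[1]), sequence):
            total += self.scores[offset].get(base, 0.0)
        return total

    def max_score(self) -> float:
        return sum(max(col.values()) for col in self.scores.values())

    def consensus(self) -> str:
        return "".join(
            max(self.scores[o], key=self.scores[o].__getitem__)
            for o in range(self.window[0], self.window[1])
        )


def mononucleotide_background(genome: Mapping[str, str]) -> Dict[str, float]:
    """Genome-wide A/C/G/T frequencies (ambiguous bases ignored)."""
    counts = {b: 0 for b in BASES}
    for seq in genome.values():
        s = str(seq).upper()
        for b in BASES:
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("genome contains no unambiguous bases")
    return {b: counts[b] / total for b in BASES}
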