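"""Readers and writers for the pipeline's file formats.

FASTA via pyfaidx, SAM via pysam, tables via pandas.  The annotation model is
a small GTF subset (gene/exon/start_codon features, plus a custom ``sl_sites``
attribute on gene lines listing annotated trans-splice acceptor positions).

All files use 0-based half-open coordinates internally; GTF is converted to
1-based inclusive at the file boundary, BED stays 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from pyfaidx import Fasta

from .seq import revcomp

SAM_HEADER_SORT = "unsorted"


# ---------------------------------------------------------------------------
# genome FASTA

def load_genome(path: str) -> Dict[str, str]:
    """Load a (small) genome FASTA fully into memory as chrom -> sequence."""
    fa = Fasta(path, rebuild=False, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(reads: Iterable[Tuple[str, str]], path: str) -> None:
    """Write (name, sequence) pairs with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> Iterator[Tuple[str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header.strip()[1:].split()[0], seq


# ---------------------------------------------------------------------------
# annotation (GTF subset)

@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open genomic extent
    end: int
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)  # genomic, ascending
    start_codon: Optional[int] = None  # genomic coordinate of the A of ATG
    sl_sites: List[int] = field(default_factory=list)  # annotated acceptor coords

    @property
    def first_exon(self) -> Tuple[int, int]:
        """First exon in transcript orientation."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def five_prime_boundary(self) -> int:
        """Genomic coordinate of the first exonic base in transcript orientation."""
        e = self.first_exon
        return e[0] if self.strand == "+" else e[1] - 1


@dataclass
class Annotation:
    genes: Dict[str, Gene] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        self.genes[gene.gene_id] = gene

    def genes_on(self, chrom: str) -> List[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def overlapping(self, chrom: str, pos: int) -> List[Gene]:
        return [g for g in self.genes_on(chrom) if g.start <= pos < g.end]


def write_gtf(annotation: Annotation, path: str, source: str = "slsplice") -> None:
    with open(path, "w") as fh:
        for gene in annotation.genes.values():
            sl = ",".join(str(p) for p in gene.sl_sites)
            attrs = f'gene_id "{gene.gene_id}"; sl_sites "{sl}";'
            fh.write(
                "\t".join(
                    [gene.chrom, source, "gene", str(gene.start + 1), str(gene.end),
                     ".", gene.strand, ".", attrs]
                )
                + "\n"
            )
            for start, end in gene.exons:
                fh.write(
                    "\t".join(
                        [gene.chrom, source, "exon", str(start + 1), str(end),
                         ".", gene.strand, ".", f'gene_id "{gene.gene_id}";']
                    )
                    + "\n"
                )
            if gene.start_codon is not None:
                if gene.strand == "+":
                    s, e = gene.start_codon, gene.start_codon + 3
                else:
                    s, e = gene.start_codon - 2, gene.start_codon + 1
                fh.write(
                    "\t".join(
                        [gene.chrom, source, "start_codon", str(s + 1), str(e),
                         ".", gene.strand, ".", f'gene_id "{gene.gene_id}";']
                    )
                    + "\n"
                )


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def read_gtf(path: str) -> Annotation:
    ann = Annotation()
    exons: Dict[str, List[Tuple[int, int, str]]] = {}
    starts: Dict[str, Tuple[int, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ValueError(f"GTF line without gene_id: {line!r}")
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                sl_raw = _gtf_attr(attrs, "sl_sites") or ""
                sl = [int(x) for x in sl_raw.split(",") if x]
                ann.add(Gene(gene_id=gid, chrom=chrom, start=s, end=e, strand=strand, sl_sites=sl))
            elif feature == "exon":
                exons.setdefault(gid, []).append((s, e, strand))
            elif feature == "start_codon":
                starts[gid] = (s, e, strand)
    for gid, gene in ann.genes.items():
        gene.exons = sorted((s, e) for s, e, _ in exons.get(gid, []))
        if gid in starts:
            s, e, strand = starts[gid]
            gene.start_codon = s if strand == "+" else e - 1
    return ann


# ---------------------------------------------------------------------------
# alignments

@dataclass
class AlignmentRecord:
    """Strand-aware view of one aligned read.

    ``five_prime_pos`` is the genomic coordinate of the aligned 5' base of the
    read (highest aligned coordinate for minus-strand reads).  ``softclip5``
    and ``aligned_seq`` are in read (sequencing) orientation.  ``junctions``
    are half-open genomic intron intervals from CIGAR N operations.
    """

    query_name: str
    chrom: str
    strand: str
    ref_start: int
    ref_end: int
    five_prime_pos: int
    softclip5: str
    aligned_seq: str
    junctions: List[Tuple[int, int]]
    usable: bool = True

    def first_downstream_junction(self, pos: int) -> Optional[Tuple[int, int]]:
        """First intron junction 3' of `pos` in transcript orientation.

        Introns whose acceptor end abuts `pos` itself (cis-splicing into the
        trans-splice site) are upstream, not downstream.
        """
        if self.strand == "+":
            down = [j for j in self.junctions if j[0] >= pos]
            return min(down) if down else None
        down = [j for j in self.junctions if j[1] <= pos + 1]
        return max(down) if down else None


def _to_record(seg: pysam.AlignedSegment, ref_name: str) -> AlignmentRecord:
    cig = seg.cigartuples or []
    qs = seg.query_sequence or ""
    lead_clip = cig[0][1] if cig and cig[0][0] == 4 else 0
    trail_clip = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    hard5 = (cig and cig[0][0] == 5 and not seg.is_reverse) or (
        cig and cig[-1][0] == 5 and seg.is_reverse
    )
    junctions: List[Tuple[int, int]] = []
    pos = seg.reference_start
    for op, ln in cig:
        if op in (0, 7, 8, 2):  # M/=/X/D consume reference
            pos += ln
        elif op == 3:  # N
            junctions.append((pos, pos + ln))
            pos += ln

    aligned_plus = qs[lead_clip : len(qs) - trail_clip] if qs else ""
    if seg.is_reverse:
        strand = "-"
        five_prime = seg.reference_end - 1
        clip5 = revcomp(qs[len(qs) - trail_clip :]) if trail_clip else ""
        aligned = revcomp(aligned_plus)
    else:
        strand = "+"
        five_prime = seg.reference_start
        clip5 = qs[:lead_clip]
        aligned = aligned_plus
    return AlignmentRecord(
        query_name=seg.query_name,
        chrom=ref_name,
        strand=strand,
        ref_start=seg.reference_start,
        ref_end=seg.reference_end,
        five_prime_pos=five_prime,
        softclip5=clip5,
        aligned_seq=aligned,
        junctions=junctions,
        usable=bool(qs) and not hard5,
    )


def read_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Stream mapped reads from a SAM/BAM file as AlignmentRecords."""
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_id < 0:
                continue
            yield _to_record(seg, fh.get_reference_name(seg.reference_id))


def make_sam_header(genome: Mapping[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": SAM_HEADER_SORT},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
        }
    )


def write_sam(segments: Sequence[pysam.AlignedSegment], header: pysam.AlignmentHeader, path: str) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for seg in segments:
            fh.write(seg)


# ---------------------------------------------------------------------------
# tables

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "jad", "pssm_score", "source"]


def write_sites_bed(sites, path: str) -> None:
    """BED6+3 trans-splice site file: name=SL class, score=read support."""
    rows = []
    for s in sites:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.position,
                "end": s.position + 1,
                "name": s.sl_class,
                "score": s.n_supporting_reads,
                "strand": s.strand,
                "jad": s.best_jad,
                "pssm_score": f"{s.pssm_score:.6g}",
                "source": s.source,
            }
        )
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_sites_bed(path: str):
    from .discovery import TransSpliceSite

    sites = []
    if os.path.getsize(path) == 0:
        return sites
    df = pd.read_csv(path, sep="\t", names=BED_COLUMNS)
    for _, row in df.iterrows():
        sites.append(
            TransSpliceSite(
                chrom=str(row.chrom),
                position=int(row.start),
                strand=str(row.strand),
                sl_class=str(row["name"]),
                n_supporting_reads=int(row.score),
                best_alignment_score=0,
                best_jad=int(row.jad),
                pssm_score=float(row.pssm_score),
                source=str(row.source),
            )
        )
    return sites


def write_table(df: pd.DataFrame, path: str) -> None:
    """TSV with header, stable column order, 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
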