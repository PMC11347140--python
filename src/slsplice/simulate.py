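"""Synthetic trans-splicing datasets with full ground truth.

The generator emulates the structures a spliced-leader (SL) trans-splicing
study measures, so every downstream module is testable without real data:

* a toy genome of multi-exon genes, each with an *outron* (the region
  upstream of the trans-splice acceptor), a canonical start codon, and a
  planted acceptor immediately 3' of an AG dinucleotide with a
  UUUCAG-like outron motif;
* long reads whose trans-spliced fraction per genotype is configurable:
  trans-spliced reads carry a 3'-anchored SL remnant emitted as a 5'
  soft-clip, retained-outron reads extend upstream of the acceptor, and
  reads suffer uniform substitution errors and geometric 5' truncation;
* genes optionally planted with a cis-splice donor inside the outron
  (cis-spliced retained outron, CSRO) or an alternative downstream SL
  acceptor on the same first exon (ALT3TSS);
* short (Illumina-like) forward reads beginning with SL remnants, plus the
  post-trim alignments an aligner would produce, and an optional genomic
  locus whose sequence mimics an SL suffix (a planted false positive for
  the trimming path);
* count-level and delta-PSI-table simulators for the statistical modules.

Alignments are synthesised directly from ground truth (soft-clips, CIGAR
junctions, strands) rather than via an external aligner.  Identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from . import io as sio
from .discovery import SpliceLeader
from .io import Annotation, Gene
from .seq import revcomp

BASES = "ACGT"

# real C. elegans leader sequences (22 nt each); the pipeline depends only on
# leader identity, so any distinct pair works
DEFAULT_LEADERS = (
    SpliceLeader(name="SL1", sl_class="SL1", sequence="GGTTTAATTACCCAAGTTTGAG"),
    SpliceLeader(name="SL2", sl_class="SL2", sequence="GGTTTTAACCCAGTTACTCAAG"),
)

LABEL_TRANS = "trans_spliced"
LABEL_RETAINED = "retained_outron"
LABEL_CSRO = "cis_spliced_retained_outron"
LABEL_TRUNC = "internal_truncation"
LABEL_UNSPLICED = "unspliced"  # reads of genes without any planted site


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Default proportions follow the planted differential design: wild type
    trans-splices 90% of transcripts at each site, the mutant 50%.
    """

    seed: int = 42
    n_genes: int = 20
    chrom_length: Optional[int] = None  # derived from the gene layout if None
    outron_length: Tuple[int, int] = (50, 150)
    leaders: Tuple[SpliceLeader, ...] = DEFAULT_LEADERS
    genotypes: Tuple[str, ...] = ("wt", "mut")
    psi_by_genotype: Tuple[float, ...] = (0.9, 0.5)
    n_replicates: int = 3
    reads_per_gene: int = 50  # long reads, per genotype per replicate
    substitution_error_rate: float = 0.0
    leader_remnant: Tuple[int, int] = (10, 22)
    read_5p_truncation_p: float = 0.5  # geometric success prob; length = Geom(p) - 1
    fraction_genes_trans_spliced: float = 1.0
    frac_csro: float = 0.0
    frac_alt3tss: float = 0.0
    frac_null: float = 0.0
    cis_fraction: float = 0.8  # CSRO genes: fraction of retained reads cis-spliced
    # ALT3TSS genes: (primary, alt) trans-splicing proportions per genotype
    alt_psi_wt: Tuple[float, float] = (0.90, 0.02)
    alt_psi_mut: Tuple[float, float] = (0.30, 0.55)
    # short-read settings
    short_reads_per_gene: int = 30
    short_read_length: int = 75
    short_remnant: Tuple[int, int] = (0, 22)
    plant_false_positive_locus: bool = True
    fp_locus_reads: int = 15
    # fixed gene geometry
    flank: int = 40
    exon1_length: int = 120
    intron_length: int = 60
    exon2_length: int = 80
    start_codon_offset: int = 45  # within exon 1
    alt_site_offset: int = 36  # ALT3TSS acceptor, within exon 1
    cis_donor_offset: int = 10  # CSRO donor, within the outron

    def __post_init__(self) -> None:
        fracs = {
            "psi": self.psi_by_genotype,
            "event fractions": (self.frac_csro, self.frac_alt3tss, self.frac_null),
            "fraction_genes_trans_spliced": (self.fraction_genes_trans_spliced,),
            "cis_fraction": (self.cis_fraction,),
            "substitution_error_rate": (self.substitution_error_rate,),
        }
        for name, vals in fracs.items():
            for v in vals:
                if not (0.0 <= v <= 1.0):
                    raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if len(self.psi_by_genotype) != len(self.genotypes):
            raise ConfigurationError("psi_by_genotype must match genotypes")
        if self.frac_csro + self.frac_alt3tss + self.frac_null > 1.0:
            raise ConfigurationError("event-class fractions exceed 1")
        if self.n_genes < 1 or self.n_replicates < 1 or self.reads_per_gene < 0:
            raise ConfigurationError("counts must be positive")
        if self.outron_length[0] < 30 or self.outron_length[0] > self.outron_length[1]:
            raise ConfigurationError("outron_length must be (min, max) with min >= 30")
        if not (0 < self.leader_remnant[0] <= self.leader_remnant[1]):
            raise ConfigurationError("leader_remnant must be positive (min, max)")
        max_leader = max(len(l.sequence) for l in self.leaders)
        if self.leader_remnant[1] > max_leader or self.short_remnant[1] > max_leader:
            raise ConfigurationError("remnant length exceeds leader length")
        if not (0.0 < self.read_5p_truncation_p <= 1.0):
            raise ConfigurationError("read_5p_truncation_p must be in (0, 1]")
        for l in self.leaders:
            if not set(l.sequence.upper()) <= set("ACGTU"):
                raise ConfigurationError(f"leader {l.name} has a bad alphabet")
        if self.slot_length() * self.n_genes > (self.chrom_length or math.inf):
            raise ConfigurationError(
                "chrom_length too small for the gene layout "
                f"(need >= {self.slot_length() * self.n_genes})"
            )

    def slot_length(self) -> int:
        return (
            self.flank
            + self.outron_length[1]
            + self.exon1_length
            + self.intron_length
            + self.exon2_length
            + 60  # intergenic spacer
        )


@dataclass
class GeneLayout:
    """Placement of one simulated gene on the chromosome."""

    gene_id: str
    chrom: str
    strand: str
    g0: int  # genomic start of the gene's region (plus-strand coords)
    region_len: int
    flank: int
    outron_len: int
    e1: int
    intron: int
    e2: int
    leader: SpliceLeader
    sited: bool
    event_class: str  # RO / CSRO / ALT3TSS / null / none
    psi: Dict[str, float] = field(default_factory=dict)  # primary site
    alt_psi: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    # transcript-coordinate anchors (offset 0 = region start = flank start)
    @property
    def outron_t(self) -> int:
        return self.flank

    @property
    def acceptor_t(self) -> int:
        return self.flank + self.outron_len

    @property
    def intron_t(self) -> Tuple[int, int]:
        s = self.acceptor_t + self.e1
        return s, s + self.intron

    @property
    def end_t(self) -> int:
        return self.acceptor_t + self.e1 + self.intron + self.e2

    def t2g(self, t: int) -> int:
        if self.strand == "+":
            return self.g0 + t
        return self.g0 + self.region_len - 1 - t

    def interval_g(self, a: int, b: int) -> Tuple[int, int]:
        """Transcript interval [a, b) as an ascending genomic interval."""
        if self.strand == "+":
            return self.g0 + a, self.g0 + b
        return self.g0 + self.region_len - b, self.g0 + self.region_len - a

    @property
    def acceptor_g(self) -> int:
        return self.t2g(self.acceptor_t)


@dataclass
class PlantedSite:
    chrom: str
    position: int
    strand: str
    sl_class: str
    gene_id: str
    kind: str  # primary / alt

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.position, self.strand)


@dataclass
class LongRead:
    name: str
    chrom: str
    strand: str
    blocks: List[Tuple[int, int]]  # ascending genomic intervals
    clip5: str  # SL remnant in read orientation ("" if none)
    body: str  # aligned portion in read orientation
    genotype: str
    replicate: int
    label: str
    gene_id: str

    @property
    def sequence(self) -> str:
        return self.clip5 + self.body

    def to_record(self) -> sio.AlignmentRecord:
        junctions = [
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        ]
        five = self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1
        return sio.AlignmentRecord(
            query_name=self.name,
            chrom=self.chrom,
            strand=self.strand,
            ref_start=self.blocks[0][0],
            ref_end=self.blocks[-1][1],
            five_prime_pos=five,
            softclip5=self.clip5,
            aligned_seq=self.body,
            junctions=junctions,
        )

    def to_segment(self, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
        seg = pysam.AlignedSegment(header)
        seg.query_name = self.name
        seg.mapping_quality = 60
        seg.reference_id = header.get_tid(self.chrom)
        seg.reference_start = self.blocks[0][0]
        cig: List[Tuple[int, int]] = []
        for i, (s, e) in enumerate(self.blocks):
            if i:
                cig.append((3, s - self.blocks[i - 1][1]))
            cig.append((0, e - s))
        if self.strand == "+":
            seg.flag = 0
            if self.clip5:
                cig.insert(0, (4, len(self.clip5)))
            seg.query_sequence = self.clip5 + self.body
        else:
            seg.flag = 16
            if self.clip5:
                cig.append((4, len(self.clip5)))
            seg.query_sequence = revcomp(self.clip5 + self.body)
        seg.cigartuples = cig
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(seg.query_sequence))
        return seg


@dataclass
class GroundTruth:
    sites: List[PlantedSite] = field(default_factory=list)
    # (chrom, position, strand, genotype) -> true trans-splicing proportion
    psi: Dict[Tuple[str, int, str, str], float] = field(default_factory=dict)
    read_labels: Dict[str, str] = field(default_factory=dict)
    event_class: Dict[str, str] = field(default_factory=dict)  # gene_id -> class

    def site_keys(self) -> List[Tuple[str, int, str]]:
        return [s.key for s in self.sites]

    def to_json(self, path: str) -> None:
        payload = {
            "sites": [asdict(s) for s in self.sites],
            "psi": [
                {"chrom": c, "position": p, "strand": st, "genotype": g, "psi": v}
                for (c, p, st, g), v in self.psi.items()
            ],
            "read_labels": self.read_labels,
            "event_class": self.event_class,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: Dict[str, str]
    annotation: Annotation
    layouts: List[GeneLayout]
    truth: GroundTruth
    long_reads: Dict[Tuple[str, int], List[LongRead]] = field(default_factory=dict)
    short_reads: List[Tuple[str, str]] = field(default_factory=list)  # (name, seq)
    short_alignments: List[LongRead] = field(default_factory=list)  # post-trim records

    def all_long_reads(self) -> List[LongRead]:
        out: List[LongRead] = []
        for key in sorted(self.long_reads):
            out.extend(self.long_reads[key])
        return out

    def long_read_records(self, genotype: str | None = None, replicate: int | None = None):
        reads = (
            self.long_reads.get((genotype, replicate), [])
            if genotype is not None and replicate is not None
            else self.all_long_reads()
        )
        return [r.to_record() for r in reads]

    def short_read_records(self):
        return [r.to_record() for r in self.short_alignments]


# ---------------------------------------------------------------------------
# genome

def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _impose(codes: np.ndarray, start: int, motif: str) -> None:
    for i, b in enumerate(motif):
        codes[start + i] = BASES.index(b)


def _impose_noisy(codes: np.ndarray, start: int, motif: str, rng: np.random.Generator, p: float) -> None:
    for i, b in enumerate(motif):
        codes[start + i] = BASES.index(b) if rng.random() < p else rng.integers(0, 4)


def _acceptor_context(codes: np.ndarray, acceptor_t: int, rng: np.random.Generator) -> None:
    """Plant a UUUCAG/R-like 3' trans-splice motif with the extended
    polypyrimidine tract (-10..-4 T-rich); the AG is exact."""
    _impose_noisy(codes, acceptor_t - 10, "TTTTTTT", rng, 0.9)
    _impose_noisy(codes, acceptor_t - 3, "C", rng, 0.95)
    _impose(codes, acceptor_t - 2, "AG")
    codes[acceptor_t] = BASES.index("A" if rng.random() < 0.5 else "G")


def _donor_context(codes: np.ndarray, donor_t: int, rng: np.random.Generator) -> None:
    """Plant an AG|GTAAGT-like 5' splice site; the GT is exact."""
    _impose_noisy(codes, donor_t - 2, "AG", rng, 0.8)
    _impose(codes, donor_t, "GT")
    _impose_noisy(codes, donor_t + 2, "AAGT", rng, 0.8)


def simulate_genome(config: SimConfig) -> SimulatedDataset:
    """Build the toy genome, gene models and ground truth (no reads yet)."""
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    slot = config.slot_length()
    length = config.chrom_length or slot * config.n_genes + 200
    codes = _rand_seq(rng, length)

    n_sited = int(round(config.fraction_genes_trans_spliced * config.n_genes))
    sited_idx = set(rng.choice(config.n_genes, size=n_sited, replace=False).tolist())
    sited_order = sorted(sited_idx)
    n_csro = int(round(config.frac_csro * n_sited))
    n_alt = int(round(config.frac_alt3tss * n_sited))
    n_null = int(round(config.frac_null * n_sited))
    class_of: Dict[int, str] = {}
    for rank, gi in enumerate(sited_order):
        if rank < n_csro:
            class_of[gi] = "CSRO"
        elif rank < n_csro + n_alt:
            class_of[gi] = "ALT3TSS"
        elif rank < n_csro + n_alt + n_null:
            class_of[gi] = "null"
        else:
            class_of[gi] = "RO"

    layouts: List[GeneLayout] = []
    truth = GroundTruth()
    annotation = Annotation()
    for gi in range(config.n_genes):
        outron_len = int(rng.integers(config.outron_length[0], config.outron_length[1] + 1))
        strand = "+" if gi % 2 == 0 else "-"
        sited = gi in sited_idx
        event = class_of.get(gi, "none")
        lay = GeneLayout(
            gene_id=f"gene{gi:04d}",
            chrom=chrom,
            strand=strand,
            g0=gi * slot,
            region_len=config.flank + outron_len + config.exon1_length + config.intron_length + config.exon2_length,
            flank=config.flank,
            outron_len=outron_len,
            e1=config.exon1_length,
            intron=config.intron_length,
            e2=config.exon2_length,
            leader=config.leaders[gi % len(config.leaders)],
            sited=sited,
            event_class=event,
        )

        region = _rand_seq(rng, lay.region_len)
        i0, i1 = lay.intron_t
        _donor_context(region, i0, rng)
        _impose(region, i1 - 2, "AG")
        start_t = lay.acceptor_t + config.start_codon_offset
        _impose(region, start_t, "ATG")
        _impose_noisy(region, start_t - 3, "AAA", rng, 0.7)  # Kozak-like -3..-1

        sl_sites_g: List[int] = []
        if sited:
            _acceptor_context(region, lay.acceptor_t, rng)
            site = PlantedSite(chrom, lay.t2g(lay.acceptor_t), strand, lay.leader.sl_class, lay.gene_id, "primary")
            truth.sites.append(site)
            sl_sites_g.append(site.position)
            if event == "ALT3TSS":
                alt_t = lay.acceptor_t + config.alt_site_offset
                _acceptor_context(region, alt_t, rng)
                alt = PlantedSite(chrom, lay.t2g(alt_t), strand, lay.leader.sl_class, lay.gene_id, "alt")
                truth.sites.append(alt)
                sl_sites_g.append(alt.position)
            if event == "CSRO":
                _donor_context(region, lay.outron_t + config.cis_donor_offset, rng)
            truth.event_class[lay.gene_id] = event

            for g, base_psi in zip(config.genotypes, config.psi_by_genotype):
                if event == "null":
                    lay.psi[g] = config.psi_by_genotype[0]
                elif event == "ALT3TSS":
                    pair = config.alt_psi_wt if g == config.genotypes[0] else config.alt_psi_mut
                    lay.alt_psi[g] = pair
                    lay.psi[g] = pair[0]
                else:
                    lay.psi[g] = base_psi
                truth.psi[(chrom, lay.t2g(lay.acceptor_t), strand, g)] = lay.psi[g]
                if event == "ALT3TSS":
                    truth.psi[(chrom, lay.t2g(lay.acceptor_t + config.alt_site_offset), strand, g)] = lay.alt_psi[g][1]

        # place the region on the chromosome
        gseq = region if strand == "+" else np.array(
            [3 - c for c in region[::-1]], dtype=region.dtype
        )
        codes[lay.g0 : lay.g0 + lay.region_len] = gseq
        layouts.append(lay)

        exon1 = lay.interval_g(lay.acceptor_t, lay.acceptor_t + lay.e1)
        exon2 = lay.interval_g(i1, lay.end_t)
        gene_span = lay.interval_g(lay.outron_t, lay.end_t)
        annotation.add(
            Gene(
                gene_id=lay.gene_id,
                chrom=chrom,
                start=gene_span[0],
                end=gene_span[1],
                strand=strand,
                exons=sorted([exon1, exon2]),
                start_codon=lay.t2g(start_t),
                sl_sites=sorted(sl_sites_g),
            )
        )

    genome = {chrom: _codes_to_str(codes)}
    if config.plant_false_positive_locus and config.n_genes >= 1:
        # intergenic locus whose upstream sequence equals an SL1 3' suffix
        lay0 = layouts[0]
        q = lay0.g0 + lay0.region_len + 20
        decoy = config.leaders[0].sequence[-10:]
        genome[chrom] = genome[chrom][:q] + decoy + genome[chrom][q + len(decoy) :]
    return SimulatedDataset(
        config=config, genome=genome, annotation=annotation, layouts=layouts, truth=truth
    )


# ---------------------------------------------------------------------------
# reads

def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _transcript_seq(region: str, blocks_t: Sequence[Tuple[int, int]]) -> str:
    return "".join(region[a:b] for a, b in blocks_t)


def _region_seq(genome: Mapping[str, str], lay: GeneLayout) -> str:
    raw = genome[lay.chrom][lay.g0 : lay.g0 + lay.region_len]
    return raw if lay.strand == "+" else revcomp(raw)


def _blocks_to_genomic(lay: GeneLayout, blocks_t: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out = [lay.interval_g(a, b) for a, b in blocks_t]
    return sorted(out)


def _spliced_blocks(lay: GeneLayout, start_t: int, extra_introns: Sequence[Tuple[int, int]] = ()) -> List[Tuple[int, int]]:
    """Transcript blocks from start_t to gene end, skipping introns >= start."""
    introns = sorted(list(extra_introns) + [lay.intron_t])
    blocks = []
    pos = start_t
    for s, e in introns:
        if e <= pos:
            continue
        if s > pos:
            blocks.append((pos, s))
        pos = e
    blocks.append((pos, lay.end_t))
    return [b for b in blocks if b[1] > b[0]]


def simulate_long_reads(sim: SimulatedDataset) -> SimulatedDataset:
    """Populate `sim.long_reads` per (genotype, replicate) with ground truth."""
    config = sim.config
    rng = np.random.default_rng(config.seed + 1)
    counter = 0
    for genotype in config.genotypes:
        for rep in range(config.n_replicates):
            reads: List[LongRead] = []
            for lay in sim.layouts:
                region = _region_seq(sim.genome, lay)
                for _ in range(config.reads_per_gene):
                    counter += 1
                    name = f"lr{counter:07d}|{lay.gene_id}|{genotype}|rep{rep}"
                    read = _make_long_read(lay, region, genotype, rep, name, config, rng)
                    reads.append(read)
                    sim.truth.read_labels[name] = read.label
            sim.long_reads[(genotype, rep)] = reads
    return sim


def _truncation(config: SimConfig, rng: np.random.Generator) -> int:
    return int(rng.geometric(config.read_5p_truncation_p) - 1)


def _make_long_read(
    lay: GeneLayout,
    region: str,
    genotype: str,
    rep: int,
    name: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> LongRead:
    acceptor_t = lay.acceptor_t
    u = rng.random()
    kind = LABEL_UNSPLICED
    start_t = lay.outron_t
    clip = ""
    extra_introns: List[Tuple[int, int]] = []

    if lay.sited:
        if lay.event_class == "ALT3TSS":
            p_primary, p_alt = lay.alt_psi[genotype]
            if u < p_primary:
                kind, site_t = LABEL_TRANS, acceptor_t
            elif u < p_primary + p_alt:
                kind, site_t = LABEL_TRANS, acceptor_t + config.alt_site_offset
            else:
                kind = LABEL_RETAINED
        else:
            if u < lay.psi[genotype]:
                kind, site_t = LABEL_TRANS, acceptor_t
            else:
                kind = LABEL_RETAINED
                if lay.event_class == "CSRO" and rng.random() < config.cis_fraction:
                    kind = LABEL_CSRO

    trunc = _truncation(config, rng)
    if kind == LABEL_TRANS:
        remnant = int(rng.integers(config.leader_remnant[0], config.leader_remnant[1] + 1))
        eff = remnant - trunc
        if eff > 0:
            clip = lay.leader.sequence[-eff:]
            start_t = site_t
        else:
            start_t = min(site_t - eff, lay.end_t - 30)
        rel = start_t - site_t
        label = LABEL_TRANS if -14 <= rel <= 10 else LABEL_TRUNC
        # relabel against the primary acceptor for alt-site reads
        if label == LABEL_TRANS and site_t != acceptor_t:
            label = LABEL_TRANS
    elif kind == LABEL_CSRO:
        donor_t = lay.outron_t + config.cis_donor_offset
        start_t = int(rng.integers(0, max(donor_t - 5, 1)))
        start_t = min(start_t + trunc, donor_t - 5)
        extra_introns = [(donor_t, acceptor_t)]
        label = LABEL_CSRO
    elif kind == LABEL_RETAINED:
        max_up = min(lay.outron_len + lay.flank - 1, 80)
        up = int(rng.integers(15, max(max_up, 16)))
        start_t = acceptor_t - up + trunc
        rel = start_t - acceptor_t
        label = LABEL_RETAINED if rel < -14 else LABEL_TRUNC
    else:  # unspliced transcript of a gene without a planted site
        start_t = lay.outron_t + int(rng.integers(0, 30)) + trunc
        label = LABEL_UNSPLICED

    blocks_t = _spliced_blocks(lay, start_t, extra_introns)
    body = _transcript_seq(region, blocks_t)
    seq = _apply_errors(clip + body, config.substitution_error_rate, rng)
    clip_out, body_out = seq[: len(clip)], seq[len(clip) :]
    return LongRead(
        name=name,
        chrom=lay.chrom,
        strand=lay.strand,
        blocks=_blocks_to_genomic(lay, blocks_t),
        clip5=clip_out,
        body=body_out,
        genotype=genotype,
        replicate=rep,
        label=label,
        gene_id=lay.gene_id,
    )


def simulate_short_reads(sim: SimulatedDataset) -> SimulatedDataset:
    """Forward short reads starting with SL 3' suffixes, plus post-trim alignments.

    The emitted SAM records correspond to ground-truth trimming: remnants of at
    least 7 nt are removed before alignment, shorter remnants remain on the
    read and appear as 5' soft-clips (as a spliced aligner would report them).
    """
    config = sim.config
    rng = np.random.default_rng(config.seed + 2)
    counter = 0
    L = config.short_read_length
    for lay in sim.layouts:
        if not lay.sited:
            continue
        region = _region_seq(sim.genome, lay)
        for _ in range(config.short_reads_per_gene):
            counter += 1
            k = int(rng.integers(config.short_remnant[0], config.short_remnant[1] + 1))
            remnant = lay.leader.sequence[-k:] if k else ""
            body_len = L - k
            body = region[lay.acceptor_t : lay.acceptor_t + body_len]
            seq = _apply_errors(remnant + body, config.substitution_error_rate, rng)
            name = f"sr{counter:07d}|{lay.gene_id}|k{k}"
            sim.short_reads.append((name, seq))
            trimmed_off = k if k >= 7 else 0
            clip = seq[trimmed_off:k]
            aln_body = seq[k:]
            blocks_t = [(lay.acceptor_t, lay.acceptor_t + len(aln_body))]
            sim.short_alignments.append(
                LongRead(
                    name=name,
                    chrom=lay.chrom,
                    strand=lay.strand,
                    blocks=_blocks_to_genomic(lay, blocks_t),
                    clip5=clip,
                    body=aln_body,
                    genotype="na",
                    replicate=0,
                    label="short",
                    gene_id=lay.gene_id,
                )
            )
    if config.plant_false_positive_locus and sim.layouts:
        lay0 = sim.layouts[0]
        q = lay0.g0 + lay0.region_len + 20
        chrom_seq = sim.genome[lay0.chrom]
        for _ in range(config.fp_locus_reads):
            counter += 1
            seq = chrom_seq[q : q + L]
            name = f"sr{counter:07d}|fp_locus"
            sim.short_reads.append((name, seq))
            sim.short_alignments.append(
                LongRead(
                    name=name,
                    chrom=lay0.chrom,
                    strand="+",
                    blocks=[(q + 10, q + L)],
                    clip5="",
                    body=seq[10:],
                    genotype="na",
                    replicate=0,
                    label="short_fp",
                    gene_id="fp_locus",
                )
            )
    return sim


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Genome + long reads + short reads in one call."""
    sim = simulate_genome(config)
    simulate_long_reads(sim)
    simulate_short_reads(sim)
    return sim


# ---------------------------------------------------------------------------
# count-level simulator (for the statistical modules)

def simulate_site_counts(
    n_sites: int,
    psi_a: float,
    psi_b: float,
    n_replicates: int = 3,
    reads_per_replicate: int = 50,
    seed: int = 0,
    genotypes: Tuple[str, str] = ("wt", "mut"),
) -> pd.DataFrame:
    """Binomial per-replicate trans-spliced/retained counts for synthetic sites."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        for genotype, psi in zip(genotypes, (psi_a, psi_b)):
            for rep in range(n_replicates):
                t = int(rng.binomial(reads_per_replicate, psi))
                rows.append(
                    {
                        "site": f"site{i:05d}",
                        "genotype": genotype,
                        "replicate": rep,
                        "n_trans_spliced": t,
                        "n_retained": reads_per_replicate - t,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delta-PSI table simulator (for the effect-size module)

DONOR_WINDOW = (-3, 6)  # 5'SS -3..+6 in splice-site notation
_DONOR_COMPOSITION = {
    -3: {"A": 0.4, "C": 0.2, "G": 0.2, "T": 0.2},
    -2: {"A": 0.55, "C": 0.1, "G": 0.15, "T": 0.2},
    -1: {"A": 0.1, "C": 0.1, "G": 0.6, "T": 0.2},
    0: {"G": 0.95, "A": 0.02, "C": 0.01, "T": 0.02},  # +1
    1: {"T": 0.92, "A": 0.03, "C": 0.02, "G": 0.03},  # +2
    2: {"A": 0.55, "G": 0.25, "C": 0.1, "T": 0.1},  # +3
    3: {"A": 0.45, "G": 0.25, "T": 0.2, "C": 0.1},  # +4
    4: {"G": 0.5, "A": 0.2, "T": 0.2, "C": 0.1},  # +5
    5: {"T": 0.35, "A": 0.25, "G": 0.2, "C": 0.2},  # +6
}


def simulate_dpsi_table(
    n_sites: int,
    shifts: Mapping[Tuple[int, str], float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    window: Tuple[int, int] = DONOR_WINDOW,
) -> pd.DataFrame:
    """Synthetic 5'SS windows with planted per-(position, base) delta-PSI shifts.

    `shifts` keys use window offsets (offset 0 = first intronic base, so
    splice-site "+4" is offset 3).  The significance flag marks sites whose
    |delta-PSI| exceeds twice the noise SD.
    """
    shifts = dict(shifts or {})
    rng = np.random.default_rng(seed)
    offsets = list(range(window[0], window[1]))
    cols = {"event_id": [], "window_seq": [], "delta_psi": [], "significant": []}
    thresh = 2.0 * noise_sd if noise_sd > 0 else 0.0
    for i in range(n_sites):
        seq = []
        for o in offsets:
            comp = _DONOR_COMPOSITION.get(o, {b: 0.25 for b in BASES})
            bases = sorted(comp)
            probs = np.array([comp[b] for b in bases])
            seq.append(bases[int(rng.choice(len(bases), p=probs / probs.sum()))])
        seq = "".join(seq)
        dpsi = sum(shifts.get((o, b), 0.0) for o, b in zip(offsets, seq))
        if noise_sd > 0:
            dpsi += float(rng.normal(0.0, noise_sd))
        cols["event_id"].append(f"ev{i:05d}")
        cols["window_seq"].append(seq)
        cols["delta_psi"].append(dpsi)
        cols["significant"].append(abs(dpsi) > thresh)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# outron-region fixture for the uORF module

def simulate_outron_regions(
    n_regions: int,
    frac_inframe: float = 0.6,
    region_length: int = 90,
    seed: int = 0,
) -> List[Tuple[str, str, int]]:
    """(name, sequence, canonical_start_offset) tuples with a controlled
    fraction of regions containing an in-frame upstream ATG.

    Sequences are ATG-free except for the planted codon, so the planted
    fraction is exact.
    """
    rng = np.random.default_rng(seed)
    out = []
    n_in = int(round(frac_inframe * n_regions))
    for i in range(n_regions):
        while True:
            seq = _codes_to_str(_rand_seq(rng, region_length))
            if "ATG" not in seq:
                break
        if i < n_in:
            pos = int(rng.integers(0, (region_length - 3) // 3)) * 3
            seq = seq[:pos] + "ATG" + seq[pos + 3 :]
        out.append((f"region{i:04d}", seq, region_length))
    return out


# ---------------------------------------------------------------------------
# writers

def write_simulation(sim: SimulatedDataset, outdir: str) -> Dict[str, str]:
    """Write FASTA/GTF/FASTQ/SAM/ground-truth files; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}
    paths["genome"] = os.path.join(outdir, "genome.fa")
    sio.write_fasta(sim.genome, paths["genome"])
    paths["annotation"] = os.path.join(outdir, "genes.gtf")
    sio.write_gtf(sim.annotation, paths["annotation"])
    header = sio.make_sam_header(sim.genome)
    for (genotype, rep), reads in sorted(sim.long_reads.items()):
        key = f"long_{genotype}_rep{rep}"
        paths[key + "_fastq"] = os.path.join(outdir, key + ".fastq")
        sio.write_fastq(((r.name, r.sequence) for r in reads), paths[key + "_fastq"])
        paths[key + "_sam"] = os.path.join(outdir, key + ".sam")
        sio.write_sam([r.to_segment(header) for r in reads], header, paths[key + "_sam"])
    if sim.short_reads:
        paths["short_fastq"] = os.path.join(outdir, "short.fastq")
        sio.write_fastq(sim.short_reads, paths["short_fastq"])
        paths["short_sam"] = os.path.join(outdir, "short_trimmed.sam")
        sio.write_sam(
            [r.to_segment(header) for r in sim.short_alignments], header, paths["short_sam"]
        )
    paths["truth"] = os.path.join(outdir, "ground_truth.json")
    sim.truth.to_json(paths["truth"])
    sites_df = pd.DataFrame(
        [
            {"chrom": s.chrom, "position": s.position, "strand": s.strand,
             "sl_class": s.sl_class, "gene_id": s.gene_id, "kind": s.kind}
            for s in sim.truth.sites
        ]
    )
    paths["truth_sites"] = os.path.join(outdir, "ground_truth_sites.tsv")
    sio.write_table(sites_df, paths["truth_sites"])
    return paths
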