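"""Configuration and the end-to-end pipeline.

The pipeline chains: (optional) simulation -> long-read discovery ->
short-read discovery -> site merging -> differential trans-splicing ->
trans-acceptor motif/U2AF tables -> outron uORF analysis, writing one table
per stage into the output directory.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import differential as diff
from . import discovery as disc
from . import io as sio
from . import motifs as mot
from . import orf
from .align import ScoringScheme
from .simulate import SimConfig, simulate_dataset, write_simulation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Threshold defaults are the pipeline's canonical constants: AG search
    radius 10 nt, genomic extension 24 nt, soft-clip extension 28 nt, JAD
    cutoffs 8, trimming overlap 7 / error rate 0.09 / min length 15,
    short-read candidate support 10 / retention support 2, read window
    -14..+10, |delta-PSI| >= 0.03 and FDR < 0.05.
    """

    outdir: str = "slsplice_out"
    seed: int = 42
    # inputs (unused when `simulate` is set: the simulation writes them)
    genome: Optional[str] = None
    annotation: Optional[str] = None
    leaders: Optional[str] = None  # FASTA; names must start with SL1/SL2
    long_reads: Dict[str, List[str]] = field(default_factory=dict)  # genotype -> SAMs
    short_fastq: Optional[str] = None
    short_sam: Optional[str] = None
    simulate: Optional[SimConfig] = None
    # thresholds
    search_radius: int = 10
    genomic_ext: int = 24
    clip_ext: int = 28
    jad_train_cutoff: int = 8
    jad_final_cutoff: int = 8
    min_overlap: int = 7
    max_error_rate: float = 0.09
    min_length: int = 15
    min_candidate_reads: int = 10
    min_support: int = 2
    window: Tuple[int, int] = (-14, 10)
    min_coverage: int = 10
    alpha: float = 0.05
    fdr_cutoff: float = 0.05
    dpsi_cutoff: float = 0.03
    match: int = 2
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        if isinstance(cfg.window, list):
            cfg.window = tuple(cfg.window)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("genome", "annotation"):
                path = getattr(self, name)
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"pipeline config: missing {name} ({path!r})")
            for genotype, paths in self.long_reads.items():
                for p in paths:
                    if not os.path.exists(p):
                        raise FileNotFoundError(f"pipeline config: missing alignment {p!r}")


def load_leaders(path: Optional[str]) -> List[disc.SpliceLeader]:
    if path is None:
        from .simulate import DEFAULT_LEADERS

        return list(DEFAULT_LEADERS)
    leaders = []
    for name, seq in sio.read_fastq(path) if path.endswith("q") else _read_fasta_pairs(path):
        sl_class = "SL2" if name.upper().startswith("SL2") else "SL1"
        leaders.append(disc.SpliceLeader(name=name, sl_class=sl_class, sequence=seq))
    return leaders


def _read_fasta_pairs(path: str):
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def estimate_ro_regions(
    results: pd.DataFrame,
    alignments_by_group: Mapping[Tuple[str, int], Sequence[sio.AlignmentRecord]],
    genome: Mapping[str, str],
    annotation: sio.Annotation,
) -> List[orf.OutronRegion]:
    """Outron regions for significant retention events.

    The outron 5' end per site is the 5'-most retained-read end among all
    long reads (the reads contributing the retention signal); the region runs
    from there to the canonical start codon on the exonic (transcript)
    sequence.  Regions whose gene lacks an annotated start are skipped.
    """
    sig = results[results["significant"] & results["event_class"].isin([diff.CLASS_RO, diff.CLASS_CSRO])]
    if sig.empty:
        return []
    site_keys = [(r.chrom, r.position, r.strand) for r in sig.itertuples()]
    extremes: Dict[Tuple[str, int, str], int] = {}
    for _group, reads in alignments_by_group.items():
        for read in reads:
            for site in site_keys:
                if read.chrom != site[0] or read.strand != site[2]:
                    continue
                rel = read.five_prime_pos - site[1] if site[2] == "+" else site[1] - read.five_prime_pos
                if rel < -14 and read.ref_start <= site[1] < read.ref_end:
                    extremes[site] = min(extremes.get(site, 0), rel)
    regions: List[orf.OutronRegion] = []
    for r in sig.itertuples():
        site = (r.chrom, r.position, r.strand)
        if site not in extremes:
            continue
        gene = next(
            (annotation.genes[g] for g in r.gene.split(",") if g in annotation.genes), None
        )
        if gene is None or gene.start_codon is None:
            continue
        start_off = (
            gene.start_codon - r.position if r.strand == "+" else r.position - gene.start_codon
        )
        if start_off <= 0:
            continue
        upstream = -extremes[site]
        from .seq import window_sequence

        seq = window_sequence(genome, r.chrom, r.position, r.strand, (-upstream, start_off))
        if seq is None:
            continue
        regions.append(
            orf.OutronRegion(
                name=f"{r.chrom}:{r.position}:{r.strand}",
                sequence=seq,
                canonical_start=len(seq),
                event_class=r.event_class,
            )
        )
    return regions


def run_pipeline(config: PipelineConfig) -> Dict[str, str]:
    """Run every stage; returns the map of written artifact paths."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    artifacts: Dict[str, str] = {}

    if config.simulate is not None:
        sim = simulate_dataset(config.simulate)
        sim_paths = write_simulation(sim, os.path.join(config.outdir, "sim"))
        config.genome = sim_paths["genome"]
        config.annotation = sim_paths["annotation"]
        config.long_reads = {}
        for genotype in sim.config.genotypes:
            config.long_reads[genotype] = [
                sim_paths[f"long_{genotype}_rep{rep}_sam"]
                for rep in range(sim.config.n_replicates)
            ]
        config.short_fastq = sim_paths.get("short_fastq")
        config.short_sam = sim_paths.get("short_sam")
        artifacts.update(sim_paths)

    genome = sio.load_genome(config.genome)
    annotation = sio.read_gtf(config.annotation)
    leaders = load_leaders(config.leaders)

    # --- discovery
    pooled = []
    for genotype in sorted(config.long_reads):
        for path in config.long_reads[genotype]:
            pooled.extend(sio.read_alignments(path))
    long_sites, assignments = disc.call_long_read_sites(
        pooled, genome, leaders, config.scoring,
        search_radius=config.search_radius,
        jad_train_cutoff=config.jad_train_cutoff,
        jad_final_cutoff=config.jad_final_cutoff,
    )
    artifacts["long_sites"] = os.path.join(config.outdir, "sites_long.bed")
    sio.write_sites_bed(long_sites, artifacts["long_sites"])
    assign_df = pd.DataFrame(
        [
            {
                "read": a.read_name, "chrom": a.candidate.chrom,
                "position": a.candidate.position, "strand": a.candidate.strand,
                "leader": a.leader.name, "score": a.score, "jad": a.jad,
            }
            for a in assignments.values()
        ]
    )
    artifacts["read_assignments"] = os.path.join(config.outdir, "read_assignments.tsv")
    sio.write_table(assign_df, artifacts["read_assignments"])

    short_sites: List[disc.TransSpliceSite] = []
    if config.short_fastq and config.short_sam:
        reads = list(sio.read_fastq(config.short_fastq))
        _trimmed, trim_records = disc.trim_sl_short_reads(
            reads, leaders,
            min_overlap=config.min_overlap,
            max_error_rate=config.max_error_rate,
            min_length=config.min_length,
        )
        short_sites = disc.call_short_read_sites(
            sio.read_alignments(config.short_sam), trim_records, genome,
            min_candidate_reads=config.min_candidate_reads,
            min_support=config.min_support,
        )
    artifacts["short_sites"] = os.path.join(config.outdir, "sites_short.bed")
    sio.write_sites_bed(short_sites, artifacts["short_sites"])

    merged = disc.merge_site_sets(long_sites, short_sites)
    artifacts["merged_sites"] = os.path.join(config.outdir, "sites_merged.bed")
    sio.write_sites_bed(merged, artifacts["merged_sites"])

    # --- differential (reference genotype first)
    if config.simulate is not None:
        genotypes = tuple(config.simulate.genotypes)[:2]
    else:
        genotypes = tuple(config.long_reads)[:2]
    results = pd.DataFrame()
    if len(genotypes) == 2 and merged:
        groups = {
            (genotype, rep): list(sio.read_alignments(path))
            for genotype in genotypes
            for rep, path in enumerate(config.long_reads[genotype])
        }
        results, qc = diff.run_differential(
            [s.key for s in merged], groups, annotation, genotypes,
            min_coverage=config.min_coverage, alpha=config.alpha,
            fdr_cutoff=config.fdr_cutoff, dpsi_cutoff=config.dpsi_cutoff,
            window=config.window,
        )
        artifacts["differential"] = os.path.join(config.outdir, "differential.tsv")
        sio.write_table(results, artifacts["differential"])
        artifacts["read_class_qc"] = os.path.join(config.outdir, "read_class_qc.tsv")
        sio.write_table(qc, artifacts["read_class_qc"])

        if not results.empty:
            # trans-acceptor motif of sensitive vs background sites + U2AF tables
            from .seq import window_sequence

            sens_keys = [
                (r.chrom, r.position, r.strand)
                for r in results[results["significant"]].itertuples()
            ]
            bg_keys = [
                (r.chrom, r.position, r.strand)
                for r in results[~results["significant"]].itertuples()
            ]
            win = mot.TRANS_ACCEPTOR_WINDOW
            sens_w = [w for w in (window_sequence(genome, *k, win) for k in sens_keys) if w]
            bg_w = [w for w in (window_sequence(genome, *k, win) for k in bg_keys) if w]
            if sens_w:
                matrix = mot.build_motif(sens_w, win)
                artifacts["sensitive_motif"] = os.path.join(config.outdir, "sensitive_acceptor_motif.tsv")
                matrix.probabilities.to_csv(artifacts["sensitive_motif"], sep="\t", float_format="%.6g")
            t65, t35 = diff.u2af_class_tables(sens_keys, bg_keys, genome)
            artifacts["u2af65_table"] = os.path.join(config.outdir, "u2af65_classes.tsv")
            artifacts["u2af35_table"] = os.path.join(config.outdir, "u2af35_classes.tsv")
            t65.to_csv(artifacts["u2af65_table"], sep="\t")
            t35.to_csv(artifacts["u2af35_table"], sep="\t")

            # outron uORF analysis for significant retention events
            regions = estimate_ro_regions(results, groups, genome, annotation)
            if regions:
                contexts = orf.kozak_contexts_from_annotation(genome, annotation)
                pssm = orf.build_kozak_pssm(contexts)
                per_region = orf.analyse_regions(regions, pssm)
                artifacts["uorf_candidates"] = os.path.join(config.outdir, "uorf_candidates.tsv")
                sio.write_table(per_region, artifacts["uorf_candidates"])
                artifacts["uorf_summary"] = os.path.join(config.outdir, "uorf_summary.tsv")
                sio.write_table(orf.class_summary(per_region), artifacts["uorf_summary"])

    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), config.outdir)
    return artifacts
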