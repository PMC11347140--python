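"""Differential trans-splicing between genotypes.

Per annotated trans-splice site, overlapping reads are classified as
trans-spliced (aligned 5' end within the -14..+10 window of the acceptor) or
retained outron (5' end earlier than -14 *and* first downstream intron
junction identical to the modal junction of the trans-spliced reads; anything
else is excluded with a recorded reason).  Replicate counts are aggregated
per genotype, the genotype x category 2x2 table is tested with a G-test,
sites with p < 0.05 are checked for replicate homogeneity within each
genotype, p-values are BH-adjusted over all tested sites, and significant
events are classified as retained outron (RO), cis-spliced retained outron
(CSRO) or alternative 3' trans-splice site (ALT3TSS).

PSI here is the fraction of reads trans-spliced at a site;
delta-PSI = PSI(first genotype) - PSI(second genotype).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import AlignmentRecord, Annotation
from .seq import iupac_hamming, window_sequence
from .stats import bh_fdr, g_test, homogeneity_test

logger = logging.getLogger(__name__)

SiteKey = Tuple[str, int, str]  # (chrom, position, strand)

DEFAULT_WINDOW = (-14, 10)  # inclusive offsets of the trans-spliced 5'-end window

CLASS_RO = "RO"
CLASS_CSRO = "CSRO"
CLASS_ALT3TSS = "ALT3TSS"
CLASS_NS = "not_significant"


@dataclass
class SiteGeneAssignment:
    site: SiteKey
    gene_ids: List[str]
    distance: int  # |site - assigned gene's 5' exon boundary|


@dataclass
class SiteEvidence:
    """Read-level evidence at one site for one (genotype, replicate)."""

    n_trans: int = 0
    n_retained: int = 0
    excluded: Counter = field(default_factory=Counter)
    cis_junction_donors: Counter = field(default_factory=Counter)  # donor coord -> reads


def _rel_offset(site: SiteKey, five_prime: int) -> int:
    """5'-end offset in transcript orientation (downstream positive)."""
    chrom, pos, strand = site
    return five_prime - pos if strand == "+" else pos - five_prime


def classify_read_at_site(
    read: AlignmentRecord,
    site: SiteKey,
    modal_junction: Optional[Tuple[int, int]],
    window: Tuple[int, int] = DEFAULT_WINDOW,
) -> Tuple[str, str]:
    """(label, reason) for one read at one site.

    `modal_junction` is the modal first-downstream intron junction of the
    site's trans-spliced reads (None when they have no downstream junction).
    """
    rel = _rel_offset(site, read.five_prime_pos)
    if window[0] <= rel <= window[1]:
        return "trans_spliced", ""
    if rel < window[0]:
        if read.first_downstream_junction(site[1]) == modal_junction:
            return "retained_outron", ""
        return "excluded", "junction_mismatch"
    return "excluded", "internal_truncation"


def _cis_junction_donor(read: AlignmentRecord, site: SiteKey) -> Optional[int]:
    """Donor coordinate of an intron whose acceptor end lands on `site`."""
    chrom, pos, strand = site
    for s, e in read.junctions:
        if strand == "+" and e == pos:
            return s - 1  # last exonic base of the donor side
        if strand == "-" and s == pos + 1:
            return e
    return None


def collect_site_evidence(
    sites: Sequence[SiteKey],
    reads: Iterable[AlignmentRecord],
    window: Tuple[int, int] = DEFAULT_WINDOW,
) -> Dict[SiteKey, SiteEvidence]:
    """Classify one replicate's reads at every site (two passes: the first
    establishes each site's modal downstream junction from trans-spliced
    reads, the second classifies retained candidates against it)."""
    by_key: Dict[Tuple[str, str], List[int]] = defaultdict(list)
    key_sites: Dict[Tuple[str, str], List[SiteKey]] = defaultdict(list)
    for s in sorted(sites):
        by_key[(s[0], s[2])].append(s[1])
        key_sites[(s[0], s[2])].append(s)

    pending: Dict[SiteKey, List[AlignmentRecord]] = defaultdict(list)
    evidence: Dict[SiteKey, SiteEvidence] = {s: SiteEvidence() for s in sites}
    trans_junctions: Dict[SiteKey, Counter] = defaultdict(Counter)

    for read in reads:
        positions = by_key.get((read.chrom, read.strand))
        if not positions:
            continue
        lo = bisect_left(positions, read.ref_start - 50)
        hi = bisect_right(positions, read.ref_end + 14)
        for idx in range(lo, hi):
            site = key_sites[(read.chrom, read.strand)][idx]
            rel = _rel_offset(site, read.five_prime_pos)
            if window[0] <= rel <= window[1]:
                evidence[site].n_trans += 1
                j = read.first_downstream_junction(site[1])
                trans_junctions[site][j] += 1
            elif rel < window[0]:
                pending[site].append(read)
            else:
                evidence[site].excluded["internal_truncation"] += 1

    for site, reads_at in pending.items():
        modal = (
            trans_junctions[site].most_common(1)[0][0] if trans_junctions[site] else None
        )
        ev = evidence[site]
        for read in reads_at:
            if read.first_downstream_junction(site[1]) == modal:
                ev.n_retained += 1
                donor = _cis_junction_donor(read, site)
                if donor is not None:
                    ev.cis_junction_donors[donor] += 1
            else:
                ev.excluded["junction_mismatch"] += 1
    return evidence


def compute_psi(n_trans: int, n_retained: int) -> float:
    total = n_trans + n_retained
    if total == 0:
        raise ZeroDivisionError("PSI undefined with zero coverage")
    return n_trans / total


# ---------------------------------------------------------------------------
# gene assignment

def assign_sites_to_genes(
    sites: Sequence[SiteKey],
    annotation: Annotation,
    max_downstream: int = 1000,
) -> List[SiteGeneAssignment]:
    """Assign each site to overlapping gene(s).

    Multi-gene overlaps resolve to the gene whose annotated 5' exon boundary
    is closest; exact ties assign the site to both genes.  Sites in no gene
    fall back to the nearest downstream gene start (transcript orientation)
    within `max_downstream`, else stay unassigned (logged).
    """
    out: List[SiteGeneAssignment] = []
    n_unassigned = 0
    for site in sites:
        chrom, pos, strand = site
        overlapping = [g for g in annotation.overlapping(chrom, pos) if g.strand == strand]
        if overlapping:
            dists = {g.gene_id: abs(pos - g.five_prime_boundary) for g in overlapping}
            dmin = min(dists.values())
            out.append(
                SiteGeneAssignment(site, sorted(g for g, d in dists.items() if d == dmin), dmin)
            )
            continue
        best: Optional[Tuple[int, str]] = None
        for g in annotation.genes_on(chrom):
            if g.strand != strand:
                continue
            d = (g.five_prime_boundary - pos) if strand == "+" else (pos - g.five_prime_boundary)
            if 0 <= d <= max_downstream and (best is None or d < best[0]):
                best = (d, g.gene_id)
        if best is not None:
            out.append(SiteGeneAssignment(site, [best[1]], best[0]))
        else:
            n_unassigned += 1
    if n_unassigned:
        logger.info("site-to-gene assignment: %d sites unassigned", n_unassigned)
    return out


# ---------------------------------------------------------------------------
# event classification

def _sl_site_on_exon(annotation: Annotation, gene_ids: Sequence[str], donor: int) -> bool:
    """True if the exon carrying the cis donor also carries an annotated SL site."""
    for gid in gene_ids:
        gene = annotation.genes.get(gid)
        if gene is None:
            continue
        for s, e in gene.exons:
            if s <= donor < e:
                if any(s <= p < e for p in gene.sl_sites):
                    return True
    return False


def classify_event(
    site: SiteKey,
    delta_psi: Mapping[SiteKey, float],
    cis_donors: Counter,
    annotation: Annotation,
    gene_ids: Sequence[str],
    min_cis_reads: int = 2,
) -> str:
    """CSRO / ALT3TSS / RO for one significant site."""
    if sum(cis_donors.values()) >= min_cis_reads:
        modal_donor = cis_donors.most_common(1)[0][0]
        if not _sl_site_on_exon(annotation, gene_ids, modal_donor):
            return CLASS_CSRO
    own = abs(delta_psi.get(site, 0.0))
    chrom, pos, strand = site
    for gid in gene_ids:
        gene = annotation.genes.get(gid)
        if gene is None:
            continue
        es, ee = gene.first_exon
        for other_pos in gene.sl_sites:
            if other_pos == pos or not (es <= other_pos <= ee):
                continue
            downstream = other_pos > pos if strand == "+" else other_pos < pos
            if not downstream:
                continue
            other = delta_psi.get((chrom, other_pos, strand))
            if other is not None and abs(other) > own:
                return CLASS_ALT3TSS
    return CLASS_RO


# ---------------------------------------------------------------------------
# full differential pipeline

def run_differential(
    sites: Sequence[SiteKey],
    alignments_by_group: Mapping[Tuple[str, int], Iterable[AlignmentRecord]],
    annotation: Optional[Annotation],
    genotypes: Tuple[str, str],
    min_coverage: int = 10,
    alpha: float = 0.05,
    fdr_cutoff: float = 0.05,
    dpsi_cutoff: float = 0.03,
    window: Tuple[int, int] = DEFAULT_WINDOW,
    min_cis_reads: int = 2,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Test every site for differential trans-splicing between two genotypes.

    `alignments_by_group` maps (genotype, replicate) to that replicate's
    alignment records.  Returns (results, read-class QC) DataFrames; results
    has one row per tested site with PSI per genotype, delta-PSI, G, p, FDR,
    homogeneity p-values and event class.
    """
    sites = sorted(set(sites))
    evidence: Dict[Tuple[str, int], Dict[SiteKey, SiteEvidence]] = {}
    for group, reads in alignments_by_group.items():
        evidence[group] = collect_site_evidence(sites, reads, window=window)

    replicates: Dict[str, List[int]] = defaultdict(list)
    for genotype, rep in evidence:
        replicates[genotype].append(rep)
    for g in genotypes:
        if g not in replicates:
            raise ValueError(f"no alignments supplied for genotype {g!r}")

    assignments = {a.site: a for a in assign_sites_to_genes(sites, annotation)} if annotation else {}

    qc_rows = []
    rows = []
    cis_map: Dict[SiteKey, Counter] = {}
    genes_map: Dict[SiteKey, List[str]] = {}
    for site in sites:
        agg = {g: [0, 0] for g in genotypes}
        per_rep: Dict[str, List[Tuple[int, int]]] = {g: [] for g in genotypes}
        cis = Counter()
        excl = Counter()
        for (genotype, rep), ev_map in sorted(evidence.items()):
            ev = ev_map[site]
            if genotype in agg:
                agg[genotype][0] += ev.n_trans
                agg[genotype][1] += ev.n_retained
                per_rep[genotype].append((ev.n_trans, ev.n_retained))
            cis.update(ev.cis_junction_donors)
            excl.update(ev.excluded)
        qc_rows.append(
            {
                "chrom": site[0], "position": site[1], "strand": site[2],
                "n_trans_spliced": sum(agg[g][0] for g in genotypes),
                "n_retained": sum(agg[g][1] for g in genotypes),
                "n_internal_truncation": excl.get("internal_truncation", 0),
                "n_junction_mismatch": excl.get("junction_mismatch", 0),
            }
        )
        if any(sum(agg[g]) < min_coverage for g in genotypes):
            continue
        table = [agg[genotypes[0]], agg[genotypes[1]]]
        g_stat, df, p = g_test(table)
        psi = {g: compute_psi(*agg[g]) for g in genotypes}
        homo = {g: float("nan") for g in genotypes}
        if p < alpha:
            for g in genotypes:
                homo[g] = homogeneity_test(per_rep[g])
        assignment = assignments.get(site)
        cis_map[site] = cis
        genes_map[site] = assignment.gene_ids if assignment else []
        rows.append(
            {
                "chrom": site[0], "position": site[1], "strand": site[2],
                "gene": ",".join(assignment.gene_ids) if assignment else "",
                f"psi_{genotypes[0]}": psi[genotypes[0]],
                f"psi_{genotypes[1]}": psi[genotypes[1]],
                "delta_psi": psi[genotypes[0]] - psi[genotypes[1]],
                "g_stat": g_stat, "df": df, "p_value": p,
                f"homogeneity_p_{genotypes[0]}": homo[genotypes[0]],
                f"homogeneity_p_{genotypes[1]}": homo[genotypes[1]],
            }
        )

    results = pd.DataFrame(rows)
    qc = pd.DataFrame(qc_rows)
    if results.empty:
        logger.warning("differential: no sites passed the coverage filter")
        return results, qc

    results["fdr"] = bh_fdr(results["p_value"].to_numpy())
    homo_cols = [f"homogeneity_p_{g}" for g in genotypes]
    homo_fail = np.zeros(len(results), dtype=bool)
    for c in homo_cols:
        vals = results[c].to_numpy()
        homo_fail |= (~np.isnan(vals)) & (vals < 0.05)
    results["homogeneity_fail"] = homo_fail
    results["significant"] = (
        (results["fdr"] < fdr_cutoff)
        & (results["delta_psi"].abs() >= dpsi_cutoff)
        & ~homo_fail
    )

    dpsi_map = {
        (r.chrom, r.position, r.strand): r.delta_psi for r in results.itertuples()
    }
    classes = []
    for r in results.itertuples():
        site = (r.chrom, r.position, r.strand)
        if not r.significant:
            classes.append(CLASS_NS)
        elif annotation is None:
            classes.append(CLASS_RO)
        else:
            classes.append(
                classify_event(site, dpsi_map, cis_map[site], annotation, genes_map[site], min_cis_reads)
            )
    results["event_class"] = classes
    logger.info(
        "differential: %d sites tested, %d significant (FDR < %g, |dPSI| >= %g)",
        len(results), int(results["significant"].sum()), fdr_cutoff, dpsi_cutoff,
    )
    return results, qc


# ---------------------------------------------------------------------------
# count-table interface (replicate counts already tallied)

def differential_from_counts(
    counts: pd.DataFrame,
    genotypes: Tuple[str, str],
    min_coverage: int = 10,
    alpha: float = 0.05,
    fdr_cutoff: float = 0.05,
    dpsi_cutoff: float = 0.03,
) -> pd.DataFrame:
    """Differential testing from a tidy per-replicate count table.

    `counts` columns: site, genotype, replicate, n_trans_spliced, n_retained.
    Replicates are aggregated per genotype before the main G-test; the
    homogeneity G-tests use the per-replicate rows.
    """
    rows = []
    for site, sub in counts.groupby("site", sort=True):
        agg = {}
        per_rep = {}
        for g in genotypes:
            gsub = sub[sub["genotype"] == g]
            agg[g] = (int(gsub["n_trans_spliced"].sum()), int(gsub["n_retained"].sum()))
            per_rep[g] = list(zip(gsub["n_trans_spliced"], gsub["n_retained"]))
        if any(sum(agg[g]) < min_coverage for g in genotypes):
            continue
        g_stat, df, p = g_test([agg[genotypes[0]], agg[genotypes[1]]])
        psi = {g: compute_psi(*agg[g]) for g in genotypes}
        homo = {g: float("nan") for g in genotypes}
        if p < alpha:
            homo = {g: homogeneity_test(per_rep[g]) for g in genotypes}
        rows.append(
            {
                "site": site,
                f"psi_{genotypes[0]}": psi[genotypes[0]],
                f"psi_{genotypes[1]}": psi[genotypes[1]],
                "delta_psi": psi[genotypes[0]] - psi[genotypes[1]],
                "g_stat": g_stat, "df": df, "p_value": p,
                f"homogeneity_p_{genotypes[0]}": homo[genotypes[0]],
                f"homogeneity_p_{genotypes[1]}": homo[genotypes[1]],
            }
        )
    results = pd.DataFrame(rows)
    if results.empty:
        return results
    results["fdr"] = bh_fdr(results["p_value"].to_numpy())
    homo_fail = np.zeros(len(results), dtype=bool)
    for g in genotypes:
        vals = results[f"homogeneity_p_{g}"].to_numpy()
        homo_fail |= (~np.isnan(vals)) & (vals < 0.05)
    results["homogeneity_fail"] = homo_fail
    results["significant"] = (
        (results["fdr"] < fdr_cutoff)
        & (results["delta_psi"].abs() >= dpsi_cutoff)
        & ~homo_fail
    )
    return results


# ---------------------------------------------------------------------------
# U2AF65 / U2AF35 acceptor-motif class tables

def u2af_classes(genome: Mapping[str, str], site: SiteKey) -> Optional[Tuple[int, int]]:
    """(U2AF65, U2AF35) consensus distances for a 3' trans-splice site.

    U2AF65: Hamming distance of positions -6..-4 from TTT (polypyrimidine);
    U2AF35: IUPAC-aware distance of -3..+1 from CAGR (R = A/G).
    """
    chrom, pos, strand = site
    py = window_sequence(genome, chrom, pos, strand, (-6, -3))
    acc = window_sequence(genome, chrom, pos, strand, (-3, 1))
    if py is None or acc is None:
        return None
    return iupac_hamming(py, "TTT"), iupac_hamming(acc, "CAGR")


def u2af_class_tables(
    sensitive: Sequence[SiteKey],
    background: Sequence[SiteKey],
    genome: Mapping[str, str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency tables of U2AF65 (0-3) and U2AF35 (0-4) classes,
    sensitive vs background site sets.  Off-contig sites are skipped."""
    tab65 = pd.DataFrame(0, index=range(4), columns=["sensitive", "background"])
    tab35 = pd.DataFrame(0, index=range(5), columns=["sensitive", "background"])
    for group, keys in (("sensitive", sensitive), ("background", background)):
        for site in keys:
            classes = u2af_classes(genome, site)
            if classes is None:
                continue
            d65, d35 = classes
            tab65.loc[d65, group] += 1
            tab35.loc[d35, group] += 1
    return tab65, tab35
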