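#!/usr/bin/env python
"""Discover trans-splice sites from the simulated long and short reads.

Long-read path: AG candidates near aligned 5' ends, leader/exon expected
references, Smith-Waterman + junction alignment distance, outron PSSM with
Chi-square decile thresholding.  Short-read path: SL suffix trimming,
candidate support, genomic-leader false-positive filtering, same PSSM
machinery.  Writes BED site files under results/ and reports recovery
against the planted ground truth.
"""

import json
import sys

from slsplice import io as sio
from slsplice.discovery import (
    call_long_read_sites,
    call_short_read_sites,
    merge_site_sets,
    trim_sl_short_reads,
)
from slsplice.pipeline import load_leaders

SIMDIR = "results/sim"


def truth_keys():
    with open(f"{SIMDIR}/ground_truth.json") as fh:
        truth = json.load(fh)
    return {(s["chrom"], s["position"], s["strand"]) for s in truth["sites"]}


def report(name, found, truth):
    tp = len(found & truth)
    rec = tp / len(truth) if truth else 0.0
    prec = tp / len(found) if found else 0.0
    print(f"{name}: {len(found)} sites, recall {rec:.1%}, precision {prec:.1%}")


def main() -> int:
    genome = sio.load_genome(f"{SIMDIR}/genome.fa")
    leaders = load_leaders(None)
    truth = truth_keys()

    pooled = []
    for genotype in ("wt", "mut"):
        for rep in range(3):
            pooled.extend(sio.read_alignments(f"{SIMDIR}/long_{genotype}_rep{rep}.sam"))
    long_sites, _ = call_long_read_sites(pooled, genome, leaders)
    sio.write_sites_bed(long_sites, "results/sites_long.bed")
    report("long-read discovery", {s.key for s in long_sites}, truth)

    _, trim_records = trim_sl_short_reads(sio.read_fastq(f"{SIMDIR}/short.fastq"), leaders)
    short_sites = call_short_read_sites(
        sio.read_alignments(f"{SIMDIR}/short_trimmed.sam"), trim_records, genome
    )
    sio.write_sites_bed(short_sites, "results/sites_short.bed")
    report("short-read discovery", {s.key for s in short_sites}, truth)

    merged = merge_site_sets(long_sites, short_sites)
    sio.write_sites_bed(merged, "results/sites_merged.bed")
    report("merged non-redundant set", {s.key for s in merged}, truth)
    return 0


if __name__ == "__main__":
    sys.exit(main())
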