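#!/usr/bin/env python
"""Upstream start codons and Kozak contexts in significant retained outrons.

Estimates each retention event's outron 5' end from the most extended
supporting long reads, extracts the region up to the canonical start codon,
finds upstream ATGs with frame classification, scores Kozak contexts with a
PSSM trained on all annotated start codons, and summarises in-frame
fractions per event class.  Writes results/uorf_candidates.tsv and
results/uorf_summary.tsv.
"""

import sys

import pandas as pd

from slsplice import io as sio
from slsplice.orf import analyse_regions, build_kozak_pssm, class_summary, kozak_contexts_from_annotation
from slsplice.pipeline import estimate_ro_regions

SIMDIR = "results/sim"
GENOTYPES = ("wt", "mut")


def main() -> int:
    genome = sio.load_genome(f"{SIMDIR}/genome.fa")
    annotation = sio.read_gtf(f"{SIMDIR}/genes.gtf")
    results = pd.read_csv("results/differential.tsv", sep="\t")
    groups = {
        (g, r): list(sio.read_alignments(f"{SIMDIR}/long_{g}_rep{r}.sam"))
        for g in GENOTYPES
        for r in range(3)
    }
    regions = estimate_ro_regions(results, groups, genome, annotation)
    if not regions:
        print("no significant retention events with read support")
        return 0

    contexts = kozak_contexts_from_annotation(genome, annotation)
    pssm = build_kozak_pssm(contexts)
    per_region = analyse_regions(regions, pssm)
    sio.write_table(per_region, "results/uorf_candidates.tsv")
    summary = class_summary(per_region)
    sio.write_table(summary, "results/uorf_summary.tsv")

    print(f"analysed {len(regions)} retained-outron regions "
          f"(Kozak PSSM trained on {len(contexts)} annotated starts)")
    print(summary.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
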