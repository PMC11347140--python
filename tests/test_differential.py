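"""Differential trans-splicing: read classification, PSI, gene assignment,
event classes, aggregation invariance and the U2AF acceptor-class tables."""

import numpy as np
import pandas as pd
import pytest

from slsplice.differential import (
    CLASS_ALT3TSS,
    CLASS_CSRO,
    CLASS_NS,
    CLASS_RO,
    assign_sites_to_genes,
    classify_read_at_site,
    collect_site_evidence,
    compute_psi,
    differential_from_counts,
    run_differential,
    u2af_class_tables,
    u2af_classes,
)
from slsplice.io import AlignmentRecord, Annotation, Gene
from slsplice.simulate import SimConfig, simulate_dataset, simulate_site_counts
from slsplice.stats import g_test

pytestmark = []


def make_read(five, strand="+", junctions=(), span=200, name="r"):
    if strand == "+":
        ref_start, ref_end = five, five + span
    else:
        ref_start, ref_end = five - span + 1, five + 1
    return AlignmentRecord(
        query_name=name, chrom="c", strand=strand, ref_start=ref_start,
        ref_end=ref_end, five_prime_pos=five, softclip5="", aligned_seq="A" * 10,
        junctions=list(junctions),
    )


SITE = ("c", 100, "+")
MODAL = (150, 200)


class TestClassifyRead:
    def test_five_prime_at_site_is_trans(self):
        label, _ = classify_read_at_site(make_read(100), SITE, MODAL)
        assert label == "trans_spliced"

    @pytest.mark.parametrize("rel,expected", [(-14, "trans_spliced"), (10, "trans_spliced"),
                                              (-15, "retained_outron"), (11, "excluded")])
    def test_window_boundaries(self, rel, expected):
        label, _ = classify_read_at_site(make_read(100 + rel, junctions=[MODAL]), SITE, MODAL)
        assert label == expected

    def test_retained_requires_matching_downstream_junction(self):
        label, reason = classify_read_at_site(
            make_read(80, junctions=[(150, 190)]), SITE, MODAL
        )
        assert (label, reason) == ("excluded", "junction_mismatch")

    def test_far_downstream_is_internal_truncation(self):
        label, reason = classify_read_at_site(make_read(130), SITE, MODAL)
        assert (label, reason) == ("excluded", "internal_truncation")

    def test_minus_strand_orientation(self):
        site = ("c", 100, "-")
        # 5' end at genomic 120 is 20 nt upstream in transcript orientation
        label, _ = classify_read_at_site(make_read(120, strand="-", junctions=[(40, 80)]),
                                         site, (40, 80))
        assert label == "retained_outron"


class TestCollectEvidence:
    def test_cis_junction_recorded(self):
        reads = [make_read(100, junctions=[MODAL], name=f"t{i}") for i in range(5)]
        reads += [make_read(60, junctions=[(70, 100), MODAL], name=f"c{i}") for i in range(3)]
        ev = collect_site_evidence([SITE], reads)[SITE]
        assert ev.n_trans == 5 and ev.n_retained == 3
        assert ev.cis_junction_donors == {69: 3}

    def test_excluded_reads_not_counted(self):
        reads = [make_read(100, junctions=[MODAL]), make_read(130)]
        ev = collect_site_evidence([SITE], reads)[SITE]
        assert ev.n_trans == 1 and ev.n_retained == 0
        assert ev.excluded["internal_truncation"] == 1
        label, reason = classify_read_at_site(make_read(130), SITE, MODAL)
        assert (label, reason) == ("excluded", "internal_truncation")


class TestPsi:
    def test_basic(self):
        assert compute_psi(80, 20) == pytest.approx(0.8)
        assert compute_psi(0, 50) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            compute_psi(0, 0)

    def test_delta_psi_arithmetic(self):
        assert compute_psi(80, 20) - compute_psi(40, 60) == pytest.approx(0.4)


class TestGeneAssignment:
    def _annotation(self):
        ann = Annotation()
        ann.add(Gene("gA", "c", 0, 300, "+", exons=[(100, 200), (250, 300)]))
        ann.add(Gene("gB", "c", 150, 500, "+", exons=[(260, 350), (400, 500)]))
        return ann

    def test_single_gene(self):
        [a] = assign_sites_to_genes([("c", 100, "+")], self._annotation())
        assert a.gene_ids == ["gA"]

    def test_nearer_five_prime_boundary_wins(self):
        # site 258: |258-100|=158 for gA, |258-260|=2 for gB
        [a] = assign_sites_to_genes([("c", 258, "+")], self._annotation())
        assert a.gene_ids == ["gB"] and a.distance == 2

    def test_tie_assigns_both(self):
        ann = Annotation()
        ann.add(Gene("gA", "c", 0, 300, "+", exons=[(100, 200)]))
        ann.add(Gene("gB", "c", 50, 300, "+", exons=[(160, 250)]))
        [a] = assign_sites_to_genes([("c", 130, "+")], ann)
        assert a.gene_ids == ["gA", "gB"]

    def test_intergenic_falls_to_downstream_gene(self):
        ann = self._annotation()
        assert assign_sites_to_genes([("c", 600, "+")], ann, max_downstream=1000) == []
        [b] = assign_sites_to_genes(
            [("c", 90, "+")],
            Annotation({"g": Gene("g", "c", 95, 200, "+", exons=[(95, 200)])}),
        )
        assert b.gene_ids == ["g"]


class TestEventClassification:
    def test_planted_classes_recovered(self, diff_sim):
        """CSRO, ALT3TSS, RO and null fixtures labeled per ground truth at
        every primary site."""
        sim = diff_sim
        cfg = sim.config
        groups = {
            (g, r): sim.long_read_records(g, r)
            for g in cfg.genotypes
            for r in range(cfg.n_replicates)
        }
        results, _ = run_differential(
            sim.truth.site_keys(), groups, sim.annotation, cfg.genotypes
        )
        primary_pos = {
            s.position: s.gene_id for s in sim.truth.sites if s.kind == "primary"
        }
        total = 0
        for row in results.itertuples():
            gene = primary_pos.get(row.position)
            if gene is None:
                continue
            truth = sim.truth.event_class[gene]
            total += 1
            if truth == "null":
                assert row.event_class == CLASS_NS
            elif row.significant:
                assert row.event_class == truth
            else:
                # a planted event may only miss significance via the
                # replicate-homogeneity QC filter, never via detection
                assert row.homogeneity_fail and row.fdr < 0.05
        assert total == 12

    def test_aggregation_invariance(self, diff_sim):
        """The main test on pooled replicates equals the G-test on the
        aggregated 2x2 table."""
        sim = diff_sim
        cfg = sim.config
        groups = {
            (g, r): sim.long_read_records(g, r)
            for g in cfg.genotypes
            for r in range(cfg.n_replicates)
        }
        results, _ = run_differential(
            sim.truth.site_keys(), groups, sim.annotation, cfg.genotypes
        )
        # recompute the aggregated table for one site directly
        site = sim.truth.site_keys()[0]
        table = []
        for g in cfg.genotypes:
            t = r = 0
            for rep in range(cfg.n_replicates):
                ev = collect_site_evidence([site], sim.long_read_records(g, rep))[site]
                t += ev.n_trans
                r += ev.n_retained
            table.append([t, r])
        g_stat, _, p = g_test(table)
        row = results[results["position"] == site[1]].iloc[0]
        assert row["g_stat"] == pytest.approx(g_stat)
        assert row["p_value"] == pytest.approx(p)

    def test_every_significant_site_has_one_class(self, diff_sim):
        sim = diff_sim
        cfg = sim.config
        groups = {
            (g, r): sim.long_read_records(g, r)
            for g in cfg.genotypes
            for r in range(cfg.n_replicates)
        }
        results, _ = run_differential(sim.truth.site_keys(), groups, sim.annotation, cfg.genotypes)
        sig = results[results["significant"]]
        assert sig["event_class"].isin([CLASS_RO, CLASS_CSRO, CLASS_ALT3TSS]).all()
        assert (~results["significant"] == (results["event_class"] == CLASS_NS)).all()


class TestCountInterface:
    def test_planted_difference_detected(self):
        counts = simulate_site_counts(20, 0.9, 0.5, seed=1)
        res = differential_from_counts(counts, ("wt", "mut"))
        assert len(res) == 20
        assert (res["fdr"] < 0.05).mean() > 0.9
        assert res["delta_psi"].mean() == pytest.approx(0.4, abs=0.1)

    def test_null_mostly_unsignificant(self):
        counts = simulate_site_counts(50, 0.7, 0.7, seed=2)
        res = differential_from_counts(counts, ("wt", "mut"))
        assert res["significant"].sum() <= 2

    def test_low_coverage_skipped(self):
        counts = simulate_site_counts(5, 0.8, 0.8, n_replicates=1, reads_per_replicate=3, seed=3)
        res = differential_from_counts(counts, ("wt", "mut"), min_coverage=10)
        assert res.empty


class TestU2afTables:
    def _genome_with_context(self, context):
        # acceptor at position 30; context covers -6..+1
        seq = "A" * 24 + context + "G" * 30
        return {"c": seq}, ("c", 30, "+")

    def test_consensus_context(self):
        genome, site = self._genome_with_context("TTTCAGG")
        assert u2af_classes(genome, site) == (0, 0)

    def test_last_base_c_fails_r(self):
        genome, site = self._genome_with_context("TTTCAGC")
        assert u2af_classes(genome, site) == (0, 1)

    def test_hand_counted_distances(self):
        genome, site = self._genome_with_context("AAACAGA")
        assert u2af_classes(genome, site) == (3, 0)

    def test_table_totals_match_input(self):
        genome, site = self._genome_with_context("TTTCAGG")
        t65, t35 = u2af_class_tables([site, site], [site], genome)
        assert t65["sensitive"].sum() == 2 and t65["background"].sum() == 1
        assert t35.to_numpy().sum() == 3

    def test_off_contig_site_skipped(self):
        genome = {"c": "TTTCAGG"}
        t65, _ = u2af_class_tables([("c", 2, "+")], [], genome)
        assert t65.to_numpy().sum() == 0
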