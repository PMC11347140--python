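"""Site discovery: candidate search, read assignment, thresholding, trimming,
the short-read path, merging, and end-to-end recovery on clean simulations."""

import numpy as np
import pytest

from slsplice.align import ScoringScheme
from slsplice.discovery import (
    CandidateAcceptor,
    SpliceLeader,
    TransSpliceSite,
    assign_read_best_site,
    build_expected_reference,
    call_long_read_sites,
    call_short_read_sites,
    enumerate_ag_positions,
    find_candidate_acceptors,
    merge_site_sets,
    read_query_window,
    select_pssm_threshold,
    trim_sl_short_reads,
)
from slsplice.io import AlignmentRecord
from slsplice.seq import has_acceptor_ag, revcomp
from slsplice.stats import pearson_chi2

from conftest import random_dna


def make_record(chrom="c", strand="+", five=50, clip="", aligned="A" * 40, junctions=(),
                name="r1", ref_start=None, ref_end=None):
    if ref_start is None:
        ref_start = five if strand == "+" else five - len(aligned) + 1
    if ref_end is None:
        ref_end = ref_start + len(aligned)
    return AlignmentRecord(
        query_name=name, chrom=chrom, strand=strand, ref_start=ref_start,
        ref_end=ref_end, five_prime_pos=five, softclip5=clip,
        aligned_seq=aligned, junctions=list(junctions),
    )


class TestCandidateAcceptors:
    def test_ag_immediately_upstream(self):
        #            0123456789
        genome = {"c": "TTTTAGGCAATTTTTTTTTT"}
        read = make_record(five=6, aligned=genome["c"][6:16])
        cands = find_candidate_acceptors(read, genome, search_radius=2)
        assert any(c.position == 6 for c in cands)
        for c in cands:
            assert genome["c"][c.position - 2 : c.position] == "AG"

    def test_no_ag_in_window(self):
        genome = {"c": "T" * 40}
        read = make_record(five=20, aligned="T" * 10)
        assert find_candidate_acceptors(read, genome, search_radius=10) == []

    def test_two_ags_in_constructed_window(self):
        """AGs placed so acceptors land at offsets -3 and +4 of the read end."""
        five = 20
        seq = list("T" * 41)
        seq[five - 5 : five - 3] = "AG"  # acceptor at five - 3
        seq[five + 2 : five + 4] = "AG"  # acceptor at five + 4
        genome = {"c": "".join(seq)}
        cands = find_candidate_acceptors(make_record(five=five), genome, search_radius=10)
        assert sorted(c.position for c in cands) == [five - 3, five + 4]

    def test_minus_strand_uses_template_ag(self):
        # acceptor at 10 on minus strand: plus-strand CT at 11..12
        seq = list("A" * 30)
        seq[11:13] = "CT"
        genome = {"c": "".join(seq)}
        read = make_record(strand="-", five=10, aligned="T" * 8)
        cands = find_candidate_acceptors(read, genome, search_radius=3)
        assert [c.position for c in cands] == [10]
        assert has_acceptor_ag(genome, "c", 10, "-")


class TestExpectedReference:
    def test_concatenation(self):
        genome = {"c": "A" * 40}
        leader = SpliceLeader("SL1", "SL1", "ACGT")
        ref = build_expected_reference(leader, genome, CandidateAcceptor("c", 10, "+"))
        assert ref == "ACGT" + "A" * 24

    def test_truncated_at_contig_end(self):
        genome = {"c": "A" * 20}
        leader = SpliceLeader("SL1", "SL1", "ACGT")
        ref = build_expected_reference(leader, genome, CandidateAcceptor("c", 10, "+"))
        assert ref == "ACGT" + "A" * 10

    def test_minus_strand_reverse_complement(self, rng):
        raw = random_dna(rng, 60)
        genome = {"c": raw}
        leader = SpliceLeader("SL1", "SL1", "ACGT")
        ref = build_expected_reference(leader, genome, CandidateAcceptor("c", 40, "-"))
        assert ref == "ACGT" + revcomp(raw[17:41])


class TestReadQueryWindow:
    def test_short_clip_kept_fully(self):
        read = make_record(clip="G" * 10, aligned="A" * 40)
        assert read_query_window(read) == "G" * 10 + "A" * 24

    def test_long_clip_capped_at_28(self):
        read = make_record(clip="G" * 40, aligned="A" * 40)
        q = read_query_window(read)
        assert len(q) == 28 + 24 and q.startswith("G" * 28)

    def test_no_clip(self):
        read = make_record(clip="", aligned="A" * 40)
        assert read_query_window(read) == "A" * 24

    def test_unusable_record_rejected(self):
        read = make_record()
        read.usable = False
        with pytest.raises(ValueError):
            read_query_window(read)


class TestAssignBestSite:
    def _genome_with_site(self, rng, leader_seqs, remnant_of, pos=60):
        genome = random_dna(rng, 200)
        genome = genome[: pos - 2] + "AG" + genome[pos:]
        return {"c": genome}

    def test_single_pair_retained(self, rng):
        sl1 = SpliceLeader("SL1", "SL1", "GGTTTAATTACCCAAGTTTGAG")
        genome = self._genome_with_site(rng, [sl1.sequence], 12)
        exon = genome["c"][60:84]
        read = make_record(five=60, clip=sl1.sequence[-12:], aligned=exon + "A" * 10)
        cand = CandidateAcceptor("c", 60, "+")
        best = assign_read_best_site(read, [cand], [sl1], genome)
        assert best is not None and best.candidate.position == 60
        assert best.jad == 12

    def test_leader_class_resolved_by_remnant(self, rng):
        """A remnant matching only SL1 wins against the SL2 leader."""
        sl1 = SpliceLeader("SL1", "SL1", "GGTTTAATTACCCAAGTTTGAG")
        sl2 = SpliceLeader("SL2", "SL2", "GGTTTTAACCCAGTTACTCAAG")
        genome = self._genome_with_site(rng, None, 14)
        exon = genome["c"][60:84]
        read = make_record(five=60, clip=sl1.sequence[-14:], aligned=exon + "C" * 10)
        best = assign_read_best_site(read, [CandidateAcceptor("c", 60, "+")], [sl1, sl2], genome)
        assert best.leader.sl_class == "SL1"

    def test_all_zero_scores_unassigned(self):
        genome = {"c": "AG" + "A" * 100}
        read = make_record(five=2, clip="", aligned="C" * 30)
        sl = SpliceLeader("SL1", "SL1", "GGGGGGGGGG")
        assert assign_read_best_site(read, [CandidateAcceptor("c", 2, "+")], [sl], genome) is None


class TestThresholdSelection:
    def test_perfect_separation(self, rng):
        """With a pass fraction on a decile boundary, the returned threshold
        lies between the two perfectly separated score groups."""
        scores = np.concatenate([rng.normal(-5, 1, 70), rng.normal(10, 1, 30)])
        flags = np.array([False] * 70 + [True] * 30)
        t = select_pssm_threshold(scores, flags)
        assert scores[~flags].max() < t <= scores[flags].min()

    def test_all_pass_ties_return_lowest_boundary(self, rng):
        scores = rng.normal(0, 1, 100)
        t = select_pssm_threshold(scores, np.ones(100, dtype=bool))
        assert t == pytest.approx(np.quantile(scores, 0.1))

    def test_matches_exhaustive_boundary_oracle(self, rng):
        """100 simulated (score, flag) pairs: equals the brute-force maximiser."""
        for _ in range(20):
            scores = rng.normal(0, 3, 100)
            flags = rng.random(100) < 0.3
            got = select_pssm_threshold(scores, flags)
            best_t, best_c = None, -1.0
            for q in np.arange(1, 10) / 10.0:
                t = np.quantile(scores, q)
                hi = scores >= t
                table = [
                    [np.sum(hi & flags), np.sum(hi & ~flags)],
                    [np.sum(~hi & flags), np.sum(~hi & ~flags)],
                ]
                c = pearson_chi2(table)
                if c > best_c:
                    best_c, best_t = c, t
            assert got == pytest.approx(best_t)


class TestTrimming:
    SL1 = SpliceLeader("SL1", "SL1", "GGTTTAATTACCCAAGTTTGAG")

    def test_full_leader_trimmed(self, rng, leaders):
        insert = random_dna(rng, 40)
        reads = [("r1", self.SL1.sequence + insert)]
        trimmed, records = trim_sl_short_reads(reads, leaders)
        assert trimmed == [("r1", insert)]
        assert records["r1"].sl_class == "SL1"
        assert records["r1"].trimmed_length == 22

    def test_six_nt_suffix_below_min_overlap(self, rng, leaders):
        insert = random_dna(rng, 40)
        reads = [("r1", self.SL1.sequence[-6:] + insert)]
        trimmed, records = trim_sl_short_reads(reads, leaders)
        assert trimmed[0][1] == self.SL1.sequence[-6:] + insert
        assert "r1" not in records

    def test_two_substitutions_exceed_error_rate(self, rng, leaders):
        """2 errors over a 22-nt remnant is a rate of 0.0909 > 0.09: untrimmed."""
        remnant = list(self.SL1.sequence)
        remnant[2] = "C" if remnant[2] != "C" else "A"
        remnant[15] = "C" if remnant[15] != "C" else "A"
        read_seq = "".join(remnant) + random_dna(rng, 40)
        trimmed, records = trim_sl_short_reads([("r1", read_seq)], leaders)
        assert trimmed[0][1] == read_seq and not records

    def test_one_substitution_within_error_rate(self, rng, leaders):
        remnant = list(self.SL1.sequence)
        remnant[2] = "C" if remnant[2] != "C" else "A"
        insert = random_dna(rng, 40)
        trimmed, records = trim_sl_short_reads([("r1", "".join(remnant) + insert)], leaders)
        assert trimmed == [("r1", insert)]

    def test_min_length_discard(self, leaders):
        reads = [("r1", self.SL1.sequence + "ACGTACGTAC")]  # 10 nt remainder
        trimmed, records = trim_sl_short_reads(reads, leaders, min_length=15)
        assert trimmed == [] and records == {}


class TestShortReadSites:
    def test_fp_locus_removed_and_sites_recovered(self, clean_sim, leaders):
        sim = clean_sim
        _, records = trim_sl_short_reads(sim.short_reads, leaders)
        sites = call_short_read_sites(sim.short_read_records(), records, sim.genome)
        found = {s.key for s in sites}
        truth = set(sim.truth.site_keys())
        assert found == truth  # planted sites in, decoy locus out
        lay0 = sim.layouts[0]
        fp_pos = lay0.g0 + lay0.region_len + 20 + 10
        assert ("chrS", fp_pos, "+") not in found

    def test_single_read_positions_dropped(self, clean_sim, leaders):
        sim = clean_sim
        _, records = trim_sl_short_reads(sim.short_reads, leaders)
        sites = call_short_read_sites(
            sim.short_read_records(), records, sim.genome, min_support=2
        )
        for s in sites:
            assert s.n_supporting_reads >= 2


class TestMergeSites:
    def _site(self, pos, sl="SL1", n=3, source="long_read"):
        return TransSpliceSite("c", pos, "+", sl, n, 10, 9, 5.0, source)

    def test_disjoint_union(self):
        merged = merge_site_sets([self._site(p) for p in (1, 2, 3)],
                                 [self._site(p, source="short_read") for p in (10, 11, 12, 13)])
        assert len(merged) == 7

    def test_identical_sets_sum_support(self):
        merged = merge_site_sets([self._site(1, n=3)], [self._site(1, n=5, source="short_read")])
        assert len(merged) == 1
        assert merged[0].n_supporting_reads == 8
        assert merged[0].source == "merged"

    def test_one_shared_site(self):
        a = [self._site(p) for p in (1, 2, 3)]
        b = [self._site(p, source="short_read") for p in (3, 4)]
        assert len(merge_site_sets(a, b)) == len(a) + len(b) - 1

    def test_class_majority_prefers_support(self):
        merged = merge_site_sets([self._site(1, sl="SL1", n=1)],
                                 [self._site(1, sl="SL2", n=4, source="short_read")])
        assert merged[0].sl_class == "SL2"


class TestLongReadEndToEnd:
    def test_clean_simulation_full_recovery(self, clean_sim, leaders):
        """Zero errors, remnants >= 10 nt: every planted site at exact
        coordinates and nothing else."""
        sim = clean_sim
        sites, _ = call_long_read_sites(sim.long_read_records(), sim.genome, leaders)
        assert {s.key for s in sites} == set(sim.truth.site_keys())
        for s in sites:
            assert has_acceptor_ag(sim.genome, s.chrom, s.position, s.strand)
            assert s.n_supporting_reads >= 1 and s.best_jad >= 8

    def test_short_remnants_yield_no_sites(self, leaders):
        """Remnants all below the JAD cutoff leave nothing to retain."""
        from slsplice.simulate import SimConfig, simulate_dataset

        cfg = SimConfig(
            n_genes=4, seed=77, genotypes=("wt",), psi_by_genotype=(0.8,),
            n_replicates=1, reads_per_gene=20, leader_remnant=(3, 6),
            read_5p_truncation_p=1.0,
        )
        sim = simulate_dataset(cfg)
        sites, _ = call_long_read_sites(sim.long_read_records(), sim.genome, leaders)
        assert sites == []

    def test_sl_class_majority(self, clean_sim, leaders):
        sim = clean_sim
        sites, _ = call_long_read_sites(sim.long_read_records(), sim.genome, leaders)
        by_gene = {lay.acceptor_g: lay.leader.sl_class for lay in sim.layouts if lay.sited}
        for s in sites:
            assert s.sl_class == by_gene[s.position]


def test_enumerate_ag_positions_complete():
    genome = {"c": "AAGTCTA"}
    pos = enumerate_ag_positions(genome)
    assert ("c", 3, "+") in pos  # AG at 1..2
    assert ("c", 3, "-") in pos  # CT at 4..5 -> acceptor 3 on minus
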