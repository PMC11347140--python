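"""Synthetic-data generator: determinism, structural invariants, calibration."""

import filecmp
import os

import numpy as np
import pytest
from scipy.stats import binom

from slsplice.seq import has_acceptor_ag
from slsplice.simulate import (
    ConfigurationError,
    SimConfig,
    simulate_dataset,
    simulate_dpsi_table,
    simulate_genome,
    simulate_outron_regions,
    simulate_site_counts,
    write_simulation,
)


class TestConfig:
    def test_fraction_out_of_range(self):
        with pytest.raises(ConfigurationError):
            SimConfig(psi_by_genotype=(1.2, 0.5))

    def test_event_fractions_exceed_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(frac_csro=0.6, frac_alt3tss=0.6)

    def test_chrom_too_small(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=10, chrom_length=100)

    def test_remnant_longer_than_leader(self):
        with pytest.raises(ConfigurationError):
            SimConfig(leader_remnant=(10, 50))


class TestGenome:
    def test_single_gene_acceptor_preceded_by_ag(self):
        sim = simulate_genome(SimConfig(n_genes=1, seed=1))
        assert len(sim.truth.sites) == 1
        s = sim.truth.sites[0]
        assert has_acceptor_ag(sim.genome, s.chrom, s.position, s.strand)

    def test_planted_site_count(self):
        sim = simulate_genome(SimConfig(n_genes=100, seed=3))
        primaries = [s for s in sim.truth.sites if s.kind == "primary"]
        assert len(primaries) == 100
        assert all(
            has_acceptor_ag(sim.genome, s.chrom, s.position, s.strand)
            for s in sim.truth.sites
        )

    def test_fractional_siting(self):
        sim = simulate_genome(SimConfig(n_genes=100, seed=3, fraction_genes_trans_spliced=0.6))
        assert len([s for s in sim.truth.sites if s.kind == "primary"]) == 60

    def test_alt_sites_on_first_exon(self):
        sim = simulate_genome(SimConfig(n_genes=8, seed=4, frac_alt3tss=0.5))
        alts = [s for s in sim.truth.sites if s.kind == "alt"]
        assert len(alts) == 4
        for s in alts:
            gene = sim.annotation.genes[s.gene_id]
            es, ee = gene.first_exon
            assert es <= s.position <= ee
            assert has_acceptor_ag(sim.genome, s.chrom, s.position, s.strand)


class TestDeterminism:
    def test_identical_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_genes=4, seed=9, substitution_error_rate=0.01)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_simulation(simulate_dataset(cfg), str(d1))
        p2 = write_simulation(simulate_dataset(cfg), str(d2))
        assert set(p1) == set(p2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_differs(self):
        a = simulate_genome(SimConfig(n_genes=2, seed=1))
        b = simulate_genome(SimConfig(n_genes=2, seed=2))
        assert a.genome != b.genome


@pytest.fixture(scope="module")
def sim():
    return simulate_dataset(
        SimConfig(n_genes=10, seed=11, n_replicates=2, reads_per_gene=40,
                  frac_csro=0.2, frac_alt3tss=0.2, substitution_error_rate=0.0)
    )


class TestReadStructure:

    def test_labels_consistent_with_structure(self, sim):
        """trans_spliced 5' ends within [-14, +10] of a planted site;
        retained_outron strictly upstream of -14."""
        site_pos = {}
        for lay in sim.layouts:
            if lay.sited:
                site_pos[lay.gene_id] = [
                    s.position for s in sim.truth.sites if s.gene_id == lay.gene_id
                ]
        for reads in sim.long_reads.values():
            for read in reads:
                label = sim.truth.read_labels[read.name]
                if label not in ("trans_spliced", "retained_outron", "cis_spliced_retained_outron"):
                    continue
                rec = read.to_record()
                rels = [
                    rec.five_prime_pos - p if rec.strand == "+" else p - rec.five_prime_pos
                    for p in site_pos[read.gene_id]
                ]
                if label == "trans_spliced":
                    assert any(-14 <= rel <= 10 for rel in rels), (read.name, rels)
                else:
                    assert all(rel < -14 for rel in rels), (read.name, label, rels)

    def test_trans_reads_carry_leader_remnant(self, sim):
        for reads in sim.long_reads.values():
            for read in reads:
                if sim.truth.read_labels[read.name] == "trans_spliced" and read.clip5:
                    lay = next(l for l in sim.layouts if l.gene_id == read.gene_id)
                    assert lay.leader.sequence.endswith(read.clip5)

    def test_cis_reads_splice_into_acceptor(self, sim):
        for reads in sim.long_reads.values():
            for read in reads:
                if sim.truth.read_labels[read.name] != "cis_spliced_retained_outron":
                    continue
                rec = read.to_record()
                lay = next(l for l in sim.layouts if l.gene_id == read.gene_id)
                if rec.strand == "+":
                    assert any(e == lay.acceptor_g for _s, e in rec.junctions)
                else:
                    assert any(s == lay.acceptor_g + 1 for s, _e in rec.junctions)

    def test_zero_noise_remnant_exact(self):
        cfg = SimConfig(n_genes=2, seed=13, genotypes=("wt",), psi_by_genotype=(1.0,),
                        n_replicates=1, reads_per_gene=10, leader_remnant=(22, 22),
                        read_5p_truncation_p=1.0)
        sim = simulate_dataset(cfg)
        for read in sim.all_long_reads():
            lay = next(l for l in sim.layouts if l.gene_id == read.gene_id)
            assert read.clip5 == lay.leader.sequence[-22:]

    def test_proportion_one_no_retained_reads(self):
        cfg = SimConfig(n_genes=3, seed=14, genotypes=("wt",), psi_by_genotype=(1.0,),
                        n_replicates=1, reads_per_gene=30)
        sim = simulate_dataset(cfg)
        labels = set(sim.truth.read_labels.values())
        assert "retained_outron" not in labels

    def test_empirical_fraction_within_binomial_ci(self):
        """Observed trans-spliced fraction sits in the 99% binomial band."""
        cfg = SimConfig(n_genes=1, seed=15, genotypes=("wt",), psi_by_genotype=(0.8,),
                        n_replicates=1, reads_per_gene=1000, read_5p_truncation_p=1.0)
        sim = simulate_dataset(cfg)
        labels = list(sim.truth.read_labels.values())
        n_trans = labels.count("trans_spliced")
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.8)
        assert lo <= n_trans <= hi


class TestShortReads:
    def test_zero_remnant_starts_at_acceptor(self):
        cfg = SimConfig(n_genes=2, seed=21, short_remnant=(0, 0),
                        substitution_error_rate=0.0, plant_false_positive_locus=False)
        sim = simulate_dataset(cfg)
        for (name, seq), aln in zip(sim.short_reads, sim.short_alignments):
            lay = next(l for l in sim.layouts if l.gene_id == aln.gene_id)
            region = sim.genome["chrS"][lay.g0 : lay.g0 + lay.region_len]
            if lay.strand == "-":
                from slsplice.seq import revcomp

                region = revcomp(region)
            assert seq == region[lay.acceptor_t : lay.acceptor_t + len(seq)]

    def test_remnant_prefix_matches_leader_suffix(self):
        cfg = SimConfig(n_genes=2, seed=22, short_remnant=(7, 7),
                        substitution_error_rate=0.0, plant_false_positive_locus=False)
        sim = simulate_dataset(cfg)
        for (name, seq), aln in zip(sim.short_reads, sim.short_alignments):
            lay = next(l for l in sim.layouts if l.gene_id == aln.gene_id)
            assert seq.startswith(lay.leader.sequence[-7:])


class TestDpsiTable:
    def test_exact_shift_no_noise(self):
        df = simulate_dpsi_table(300, shifts={(3, "A"): 0.3}, noise_sd=0.0, seed=1)
        with_a = df[df["window_seq"].str[6] == "A"]
        without = df[df["window_seq"].str[6] != "A"]
        assert np.allclose(with_a["delta_psi"], 0.3)
        assert np.allclose(without["delta_psi"], 0.0)

    def test_empty(self):
        assert simulate_dpsi_table(0).empty

    def test_null_mean_within_clt_bound(self):
        df = simulate_dpsi_table(500, shifts=None, noise_sd=0.1, seed=2)
        assert abs(df["delta_psi"].mean()) <= 3 * 0.1 / np.sqrt(500)


def test_site_counts_shape_and_range():
    df = simulate_site_counts(5, 0.9, 0.5, n_replicates=3, reads_per_replicate=50, seed=0)
    assert len(df) == 5 * 2 * 3
    assert ((df["n_trans_spliced"] + df["n_retained"]) == 50).all()


def test_outron_region_fixture_fraction_exact():
    regions = simulate_outron_regions(50, frac_inframe=0.6, seed=3)
    n_inframe = sum(
        ("ATG" in seq and seq.find("ATG") % 3 == 0) for _n, seq, _c in regions
    )
    assert n_inframe == 30
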