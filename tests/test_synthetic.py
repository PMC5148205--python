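import json
import math

import numpy as np
import pytest

from prophagekit.att_finder import AttSitePair
from prophagekit.excision import excise
from prophagekit.genome_io import gene_sequence, reverse_complement
from prophagekit.quant import count_junction_reads, fit_standard_curve
from prophagekit.synthetic import (FlankEdit, SynthConfig, SynthConfigError,
                                   build_host_with_prophage, read_fasta_seqs,
                                   simulate_colony_screen, simulate_pileup,
                                   simulate_population_reads, simulate_qpcr,
                                   standard_rows_to_points, stream,
                                   write_fasta)


class TestGenomeBuilder:
    def test_same_seed_reproduces_identical_bytes(self):
        cfg = SynthConfig(seed=17)
        a = build_host_with_prophage(cfg)
        b = build_host_with_prophage(cfg)
        assert a[0].seq == b[0].seq
        assert a[1].seq == b[1].seq
        assert a[2].to_json() == b[2].to_json()

    def test_truth_self_consistency(self, planted_locus):
        """Re-deriving truth from the emitted genomes by direct inspection
        matches the record: core copies at the stated coordinates, anchor
        genes differing by exactly the planted edit."""
        lysogen, excised, truth = planted_locus
        ls, le = truth.attL
        rs, re_ = truth.attR
        assert lysogen.seq[ls - 1:le] == truth.core_seq
        assert lysogen.seq[rs - 1:re_] == truth.core_seq
        # the core appears exactly twice in the lysogen, once in the excised
        assert lysogen.seq.count(truth.core_seq) == 2
        assert excised.seq.count(truth.core_seq) == 1
        ref = gene_sequence(lysogen, lysogen.feature("anchor_tmRNA"))
        var = gene_sequence(excised, excised.feature("anchor_tmRNA"))
        v = truth.planted_variant
        assert v.kind == "deletion"
        assert ref[:v.position - 1] + ref[v.position:] == var
        assert ref[v.position - 1] == v.ref == "T"

    def test_excision_of_lysogen_reproduces_excised_genome(self, planted_locus):
        lysogen, excised, truth = planted_locus
        att = AttSitePair(attL=truth.attL, attR=truth.attR,
                          core_len=len(truth.core_seq),
                          core_seq=truth.core_seq)
        products = excise(lysogen, att)
        assert products.chromosome_after == excised.seq

    def test_junction_windows_recorded_in_truth(self, planted_locus):
        lysogen, excised, truth = planted_locus
        assert truth.attB_junction in excised.seq
        assert truth.attL_junction in lysogen.seq
        assert truth.attB_junction != truth.attL_junction
        assert truth.core_seq in truth.attP_junction

    def test_flank_edit_substitution(self):
        cfg = SynthConfig(seed=9, flank_edit=FlankEdit("substitution", 1, "G"))
        lysogen, excised, truth = build_host_with_prophage(cfg)
        v = truth.planted_variant
        assert v.kind == "substitution" and v.alt == "G" and v.ref != "G"
        ref = gene_sequence(lysogen, lysogen.feature("anchor_tmRNA"))
        var = gene_sequence(excised, excised.feature("anchor_tmRNA"))
        assert len(ref) == len(var)
        diffs = [i for i, (a, b) in enumerate(zip(ref, var)) if a != b]
        assert diffs == [v.position - 1]

    def test_no_flank_edit_gives_identical_gene(self):
        cfg = SynthConfig(seed=9, flank_edit=None)
        lysogen, excised, truth = build_host_with_prophage(cfg)
        assert truth.planted_variant is None
        ref = gene_sequence(lysogen, lysogen.feature("anchor_tmRNA"))
        var = gene_sequence(excised, excised.feature("anchor_tmRNA"))
        assert ref == var

    def test_config_validation(self):
        with pytest.raises(SynthConfigError):
            SynthConfig(seed=1, core_len=6000, prophage_len=5000)
        with pytest.raises(SynthConfigError):
            SynthConfig(seed=1, excision_fraction=1.5)
        with pytest.raises(SynthConfigError):
            SynthConfig(seed=1, qpcr_efficiency=2.5)
        with pytest.raises(SynthConfigError):
            SynthConfig(seed=1, flank_edit=FlankEdit("deletion", 14))

    def test_published_scale_geometry(self):
        cfg = SynthConfig(seed=2, genome_len=100_000, prophage_len=36_000,
                          n_phage_genes=30)
        lysogen, _, truth = build_host_with_prophage(cfg)
        assert truth.span == 36_000
        n_cds = sum(1 for f in lysogen.features
                    if f.kind == "CDS"
                    and truth.attL[1] < f.start and f.end < truth.attR[0])
        assert n_cds == 30


class TestReads:
    def test_extreme_fractions_give_one_sided_junctions(self, default_cfg,
                                                        planted_locus):
        lysogen, excised, truth = planted_locus
        import dataclasses
        for p, expect_zero in ((0.0, "n_attB"), (1.0, "n_attL")):
            cfg = dataclasses.replace(default_cfg, excision_fraction=p,
                                      base_error=0.0, n_reads=3000)
            reads, _ = simulate_population_reads(cfg, lysogen, excised)
            counts = count_junction_reads(reads, truth.attB_junction,
                                          truth.attL_junction,
                                          core=truth.core_seq)
            assert getattr(counts, expect_zero) == 0

    def test_reads_deterministic_and_error_rate_sane(self, default_cfg,
                                                     planted_locus):
        lysogen, excised, _ = planted_locus
        r1, _ = simulate_population_reads(default_cfg, lysogen, excised)
        r2, _ = simulate_population_reads(default_cfg, lysogen, excised)
        assert r1 == r2
        assert all(len(r) == default_cfg.read_len for r in r1)

    def test_read_base_composition_matches_genome(self, default_cfg,
                                                  planted_locus):
        """GC content of simulated reads within 3 sigma of the source."""
        lysogen, excised, _ = planted_locus
        reads, _ = simulate_population_reads(default_cfg, lysogen, excised)
        gc_genome = (lysogen.seq.count("G") + lysogen.seq.count("C")) \
            / len(lysogen.seq)
        n_bases = sum(len(r) for r in reads)
        gc_reads = sum(r.count("G") + r.count("C") for r in reads) / n_bases
        sigma = math.sqrt(gc_genome * (1 - gc_genome) / n_bases)
        # reads are not independent draws, allow a generous envelope
        assert abs(gc_reads - gc_genome) < 30 * sigma

    def test_estimator_recovery_at_three_percent(self, planted_locus):
        lysogen, excised, truth = planted_locus
        cfg = SynthConfig(seed=8, excision_fraction=0.03, n_reads=100_000)
        reads, _ = simulate_population_reads(cfg, lysogen, excised)
        counts = count_junction_reads(reads, truth.attB_junction,
                                      truth.attL_junction,
                                      core=truth.core_seq)
        lo, hi = counts.ci
        assert lo <= 0.03 <= hi

    def test_fasta_round_trip(self, tmp_path):
        reads = ["ACGTACGT", "GGGGCCCC"]
        path = tmp_path / "r.fasta"
        write_fasta(reads, path)
        assert read_fasta_seqs(path) == reads

    def test_read_len_validation(self, planted_locus):
        lysogen, excised, _ = planted_locus
        cfg = SynthConfig(seed=1, read_len=60_000)
        with pytest.raises(SynthConfigError):
            simulate_population_reads(cfg, lysogen, excised)


class TestQpcr:
    def test_noiseless_wells_invert_exactly(self):
        cfg = SynthConfig(seed=4, qpcr_noise_sd=0.0, excision_fraction=0.0014)
        standard, wells, _ = simulate_qpcr(cfg)
        curve = fit_standard_curve(standard_rows_to_points(standard))
        assert abs(curve.slope + math.log2(10)) < 1e-9
        assert curve.r2 == pytest.approx(1.0)
        from prophagekit.quant import frequencies_from_wells
        out = frequencies_from_wells(wells, curve)
        assert out.loc[0, "frequency"] == pytest.approx(0.0014, rel=1e-9)

    def test_fraction_zero_in_standard_series_rejected(self):
        cfg = SynthConfig(seed=4, standard_fractions=(0.1, 0.01, 0.0))
        with pytest.raises(SynthConfigError):
            simulate_qpcr(cfg)

    def test_deterministic(self):
        cfg = SynthConfig(seed=23)
        assert simulate_qpcr(cfg)[0] == simulate_qpcr(cfg)[0]


class TestPileup:
    def test_no_mutations_zero_error_is_pure_reference(self, planted_locus):
        lysogen, _, _ = planted_locus
        cfg = SynthConfig(seed=3, base_error=0.0, mutations=())
        sites, _ = simulate_pileup(cfg, lysogen, n_background_sites=100)
        for s in sites:
            assert s.counts[s.ref] == s.depth

    def test_planted_frequency_recovered(self, planted_locus):
        lysogen, _, _ = planted_locus
        pos = 25_000
        ref = lysogen.seq[pos - 1]
        alt = "A" if ref != "A" else "C"
        cfg = SynthConfig(seed=3, mean_depth=1000,
                          mutations=((pos, ref, alt, 0.24),))
        sites, truth = simulate_pileup(cfg, lysogen, n_background_sites=10)
        site = next(s for s in sites if s.pos == pos)
        assert abs(site.counts[alt] / site.depth - 0.24) < 0.05
        assert truth.mutation_frequencies == ((pos, ref, alt, 0.24),)

    def test_overlapping_mutations_rejected(self, planted_locus):
        lysogen, _, _ = planted_locus
        ref = lysogen.seq[99]
        cfg = SynthConfig(seed=3, mutations=((100, ref, "A", 0.1),
                                             (100, ref, "C", 0.1)))
        with pytest.raises(SynthConfigError):
            simulate_pileup(cfg, lysogen)

    def test_wrong_reference_base_rejected(self, planted_locus):
        lysogen, _, _ = planted_locus
        ref = lysogen.seq[99]
        wrong = "A" if ref != "A" else "C"
        cfg = SynthConfig(seed=3, mutations=((100, wrong, "G", 0.1),))
        with pytest.raises(SynthConfigError):
            simulate_pileup(cfg, lysogen)


class TestColonyScreen:
    def test_degenerate_probabilities(self):
        assert simulate_colony_screen(200, 0.0, seed=1) == 0
        assert simulate_colony_screen(200, 1.0, seed=1) == 200

    def test_mean_positive_count_matches_binomial_expectation(self):
        """Binomial(200, 0.01): mean positives over 1e5 replicates = 2.00."""
        draws = simulate_colony_screen(200, 0.01, seed=5, replicates=100_000)
        assert abs(float(np.mean(draws)) - 2.0) < 0.05

    def test_validation(self):
        with pytest.raises(SynthConfigError):
            simulate_colony_screen(0, 0.5, seed=1)


def test_streams_are_label_independent():
    """Draws from one labelled stream do not perturb another."""
    a1 = stream(5, "alpha").integers(0, 100, size=10)
    _ = stream(5, "beta").integers(0, 100, size=1000)
    a2 = stream(5, "alpha").integers(0, 100, size=10)
    assert list(a1) == list(a2)
    assert list(stream(5, "alpha").integers(0, 100, 10)) != \
        list(stream(6, "alpha").integers(0, 100, 10))
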