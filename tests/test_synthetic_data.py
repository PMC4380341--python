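"""The ground-truthed simulator: neutral model, sweeps, gene modes, formats."""

from __future__ import annotations

import io

import numpy as np
import pytest

from poolsweep.errors import ConfigError
from poolsweep.io_formats import ParseStats, ReferenceGenome, read_gtf, read_pileup
from poolsweep.site_stats import matrices_from_pileup
from poolsweep.coding_selection import classify_codon_change
from poolsweep.synthetic_data import (
    SimConfig,
    build_reference,
    generate,
    harmonic,
    implant_gene_variants,
    implant_sweep,
    make_gene_models,
    render_pileup,
    sample_site_frequencies,
    simulate_site_counts,
)


class TestSiteFrequencies:
    def test_zero_theta_yields_no_polymorphism(self, rng):
        assert sample_site_frequencies(10_000, 0.0, 100, rng) == {}

    def test_watterson_expected_site_count(self, rng):
        length, theta, pool = 1_000_000, 1e-3, 100
        freqs = sample_site_frequencies(length, theta, pool, rng)
        expected = length * theta * harmonic(pool)  # ~5177
        assert abs(len(freqs) - expected) < 3 * np.sqrt(expected)

    def test_frequency_support_is_open_interval(self, rng):
        freqs = sample_site_frequencies(200_000, 2e-3, 100, rng)
        arr = np.array([v.freq for v in freqs.values()])
        assert np.all((arr > 0) & (arr < 1))
        assert {v.alt_pick for v in freqs.values()} <= {0, 1, 2}
        assert all(1 <= p <= 200_000 for p in freqs)

    def test_rare_alleles_dominate_the_spectrum(self, rng):
        # folded neutral spectrum: the rarest classes carry the most sites
        freqs = sample_site_frequencies(2_000_000, 2e-3, 100, rng)
        minor = np.minimum([v.freq for v in freqs.values()],
                           [1 - v.freq for v in freqs.values()])
        assert (minor <= 0.05).mean() > (minor >= 0.45).mean()


class TestImplantSweep:
    def test_factor_one_is_identity(self, rng):
        freqs = sample_site_frequencies(50_000, 2e-3, 100, rng)
        assert implant_sweep(freqs, (0, 50_000), 1.0, rng) == freqs

    def test_huge_factor_fixes_region(self, rng):
        freqs = sample_site_frequencies(50_000, 2e-3, 100, rng)
        out = implant_sweep(freqs, (0, 50_000), 1e6, rng)
        assert all(v.freq == 1.0 for v in out.values())  # only fixed-alt survivors

    def test_binomial_thinning_rate(self, rng):
        freqs = sample_site_frequencies(500_000, 2e-3, 100, rng)
        out = implant_sweep(freqs, (0, 500_000), 100.0, rng)
        survivors = sum(1 for v in out.values() if v.freq < 1.0)
        expected = len(freqs) / 100
        assert abs(survivors - expected) < 3 * np.sqrt(expected)

    def test_outside_region_untouched(self, rng):
        freqs = sample_site_frequencies(100_000, 2e-3, 100, rng)
        out = implant_sweep(freqs, (0, 50_000), 1e9, rng)
        left = {p: v for p, v in freqs.items() if p > 50_000}
        assert {p: v for p, v in out.items() if p > 50_000} == left


class TestSimulatedCounts:
    CFG = SimConfig(seed=0, chrom_lengths={"c": 2_000}, gene_count=0,
                    selected_genes=[], sweeps=[], gene_chrom="c", error_rate=0.0)

    def test_no_polymorphism_no_error_is_reference_monomorphic(self, rng):
        ref = build_reference({"c": 2_000}, rng)["c"]
        mat = simulate_site_counts({}, ref, "c", self.CFG, rng)
        assert not mat.polymorphic_mask().any()
        codes = mat.ref_codes
        np.testing.assert_array_equal(
            mat.counts.sum(axis=1), mat.counts[np.arange(len(mat)), codes]
        )

    def test_binomial_read_sampling_at_half_frequency(self, rng):
        from poolsweep.synthetic_data import SiteVariant

        length = 20_000
        ref = build_reference({"c": length}, rng)["c"]
        freqs = {p: SiteVariant(0.5, 0) for p in range(1, length + 1)}
        mat = simulate_site_counts(freqs, ref, "c", self.CFG, rng)
        cov = mat.coverage
        alt = cov - mat.counts[np.arange(len(mat)), mat.ref_codes]
        frac = alt.sum() / cov.sum()
        se = 0.5 / np.sqrt(cov.sum())
        assert abs(frac - 0.5) < 3 * se

    def test_pileup_round_trip_reproduces_counts_exactly(self, rng):
        cfg = SimConfig(seed=0, chrom_lengths={"c": 3_000}, gene_count=0,
                        selected_genes=[], sweeps=[], gene_chrom="c", error_rate=0.0)
        ref = build_reference({"c": 3_000}, rng)["c"]
        freqs = sample_site_frequencies(3_000, 5e-3, 100, rng)
        mat = simulate_site_counts(freqs, ref, "c", cfg, rng)
        text = "\n".join(render_pileup(mat, ref, cfg, rng)) + "\n"
        stats = ParseStats()
        back = matrices_from_pileup(
            read_pileup(io.StringIO(text), min_base_quality=0, stats=stats)
        )["c"]
        assert stats.n_malformed == 0
        kept = mat.coverage > 0  # zero-coverage columns are omitted from pileup
        np.testing.assert_array_equal(back.positions, mat.positions[kept])
        np.testing.assert_array_equal(back.counts, mat.counts[kept])


class TestGeneModels:
    def test_zero_genes_empty_gtf(self, rng):
        cfg = SimConfig(chrom_lengths={"2L": 50_000, "2R": 50_000}, gene_count=0,
                        selected_genes=[], sweeps=[])
        ref = ReferenceGenome(build_reference(cfg.chrom_lengths, rng))
        gtf, genes = make_gene_models(cfg, ref)
        assert gtf == "" and genes == []

    def test_alternating_strands_and_codon_length(self, rng):
        cfg = SimConfig(chrom_lengths={"2L": 100_000, "2R": 100_000},
                        selected_genes=[], sweeps=[], gene_count=6)
        ref = ReferenceGenome(build_reference(cfg.chrom_lengths, rng))
        _, genes = make_gene_models(cfg, ref)
        assert [g.strand for g in genes] == ["+", "-", "+", "-", "+", "-"]
        assert all(g.cds_length == cfg.gene_length for g in genes)
        spans = [g.span for g in genes]
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))  # non-overlapping

    def test_gtf_text_round_trips_through_reader(self, rng):
        cfg = SimConfig(chrom_lengths={"2L": 100_000, "2R": 100_000},
                        selected_genes=[], sweeps=[], gene_count=4)
        ref = ReferenceGenome(build_reference(cfg.chrom_lengths, rng))
        gtf, genes = make_gene_models(cfg, ref)
        parsed = read_gtf(io.StringIO(gtf))
        assert parsed == genes

    def test_overfull_chromosome_rejected(self, rng):
        cfg = SimConfig(chrom_lengths={"2L": 50_000, "2R": 50_000},
                        selected_genes=[], sweeps=[], gene_count=50)
        ref = ReferenceGenome(build_reference(cfg.chrom_lengths, rng))
        with pytest.raises(ConfigError, match="cannot fit"):
            make_gene_models(cfg, ref)


class TestGeneVariantModes:
    @pytest.fixture()
    def setup(self, rng):
        cfg = SimConfig(chrom_lengths={"2L": 100_000, "2R": 100_000},
                        selected_genes=[], sweeps=[], gene_count=2)
        ref = ReferenceGenome(build_reference(cfg.chrom_lengths, rng))
        _, genes = make_gene_models(cfg, ref)
        return ref, genes

    def kinds(self, freqs, gene, ref):
        out = []
        for pos in gene.cds_positions():
            if pos in freqs:
                alt_pick = freqs[pos].alt_pick
                ref_code = "ACGT".index(ref.base(gene.chrom, pos))
                alt = "ACGT"[alt_pick + (alt_pick >= ref_code)]
                out.append(classify_codon_change(gene, ref, pos, alt).kind)
        return out

    @pytest.mark.parametrize("strand_idx", [0, 1])
    def test_syn_only_mode_implants_only_silent_variants(self, setup, rng, strand_idx):
        ref, genes = setup
        gene = genes[strand_idx]
        freqs = implant_gene_variants({}, gene, ref, "syn_only", rng)
        kinds = self.kinds(freqs, gene, ref)
        assert len(kinds) == 3
        assert set(kinds) == {"synonymous"}

    @pytest.mark.parametrize("strand_idx", [0, 1])
    def test_nonsyn_excess_mode_overweights_amino_changes(self, setup, rng, strand_idx):
        ref, genes = setup
        gene = genes[strand_idx]
        freqs = implant_gene_variants({}, gene, ref, "nonsyn_excess", rng)
        kinds = self.kinds(freqs, gene, ref)
        assert kinds.count("synonymous") == 3
        assert kinds.count("nonsynonymous") >= 2 * (kinds.count("synonymous"))

    def test_neutral_mode_leaves_background(self, setup, rng):
        ref, genes = setup
        background = {genes[0].cds_positions()[0]: None}
        assert implant_gene_variants(background, genes[0], ref, "neutral", rng) == background


class TestGenerate:
    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SimConfig(seed=42, chrom_lengths={"2L": 40_000, "2R": 40_000},
                        sweeps=[("2L", 10_000, 30_000, 50.0)], gene_count=2,
                        selected_genes=[("g001", "nonsyn_excess")])
        a, b = generate(cfg), generate(cfg)
        assert a.ref.sequences == b.ref.sequences
        assert a.gtf_text == b.gtf_text
        assert a.truth.frequencies == b.truth.frequencies
        for chrom in cfg.chrom_lengths:
            np.testing.assert_array_equal(a.selected[chrom].counts, b.selected[chrom].counts)
            np.testing.assert_array_equal(a.control[chrom].counts, b.control[chrom].counts)

    def test_truth_heterozygosity_calibrates_to_theta(self, default_sim):
        # realized pool heterozygosity on the neutral arm matches theta
        cfg = default_sim.config
        n = cfg.pool_size
        freqs = default_sim.truth.frequencies["control"]["2R"]
        p = np.array([v.freq for v in freqs.values()])
        het = (n / (n - 1)) * 2 * p * (1 - p)
        length = cfg.chrom_lengths["2R"]
        mean_het = het.sum() / length
        se = np.sqrt(np.sum((het / length) ** 2))  # independent-site MC error
        assert abs(mean_het - cfg.theta) < 3 * se

    def test_written_files_parse_cleanly(self, small_sim):
        paths = small_sim.paths
        ref = ReferenceGenome.from_fasta(paths["ref"])
        assert set(ref.sequences) == set(small_sim.config.chrom_lengths)
        genes = read_gtf(str(paths["gtf"]))
        assert [g.gene_id for g in genes] == [g.gene_id for g in small_sim.genes]
        stats = ParseStats()
        with open(paths["selected"]) as fh:
            mats = matrices_from_pileup(read_pileup(fh, min_base_quality=0, stats=stats))
        assert stats.n_malformed == 0
        np.testing.assert_array_equal(
            mats["2L"].counts, small_sim.selected["2L"].counts[small_sim.selected["2L"].coverage > 0]
        )

    def test_truth_records_every_gene_once(self, small_sim):
        modes = small_sim.truth.gene_modes
        assert sorted(modes) == sorted(g.gene_id for g in small_sim.genes)
        assert set(modes.values()) <= {"neutral", "nonsyn_excess", "syn_only"}

    def test_sweep_region_diversity_reduced_in_selected_pool_only(self, small_sim):
        from poolsweep.site_stats import SnpCallConfig

        cfg = SnpCallConfig(2, 2, 75, 25)
        chrom, s0, e0, _ = small_sim.truth.sweeps[0]
        sel = small_sim.selected[chrom].slice_span(s0, e0)
        con = small_sim.control[chrom].slice_span(s0, e0)
        sel_pi = (sel.pi_values() * sel.snp_mask(cfg)).sum()
        con_pi = (con.pi_values() * con.snp_mask(cfg)).sum()
        assert sel_pi < 0.05 * con_pi
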