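"""Synthetic-data generator: determinism, conservation, and planted structure."""
import numpy as np
import pandas as pd
import pytest

from nascentmetrics import simulate, tags
from nascentmetrics.metrics import GRO_BODY_WINDOW, elongation_efficiency
from nascentmetrics.promoter import promoter_gc, scan_tata
from nascentmetrics.simulate import SimConfig


def small_config(**overrides):
    base = dict(n_genes=10, genome_length=150_000, gene_length_range=(3000, 4000),
                library_sizes={"chip": 5000, "gro": 5000, "rna": 5000, "cage": 1000},
                seed=3)
    base.update(overrides)
    return SimConfig(**base)


# -- annotation ----------------------------------------------------------------

def test_seeded_determinism_is_byte_identical(tmp_path):
    outputs = []
    for _ in range(2):
        cfg = small_config(n_genes=2, genome_length=50_000, seed=1)
        genes, truth = simulate.build_annotation(cfg)
        genome = simulate.synthesize_genome_sequence(genes, truth, cfg)
        libs = [
            simulate.simulate_chip_library(genes, truth, "polII_paused", "basal", cfg),
            simulate.simulate_gro_library(genes, truth, "basal", cfg),
            simulate.simulate_rna_library(genes, truth, "basal", cfg),
            simulate.simulate_cage_library(genes, truth, cfg),
        ]
        expr = simulate.simulate_expression_table(truth, cfg)
        outputs.append((genes, truth, genome, libs, expr))
    (g1, t1, s1, l1, e1), (g2, t2, s2, l2, e2) = outputs
    assert g1 == g2
    pd.testing.assert_frame_equal(t1, t2)
    assert s1 == s2
    for a, b in zip(l1, l2):
        pd.testing.assert_frame_equal(a.tags, b.tags)
    pd.testing.assert_frame_equal(e1, e2)


def test_degenerate_class_fractions_all_ie():
    cfg = small_config(class_fractions={"IE": 1.0, "late": 0.0, "other": 0.0})
    _, truth = simulate.build_annotation(cfg)
    assert (truth["kinetic_class"] == "IE").all()


def test_fifty_genes_pairwise_non_overlapping():
    cfg = small_config(n_genes=50, genome_length=5_000_000,
                       gene_length_range=(4000, 8000))
    genes, truth = simulate.build_annotation(cfg)
    assert len(genes) == 50 and len(truth) == 50
    spans = sorted((g.tx_start, g.tx_end) for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):   # brute-force sweep
        assert e1 <= s2


def test_placement_failure_raises_named_error():
    with pytest.raises(ValueError, match="genome"):
        simulate.build_annotation(small_config(n_genes=100, genome_length=100_000))


# -- genome sequence -----------------------------------------------------------

def test_promoter_gc_composition_and_degenerate_case():
    cfg = small_config(n_genes=20, genome_length=300_000, seed=5)
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth.loc[truth.index[0], "promoter_gc"] = 1.0
    truth.loc[truth.index[0], "has_tata"] = False
    genome = simulate.synthesize_genome_sequence(genes, truth, cfg)
    rec0 = promoter_gc(genome, genes[0])
    assert rec0.gc == 1.0                     # degenerate composition
    for g, (_, row) in zip(genes[1:], truth.iloc[1:].iterrows()):
        rec = promoter_gc(genome, g)
        assert abs(rec.gc - row["promoter_gc"]) <= 0.03


def test_mean_realized_gc_near_target():
    cfg = small_config(n_genes=100, genome_length=1_500_000,
                       gene_length_range=(3000, 3000),
                       class_fractions={"IE": 1.0, "late": 0.0, "other": 0.0},
                       gc_level_map={"IE": 0.63, "late": 0.5, "other": 0.5},
                       gc_sd=0.0)
    genes, truth = simulate.build_annotation(cfg)
    genome = simulate.synthesize_genome_sequence(genes, truth, cfg)
    mean_gc = np.mean([promoter_gc(genome, g).gc for g in genes])
    assert 0.60 <= mean_gc <= 0.66


def test_planted_tata_round_trip():
    cfg = small_config(n_genes=30, genome_length=400_000,
                       tata_fraction_map={"IE": 0.5, "late": 0.5, "other": 0.5})
    genes, truth = simulate.build_annotation(cfg)
    genome = simulate.synthesize_genome_sequence(genes, truth, cfg)
    for g, has in zip(genes, truth["has_tata"]):
        assert scan_tata(genome, g).hit == bool(has)


# -- ChIP ----------------------------------------------------------------------

def test_chip_count_conservation_and_unknown_mark():
    cfg = small_config()
    genes, truth = simulate.build_annotation(cfg)
    lib = simulate.simulate_chip_library(genes, truth, "histone_bimodal", "basal", cfg)
    assert lib.total_mapped == cfg.library_sizes["chip"]
    with pytest.raises(ValueError, match="mark_spec"):
        simulate.simulate_chip_library(genes, truth, "h3k27", "basal", cfg)
    with pytest.raises(ValueError, match="condition"):
        simulate.simulate_chip_library(genes, truth, "tf_point", "KLA_24h", cfg)


# -- GRO -----------------------------------------------------------------------

def test_gro_zero_elongation_means_empty_body_window():
    cfg = small_config(background_fraction=0.0)
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["ee_basal"] = 0.0
    lib = simulate.simulate_gro_library(genes, truth, "basal", cfg)
    for g in genes:
        lo, hi = g.window_to_genomic(*GRO_BODY_WINDOW)
        assert lib.count_in(g.chrom, lo, hi, strand=g.strand) == 0
    assert lib.total_mapped == cfg.library_sizes["gro"]


def test_gro_no_antisense_when_disabled():
    cfg = small_config(background_fraction=0.0, gro_antisense_fraction=0.0)
    genes, truth = simulate.build_annotation(cfg)
    lib = simulate.simulate_gro_library(genes, truth, "basal", cfg)
    for g in genes:
        anti = "-" if g.strand == "+" else "+"
        assert lib.count_in(g.chrom, g.tx_start - 2000, g.tx_end + 2000, strand=anti) == 0


def test_gro_single_gene_unit_efficiency_recovered():
    cfg = small_config(n_genes=1, genome_length=20_000, background_fraction=0.0,
                       gro_antisense_fraction=0.0, library_sizes={"gro": 10_000})
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["ee_basal"] = 1.0
    lib = simulate.simulate_gro_library(genes, truth, "basal", cfg)
    rec = elongation_efficiency(lib, genes[0])
    assert 0.9 <= rec.efficiency <= 1.1


def test_gro_short_gene_error_names_gene():
    cfg = small_config(gene_length_range=(2000, 2400))
    genes, truth = simulate.build_annotation(cfg)
    with pytest.raises(ValueError, match="g0000"):
        simulate.simulate_gro_library(genes, truth, "basal", cfg)


# -- RNA -----------------------------------------------------------------------

def test_rna_pure_mature_mixture_avoids_introns():
    cfg = small_config()
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["true_splicing_efficiency"] = 1.0
    lib = simulate.simulate_rna_library(genes, truth, "basal", cfg)
    assert lib.total_mapped == cfg.library_sizes["rna"]
    for g in genes:
        for s, e in g.introns:
            assert lib.count_in(g.chrom, s, e, strand=g.strand) == 0
            assert lib.count_in(g.chrom, s, e, strand=g.strand, column="pos3") == 0


def test_rna_pure_unspliced_has_no_junction_reads():
    cfg = small_config()
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["true_splicing_efficiency"] = 0.0
    lib = simulate.simulate_rna_library(genes, truth, "basal", cfg)
    assert not lib.tags["spliced"].any()


# -- CAGE ----------------------------------------------------------------------

def test_cage_degenerate_cluster_and_round_trip():
    from nascentmetrics.promoter import refine_tss_from_cage
    cfg = small_config(cage_dispersion=0.0, cage_noise_fraction=0.0)
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["true_tss_offset"] = -80
    lib = simulate.simulate_cage_library(genes, truth, cfg)
    assert lib.total_mapped == cfg.library_sizes["cage"]
    for g in genes:
        expected = g.tss - 80 if g.strand == "+" else g.tss + 80
        positions = np.unique(lib.positions(g.chrom, g.strand))
        assert expected in positions
        assert refine_tss_from_cage(lib, g).refined_tss == expected


def test_cage_offset_precondition():
    cfg = small_config()
    genes, truth = simulate.build_annotation(cfg)
    truth = truth.copy()
    truth["true_tss_offset"] = 990
    with pytest.raises(ValueError, match="offsets exceed"):
        simulate.simulate_cage_library(genes, truth, cfg)


# -- expression -----------------------------------------------------------------

def test_expression_labels_survive_configured_noise():
    cfg = small_config(n_genes=200, genome_length=2_000_000,
                       expression_noise_sd=0.05)
    genes, truth = simulate.build_annotation(cfg)
    table = simulate.simulate_expression_table(truth, cfg)
    assert (table["kinetic_class"].to_numpy()
            == truth["kinetic_class"].to_numpy()).all()


def test_expression_noise_too_large_rejected():
    cfg = small_config(expression_noise_sd=0.2)
    genes, truth = simulate.build_annotation(cfg)
    with pytest.raises(ValueError, match="noise"):
        simulate.simulate_expression_table(truth, cfg)


def test_config_invariants_validated():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(class_fractions={"IE": 0.5, "late": 0.2, "other": 0.2}).validate()
    with pytest.raises(ValueError, match="read lengths"):
        SimConfig(read_length_rna=0).validate()
    with pytest.raises(ValueError, match="splicing"):
        SimConfig(splicing_efficiency_range=(0.5, 1.2)).validate()
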