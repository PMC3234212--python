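"""Elongation efficiency, splicing estimators, and enrichment calls."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_library
from nascentmetrics import metrics, simulate
from nascentmetrics.genes import GeneModel
from nascentmetrics.simulate import SimConfig
from nascentmetrics.tags import TagLibrary


@pytest.fixture
def long_gene():
    return GeneModel("g", "chr1", "+", 50_000, 60_000, ((50_000, 60_000),))


# -- elongation efficiency ----------------------------------------------------

def test_elongation_ratio_by_definition(long_gene):
    tss = long_gene.tss
    rows = [("chr1", tss + (i % 200) - 25, "+") for i in range(100)]       # promoter
    rows += [("chr1", tss + 500 + (i % 2000), "+") for i in range(400)]    # body
    lib = make_library(rows)
    rec = metrics.elongation_efficiency(lib, long_gene, target=lib.total_mapped)
    assert rec.promoter_density == pytest.approx(0.5)
    assert rec.body_density == pytest.approx(0.2)
    assert rec.efficiency == pytest.approx(0.4)
    assert rec.evaluable


def test_elongation_zero_body_and_empty_promoter(long_gene):
    promoter_only = make_library([("chr1", long_gene.tss + 10, "+")] * 5)
    rec = metrics.elongation_efficiency(promoter_only, long_gene)
    assert rec.efficiency == 0.0 and rec.evaluable
    body_only = make_library([("chr1", long_gene.tss + 600, "+")] * 5)
    rec = metrics.elongation_efficiency(body_only, long_gene)
    assert not rec.evaluable and math.isnan(rec.efficiency)


def test_elongation_short_gene_not_evaluable():
    g = GeneModel("short", "chr1", "+", 1000, 3000, ((1000, 3000),))
    lib = make_library([("chr1", 1010, "+")] * 10)
    assert not metrics.elongation_efficiency(lib, g).evaluable


def test_elongation_requires_stranded(long_gene):
    lib = make_library([("chr1", 1, "+")], stranded=False)
    with pytest.raises(ValueError, match="stranded"):
        metrics.elongation_efficiency(lib, long_gene)


def test_elongation_depth_rescaling_invariance(long_gene):
    rows = [("chr1", long_gene.tss + 30, "+")] * 7 + \
           [("chr1", long_gene.tss + 900, "+")] * 13
    single = make_library(rows)
    double = make_library(rows * 2)
    r1 = metrics.elongation_efficiency(single, long_gene)
    r2 = metrics.elongation_efficiency(double, long_gene)
    assert r1.efficiency == pytest.approx(r2.efficiency)


# -- splicing: density route ---------------------------------------------------

def test_splicing_density_ratio(plus_gene):
    # plus_gene: 6 kb exon, 4 kb intron; 120 exon tags (20/kb), 8 intron (2/kb)
    rows = [("chr1", 10_000 + i, "+") for i in range(120)]
    rows += [("chr1", 12_100 + i, "+") for i in range(8)]
    lib = make_library(rows)
    rec = metrics.splicing_efficiency_density(lib, plus_gene, target=lib.total_mapped)
    assert rec.evaluable_density
    assert rec.efficiency_density == pytest.approx(1 - 2.0 / 20.0)


def test_splicing_density_filter_is_strict(plus_gene):
    # zero intron tags: exon density fine, but the >1 read/kb floor fails
    lib = make_library([("chr1", 10_000 + i, "+") for i in range(120)])
    rec = metrics.splicing_efficiency_density(lib, plus_gene)
    assert not rec.evaluable_density and math.isnan(rec.efficiency_density)


def test_splicing_density_single_exon_inevaluable():
    g = GeneModel("g", "chr1", "+", 0, 2000, ((0, 2000),))
    lib = make_library([("chr1", 10, "+")] * 10)
    assert not metrics.splicing_efficiency_density(lib, g).evaluable_density


# -- splicing: junction route ----------------------------------------------------

def _rna_lib(rows):
    """rows: (pos5, pos3, strand, spliced)."""
    df = pd.DataFrame(rows, columns=["pos", "pos3", "strand", "spliced"])
    df.insert(0, "chrom", "chr1")
    return TagLibrary(df, read_length=32, stranded=True)


def test_junction_ratio_hand_example(plus_gene):
    # first 5' junction of plus_gene at 12000 (first intronic base)
    rows = [(11_800, 12_000 + 7 + (i % 19), "+", False) for i in range(2)]   # spanning
    rows += [(11_900, 12_000 - 25 + (i % 19), "+", True) for i in range(20)]  # exonic
    lib = _rna_lib(rows)
    recs, aggregate = metrics.splicing_efficiency_junction(lib, [plus_gene])
    assert recs[0].evaluable_junction
    # per-gene averages over both junctions; only the first has counts, so use
    # the pooled aggregate for the ratio check: 1 - (2/19)/(20/19)
    assert aggregate == pytest.approx(0.9)


def test_junction_zero_spanning_gives_unity(plus_gene):
    rows = [(11_900, 12_000 - 10, "+", True) for _ in range(10)]
    lib = _rna_lib(rows)
    recs, aggregate = metrics.splicing_efficiency_junction(lib, [plus_gene])
    assert aggregate == pytest.approx(1.0)
    assert recs[0].efficiency_junction == pytest.approx(1.0)


def test_junction_windows_on_minus_strand(minus_gene):
    # first transcribed junction of minus_gene at 27999; spanning 3' ends are
    # genomically below it, exonic 3' ends above it
    rows = [(28_100, 27_999 - 10, "-", False)] * 3     # offset +10: spanning
    rows += [(28_100, 27_999 + 10, "-", True)] * 12    # offset -10: exonic
    lib = _rna_lib(rows)
    _, aggregate = metrics.splicing_efficiency_junction(lib, [minus_gene])
    assert aggregate == pytest.approx(1 - 3.0 / 12.0)


def test_junction_read_length_warning(plus_gene):
    df = pd.DataFrame({"chrom": ["chr1"], "pos": [11_900], "pos3": [11_925],
                       "strand": ["+"], "spliced": [False]})
    lib = TagLibrary(df, read_length=26, stranded=True)
    with pytest.warns(UserWarning, match="32-bp"):
        metrics.splicing_efficiency_junction(lib, [plus_gene])


def test_both_estimators_bounded_by_one():
    cfg = SimConfig(n_genes=8, genome_length=200_000, gene_length_range=(3000, 4000),
                    splicing_efficiency_range=(0.2, 0.99),
                    library_sizes={"rna": 40_000}, seed=9)
    genes, truth = simulate.build_annotation(cfg)
    lib = simulate.simulate_rna_library(genes, truth, "basal", cfg)
    jrecs, aggregate = metrics.splicing_efficiency_junction(lib, genes)
    assert aggregate <= 1.0
    for g, j in zip(genes, jrecs):
        d = metrics.splicing_efficiency_density(lib, g)
        if d.evaluable_density:
            assert d.efficiency_density <= 1.0
        if j.evaluable_junction:
            assert j.efficiency_junction <= 1.0


# -- enrichment over background ---------------------------------------------------

def _uniform_library(rng, n, genome_length):
    return make_library([
        ("chr1", int(p), s) for p, s in zip(
            rng.integers(0, genome_length, n), rng.choice(["+", "-"], n))
    ])


def test_enrichment_poisson_tail_matches_direct_summation(long_gene):
    # expected background 1.0 in the window: 1000 tags, genome 1000 * 2001 bp
    genome_length = 1000 * 2001
    rows = [("chr1", long_gene.tss + (i % 100) - 50, "+") for i in range(30)]
    rows += [("chr1", 10_000_000 + 137 * i, "+") for i in range(970)]
    lib = make_library(rows)
    calls = metrics.promoter_enrichment(lib, [long_gene], genome_length, alpha=0.001)
    call = calls[0]
    mu = 1.0
    direct = 1.0 - sum(math.exp(-mu) * mu ** k / math.factorial(k) for k in range(30))
    assert call.p_value == pytest.approx(direct, rel=1e-9)
    assert call.enriched
    assert call.observed > call.expected_background


def test_enrichment_zero_observed_not_enriched(long_gene):
    lib = make_library([("chr1", 5_000_000, "+")] * 100)
    calls = metrics.promoter_enrichment(lib, [long_gene], 10_000_000)
    assert not calls[0].enriched


def test_enrichment_false_positive_control():
    """Uniform background: enriched fraction stays at or below the nominal level."""
    cfg = SimConfig(n_genes=100, genome_length=1_500_000,
                    gene_length_range=(3000, 3000), seed=2)
    genes, _ = simulate.build_annotation(cfg)
    n_enriched = 0
    n_tests = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        lib = _uniform_library(rng, 30_000, cfg.genome_length)
        calls = metrics.promoter_enrichment(lib, genes, cfg.genome_length, alpha=0.001)
        n_enriched += sum(c.enriched for c in calls)
        n_tests += len(calls)
    assert n_enriched / n_tests <= 0.001


def test_enrichment_requires_genome_length(long_gene):
    lib = make_library([("chr1", 1, "+")])
    with pytest.raises(ValueError, match="genome length"):
        metrics.promoter_enrichment(lib, [long_gene], 0)
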