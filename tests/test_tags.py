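"""Tag I/O, normalization, shifting, and window counting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_library
from nascentmetrics import tags
from nascentmetrics.genes import GeneModel


# -- BED reading --------------------------------------------------------------

def test_read_bed_five_prime_convention(tmp_path):
    path = tmp_path / "tags.bed"
    path.write_text("chr1\t100\t125\tr1\t1\t+\nchr1\t100\t132\tr2\t1\t-\n")
    lib = tags.read_tag_bed(path)
    assert lib.total_mapped == 2
    plus = lib.tags[lib.tags["strand"] == "+"]
    minus = lib.tags[lib.tags["strand"] == "-"]
    assert plus["pos"].tolist() == [100]      # + reads: 5' end = start
    assert minus["pos"].tolist() == [131]     # - reads: 5' end = end - 1


@pytest.mark.parametrize("line,match", [
    ("chr1\t100\t125\tr1\t1", "6 columns"),
    ("chr1\tx\t125\tr1\t1\t+", "non-integer"),
    ("chr1\t100\t125\tr1\t1\t.", "strand"),
])
def test_read_bed_rejects_malformed_lines(tmp_path, line, match):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t1\t26\tr0\t1\t+\n" + line + "\n")
    with pytest.raises(ValueError, match=match) as exc:
        tags.read_tag_bed(path)
    assert ":2:" in str(exc.value)  # line number reported


def test_empty_library_guards(tmp_path):
    path = tmp_path / "empty.bed"
    path.write_text("")
    lib = tags.read_tag_bed(path)
    assert lib.total_mapped == 0
    with pytest.raises(ValueError, match="empty"):
        tags.normalize_library(lib)


def test_bed_round_trip(tmp_path, plus_gene):
    lib = make_library([("chr1", 100, "+"), ("chr1", 500, "-"), ("chr1", 250, "+")],
                       read_length=25)
    path = tmp_path / "rt.bed"
    tags.write_tag_bed(lib, path)
    back = tags.read_tag_bed(path)
    assert sorted(back.tags["pos"]) == sorted(lib.tags["pos"])
    assert back.read_length == 25


# -- normalization ------------------------------------------------------------

def test_normalization_weight_values():
    lib = make_library([("chr1", i, "+") for i in range(10)])
    assert tags.normalize_library(lib, target=20) == 2.0
    assert tags.normalize_library(lib, target=10) == 1.0
    # weighted library mass equals the target
    w = tags.normalize_library(lib)
    assert abs(w * lib.total_mapped - 1e7) / 1e7 < 1e-6


# -- shifting -----------------------------------------------------------------

@pytest.mark.parametrize("frag,expected_plus,expected_minus", [
    (200, 1100, 900),
    (199, 1099, 901),   # floor(199/2) = 99
])
def test_half_fragment_shift(frag, expected_plus, expected_minus):
    lib = make_library([("chr1", 1000, "+"), ("chr1", 1000, "-")],
                       fragment_length=frag)
    shifted = tags.shift_tags(lib)
    assert shifted.tags[shifted.tags["strand"] == "+"]["pos"].tolist() == [expected_plus]
    assert shifted.tags[shifted.tags["strand"] == "-"]["pos"].tolist() == [expected_minus]


def test_shift_requires_fragment_length():
    lib = make_library([("chr1", 1000, "+")])
    with pytest.raises(ValueError, match="fragment_length"):
        tags.shift_tags(lib)


# -- promoter counting --------------------------------------------------------

def test_promoter_count_weighting_and_bounds(plus_gene):
    tss = plus_gene.tss
    lib = make_library([
        ("chr1", tss - 1000, "+"),   # inclusive lower bound: counted
        ("chr1", tss, "-"),          # both strands by default
        ("chr1", tss + 1000, "+"),   # inclusive upper bound: counted
        ("chr1", tss + 1001, "+"),   # outside
        ("chr1", tss - 1001, "-"),   # outside
        ("chr1", tss, "+"),
    ])
    # weight 2.0: 6 tags, target 12
    count = tags.promoter_tag_count(lib, plus_gene, target=12)
    assert count.raw_count == 4
    assert count.normalized_count == pytest.approx(8.0)


def test_promoter_count_matches_bruteforce_on_random_fixture():
    rng = np.random.default_rng(7)
    genes = [GeneModel(f"g{i}", "chr1", "+" if i % 2 else "-",
                       5000 * i + 2000, 5000 * i + 5000,
                       ((5000 * i + 2000, 5000 * i + 5000),)) for i in range(20)]
    rows = [("chr1", int(p), s) for p, s in zip(
        rng.integers(0, 110_000, 5000), rng.choice(["+", "-"], 5000))]
    lib = make_library(rows)
    w = tags.normalize_library(lib)
    for g in genes:
        bf = sum(1 for c, p, s in rows if abs(p - g.tss) <= 1000)
        assert tags.promoter_tag_count(lib, g).normalized_count == pytest.approx(bf * w)


# -- TSS profiles -------------------------------------------------------------

def test_profile_single_tag_lands_in_expected_bin(plus_gene):
    lib = make_library([("chr1", plus_gene.tss + 40, "+")])
    prof = tags.tss_profile(lib, [plus_gene], target=1)
    hot = prof.offsets[prof.density > 0]
    assert hot.tolist() == [25]              # bin [25, 50)
    assert prof.mode_offset() == 37.5


def test_profile_strand_mirror_invariance(plus_gene, minus_gene):
    # identical tag pattern in gene-oriented coordinates on both strands
    offsets = [-300, -40, 0, 40, 40, 1000]
    lib_plus = make_library([("chr1", plus_gene.tss + o, "+") for o in offsets])
    lib_minus = make_library([("chr1", minus_gene.tss - o, "-") for o in offsets])
    p1 = tags.tss_profile(lib_plus, [plus_gene], target=1)
    p2 = tags.tss_profile(lib_minus, [minus_gene], target=1)
    assert np.allclose(p1.density, p2.density)


def test_profile_rejects_uneven_binning(plus_gene):
    lib = make_library([("chr1", 1, "+")])
    with pytest.raises(ValueError, match="does not divide"):
        tags.tss_profile(lib, [plus_gene], span=2000, bin_size=30)


# -- densities and RPKM -------------------------------------------------------

def test_gene_body_density(plus_gene):
    # 100 tags inside a 10-kb body with weight 1 -> 10 per kb
    lib = make_library([("chr1", 10_000 + 7 * i, "+") for i in range(100)])
    d = tags.gene_body_density(lib, plus_gene, target=lib.total_mapped)
    assert d == pytest.approx(10.0)


def test_gene_body_density_sense_only(minus_gene):
    lib = make_library([("chr1", 25_000, "+"), ("chr1", 25_000, "-")])
    d = tags.gene_body_density(lib, minus_gene, sense_only=True,
                               target=lib.total_mapped)
    assert d == pytest.approx(1 / 10.0)      # only the '-' tag counts


def test_exon_intron_density(plus_gene):
    # plus_gene: 6 kb exons, 4 kb introns
    lib = make_library(
        [("chr1", 10_010 + i, "+") for i in range(12)]        # exonic sense
        + [("chr1", 12_500 + i, "+") for i in range(8)]       # intronic sense
        + [("chr1", 10_010, "-")] * 5                          # antisense ignored
    )
    d = tags.exon_intron_density(lib, plus_gene, target=lib.total_mapped)
    assert d.exon_raw == 12 and d.intron_raw == 8
    assert d.exon_density == pytest.approx(2.0)
    assert d.intron_density == pytest.approx(2.0)
    assert d.exon_raw_per_kb == pytest.approx(2.0)


def test_exon_intron_requires_stranded(plus_gene):
    lib = make_library([("chr1", 10_010, "+")], stranded=False)
    with pytest.raises(ValueError, match="stranded"):
        tags.exon_intron_density(lib, plus_gene)


def test_single_exon_gene_intron_density_undefined():
    g = GeneModel("g", "chr1", "+", 0, 1000, ((0, 1000),))
    lib = make_library([("chr1", 10, "+")])
    d = tags.exon_intron_density(lib, g)
    assert d.intron_density is None
    assert d.intron_raw_per_kb is None


def test_rpkm_hand_computed(plus_gene):
    # 200 of 1000 tags in the 10-kb body: 200 / 10 kb / (1000/1e6) = 20000
    rows = [("chr1", 10_000 + i, "+") for i in range(200)]
    rows += [("chr1", 500_000 + i, "+") for i in range(800)]
    lib = make_library(rows)
    assert tags.rpkm(lib, plus_gene) == pytest.approx(20_000.0)
    empty_region_gene = GeneModel("g", "chr1", "+", 40_000, 42_000, ((40_000, 42_000),))
    assert tags.rpkm(lib, empty_region_gene) == 0.0


# -- monotonicity property ----------------------------------------------------

@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=-1000, max_value=1000))
def test_adding_tag_in_window_never_decreases_count(offset):
    gene = GeneModel("g", "chr1", "+", 5000, 9000, ((5000, 9000),))
    base = [("chr1", 5000 + 13 * i, "+") for i in range(50)]
    before = tags.promoter_tag_count(make_library(base), gene, target=1).raw_count
    after = tags.promoter_tag_count(
        make_library(base + [("chr1", gene.tss + offset, "+")]), gene,
        target=1).raw_count
    assert after == before + 1
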