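"""Synthetic genome, annotation, and tag-library generator with ground truth.

Every simulated dataset carries a truth table (one row per gene) recording the
planted parameters — kinetic class, per-condition elongation efficiency,
splicing efficiency, true TSS offset, promoter GC, TATA flag, expression
triplet — so every downstream estimator can be checked by parameter recovery.

The distributional choices here are generative stand-ins chosen for analytic
tractability of the expected window densities (Gaussian peaks, uniform gene
bodies and background); real libraries carry mappability structure, PCR
duplicates and sequence-composition biases that are deliberately not modeled.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel, check_non_overlapping
from .kinetics import classify_kinetics
from .metrics import GRO_BODY_WINDOW, GRO_PROMOTER_WINDOW
from .promoter import PROMOTER_WINDOW, TATA_WINDOW, consensus_matches
from .tags import TagLibrary

CONDITIONS = ("basal", "KLA_1h")
MARK_SPECS = ("histone_bimodal", "polII_paused", "tf_point")
CHROM = "chrSim"

# noiseless fold-change draw ranges per kinetic class: (fc_1h range, fc_12h range).
# Margins leave room for multiplicative noise without flipping class labels.
_FC_RANGES = {
    "IE": ((4.0, 12.0), (2.0, 12.0)),
    "late": ((0.85, 0.98), (5.0, 15.0)),
    "other": ((1.3, 2.4), (0.5, 3.0)),
}
_NOISE_CLIP_SD = 2.0  # multiplicative noise is exp(eps), eps clipped at +/- 2 sd


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator. Defaults emulate a small
    TLR4-stimulation experiment: paused Pol II at +40 bp, bimodal promoter
    histone marks with a nadir at -50 bp, 25-bp ChIP tags and 32-bp RNA/GRO
    tags, depth-normalizable libraries."""

    n_genes: int = 100
    genome_length: int = 2_000_000
    gene_length_range: tuple[int, int] = (4000, 8000)
    n_exons_range: tuple[int, int] = (3, 6)
    class_fractions: dict = field(
        default_factory=lambda: {"IE": 0.3, "late": 0.3, "other": 0.4})
    pause_peak_center: int = 40
    pause_peak_sd: float = 50.0
    histone_nadir: int = -50
    histone_peak_spacing: int = 300
    histone_peak_sd: float = 150.0
    tf_peak_sd: float = 35.0
    elongation_efficiency_map: dict = field(default_factory=lambda: {
        ("IE", "basal"): 0.2, ("IE", "KLA_1h"): 1.0,
        ("late", "basal"): 0.3, ("late", "KLA_1h"): 0.35,
        ("other", "basal"): 0.5, ("other", "KLA_1h"): 0.5,
    })
    splicing_efficiency_range: tuple[float, float] = (0.85, 0.99)
    splicing_efficiency_values: tuple[float, ...] | None = None  # cycled if given
    tss_offset_range: tuple[int, int] = (-80, 80)
    gc_level_map: dict = field(
        default_factory=lambda: {"IE": 0.63, "late": 0.45, "other": 0.50})
    gc_sd: float = 0.05
    tata_fraction_map: dict = field(
        default_factory=lambda: {"IE": 0.38, "late": 0.11, "other": 0.15})
    library_sizes: dict = field(default_factory=lambda: {
        "chip": 400_000, "gro": 600_000, "rna": 1_000_000, "cage": 50_000})
    read_length_chip: int = 25
    read_length_rna: int = 32
    fragment_length: int = 200
    background_fraction: float = 0.05
    gro_antisense_fraction: float = 0.10
    gro_allocation: str = "expression"   # per-gene read budget: 'expression' | 'equal'
    cage_dispersion: float = 5.0
    cage_noise_fraction: float = 0.10
    expression_noise_sd: float = 0.05
    min_exon_length: int = 100
    min_intron_length: int = 200
    min_gene_gap: int = 500
    edge_margin: int = 3000
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        if any(v < 0 for v in self.elongation_efficiency_map.values()):
            raise ValueError("elongation efficiencies must be >= 0")
        lo, hi = self.splicing_efficiency_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("splicing efficiencies must lie in [0, 1]")
        if self.splicing_efficiency_values is not None and any(
                not 0 <= v <= 1 for v in self.splicing_efficiency_values):
            raise ValueError("splicing efficiencies must lie in [0, 1]")
        if self.read_length_chip <= 0 or self.read_length_rna <= 0:
            raise ValueError("read lengths must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.fragment_length < self.read_length_chip:
            raise ValueError("fragment_length must be >= ChIP read length")
        if self.gro_allocation not in ("expression", "equal"):
            raise ValueError("gro_allocation must be 'expression' or 'equal'")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *stream])


def _split_total(total: int, n: int) -> np.ndarray:
    """Split ``total`` into n near-equal integer parts (deterministic)."""
    base, rem = divmod(total, n)
    out = np.full(n, base, dtype=np.int64)
    out[:rem] += 1
    return out


# -- annotation and truth ----------------------------------------------------

def build_annotation(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place non-overlapping gene models on both strands and draw per-gene truth."""
    config.validate()
    rng = config.rng(1)
    n = config.n_genes
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, size=n)
    needed = (2 * config.edge_margin + int(lengths.sum())
              + (n - 1) * config.min_gene_gap)
    if needed > config.genome_length:
        raise ValueError(
            f"cannot place {n} non-overlapping genes of total length "
            f"{int(lengths.sum())} bp plus gaps in a {config.genome_length} bp "
            f"genome (needs >= {needed} bp)")
    slack = config.genome_length - needed
    extra = rng.multinomial(slack, np.full(n, 1.0 / n)) if slack > 0 else np.zeros(n, int)
    strands = rng.choice(["+", "-"], size=n)
    classes = rng.choice(list(config.class_fractions.keys()), size=n,
                         p=list(config.class_fractions.values()))

    genes: list[GeneModel] = []
    cursor = config.edge_margin
    for i in range(n):
        start = cursor + (config.min_gene_gap if i > 0 else 0) + int(extra[i])
        end = start + int(lengths[i])
        exons = _draw_exons(rng, start, end, config)
        genes.append(GeneModel(f"g{i:04d}", CHROM, str(strands[i]), start, end, exons))
        cursor = end
    check_non_overlapping(genes)

    truth = _draw_truth(rng, genes, classes, config)
    return genes, truth


def _draw_exons(rng: np.random.Generator, start: int, end: int,
                config: SimConfig) -> tuple[tuple[int, int], ...]:
    length = end - start
    lo, hi = config.n_exons_range
    n_ex = int(rng.integers(lo, hi + 1))
    me, mi = config.min_exon_length, config.min_intron_length
    while n_ex > 1 and n_ex * me + (n_ex - 1) * mi > length:
        n_ex -= 1
    if n_ex == 1:
        return ((start, end),)
    n_parts = 2 * n_ex - 1
    mins = np.array([me if i % 2 == 0 else mi for i in range(n_parts)])
    extra = rng.multinomial(length - int(mins.sum()), np.full(n_parts, 1.0 / n_parts))
    parts = mins + extra
    bounds = start + np.concatenate([[0], np.cumsum(parts)])
    return tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_parts, 2))


def _draw_truth(rng: np.random.Generator, genes: Sequence[GeneModel],
                classes: np.ndarray, config: SimConfig) -> pd.DataFrame:
    n = len(genes)
    if config.splicing_efficiency_values is not None:
        vals = config.splicing_efficiency_values
        se = np.array([vals[i % len(vals)] for i in range(n)])
    else:
        se = rng.uniform(*config.splicing_efficiency_range, size=n)
    offsets = rng.integers(config.tss_offset_range[0],
                           config.tss_offset_range[1] + 1, size=n)
    gc = np.clip(
        np.array([rng.normal(config.gc_level_map[c], config.gc_sd) for c in classes]),
        0.25, 0.90)
    tata = np.array([rng.random() < config.tata_fraction_map[c] for c in classes])
    expr0 = 10.0 * rng.lognormal(0.0, 0.5, size=n)
    fc1 = np.array([rng.uniform(*_FC_RANGES[c][0]) for c in classes])
    fc12 = np.array([rng.uniform(*_FC_RANGES[c][1]) for c in classes])
    ee = {
        cond: np.array([config.elongation_efficiency_map[(c, cond)] for c in classes])
        for cond in CONDITIONS
    }
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "kinetic_class": classes,
        "ee_basal": ee["basal"],
        "ee_KLA_1h": ee["KLA_1h"],
        "true_splicing_efficiency": se,
        "true_tss_offset": offsets.astype(int),
        "promoter_gc": gc,
        "has_tata": tata,
        "expr_0h": expr0,
        "expr_1h": expr0 * fc1,
        "expr_12h": expr0 * fc12,
    })


# -- genome sequence ---------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TATA_SITE = "TATAAAAG"  # contains TATAAA; always matches the TATAWAWR consensus


def synthesize_genome_sequence(genes: Sequence[GeneModel], truth: pd.DataFrame,
                               config: SimConfig,
                               promoter_window: tuple[int, int] = PROMOTER_WINDOW,
                               ) -> dict[str, str]:
    """I.i.d. background sequence with class-dependent promoter GC and
    plantable TATA sites.

    The promoter window of each gene realizes its planted GC exactly (by
    composition) up to the TATA overwrite; promoters without a planted TATA
    are re-shuffled until no consensus match starts in the TATA window, so a
    noise-free positional scan recovers the planted fraction exactly.
    """
    rng = config.rng(2)
    codes = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    a, b = promoter_window
    win_len = b - a
    tata_lo = TATA_WINDOW[0] - a            # window-local start offsets
    tata_hi = TATA_WINDOW[1] - a
    truth_idx = truth.set_index("gene_id")
    for gene in genes:
        lo, hi = gene.window_to_genomic(a, b)
        if lo < 0 or hi > config.genome_length:
            raise ValueError(
                f"{gene.gene_id}: promoter window [{lo}, {hi}) extends past contig edge")
        row = truth_idx.loc[gene.gene_id]
        win = _promoter_codes(rng, win_len, float(row["promoter_gc"]),
                              bool(row["has_tata"]), tata_lo, tata_hi, gene.gene_id)
        if gene.strand == "-":
            win = (3 - win)[::-1]
        codes[lo:hi] = win
    return {CHROM: _BASES[codes].tobytes().decode()}


def _promoter_codes(rng: np.random.Generator, win_len: int, gc: float,
                    has_tata: bool, tata_lo: int, tata_hi: int,
                    gene_id: str) -> np.ndarray:
    n_gc = int(round(gc * win_len))
    site = np.frombuffer(_TATA_SITE.encode(), dtype=np.uint8)
    site_codes = np.searchsorted(_BASES, site).astype(np.uint8)
    for _ in range(100):
        gc_codes = rng.integers(0, 2, size=n_gc, dtype=np.uint8) + 1       # C or G
        at_codes = rng.integers(0, 2, size=win_len - n_gc, dtype=np.uint8) * 3  # A or T
        win = np.concatenate([gc_codes, at_codes])
        rng.shuffle(win)
        if has_tata:
            s = int(rng.integers(tata_lo, tata_hi + 1))
            win[s:s + len(site_codes)] = site_codes
            return win
        scan = _BASES[win[tata_lo:tata_hi + len(site_codes)]].tobytes().decode()
        if not consensus_matches(scan):
            return win
    raise RuntimeError(
        f"{gene_id}: could not generate a TATA-free promoter in 100 attempts")


def write_genome_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -- tag libraries -----------------------------------------------------------

def _background_tags(rng: np.random.Generator, n: int, genome_length: int,
                     read_length: int) -> tuple[np.ndarray, np.ndarray]:
    # stay one read length clear of the contig edges so BED records are valid
    pos = rng.integers(read_length, genome_length - read_length, size=n)
    strand = rng.choice(["+", "-"], size=n)
    return pos, strand


def _as_library(pos_parts, strand_parts, read_length, fragment_length, stranded,
                extra: dict | None = None) -> TagLibrary:
    tags = pd.DataFrame({
        "chrom": CHROM,
        "pos": np.concatenate(pos_parts).astype(np.int64),
        "strand": np.concatenate(strand_parts),
    })
    if extra:
        for k, v in extra.items():
            tags[k] = np.concatenate(v)
    return TagLibrary(tags, read_length=read_length,
                      fragment_length=fragment_length, stranded=stranded)


def simulate_chip_library(genes: Sequence[GeneModel], truth: pd.DataFrame,
                          mark_spec: str, condition: str,
                          config: SimConfig) -> TagLibrary:
    """ChIP tag library with a mark-specific profile around each TSS.

    Fragment centers are drawn from the mark's mixture; each tag is the 5' end
    of a random-strand read offset by half the fragment length, so the
    half-fragment shift downstream recovers the planted profile exactly.
    """
    if mark_spec not in MARK_SPECS:
        raise ValueError(f"unknown mark_spec {mark_spec!r}; expected one of {MARK_SPECS}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = config.rng(3, MARK_SPECS.index(mark_spec), CONDITIONS.index(condition))
    n_total = int(config.library_sizes["chip"])
    n_bg = int(round(config.background_fraction * n_total))
    per_gene = _split_total(n_total - n_bg, len(genes))
    half = config.fragment_length // 2
    pos_parts, strand_parts = [], []
    for gene, n_g in zip(genes, per_gene):
        x = _mark_offsets(rng, mark_spec, int(n_g), config)
        centers = gene.tss + gene.orient * x
        strand = rng.choice(["+", "-"], size=int(n_g))
        pos = np.where(strand == "+", centers - half, centers + half)
        rl = config.read_length_chip
        pos_parts.append(np.clip(pos, rl, config.genome_length - 1 - rl))
        strand_parts.append(strand)
    bg_pos, bg_strand = _background_tags(rng, n_bg, config.genome_length,
                                         config.read_length_chip)
    pos_parts.append(bg_pos)
    strand_parts.append(bg_strand)
    return _as_library(pos_parts, strand_parts, config.read_length_chip,
                       config.fragment_length, stranded=False)


def _mark_offsets(rng: np.random.Generator, mark_spec: str, n: int,
                  config: SimConfig) -> np.ndarray:
    if mark_spec == "polII_paused":
        x = rng.normal(config.pause_peak_center, config.pause_peak_sd, size=n)
    elif mark_spec == "tf_point":
        x = rng.normal(0.0, config.tf_peak_sd, size=n)
    else:  # histone_bimodal: equal mixture with nadir midway between the peaks
        side = rng.random(n) < 0.5
        centers = np.where(side, config.histone_nadir - config.histone_peak_spacing,
                           config.histone_nadir + config.histone_peak_spacing)
        x = rng.normal(centers, config.histone_peak_sd)
    return np.rint(x).astype(np.int64)


def simulate_gro_library(genes: Sequence[GeneModel], truth: pd.DataFrame,
                         condition: str, config: SimConfig) -> TagLibrary:
    """Stranded GRO-Seq library: promoter-proximal peak + uniform gene body.

    Sense tags mix a uniform promoter component over [-25, +175) and a uniform
    gene-body component over [+500, +2500) with weights chosen so the expected
    window-density ratio equals the gene's planted elongation efficiency; a
    divergent antisense component sits upstream of the TSS. Per-gene read
    budgets are proportional to the gene's planted expression at the matching
    timepoint (0 h for basal, 1 h for KLA) unless ``gro_allocation='equal'``,
    so transcriptional induction is visible in gene-body tag counts.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = config.rng(4, CONDITIONS.index(condition))
    body_needed = GRO_BODY_WINDOW[1]
    for gene in genes:
        if gene.span < body_needed:
            raise ValueError(
                f"{gene.gene_id}: span {gene.span} bp < {body_needed} bp required "
                f"for the gene-body window")
    ee = truth.set_index("gene_id")[f"ee_{condition}"]
    n_total = int(config.library_sizes["gro"])
    n_bg = int(round(config.background_fraction * n_total))
    if config.gro_allocation == "expression":
        expr_col = {"basal": "expr_0h", "KLA_1h": "expr_1h"}[condition]
        wts = (truth.set_index("gene_id")[expr_col]
               .reindex([g.gene_id for g in genes]).to_numpy(dtype=float))
        per_gene = rng.multinomial(n_total - n_bg, wts / wts.sum())
    else:
        per_gene = _split_total(n_total - n_bg, len(genes))
    p_len = GRO_PROMOTER_WINDOW[1] - GRO_PROMOTER_WINDOW[0]
    b_len = GRO_BODY_WINDOW[1] - GRO_BODY_WINDOW[0]
    width_ratio = b_len / p_len
    pos_parts, strand_parts = [], []
    anti_strand = {"+": "-", "-": "+"}
    for gene, n_g in zip(genes, per_gene):
        n_anti = int(round(config.gro_antisense_fraction * n_g))
        n_sense = int(n_g) - n_anti
        e = float(ee.loc[gene.gene_id])
        p_body = width_ratio * e / (1.0 + width_ratio * e)
        n_body = rng.binomial(n_sense, p_body)
        off_body = rng.integers(*GRO_BODY_WINDOW, size=n_body)
        off_prom = rng.integers(*GRO_PROMOTER_WINDOW, size=n_sense - n_body)
        off_anti = rng.integers(-500, 0, size=n_anti)
        sense_pos = gene.tss + gene.orient * np.concatenate([off_prom, off_body])
        anti_pos = gene.tss + gene.orient * off_anti
        pos_parts.extend([sense_pos, anti_pos])
        strand_parts.extend([
            np.full(n_sense, gene.strand), np.full(n_anti, anti_strand[gene.strand])
        ])
    bg_pos, bg_strand = _background_tags(rng, n_bg, config.genome_length,
                                         config.read_length_rna)
    pos_parts.append(bg_pos)
    strand_parts.append(bg_strand)
    return _as_library(pos_parts, strand_parts, config.read_length_rna, None,
                       stranded=True)


def simulate_rna_library(genes: Sequence[GeneModel], truth: pd.DataFrame,
                         condition: str, config: SimConfig) -> TagLibrary:
    """Total-RNA tag library mixing spliced (mature) and unspliced templates.

    Read starts are uniform over every template position with per-bp rates in
    ratio SE : (1 - SE) between the mature and unspliced templates, so both
    the intron/exon density estimator and the junction 3'-end estimator
    recover the planted splicing efficiency; reads starting within one read
    length of a template's 3' end are truncated at the template end (this
    keeps the 5'-end density exactly uniform, and such 3' ends lie well away
    from any junction window). Each tag records its genomic 5' end, the
    genomic 3'-end position under its template, and a junction flag.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = config.rng(5, CONDITIONS.index(condition))
    rl = config.read_length_rna
    se_map = truth.set_index("gene_id")["true_splicing_efficiency"]
    per_gene = _split_total(int(config.library_sizes["rna"]), len(genes))
    pos_parts, strand_parts = [], []
    pos3_parts, spliced_parts = [], []
    for gene, n_g in zip(genes, per_gene):
        se = float(se_map.loc[gene.gene_id])
        lm = gene.exon_length
        lg = gene.span
        if lm < rl:
            raise ValueError(f"{gene.gene_id}: mature transcript shorter than read length")
        denom = se * lm + (1.0 - se) * lg
        p_mature = se * lm / denom if denom > 0 else 0.0
        n_m = int(rng.binomial(int(n_g), p_mature))
        n_u = int(n_g) - n_m
        # mature: uniform over spliced-transcript start positions
        t5 = rng.integers(0, lm, size=n_m)
        t3 = np.minimum(t5 + rl - 1, lm - 1)
        g5_m = gene.transcript_to_genomic(t5)
        g3_m = gene.transcript_to_genomic(t3)
        # unspliced: uniform over genomic-contiguous start positions
        u = rng.integers(0, lg, size=n_u)
        if gene.strand == "+":
            g5_u = gene.tx_start + u
            g3_u = np.minimum(g5_u + rl - 1, gene.tx_end - 1)
        else:
            g5_u = gene.tx_end - 1 - u
            g3_u = np.maximum(g5_u - rl + 1, gene.tx_start)
        pos_parts.append(np.concatenate([g5_m, g5_u]))
        pos3_parts.append(np.concatenate([g3_m, g3_u]))
        spliced_parts.append(np.concatenate([
            np.abs(g3_m - g5_m) != t3 - t5, np.zeros(n_u, dtype=bool)]))
        strand_parts.append(np.full(int(n_g), gene.strand))
    return _as_library(pos_parts, strand_parts, rl, None, stranded=True,
                       extra={"pos3": pos3_parts, "spliced": spliced_parts})


def simulate_cage_library(genes: Sequence[GeneModel], truth: pd.DataFrame,
                          config: SimConfig, flank: int = 1000,
                          cluster_width: int = 100) -> TagLibrary:
    """CAGE 5'-end tags clustered at the true TSS plus uniform noise in +/-1 kb."""
    rng = config.rng(6)
    offsets = truth.set_index("gene_id")["true_tss_offset"]
    max_off = flank - cluster_width // 2
    bad = offsets[offsets.abs() > max_off]
    if len(bad):
        raise ValueError(
            f"true TSS offsets exceed {max_off} bp for genes {list(bad.index[:5])}")
    per_gene = _split_total(int(config.library_sizes["cage"]), len(genes))
    pos_parts, strand_parts = [], []
    for gene, n_g in zip(genes, per_gene):
        true_off = int(offsets.loc[gene.gene_id])
        n_noise = int(round(config.cage_noise_fraction * n_g))
        n_cluster = int(n_g) - n_noise
        if config.cage_dispersion > 0:
            d = true_off + np.rint(
                rng.normal(0.0, config.cage_dispersion, size=n_cluster)).astype(np.int64)
            d = np.clip(d, -flank, flank)
        else:
            d = np.full(n_cluster, true_off, dtype=np.int64)
        noise = rng.integers(-flank, flank + 1, size=n_noise)
        off = np.concatenate([d, noise])
        pos_parts.append(gene.tss + gene.orient * off)
        strand_parts.append(np.full(int(n_g), gene.strand))
    return _as_library(pos_parts, strand_parts, 27, None, stranded=True)


# -- expression --------------------------------------------------------------

def max_label_safe_noise_sd() -> float:
    """Largest multiplicative noise sd (with the +/-2 sd clip) for which the
    planted fold-change ranges cannot cross a classification boundary."""
    clip = 2 * _NOISE_CLIP_SD  # two noisy values enter each ratio
    bounds = [
        math.log(_FC_RANGES["IE"][0][0] / 3.0) / clip,       # IE stays > 3x
        math.log(1.2 / _FC_RANGES["late"][0][1]) / clip,     # late stays < 1.2x
        math.log(_FC_RANGES["late"][1][0] / 4.0) / clip,     # late stays > 4x at 12 h
        math.log(3.0 / _FC_RANGES["other"][0][1]) / clip,    # other stays < 3x
        math.log(4.0 / _FC_RANGES["other"][1][1]) / clip,    # other stays < 4x at 12 h
    ]
    return min(bounds)


def simulate_expression_table(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Three-timepoint expression with multiplicative lognormal noise.

    Noise is clipped at +/-2 sd so the planted draw margins guarantee that
    kinetic-class labels survive; a noise sd too large for that guarantee is
    rejected.
    """
    sd = config.expression_noise_sd
    limit = max_label_safe_noise_sd()
    if sd > limit:
        raise ValueError(
            f"expression_noise_sd={sd} cannot guarantee label consistency "
            f"(max {limit:.4f} for the built-in fold-change margins)")
    rng = config.rng(7)
    out = truth[["gene_id", "expr_0h", "expr_1h", "expr_12h"]].copy()
    if sd > 0:
        eps = np.clip(rng.normal(0.0, sd, size=(len(out), 3)),
                      -_NOISE_CLIP_SD * sd, _NOISE_CLIP_SD * sd)
        for j, col in enumerate(["expr_0h", "expr_1h", "expr_12h"]):
            out[col] = out[col].to_numpy() * np.exp(eps[:, j])
    out["fc_1h"] = out["expr_1h"] / out["expr_0h"]
    out["fc_12h"] = out["expr_12h"] / out["expr_0h"]
    out["kinetic_class"] = [
        classify_kinetics(a, b, c)
        for a, b, c in zip(out["expr_0h"], out["expr_1h"], out["expr_12h"])
    ]
    return out


# -- induction benchmark -------------------------------------------------------

def simulate_induction_pair(n_genes: int = 500, n_induced: int = 50,
                            fold: float = 5.0, rpkm_induced: float = 2.0,
                            depth: int = 1_000_000, gene_length: int = 40_000,
                            seed: int = 0) -> tuple[list[GeneModel], pd.DataFrame,
                                                    TagLibrary, TagLibrary]:
    """Paired GRO-Seq libraries with a planted set of induced genes.

    Induced genes carry ``rpkm_induced`` in the treated library and
    ``rpkm_induced / fold`` basally; null genes share one expression level
    across conditions, scaled to absorb the remaining library mass. Reads are
    placed uniformly over sense-strand gene bodies with no genomic background
    (at these depths a uniform background would dominate the low-RPKM planted
    signal symmetrically in both conditions; the benchmark isolates the count
    test).
    """
    cfg = SimConfig(
        n_genes=n_genes,
        genome_length=n_genes * (gene_length + 1000) + 10_000,
        gene_length_range=(gene_length, gene_length),
        n_exons_range=(1, 1),
        background_fraction=0.0,
        seed=seed,
    )
    genes, _ = build_annotation(cfg)
    rng = cfg.rng(8)
    induced = np.zeros(n_genes, dtype=bool)
    induced[rng.choice(n_genes, size=n_induced, replace=False)] = True
    lam_t = np.empty(n_genes)
    lam_b = np.empty(n_genes)
    target = rpkm_induced * (gene_length / 1000.0) * (depth / 1e6)
    lam_t[induced] = target
    lam_b[induced] = target / fold
    null_raw = rng.lognormal(0.0, 0.5, size=int((~induced).sum()))
    null_scaled = null_raw * (depth - lam_t[induced].sum()) / null_raw.sum()
    lam_t[~induced] = null_scaled
    lam_b[~induced] = null_scaled
    libs = []
    for lam in (lam_b, lam_t):
        counts = rng.multinomial(depth, lam / lam.sum())
        pos_parts, strand_parts = [], []
        for gene, c in zip(genes, counts):
            pos_parts.append(rng.integers(gene.tx_start, gene.tx_end, size=int(c)))
            strand_parts.append(np.full(int(c), gene.strand))
        libs.append(_as_library(pos_parts, strand_parts, 32, None, stranded=True))
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "induced": induced,
        "lambda_basal": lam_b,
        "lambda_treated": lam_t,
    })
    return genes, truth, libs[0], libs[1]


# -- tables -------------------------------------------------------------------

def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (e.g. YAML) dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("gene_length_range", "n_exons_range", "tss_offset_range",
                "splicing_efficiency_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "elongation_efficiency_map" in d and isinstance(
            d["elongation_efficiency_map"], dict):
        emap = {}
        for k, v in d["elongation_efficiency_map"].items():
            if isinstance(k, str):
                cls, cond = k.split(":")
                emap[(cls, cond)] = float(v)
            else:
                emap[tuple(k)] = float(v)
        d["elongation_efficiency_map"] = emap
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
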