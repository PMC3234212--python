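"""Per-gene transcription metrics from nascent and total RNA tag libraries.

Elongation efficiency is the ratio of sense-strand GRO-Seq tag density in the
gene body window [+500, +2500) to the density in the promoter-proximal window
[-25, +175); values near 0 indicate promoter-proximal Pol II pausing, values
near 1 indicate efficient release into elongation.

Splicing efficiency is estimated two ways from total-RNA tags:
  * density route: 1 - intron/exon sense-tag density, evaluable only when both
    raw densities exceed 1 read per kb;
  * junction route: depletion of read 3' ends extending across 5' splice
    junctions on the unspliced template, using the 19-bp windows [+7, +25]
    (intronic, junction-spanning) and [-25, -7] (exonic) with position 0 the
    first intronic base.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genes import GeneModel
from .tags import (NORMALIZATION_TARGET, PromoterCount, TagLibrary,
                   exon_intron_density, normalize_library)

GRO_PROMOTER_WINDOW = (-25, 175)     # half-open, gene-oriented bp
GRO_BODY_WINDOW = (500, 2500)        # half-open, gene-oriented bp
JUNCTION_SPANNING_WINDOW = (7, 25)   # inclusive, 3'-end offsets from the junction
JUNCTION_EXON_WINDOW = (-25, -7)     # inclusive


@dataclass
class ElongationRecord:
    gene_id: str
    condition: str
    promoter_density: float     # weighted tags/bp in [-25, +175)
    body_density: float         # weighted tags/bp in [+500, +2500)
    efficiency: float           # body / promoter; NaN when not evaluable
    evaluable: bool


@dataclass
class SplicingRecord:
    gene_id: str
    condition: str = ""
    exon_density: float = math.nan
    intron_density: float = math.nan
    efficiency_density: float = math.nan
    evaluable_density: bool = False
    junction_spanning_density: float = math.nan   # 3'-end tags/bp, [+7, +25]
    junction_exon_density: float = math.nan       # 3'-end tags/bp, [-25, -7]
    efficiency_junction: float = math.nan
    evaluable_junction: bool = False


@dataclass
class EnrichmentCall:
    gene_id: str
    mark: str
    observed: float             # normalized promoter count
    expected_background: float  # normalized count under uniform background
    p_value: float
    q_value: float
    enriched: bool


def elongation_efficiency(gro: TagLibrary, gene: GeneModel, condition: str = "",
                          promoter_window: tuple[int, int] = GRO_PROMOTER_WINDOW,
                          body_window: tuple[int, int] = GRO_BODY_WINDOW,
                          target: float = NORMALIZATION_TARGET) -> ElongationRecord:
    """Sense-strand gene-body / promoter-proximal GRO-Seq density ratio."""
    if not gro.stranded:
        raise ValueError("elongation efficiency requires a stranded GRO-Seq library")
    w = normalize_library(gro, target)
    plo, phi = gene.window_to_genomic(*promoter_window)
    blo, bhi = gene.window_to_genomic(*body_window)
    p_raw = gro.count_in(gene.chrom, plo, phi, strand=gene.strand)
    b_raw = gro.count_in(gene.chrom, blo, bhi, strand=gene.strand)
    p_den = p_raw * w / (promoter_window[1] - promoter_window[0])
    b_den = b_raw * w / (body_window[1] - body_window[0])
    evaluable = p_raw > 0 and gene.span >= body_window[1]
    eff = b_den / p_den if evaluable else math.nan
    return ElongationRecord(gene.gene_id, condition, p_den, b_den, eff, evaluable)


def splicing_efficiency_density(rna: TagLibrary, gene: GeneModel, condition: str = "",
                                min_raw_per_kb: float = 1.0,
                                target: float = NORMALIZATION_TARGET) -> SplicingRecord:
    """1 - intron/exon sense tag density; evaluable only above the raw-density floor.

    The >1 read/kb floor is applied to raw (pre-normalization) read counts: it
    is an information filter on how well each feature is sampled, not an
    abundance comparison.
    """
    d = exon_intron_density(rna, gene, target)
    rec = SplicingRecord(gene.gene_id, condition)
    if d.intron_density is None:
        return rec
    rec.exon_density = d.exon_density
    rec.intron_density = d.intron_density
    if d.exon_raw_per_kb > min_raw_per_kb and d.intron_raw_per_kb > min_raw_per_kb:
        rec.evaluable_density = True
        rec.efficiency_density = 1.0 - d.intron_density / d.exon_density
    return rec


def splicing_efficiency_junction(rna: TagLibrary, genes: Sequence[GeneModel],
                                 condition: str = "",
                                 spanning_window: tuple[int, int] = JUNCTION_SPANNING_WINDOW,
                                 exon_window: tuple[int, int] = JUNCTION_EXON_WINDOW,
                                 ) -> tuple[list[SplicingRecord], float]:
    """Splicing efficiency from read 3' ends around 5' splice junctions.

    Per gene, efficiency is the mean over its junctions of
    1 - spanning_density / exonic_density; the aggregate pools 3'-end counts
    over every junction in the gene set. Returns (records, aggregate).
    """
    if not rna.stranded:
        raise ValueError("junction analysis requires a stranded library")
    if rna.read_length != 32:
        warnings.warn(
            f"junction windows were derived for 32-bp tags; library has "
            f"{rna.read_length}-bp reads", stacklevel=2)
    col = "pos3" if "pos3" in rna.tags.columns else None
    span_w = spanning_window[1] - spanning_window[0] + 1
    exon_w = exon_window[1] - exon_window[0] + 1
    records = []
    pool_span = 0
    pool_exon = 0
    for gene in genes:
        rec = SplicingRecord(gene.gene_id, condition)
        juncs = gene.splice_junctions_5p()
        if juncs:
            span_raw = 0
            exon_raw = 0
            effs = []
            for j in juncs:
                s_cnt, e_cnt = _junction_counts(rna, gene, j, col,
                                                spanning_window, exon_window)
                span_raw += s_cnt
                exon_raw += e_cnt
                if e_cnt > 0:
                    effs.append(1.0 - (s_cnt / span_w) / (e_cnt / exon_w))
            pool_span += span_raw
            pool_exon += exon_raw
            n = len(juncs)
            rec.junction_spanning_density = span_raw / (n * span_w)
            rec.junction_exon_density = exon_raw / (n * exon_w)
            if effs:
                rec.evaluable_junction = True
                rec.efficiency_junction = float(np.mean(effs))
        records.append(rec)
    aggregate = math.nan
    if pool_exon > 0:
        aggregate = 1.0 - (pool_span / span_w) / (pool_exon / exon_w)
    return records, aggregate


def _junction_counts(rna: TagLibrary, gene: GeneModel, junction: int,
                     pos3_col: str | None, spanning_window: tuple[int, int],
                     exon_window: tuple[int, int]) -> tuple[int, int]:
    """Raw 3'-end counts in the spanning and exonic windows of one junction."""
    lo_s, hi_s = _window_genomic(gene, junction, spanning_window)
    lo_e, hi_e = _window_genomic(gene, junction, exon_window)
    if pos3_col is None:
        # no template information: infer contiguous 3' ends by shifting the
        # windows back to 5'-end space (equivalent to shifting every 3' end)
        d = (rna.read_length - 1) * gene.orient
        s_cnt = rna.count_in(gene.chrom, lo_s - d, hi_s - d, strand=gene.strand)
        e_cnt = rna.count_in(gene.chrom, lo_e - d, hi_e - d, strand=gene.strand)
        return s_cnt, e_cnt
    s_cnt = rna.count_in(gene.chrom, lo_s, hi_s, strand=gene.strand, column=pos3_col)
    e_cnt = rna.count_in(gene.chrom, lo_e, hi_e, strand=gene.strand, column=pos3_col)
    return s_cnt, e_cnt


def _window_genomic(gene: GeneModel, junction: int,
                    window: tuple[int, int]) -> tuple[int, int]:
    """Genomic half-open interval for an inclusive junction-relative offset window."""
    a, b = window
    if gene.strand == "+":
        return junction + a, junction + b + 1
    return junction - b, junction - a + 1


def promoter_enrichment(lib: TagLibrary, genes: Sequence[GeneModel], genome_length: int,
                        mark: str = "", window: int = 1000, alpha: float = 0.001,
                        target: float = NORMALIZATION_TARGET) -> list[EnrichmentCall]:
    """Call promoters enriched over a uniform genomic background.

    The expected background count is the library mass spread uniformly over
    the genome; the per-promoter p-value is the Poisson upper tail on the raw
    window count, corrected across the gene set with Benjamini-Hochberg.
    """
    if genome_length is None or genome_length <= 0:
        raise ValueError("genome length must be set for background enrichment calls")
    w = normalize_library(lib, target)
    win_len = 2 * window + 1
    mu = lib.total_mapped * win_len / genome_length
    raws = np.array([
        lib.count_in(g.chrom, g.tss - window, g.tss + window + 1) for g in genes
    ])
    pvals = stats.poisson.sf(raws - 1, mu)
    rejected, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    calls = []
    for gene, raw, p, q, rej in zip(genes, raws, pvals, qvals, rejected):
        enriched = bool(rej) and raw * w > mu * w
        calls.append(EnrichmentCall(gene.gene_id, mark, raw * w, mu * w,
                                    float(p), float(q), enriched))
    return calls
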