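"""Tag libraries: reading, depth normalization, fragment shifting, and counting.

A *tag* is the 5' end of one uniquely mapped sequencing read. Every density
downstream is a weighted tag count after normalizing the library to a fixed
number of mapped tags (default 10^7), i.e. each tag carries weight
``target / total_mapped``.

ChIP tags are shifted toward the fragment center by half the estimated
fragment length before counting; GRO-Seq, RNA-Seq and CAGE tags are used at
their raw 5' ends (the 5' end itself is the signal for those assays).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

NORMALIZATION_TARGET = 10_000_000


@dataclass
class TagLibrary:
    """Uniquely mapped read 5' ends with strand, plus library metadata.

    ``tags`` columns: chrom (str), pos (int, 0-based 5' end), strand ('+'/'-').
    RNA libraries may carry ``pos3`` (genomic 3'-end position under the read's
    template) and ``spliced`` (bool junction flag).
    """

    tags: pd.DataFrame
    read_length: int = 25
    fragment_length: int | None = None
    stranded: bool = True
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    REQUIRED = ("chrom", "pos", "strand")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.tags.columns:
                raise ValueError(f"tag table lacks required column {col!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    @property
    def total_mapped(self) -> int:
        return len(self.tags)

    def positions(self, chrom: str, strand: str | None = None, column: str = "pos") -> np.ndarray:
        """Sorted positions on a chromosome, optionally restricted to one strand."""
        key = (chrom, strand, column)
        if key not in self._index:
            t = self.tags
            mask = t["chrom"].to_numpy() == chrom
            if strand is not None:
                mask &= t["strand"].to_numpy() == strand
            self._index[key] = np.sort(t[column].to_numpy()[mask].astype(np.int64))
        return self._index[key]

    def count_in(self, chrom: str, lo: int, hi: int, strand: str | None = None,
                 column: str = "pos") -> int:
        """Raw tag count with ``column`` position in the half-open interval [lo, hi)."""
        p = self.positions(chrom, strand, column)
        return int(np.searchsorted(p, hi) - np.searchsorted(p, lo))


@dataclass
class DensityProfile:
    """TSS-anchored binned tag density, gene-oriented and summed over genes."""

    offsets: np.ndarray        # left edge of each bin, bp relative to TSS
    density: np.ndarray        # tags per bp per normalization target
    bin_size: int
    n_genes: int

    def mode_offset(self) -> float:
        """Center of the maximum-density bin."""
        i = int(np.argmax(self.density))
        return float(self.offsets[i] + self.bin_size / 2)

    def min_offset(self, lo: int | None = None, hi: int | None = None) -> float:
        """Center of the minimum-density bin, optionally restricted to [lo, hi)."""
        mask = np.ones(len(self.offsets), dtype=bool)
        if lo is not None:
            mask &= self.offsets >= lo
        if hi is not None:
            mask &= self.offsets + self.bin_size <= hi
        idx = np.flatnonzero(mask)
        i = idx[int(np.argmin(self.density[idx]))]
        return float(self.offsets[i] + self.bin_size / 2)


@dataclass
class PromoterCount:
    gene_id: str
    assay: str
    condition: str
    normalized_count: float
    raw_count: int
    window: int


# -- I/O --------------------------------------------------------------------

def read_tag_bed(path: str | Path, fragment_length: int | None = None,
                 stranded: bool = True) -> TagLibrary:
    """Read a BED6 tag file; the tag is the read's 5' end by BED convention.

    5' end = start for '+' records, end - 1 for '-' records. Malformed lines
    are rejected with their line number.
    """
    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if not (0 <= start < end):
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            chroms.append(f[0])
            pos.append(start if strand == "+" else end - 1)
            strands.append(strand)
            lengths.append(end - start)
    read_length = int(np.median(lengths)) if lengths else 1
    tags = pd.DataFrame({"chrom": chroms, "pos": np.array(pos, dtype=np.int64),
                         "strand": strands})
    return TagLibrary(tags, read_length=read_length, fragment_length=fragment_length,
                      stranded=stranded)


def write_tag_bed(lib: TagLibrary, path: str | Path) -> None:
    t = lib.tags
    rl = lib.read_length
    pos = t["pos"].to_numpy()
    start = np.where(t["strand"].to_numpy() == "+", pos, pos - rl + 1)
    out = pd.DataFrame({
        "chrom": t["chrom"], "start": start, "end": start + rl,
        "name": [f"t{i}" for i in range(len(t))], "score": 1, "strand": t["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(lib: TagLibrary, path: str | Path,
                   target: float = NORMALIZATION_TARGET) -> None:
    """Normalized per-position 5'-end coverage as a bedGraph track."""
    w = normalize_library(lib, target)
    with open(path, "w") as fh:
        for chrom in sorted(lib.tags["chrom"].unique()):
            p = lib.positions(chrom)
            uniq, counts = np.unique(p, return_counts=True)
            for u, c in zip(uniq, counts):
                fh.write(f"{chrom}\t{u}\t{u + 1}\t{c * w:.4f}\n")


# -- normalization and shifting ----------------------------------------------

def normalize_library(lib: TagLibrary, target: float = NORMALIZATION_TARGET) -> float:
    """Per-tag weight so the weighted library mass equals ``target``."""
    if lib.total_mapped == 0:
        raise ValueError("cannot normalize an empty library (total_mapped = 0)")
    return target / lib.total_mapped


def shift_tags(lib: TagLibrary) -> TagLibrary:
    """Shift each tag by half the fragment length toward the fragment center.

    '+' tags move downstream by floor(fragment_length / 2), '-' tags upstream
    by the same amount. Intended for ChIP libraries only.
    """
    if lib.fragment_length is None:
        raise ValueError("fragment_length unset; required to shift ChIP tags")
    half = lib.fragment_length // 2
    t = lib.tags.copy()
    sign = np.where(t["strand"].to_numpy() == "+", 1, -1)
    t["pos"] = t["pos"].to_numpy() + half * sign
    return TagLibrary(t, read_length=lib.read_length,
                      fragment_length=lib.fragment_length, stranded=lib.stranded)


# -- counting ----------------------------------------------------------------

def _sense_strand(gene: GeneModel, sense_only: bool) -> str | None:
    return gene.strand if sense_only else None


def promoter_tag_count(lib: TagLibrary, gene: GeneModel, window: int = 1000,
                       target: float = NORMALIZATION_TARGET, sense_only: bool = False,
                       assay: str = "", condition: str = "") -> PromoterCount:
    """Weighted tag count within ``window`` bp of the TSS (inclusive both ends)."""
    if window <= 0:
        raise ValueError("promoter window must be positive")
    w = normalize_library(lib, target)
    raw = lib.count_in(gene.chrom, gene.tss - window, gene.tss + window + 1,
                       strand=_sense_strand(gene, sense_only))
    return PromoterCount(gene.gene_id, assay, condition, raw * w, raw, window)


def tss_profile(lib: TagLibrary, genes: Sequence[GeneModel], span: int = 2000,
                bin_size: int = 25, target: float = NORMALIZATION_TARGET,
                sense_only: bool = False) -> DensityProfile:
    """Cumulative gene-oriented tag density around the TSS, in per-bp units.

    Offsets cover [-span, span) in ``bin_size`` bins; minus-strand genes are
    mirrored so downstream is always positive.
    """
    if (2 * span) % bin_size != 0:
        raise ValueError(f"bin size {bin_size} does not divide profile range {2 * span}")
    n_bins = 2 * span // bin_size
    w = normalize_library(lib, target)
    counts = np.zeros(n_bins, dtype=np.int64)
    for gene in genes:
        strand = _sense_strand(gene, sense_only)
        lo, hi = gene.window_to_genomic(-span, span)
        p = lib.positions(gene.chrom, strand)
        sel = p[np.searchsorted(p, lo):np.searchsorted(p, hi)]
        if len(sel) == 0:
            continue
        off = gene.offset_of(sel)
        counts += np.bincount((off + span) // bin_size, minlength=n_bins)
    offsets = np.arange(-span, span, bin_size)
    return DensityProfile(offsets, counts * w / bin_size, bin_size, len(genes))


def gene_body_density(lib: TagLibrary, gene: GeneModel, sense_only: bool = False,
                      target: float = NORMALIZATION_TARGET) -> float:
    """Weighted tag density over [tx_start, tx_end), in tags per kb."""
    if gene.span <= 0:
        raise ValueError(f"{gene.gene_id}: zero-length gene")
    w = normalize_library(lib, target)
    raw = lib.count_in(gene.chrom, gene.tx_start, gene.tx_end,
                       strand=_sense_strand(gene, sense_only))
    return raw * w / (gene.span / 1000.0)


@dataclass
class ExonIntronDensity:
    """Sense-strand exon and intron tag densities, per kb (weighted), with raw counts."""

    gene_id: str
    exon_density: float
    intron_density: float | None        # None for single-exon genes
    exon_raw: int
    intron_raw: int
    exon_length: int
    intron_length: int

    @property
    def exon_raw_per_kb(self) -> float:
        return self.exon_raw / (self.exon_length / 1000.0)

    @property
    def intron_raw_per_kb(self) -> float | None:
        if self.intron_length == 0:
            return None
        return self.intron_raw / (self.intron_length / 1000.0)


def exon_intron_density(lib: TagLibrary, gene: GeneModel,
                        target: float = NORMALIZATION_TARGET) -> ExonIntronDensity:
    """Strand-specific exon/intron densities from unshifted 5'-end positions."""
    if not lib.stranded:
        raise ValueError("exon/intron densities require a stranded library")
    w = normalize_library(lib, target)
    exon_raw = sum(lib.count_in(gene.chrom, s, e, strand=gene.strand)
                   for s, e in gene.exons)
    intron_raw = sum(lib.count_in(gene.chrom, s, e, strand=gene.strand)
                     for s, e in gene.introns)
    exon_len, intron_len = gene.exon_length, gene.intron_length
    exon_density = exon_raw * w / (exon_len / 1000.0)
    intron_density = (intron_raw * w / (intron_len / 1000.0)) if intron_len > 0 else None
    return ExonIntronDensity(gene.gene_id, exon_density, intron_density,
                             exon_raw, intron_raw, exon_len, intron_len)


def rpkm(lib: TagLibrary, gene: GeneModel, sense_only: bool = False) -> float:
    """Raw reads per kb of gene body per million mapped tags."""
    if gene.span <= 0:
        raise ValueError(f"{gene.gene_id}: zero-length gene")
    if lib.total_mapped == 0:
        raise ValueError("empty library")
    raw = lib.count_in(gene.chrom, gene.tx_start, gene.tx_end,
                       strand=_sense_strand(gene, sense_only))
    return raw / (gene.span / 1000.0) / (lib.total_mapped / 1e6)


def write_profile_tsv(profile: DensityProfile, path: str | Path) -> None:
    pd.DataFrame({"offset": profile.offsets, "density": profile.density}).to_csv(
        path, sep="\t", index=False
    )
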