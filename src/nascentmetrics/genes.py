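"""Gene models and annotation I/O.

All coordinates are 0-based, half-open internally (BED native). GTF is
converted on read/write (1-based, closed). Gene-oriented offsets place the
TSS at 0 with downstream positive along the gene strand.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene model: transcript span plus exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"{self.gene_id}: invalid span [{self.tx_start}, {self.tx_end})")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon [{s}, {e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(f"{self.gene_id}: exons must cover the transcript ends")

    # -- geometry ---------------------------------------------------------
    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (0-based)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def orient(self) -> int:
        return 1 if self.strand == "+" else -1

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_length(self) -> int:
        return sum(e - s for s, e in self.introns)

    def offset_of(self, pos):
        """Gene-oriented offset of genomic position(s) relative to the TSS."""
        return (np.asarray(pos) - self.tss) * self.orient

    def offset_to_genomic(self, offset):
        return self.tss + np.asarray(offset) * self.orient

    def window_to_genomic(self, start: int, end: int) -> Interval:
        """Genomic half-open interval covering gene-oriented offsets [start, end)."""
        if self.strand == "+":
            return self.tss + start, self.tss + end
        return self.tss - end + 1, self.tss - start + 1

    def splice_junctions_5p(self) -> tuple[int, ...]:
        """Genomic coordinates of the first intronic base of each 5' splice junction.

        Returned in gene orientation (first junction transcribed first).
        """
        if self.strand == "+":
            return tuple(s for s, _ in self.introns)
        return tuple(e - 1 for _, e in reversed(self.introns))

    def transcript_to_genomic(self, t) -> np.ndarray:
        """Map transcript coordinates (0 = TSS base, spliced) to genomic positions."""
        t = np.asarray(t, dtype=np.int64)
        lengths = np.array([e - s for s, e in self.exons], dtype=np.int64)
        if self.strand == "-":
            lengths = lengths[::-1]
        cum = np.concatenate([[0], np.cumsum(lengths)])
        if np.any((t < 0) | (t >= cum[-1])):
            raise ValueError(f"{self.gene_id}: transcript coordinate out of range")
        idx = np.searchsorted(cum, t, side="right") - 1
        within = t - cum[idx]
        if self.strand == "+":
            starts = np.array([s for s, _ in self.exons], dtype=np.int64)
            return starts[idx] + within
        ends = np.array([e for _, e in reversed(self.exons)], dtype=np.int64)
        return ends[idx] - 1 - within


# -- BED12 ----------------------------------------------------------------

def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 line ({exc})") from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


# -- GTF ------------------------------------------------------------------

def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "nascentmetrics") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Minimal GTF reader: collects exon features grouped by gene_id."""
    import re

    by_gene: dict[str, dict] = {}
    attr_re = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GTF requires 9 columns")
            if f[2] != "exon":
                continue
            m = attr_re.search(f[8])
            if m is None:
                raise ValueError(f"{path}:{lineno}: exon feature lacks gene_id attribute")
            rec = by_gene.setdefault(
                m.group(1), {"chrom": f[0], "strand": f[6], "exons": []}
            )
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    genes = []
    for gid, rec in by_gene.items():
        exons = tuple(sorted(rec["exons"]))
        genes.append(
            GeneModel(gid, rec["chrom"], rec["strand"], exons[0][0], exons[-1][1], exons)
        )
    return genes


def check_non_overlapping(genes: Sequence[GeneModel]) -> None:
    """Raise if any two gene spans overlap (either strand, same chromosome)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.tx_start)
        for a, b in zip(gs, gs[1:]):
            if b.tx_start < a.tx_end:
                raise ValueError(f"genes {a.gene_id} and {b.gene_id} overlap on {chrom}")
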