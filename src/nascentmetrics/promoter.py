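"""Promoter sequence analysis: GC content, CAGE TSS refinement, TATA scanning,
and known-motif enrichment.

Promoter sequences are extracted gene-oriented (reverse-complemented for
minus-strand genes) over a configurable window, default [-500, +100) around
the TSS — the same window used for motif analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genes import GeneModel
from .tags import TagLibrary

PROMOTER_WINDOW = (-500, 100)
TATA_WINDOW = (-35, -20)       # inclusive motif-start offsets from the TSS
TATA_CONSENSUS = "TATAWAWR"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def consensus_matches(seq: str, consensus: str = TATA_CONSENSUS) -> list[int]:
    """Start positions (0-based) of every IUPAC-consensus match in ``seq``."""
    k = len(consensus)
    sets = [_IUPAC[c] for c in consensus.upper()]
    seq = seq.upper()
    return [
        i for i in range(len(seq) - k + 1)
        if all(seq[i + j] in sets[j] for j in range(k))
    ]


def extract_promoter_seq(genome: Mapping[str, str], gene: GeneModel,
                         window: tuple[int, int] = PROMOTER_WINDOW,
                         tss: int | None = None) -> str:
    """Gene-oriented promoter sequence over the half-open offset window."""
    if tss is None:
        tss = gene.tss
    a, b = window
    if gene.strand == "+":
        lo, hi = tss + a, tss + b
    else:
        lo, hi = tss - b + 1, tss - a + 1
    contig = genome[gene.chrom]
    if lo < 0 or hi > len(contig):
        raise ValueError(
            f"{gene.gene_id}: promoter window [{lo}, {hi}) extends past contig edge")
    seq = str(contig[lo:hi])
    return seq if gene.strand == "+" else reverse_complement(seq)


@dataclass
class GcRecord:
    gene_id: str
    gc: float
    window: tuple[int, int]


def promoter_gc(genome: Mapping[str, str], gene: GeneModel,
                window: tuple[int, int] = PROMOTER_WINDOW) -> GcRecord:
    """Promoter GC fraction; ambiguous bases excluded from both counts."""
    seq = extract_promoter_seq(genome, gene, window).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError(f"{gene.gene_id}: promoter window has no unambiguous bases")
    return GcRecord(gene.gene_id, gc / (gc + at), window)


def optimal_gc_cutoff(gc_a: Sequence[float], gc_b: Sequence[float]) -> tuple[float, float]:
    """Threshold (among observed values) maximizing |P(a > t) - P(b > t)|.

    Ties are broken toward the smallest threshold. Returns (cutoff,
    discrimination).
    """
    a = np.asarray(gc_a, dtype=float)
    b = np.asarray(gc_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both GC sets must be non-empty")
    best_t, best_d = math.nan, -1.0
    for t in np.unique(np.concatenate([a, b])):
        d = abs(np.mean(a > t) - np.mean(b > t))
        if d > best_d:
            best_t, best_d = float(t), float(d)
    return best_t, best_d


@dataclass
class RefinedTSS:
    gene_id: str
    cluster_start: int        # genomic bp of the 100-bp max-density window
    cluster_end: int
    refined_tss: int          # genomic bp
    cluster_tag_count: float
    refined: bool             # False when the gene had no CAGE tags


def refine_tss_from_cage(cage: TagLibrary, gene: GeneModel, flank: int = 1000,
                         cluster_width: int = 100) -> RefinedTSS:
    """Refine the annotated TSS from CAGE 5'-end tags.

    Sense-strand tags within ``flank`` bp of the annotated TSS (inclusive) are
    collected; the ``cluster_width``-bp window with the most tags (1-bp steps)
    is the primary TSS cluster, and the single bp with the most tags inside it
    becomes the refined TSS. Ties go to the 5'-most window, then the 5'-most
    bp, in gene orientation. Genes without tags keep the annotated TSS.
    """
    if not cage.stranded:
        raise ValueError("CAGE refinement requires a stranded library")
    p = cage.positions(gene.chrom, strand=gene.strand)
    lo, hi = gene.tss - flank, gene.tss + flank + 1
    sel = p[np.searchsorted(p, lo):np.searchsorted(p, hi)]
    if len(sel) == 0:
        return RefinedTSS(gene.gene_id, gene.tss, gene.tss + 1, gene.tss, 0.0, False)
    off = gene.offset_of(sel) + flank            # 0 .. 2*flank
    counts = np.bincount(off, minlength=2 * flank + 1)
    window_sums = np.convolve(counts, np.ones(cluster_width, dtype=np.int64), "valid")
    best_start = int(np.argmax(window_sums))     # 5'-most on ties (argmax rule)
    inside = counts[best_start:best_start + cluster_width]
    best_bp = best_start + int(np.argmax(inside))
    refined_genomic = int(gene.offset_to_genomic(best_bp - flank))
    win_lo = int(gene.offset_to_genomic(best_start - flank))
    win_hi = int(gene.offset_to_genomic(best_start - flank + cluster_width - 1))
    cluster_start, cluster_end = min(win_lo, win_hi), max(win_lo, win_hi) + 1
    return RefinedTSS(gene.gene_id, cluster_start, cluster_end, refined_genomic,
                      float(window_sums[best_start]), True)


@dataclass
class Pwm:
    """Position weight matrix as per-position log-odds over A, C, G, T."""

    motif_id: str
    matrix: np.ndarray            # shape (length, 4), log-odds vs background
    score_threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4) over A,C,G,T")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def scores(self, seq: str) -> np.ndarray:
        """Log-odds score at every start position (NaN where ambiguous bases)."""
        idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        code = np.full(idx.shape, -1, dtype=np.int8)
        for i, base in enumerate(b"ACGT"):
            code[idx == base] = i
        k = self.length
        n = len(seq) - k + 1
        if n <= 0:
            return np.empty(0)
        out = np.zeros(n)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            c = code[j:j + n]
            ok = c >= 0
            valid &= ok
            out[ok] += self.matrix[j, c[ok]]
        out[~valid] = np.nan
        return out


def read_jaspar(path, pseudocount: float = 0.5, threshold_fraction: float = 0.8) -> list[Pwm]:
    """Read JASPAR-format count matrices into log-odds PWMs (uniform background).

    ``score_threshold`` defaults to ``threshold_fraction`` of the maximum
    achievable score of each matrix.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        logodds = np.log2(probs / 0.25)
        pwm = Pwm(m.matrix_id or m.name, logodds, 0.0)
        pwm.score_threshold = threshold_fraction * pwm.max_score
        pwms.append(pwm)
    return pwms


@dataclass
class TataHit:
    gene_id: str
    hit: bool
    position: int | None          # motif start, bp relative to TSS
    score: float
    site: str


def scan_tata(genome: Mapping[str, str], gene: GeneModel,
              window: tuple[int, int] = TATA_WINDOW,
              consensus: str = TATA_CONSENSUS, pwm: Pwm | None = None,
              tss: int | None = None) -> TataHit:
    """Positional TATA scan: best motif match starting within ``window``.

    ``window`` bounds are inclusive motif-start offsets on the sense strand.
    With a consensus (default TATAWAWR) a hit is an exact degenerate-code
    match; with a ``pwm``, any position scoring at or above its threshold.
    """
    a, b = window
    k = pwm.length if pwm is not None else len(consensus)
    seq = extract_promoter_seq(genome, gene, (a, b + k), tss=tss)
    if pwm is not None:
        sc = pwm.scores(seq)
        sc = sc[: b - a + 1]
        if len(sc) == 0 or not np.any(sc >= pwm.score_threshold):
            return TataHit(gene.gene_id, False, None, float("-inf"), "")
        i = int(np.nanargmax(sc))
        return TataHit(gene.gene_id, True, a + i, float(sc[i]), seq[i:i + k])
    hits = [i for i in consensus_matches(seq, consensus) if i <= b - a]
    if not hits:
        return TataHit(gene.gene_id, False, None, 0.0, "")
    i = hits[0]
    return TataHit(gene.gene_id, True, a + i, 1.0, seq[i:i + k])


@dataclass
class EnrichmentReport:
    motif_id: str
    n_foreground: int
    n_background: int
    hits_foreground: int
    hits_background: int
    fraction_foreground: float
    fraction_background: float
    p_value: float


def motif_enrichment(foreground: Sequence[GeneModel], background: Sequence[GeneModel],
                     pwm: Pwm, genome: Mapping[str, str],
                     region: tuple[int, int] = PROMOTER_WINDOW) -> EnrichmentReport:
    """ZOOPS known-motif enrichment of foreground over background promoters.

    Presence = best hit at or above the PWM threshold anywhere in the region
    (zero-or-one occurrence per sequence). The p-value is the exact
    hypergeometric upper tail on the foreground hit count given the pooled
    hit count.
    """
    if len(foreground) == 0:
        raise ValueError("foreground gene set is empty")

    def has_hit(gene: GeneModel) -> bool:
        sc = pwm.scores(extract_promoter_seq(genome, gene, region))
        return bool(len(sc) and np.nanmax(sc) >= pwm.score_threshold)

    kf = sum(has_hit(g) for g in foreground)
    kb = sum(has_hit(g) for g in background)
    nf, nb = len(foreground), len(background)
    # population nf+nb promoters, kf+kb hits, nf draws, >= kf successes
    p = float(stats.hypergeom.sf(kf - 1, nf + nb, kf + kb, nf))
    return EnrichmentReport(pwm.motif_id, nf, nb, kf, kb,
                            kf / nf, kb / nb if nb else math.nan, p)
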