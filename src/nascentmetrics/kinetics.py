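"""Kinetic gene classification and induced-gene calling.

Genes are classified from three-timepoint expression (0 h, 1 h, 12 h after
TLR4 stimulation):

  * immediate/early (IE): induced more than 3-fold at 1 h;
  * late: induced less than 1.2-fold at 1 h but more than 4-fold at 12 h;
  * other: everything else.

All inequalities are strict, so a gene at exactly 3-fold (or exactly
1.2-fold) is not IE (not late).

Induced-gene calling from paired GRO-Seq libraries uses depth-normalized
sense gene-body counts: fold change with a 0.5 pseudocount on both raw
counts, a conditional binomial test on the raw count split (expected split
given the two library depths), Benjamini-Hochberg correction across genes,
and the filters fold change > 3, treated RPKM > 0.25, q < 0.10.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genes import GeneModel
from .tags import TagLibrary, rpkm

KineticClass = str  # 'IE' | 'late' | 'other'


@dataclass
class ExpressionRecord:
    gene_id: str
    expr_0h: float
    expr_1h: float
    expr_12h: float

    @property
    def fc_1h(self) -> float:
        return self.expr_1h / self.expr_0h

    @property
    def fc_12h(self) -> float:
        return self.expr_12h / self.expr_0h


def classify_kinetics(expr_0h: float, expr_1h: float, expr_12h: float) -> KineticClass:
    """Assign IE / late / other from a three-timepoint expression triplet."""
    if expr_0h <= 0:
        raise ValueError("basal expression must be positive")
    fc_1h = expr_1h / expr_0h
    fc_12h = expr_12h / expr_0h
    if fc_1h > 3.0:
        return "IE"
    if fc_1h < 1.2 and fc_12h > 4.0:
        return "late"
    return "other"


def classify_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add fold changes and kinetic_class columns to an expression table."""
    out = table.copy()
    out["fc_1h"] = out["expr_1h"] / out["expr_0h"]
    out["fc_12h"] = out["expr_12h"] / out["expr_0h"]
    out["kinetic_class"] = [
        classify_kinetics(a, b, c)
        for a, b, c in zip(out["expr_0h"], out["expr_1h"], out["expr_12h"])
    ]
    return out


def call_induced_genes(gro_basal: TagLibrary, gro_treated: TagLibrary,
                       genes: Sequence[GeneModel], fold_threshold: float = 3.0,
                       rpkm_min: float = 0.25, q_max: float = 0.10,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Call genes induced between two GRO-Seq libraries from gene-body counts."""
    for lib, name in ((gro_basal, "basal"), (gro_treated, "treated")):
        if not lib.stranded:
            raise ValueError(f"{name} library must be stranded")
        if lib.total_mapped == 0:
            raise ValueError(f"{name} library has zero mapped tags")
    db, dt = gro_basal.total_mapped, gro_treated.total_mapped
    p_null = dt / (db + dt)
    rows = []
    for g in genes:
        nb = gro_basal.count_in(g.chrom, g.tx_start, g.tx_end, strand=g.strand)
        nt = gro_treated.count_in(g.chrom, g.tx_start, g.tx_end, strand=g.strand)
        fc = ((nt + pseudocount) / dt) / ((nb + pseudocount) / db)
        n = nb + nt
        p = stats.binom.sf(nt - 1, n, p_null) if n > 0 else 1.0
        rows.append((g.gene_id, nb, nt, fc, float(p),
                     rpkm(gro_basal, g, sense_only=True),
                     rpkm(gro_treated, g, sense_only=True)))
    out = pd.DataFrame(rows, columns=["gene_id", "count_basal", "count_treated",
                                      "fold_change", "p_value", "rpkm_basal",
                                      "rpkm_treated"])
    _, qvals, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["fdr_q"] = qvals
    out["induced"] = ((out["fold_change"] > fold_threshold)
                      & (out["rpkm_treated"] > rpkm_min)
                      & (out["fdr_q"] < q_max))
    return out


def overlap_by_genotype(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                        fold_threshold: float = 3.0,
                        unresponsive_below: float = 2.0) -> dict:
    """Bin the induced genes of A by their fold change in B.

    Bins partition A's induced set: also induced (B fold change > 3),
    unresponsive (B fold change < 2 or not evaluable in B), and the
    intermediate [2, 3] band.
    """
    b = calls_b.set_index("gene_id")
    induced_a = calls_a[calls_a["induced"]]
    missing = set(induced_a["gene_id"]) - set(b.index)
    if missing:
        raise ValueError(f"gene universes differ: {sorted(missing)[:5]} absent from B")
    also, unresponsive, intermediate = 0, 0, 0
    for gid in induced_a["gene_id"]:
        fc = b.at[gid, "fold_change"]
        if not np.isfinite(fc) or fc < unresponsive_below:
            unresponsive += 1
        elif fc > fold_threshold:
            also += 1
        else:
            intermediate += 1
    return {"n_induced_a": int(len(induced_a)), "also_induced_in_b": also,
            "unresponsive_in_b": unresponsive, "intermediate_in_b": intermediate}


def tss_proximal_binding(peaks: pd.DataFrame, genes: Sequence[GeneModel],
                         radius: int = 500) -> tuple[pd.DataFrame, float]:
    """Flag genes with a peak center within ``radius`` bp of the TSS (inclusive).

    ``peaks`` needs columns chrom, start, end; the peak position is the
    interval midpoint. Returns the per-gene flag table and the flagged
    fraction of the query set.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    centers: dict[str, np.ndarray] = {}
    for chrom, grp in peaks.groupby("chrom"):
        centers[chrom] = np.sort(
            ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
        )
    rows = []
    for g in genes:
        c = centers.get(g.chrom)
        if c is None:
            hit = False
        else:
            lo = np.searchsorted(c, g.tss - radius)
            hi = np.searchsorted(c, g.tss + radius, side="right")
            hit = hi > lo
        rows.append((g.gene_id, bool(hit)))
    table = pd.DataFrame(rows, columns=["gene_id", "tss_proximal"])
    fraction = float(table["tss_proximal"].mean()) if len(table) else 0.0
    return table, fraction


def read_peak_bed(path) -> pd.DataFrame:
    """Read peak intervals from a BED file (first three columns used)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED requires 3 columns")
            rows.append((f[0], int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
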