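"""Enhancer-target assignment and direction-coordinated enhancer-gene pairs.

Targets are assigned two ways: a basal-plus-extension regulatory-domain model
(nearest-gene style: a basal window around each TSS, extended up to 1 Mb but
never past a neighbour's basal region), and chromatin-loop anchors connecting
an enhancer to a gene's promoter.  Candidate pairs whose enhancer RPM and
gene expression move strictly in the same direction at both timepoint steps
are called coordinated (up or down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .catalog import ElementCatalog, ElementRecord, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "DETable",
    "RegulatoryDomain",
    "LoopSet",
    "PairRecord",
    "consistent_de_genes",
    "build_domains",
    "assign_by_domain",
    "assign_by_loops",
    "coordinated_pairs",
    "read_de_table",
    "read_loops",
]


@dataclass
class DETable:
    """Differential-expression results for one contrast against baseline."""

    contrast: str
    rows: dict[str, tuple[float, float]]  # gene_id -> (log2fc, fdr)

    def __post_init__(self) -> None:
        for g, (_, fdr) in self.rows.items():
            if not (0.0 <= fdr <= 1.0):
                raise ValueError(f"gene {g}: FDR {fdr} out of [0, 1]")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    domain: GenomicInterval


@dataclass
class LoopSet:
    loops: list[tuple[GenomicInterval, GenomicInterval]]


@dataclass(frozen=True)
class PairRecord:
    enhancer_id: str
    gene_id: str
    evidence: Literal["domain", "loop", "both"]
    direction: Literal["up", "down", None] = None


def consistent_de_genes(
    de_8v0: DETable,
    de_16v0: DETable,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Genes passing |log2FC| > lfc_min and FDR < fdr_max in BOTH contrasts,
    with the same sign; returns (up, down).  A gene absent from either table
    fails that contrast."""
    up: set[str] = set()
    down: set[str] = set()
    for gene, (lfc_a, fdr_a) in de_8v0.rows.items():
        if gene not in de_16v0.rows:
            continue
        lfc_b, fdr_b = de_16v0.rows[gene]
        if fdr_a < fdr_max and fdr_b < fdr_max:
            if lfc_a > lfc_min and lfc_b > lfc_min:
                up.add(gene)
            elif lfc_a < -lfc_min and lfc_b < -lfc_min:
                down.add(gene)
    return up, down


def build_domains(
    genes: Sequence[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    Each gene's basal region spans basal_up bp upstream to basal_down bp
    downstream of its TSS (strand-oriented).  The basal region is then
    extended on both sides up to ``max_ext`` bp, stopping at the nearest
    neighbouring basal-region boundary and the chromosome edge.  Domains may
    overlap only where basal regions themselves overlap.
    """
    basal: list[tuple[GeneModel, int, int]] = []
    for g in genes:
        tss = g.tss
        if g.interval.strand == "+":
            lo, hi = tss - basal_up, tss + basal_down
        else:
            lo, hi = tss - basal_down + 1, tss + basal_up + 1
        lo = max(lo, 0)
        size = chrom_sizes.get(g.interval.chrom) if chrom_sizes else None
        if size is not None:
            hi = min(hi, size)
        basal.append((g, lo, hi))

    by_chrom: dict[str, list[tuple[GeneModel, int, int]]] = {}
    for rec in basal:
        by_chrom.setdefault(rec[0].interval.chrom, []).append(rec)

    out: list[RegulatoryDomain] = []
    for chrom, recs in by_chrom.items():
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        for i, (g, lo, hi) in enumerate(recs):
            left_bound = 0
            right_bound = size if size is not None else None
            for j, (_, olo, ohi) in enumerate(recs):
                if j == i:
                    continue
                if ohi <= lo:
                    left_bound = max(left_bound, ohi)
                elif olo < lo < ohi:  # neighbour basal overhangs on the left
                    left_bound = max(left_bound, lo)
                if olo >= hi:
                    right_bound = olo if right_bound is None else min(right_bound, olo)
                elif olo < hi < ohi:  # neighbour basal overhangs on the right
                    right_bound = hi if right_bound is None else min(right_bound, hi)
            ext_lo = max(lo - max_ext, left_bound, 0)
            ext_hi = hi + max_ext
            if right_bound is not None:
                ext_hi = min(ext_hi, right_bound)
            out.append(
                RegulatoryDomain(g.gene_id, GenomicInterval(chrom, ext_lo, ext_hi, id=g.gene_id))
            )
    return out


def assign_by_domain(
    enhancer: ElementRecord, domains: Sequence[RegulatoryDomain]
) -> list[str]:
    """All genes whose regulatory domain contains the enhancer midpoint."""
    mid = enhancer.interval.midpoint
    chrom = enhancer.interval.chrom
    return sorted(
        d.gene_id
        for d in domains
        if d.domain.chrom == chrom and d.domain.start <= mid < d.domain.end
    )


def assign_by_loops(
    enhancers: ElementCatalog | Sequence[ElementRecord],
    promoters: Sequence[ElementRecord],
    promoter_gene: Mapping[str, str],
    loops: LoopSet,
) -> list[PairRecord]:
    """Pairs supported by a loop: one anchor over the enhancer (>= 1 bp), the
    other over the target gene's promoter.  Duplicates are collapsed."""
    enh_list = list(enhancers)
    etrees: dict[str, IntervalTree] = {}
    for e in enh_list:
        etrees.setdefault(e.interval.chrom, IntervalTree()).addi(
            e.interval.start, e.interval.end, e.id
        )
    ptrees: dict[str, IntervalTree] = {}
    for p in promoters:
        gene = promoter_gene.get(p.id)
        if gene is None:
            continue
        ptrees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, gene
        )

    def hits(trees: dict[str, IntervalTree], anchor: GenomicInterval) -> set[str]:
        t = trees.get(anchor.chrom)
        if t is None:
            return set()
        return {iv.data for iv in t.overlap(anchor.start, anchor.end)}

    found: set[tuple[str, str]] = set()
    for a1, a2 in loops.loops:
        for enh_anchor, prom_anchor in ((a1, a2), (a2, a1)):
            for eid in hits(etrees, enh_anchor):
                for gene in hits(ptrees, prom_anchor):
                    found.add((eid, gene))
    return [PairRecord(e, g, "loop") for e, g in sorted(found)]


def coordinated_pairs(
    pairs: Sequence[PairRecord],
    enh_rpm: Mapping[str, Sequence[float]],
    gene_expr: Mapping[str, Sequence[float]],
    eps: float = 0.0,
) -> list[PairRecord]:
    """Keep pairs whose enhancer and gene move strictly together at both steps.

    Down: v0 - v1 > eps and v1 - v2 > eps for both members; up symmetric.
    Pairs with a member missing from the expression maps are dropped with a
    logged reason.
    """

    def direction(triple: Sequence[float]) -> str | None:
        v0, v1, v2 = triple
        if v0 - v1 > eps and v1 - v2 > eps:
            return "down"
        if v1 - v0 > eps and v2 - v1 > eps:
            return "up"
        return None

    out: list[PairRecord] = []
    for pr in pairs:
        e_triple = enh_rpm.get(pr.enhancer_id)
        g_triple = gene_expr.get(pr.gene_id)
        if e_triple is None or g_triple is None:
            logger.info(
                "pair (%s, %s) dropped: missing %s expression",
                pr.enhancer_id,
                pr.gene_id,
                "enhancer" if e_triple is None else "gene",
            )
            continue
        d_e, d_g = direction(e_triple), direction(g_triple)
        if d_e is not None and d_e == d_g:
            out.append(PairRecord(pr.enhancer_id, pr.gene_id, pr.evidence, d_e))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_de_table(path: str | Path, contrast: str) -> DETable:
    """TSV with columns gene_id, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    rows = {r.gene_id: (float(r.log2fc), float(r.fdr)) for r in df.itertuples()}
    return DETable(contrast, rows)


def read_loops(path: str | Path) -> LoopSet:
    """Six-column BEDPE-like TSV: chrom1 start1 end1 chrom2 start2 end2."""
    loops = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            loops.append(
                (
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                )
            )
    return LoopSet(loops)
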