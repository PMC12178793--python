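"""Element catalog curation: BED reading, enhancer exclusion, distal/proximal classes.

Candidate enhancers are screened against gene bodies (extended by a pad on
both sides, 1 kb by default) and a signal-artifact blacklist; survivors are
split into *proximal* (1-2 kb upstream of the nearest TSS) and *distal*
(>2 kb upstream) enhancers.  Promoters are strand-annotated by nearest TSS.

Coordinates follow the BED convention throughout: 0-based, half-open,
overlap means at least one shared base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from intervaltree import IntervalTree

Strand = Literal["+", "-", "."]

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ElementRecord",
    "ElementCatalog",
    "read_bed",
    "read_genes",
    "filter_enhancers",
    "classify_enhancer_distance",
    "annotate_promoter_strand",
    "build_catalog",
    "write_catalog",
    "read_catalog",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open chromosome span with optional strand and id."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a mandatory strand; the TSS is derived from it."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded (+ or -)")

    @property
    def tss(self) -> int:
        """Transcription start: interval start on +, end-1 on -."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class ElementRecord:
    """A promoter or enhancer; enhancers additionally carry distal/proximal."""

    interval: GenomicInterval
    element_class: Literal["promoter", "enhancer"]
    subclass: Literal["distal", "proximal", "not_applicable"] = "not_applicable"

    def __post_init__(self) -> None:
        if self.element_class != "enhancer" and self.subclass != "not_applicable":
            raise ValueError("subclass is only meaningful for enhancers")

    @property
    def id(self) -> str:
        eid = self.interval.id
        if eid is None:
            raise ValueError("element has no id")
        return eid


@dataclass
class ElementCatalog:
    """The curated element set plus a free-text provenance note."""

    elements: list[ElementRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise ValueError("element ids must be unique within a catalog")

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def subset(self, element_class: str) -> list[ElementRecord]:
        return [e for e in self.elements if e.element_class == element_class]

    @property
    def enhancers(self) -> list[ElementRecord]:
        return self.subset("enhancer")

    @property
    def promoters(self) -> list[ElementRecord]:
        return self.subset("promoter")


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str | Path, stranded: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 (extra columns ignored) into intervals, file order kept.

    Track and comment lines (``track``, ``browser``, ``#``) are skipped.
    Malformed coordinates raise with the offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand: Strand = "."
            if stranded and len(fields) > 5 and fields[5] in ("+", "-"):
                strand = fields[5]  # type: ignore[assignment]
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from TSV (gene_id, chrom, start, end, strand) or BED6."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if lineno == 1 and f[0] in ("gene_id", "gene"):
                continue  # header
            if len(f) >= 6 and f[5] in ("+", "-"):  # BED6: chrom start end name score strand
                chrom, start, end, gid, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            elif len(f) >= 5:  # TSV: gene_id chrom start end strand
                gid, chrom, start, end, strand = f[0], f[1], int(f[2]), int(f[3]), f[4]
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized gene line")
            genes.append(
                GeneModel(gid, GenomicInterval(chrom, start, end, strand, gid))  # type: ignore[arg-type]
            )
    return genes


# ---------------------------------------------------------------------------
# Curation operations


def _tree_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def filter_enhancers(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    blacklist: Sequence[GenomicInterval],
    pad: int = 1000,
) -> tuple[list[GenomicInterval], list[tuple[GenomicInterval, str]]]:
    """Drop enhancers over padded gene bodies or blacklist regions.

    An enhancer is removed iff it overlaps (>= 1 bp) any gene interval
    extended by ``pad`` bp on both sides (a coding-region proxy spanning TSS
    to TES), or any blacklist interval.  Returns ``(kept, removed)`` where
    each removed record carries a reason, ``coding_overlap`` or ``blacklist``;
    the two lists partition the input exactly.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    gene_trees = _tree_by_chrom(
        GenomicInterval(g.interval.chrom, max(0, g.interval.start - pad), g.interval.end + pad)
        for g in genes
    )
    black_trees = _tree_by_chrom(blacklist)
    kept: list[GenomicInterval] = []
    removed: list[tuple[GenomicInterval, str]] = []
    for enh in enhancers:
        gt = gene_trees.get(enh.chrom)
        bt = black_trees.get(enh.chrom)
        if gt is not None and gt.overlaps(enh.start, enh.end):
            removed.append((enh, "coding_overlap"))
        elif bt is not None and bt.overlaps(enh.start, enh.end):
            removed.append((enh, "blacklist"))
        else:
            kept.append(enh)
    return kept, removed


def classify_enhancer_distance(
    enhancer: GenomicInterval, genes: Sequence[GeneModel]
) -> Literal["proximal", "distal", "excluded"]:
    """Classify an enhancer by its upstream distance to the nearest TSS.

    The reference point is the enhancer midpoint.  Among genes that have the
    midpoint on their upstream side (midpoint < TSS for + genes, > TSS for -),
    take the minimum |TSS - midpoint|; if no gene has the enhancer upstream,
    fall back to the unsigned distance to the nearest TSS.  Distances in
    (1000, 2000] are proximal, > 2000 distal, <= 1000 excluded.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    mid = enhancer.midpoint
    upstream: list[int] = []
    anywhere: list[int] = []
    for g in genes:
        if g.interval.chrom != enhancer.chrom:
            continue
        d = abs(g.tss - mid)
        anywhere.append(d)
        if (g.interval.strand == "+" and mid < g.tss) or (
            g.interval.strand == "-" and mid > g.tss
        ):
            upstream.append(d)
    pool = upstream or anywhere
    if not pool:  # no gene on this chromosome: treat as unbounded distance
        return "distal"
    d = min(pool)
    if d <= 1000:
        return "excluded"
    return "proximal" if d <= 2000 else "distal"


def annotate_promoter_strand(
    promoters: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[GenomicInterval]:
    """Assign each promoter the strand of its nearest TSS.

    Distance is from the promoter midpoint; ties between equidistant TSSs are
    broken by the lexicographically smaller gene_id, making the assignment
    deterministic.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    out: list[GenomicInterval] = []
    for prom in promoters:
        mid = prom.midpoint
        best: tuple[int, str, Strand] | None = None
        for g in genes:
            if g.interval.chrom != prom.chrom:
                continue
            key = (abs(g.tss - mid), g.gene_id, g.interval.strand)
            if best is None or key < best:
                best = key
        strand: Strand = best[2] if best is not None else "."
        out.append(replace(prom, strand=strand))
    return out


# ---------------------------------------------------------------------------
# Catalog assembly and TSV round-trip


def build_catalog(
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    blacklist: Sequence[GenomicInterval] = (),
    pad: int = 1000,
    provenance: str = "",
) -> tuple[ElementCatalog, pd.DataFrame]:
    """Run the full curation: filter, classify, strand-annotate.

    Returns the catalog of retained elements plus a removal table
    (id, chrom, start, end, reason) for the audit trail.  Enhancers whose
    nearest-TSS distance lands <= 1 kb after filtering are recorded as
    removed with reason ``too_close``.
    """
    kept, removed = filter_enhancers(enhancers, genes, blacklist, pad=pad)
    records: list[ElementRecord] = []
    removal_rows = [
        {"id": iv.id, "chrom": iv.chrom, "start": iv.start, "end": iv.end, "reason": r}
        for iv, r in removed
    ]
    for enh in kept:
        sub = classify_enhancer_distance(enh, genes)
        if sub == "excluded":
            removal_rows.append(
                {"id": enh.id, "chrom": enh.chrom, "start": enh.start,
                 "end": enh.end, "reason": "too_close"}
            )
            continue
        records.append(ElementRecord(enh, "enhancer", sub))
    for prom in annotate_promoter_strand(promoters, genes):
        records.append(ElementRecord(prom, "promoter"))
    catalog = ElementCatalog(records, provenance=provenance)
    removals = pd.DataFrame(removal_rows, columns=["id", "chrom", "start", "end", "reason"])
    return catalog, removals


def write_catalog(catalog: ElementCatalog, path: str | Path) -> None:
    rows = [
        {
            "id": e.id,
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "strand": e.interval.strand,
            "element_class": e.element_class,
            "subclass": e.subclass,
        }
        for e in catalog.elements
    ]
    pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand", "element_class", "subclass"]
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> ElementCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = [
        ElementRecord(
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.id),
            r.element_class,
            r.subclass,
        )
        for r in df.itertuples()
    ]
    return ElementCatalog(records, provenance=str(path))
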