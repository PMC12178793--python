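"""TF footprint activity variability and p53 partitioning.

Footprints (short protected intervals inside accessible chromatin, each with
a protection score and a fragment tag count) are restricted to the element
catalog, aggregated per TF into a TF x timepoint binding-activity table, and
ranked by the sample standard deviation of activity across the three damage
timepoints; the top of that ranking is the highly variable TF set.  Elements
are independently partitioned into p53-bound and p53-free classes by overlap
with p53 ChIP peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import ElementCatalog, GenomicInterval
from .states import PeakSet
from .stats import TestResult, ks2

logger = logging.getLogger(__name__)

Metric = Literal["protection", "tag_count", "combined"]

__all__ = [
    "FootprintRecord",
    "ActivityTable",
    "P53Partition",
    "footprints_in_elements",
    "build_activity_table",
    "rank_by_sd",
    "top_overlap",
    "partition_by_p53",
    "group_signal_compare",
    "read_footprints",
]


@dataclass(frozen=True)
class FootprintRecord:
    """One TF footprint call at one timepoint.

    ``tf_name`` may contain '::' for a TF complex; such names are always
    compared verbatim, never split.
    """

    tf_name: str
    interval: GenomicInterval
    protection_score: float
    tag_count: float
    timepoint: str

    def __post_init__(self) -> None:
        if not self.tf_name:
            raise ValueError("tf_name must be non-empty")
        if self.tag_count < 0:
            raise ValueError("tag_count must be >= 0")


@dataclass
class ActivityTable:
    """TF x timepoint binding activity (one triple per TF)."""

    rows: dict[str, tuple[float, float, float]]
    activity_metric: Metric

    def __post_init__(self) -> None:
        for tf, triple in self.rows.items():
            if len(triple) != 3 or not all(np.isfinite(triple)):
                raise ValueError(f"TF {tf}: activity must be 3 finite values")


@dataclass
class P53Partition:
    p53BER: set[str]
    p53FER: set[str]
    p53BPR: set[str]
    p53FPR: set[str]


def footprints_in_elements(
    footprints: Sequence[FootprintRecord], elements: ElementCatalog
) -> tuple[list[FootprintRecord], dict[str, int]]:
    """Footprints overlapping (>= 1 bp) any catalog element, with per-timepoint tallies."""
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end
        )
    subset: list[FootprintRecord] = []
    counts: dict[str, int] = {}
    for fp in footprints:
        t = trees.get(fp.interval.chrom)
        if t is not None and t.overlaps(fp.interval.start, fp.interval.end):
            subset.append(fp)
            counts[fp.timepoint] = counts.get(fp.timepoint, 0) + 1
    return subset, counts


def build_activity_table(
    footprints: Sequence[FootprintRecord],
    metric: Metric = "combined",
    timepoints: Sequence[str] = ("0h", "8h", "16h"),
) -> ActivityTable:
    """Aggregate footprints into per-TF activity triples.

    Activity(tf, t) is the mean of the chosen metric over that TF's
    footprints at t.  The ``combined`` metric is the mean of the min-max
    normalized protection score and tag count, each normalized across the
    whole footprint set so the two components are on a common [0, 1] scale.
    TFs missing any timepoint are dropped with a logged reason.
    """
    if not footprints:
        return ActivityTable({}, metric)
    prot = np.asarray([fp.protection_score for fp in footprints], dtype=float)
    tags = np.asarray([fp.tag_count for fp in footprints], dtype=float)

    def _minmax(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return np.zeros_like(v) if span == 0 else (v - v.min()) / span

    if metric == "protection":
        score = prot
    elif metric == "tag_count":
        score = tags
    else:
        score = (_minmax(prot) + _minmax(tags)) / 2.0

    acc: dict[str, dict[str, list[float]]] = {}
    for fp, s in zip(footprints, score):
        acc.setdefault(fp.tf_name, {}).setdefault(fp.timepoint, []).append(float(s))

    rows: dict[str, tuple[float, float, float]] = {}
    for tf in sorted(acc):
        per_tp = acc[tf]
        if any(tp not in per_tp for tp in timepoints):
            logger.info("TF %s dropped: missing timepoint(s)", tf)
            continue
        rows[tf] = tuple(float(np.mean(per_tp[tp])) for tp in timepoints)  # type: ignore[assignment]
    return ActivityTable(rows, metric)


def rank_by_sd(table: ActivityTable, top_n: int = 30) -> list[str]:
    """TFs in descending order of activity standard deviation (ddof=1) across
    the three timepoints; ties broken lexicographically; first top_n returned."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(
        table.rows,
        key=lambda tf: (-float(np.std(table.rows[tf], ddof=1)), tf),
    )
    return ranked[:top_n]


def top_overlap(top_a: Sequence[str], top_b: Sequence[str]) -> tuple[set[str], int]:
    """Exact string intersection of two top-TF lists ('::' names verbatim)."""
    shared = set(top_a) & set(top_b)
    return shared, len(shared)


def partition_by_p53(elements: ElementCatalog, p53_peaks: PeakSet) -> P53Partition:
    """Split enhancers/promoters into p53-bound and p53-free classes.

    Overlap >= 1 bp with a p53 peak puts an element in the bound class
    (p53BER for enhancers, p53BPR for promoters); otherwise the free class.
    """
    if p53_peaks.assay != "p53":
        raise ValueError("peak set must be the p53 assay")
    part = P53Partition(set(), set(), set(), set())
    trees = p53_peaks.trees()
    for el in elements:
        t = trees.get(el.interval.chrom)
        bound = t is not None and t.overlaps(el.interval.start, el.interval.end)
        if el.element_class == "enhancer":
            (part.p53BER if bound else part.p53FER).add(el.id)
        else:
            (part.p53BPR if bound else part.p53FPR).add(el.id)
    n_enh = len(elements.enhancers)
    n_prom = len(elements.promoters)
    assert len(part.p53BER) + len(part.p53FER) == n_enh
    assert len(part.p53BPR) + len(part.p53FPR) == n_prom
    return part


def group_signal_compare(
    group_a: set[str],
    group_b: set[str],
    values: Mapping[str, float],
) -> TestResult:
    """Two-sample KS test between the signal values of two element-id groups."""
    a = [values[i] for i in sorted(group_a) if i in values]
    b = [values[i] for i in sorted(group_b) if i in values]
    if not a or not b:
        raise ValueError("both groups must be non-empty after matching to values")
    return ks2(a, b)


def read_footprints(path: str | Path) -> list[FootprintRecord]:
    """TSV: tf_name, chrom, start, end, protection_score, tag_count, timepoint."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "timepoint": str})
    return [
        FootprintRecord(
            r.tf_name,
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            float(r.protection_score),
            float(r.tag_count),
            str(r.timepoint),
        )
        for r in df.itertuples()
    ]
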