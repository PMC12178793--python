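"""Binary element states from peak overlap, trajectory classes, random controls.

An element is "accessible" (ATAC) or "active" (H3K27ac) at a timepoint iff it
shares at least one base with a peak from that timepoint; "expressed" iff its
RPM is positive.  Over the three damage timepoints an element is consistently
positive (all three states set), consistently negative (none set), or dynamic.
Two control sets mirror the study design: fixed-length random genomic regions,
and randomly drawn accessible (peak) regions that avoid the element catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import ElementCatalog, ElementRecord, GenomicInterval

Category = Literal["consistent_positive", "consistent_negative", "dynamic"]

__all__ = [
    "PeakSet",
    "StateTrajectory",
    "overlap_state",
    "trajectory_category",
    "expression_trajectory",
    "trajectory_table",
    "random_regions",
    "random_accessible_regions",
]


@dataclass
class PeakSet:
    """Peak calls for one assay at one timepoint ('static' for p53)."""

    assay: Literal["ATAC", "H3K27ac", "p53"]
    timepoint: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.timepoint == "static" and self.assay != "p53":
            raise ValueError("'static' timepoint is reserved for p53 peaks")
        self._trees: dict[str, IntervalTree] | None = None

    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            self._trees = {}
            for p in self.peaks:
                self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        return self._trees


@dataclass(frozen=True)
class StateTrajectory:
    element_id: str
    assay: str
    states: tuple[bool, bool, bool]
    category: Category = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", trajectory_category(self.states))


def overlap_state(element: ElementRecord, peaks: PeakSet) -> bool:
    """True iff the element shares >= 1 bp with any peak."""
    tree = peaks.trees().get(element.interval.chrom)
    return bool(tree is not None and tree.overlaps(element.interval.start, element.interval.end))


def trajectory_category(states: Sequence[bool]) -> Category:
    """All-true -> consistent_positive; all-false -> consistent_negative; else dynamic."""
    if len(states) != 3:
        raise ValueError(f"expected exactly 3 states, got {len(states)}")
    if all(states):
        return "consistent_positive"
    if not any(states):
        return "consistent_negative"
    return "dynamic"


def expression_trajectory(rpms: Sequence[float]) -> Category:
    """Consistently expressed (all RPM > 0), non-expressed (all = 0), or dynamic."""
    if len(rpms) != 3:
        raise ValueError(f"expected exactly 3 RPM values, got {len(rpms)}")
    if any(v < 0 for v in rpms):
        raise ValueError("RPM values cannot be negative")
    return trajectory_category([v > 0 for v in rpms])


def trajectory_table(
    elements: Sequence[ElementRecord],
    peaksets: Sequence[PeakSet],
    assay: str,
    timepoints: Sequence[str] = ("0h", "8h", "16h"),
) -> pd.DataFrame:
    """Per-element state triple and category for one assay.

    ``peaksets`` must contain one PeakSet per timepoint for the given assay.
    """
    by_tp = {ps.timepoint: ps for ps in peaksets if ps.assay == assay}
    missing = [tp for tp in timepoints if tp not in by_tp]
    if missing:
        raise ValueError(f"missing {assay} peak sets for timepoints: {missing}")
    rows = []
    for el in elements:
        states = tuple(overlap_state(el, by_tp[tp]) for tp in timepoints)
        rows.append(
            {
                "element_id": el.id,
                "assay": assay,
                **{f"state_{tp}": s for tp, s in zip(timepoints, states)},
                "category": trajectory_category(states),
            }
        )
    return pd.DataFrame(rows)


def random_regions(
    chrom_sizes: Mapping[str, int],
    n: int = 10_000,
    length: int = 2000,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Draw n fixed-length regions uniformly per-base across the genome.

    Chromosomes shorter than ``length`` are excluded; among the rest the
    chromosome is chosen with probability proportional to its length, then
    the start uniformly so the region fits.  Regions may overlap each other
    and any elements; deterministic given the seed.
    """
    eligible = [(c, s) for c, s in chrom_sizes.items() if s >= length]
    if not eligible:
        raise ValueError(f"no chromosome is at least {length} bp long")
    rng = np.random.default_rng(seed)
    names = [c for c, _ in eligible]
    sizes = np.asarray([s for _, s in eligible], dtype=float)
    probs = sizes / sizes.sum()
    picks = rng.choice(len(names), size=n, p=probs)
    out = []
    for i, ci in enumerate(picks):
        max_start = eligible[ci][1] - length
        start = int(rng.integers(0, max_start + 1))
        out.append(GenomicInterval(names[ci], start, start + length, id=f"rand_{i}"))
    return out


def random_accessible_regions(
    peaks: PeakSet,
    elements: ElementCatalog,
    n: int,
    seed: int = 0,
) -> tuple[list[GenomicInterval], bool]:
    """Sample peaks (verbatim, lengths preserved) that avoid all catalog elements.

    Uniform sample without replacement from the peaks having zero overlap
    with any element.  If fewer than ``n`` peaks are eligible, all of them
    are returned and the warning flag is set.
    """
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end
        )
    eligible = [
        p
        for p in peaks.peaks
        if not (p.chrom in trees and trees[p.chrom].overlaps(p.start, p.end))
    ]
    rng = np.random.default_rng(seed)
    if len(eligible) <= n:
        return list(eligible), len(eligible) < n
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)], False
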