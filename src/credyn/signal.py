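"""Per-element signal quantification (RPM) and center-anchored profile matrices.

Sequencing output is represented as plain fragment sets (BED intervals plus a
library total), the processed form of aligned reads.  Region expression is
reads-per-million: the number of fragments overlapping the region by >= 1 bp,
scaled by the library total.  Profile matrices mirror the coverage-tool
convention: per-base coverage around each element center, averaged in fixed
bins, CPM-normalized, optionally mean-smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import ElementRecord, GenomicInterval

Assay = Literal["RNA", "ATAC", "H3K27ac"]

__all__ = [
    "FragmentSet",
    "SignalMatrix",
    "region_rpm",
    "region_rpm_batch",
    "expressed_flag",
    "profile_matrix",
    "subtract_tracks",
    "read_fragment_manifest",
    "read_bedgraph",
]


@dataclass
class FragmentSet:
    """Fragments from one sample (one assay at one timepoint)."""

    fragments: list[GenomicInterval]
    total_count: int
    assay: Assay
    timepoint: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.total_count < 1:
            raise ValueError("total_count must be >= 1")
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted start and end arrays per chromosome, built lazily."""
        if self._index is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for f in self.fragments:
                s, e = idx.setdefault(f.chrom, ([], []))
                s.append(f.start)
                e.append(f.end)
            self._index = {
                c: (np.sort(np.asarray(s, dtype=np.int64)),
                    np.sort(np.asarray(e, dtype=np.int64)))
                for c, (s, e) in idx.items()
            }
        return self._index


def region_rpm(frags: FragmentSet, region: GenomicInterval) -> float:
    """Reads-per-million over a region.

    Counts fragments overlapping the region by >= 1 bp and scales by the
    library total: ``count / total_count * 1e6``.
    """
    if frags.total_count <= 0:
        raise ValueError("total_count must be positive")
    idx = frags._chrom_index().get(region.chrom)
    if idx is None:
        return 0.0
    starts, ends = idx
    # overlap count = #(start < region.end) - #(end <= region.start)
    n = np.searchsorted(starts, region.end, side="left") - np.searchsorted(
        ends, region.start, side="right"
    )
    return float(n) / frags.total_count * 1e6


def region_rpm_batch(frags: FragmentSet, regions: Sequence[GenomicInterval]) -> np.ndarray:
    """Vectorized :func:`region_rpm` over many regions (same definition)."""
    out = np.zeros(len(regions), dtype=float)
    index = frags._chrom_index()
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, rows in by_chrom.items():
        idx = index.get(chrom)
        if idx is None:
            continue
        starts, ends = idx
        r_start = np.asarray([regions[i].start for i in rows])
        r_end = np.asarray([regions[i].end for i in rows])
        n = np.searchsorted(starts, r_end, side="left") - np.searchsorted(
            ends, r_start, side="right"
        )
        out[rows] = n / frags.total_count * 1e6
    return out


def expressed_flag(rpm_t0: float) -> bool:
    """True iff the element has any signal pre-damage (RPM > 0 at 0 h)."""
    if rpm_t0 < 0:
        raise ValueError("RPM cannot be negative")
    return rpm_t0 > 0


@dataclass
class SignalMatrix:
    """Elements x bins matrix of normalized signal around element centers."""

    element_ids: list[str]
    bin_edges: np.ndarray  # offsets relative to center, len = n_bins + 1
    values: np.ndarray  # (n_elements, n_bins)
    params: tuple[int, int, int]  # (flank, bin, smooth) in bp

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.element_ids):
            raise ValueError("row count must equal number of element ids")

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) // 2
        df = pd.DataFrame(self.values, columns=[str(int(c)) for c in centers])
        df.insert(0, "element_id", self.element_ids)
        return df


def _smooth_bins(binned: np.ndarray, bin_size: int, smooth: int) -> np.ndarray:
    """Mean-smooth each row over bins whose centers fall inside a window of
    ``smooth`` bp around the target bin center; window truncated at edges."""
    if smooth <= 0:
        return binned
    # bin j enters bin i's window iff |center_j - center_i| < (smooth + bin)/2,
    # i.e. iff the bin overlaps the smooth-bp window around bin i's center
    half = (smooth + bin_size - 1) // (2 * bin_size)
    if half == 0:
        return binned
    n = binned.shape[1]
    out = np.empty_like(binned, dtype=float)
    csum = np.cumsum(np.pad(binned, ((0, 0), (1, 0))), axis=1)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[:, i] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def profile_matrix(
    frags: FragmentSet,
    elements: Sequence[ElementRecord],
    flank: int = 1000,
    bin: int = 50,
    smooth: int = 60,
) -> SignalMatrix:
    """Binned, CPM-normalized per-base coverage around element centers.

    Coverage is accumulated per base in ``[center - flank, center + flank)``,
    averaged within ``bin``-bp bins, scaled to counts-per-million of the
    library total, then mean-smoothed over a ``smooth``-bp window (truncated
    at the matrix edges).  Rows of minus-strand elements are reversed so bins
    always run 5' to 3'.  Windows extending below position 0 are truncated;
    the missing bases contribute zero coverage.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    n_bins = 2 * flank // bin
    # per-chromosome fragment arrays for windowed coverage
    grouped: dict[str, tuple[list[int], list[int]]] = {}
    for f in frags.fragments:
        s, e = grouped.setdefault(f.chrom, ([], []))
        s.append(f.start)
        e.append(f.end)
    frag_by_chrom = {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in grouped.items()
    }

    values = np.zeros((len(elements), n_bins), dtype=float)
    for row, el in enumerate(elements):
        center = el.interval.midpoint
        w_lo, w_hi = center - flank, center + flank
        cov = np.zeros(2 * flank, dtype=float)
        pair = frag_by_chrom.get(el.interval.chrom)
        if pair is not None:
            fs, fe = pair
            sel = (fs < w_hi) & (fe > w_lo)
            for s, e in zip(fs[sel], fe[sel]):
                a = max(int(s), w_lo, 0) - w_lo
                b = min(int(e), w_hi) - w_lo
                if b > a:
                    cov[a:b] += 1.0
        if w_lo < 0:  # truncated window: bases below 0 have no coverage
            cov[: -w_lo] = 0.0
        binned = cov.reshape(n_bins, bin).mean(axis=1)
        values[row] = binned
    values = values / frags.total_count * 1e6
    values = _smooth_bins(values, bin, smooth)
    for row, el in enumerate(elements):
        if el.interval.strand == "-":
            values[row] = values[row][::-1]
    edges = np.arange(-flank, flank + 1, bin, dtype=int)
    return SignalMatrix([e.id for e in elements], edges, values, (flank, bin, smooth))


def subtract_tracks(treatment: SignalMatrix, control: SignalMatrix) -> SignalMatrix:
    """Elementwise treatment minus control; negative values are permitted."""
    if (
        treatment.element_ids != control.element_ids
        or not np.array_equal(treatment.bin_edges, control.bin_edges)
        or treatment.params != control.params
    ):
        raise ValueError("matrices must share element_ids, bin_edges and params")
    return SignalMatrix(
        list(treatment.element_ids),
        treatment.bin_edges.copy(),
        treatment.values - control.values,
        treatment.params,
    )


# ---------------------------------------------------------------------------
# I/O


def read_fragment_manifest(path: str | Path) -> list[FragmentSet]:
    """Load fragment sets listed in a manifest TSV.

    Columns: sample, assay, timepoint, path, total_count.  Fragment paths are
    resolved relative to the manifest's directory.
    """
    from .catalog import read_bed

    base = Path(path).parent
    df = pd.read_csv(path, sep="\t")
    sets: list[FragmentSet] = []
    for r in df.itertuples():
        frag_path = Path(r.path)
        if not frag_path.is_absolute():
            frag_path = base / frag_path
        sets.append(
            FragmentSet(
                read_bed(frag_path),
                int(r.total_count),
                r.assay,
                str(r.timepoint),
                label=str(r.sample),
            )
        )
    return sets


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-base coverage arrays per chromosome."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            spans.setdefault(chrom, []).append((int(s), int(e), float(v)))
    out: dict[str, np.ndarray] = {}
    for chrom, rows in spans.items():
        size = max(e for _, e, _ in rows)
        arr = np.zeros(size, dtype=float)
        for s, e, v in rows:
            arr[s:e] = v
        out[chrom] = arr
    return out
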