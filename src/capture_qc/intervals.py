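"""Genomic intervals and interval algebra for capture designs.

Coordinate conventions
----------------------
All intervals in this package are 0-based, half-open ``[start, end)`` —
the BED convention. VCF positions are 1-based at the file boundary and
are converted on read (see :mod:`capture_qc.io`).

A :class:`TargetDesign` is the in-memory form of a capture design (BED):
a named, sorted, merged, non-overlapping set of intervals. Overlapping
and abutting input intervals are merged so region counts are
deterministic. Designs support fast vectorised overlap queries
(numpy ``searchsorted`` over the sorted, disjoint interval arrays),
which back all on-target and per-region computations.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TargetDesign",
    "merge_intervals",
    "common_regions",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_abutting: bool = True
) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping (and, by default, abutting) ones.

    Names of merged intervals are joined with ``,`` when they differ;
    a run of identical names keeps the single name.
    """
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and (
            iv.start < out[-1].end or (merge_abutting and iv.start == out[-1].end)
        ):
            prev = out[-1]
            names = [n for n in (prev.name, iv.name) if n]
            name = None
            if names:
                uniq = list(dict.fromkeys(names))
                name = ",".join(uniq)
            out[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end), name
            )
        else:
            out.append(iv)
    return out


class _ChromIndex:
    """Sorted disjoint interval arrays for one chromosome."""

    __slots__ = ("starts", "ends", "offsets", "indices")

    def __init__(self, intervals: Sequence[GenomicInterval], indices: Sequence[int]):
        self.starts = np.asarray([iv.start for iv in intervals], dtype=np.int64)
        self.ends = np.asarray([iv.end for iv in intervals], dtype=np.int64)
        lengths = self.ends - self.starts
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        # positions of these intervals in the design-wide interval tuple
        self.indices = np.asarray(indices, dtype=np.int64)


class TargetDesign:
    """A named set of merged, sorted, non-overlapping capture regions.

    Parameters
    ----------
    name:
        Label for the design (e.g. the capture method it belongs to).
    intervals:
        Any iterable of :class:`GenomicInterval`; they are sorted and
        merged on construction.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        self.name = name
        self.intervals: tuple[GenomicInterval, ...] = tuple(merge_intervals(intervals))

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetDesign):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return (
            f"TargetDesign({self.name!r}, {len(self.intervals)} regions, "
            f"{self.total_size} bp)"
        )

    @property
    def total_size(self) -> int:
        """Total targeted bases (sum of interval lengths)."""
        return sum(iv.length for iv in self.intervals)

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    @functools.cached_property
    def _index(self) -> dict[str, _ChromIndex]:
        by_chrom: dict[str, tuple[list[GenomicInterval], list[int]]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, ([], []))
            by_chrom[iv.chrom][0].append(iv)
            by_chrom[iv.chrom][1].append(i)
        return {c: _ChromIndex(ivs, idx) for c, (ivs, idx) in by_chrom.items()}

    # -- overlap queries ----------------------------------------------
    def any_overlap(self, chrom: str, starts, ends) -> np.ndarray:
        """Boolean array: does each half-open span overlap the design by >= 1 bp."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        idx = self._index.get(chrom)
        if idx is None or len(idx.starts) == 0:
            return np.zeros(starts.shape, dtype=bool)
        # first interval whose end is > span start
        j = np.searchsorted(idx.ends, starts, side="right")
        inside = j < len(idx.starts)
        res = np.zeros(starts.shape, dtype=bool)
        jj = np.clip(j, 0, len(idx.starts) - 1)
        res[inside] = idx.starts[jj][inside] < ends[inside]
        return res

    def overlap_bases(self, chrom: str, starts, ends) -> np.ndarray:
        """Number of design bases each span covers (vectorised)."""
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        idx = self._index.get(chrom)
        out = np.zeros(starts.shape, dtype=np.int64)
        if idx is None or len(idx.starts) == 0:
            return out
        # intervals j .. j2-1 are the ones each span can overlap
        j = np.searchsorted(idx.ends, starts, side="right")
        j2 = np.searchsorted(idx.starts, ends, side="left")
        span = j2 - j
        for k in range(int(span.max(initial=0))):
            cur = j + k
            active = cur < j2
            cc = np.clip(cur, 0, len(idx.starts) - 1)
            lo = np.maximum(starts, idx.starts[cc])
            hi = np.minimum(ends, idx.ends[cc])
            out += np.where(active, np.maximum(hi - lo, 0), 0)
        return out

    def overlap_ranges(self, chrom: str, starts, ends) -> tuple[np.ndarray, np.ndarray]:
        """Design-wide region-index ranges ``[first, last)`` overlapped by each span.

        Per-chromosome intervals occupy a contiguous block of the
        design-wide interval tuple, so the pair of arrays fully
        describes which regions each half-open span touches.
        """
        starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
        ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
        idx = self._index.get(chrom)
        if idx is None or len(idx.starts) == 0:
            z = np.zeros(starts.shape, dtype=np.int64)
            return z, z
        j = np.searchsorted(idx.ends, starts, side="right")
        j2 = np.searchsorted(idx.starts, ends, side="left")
        base = int(idx.indices[0])
        return base + j, base + np.maximum(j2, j)

    def region_index_of(self, chrom: str, pos: int) -> int | None:
        """Design-wide index of the interval containing 0-based ``pos``, else None."""
        idx = self._index.get(chrom)
        if idx is None:
            return None
        j = int(np.searchsorted(idx.ends, pos, side="right"))
        if j < len(idx.starts) and idx.starts[j] <= pos < idx.ends[j]:
            return int(idx.indices[j])
        return None

    def contains(self, chrom: str, pos: int) -> bool:
        return self.region_index_of(chrom, pos) is not None

    # -- algebra -------------------------------------------------------
    def pad(self, padding: int) -> "TargetDesign":
        """Symmetrically extend every interval by ``padding`` bp (clipped at 0)."""
        if padding == 0:
            return self
        if padding < 0:
            raise ValueError("padding must be >= 0")
        return TargetDesign(
            self.name,
            (
                GenomicInterval(iv.chrom, max(0, iv.start - padding), iv.end + padding, iv.name)
                for iv in self.intervals
            ),
        )

    def intersect(self, other: "TargetDesign") -> "TargetDesign":
        """Base-level intersection with another design (two-pointer sweep)."""
        out: list[GenomicInterval] = []
        mine = self._index
        for chrom, idx in mine.items():
            oidx = other._index.get(chrom)
            if oidx is None:
                continue
            i = j = 0
            a_s, a_e = idx.starts, idx.ends
            b_s, b_e = oidx.starts, oidx.ends
            while i < len(a_s) and j < len(b_s):
                lo = max(a_s[i], b_s[j])
                hi = min(a_e[i], b_e[j])
                if lo < hi:
                    out.append(GenomicInterval(chrom, int(lo), int(hi)))
                if a_e[i] <= b_e[j]:
                    i += 1
                else:
                    j += 1
        return TargetDesign(f"{self.name}&{other.name}", out)


def common_regions(designs: Sequence[TargetDesign]) -> TargetDesign:
    """Base-level intersection of two or more designs.

    The multi-method comparison restricts every depth and variant metric
    to the regions shared by all capture designs; this computes that
    common design. An empty intersection is returned as an empty design
    with a logged warning, not an error.
    """
    if len(designs) < 2:
        raise ValueError("common_regions requires at least 2 designs")
    result = designs[0]
    for d in designs[1:]:
        result = result.intersect(d)
    result.name = "common"
    if len(result) == 0:
        logger.warning("common_regions: designs share no bases")
    return result
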