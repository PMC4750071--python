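"""Coordinate-based PCR-duplicate marking and duplicate-rate summaries.

Fragments sharing the key ``(chrom, frag_start, frag_end,
strand_orientation)`` — pair outer coordinates plus library
orientation — form one duplicate set. In each set the fragment with the
highest total base quality stays unmarked (ties broken by the
lexicographically smallest record name, Picard's convention); every
other member is flagged ``is_duplicate``. Marking only sets flags:
duplicate fragments stay in the stream so both raw and
duplicates-excluded metrics can be computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import TargetDesign
from .io import FragmentRecord

__all__ = ["DuplicateSummary", "mark_duplicates", "duplicate_summary"]


@dataclass
class DuplicateSummary:
    total_reads: int
    duplicate_reads: int
    per_region_duplicate_fraction: dict[int, float | None] = field(default_factory=dict)

    @property
    def duplicate_fraction(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.duplicate_reads / self.total_reads


def mark_duplicates(fragments: list[FragmentRecord]) -> list[FragmentRecord]:
    """Flag all but the best fragment in every duplicate set (in place).

    Idempotent and independent of input order: flags depend only on the
    multiset of (key, base_quality_sum, name) triples. Returns the same
    list for chaining.
    """
    by_key: dict[tuple, list[FragmentRecord]] = {}
    for frag in fragments:
        by_key.setdefault(frag.duplicate_key, []).append(frag)
    for members in by_key.values():
        best = min(members, key=lambda f: (-f.base_quality_sum, f.name))
        for frag in members:
            frag.is_duplicate = frag is not best
    return fragments


def duplicate_summary(
    fragments: list[FragmentRecord], design: TargetDesign | None = None
) -> DuplicateSummary:
    """Global and per-region duplicate read fractions (2 reads/fragment).

    Per-region fractions are computed over fragments overlapping each
    design interval; a region with no overlapping fragments reports
    ``None`` (missing), not 0.
    """
    n_reads = sum(len(f.read_spans) for f in fragments)
    n_dup = sum(len(f.read_spans) for f in fragments if f.is_duplicate)
    per_region: dict[int, float | None] = {}
    if design is not None:
        totals = np.zeros(len(design), dtype=np.int64)
        dups = np.zeros(len(design), dtype=np.int64)
        by_chrom: dict[str, list[FragmentRecord]] = {}
        for f in fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        for chrom, frs in by_chrom.items():
            starts = np.array([f.frag_start for f in frs], dtype=np.int64)
            ends = np.array([f.frag_end for f in frs], dtype=np.int64)
            nread = np.array([len(f.read_spans) for f in frs], dtype=np.int64)
            isdup = np.array([f.is_duplicate for f in frs], dtype=bool)
            first, last = design.overlap_ranges(chrom, starts, ends)
            for k in range(int((last - first).max(initial=0))):
                cur = first + k
                active = cur < last
                np.add.at(totals, cur[active], nread[active])
                np.add.at(dups, cur[active & isdup], nread[active & isdup])
        for k in range(len(design)):
            per_region[k] = float(dups[k] / totals[k]) if totals[k] else None
    return DuplicateSummary(n_reads, n_dup, per_region)
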