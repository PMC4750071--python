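"""Depth-of-coverage statistics over a capture design.

Depth at a targeted base counts aligned *read* spans covering it (both
mates contribute; overlapping mates double-count, matching samtools
depth defaults). With ``exclude_duplicates`` set, reads of fragments
flagged as PCR duplicates are left out — the "dedup DOC" reported next
to the raw DOC.

Derived statistics:

* threshold tables — fraction of targeted bases covered at >= t X;
* depth-distribution curves — per-region (fraction of regions with
  mean depth above d) and per-base variants;
* evenness score (ES) — uniformity of coverage relative to its mean,
  100% for perfectly uniform depth, independent of sequencing depth;
* normalised per-region DOC — region mean depth divided by the
  design-wide mean, so methods at different depths can be compared;
* GC-binned coverage profiles and per-region RMS mapping-quality
  summaries (pseudogene screening).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, TargetDesign
from .io import FragmentRecord, ReferenceSequence

logger = logging.getLogger(__name__)

__all__ = [
    "DepthProfile",
    "RegionCoverage",
    "EvennessResult",
    "compute_depth",
    "coverage_thresholds",
    "depth_distribution_curve",
    "base_distribution_curve",
    "evenness_score",
    "per_region_coverage",
    "normalized_doc",
    "gc_coverage_profile",
    "region_mapq_summary",
]


@dataclass
class DepthProfile:
    """Per-base depth over a design, addressed by (region index, offset)."""

    design: TargetDesign
    depths: dict[int, np.ndarray]
    dedup: bool = False

    def region_depths(self, region_index: int) -> np.ndarray:
        return self.depths[region_index]

    def all_depths(self) -> np.ndarray:
        if not self.depths:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([self.depths[i] for i in sorted(self.depths)])

    @property
    def mean_doc(self) -> float:
        d = self.all_depths()
        return float(d.mean()) if d.size else 0.0


@dataclass
class RegionCoverage:
    region: GenomicInterval
    region_index: int
    a_doc: float
    n_doc: float | None = None
    gc_fraction: float | None = None
    pct_ge: dict[int, float] = field(default_factory=dict)
    mean_mapq: float | None = None


@dataclass
class EvennessResult:
    es_percent: float
    mean_depth_used: float


def compute_depth(
    fragments: list[FragmentRecord],
    design: TargetDesign,
    exclude_duplicates: bool = False,
) -> DepthProfile:
    """Per-base depth over every design interval from aligned read spans."""
    if len(design) == 0:
        raise ValueError("cannot compute depth over an empty design")
    spans: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        if exclude_duplicates and f.is_duplicate:
            continue
        # aligned blocks, not outer read spans: deleted reference bases
        # (CIGAR D) do not contribute depth, matching samtools
        spans.setdefault(f.chrom, []).extend(f.aligned_blocks)

    depths: dict[int, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(design):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))

    for chrom, regions in by_chrom.items():
        maxend = max(iv.end for _, iv in regions)
        diff = np.zeros(maxend + 1, dtype=np.int64)
        chrom_spans = spans.get(chrom, [])
        if chrom_spans:
            arr = np.asarray(chrom_spans, dtype=np.int64)
            s = np.clip(arr[:, 0], 0, maxend)
            e = np.clip(arr[:, 1], 0, maxend)
            np.add.at(diff, s, 1)
            np.add.at(diff, e, -1)
        cum = np.cumsum(diff)
        for i, iv in regions:
            depths[i] = cum[iv.start : iv.end].copy()
    return DepthProfile(design=design, depths=depths, dedup=exclude_duplicates)


def coverage_thresholds(profile: DepthProfile, thresholds) -> dict[int, float]:
    """Fraction of targeted bases covered at >= t for each threshold t."""
    d = profile.all_depths()
    return {int(t): float(np.mean(d >= t)) for t in thresholds}


def depth_distribution_curve(
    region_coverages: list[RegionCoverage], grid
) -> dict[float, float]:
    """Fraction of regions with mean depth strictly above each grid point."""
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    a = np.array([rc.a_doc for rc in region_coverages], dtype=float)
    return {float(g): float(np.mean(a > g)) for g in grid}


def base_distribution_curve(profile: DepthProfile, grid) -> dict[float, float]:
    """Per-base variant: fraction of targeted bases with depth strictly above d."""
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    d = profile.all_depths()
    return {float(g): float(np.mean(d > g)) for g in grid}


def evenness_score(profile: DepthProfile | np.ndarray) -> EvennessResult:
    """Evenness score of a depth profile, as a percentage.

    ES = 100 * (1/floor(C)) * sum_{i=1}^{floor(C)} F(i), where C is the
    mean depth over targeted bases and F(i) the fraction of targeted
    bases covered at >= i. Perfectly uniform coverage scores exactly
    100; the score does not depend on the overall sequencing depth
    (up to the integer discretisation of the mean).
    """
    depths = profile.all_depths() if isinstance(profile, DepthProfile) else np.asarray(profile)
    if depths.size == 0 or not depths.any():
        raise ValueError("evenness score undefined for an all-zero profile")
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")
    cbar = float(depths.mean())
    m = math.floor(cbar)
    if m < 1:
        logger.warning("mean depth %.3f < 1; evenness degenerates to 100*F(1)", cbar)
        m = 1
    counts = np.bincount(depths.astype(np.int64), minlength=m + 1)
    below = np.cumsum(counts)  # below[i] = #bases with depth <= i
    total = depths.size
    f = (total - below[:m]) / total  # F(1..m): depth >= i  <=>  not depth <= i-1
    return EvennessResult(es_percent=float(100.0 * f.mean()), mean_depth_used=cbar)


def per_region_coverage(
    profile: DepthProfile,
    reference: ReferenceSequence | None = None,
    thresholds=(),
) -> list[RegionCoverage]:
    """Per-region mean depth (aDOC), GC fraction and threshold table."""
    out = []
    for i, iv in enumerate(profile.design):
        d = profile.region_depths(i)
        gc = reference.gc_fraction(iv.chrom, iv.start, iv.end) if reference else None
        pct = {int(t): float(np.mean(d >= t)) for t in thresholds}
        out.append(
            RegionCoverage(region=iv, region_index=i, a_doc=float(d.mean()), gc_fraction=gc, pct_ge=pct)
        )
    return out


def normalized_doc(region_coverages: list[RegionCoverage]) -> list[RegionCoverage]:
    """Fill nDOC_i = aDOC_i / aDOC, with aDOC the length-weighted global mean.

    The length-weighted mean of the resulting nDOC values is exactly 1.
    """
    lengths = np.array([rc.region.length for rc in region_coverages], dtype=float)
    a = np.array([rc.a_doc for rc in region_coverages], dtype=float)
    global_mean = float((a * lengths).sum() / lengths.sum())
    if global_mean <= 0:
        raise ValueError("global mean depth is zero; normalized DOC undefined")
    for rc in region_coverages:
        rc.n_doc = rc.a_doc / global_mean
    return region_coverages


def gc_coverage_profile(
    region_coverages: list[RegionCoverage],
    reference: ReferenceSequence | None = None,
    bin_width: float = 0.05,
) -> list[dict]:
    """Mean/SD of normalised DOC per GC bin.

    Regions are binned by ``floor(gc / bin_width)``; empty bins are
    omitted; regions whose GC is undefined (all-N sequence) are
    excluded with a warning. GC uses informative bases only.
    """
    if not (0 < bin_width <= 0.25):
        raise ValueError("bin_width must be in (0, 0.25]")
    rows: dict[int, list[float]] = {}
    for rc in region_coverages:
        gc = rc.gc_fraction
        if gc is None and reference is not None:
            gc = reference.gc_fraction(rc.region.chrom, rc.region.start, rc.region.end)
        if gc is None:
            logger.warning("region %s has no informative bases; excluded from GC profile", rc.region)
            continue
        if rc.n_doc is None:
            raise ValueError("normalized_doc must be computed before the GC profile")
        b = min(int(gc / bin_width), int(1.0 / bin_width) - 1)
        rows.setdefault(b, []).append(rc.n_doc)
    table = []
    for b in sorted(rows):
        vals = np.array(rows[b])
        table.append(
            {
                "gc_low": b * bin_width,
                "gc_high": (b + 1) * bin_width,
                "mean_n_doc": float(vals.mean()),
                "sd_n_doc": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_regions": int(vals.size),
            }
        )
    return table


@dataclass
class RegionMapq:
    region: GenomicInterval
    region_index: int
    rms_mapq: float | None
    status: str  # "ok" | "low_mapq" | "no_data"


def region_mapq_summary(
    fragments: list[FragmentRecord],
    design: TargetDesign,
    mapq_floor: float = 20.0,
) -> list[RegionMapq]:
    """Per-region RMS mapping quality; regions below the floor are flagged.

    Low RMS MAPQ over a region is the footprint of co-captured
    homologous sequence (pseudogene contamination): reads map
    ambiguously and the aligner assigns near-zero mapping quality.
    Regions without any overlapping reads are reported as ``no_data``,
    distinct from genuinely low MAPQ.
    """
    sumsq = np.zeros(len(design), dtype=float)
    counts = np.zeros(len(design), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for f in fragments:
        for (s, e), q in zip(f.read_spans, list(f.mapqs) * len(f.read_spans)):
            by_chrom.setdefault(f.chrom, []).append((s, e, q))
    for chrom, triples in by_chrom.items():
        arr = np.asarray(triples, dtype=float)
        first, last = design.overlap_ranges(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64))
        q2 = arr[:, 2] ** 2
        for k in range(int((last - first).max(initial=0))):
            cur = first + k
            active = cur < last
            np.add.at(sumsq, cur[active], q2[active])
            np.add.at(counts, cur[active], 1)
    out = []
    for i, iv in enumerate(design):
        if counts[i] == 0:
            out.append(RegionMapq(iv, i, None, "no_data"))
        else:
            rms = math.sqrt(sumsq[i] / counts[i])
            out.append(RegionMapq(iv, i, rms, "low_mapq" if rms < mapq_floor else "ok"))
    return out
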