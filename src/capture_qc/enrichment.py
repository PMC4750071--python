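"""On-target fractions, Enrichment Factor, fragment sizes, base quality.

The on-target read fraction is the proportion of aligned reads whose
span overlaps the (optionally padded) capture design by at least one
base; the base fraction counts aligned bases falling inside the design.
Because designs differ in size between capture methods, the Enrichment
Factor normalises the on-target base fraction by the fraction of the
genome the design occupies::

    EF = on_target_base_fraction / (target_size / genome_size)

so EF = 1 means no enrichment at all and values in the thousands are
typical for small custom panels. Both computations default to raw
(duplicates included) reads, which is the convention for a raw
on-target percentage; set ``exclude_duplicates`` to restrict to the
unique library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .intervals import TargetDesign
from .io import FragmentRecord

__all__ = [
    "EnrichmentResult",
    "RunStats",
    "on_target_fractions",
    "enrichment_factor",
    "fragment_size_stats",
    "q30_fraction",
    "run_stats",
]

HG19_GENOME_SIZE = 3_095_693_983  # for real human runs; simulations use the toy genome


@dataclass
class EnrichmentResult:
    on_target_read_fraction: float
    on_target_base_fraction: float
    target_size: int
    genome_size: int

    @property
    def enrichment_factor(self) -> float:
        return self.on_target_base_fraction / (self.target_size / self.genome_size)


@dataclass
class RunStats:
    total_reads: int
    total_bases: int
    q30_fraction: float
    fragment_size_median: float
    fragment_size_iqr: float


def on_target_fractions(
    fragments: list[FragmentRecord],
    design: TargetDesign,
    padding: int = 0,
    exclude_duplicates: bool = False,
) -> tuple[float, float]:
    """(read fraction, aligned-base fraction) overlapping the padded design.

    A read is on-target iff its aligned span overlaps the design by
    >= 1 bp; the base fraction counts only the bases inside the design.
    """
    padded = design.pad(padding)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        if exclude_duplicates and f.is_duplicate:
            continue
        by_chrom.setdefault(f.chrom, []).extend(f.read_spans)
    n_reads = on_reads = 0
    n_bases = on_bases = 0
    for chrom, spans in by_chrom.items():
        arr = np.asarray(spans, dtype=np.int64)
        s, e = arr[:, 0], arr[:, 1]
        hit = padded.any_overlap(chrom, s, e)
        bp = padded.overlap_bases(chrom, s, e)
        n_reads += len(s)
        on_reads += int(hit.sum())
        n_bases += int((e - s).sum())
        on_bases += int(bp.sum())
    if n_reads == 0:
        return 0.0, 0.0
    return on_reads / n_reads, on_bases / n_bases


def enrichment_result(
    fragments: list[FragmentRecord],
    design: TargetDesign,
    genome_size: int,
    padding: int = 0,
    exclude_duplicates: bool = False,
) -> EnrichmentResult:
    rf, bf = on_target_fractions(fragments, design, padding, exclude_duplicates)
    return EnrichmentResult(rf, bf, design.total_size, genome_size)


def enrichment_factor(
    on_target_base_fraction: float, design: TargetDesign, genome_size: int
) -> float:
    """EF = base fraction * genome size / target size."""
    if design.total_size <= 0:
        raise ValueError("design has zero target size")
    if genome_size < design.total_size:
        raise ValueError("genome_size must be >= design.total_size")
    return on_target_base_fraction * genome_size / design.total_size


def fragment_size_stats(
    fragments: list[FragmentRecord], bin_width: int = 10
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Median, IQR and a histogram (``bin_width`` bp bins) of fragment lengths."""
    if not fragments:
        raise ValueError("no fragments")
    lengths = np.array([f.fragment_length for f in fragments], dtype=float)
    median = float(np.median(lengths))
    q1, q3 = np.percentile(lengths, [25, 75])
    lo = int(lengths.min() // bin_width) * bin_width
    hi = int(lengths.max() // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, _ = np.histogram(lengths, bins=edges)
    return median, float(q3 - q1), (edges, hist)


def q30_fraction(path: str | Path, threshold: int = 30) -> float:
    """Fraction of base calls at Phred >= ``threshold`` in a FASTQ or SAM/BAM."""
    path = Path(path)
    total = ge = 0
    if path.suffix.lower() in (".fastq", ".fq") or path.name.endswith((".fastq.gz", ".fq.gz")):
        with pysam.FastxFile(str(path)) as fx:
            for rec in fx:
                if rec.quality is None:
                    raise ValueError(f"{path}: record {rec.name} has no qualities")
                q = np.frombuffer(rec.quality.encode(), dtype=np.uint8).astype(int) - 33
                total += q.size
                ge += int((q >= threshold).sum())
    else:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for rec in af:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                quals = rec.query_qualities
                if quals is None:
                    raise ValueError(f"{path}: read {rec.query_name} has no qualities")
                q = np.asarray(quals, dtype=int)
                total += q.size
                ge += int((q >= threshold).sum())
    if total == 0:
        raise ValueError(f"{path}: no base qualities found")
    return ge / total


def run_stats(sam_path: str | Path) -> RunStats:
    """Raw-run summary: read/base totals, Q30 fraction, fragment sizes.

    Fragment sizes come from the template length of the leftmost read
    of each properly paired fragment.
    """
    total_reads = total_bases = ge30 = 0
    tlens: list[int] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            total_reads += 1
            quals = rec.query_qualities
            if quals is not None:
                q = np.asarray(quals, dtype=int)
                total_bases += q.size
                ge30 += int((q >= 30).sum())
            if rec.is_proper_pair and rec.template_length > 0:
                tlens.append(rec.template_length)
    if total_bases == 0:
        raise ValueError(f"{sam_path}: no base qualities found")
    lengths = np.array(tlens, dtype=float)
    q1, q3 = (np.percentile(lengths, [25, 75]) if lengths.size else (0.0, 0.0))
    return RunStats(
        total_reads=total_reads,
        total_bases=total_bases,
        q30_fraction=ge30 / total_bases,
        fragment_size_median=float(np.median(lengths)) if lengths.size else 0.0,
        fragment_size_iqr=float(q3 - q1),
    )
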