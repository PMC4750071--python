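"""Readers and writers for the standard formats the pipeline touches.

Formats and conventions
-----------------------
* BED: 3+ tab-separated columns, 0-based half-open; read into
  :class:`~capture_qc.intervals.TargetDesign` (sorted/merged).
* SAM/BAM: htslib via pysam; coordinate-sorted paired-end input is
  collapsed into one :class:`FragmentRecord` per proper pair (outer
  fragment coordinates).
* VCF >= 4.1: pysam ``VariantFile``; records are decomposed per ALT,
  left-normalised (shared leading/trailing bases trimmed) and converted
  to 0-based positions internally. :class:`VariantCall` keeps the
  1-based VCF ``pos`` for reporting.
* FASTA: in-memory :class:`ReferenceSequence`, loadable from disk.

All interval arithmetic downstream is 0-based half-open; only VCF
positions are 1-based, at this boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .intervals import GenomicInterval, TargetDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSequence",
    "FragmentRecord",
    "VariantCall",
    "read_bed",
    "write_bed",
    "read_alignments",
    "read_vcf",
    "write_vcf",
    "normalize_alleles",
]

_VALID_BASES = set("ACGTN")


class ReferenceSequence:
    """Reference contigs held in memory, with half-open interval queries."""

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            bad = set(seq.upper()) - _VALID_BASES
            if bad:
                raise ValueError(f"contig {name} contains invalid bases: {sorted(bad)}")
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequence":
        with pysam.FastaFile(str(path)) as fa:
            return cls({name: fa.fetch(name) for name in fa.references})

    @property
    def contig_names(self) -> list[str]:
        return list(self._contigs)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self._contigs.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._contigs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"interval {chrom}:{start}-{end} outside contig")
        return seq[start:end]

    def sequence(self, chrom: str) -> str:
        return self._contigs[chrom]

    def gc_fraction(self, chrom: str, start: int, end: int) -> float | None:
        """GC over informative (non-N) bases; None if the span is all N."""
        seq = self.fetch(chrom, start, end)
        gc = seq.count("G") + seq.count("C")
        informative = len(seq) - seq.count("N")
        if informative == 0:
            return None
        return gc / informative

    def write_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


@dataclass(slots=True)
class FragmentRecord:
    """An aligned read pair abstracted as one sequenced fragment.

    ``strand_orientation`` distinguishes innie pairs by which read sits
    on the forward strand: ``"FR"`` (read1 leftmost/forward), ``"RF"``
    (read2 leftmost/forward), ``"other"`` for non-innie layouts. Both
    orientations are innie at the fragment level, but they are distinct
    library molecules and therefore distinct duplicate-marking keys
    (Picard keys on read1 strand).
    """

    chrom: str
    frag_start: int
    frag_end: int
    strand_orientation: str = "FR"
    mapqs: tuple[int, ...] = (60, 60)
    read_spans: tuple[tuple[int, int], ...] = ()
    aligned_blocks: tuple[tuple[int, int], ...] = ()
    read_length: int = 0
    base_quality_sum: int = 0
    is_duplicate: bool = False
    name: str = ""
    sample_id: str = ""
    method_id: str = ""

    def __post_init__(self) -> None:
        if not self.frag_start < self.frag_end:
            raise ValueError("frag_start must be < frag_end")
        if any(not (0 <= q <= 255) for q in self.mapqs):
            raise ValueError("MAPQ out of [0, 255]")
        if not self.read_spans:
            # derive read spans from the outer fragment span
            L = self.read_length or (self.frag_end - self.frag_start)
            self.read_spans = (
                (self.frag_start, min(self.frag_start + L, self.frag_end)),
                (max(self.frag_end - L, self.frag_start), self.frag_end),
            )
        if not self.aligned_blocks:
            # without CIGAR detail, aligned blocks are the read spans
            self.aligned_blocks = self.read_spans

    @property
    def fragment_length(self) -> int:
        return self.frag_end - self.frag_start

    @property
    def mapq_rms(self) -> float:
        return math.sqrt(sum(q * q for q in self.mapqs) / len(self.mapqs))

    @property
    def duplicate_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.frag_start, self.frag_end, self.strand_orientation)


@dataclass(slots=True)
class VariantCall:
    """A normalised variant with genotype class and supporting depths.

    ``pos`` follows the VCF convention (1-based); use ``pos0`` for the
    package-internal 0-based coordinate.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype_class: str = "het"  # "het" | "hom"
    variant_class: str = "snv"  # "snv" | "indel"
    filter_status: str = "PASS"
    depth: int | None = None
    alt_depth: int | None = None
    qual: float | None = None
    mq: float | None = None
    sample_id: str = ""
    method_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.depth is not None and self.alt_depth is not None:
            if not (0 <= self.alt_depth <= self.depth):
                raise ValueError("require 0 <= alt_depth <= depth")
        if self.genotype_class not in ("het", "hom"):
            raise ValueError("genotype_class must be 'het' or 'hom'")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_balance(self) -> float | None:
        if self.depth in (None, 0) or self.alt_depth is None:
            return None
        return self.alt_depth / self.depth

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "snv"


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, name: str | None = None) -> TargetDesign:
    """Parse a BED file into a merged, sorted :class:`TargetDesign`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            iv_name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            intervals.append(GenomicInterval(cols[0], start, end, iv_name))
    return TargetDesign(name or Path(path).stem, intervals)


def write_bed(design: TargetDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in design:
            name = iv.name if iv.name else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------


def read_alignments(
    path: str | Path,
    region_filter: TargetDesign | None = None,
    sample_id: str = "",
    method_id: str = "",
    include_improper_as_single: bool = False,
) -> tuple[list[FragmentRecord], int]:
    """Collapse a coordinate-sorted paired-end SAM/BAM into fragments.

    Returns ``(fragments, skip_tally)``. Unmapped, secondary and
    supplementary records are skipped and tallied; a read pair that is
    not flagged properly paired is skipped as one unit (or, when
    ``include_improper_as_single`` is set, each read becomes a
    single-end fragment). Existing duplicate flags are preserved.
    """
    fragments: list[FragmentRecord] = []
    skipped = 0
    pending: dict[str, tuple] = {}

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(f"{path}: input must be coordinate-sorted (SO={so!r})")
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if not rec.is_paired:
                skipped += 1
                continue
            qsum = int(sum(rec.query_qualities)) if rec.query_qualities is not None else 0
            info = (
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                rec.mapping_quality,
                qsum,
                rec.is_read1,
                rec.is_reverse,
                rec.is_duplicate,
                rec.is_proper_pair,
                rec.query_length,
                tuple(rec.get_blocks()),
            )
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = info
                continue
            frag = _pair_to_fragment(rec.query_name, mate, info, sample_id, method_id)
            if frag is None:
                if include_improper_as_single:
                    for half in (mate, info):
                        fragments.append(_single_to_fragment(rec.query_name, half, sample_id, method_id))
                else:
                    skipped += 1
                continue
            fragments.append(frag)
        # unmatched singletons
        skipped += len(pending)

    if region_filter is not None:
        kept = []
        for f in fragments:
            if region_filter.any_overlap(f.chrom, [f.frag_start], [f.frag_end])[0]:
                kept.append(f)
        fragments = kept
    return fragments, skipped


def _pair_to_fragment(qname, a, b, sample_id, method_id) -> FragmentRecord | None:
    (ch_a, s_a, e_a, mq_a, q_a, r1_a, rev_a, dup_a, prop_a, len_a, blk_a) = a
    (ch_b, s_b, e_b, mq_b, q_b, r1_b, rev_b, dup_b, prop_b, len_b, blk_b) = b
    if ch_a != ch_b or not (prop_a and prop_b):
        return None
    left, right = (a, b) if s_a <= s_b else (b, a)
    if (not left[6]) and right[6]:  # leftmost forward, rightmost reverse: innie
        orientation = "FR" if left[5] else "RF"
    else:
        orientation = "other"
    frag_start = min(s_a, s_b)
    frag_end = max(e_a, e_b)
    return FragmentRecord(
        chrom=ch_a,
        frag_start=frag_start,
        frag_end=frag_end,
        strand_orientation=orientation,
        mapqs=(mq_a, mq_b),
        read_spans=tuple(sorted([(s_a, e_a), (s_b, e_b)])),
        aligned_blocks=tuple(sorted(blk_a + blk_b)),
        read_length=max(len_a, len_b),
        base_quality_sum=q_a + q_b,
        is_duplicate=dup_a or dup_b,
        name=qname,
        sample_id=sample_id,
        method_id=method_id,
    )


def _single_to_fragment(qname, a, sample_id, method_id) -> FragmentRecord:
    (ch, s, e, mq, q, _r1, rev, dup, _prop, ln, blk) = a
    return FragmentRecord(
        chrom=ch,
        frag_start=s,
        frag_end=e,
        strand_orientation="R" if rev else "F",
        mapqs=(mq,),
        read_spans=((s, e),),
        aligned_blocks=tuple(blk),
        read_length=ln,
        base_quality_sum=q,
        is_duplicate=dup,
        name=qname,
        sample_id=sample_id,
        method_id=method_id,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared leading/trailing bases (1-based ``pos`` adjusted).

    Trailing bases are trimmed first, then leading bases; each allele is
    left with at least one base. Idempotent.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _variant_class(ref: str, alt: str) -> str:
    return "snv" if len(ref) == 1 and len(alt) == 1 else "indel"


def read_vcf(
    path: str | Path,
    common: TargetDesign | None = None,
    sample_id: str = "",
    method_id: str = "",
) -> list[VariantCall]:
    """Read a VCF into normalised :class:`VariantCall` records.

    Multi-allelic records are decomposed into one call per ALT carried
    by the genotype; calls outside ``common`` (when given) are dropped;
    records with missing genotypes are skipped with a warning. Missing
    allelic depths leave ``alt_depth`` as None (allele balance
    unavailable).
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if not rec.alts:
                continue
            if samples:
                sample = rec.samples[samples[0]]
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    logger.warning("%s:%s missing genotype; variant skipped", rec.chrom, rec.pos)
                    continue
                ad = sample.get("AD")
                dp = sample.get("DP")
            else:
                gt, ad, dp = (1, 1), None, None
            filt = list(rec.filter.keys())
            filter_status = "PASS" if (not filt or filt == ["PASS"]) else ";".join(filt)
            mq = rec.info.get("MQ") if "MQ" in rec.info else None
            if isinstance(mq, tuple):
                mq = mq[0]
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or alt in (".", "*"):
                    continue
                n_alt = sum(1 for a in gt if a == ai)
                if n_alt == 0:
                    continue
                genotype_class = "hom" if n_alt == len([a for a in gt if a is not None]) else "het"
                pos, ref_n, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                if common is not None and not common.contains(rec.chrom, pos - 1):
                    continue
                depth = int(dp) if dp is not None else None
                alt_depth = None
                if ad is not None and ad[ai] is not None:
                    alt_depth = int(ad[ai])
                    if depth is None:
                        depth = int(sum(x for x in ad if x is not None))
                if alt_depth is not None and depth is not None:
                    alt_depth = min(alt_depth, depth)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref_n,
                        alt=alt_n,
                        genotype_class=genotype_class,
                        variant_class=_variant_class(ref_n, alt_n),
                        filter_status=filter_status,
                        depth=depth,
                        alt_depth=alt_depth,
                        qual=rec.qual,
                        mq=float(mq) if mq is not None else None,
                        sample_id=sample_id,
                        method_id=method_id,
                    )
                )
    return calls


def write_vcf(
    variants: list[VariantCall],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write calls as a minimal VCF 4.2 with GT:DP:AD."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=capture-qc",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FILTER=<ID=LowAB,Description="Low fraction of alt-supporting reads">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    if contig_lengths:
        for name, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        gt = "1/1" if v.genotype_class == "hom" else "0/1"
        qual = f"{v.qual:.1f}" if v.qual is not None else "."
        info = f"MQ={v.mq:.1f}" if v.mq is not None else "."
        if v.depth is not None and v.alt_depth is not None:
            fmt = f"GT:DP:AD\t{gt}:{v.depth}:{v.depth - v.alt_depth},{v.alt_depth}"
        else:
            fmt = f"GT\t{gt}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t{v.filter_status}\t{info}\t{fmt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
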