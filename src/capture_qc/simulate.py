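"""Synthetic capture-sequencing runs with per-method presets.

The generator emits a complete desk-scale sequencing run — reference
FASTA, capture design BED, coordinate-sorted SAM of aligned read
pairs, truth VCF of spiked variants and a truth-parameter table — with
the statistical structure the QC pipeline assumes:

* unique library fragments are placed on or off target with probability
  ``on_target_prob`` (an on-target fragment is drawn so both of its
  read spans overlap the design; an off-target fragment so neither
  does, which makes the read-level on-target fraction an unbiased
  estimate of the preset probability);
* fragment lengths are normal, truncated below at twice the read
  length;
* capture affinity can depend on fragment GC via ``gc_response``
  (rejection sampling), reproducing the high-GC coverage falloff of
  hybridisation capture;
* PCR duplication gives every unique fragment ``k`` sequenced copies
  with ``k - 1`` geometric — the memoryless single-parameter
  amplification model. For that parameterisation the expected
  duplicate read fraction is ``1 - p`` exactly, so ``p`` solves in
  closed form from the preset ``dup_fraction``;
* the total pair count is calibrated (by a pilot draw) so the raw mean
  depth over the design matches ``raw_mean_doc``;
* spiked variants are injected into reads at their true allele
  fraction (0.5 het / 1.0 hom, at the fragment level so PCR copies
  share alleles) before per-base sequencing errors;
* reads inside declared "pseudogene-like" blocks get MAPQ drawn from
  {0..10}, mimicking co-capture of homologous sequence, without
  modelling the homology itself.

Reads are emitted pre-aligned (no aligner in the loop): coordinates
are known by construction. Everything is deterministic given
``(seed, parameters)``.

Method presets
--------------
``PRESETS`` carries three named presets whose duplicate fractions
(7.7% / 18.5% / 41.2%), on-target read fractions (86% / 75% / 85%) and
raw mean depths (~370X) reproduce the printed per-method
characteristics of the NimbleGen SeqCap EZ Choice, SureSelect QXT and
Illumina NRCCE capture chemistries on a custom panel; fragment-size
parameters respect the published ordering (QXT longer and more
dispersed; NRCCE more dispersed than NimbleGen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .intervals import GenomicInterval, TargetDesign
from .io import ReferenceSequence, VariantCall, write_bed, write_vcf

__all__ = [
    "MethodPreset",
    "TruthTable",
    "PRESETS",
    "gc_dropoff",
    "generate_reference",
    "generate_design",
    "spike_variants",
    "simulate_run",
    "simulate_callsets",
    "draw_fragment_lengths",
]


@dataclass(frozen=True)
class MethodPreset:
    """Generative parameters of one simulated capture method."""

    name: str
    frag_mean: float
    frag_sd: float
    on_target_prob: float
    dup_fraction: float
    raw_mean_doc: float
    error_rate: float = 0.001
    read_length: int = 100
    q30_fraction: float = 0.90
    gc_response: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for p, label in [
            (self.on_target_prob, "on_target_prob"),
            (self.dup_fraction, "dup_fraction"),
            (self.error_rate, "error_rate"),
            (self.q30_fraction, "q30_fraction"),
        ]:
            if not (0 <= p <= 1):
                raise ValueError(f"{label} must be in [0, 1]")
        if self.dup_fraction >= 1:
            raise ValueError("dup_fraction must be < 1")
        if self.frag_sd <= 0 or self.raw_mean_doc <= 0 or self.read_length <= 0:
            raise ValueError("frag_sd, raw_mean_doc and read_length must be positive")

    def with_overrides(self, **kwargs) -> "MethodPreset":
        return replace(self, **kwargs)


PRESETS: dict[str, MethodPreset] = {
    "nimblegen": MethodPreset(
        name="NimbleGen", frag_mean=250, frag_sd=60,
        on_target_prob=0.86, dup_fraction=0.077, raw_mean_doc=370.0,
    ),
    "qxt": MethodPreset(
        name="SureSelectQXT", frag_mean=320, frag_sd=110,
        on_target_prob=0.75, dup_fraction=0.185, raw_mean_doc=370.0,
    ),
    "nrcce": MethodPreset(
        name="NRCCE", frag_mean=250, frag_sd=85,
        on_target_prob=0.85, dup_fraction=0.412, raw_mean_doc=371.0,
    ),
}


def gc_dropoff(knee: float = 0.65, slope: float = 3.0, floor: float = 0.2) -> Callable[[float], float]:
    """Capture-affinity curve: flat up to ``knee``, then linear falloff.

    Mirrors the empirical loss of capture efficiency above ~65-70% GC.
    """

    def response(gc: float) -> float:
        if gc <= knee:
            return 1.0
        return max(floor, 1.0 - slope * (gc - knee))

    return response


@dataclass
class TruthTable:
    """Realized per-run values, the acceptance surface for recovery tests."""

    preset_name: str
    seed: int
    n_unique_fragments: int
    total_read_pairs: int
    realized_duplicate_fraction: float
    realized_on_target_fraction: float
    variants: list[VariantCall] = field(default_factory=list)
    true_allele_fractions: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return 2 * self.total_read_pairs

    def to_dict(self) -> dict:
        return {
            "preset": self.preset_name,
            "seed": self.seed,
            "n_unique_fragments": self.n_unique_fragments,
            "total_read_pairs": self.total_read_pairs,
            "total_reads": self.total_reads,
            "realized_duplicate_fraction": self.realized_duplicate_fraction,
            "realized_on_target_fraction": self.realized_on_target_fraction,
            "n_variants": len(self.variants),
            "variants": [
                {
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                    "genotype": v.genotype_class, "class": v.variant_class,
                    "true_af": self.true_allele_fractions.get(v.key, 1.0 if v.genotype_class == "hom" else 0.5),
                }
                for v in self.variants
            ],
            "files": self.files,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# reference and design generation
# ---------------------------------------------------------------------------


def generate_reference(
    n_contigs: int = 2,
    contig_length: int = 300_000,
    gc_landscape: float | Sequence[float] = 0.45,
    seed: int = 0,
) -> ReferenceSequence:
    """Random reference with a controlled GC landscape.

    ``gc_landscape`` is either a single GC fraction or a sequence of
    block GC fractions; blocks divide each contig equally. Base counts
    are quota-sampled (exact GC up to rounding, positions shuffled), so
    the realized per-block GC is within rounding of the specification.
    """
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    blocks = [gc_landscape] if isinstance(gc_landscape, (int, float)) else list(gc_landscape)
    if any(not (0 <= g <= 1) for g in blocks):
        raise ValueError("GC fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    block_len = contig_length // len(blocks)
    for ci in range(n_contigs):
        parts = []
        for bi, gc in enumerate(blocks):
            ln = block_len if bi < len(blocks) - 1 else contig_length - block_len * (len(blocks) - 1)
            n_gc = int(round(gc * ln))
            n_g = n_gc // 2
            n_a = (ln - n_gc) // 2
            codes = np.concatenate([
                np.full(n_g, ord("G"), dtype=np.uint8),
                np.full(n_gc - n_g, ord("C"), dtype=np.uint8),
                np.full(n_a, ord("A"), dtype=np.uint8),
                np.full(ln - n_gc - n_a, ord("T"), dtype=np.uint8),
            ])
            rng.shuffle(codes)
            parts.append(codes.tobytes().decode("ascii"))
        contigs[f"chr{ci + 1}"] = "".join(parts)
    return ReferenceSequence(contigs)


def generate_design(
    reference: ReferenceSequence,
    n_regions: int = 300,
    region_length_range: tuple[int, int] = (150, 250),
    seed: int = 0,
    min_gap: int = 200,
    edge_margin: int = 1000,
) -> TargetDesign:
    """Exactly ``n_regions`` disjoint regions placed over the contigs.

    Regions are allocated to contigs proportionally to length and laid
    out left to right with random slack between them; an error is
    raised if the contigs cannot hold them with the requested gaps.
    """
    rng = np.random.default_rng(seed)
    lo, hi = region_length_range
    if not (0 < lo <= hi):
        raise ValueError("invalid region_length_range")
    names = reference.contig_names
    lengths = reference.contig_lengths
    total_len = sum(lengths.values())
    alloc = {c: int(n_regions * lengths[c] / total_len) for c in names}
    i = 0
    while sum(alloc.values()) < n_regions:
        alloc[names[i % len(names)]] += 1
        i += 1
    while sum(alloc.values()) > n_regions:
        alloc[names[-1]] -= 1

    intervals = []
    idx = 0
    for c in names:
        k = alloc[c]
        if k == 0:
            continue
        reg_lens = rng.integers(lo, hi + 1, size=k)
        usable = lengths[c] - 2 * edge_margin
        slack = usable - int(reg_lens.sum()) - (k - 1) * min_gap
        if slack < 0:
            raise ValueError(
                f"cannot place {k} regions of {lo}-{hi} bp on {c} "
                f"({lengths[c]} bp) with min_gap={min_gap}"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        pos = edge_margin
        prev_cut = 0
        for i in range(k):
            pos += int(cuts[i] - prev_cut)
            prev_cut = int(cuts[i])
            intervals.append(GenomicInterval(c, pos, pos + int(reg_lens[i]), f"region_{idx:04d}"))
            pos += int(reg_lens[i]) + min_gap
            idx += 1
    return TargetDesign("synthetic_design", intervals)


# ---------------------------------------------------------------------------
# variant spiking
# ---------------------------------------------------------------------------

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def spike_variants(
    design: TargetDesign,
    reference: ReferenceSequence,
    n_snv: int,
    n_indel: int,
    het_fraction: float = 0.5,
    tstv_target: float = 2.815,
    seed: int = 0,
) -> list[VariantCall]:
    """Plant SNVs and indels at distinct positions inside the design.

    SNV substitution types are drawn with transition probability
    ``tstv_target / (1 + tstv_target)`` so the expected Ts/Tv ratio
    equals the target. Indel lengths are 1-6 bp; when ``n_indel >= 1``
    the first indel is forced to be a 6 bp deletion (the classic
    missed-variant scenario for capture panels). Genotypes are
    heterozygous with probability ``het_fraction``.
    """
    if tstv_target <= 0:
        raise ValueError("tstv_target must be positive")
    rng = np.random.default_rng(seed)
    margin = 10
    candidates: list[tuple[str, int]] = []
    for iv in design:
        if iv.length > 2 * margin:
            candidates.append((iv.chrom, iv.start + margin, iv.end - margin))
    if not candidates:
        raise ValueError("design has no regions large enough for spiking")
    region_sizes = np.array([e - s for _, s, e in candidates], dtype=float)
    weights = region_sizes / region_sizes.sum()

    def draw_positions(
        n: int, min_spacing: int, avoid: list[tuple[str, int, int]]
    ) -> list[tuple[str, int]]:
        # same-class spacing via buckets of width min_spacing (only the
        # three neighbouring buckets can conflict); cross-class exclusion
        # zones in ``avoid`` are checked linearly (few entries)
        buckets: dict[tuple[str, int], list[int]] = {}
        out: list[tuple[str, int]] = []
        tries = 0
        while len(out) < n:
            tries += 1
            if tries > 200 * max(n, 1) + 1000:
                raise ValueError("could not place variants: positions exhausted")
            ri = int(rng.choice(len(candidates), p=weights))
            chrom, s, e = candidates[ri]
            pos = int(rng.integers(s, e))
            b = pos // min_spacing
            if any(
                abs(p - pos) < min_spacing
                for bb in (b - 1, b, b + 1)
                for p in buckets.get((chrom, bb), ())
            ):
                continue
            if any(c == chrom and abs(p - pos) < w for c, p, w in avoid):
                continue
            buckets.setdefault((chrom, b), []).append(pos)
            out.append((chrom, pos))
        return out

    # indels first: they need wide exclusive windows (no second variant
    # inside a read carrying the indel)
    indel_spacing = 2 * 150
    indel_pos = draw_positions(n_indel, indel_spacing, [])
    snv_pos = draw_positions(
        n_snv, 2, [(c, p, indel_spacing) for c, p in indel_pos]
    )

    p_ts = tstv_target / (1.0 + tstv_target)
    variants: list[VariantCall] = []
    for i, (chrom, pos0) in enumerate(indel_pos):
        het = rng.random() < het_fraction
        if i == 0:
            length, is_del = 6, True
        else:
            length = int(rng.integers(1, 7))
            is_del = bool(rng.random() < 0.5)
        anchor = reference.fetch(chrom, pos0, pos0 + 1)
        if is_del:
            ref = anchor + reference.fetch(chrom, pos0 + 1, pos0 + 1 + length)
            alt = anchor
        else:
            ref = anchor
            ins = "".join(rng.choice(list("ACGT"), size=length))
            alt = anchor + ins
        if ref == alt:  # degenerate insertion equal to ref extension; reroll base
            alt = anchor + "A" * length if not alt.endswith("A" * length) else anchor + "C" * length
        variants.append(
            VariantCall(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                genotype_class="het" if het else "hom", variant_class="indel",
            )
        )
    for chrom, pos0 in snv_pos:
        ref = reference.fetch(chrom, pos0, pos0 + 1)
        if ref == "N":
            continue
        if rng.random() < p_ts:
            alt = _TS_PARTNER[ref]
        else:
            alt = _TV_PARTNERS[ref][int(rng.integers(0, 2))]
        het = rng.random() < het_fraction
        variants.append(
            VariantCall(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                genotype_class="het" if het else "hom", variant_class="snv",
            )
        )
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------


def draw_fragment_lengths(preset: MethodPreset, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal fragment lengths (>= 2 x read length), integer bp."""
    min_len = 2 * preset.read_length
    out = np.empty(n, dtype=np.int64)
    need = n
    filled = 0
    while need > 0:
        draw = np.round(rng.normal(preset.frag_mean, preset.frag_sd, size=int(need * 1.8) + 16)).astype(np.int64)
        draw = draw[draw >= min_len][:need]
        out[filled : filled + draw.size] = draw
        filled += draw.size
        need -= draw.size
    return out


class _FragmentSampler:
    """Vectorised rejection sampler for unique fragment placement."""

    def __init__(self, reference: ReferenceSequence, design: TargetDesign, preset: MethodPreset):
        self.ref = reference
        self.design = design
        self.preset = preset
        self.contig_names = reference.contig_names
        self.contig_len = np.array([reference.contig_lengths[c] for c in self.contig_names], dtype=np.int64)
        self.contig_w = self.contig_len / self.contig_len.sum()
        ivs = list(design)
        self.region_chrom_idx = np.array([self.contig_names.index(iv.chrom) for iv in ivs], dtype=np.int64)
        self.region_start = np.array([iv.start for iv in ivs], dtype=np.int64)
        self.region_len = np.array([iv.length for iv in ivs], dtype=np.int64)
        w = self.region_len.astype(float)
        self.region_w = w / w.sum()
        if preset.gc_response is not None:
            grid = np.linspace(0, 1, 201)
            self.resp_max = max(preset.gc_response(g) for g in grid)
            if not np.isfinite(self.resp_max) or self.resp_max <= 0:
                raise ValueError("gc_response must be positive somewhere and finite")
        else:
            self.resp_max = None

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (chrom_idx, start, length, on_target) for n unique fragments."""
        L = self.preset.read_length
        chrom_idx = np.empty(n, dtype=np.int64)
        start = np.empty(n, dtype=np.int64)
        length = np.empty(n, dtype=np.int64)
        # fix the on/off-target assignment before placement: rejection rates
        # differ between the two classes, so redrawing the flag inside the
        # loop would bias the realized on-target fraction away from the preset
        on_flag = rng.random(n) < self.preset.on_target_prob
        remaining = np.arange(n)
        while remaining.size:
            m = remaining.size
            flen = draw_fragment_lengths(self.preset, m, rng)
            on = on_flag[remaining]
            cand_chrom = np.empty(m, dtype=np.int64)
            cand_start = np.empty(m, dtype=np.int64)
            if on.any():
                k = int(on.sum())
                ridx = rng.choice(len(self.region_w), size=k, p=self.region_w)
                anchor = self.region_start[ridx] + (rng.random(k) * self.region_len[ridx]).astype(np.int64)
                cand_start[on] = anchor - (rng.random(k) * flen[on]).astype(np.int64)
                cand_chrom[on] = self.region_chrom_idx[ridx]
            off = ~on
            if off.any():
                k = int(off.sum())
                cidx = rng.choice(len(self.contig_w), size=k, p=self.contig_w)
                span = np.maximum(self.contig_len[cidx] - flen[off], 1)
                cand_start[off] = (rng.random(k) * span).astype(np.int64)
                cand_chrom[off] = cidx
            cand_end = cand_start + flen
            good = (cand_start >= 0) & (cand_end <= self.contig_len[cand_chrom])
            for ci, cname in enumerate(self.contig_names):
                mm = good & (cand_chrom == ci)
                if not mm.any():
                    continue
                s = cand_start[mm]
                e = cand_end[mm]
                left_hit = self.design.any_overlap(cname, s, s + L)
                right_hit = self.design.any_overlap(cname, e - L, e)
                ok = np.where(on[mm], left_hit & right_hit, ~(left_hit | right_hit))
                gg = good[mm]
                gg &= ok
                good[mm] = gg
            if self.resp_max is not None:
                sel = np.flatnonzero(good)
                if sel.size:
                    accept_u = rng.random(sel.size)
                    resp = self.preset.gc_response
                    keep = np.ones(sel.size, dtype=bool)
                    for ii, j in enumerate(sel):
                        c = self.contig_names[cand_chrom[j]]
                        seq = self.ref.fetch(c, int(cand_start[j]), int(cand_end[j]))
                        gc = (seq.count("G") + seq.count("C")) / len(seq)
                        keep[ii] = accept_u[ii] < resp(gc) / self.resp_max
                    good[sel] = keep
            accepted = np.flatnonzero(good)
            tgt = remaining[accepted]
            chrom_idx[tgt] = cand_chrom[accepted]
            start[tgt] = cand_start[accepted]
            length[tgt] = flen[accepted]
            remaining = remaining[~good]
        return chrom_idx, start, length, on_flag


def _apply_variants(ctg: str, rs: int, L: int, vs: list[VariantCall]) -> tuple[str, str]:
    """Sequence and CIGAR of a read at [rs, rs+L) carrying the given alleles.

    At most one indel is applied per read (spiking enforces wide indel
    spacing); an indel only partially covered by the read is left
    unapplied, so edge reads show the reference allele — as they would
    in a real alignment.
    """
    max_del = max((len(v.ref) - 1 for v in vs), default=0)
    window = ctg[rs : rs + L + max_del]
    cigar = f"{L}M"
    # apply right-to-left so earlier offsets stay valid
    for v in sorted(vs, key=lambda v: -v.pos0):
        off = v.pos0 - rs
        if v.variant_class == "snv":
            if 0 <= off < L:
                window = window[:off] + v.alt + window[off + 1 :]
        elif len(v.ref) > len(v.alt):  # deletion
            dlen = len(v.ref) - 1
            if 0 <= off < L - 1 and off + 1 + dlen <= len(window):
                window = window[: off + 1] + window[off + 1 + dlen :]
                cigar = f"{off + 1}M{dlen}D{L - off - 1}M"
        else:  # insertion
            ilen = len(v.alt) - 1
            if 0 <= off < L - 1:
                window = window[: off + 1] + v.alt[1:] + window[off + 1 :]
                keep = L - off - 1 - ilen
                if keep <= 0:
                    cigar = f"{off + 1}M{L - off - 1}I"
                else:
                    cigar = f"{off + 1}M{ilen}I{keep}M"
    return window[:L], cigar


def simulate_run(
    reference: ReferenceSequence,
    design: TargetDesign,
    preset: MethodPreset,
    seed: int,
    out_dir: str | Path,
    n_pairs: int | None = None,
    variants: list[VariantCall] | None = None,
    pseudogene_blocks: TargetDesign | None = None,
    ref_bias: float = 0.0,
    sample_id: str = "sample01",
    write_reference: bool = True,
    calibration_pairs: int = 4000,
) -> TruthTable:
    """Simulate one capture run; write run.sam / truth.vcf / design.bed / truth.json.

    ``n_pairs`` is the total sequenced read-pair count including
    duplicates; when None it is calibrated so the raw mean depth over
    the design matches ``preset.raw_mean_doc``. ``ref_bias`` is the
    probability that an alt-carrying unique fragment reverts to the
    reference allele (capture/alignment bias against the alt), used
    for allele-balance experiments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    preset_p = 1.0 - preset.dup_fraction
    L = preset.read_length
    sampler = _FragmentSampler(reference, design, preset)
    variants = variants or []

    if n_pairs is None:
        ci, st, ln, _on = sampler.draw(calibration_pairs, rng)
        bases = np.zeros(calibration_pairs, dtype=np.int64)
        for k, cname in enumerate(sampler.contig_names):
            mm = ci == k
            if not mm.any():
                continue
            s, e = st[mm], st[mm] + ln[mm]
            bases[mm] = design.overlap_bases(cname, s, s + L) + design.overlap_bases(cname, e - L, e)
        mean_b = float(bases.mean())
        if mean_b <= 0:
            raise ValueError("calibration produced no on-target bases; depth unattainable")
        n_pairs = int(round(preset.raw_mean_doc * design.total_size / mean_b))
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")

    n_unique = max(1, int(round(n_pairs * preset_p)))
    chrom_idx, start, flen, on_flag = sampler.draw(n_unique, rng)
    end = start + flen
    orient = rng.integers(0, 2, size=n_unique)  # 0: FR (read1 leftmost), 1: RF
    mapq = np.full(n_unique, 60, dtype=np.int64)
    if pseudogene_blocks is not None:
        for k, cname in enumerate(sampler.contig_names):
            mm = chrom_idx == k
            if mm.any():
                hit = pseudogene_blocks.any_overlap(cname, start[mm], end[mm])
                sub = mapq[mm]
                sub[hit] = rng.integers(0, 11, size=int(hit.sum()))
                mapq[mm] = sub

    # fragment-level variant carriers (PCR copies share alleles)
    carriers: dict[int, list[VariantCall]] = {}
    true_af: dict[tuple, float] = {}
    for v in variants:
        k = sampler.contig_names.index(v.chrom)
        cover = (chrom_idx == k) & (start <= v.pos0) & (end > v.pos0)
        af = 1.0 if v.genotype_class == "hom" else 0.5
        carry = cover.copy()
        if v.genotype_class == "het":
            carry &= rng.random(n_unique) < 0.5
        if ref_bias > 0:
            carry &= rng.random(n_unique) >= ref_bias
            af *= 1.0 - ref_bias
        true_af[v.key] = af
        for j in np.flatnonzero(carry):
            carriers.setdefault(int(j), []).append(v)

    copies = rng.geometric(preset_p, size=n_unique) if preset_p < 1.0 else np.ones(n_unique, dtype=np.int64)
    total_pairs = int(copies.sum())
    rep = np.repeat(np.arange(n_unique), copies)
    first_of = np.repeat(np.cumsum(copies) - copies, copies)
    copy_no = np.arange(total_pairs) - first_of

    n_reads = 2 * total_pairs
    q_hi = 37
    q_lo = 22
    qmask = rng.random((n_reads, L)) < preset.q30_fraction
    qbytes = np.where(qmask, np.uint8(q_hi + 33), np.uint8(q_lo + 33))
    del qmask
    err_counts = rng.binomial(L, preset.error_rate, size=n_reads)
    total_err = int(err_counts.sum())
    err_pos = rng.integers(0, L, size=total_err)
    err_pick = rng.integers(0, 3, size=total_err)
    err_off = np.concatenate([[0], np.cumsum(err_counts)])

    contig_strings = [reference.sequence(c) for c in sampler.contig_names]
    # precompute per-fragment variant read templates
    var_templates: dict[int, tuple[str, str, str, str]] = {}
    for j, vs in carriers.items():
        ctg = contig_strings[chrom_idx[j]]
        ls = int(start[j])
        rs = int(end[j]) - L
        seq_l, cig_l = _apply_variants(ctg, ls, L, [v for v in vs if ls <= v.pos0 < ls + L])
        seq_r, cig_r = _apply_variants(ctg, rs, L, [v for v in vs if rs <= v.pos0 < rs + L])
        var_templates[j] = (seq_l, cig_l, seq_r, cig_r)

    default_cigar = f"{L}M"
    other_bases = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG", 78: "ACG"}  # keyed by ord
    lines: list[str] = []
    sort_chrom = np.empty(n_reads, dtype=np.int64)
    sort_pos = np.empty(n_reads, dtype=np.int64)

    def _finish_read(seq: str, ridx: int) -> tuple[str, str]:
        nerr = err_counts[ridx]
        if nerr:
            ba = bytearray(seq, "ascii")
            o = err_off[ridx]
            for t in range(nerr):
                p = err_pos[o + t]
                ba[p] = ord(other_bases.get(ba[p], "ACG")[err_pick[o + t]])
            seq = ba.decode("ascii")
        return seq, qbytes[ridx].tobytes().decode("ascii")

    for j in range(total_pairs):
        f = int(rep[j])
        ci_ = int(chrom_idx[f])
        cname = sampler.contig_names[ci_]
        s = int(start[f])
        e = int(end[f])
        fl = e - s
        tmpl = var_templates.get(f)
        if tmpl is None:
            ctg = contig_strings[ci_]
            seq_l, cig_l = ctg[s : s + L], default_cigar
            seq_r, cig_r = ctg[e - L : e], default_cigar
        else:
            seq_l, cig_l, seq_r, cig_r = tmpl
        seq_l, qual_l = _finish_read(seq_l, 2 * j)
        seq_r, qual_r = _finish_read(seq_r, 2 * j + 1)
        if orient[f] == 0:
            flag_l, flag_r = 99, 147
        else:
            flag_l, flag_r = 163, 83
        qname = f"F{f:07d}C{copy_no[j]}"
        mq = int(mapq[f])
        pos_l = s + 1
        pos_r = e - L + 1
        lines.append(
            f"{qname}\t{flag_l}\t{cname}\t{pos_l}\t{mq}\t{cig_l}\t=\t{pos_r}\t{fl}\t{seq_l}\t{qual_l}"
        )
        lines.append(
            f"{qname}\t{flag_r}\t{cname}\t{pos_r}\t{mq}\t{cig_r}\t=\t{pos_l}\t{-fl}\t{seq_r}\t{qual_r}"
        )
        sort_chrom[2 * j] = ci_
        sort_chrom[2 * j + 1] = ci_
        sort_pos[2 * j] = pos_l
        sort_pos[2 * j + 1] = pos_r

    order = np.lexsort((sort_pos, sort_chrom))
    sam_path = out_dir / "run.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for cname in sampler.contig_names:
            fh.write(f"@SQ\tSN:{cname}\tLN:{reference.contig_lengths[cname]}\n")
        fh.write(f"@RG\tID:{sample_id}\tSM:{sample_id}\tPL:ILLUMINA\n")
        fh.write("@PG\tID:capture-qc\tPN:capture-qc\n")
        for i in order:
            fh.write(lines[i])
            fh.write("\n")

    # read-level realized on-target fraction, copy-weighted
    on_reads = 0
    for k, cname in enumerate(sampler.contig_names):
        mm = chrom_idx == k
        if not mm.any():
            continue
        s, e = start[mm], end[mm]
        lh = design.any_overlap(cname, s, s + L).astype(np.int64)
        rh = design.any_overlap(cname, e - L, e).astype(np.int64)
        on_reads += int(((lh + rh) * copies[mm]).sum())
    realized_on = on_reads / n_reads

    vcf_path = out_dir / "truth.vcf"
    write_vcf(variants, vcf_path, reference.contig_lengths, sample=sample_id)
    bed_path = out_dir / "design.bed"
    write_bed(design, bed_path)
    files = {"sam": str(sam_path), "vcf": str(vcf_path), "bed": str(bed_path)}
    if write_reference:
        fa_path = out_dir / "reference.fa"
        reference.write_fasta(fa_path)
        files["fasta"] = str(fa_path)

    truth = TruthTable(
        preset_name=preset.name,
        seed=seed,
        n_unique_fragments=n_unique,
        total_read_pairs=total_pairs,
        realized_duplicate_fraction=1.0 - n_unique / total_pairs,
        realized_on_target_fraction=realized_on,
        variants=variants,
        true_allele_fractions=true_af,
        files=files,
    )
    truth.save(out_dir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# downstream callset simulation (variant calling itself is upstream/out of scope)
# ---------------------------------------------------------------------------


def simulate_callsets(
    truth_variants: list[VariantCall],
    method_ids: Sequence[str],
    seed: int,
    mean_depth: float = 300.0,
    hom_error: float = 0.008,
    af_spread: float = 0.0,
    ref_bias: float = 0.0,
    min_af: float = 0.2,
    min_alt_reads: int = 3,
    min_depth: int = 10,
    pass_af: float = 0.25,
) -> dict[str, list[VariantCall]]:
    """Per-method callsets downstream of a shared truth set.

    Each truth variant gets one latent allele fraction (0.5 het /
    ``1 - hom_error`` hom, jittered by ``af_spread`` and shifted by
    ``ref_bias`` for hets); each method then observes Poisson depth and
    binomial allelic depth and calls the variant when it clears the
    allele-fraction and read-support thresholds. Detection is thereby
    tied to allele balance: variants missed by some methods are the
    low-AB ones, and calls below ``pass_af`` carry a non-PASS filter.
    """
    rng = np.random.default_rng(seed)
    latent: dict[tuple, float] = {}
    for v in truth_variants:
        if v.genotype_class == "hom":
            af = 1.0 - hom_error
        else:
            af = 0.5 * (1.0 - ref_bias) + (rng.normal(0, af_spread) if af_spread > 0 else 0.0)
        latent[v.key] = float(np.clip(af, 0.02, 1.0))
    callsets: dict[str, list[VariantCall]] = {}
    for m in method_ids:
        calls: list[VariantCall] = []
        for v in truth_variants:
            depth = int(rng.poisson(mean_depth))
            if depth < min_depth:
                continue
            alt = int(rng.binomial(depth, latent[v.key]))
            if alt < min_alt_reads or alt / depth < min_af:
                continue
            qual = float(max(10.0, min(3000.0, 35.0 + 8.0 * alt + rng.normal(0, 25))))
            mq = float(np.clip(60.0 - abs(rng.normal(0, 1.5)), 0, 60))
            calls.append(
                VariantCall(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    genotype_class=v.genotype_class, variant_class=v.variant_class,
                    filter_status="PASS" if alt / depth >= pass_af else "LowAB",
                    depth=depth, alt_depth=alt, qual=qual, mq=mq, method_id=m,
                )
            )
        callsets[m] = calls
    return callsets
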