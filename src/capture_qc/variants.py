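"""Multi-callset variant concordance and per-callset quality statistics.

Variant identity everywhere in this module is the exact key
``(chrom, pos, ref, alt)`` after left-normalisation and multi-allelic
decomposition (see :mod:`capture_qc.io`); no fuzzy indel matching is
attempted. Concordance over three methods is reported as the seven
Venn cells; allele balance (alt reads / total reads) is summarised per
genotype x variant-class stratum over PASS calls; Ts/Tv counts
transitions (A<->G, C<->T) against all other single-base substitutions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "AlleleBalanceSummary",
    "concordance",
    "tstv_ratio",
    "allele_balance_summary",
    "truth_sensitivity",
    "call_quality_summary",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class ConcordanceResult:
    """Counts for the 7 Venn cells over three callsets A, B, C."""

    methods: tuple[str, str, str]
    cells: dict[str, int]  # keys: "ABC", "AB", "AC", "BC", "A", "B", "C"
    keys_by_cell: dict[str, set] = field(default_factory=dict)

    def per_method_total(self, method_label: str) -> int:
        return sum(n for cell, n in self.cells.items() if method_label in cell)

    @property
    def n_common(self) -> int:
        return self.cells["ABC"]


def _collapse(calls: list[VariantCall], label: str) -> dict[tuple, VariantCall]:
    out: dict[tuple, VariantCall] = {}
    for v in calls:
        if v.key in out:
            logger.warning("%s: duplicate variant key %s collapsed", label, v.key)
        out[v.key] = v
    return out


def concordance(callsets: dict[str, list[VariantCall]]) -> ConcordanceResult:
    """Three-way Venn of variant keys.

    All variants are included regardless of filter status (discordant
    calls are frequently the filtered ones, and dropping them would
    hide exactly the disagreement being measured). Duplicate keys
    within one callset are collapsed with a warning.
    """
    if len(callsets) != 3:
        raise ValueError("concordance expects exactly 3 callsets")
    methods = tuple(callsets)
    labels = ("A", "B", "C")
    sets = {
        lab: set(_collapse(callsets[m], m)) for lab, m in zip(labels, methods)
    }
    a, b, c = sets["A"], sets["B"], sets["C"]
    keys_by_cell = {
        "ABC": a & b & c,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
    }
    return ConcordanceResult(
        methods=methods,
        cells={k: len(v) for k, v in keys_by_cell.items()},
        keys_by_cell=keys_by_cell,
    )


def tstv_ratio(variants: list[VariantCall]) -> float:
    """Transitions / transversions over SNVs; inf (with warning) if no Tv."""
    ts = tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if (v.ref, v.alt) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        logger.warning("no transversions observed; Ts/Tv ratio is infinite")
        return math.inf
    return ts / tv


@dataclass
class AlleleBalanceSummary:
    genotype_class: str
    variant_class: str
    mean_ab: float
    sd_ab: float
    n: int


def allele_balance_summary(
    variants: list[VariantCall], pass_only: bool = True
) -> list[AlleleBalanceSummary]:
    """Mean/SD of alt_depth/depth per (genotype x variant-class) stratum.

    Defaults to PASS calls only, the convention for reporting allele
    balance of accepted variants. Calls without usable depths are
    excluded with a warning.
    """
    strata: dict[tuple[str, str], list[float]] = {}
    for v in variants:
        if pass_only and v.filter_status != "PASS":
            continue
        ab = v.allele_balance
        if ab is None:
            logger.warning("variant %s has no usable depths; excluded from AB", v.key)
            continue
        strata.setdefault((v.genotype_class, v.variant_class), []).append(ab)
    out = []
    for (gt, vc), vals in sorted(strata.items()):
        arr = np.array(vals)
        out.append(
            AlleleBalanceSummary(
                genotype_class=gt,
                variant_class=vc,
                mean_ab=float(arr.mean()),
                sd_ab=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                n=int(arr.size),
            )
        )
    return out


def truth_sensitivity(
    calls: list[VariantCall], truth: list[VariantCall], window: int = 10
) -> tuple[int, int, list[dict]]:
    """(n_found, n_truth, misses) by exact key membership.

    Each missed truth variant is reported with nearest-call
    diagnostics: any call within ``window`` bp and its allele balance —
    the forensics needed when a variant is present in the reads at
    reduced allele fraction but absent from the callset.
    """
    call_keys = {v.key for v in calls}
    by_chrom: dict[str, list[VariantCall]] = {}
    for v in calls:
        by_chrom.setdefault(v.chrom, []).append(v)
    misses = []
    n_found = 0
    for t in truth:
        if t.key in call_keys:
            n_found += 1
            continue
        nearby = [
            {
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "allele_balance": c.allele_balance,
                "filter_status": c.filter_status,
            }
            for c in by_chrom.get(t.chrom, [])
            if abs(c.pos - t.pos) <= window
        ]
        misses.append(
            {"chrom": t.chrom, "pos": t.pos, "ref": t.ref, "alt": t.alt, "nearby_calls": nearby}
        )
    return n_found, len(truth), misses


def call_quality_summary(variants: list[VariantCall]) -> dict:
    """Mean QUAL and mean MQ over PASS calls, with missing-value counts."""
    quals = [v.qual for v in variants if v.filter_status == "PASS" and v.qual is not None]
    mqs = [v.mq for v in variants if v.filter_status == "PASS" and v.mq is not None]
    return {
        "mean_qual": float(np.mean(quals)) if quals else None,
        "n_qual": len(quals),
        "mean_mq": float(np.mean(mqs)) if mqs else None,
        "n_mq": len(mqs),
    }
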