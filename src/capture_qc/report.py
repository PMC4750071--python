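"""Pipeline orchestration and machine-readable run reports.

``run_pipeline`` drives the full flow — simulate per-method runs for a
set of samples, mark duplicates, compute coverage/enrichment/variant
metrics, and compare methods — and assembles everything into a
:class:`RunReport` that serialises to JSON (nested) and TSV (flat).
Reports are deterministic given the configured seed and carry a
provenance block (seed, package version, parameters) instead of
timestamps, so identical configurations produce byte-identical
reports.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (
    compute_depth,
    coverage_thresholds,
    evenness_score,
    gc_coverage_profile,
    normalized_doc,
    per_region_coverage,
    region_mapq_summary,
)
from .dedup import duplicate_summary, mark_duplicates
from .enrichment import enrichment_result, run_stats
from .io import read_alignments
from .simulate import (
    PRESETS,
    generate_design,
    generate_reference,
    simulate_callsets,
    simulate_run,
    spike_variants,
)
from .variants import (
    allele_balance_summary,
    call_quality_summary,
    concordance,
    truth_sensitivity,
    tstv_ratio,
)
from .stats import metric_comparison_table

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DataError", "RunReport", "default_config", "validate_config", "run_pipeline"]


class ConfigError(Exception):
    """Invalid or incomplete configuration (exit code 2 at the CLI)."""


class DataError(Exception):
    """Failure while reading or computing on data (exit code 3 at the CLI)."""


def default_config() -> dict:
    return {
        "seed": 1,
        "out_dir": "capture_qc_out",
        "simulate": {
            "presets": ["nimblegen", "qxt", "nrcce"],
            "samples": 2,
            "n_pairs": 8000,
            "reference": {"n_contigs": 2, "contig_length": 300_000, "gc_landscape": 0.45},
            "design": {"n_regions": 300, "region_length_range": [150, 250]},
            "variants": {"n_snv": 150, "n_indel": 8, "het_fraction": 0.6, "tstv_target": 2.815},
        },
        "thresholds": [20, 50, 100, 280],
        "gc_bin_width": 0.05,
        "mapq_floor": 20,
        "padding": 0,
        "alpha": 0.025,
    }


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults and sanity-check it."""
    merged = default_config()
    config = config or {}
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            for k2, v2 in value.items():
                if k2 not in merged[key]:
                    raise ConfigError(f"unknown config key: {key}.{k2}")
                if isinstance(merged[key][k2], dict) and isinstance(v2, dict):
                    merged[key][k2].update(v2)
                else:
                    merged[key][k2] = v2
        else:
            merged[key] = value
    sim = merged["simulate"]
    unknown = [p for p in sim["presets"] if p not in PRESETS]
    if unknown:
        raise ConfigError(f"unknown presets: {unknown}; available: {sorted(PRESETS)}")
    if sim["samples"] < 1:
        raise ConfigError("simulate.samples must be >= 1")
    if not (0 < merged["alpha"] < 1):
        raise ConfigError("alpha must be in (0, 1)")
    if any(t < 0 for t in merged["thresholds"]):
        raise ConfigError("thresholds must be non-negative")
    return merged


@dataclass
class RunReport:
    """All computed metrics for one pipeline execution."""

    provenance: dict
    rows: list[dict] = field(default_factory=list)  # one per sample x method
    concordance_by_sample: dict = field(default_factory=dict)
    mean_common_variants: float | None = None
    comparisons: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "rows": self.rows,
            "concordance_by_sample": self.concordance_by_sample,
            "mean_common_variants": self.mean_common_variants,
            "comparisons": self.comparisons,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load_json(cls, path: str | Path) -> "RunReport":
        d = json.loads(Path(path).read_text())
        return cls(
            provenance=d["provenance"],
            rows=d["rows"],
            concordance_by_sample=d["concordance_by_sample"],
            mean_common_variants=d["mean_common_variants"],
            comparisons=d["comparisons"],
        )

    def to_tsv(self, path: str | Path) -> None:
        flat = []
        for row in self.rows:
            flat.append({k: v for k, v in row.items() if not isinstance(v, (dict, list))})
        pd.DataFrame(flat).to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> RunReport:
    """Simulate -> dedup -> coverage -> enrich -> concord -> compare.

    The same reference, design and per-sample truth variants are shared
    by all methods (the same patients sequenced three ways); only the
    capture/sequencing process differs by preset.
    """
    cfg = validate_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim = cfg["simulate"]

    reference = generate_reference(seed=seed, **sim["reference"])
    design = generate_design(
        reference,
        n_regions=sim["design"]["n_regions"],
        region_length_range=tuple(sim["design"]["region_length_range"]),
        seed=seed + 1,
    )

    report = RunReport(
        provenance={"seed": seed, "version": __version__, "config": copy.deepcopy(cfg)}
    )

    samples = [f"sample{i + 1:02d}" for i in range(sim["samples"])]
    truth_by_sample = {}
    callsets_by_sample = {}
    for si, sample in enumerate(samples):
        truth_by_sample[sample] = spike_variants(
            design,
            reference,
            n_snv=sim["variants"]["n_snv"],
            n_indel=sim["variants"]["n_indel"],
            het_fraction=sim["variants"]["het_fraction"],
            tstv_target=sim["variants"]["tstv_target"],
            seed=seed + 100 + si,
        )
        callsets_by_sample[sample] = simulate_callsets(
            truth_by_sample[sample],
            method_ids=list(sim["presets"]),
            seed=seed + 200 + si,
            af_spread=0.06,
        )

    per_sample_metric: dict[str, dict[str, dict[str, float]]] = {}
    for mi, preset_key in enumerate(sim["presets"]):
        preset = PRESETS[preset_key]
        for si, sample in enumerate(samples):
            run_seed = seed + 1000 + 37 * mi + si
            run_dir = out / f"{preset_key}_{sample}"
            try:
                truth = simulate_run(
                    reference,
                    design,
                    preset,
                    seed=run_seed,
                    out_dir=run_dir,
                    n_pairs=sim["n_pairs"],
                    variants=truth_by_sample[sample],
                    sample_id=sample,
                    write_reference=False,
                )
                fragments, skipped = read_alignments(
                    truth.files["sam"], sample_id=sample, method_id=preset_key
                )
                mark_duplicates(fragments)
                dup = duplicate_summary(fragments)
                enr = enrichment_result(
                    fragments, design, reference.genome_size, padding=cfg["padding"]
                )
                raw = compute_depth(fragments, design, exclude_duplicates=False)
                dedup = compute_depth(fragments, design, exclude_duplicates=True)
                es = evenness_score(dedup)
                thresholds = coverage_thresholds(dedup, cfg["thresholds"])
                regions = normalized_doc(
                    per_region_coverage(dedup, reference, thresholds=cfg["thresholds"])
                )
                gc_table = gc_coverage_profile(regions, bin_width=cfg["gc_bin_width"])
                low_mapq = [
                    r.region.name
                    for r in region_mapq_summary(fragments, design, cfg["mapq_floor"])
                    if r.status == "low_mapq"
                ]
                stats_ = run_stats(truth.files["sam"])
                calls = callsets_by_sample[sample][preset_key]
                ab = allele_balance_summary(calls)
                quality = call_quality_summary(calls)
                n_found, n_truth, _misses = truth_sensitivity(calls, truth_by_sample[sample])
            except (OSError, ValueError) as exc:
                raise DataError(f"stage failure for {preset_key}/{sample}: {exc}") from exc
            row = {
                "sample": sample,
                "method": preset_key,
                "n_pairs": truth.total_read_pairs,
                "skipped_records": skipped,
                "duplicate_fraction": dup.duplicate_fraction,
                "on_target_read_fraction": enr.on_target_read_fraction,
                "on_target_base_fraction": enr.on_target_base_fraction,
                "enrichment_factor": enr.enrichment_factor,
                "raw_mean_doc": raw.mean_doc,
                "dedup_mean_doc": dedup.mean_doc,
                "evenness_score": es.es_percent,
                "q30_fraction": stats_.q30_fraction,
                "fragment_size_median": stats_.fragment_size_median,
                "fragment_size_iqr": stats_.fragment_size_iqr,
                "tstv": tstv_ratio(calls),
                "truth_sensitivity": n_found / n_truth if n_truth else None,
                "pct_ge": {str(k): v for k, v in thresholds.items()},
                "gc_table": gc_table,
                "allele_balance": [vars(s) for s in ab],
                "call_quality": quality,
                "low_mapq_regions": low_mapq,
            }
            report.rows.append(row)
            per_sample_metric.setdefault("duplicate_fraction", {}).setdefault(preset_key, {})[
                sample
            ] = dup.duplicate_fraction
            per_sample_metric.setdefault("dedup_mean_doc", {}).setdefault(preset_key, {})[
                sample
            ] = dedup.mean_doc
            logger.info("finished %s/%s (%d pairs)", preset_key, sample, truth.total_read_pairs)

    if len(sim["presets"]) == 3:
        commons = []
        for sample in samples:
            res = concordance(callsets_by_sample[sample])
            report.concordance_by_sample[sample] = dict(res.cells)
            commons.append(res.n_common)
        report.mean_common_variants = float(np.mean(commons))

    if len(samples) >= 2 and len(sim["presets"]) >= 2:
        for metric, data in per_sample_metric.items():
            try:
                table = metric_comparison_table(data, alpha=cfg["alpha"], metric=metric)
                report.comparisons.extend(table.to_dict(orient="records"))
            except ValueError as exc:
                logger.warning("comparison for %s undefined: %s", metric, exc)

    report.save_json(out / "report.json")
    report.to_tsv(out / "report.tsv")
    return report
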