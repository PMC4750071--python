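# capture-qc

QC and benchmarking toolkit for **hybrid-capture target-enrichment
sequencing**, plus a synthetic sequencing-run generator with
per-method presets so the whole pipeline can be exercised and
validated without access to patient data.

Diagnostic laboratories that sequence custom gene panels must
periodically re-assess their library-enrichment chemistry: protocols
differ sharply in PCR-duplicate burden, on-target yield, evenness of
coverage, GC robustness and, ultimately, in the consistency of the
variant callsets they produce. `capture-qc` implements the complete
comparison methodology for that assessment — the metrics, the
multi-method variant concordance, and the paired nonparametric
statistics — for anyone benchmarking capture kits (e.g. NimbleGen
SeqCap EZ Choice vs. SureSelect QXT vs. Illumina Nextera Rapid Custom
Capture Enrichment on a deafness/retinopathy panel) or validating a
targeted-sequencing workflow.

## What it computes

For each sample × method (from a coordinate-sorted SAM/BAM, a BED
design, a FASTA reference and VCF callsets):

* **Duplicates** — coordinate-based PCR-duplicate marking on fragment
  outer coordinates `(chrom, start, end, orientation)`, keeping the
  highest-base-quality fragment per set; global and per-region
  duplicate read fractions.
* **Enrichment** — on-target read/base fractions (≥ 1 bp overlap with
  the optionally padded design) and the **Enrichment Factor**

  ```
  EF = on-target base fraction / (target size / genome size)
  ```

  which makes capture efficiency comparable across designs of
  different sizes.
* **Coverage** — per-base depth of coverage (DOC) raw and
  duplicates-excluded, threshold tables (fraction of targeted bases
  ≥ 20/50/100/280X), per-region and per-base depth-distribution
  curves, and the **evenness score**

  ```
  ES = 100 · (1/⌊C̄⌋) · Σ_{i=1..⌊C̄⌋} F(i),   F(i) = fraction of targeted bases with depth ≥ i
  ```

  (100 % ⇔ perfectly uniform coverage, independent of depth); the
  normalised per-region depth `nDOC_i = aDOC_i / aDOC` for
  cross-method comparison; GC-binned nDOC profiles; per-region RMS
  mapping quality for pseudogene screening.
* **Variants** — left-normalised, multi-allelic-decomposed callsets
  restricted to the designs' common regions; three-way concordance
  (7 Venn cells), Ts/Tv ratio, allele-balance summaries per
  genotype × variant class, QUAL/MQ summaries, and truth-set
  sensitivity with near-miss forensics.
* **Statistics** — paired one-sided Wilcoxon signed-rank tests
  (exact, by full null-distribution computation, up to n = 25 pairs;
  tie-corrected normal approximation beyond), for every method pair
  and metric.

The synthetic generator (`capture_qc.simulate`) emits complete runs —
reference FASTA, design BED, aligned SAM, truth VCF, truth-parameter
JSON — under presets that encode each method's published duplicate
fraction (7.7 % / 18.5 % / 41.2 %), on-target fraction
(86 % / 75 % / 85 %) and ~370X raw depth, with controllable fragment
sizes, GC-dependent capture response, spiked variants and
pseudogene-like low-MAPQ blocks.

## Worked example

Simulate an NRCCE-like run at full preset depth, mark duplicates and
compute coverage:

```bash
capture-qc simulate --preset nrcce --seed 7 --out demo
capture-qc dedup    --in demo/run.sam --report demo/dedup.json
capture-qc coverage --in demo/run.sam --design demo/design.bed --ref demo/reference.fa
```

prints (abridged):

```
"n_unique_fragments": 119181,  "total_read_pairs": 202613,
"realized_duplicate_fraction": 0.4118,  "realized_on_target_fraction": 0.8528
...
"duplicate_fraction": 0.4142
...
"raw_mean_doc": 372.3,  "dedup_mean_doc": 217.8,  "evenness_score": 88.5,
"pct_ge": {"20": 0.9997, "50": 0.9997, "100": 0.9823, "280": 0.1742}
```

Reading: the generator produced ~203k read pairs of which 41.2 % are
PCR copies; coordinate marking recovers 41.4 % (the small excess is
coincidental coordinate collisions, unavoidable for any
coordinate-keyed dedup at 370X on a 60 kb design). Raw mean depth
372X collapses to 218X once duplicates are excluded — at this
duplicate load nearly half the sequencing is useless for calling —
while 99.97 % of targeted bases still clear 20X and the evenness
score is 88.5 %.

`capture-qc all --seed 1 --out out/` runs the full three-preset,
multi-sample comparison and writes `report.json` / `report.tsv`
including the concordance Venn and the Wilcoxon comparison table
(α = 0.025, no multiple-testing correction; a Bonferroni column is
emitted for transparency). See `capture-qc --help` for the
`simulate / dedup / coverage / enrich / concord / compare / all`
subcommands.

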