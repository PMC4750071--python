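"""Generator behaviour: determinism, placement, duplication, spiking."""

import numpy as np
import pytest

from capture_qc.io import read_alignments
from capture_qc.simulate import (
    PRESETS,
    MethodPreset,
    draw_fragment_lengths,
    generate_design,
    generate_reference,
    simulate_run,
    spike_variants,
)


class TestReference:
    def test_all_gc_landscape_gives_only_gc_bases(self):
        ref = generate_reference(n_contigs=1, contig_length=2000, gc_landscape=1.0, seed=0)
        assert set(ref.sequence("chr1")) <= {"G", "C"}

    def test_realized_gc_within_binomial_bound(self):
        ref = generate_reference(n_contigs=1, contig_length=10_000, gc_landscape=0.5, seed=1)
        assert 0.47 <= ref.gc_fraction("chr1", 0, 10_000) <= 0.53

    def test_block_landscape_realizes_each_block(self):
        ref = generate_reference(
            n_contigs=1, contig_length=20_000, gc_landscape=[0.2, 0.8], seed=2
        )
        assert abs(ref.gc_fraction("chr1", 0, 10_000) - 0.2) < 0.03
        assert abs(ref.gc_fraction("chr1", 10_000, 20_000) - 0.8) < 0.03

    def test_same_seed_reproduces_sequence(self):
        a = generate_reference(seed=7, contig_length=5000)
        b = generate_reference(seed=7, contig_length=5000)
        assert a.sequence("chr1") == b.sequence("chr1")

    def test_infeasible_gc_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(gc_landscape=1.5, seed=0)


class TestDesignGeneration:
    def test_exact_region_count_and_no_overlaps(self, toy_reference):
        d = generate_design(toy_reference, n_regions=100, region_length_range=(50, 120), seed=3)
        assert len(d) == 100
        ivs = list(d)
        for a in range(len(ivs)):  # brute-force pairwise oracle
            for b in range(a + 1, len(ivs)):
                if ivs[a].chrom == ivs[b].chrom:
                    assert ivs[a].end <= ivs[b].start or ivs[b].end <= ivs[a].start

    def test_single_region(self, toy_reference):
        d = generate_design(toy_reference, n_regions=1, seed=4)
        assert len(d) == 1

    def test_impossible_placement_errors(self, toy_reference):
        with pytest.raises(ValueError):
            generate_design(toy_reference, n_regions=5000, region_length_range=(200, 300), seed=5)

    def test_deterministic_under_seed(self, toy_reference):
        a = generate_design(toy_reference, n_regions=30, seed=6)
        b = generate_design(toy_reference, n_regions=30, seed=6)
        assert a.intervals == b.intervals


class TestSimulateRun:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path, toy_reference, toy_design):
        outs = []
        for sub in ("a", "b"):
            variants = spike_variants(toy_design, toy_reference, 10, 2, seed=20)
            simulate_run(
                toy_reference, toy_design, PRESETS["qxt"], seed=21,
                out_dir=tmp_path / sub, n_pairs=500, variants=variants,
            )
            outs.append(tmp_path / sub)
        for fn in ("run.sam", "truth.vcf", "design.bed"):
            assert (outs[0] / fn).read_bytes() == (outs[1] / fn).read_bytes()

    def test_zero_dup_fraction_yields_no_duplicates(self, tmp_path, toy_reference, toy_design):
        preset = PRESETS["nimblegen"].with_overrides(dup_fraction=0.0)
        truth = simulate_run(
            toy_reference, toy_design, preset, seed=22, out_dir=tmp_path, n_pairs=800
        )
        assert truth.realized_duplicate_fraction == 0.0
        assert truth.n_unique_fragments == truth.total_read_pairs

    def test_full_on_target_probability_puts_every_read_on_target(
        self, tmp_path, toy_reference, toy_design
    ):
        preset = PRESETS["nimblegen"].with_overrides(on_target_prob=1.0)
        truth = simulate_run(
            toy_reference, toy_design, preset, seed=23, out_dir=tmp_path, n_pairs=800
        )
        assert truth.realized_on_target_fraction == 1.0
        frags, _ = read_alignments(truth.files["sam"])
        for f in frags:
            for s, e in f.read_spans:
                assert toy_design.any_overlap(f.chrom, [s], [e])[0]

    def test_read_conservation_against_truth_table(self, small_run):
        """Every SAM read pair belongs to exactly one truth unique fragment."""
        truth = small_run["truth"]
        frags = small_run["fragments"]
        assert len(frags) == truth.total_read_pairs
        unique_ids = {f.name.split("C")[0] for f in frags}
        assert len(unique_ids) == truth.n_unique_fragments

    def test_pseudogene_blocks_get_low_mapq(self, tmp_path, toy_reference, toy_design):
        from capture_qc.intervals import TargetDesign

        block = TargetDesign("pseudo", [toy_design.intervals[0]])
        truth = simulate_run(
            toy_reference, toy_design, PRESETS["nimblegen"], seed=24,
            out_dir=tmp_path, n_pairs=2000, pseudogene_blocks=block,
        )
        frags, _ = read_alignments(truth.files["sam"])
        iv = block.intervals[0]
        inside = [f for f in frags if f.chrom == iv.chrom and f.frag_start < iv.end and f.frag_end > iv.start]
        assert inside and all(max(f.mapqs) <= 10 for f in inside)

    def test_invalid_dup_fraction_rejected(self):
        with pytest.raises(ValueError):
            MethodPreset(name="x", frag_mean=250, frag_sd=50, on_target_prob=0.8,
                         dup_fraction=1.0, raw_mean_doc=100)


class TestFragmentLengths:
    def test_truncated_below_twice_read_length(self, rng):
        p = PRESETS["qxt"]
        lens = draw_fragment_lengths(p, 5000, rng)
        assert lens.min() >= 2 * p.read_length

    def test_preset_dispersion_ordering(self, rng):
        draws = {k: draw_fragment_lengths(PRESETS[k], 20_000, rng) for k in PRESETS}
        iqr = {k: np.subtract(*np.percentile(v, [75, 25])) for k, v in draws.items()}
        assert np.median(draws["qxt"]) > np.median(draws["nimblegen"])
        assert iqr["qxt"] > iqr["nrcce"] > iqr["nimblegen"]


class TestSpikeVariants:
    def test_balanced_tstv_target_gives_equal_expected_counts(self, toy_reference, toy_design):
        vs = spike_variants(toy_design, toy_reference, n_snv=400, n_indel=0,
                            tstv_target=1.0, seed=30)
        ts = sum((v.ref, v.alt) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")} for v in vs)
        # binomial(400, 0.5): 3 sigma band
        assert abs(ts - 200) < 3 * np.sqrt(400 * 0.25)

    def test_all_homozygous_when_het_fraction_zero(self, toy_reference, toy_design):
        vs = spike_variants(toy_design, toy_reference, 50, 5, het_fraction=0.0, seed=31)
        assert all(v.genotype_class == "hom" for v in vs)

    def test_first_indel_is_six_bp_deletion(self, toy_reference, toy_design):
        vs = spike_variants(toy_design, toy_reference, 5, 3, seed=32)
        indels = [v for v in vs if v.variant_class == "indel"]
        assert any(len(v.ref) - len(v.alt) == 6 for v in indels)

    def test_positions_distinct_and_inside_design(self, toy_reference, toy_design):
        vs = spike_variants(toy_design, toy_reference, 60, 5, seed=33)
        keys = [(v.chrom, v.pos) for v in vs]
        assert len(set(keys)) == len(keys)
        assert all(toy_design.contains(v.chrom, v.pos0) for v in vs)

    def test_position_exhaustion_errors(self, toy_reference):
        d = generate_design(toy_reference, n_regions=2, region_length_range=(60, 80), seed=34)
        with pytest.raises(ValueError, match="exhausted|place"):
            spike_variants(d, toy_reference, n_snv=500, n_indel=0, seed=35)
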