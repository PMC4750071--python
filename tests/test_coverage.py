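"""Depth, thresholds, evenness, normalised DOC, GC bins, MAPQ flags."""

import math
import subprocess

import numpy as np
import pytest

from capture_qc.coverage import (
    DepthProfile,
    base_distribution_curve,
    compute_depth,
    coverage_thresholds,
    depth_distribution_curve,
    evenness_score,
    gc_coverage_profile,
    normalized_doc,
    per_region_coverage,
    region_mapq_summary,
)
from capture_qc.intervals import GenomicInterval, TargetDesign
from capture_qc.io import FragmentRecord, ReferenceSequence


def single_read(chrom, start, end, mapq=60, dup=False, name="q"):
    return FragmentRecord(
        chrom=chrom, frag_start=start, frag_end=end, read_spans=((start, end),),
        mapqs=(mapq,), name=name, is_duplicate=dup,
    )


def profile_from(depths_by_region, design):
    return DepthProfile(design, {i: np.asarray(d) for i, d in depths_by_region.items()})


class TestComputeDepth:
    def test_single_read_half_covering_a_region(self):
        design = TargetDesign("d", [GenomicInterval("chr1", 0, 100)])
        prof = compute_depth([single_read("chr1", 0, 50)], design)
        d = prof.region_depths(0)
        assert (d[:50] == 1).all() and (d[50:] == 0).all()
        assert prof.mean_doc == pytest.approx(0.5)

    def test_empty_design_is_an_error(self):
        with pytest.raises(ValueError):
            compute_depth([], TargetDesign("d", []))

    def test_excluding_duplicates_is_noop_without_duplicates(self, small_run):
        frags = [f for f in small_run["fragments"]]
        for f in frags:
            f.is_duplicate = False
        raw = compute_depth(frags, small_run["design"])
        dd = compute_depth(frags, small_run["design"], exclude_duplicates=True)
        assert all(
            (raw.region_depths(i) == dd.region_depths(i)).all() for i in range(len(small_run["design"]))
        )
        from capture_qc.dedup import mark_duplicates
        mark_duplicates(frags)  # restore fixture state

    def test_dedup_depth_never_exceeds_raw_depth(self, small_run):
        raw = compute_depth(small_run["fragments"], small_run["design"])
        dd = compute_depth(small_run["fragments"], small_run["design"], exclude_duplicates=True)
        for i in range(len(small_run["design"])):
            assert (dd.region_depths(i) <= raw.region_depths(i)).all()

    def test_matches_samtools_depth(self, small_run):
        """Independent oracle: samtools depth -a over the design."""
        out = subprocess.run(
            ["samtools", "depth", "-a", "-b", str(small_run["dir"] / "design.bed"),
             str(small_run["truth"].files["sam"])],
            capture_output=True, text=True, check=True,
        ).stdout
        oracle = {}
        for line in out.strip().split("\n"):
            c, p, d = line.split("\t")
            oracle[(c, int(p) - 1)] = int(d)
        prof = compute_depth(small_run["fragments"], small_run["design"])
        for i, iv in enumerate(small_run["design"]):
            for off, d in enumerate(prof.region_depths(i)):
                assert oracle.get((iv.chrom, iv.start + off), 0) == int(d)


class TestThresholdsAndCurves:
    design1 = TargetDesign("d", [GenomicInterval("chr1", 0, 3)])

    def test_threshold_table_example(self):
        prof = profile_from({0: [10, 25, 60]}, self.design1)
        assert coverage_thresholds(prof, [20, 50]) == {20: pytest.approx(2 / 3), 50: pytest.approx(1 / 3)}

    def test_threshold_zero_is_always_one(self):
        prof = profile_from({0: [0, 5, 9]}, self.design1)
        assert coverage_thresholds(prof, [0])[0] == 1.0

    def test_thresholds_match_brute_force_and_decrease(self, rng):
        depths = rng.integers(0, 300, 500)
        design = TargetDesign("d", [GenomicInterval("chr1", 0, 500)])
        prof = profile_from({0: depths}, design)
        table = coverage_thresholds(prof, range(0, 320, 7))
        prev = 1.1
        for t, frac in table.items():
            assert frac == sum(1 for d in depths if d >= t) / 500
            assert frac <= prev
            prev = frac

    def test_region_curve_example(self):
        rcs = [
            type("R", (), {"a_doc": v})() for v in (50.0, 150.0, 300.0)
        ]
        curve = depth_distribution_curve(rcs, [100, 280])
        assert curve == {100.0: pytest.approx(2 / 3), 280.0: pytest.approx(1 / 3)}
        assert depth_distribution_curve(rcs, [500])[500.0] == 0.0

    def test_region_curve_matches_brute_force(self, rng):
        vals = rng.uniform(0, 400, 200)
        rcs = [type("R", (), {"a_doc": float(v)})() for v in vals]
        grid = sorted(set(rng.uniform(0, 450, 25)))
        curve = depth_distribution_curve(rcs, grid)
        for g in grid:
            assert curve[float(g)] == sum(1 for v in vals if v > g) / 200

    def test_base_curve_uses_strict_inequality(self):
        design = TargetDesign("d", [GenomicInterval("chr1", 0, 4)])
        prof = profile_from({0: [10, 10, 20, 30]}, design)
        assert base_distribution_curve(prof, [10])[10.0] == pytest.approx(0.5)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            depth_distribution_curve([], [5, 5])


class TestEvenness:
    @pytest.mark.parametrize("k", [1, 7, 50])
    def test_uniform_profile_scores_exactly_100(self, k):
        assert evenness_score(np.full(1000, k)).es_percent == 100.0

    def test_half_covered_profile_scores_50(self):
        assert evenness_score(np.array([2, 2, 0, 0])).es_percent == 50.0

    def test_two_level_profile_scores_75(self):
        assert evenness_score(np.array([1, 1, 1, 1, 4, 4, 4, 4])).es_percent == 75.0

    def test_all_zero_profile_is_an_error(self):
        with pytest.raises(ValueError):
            evenness_score(np.zeros(10, dtype=int))

    def test_score_approximately_invariant_to_depth_scaling(self, rng):
        depths = rng.poisson(80, 2000)
        base = evenness_score(depths).es_percent
        for k in (2, 5):
            scaled = evenness_score(depths * k).es_percent
            assert abs(scaled - base) < 1.0

    def test_100_only_for_constant_depth_at_integer_mean(self, rng):
        depths = np.full(500, 37)
        depths[13] += 5
        depths[99] -= 5  # keep the mean integral
        assert evenness_score(depths).es_percent < 100.0


class TestNormalizedDoc:
    def _regions(self, a_docs, lengths):
        rcs = []
        pos = 0
        for i, (a, ln) in enumerate(zip(a_docs, lengths)):
            iv = GenomicInterval("chr1", pos, pos + ln)
            pos += ln + 10
            rcs.append(
                type("R", (), {"region": iv, "a_doc": float(a), "n_doc": None})()
            )
        return rcs

    def test_doubling_region_scores_two(self):
        rcs = self._regions([400, 200, 0], [100, 100, 100])
        normalized_doc(rcs)
        assert rcs[0].n_doc == pytest.approx(2.0)

    def test_identical_regions_all_score_one(self):
        rcs = self._regions([120] * 5, [80] * 5)
        normalized_doc(rcs)
        assert all(r.n_doc == pytest.approx(1.0) for r in rcs)

    def test_length_weighted_mean_is_exactly_one(self, rng):
        rcs = self._regions(rng.uniform(1, 500, 50), rng.integers(50, 400, 50))
        normalized_doc(rcs)
        lens = np.array([r.region.length for r in rcs])
        ndocs = np.array([r.n_doc for r in rcs])
        assert (ndocs * lens).sum() / lens.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_global_mean_is_an_error(self):
        rcs = self._regions([0, 0], [100, 100])
        with pytest.raises(ValueError):
            normalized_doc(rcs)


class TestGc:
    def test_gc_fraction_examples(self):
        ref = ReferenceSequence({"chr1": "ATGCGGGGAANN"})
        assert ref.gc_fraction("chr1", 0, 4) == pytest.approx(0.5)
        assert ref.gc_fraction("chr1", 4, 8) == 1.0
        assert ref.gc_fraction("chr1", 8, 12) == 0.0  # over 2 informative bases
        assert ref.gc_fraction("chr1", 10, 12) is None

    def test_binning_and_bin_width_validation(self, small_run):
        prof = compute_depth(small_run["fragments"], small_run["design"], exclude_duplicates=True)
        rcs = normalized_doc(per_region_coverage(prof, small_run["reference"]))
        table = gc_coverage_profile(rcs, bin_width=0.05)
        assert sum(row["n_regions"] for row in table) == len(rcs)
        for row in table:
            assert 0 <= row["gc_low"] < row["gc_high"] <= 1.0 + 1e-9
        with pytest.raises(ValueError):
            gc_coverage_profile(rcs, bin_width=0.5)


class TestRegionMapq:
    def test_rms_of_mixed_mapq(self):
        design = TargetDesign("d", [GenomicInterval("chr1", 0, 100)])
        frags = [single_read("chr1", 0, 100, mapq=0, name="a"),
                 single_read("chr1", 0, 100, mapq=60, name="b")]
        out = region_mapq_summary(frags, design, mapq_floor=20)
        assert out[0].rms_mapq == pytest.approx(math.sqrt((0 + 60**2) / 2))
        assert out[0].status == "ok"  # RMS 42.43 clears a floor of 20
        assert region_mapq_summary(frags, design, mapq_floor=50)[0].status == "low_mapq"

    def test_high_mapq_region_not_flagged(self):
        design = TargetDesign("d", [GenomicInterval("chr1", 0, 100)])
        frags = [single_read("chr1", 0, 100, mapq=60)]
        assert region_mapq_summary(frags, design, 20)[0].status == "ok"

    def test_region_without_reads_is_no_data(self):
        design = TargetDesign("d", [GenomicInterval("chr1", 0, 100),
                                    GenomicInterval("chr1", 5000, 5100)])
        frags = [single_read("chr1", 0, 100, mapq=60)]
        out = region_mapq_summary(frags, design, 20)
        assert out[1].status == "no_data" and out[1].rms_mapq is None
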