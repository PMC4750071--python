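"""Concordance Venn, Ts/Tv, allele balance, truth sensitivity."""

import math

import numpy as np
import pytest

from capture_qc.io import VariantCall
from capture_qc.simulate import simulate_callsets
from capture_qc.variants import (
    allele_balance_summary,
    call_quality_summary,
    concordance,
    truth_sensitivity,
    tstv_ratio,
)


def snv(pos, ref="A", alt="G", chrom="chr1", **kw):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestConcordance:
    def test_small_example(self):
        v1, v2, v3 = snv(10), snv(20), snv(30)
        res = concordance({"m1": [v1, v2], "m2": [v2, v3], "m3": [v2]})
        assert res.cells == {"ABC": 1, "AB": 0, "AC": 0, "BC": 0, "A": 1, "B": 1, "C": 0}

    def test_identical_callsets_all_common(self):
        calls = [snv(p) for p in range(1, 50)]
        res = concordance({"a": calls, "b": list(calls), "c": list(calls)})
        assert res.cells["ABC"] == 49
        assert all(res.cells[c] == 0 for c in res.cells if c != "ABC")

    def test_cells_match_set_algebra_oracle(self, rng):
        keys = [snv(int(p)) for p in rng.choice(10_000, 700, replace=False)]
        sets = {m: [] for m in "xyz"}
        membership = {}
        for v in keys:
            mask = tuple(rng.random(3) < 0.8)
            if not any(mask):
                mask = (True, False, False)
            membership[v.key] = mask
            for m, keep in zip("xyz", mask):
                if keep:
                    sets[m].append(v)
        res = concordance(sets)
        for cell, count in res.cells.items():
            want = {"A": cell in ("ABC", "AB", "AC", "A"),
                    "B": cell in ("ABC", "AB", "BC", "B"),
                    "C": cell in ("ABC", "AC", "BC", "C")}
            expected = sum(
                1 for mask in membership.values()
                if mask == (want["A"], want["B"], want["C"])
            )
            assert count == expected

    def test_cells_partition_each_callset(self, rng):
        sets = {
            m: [snv(int(p)) for p in rng.choice(500, int(rng.integers(40, 90)), replace=False)]
            for m in ("m1", "m2", "m3")
        }
        res = concordance(sets)
        for label, m in zip("ABC", res.methods):
            assert res.per_method_total(label) == len({v.key for v in sets[m]})

    def test_duplicate_keys_collapse_with_warning(self, caplog):
        dup = [snv(10), snv(10)]
        res = concordance({"a": dup, "b": [snv(10)], "c": [snv(10)]})
        assert res.cells["ABC"] == 1

    def test_requires_three_callsets(self):
        with pytest.raises(ValueError):
            concordance({"a": [], "b": []})


class TestTsTv:
    def test_two_transitions_one_transversion(self):
        vs = [snv(1, "A", "G"), snv(2, "C", "T"), snv(3, "A", "C")]
        assert tstv_ratio(vs) == pytest.approx(2.0)

    def test_no_transversions_is_infinite(self):
        assert math.isinf(tstv_ratio([snv(1, "A", "G")]))

    def test_indels_are_ignored(self):
        vs = [snv(1, "A", "G"),
              VariantCall("chr1", 5, "AT", "A", variant_class="indel"),
              snv(9, "A", "T")]
        assert tstv_ratio(vs) == pytest.approx(1.0)

    def test_invariant_under_strand_complement(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        bases = "ACGT"
        vs = []
        for _ in range(300):
            r, a = rng.choice(list(bases), 2, replace=False)
            vs.append(snv(int(rng.integers(1, 10_000)), str(r), str(a)))
        flipped = [snv(v.pos, comp[v.ref], comp[v.alt]) for v in vs]
        assert tstv_ratio(vs) == pytest.approx(tstv_ratio(flipped))


class TestAlleleBalance:
    def test_strata_and_means(self):
        vs = [
            snv(1, depth=100, alt_depth=50),
            snv(2, depth=100, alt_depth=46),
            snv(3, genotype_class="hom", depth=100, alt_depth=99),
            VariantCall("chr1", 9, "AT", "A", variant_class="indel", depth=80, alt_depth=40),
        ]
        out = {(s.genotype_class, s.variant_class): s for s in allele_balance_summary(vs)}
        assert out[("het", "snv")].mean_ab == pytest.approx(0.48)
        assert out[("het", "snv")].n == 2
        assert out[("hom", "snv")].mean_ab == pytest.approx(0.99)
        assert out[("het", "indel")].mean_ab == pytest.approx(0.5)

    def test_pass_only_excludes_filtered(self):
        vs = [snv(1, depth=100, alt_depth=50),
              snv(2, filter_status="LowAB", depth=100, alt_depth=10)]
        out = allele_balance_summary(vs, pass_only=True)
        assert len(out) == 1 and out[0].n == 1
        out_all = allele_balance_summary(vs, pass_only=False)
        assert out_all[0].n == 2

    def test_zero_depth_variant_excluded(self):
        vs = [snv(1, depth=0, alt_depth=0), snv(2, depth=10, alt_depth=5)]
        out = allele_balance_summary(vs)
        assert out[0].n == 1

    def test_het_mean_converges_to_half_without_bias(self, rng):
        truth = [snv(int(p), depth=None, alt_depth=None)
                 for p in rng.choice(100_000, 500, replace=False)]
        calls = simulate_callsets(truth, ["m"], seed=5, mean_depth=300)["m"]
        out = {(s.genotype_class, s.variant_class): s for s in allele_balance_summary(calls)}
        assert 0.49 <= out[("het", "snv")].mean_ab <= 0.51

    def test_reference_bias_shifts_het_balance_down(self, rng):
        truth = [snv(int(p)) for p in rng.choice(100_000, 500, replace=False)]
        biased = simulate_callsets(truth, ["m"], seed=6, mean_depth=300, ref_bias=0.1)["m"]
        out = {(s.genotype_class, s.variant_class): s for s in allele_balance_summary(biased)}
        assert out[("het", "snv")].mean_ab < 0.48

    def test_discordant_variants_have_lower_balance_than_triple_concordant(self, rng):
        """Dropout tied to low AB pushes discordant calls below the common set."""
        truth = [snv(int(p)) for p in rng.choice(500_000, 800, replace=False)]
        callsets = simulate_callsets(
            truth, ["a", "b", "c"], seed=7, mean_depth=40, af_spread=0.12, min_af=0.35
        )
        res = concordance(callsets)
        common = res.keys_by_cell["ABC"]
        ab_common, ab_discordant = [], []
        for calls in callsets.values():
            for v in calls:
                (ab_common if v.key in common else ab_discordant).append(v.allele_balance)
        assert len(ab_discordant) > 20
        assert np.mean(ab_discordant) < np.mean(ab_common)


class TestTruthSensitivity:
    def test_full_recall(self):
        truth = [snv(p) for p in range(1, 21)]
        found, total, misses = truth_sensitivity(list(truth), truth)
        assert (found, total, misses) == (20, 20, [])

    def test_one_missed_variant_reported_with_neighbourhood(self):
        truth = [snv(p * 100) for p in range(1, 21)]
        calls = truth[:-1] + [
            VariantCall("chr1", 1998, "C", "A", depth=282, alt_depth=55, filter_status="LowAB")
        ]
        found, total, misses = truth_sensitivity(calls, truth)
        assert (found, total) == (19, 20)
        assert misses[0]["pos"] == 2000
        nearby = misses[0]["nearby_calls"]
        assert nearby and nearby[0]["allele_balance"] == pytest.approx(55 / 282)

    def test_matches_brute_force_membership(self, rng):
        truth = [snv(int(p)) for p in rng.choice(5000, 60, replace=False)]
        calls = [snv(int(p)) for p in rng.choice(5000, 200, replace=False)]
        found, total, misses = truth_sensitivity(calls, truth)
        call_keys = {c.key for c in calls}
        assert found == sum(t.key in call_keys for t in truth)
        assert total == 60 and len(misses) == total - found


class TestCallQuality:
    def test_mean_qual(self):
        vs = [snv(1, qual=100.0), snv(2, qual=200.0)]
        out = call_quality_summary(vs)
        assert out["mean_qual"] == pytest.approx(150.0) and out["n_qual"] == 2

    def test_all_missing_reported_unavailable(self):
        out = call_quality_summary([snv(1), snv(2)])
        assert out["mean_mq"] is None and out["n_mq"] == 0

    def test_matches_arithmetic_mean_oracle(self, rng):
        quals = rng.uniform(10, 2000, 50)
        mqs = rng.uniform(10, 60, 50)
        vs = [snv(i + 1, qual=float(q), mq=float(m)) for i, (q, m) in enumerate(zip(quals, mqs))]
        out = call_quality_summary(vs)
        assert out["mean_qual"] == pytest.approx(quals.mean())
        assert out["mean_mq"] == pytest.approx(mqs.mean())
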