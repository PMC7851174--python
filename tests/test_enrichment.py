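import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sqtlmap.enrichment import (
    AnnotationTrack,
    MatchedNullSpec,
    PwmDelta,
    assign_bin,
    enrichment_or,
    heteropleiotropy_call,
    location_profile,
    pwm_delta,
    sample_matched_null,
    top_variants_per_gene,
)


class TestAssignBin:
    def test_plus_strand_example(self):
        assert assign_bin(150, 0, 2000, "+") == 2

    def test_minus_strand_mirrors(self):
        assert assign_bin(150, 0, 2000, "-") == 19

    def test_boundaries(self):
        assert assign_bin(0, 0, 2000, "+") == 1
        assert assign_bin(1999, 0, 2000, "+") == 20

    def test_outside_region_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(2000, 0, 2000, "+")


def _variants(n, rng, bins=None, mafs=None, prefix="v"):
    return pd.DataFrame({
        "variant_id": [f"{prefix}{i}" for i in range(n)],
        "chrom": "chr1",
        "pos": rng.integers(0, 100_000, n),
        "maf": mafs if mafs is not None else rng.uniform(0.05, 0.45, n),
        "bin": bins if bins is not None else rng.integers(1, 21, n),
    })


class TestMatchedNull:
    def test_draws_respect_bin_and_maf_tolerance(self, rng):
        sqtls = _variants(5, rng, bins=[3] * 5, mafs=[0.10] * 5)
        cands = _variants(
            200, rng, bins=[3] * 200,
            mafs=rng.uniform(0.08, 0.12, 200), prefix="c",
        )
        spec = MatchedNullSpec(n_sets=20)
        sets = sample_matched_null(sqtls, cands, spec, seed=1)
        lookup = cands.set_index("variant_id")
        for s in sets:
            assert len(s) == 5
            assert len(set(s)) == 5  # without replacement within a set
            for vid in s:
                assert lookup.loc[vid, "bin"] == 3
                assert abs(lookup.loc[vid, "maf"] - 0.10) <= 0.02 + 1e-12

    def test_pool_equal_to_sqtls_gives_permutations(self, rng):
        sqtls = _variants(6, rng, bins=[1] * 6, mafs=[0.2] * 6)
        cands = sqtls.copy()
        sets = sample_matched_null(sqtls, cands, MatchedNullSpec(n_sets=10), seed=2)
        for s in sets:
            assert sorted(s) == sorted(sqtls["variant_id"])

    def test_fixed_seed_reproducible(self, rng):
        sqtls = _variants(5, rng, bins=[2] * 5, mafs=[0.3] * 5)
        cands = _variants(100, rng, prefix="c")
        a = sample_matched_null(sqtls, cands, MatchedNullSpec(n_sets=5), seed=9)
        b = sample_matched_null(sqtls, cands, MatchedNullSpec(n_sets=5), seed=9)
        for x, y in zip(a, b):
            assert list(x) == list(y)

    def test_empty_bin_rejected(self, rng):
        sqtls = _variants(2, rng, bins=[7, 7], mafs=[0.1, 0.1])
        cands = _variants(50, rng, bins=[1] * 50, prefix="c")
        with pytest.raises(ValueError, match="bin"):
            sample_matched_null(sqtls, cands, MatchedNullSpec(n_sets=2), seed=0)


class TestEnrichmentOr:
    def _setup(self, rng, n=100, sqtl_rate=0.10, null_rate=0.05):
        # annotated variants sit inside the track interval; others far away
        n_in_s = int(sqtl_rate * n)
        n_in_c = int(null_rate * n)
        pos_s = np.r_[rng.integers(0, 1000, n_in_s), rng.integers(50_000, 60_000, n - n_in_s)]
        sqtls = pd.DataFrame({
            "variant_id": [f"s{i}" for i in range(n)], "chrom": "chr1", "pos": pos_s,
            "maf": 0.2, "bin": 1,
        })
        pos_c = np.r_[rng.integers(0, 1000, n_in_c), rng.integers(50_000, 60_000, n - n_in_c)]
        cands = pd.DataFrame({
            "variant_id": [f"c{i}" for i in range(n)], "chrom": "chr1", "pos": pos_c,
            "maf": 0.2, "bin": 1,
        })
        track = AnnotationTrack("t", [("chr1", 0, 1000)])
        return sqtls, cands, track

    def test_hand_two_by_two(self, rng):
        sqtls, cands, track = self._setup(rng)
        # null sets are all 100 candidates -> mean annotated 5
        sets = [cands["variant_id"].to_numpy()] * 10
        res = enrichment_or(sqtls, sets, [track], candidates=cands)[0]
        assert res.n_sqtl_annotated == 10
        assert res.mean_null_annotated == pytest.approx(5.0)
        assert res.or_value == pytest.approx((10 * 95) / (90 * 5), rel=1e-9)  # 2.111

    def test_identical_rates_give_or_one(self, rng):
        sqtls, cands, track = self._setup(rng, sqtl_rate=0.05, null_rate=0.05)
        sets = [cands["variant_id"].to_numpy()] * 5
        res = enrichment_or(sqtls, sets, [track], candidates=cands)[0]
        assert res.or_value == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_tail_sum(self, rng):
        sqtls, cands, track = self._setup(rng, sqtl_rate=0.20, null_rate=0.05)
        sets = [cands["variant_id"].to_numpy()] * 5
        res = enrichment_or(sqtls, sets, [track], candidates=cands)[0]
        # exhaustive two-sided Fisher: sum of hypergeometric point masses
        # no larger than the observed table's
        a, b, c, d = 20, 80, 5, 95
        M, n_draws, K = a + b + c + d, a + b, a + c
        p_obs = hypergeom.pmf(a, M, K, n_draws)
        p_two = sum(
            hypergeom.pmf(x, M, K, n_draws)
            for x in range(max(0, n_draws + K - M), min(K, n_draws) + 1)
            if hypergeom.pmf(x, M, K, n_draws) <= p_obs * (1 + 1e-9)
        )
        assert res.fisher_p == pytest.approx(p_two, rel=1e-6)

    def test_rare_annotation_dropped_from_fdr(self, rng):
        sqtls, cands, track = self._setup(rng, sqtl_rate=0.04, null_rate=0.01)
        sets = [cands["variant_id"].to_numpy()] * 5
        res = enrichment_or(sqtls, sets, [track], candidates=cands)[0]
        assert res.dropped  # mean null count 1 < 5
        assert np.isnan(res.fdr_q)

    def test_top_variants_per_gene(self):
        pairs = pd.DataFrame({
            "gene_id": ["g1"] * 15 + ["g2"] * 3,
            "variant_id": [f"v{i}" for i in range(18)],
            "p_nominal": np.linspace(1e-8, 0.04, 18),
        })
        top = top_variants_per_gene(pairs, k=10)
        assert (top.groupby("gene_id").size() <= 10).all()
        assert len(top) == 13


class TestLocationProfile:
    def test_uniform_positions_give_flat_profile(self, rng):
        regions = pd.DataFrame({
            "region_id": [f"r{i}" for i in range(200)],
            "chrom": "chr1",
            "start": 0,
            "end": 2000,
            "strand": np.where(rng.uniform(size=200) < 0.5, "+", "-"),
        })
        rows = []
        for rid in regions["region_id"]:
            for pos in rng.integers(0, 2000, size=10):
                rows.append({"variant_id": "v", "chrom": "chr1", "pos": pos,
                             "region_id": rid})
        profile = location_profile(pd.DataFrame(rows), regions)
        assert profile.sum() == pytest.approx(1.0)
        se = np.sqrt(0.05 * 0.95 / (10 * 200))
        assert np.abs(profile - 0.05).max() <= 4 * se

    def test_minus_strand_orientation(self):
        regions = pd.DataFrame({
            "region_id": ["r0"] * 1 + ["pad1", "pad2", "pad3", "pad4"],
            "chrom": "chr1", "start": 0,
            "end": [2000, 2000, 2000, 2000, 2000], "strand": "-",
        })
        sqtls = pd.DataFrame({
            "variant_id": ["v"], "chrom": ["chr1"], "pos": [150], "region_id": ["r0"],
        })
        profile = location_profile(sqtls, regions)
        assert profile[18] == 1.0  # bin 19

    def test_shortest_regions_filtered(self, rng):
        regions = pd.DataFrame({
            "region_id": ["short", "a", "b", "c", "d"],
            "chrom": "chr1", "start": 0,
            "end": [10, 2000, 2000, 2000, 2000], "strand": "+",
        })
        sqtls = pd.DataFrame({
            "variant_id": ["v1", "v2"], "chrom": "chr1",
            "pos": [5, 100], "region_id": ["short", "a"],
        })
        profile = location_profile(sqtls, regions)
        assert profile[1] == 1.0  # only region 'a' contributes


def _reference_rule(c):
    """Independently coded restatement of the heteropleiotropy definition."""
    return (
        c[("g1", "t1", "sqtl")] and not c[("g1", "t1", "eqtl")]
        and not c[("g2", "t2", "sqtl")] and c[("g2", "t2", "eqtl")]
        and not any(c[("g2", "t1", m)] for m in ("sqtl", "eqtl"))
        and not any(c[("g1", "t2", m)] for m in ("sqtl", "eqtl"))
    )


class TestHeteropleiotropy:
    KEYS = [(g, t, m) for g in ("g1", "g2") for t in ("t1", "t2")
            for m in ("sqtl", "eqtl")]

    def test_canonical_positive_case(self):
        calls = {k: False for k in self.KEYS}
        calls[("g1", "t1", "sqtl")] = True
        calls[("g2", "t2", "eqtl")] = True
        assert heteropleiotropy_call(calls) is True

    def test_shared_sqtl_eqtl_violates_rule(self):
        calls = {k: False for k in self.KEYS}
        calls[("g1", "t1", "sqtl")] = True
        calls[("g1", "t1", "eqtl")] = True
        calls[("g2", "t2", "eqtl")] = True
        assert heteropleiotropy_call(calls) is False

    def test_exhaustive_truth_table(self):
        for bits in itertools.product([False, True], repeat=8):
            calls = dict(zip(self.KEYS, bits))
            assert heteropleiotropy_call(calls) == _reference_rule(calls)

    def test_missing_call_not_evaluable(self):
        calls = {k: False for k in self.KEYS}
        del calls[("g1", "t2", "eqtl")]
        assert heteropleiotropy_call(calls) is None


class TestPwmDelta:
    def test_uniform_pwm_gives_zero_delta(self):
        pwm = np.full((5, 4), 0.25)
        out = pwm_delta("ACGTA", 2, "G", "T", pwm)
        assert out.delta == pytest.approx(0.0)

    def test_hand_log_arithmetic(self):
        # single informative column: p(A)=0.85, p(G)=0.05
        pwm = np.array([[0.85, 0.05, 0.05, 0.05]])
        out = pwm_delta("A", 0, "A", "G", pwm)
        expected = abs(np.log2(0.05 / 0.25) - np.log2(0.85 / 0.25))
        assert out.delta == pytest.approx(expected, abs=1e-3)
        assert out.delta == pytest.approx(4.087, abs=1e-3)

    def test_delta_symmetric_in_alleles(self):
        pwm = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1]])
        d1 = pwm_delta("AC", 1, "C", "G", pwm).delta
        d2 = pwm_delta("AG", 1, "G", "C", pwm).delta
        assert d1 == pytest.approx(d2)

    def test_variant_outside_site_rejected(self):
        pwm = np.full((3, 4), 0.25)
        with pytest.raises(ValueError):
            pwm_delta("ACG", 5, "A", "G", pwm)

    def test_indel_flagged_unsupported(self):
        pwm = np.full((3, 4), 0.25)
        out = pwm_delta("ACG", 1, "CG", "C", pwm)
        assert out.unsupported and np.isnan(out.delta)

    def test_reference_mismatch_rejected(self):
        pwm = np.full((3, 4), 0.25)
        with pytest.raises(ValueError, match="mismatch"):
            pwm_delta("ACG", 1, "T", "G", pwm)
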