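"""Threshold derivation, six-way site classification, mask serialization."""

import numpy as np
import pytest
from helpers import classify_oracle
from hypothesis import given, settings
from hypothesis import strategies as st

from accessmask import (
    PILOT,
    STRICT,
    PileupTrack,
    Reference,
    SiteStats,
    autosomal_mean_depth,
    autosomal_mean_mq,
    build_mask,
    classify_site,
    derive_thresholds,
    mask_to_bed,
    read_mask_fasta,
    summarize_mask,
    write_mask_fasta,
)
from accessmask.mask import MaskProfile, MaskTrack, mask_from_intervals
from conftest import random_track


def track_of(depths, mq0=None, mq_sum=None, chrom="chr1"):
    t = PileupTrack.zeros({chrom: len(depths)})
    t.depth[chrom] = np.asarray(depths, dtype=np.int64)
    if mq0 is not None:
        t.mq0[chrom] = np.asarray(mq0, dtype=np.int64)
    if mq_sum is not None:
        t.mq_sum[chrom] = np.asarray(mq_sum, dtype=np.int64)
    return t


class TestAutosomalMeans:
    def test_uniform_depth(self):
        ref = Reference({"chr1": "ACGT" * 3})
        t = track_of([10] * 12)
        assert autosomal_mean_depth(t, ref, ["chr1"]) == 10

    def test_mean_of_zero_and_twenty(self):
        ref = Reference({"chr1": "AC"})
        assert autosomal_mean_depth(track_of([0, 20]), ref, ["chr1"]) == 10

    def test_n_sites_excluded_from_the_mean(self):
        # hand recount: 10-site track, 5 N sites at depth 500, 5 at 10 -> 10
        ref = Reference({"chr1": "NNNNNACGTA"})
        t = track_of([500] * 5 + [10] * 5)
        assert autosomal_mean_depth(t, ref, ["chr1"]) == 10

    def test_empty_autosome_set_rejected(self):
        ref = Reference({"chr1": "ACGT"})
        with pytest.raises(ValueError, match="empty autosome"):
            autosomal_mean_depth(track_of([1, 1, 1, 1]), ref, [])

    def test_all_n_autosomes_rejected(self):
        ref = Reference({"chr1": "NNNN"})
        with pytest.raises(ValueError, match="non-N"):
            autosomal_mean_depth(track_of([1, 1, 1, 1]), ref, ["chr1"])

    def test_read_weighted_mean_mq(self):
        ref = Reference({"chr1": "AC"})
        t = track_of([2, 3], mq_sum=[100, 120])
        assert autosomal_mean_mq(t, ref, ["chr1"]) == pytest.approx(220 / 5)

    def test_mean_mq_is_60_when_every_read_is_60(self):
        ref = Reference({"chr1": "ACGT"})
        t = track_of([5, 1, 2, 3], mq_sum=[300, 60, 120, 180])
        assert autosomal_mean_mq(t, ref, ["chr1"]) == 60

    def test_half_mq0_half_60_averages_30(self):
        ref = Reference({"chr1": "AC"})
        t = track_of([4, 4], mq0=[2, 2], mq_sum=[120, 120])
        assert autosomal_mean_mq(t, ref, ["chr1"]) == 30

    def test_zero_depth_rejected_for_mq(self):
        ref = Reference({"chr1": "ACGT"})
        with pytest.raises(ValueError, match="zero total"):
            autosomal_mean_mq(track_of([0, 0, 0, 0]), ref, ["chr1"])


class TestThresholds:
    def test_pilot_bounds_from_cohort_mean(self):
        thr = derive_thresholds(20_360, PILOT)
        assert thr.depth_low == 10_180
        assert thr.depth_high == 40_720
        assert thr.avg_mq_min is None

    def test_strict_bounds_from_cohort_mean(self):
        thr = derive_thresholds(20_360, STRICT, avg_mq_cutoff=56)
        assert thr.depth_low == 10_180
        assert thr.depth_high == 30_540
        assert thr.avg_mq_min == 56

    def test_multiplier_arithmetic(self):
        thr = derive_thresholds(100, PILOT)
        assert (thr.depth_low, thr.depth_high) == (50, 200)

    def test_strict_without_cutoff_demands_the_mean_mq(self):
        with pytest.raises(ValueError, match="autosomal_mean_mq"):
            derive_thresholds(20_360, STRICT)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            derive_thresholds(0, PILOT)

    def test_bounds_strictly_increase_with_the_mean(self):
        lo = derive_thresholds(100, PILOT)
        hi = derive_thresholds(101, PILOT)
        assert hi.depth_low > lo.depth_low and hi.depth_high > lo.depth_high

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="multiplier"):
            MaskProfile("bad", 2.0, 0.5, 0.1, True, False)


PILOT_THR = derive_thresholds(20_360, PILOT)
STRICT_THR = derive_thresholds(20_360, STRICT, avg_mq_cutoff=56)


class TestClassifySite:
    def test_n_base_wins_regardless_of_stats(self):
        assert classify_site(SiteStats(20_360, 0, 60 * 20_360), "N", PILOT_THR) == "N"
        assert classify_site(SiteStats(0, 0, 0), "n", STRICT_THR) == "N"

    def test_fully_accessible_site_passes_strict(self):
        s = SiteStats(20_360, 0, 60 * 20_360)
        assert classify_site(s, "A", STRICT_THR) == "P"

    def test_low_depth(self):
        assert classify_site(SiteStats(9_000, 0, 9_000 * 60), "A", PILOT_THR) == "L"

    def test_depth_bounds_pass_inclusively(self):
        for thr in (PILOT_THR, STRICT_THR):
            lo = int(thr.depth_low)
            hi = int(thr.depth_high)
            assert classify_site(SiteStats(lo, 0, lo * 60), "A", thr) == "P"
            assert classify_site(SiteStats(hi, 0, hi * 60), "A", thr) == "P"
            assert classify_site(SiteStats(lo - 1, 0, (lo - 1) * 60), "A", thr) == "L"
            assert classify_site(SiteStats(hi + 1, 0, (hi + 1) * 60), "A", thr) == "H"

    def test_pilot_mq0_passes_at_exactly_20_percent(self):
        assert classify_site(SiteStats(20_000, 4_000, 16_000 * 60), "A",
                             PILOT_THR) == "P"
        assert classify_site(SiteStats(20_000, 5_000, 15_000 * 60), "A",
                             PILOT_THR) == "Z"

    def test_strict_mq0_fails_at_exactly_a_tenth_percent(self):
        # 30/20,000 = 0.15% >= 0.1% -> Z; 20/20,000 = exactly 0.1% -> Z
        assert classify_site(SiteStats(20_000, 30, 19_970 * 60), "A",
                             STRICT_THR) == "Z"
        assert classify_site(SiteStats(20_000, 20, 19_980 * 60), "A",
                             STRICT_THR) == "Z"
        # 10/20,000 = 0.05% passes the MQ0 rule but mean MQ 50 < 56 -> Q
        assert classify_site(SiteStats(20_000, 10, 20_000 * 50), "A",
                             STRICT_THR) == "Q"

    def test_strict_mean_mq_passes_at_exactly_the_cutoff(self):
        assert classify_site(SiteStats(20_000, 0, 20_000 * 56), "A",
                             STRICT_THR) == "P"

    def test_zero_depth_is_low_not_a_division_error(self):
        assert classify_site(SiteStats(0, 0, 0), "A", STRICT_THR) == "L"


def boundary_grid(mean=20_360, cutoff=56):
    """(depth, mq0, mq_sum, base) cases straddling every rule boundary ±1."""
    depths = set()
    for anchor in (0, 0.5 * mean, mean, 1.5 * mean, 2.0 * mean):
        for d in (anchor - 1, anchor, anchor + 1):
            if d >= 0:
                depths.add(int(d))
    cases = []
    for d in sorted(depths):
        mq0s = {0, d}
        for frac in (0.001, 0.20):
            k = int(frac * d)
            mq0s.update(x for x in (k - 1, k, k + 1) if 0 <= x <= d)
        sums = {0, 60 * d}
        k = cutoff * d
        sums.update(x for x in (k - 1, k, k + 1) if 0 <= x <= 60 * d)
        for m0 in sorted(mq0s):
            for ms in sorted(sums):
                for base in ("A", "N"):
                    cases.append((d, m0, ms, base))
    return cases


@pytest.mark.parametrize("profile_name", ["pilot", "strict"])
def test_classification_matches_truth_table_on_every_boundary(profile_name):
    mean, cutoff = 20_360, 56
    if profile_name == "pilot":
        thr = derive_thresholds(mean, PILOT)
    else:
        thr = derive_thresholds(mean, STRICT, avg_mq_cutoff=cutoff)
    for d, m0, ms, base in boundary_grid(mean, cutoff):
        got = classify_site(SiteStats(d, m0, ms), base, thr)
        want = classify_oracle(d, m0, ms, base, mean, profile_name, cutoff)
        assert got == want, (d, m0, ms, base)


class TestBuildMask:
    def test_all_n_chromosome_is_all_n(self):
        ref = Reference({"chr1": "N" * 50})
        m = build_mask(track_of([5] * 50), ref, PILOT_THR)
        assert (m.codes["chr1"] == "N").all()

    def test_uniform_good_coverage_is_all_p(self):
        ref = Reference({"chr1": "ACGT" * 25})
        thr = derive_thresholds(10, PILOT)
        m = build_mask(track_of([10] * 100, mq_sum=[600] * 100), ref, thr)
        assert (m.codes["chr1"] == "P").all()

    def test_vectorized_equals_per_site_classification(self):
        rng = np.random.default_rng(12)
        lengths = {"c1": 300, "c2": 200}
        t = random_track(rng, lengths, max_depth=40)
        bases = rng.choice(list("ACGTN"), size=500)
        ref = Reference({"c1": "".join(bases[:300]), "c2": "".join(bases[300:])})
        thr = derive_thresholds(15, STRICT, avg_mq_cutoff=40)
        m = build_mask(t, ref, thr)
        for chrom, n in lengths.items():
            for i in range(n):
                assert m.codes[chrom][i] == classify_site(
                    t.site(chrom, i + 1), ref.sequences[chrom][i], thr)

    def test_length_mismatch_rejected(self):
        ref = Reference({"chr1": "ACGT"})
        with pytest.raises(ValueError, match="mismatch"):
            build_mask(track_of([1] * 5), ref, PILOT_THR)

    def test_planted_low_region_recovered_as_contiguous_l(
            self, tiny_config, tiny_reference, tiny_pileup):
        track, _ = tiny_pileup
        mean = autosomal_mean_depth(track, tiny_reference, tiny_config.autosomes)
        m = build_mask(track, tiny_reference, derive_thresholds(mean, PILOT))
        region = m.codes["chr1"][12_000:14_000]
        assert (region == "L").mean() > 0.99


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), mean=st.floats(5, 500))
def test_strict_accessible_sites_nest_inside_pilot(seed, mean):
    """Every strict-P base is pilot-P: narrower depth window, harsher MQ0
    rule, and the Q criterion only removes sites."""
    rng = np.random.default_rng(seed)
    lengths = {"c": 400}
    t = random_track(rng, lengths, max_depth=int(3 * mean) + 2)
    bases = rng.choice(list("ACGTN"), size=400)
    ref = Reference({"c": "".join(bases)})
    cutoff = rng.uniform(0, 60)
    pilot = build_mask(t, ref, derive_thresholds(mean, PILOT))
    strict = build_mask(t, ref, derive_thresholds(mean, STRICT, cutoff))
    strict_p = strict.codes["c"] == "P"
    pilot_p = pilot.codes["c"] == "P"
    assert (pilot_p[strict_p]).all()


class TestSummary:
    def test_counts_and_fractions(self):
        m = MaskTrack({"c": np.array(list("N" * 5 + "P" * 95), dtype="U1")},
                      profile_name="pilot")
        s = summarize_mask(m, PILOT)
        assert s.counts.loc["genome", "N"] == 5
        assert s.fractions.loc["genome", "P"] == pytest.approx(0.95)

    def test_fractions_sum_to_one(self, tiny_config, tiny_reference, tiny_pileup):
        track, _ = tiny_pileup
        mean = autosomal_mean_depth(track, tiny_reference, tiny_config.autosomes)
        m = build_mask(track, tiny_reference, derive_thresholds(mean, PILOT))
        s = summarize_mask(m)
        np.testing.assert_allclose(s.fractions.sum(axis=1), 1.0, atol=1e-4)
        assert (s.counts.sum(axis=1).loc["genome"]
                == sum(tiny_config.chromosomes.values()))

    def test_profile_provenance_checked(self):
        m = MaskTrack({"c": np.array(list("PP"), dtype="U1")},
                      profile_name="strict")
        with pytest.raises(ValueError, match="pilot"):
            summarize_mask(m, PILOT)

    def test_tsv_render(self, tmp_path):
        m = MaskTrack({"c": np.array(list("NLHZQP"), dtype="U1")},
                      profile_name="strict")
        out = tmp_path / "summary.tsv"
        summarize_mask(m).to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[1] == "#scope\tN\tL\tH\tZ\tQ\tP\ttotal_bases"
        assert lines[2].startswith("genome\t16.67%")


class TestBedAndFasta:
    def test_run_length_encoding(self):
        m = MaskTrack({"c": np.array(list("PPNPP"), dtype="U1")})
        assert mask_to_bed(m, "P") == [("c", 0, 2), ("c", 3, 5)]

    def test_unknown_category_rejected(self):
        m = MaskTrack({"c": np.array(list("PP"), dtype="U1")})
        with pytest.raises(ValueError, match="unknown category"):
            mask_to_bed(m, "X")

    def test_category_beds_tile_the_chromosome(self):
        rng = np.random.default_rng(30)
        codes = rng.choice(list("NLHZQP"), size=500)
        m = MaskTrack({"c": codes.astype("U1")})
        covered = np.zeros(500, dtype=int)
        for cat in "NLHZQP":
            for _, s, e in mask_to_bed(m, cat):
                covered[s:e] += 1
        assert (covered == 1).all()

    def test_bed_round_trip_is_identity(self):
        rng = np.random.default_rng(31)
        codes = rng.choice(list("NLHZQP"), size=300)
        m = MaskTrack({"c": codes.astype("U1")}, profile_name="pilot")
        per_cat = {cat: mask_to_bed(m, cat) for cat in "NLHZQP"}
        rebuilt = mask_from_intervals(per_cat, {"c": 300}, profile_name="pilot")
        assert rebuilt == m
        for cat in "NLHZQP":
            assert mask_to_bed(rebuilt, cat) == per_cat[cat]

    def test_mask_fasta_round_trip(self, tmp_path):
        rng = np.random.default_rng(32)
        m = MaskTrack({"c1": rng.choice(list("NLHZQP"), size=130).astype("U1"),
                       "c2": rng.choice(list("NP"), size=61).astype("U1")})
        path = tmp_path / "mask.fa"
        write_mask_fasta(m, path)
        text = path.read_text().splitlines()
        assert text[0] == ">c1"
        assert all(len(line) <= 60 for line in text)
        assert read_mask_fasta(path) == m
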