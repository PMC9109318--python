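"""Scar-score behaviour: rule clauses, canonicalization, and independently
written brute-force oracles on random profiles."""

import numpy as np
import pytest

from hrdscar.genome import Segment, SegmentProfile
from hrdscar.scars import ScarConfig, hrd_score, loh_score, lst_score, tai_score

from conftest import MB, diploid_profile, profile, random_profile, seg

CFG = ScarConfig()


# ---------------------------------------------------------------- oracles
# Deliberately plain re-statements of the counting rules, used only on
# profiles that are already canonical (adjacent states always differ).

def oracle_loh(p, build, cfg=CFG):
    n = 0
    for s in p.segments:
        if not build[s.chrom].is_autosome and cfg.autosomes_only:
            continue
        whole = s.length_bp >= cfg.whole_chrom_fraction * build[s.chrom].length_bp
        if s.mcn == 0 and s.tcn > 0 and s.length_bp >= cfg.loh_min_len_bp and not whole:
            n += 1
    return n


def oracle_tai(p, build, cfg=CFG):
    n = 0
    for chrom, segs in p.by_chromosome().items():
        if not build[chrom].is_autosome and cfg.autosomes_only:
            continue
        ends = [segs[0]] if len(segs) == 1 else [segs[0], segs[-1]]
        for s in ends:
            imbalanced = s.mcn != s.tcn - s.mcn
            crosses = (
                s.start_bp < build[chrom].centromere_end_bp
                and s.end_bp > build[chrom].centromere_start_bp
            )
            if imbalanced and s.length_bp >= cfg.tai_min_len_bp:
                if cfg.tai_exclude_centromere_crossing and crosses:
                    continue
                n += 1
    return n


def oracle_lst_no_smoothing_needed(p, build, cfg=CFG):
    """Valid only when no segment is shorter than the smoothing scale and no
    neighbours share a state (so smoothing and fusing are no-ops)."""

    def arm(s):
        if s.end_bp <= build[s.chrom].centromere_start_bp:
            return "p"
        if s.start_bp >= build[s.chrom].centromere_end_bp:
            return "q"
        return "cen"

    n = 0
    for chrom, segs in p.by_chromosome().items():
        if not build[chrom].is_autosome and cfg.autosomes_only:
            continue
        for a, b in zip(segs, segs[1:]):
            if a.state == b.state:
                continue
            if min(a.length_bp, b.length_bp) < cfg.lst_min_seg_bp:
                continue
            if b.start_bp - a.end_bp - 1 > cfg.lst_max_gap_bp:
                continue
            if cfg.lst_per_arm and (arm(a) != arm(b) or arm(a) == "cen"):
                continue
            n += 1
    return n


# ---------------------------------------------------------------- LOH

class TestLOH:
    def test_balanced_diploid_scores_zero(self, hg19):
        assert loh_score(diploid_profile(hg19)) == 0

    def test_long_interstitial_loh_counts(self, hg19):
        chr2 = hg19["chr2"]
        p = profile(
            hg19,
            seg("chr2", 1, 30 * MB, 1, 0),
            seg("chr2", 30 * MB + 1, chr2.length_bp, 2, 1),
        )
        assert loh_score(p) == 1

    def test_each_exclusion_clause(self, hg19):
        chr2_len = hg19["chr2"].length_bp
        whole = profile(hg19, seg("chr2", 1, chr2_len, 1, 0))
        assert loh_score(whole) == 0  # whole-chromosome exclusion
        zero_tcn = profile(hg19, seg("chr2", 1, 30 * MB, 0, 0))
        assert loh_score(zero_tcn) == 0  # tCN > 0 required
        short = profile(hg19, seg("chr2", 1, 14 * MB, 1, 0))
        assert loh_score(short) == 0  # >= 15 Mb required

    def test_whole_chromosome_fraction_boundary(self, hg19):
        chr2_len = hg19["chr2"].length_bp
        just_under = profile(hg19, seg("chr2", 1, int(0.89 * chr2_len), 1, 0))
        assert loh_score(just_under) == 1
        at_fraction = profile(hg19, seg("chr2", 1, int(0.91 * chr2_len), 1, 0))
        assert loh_score(at_fraction) == 0

    def test_sex_chromosomes_excluded_by_default(self, hg19):
        p = profile(hg19, seg("chrX", 1, 30 * MB, 1, 0))
        assert loh_score(p) == 0
        assert loh_score(p, ScarConfig(autosomes_only=False)) == 1


# ---------------------------------------------------------------- TAI

class TestTAI:
    def test_terminal_imbalance_counts(self, hg19):
        chr3 = hg19["chr3"]
        p = profile(
            hg19,
            seg("chr3", 1, chr3.length_bp - 20 * MB, 2, 1),
            seg("chr3", chr3.length_bp - 20 * MB + 1, chr3.length_bp, 3, 1),
        )
        assert tai_score(p) == 1

    def test_interior_imbalance_does_not_count(self, hg19):
        chr3 = hg19["chr3"]
        p = profile(
            hg19,
            seg("chr3", 1, 40 * MB, 2, 1),
            seg("chr3", 40 * MB + 1, 60 * MB, 3, 1),
            seg("chr3", 60 * MB + 1, chr3.length_bp, 2, 1),
        )
        assert tai_score(p) == 0

    def test_balanced_terminal_does_not_count(self, hg19):
        p = profile(hg19, seg("chr3", 1, 30 * MB, 2, 1))
        assert tai_score(p) == 0

    def test_centromere_crossing_exclusion_flag(self, hg19):
        chr3 = hg19["chr3"]
        crossing = profile(hg19, seg("chr3", 1, chr3.centromere_end_bp + 10 * MB, 3, 1))
        assert tai_score(crossing) == 0
        assert tai_score(crossing, ScarConfig(tai_exclude_centromere_crossing=False)) == 1

    def test_min_length_filter(self, hg19):
        p = profile(hg19, seg("chr3", 1, 5 * MB, 3, 1))
        assert tai_score(p) == 1
        assert tai_score(p, ScarConfig(tai_min_len_bp=10 * MB)) == 0


# ---------------------------------------------------------------- LST

class TestLST:
    def test_adjacent_large_break_counts(self, hg19):
        p = profile(
            hg19,
            seg("chr1", 1, 12 * MB, 2, 1),
            seg("chr1", 12 * MB + 1, 24 * MB, 3, 1),
        )
        assert lst_score(p, hg19) == 1

    def test_short_segment_or_wide_gap_fails(self, hg19):
        short = profile(
            hg19,
            seg("chr1", 1, 12 * MB, 2, 1),
            seg("chr1", 12 * MB + 1, 20 * MB, 3, 1),  # 8 Mb < 10 Mb
        )
        assert lst_score(short, hg19) == 0
        wide = profile(
            hg19,
            seg("chr1", 1, 12 * MB, 2, 1),
            seg("chr1", 16 * MB + 1, 28 * MB, 3, 1),  # 4 Mb gap > 3 Mb
        )
        assert lst_score(wide, hg19) == 0

    def test_alternating_run_counts_k_minus_1(self, hg19):
        k = 8
        segs, pos = [], 1
        for i in range(k):
            state = (2, 1) if i % 2 == 0 else (3, 1)
            segs.append(seg("chr1", pos, pos + 11 * MB - 1, *state))
            pos += 11 * MB
        assert pos < hg19["chr1"].centromere_start_bp  # stays on the p arm
        assert lst_score(profile(hg19, *segs), hg19) == k - 1

    def test_smoothing_removes_sliver_and_merges_equal_flanks(self, hg19):
        p = profile(
            hg19,
            seg("chr1", 1, 15 * MB, 2, 1),
            seg("chr1", 15 * MB + 1, 17 * MB, 1, 0),  # 2 Mb sliver
            seg("chr1", 17 * MB + 1, 32 * MB, 2, 1),
        )
        assert lst_score(p, hg19) == 0  # sliver removed, equal flanks re-fuse

    def test_sliver_between_distinct_flanks_on_vs_off(self, hg19):
        p = profile(
            hg19,
            seg("chr1", 1, 15 * MB, 2, 1),
            seg("chr1", 15 * MB + 1, 17 * MB, 1, 0),  # 2 Mb third state
            seg("chr1", 17 * MB + 1, 32 * MB, 3, 1),
        )
        assert lst_score(p, hg19) == 1  # sliver smoothed away, flanks adjacent
        assert lst_score(p, hg19, ScarConfig(lst_smooth_bp=0)) == 0  # sliver blocks both pairs

    def test_per_arm_excludes_centromere_straddling_pairs(self, hg19):
        chr1 = hg19["chr1"]
        a_end = chr1.centromere_start_bp
        p = profile(
            hg19,
            seg("chr1", a_end - 15 * MB + 1, a_end, 2, 1),
            seg("chr1", chr1.centromere_end_bp, chr1.centromere_end_bp + 15 * MB - 1, 3, 1),
        )
        assert lst_score(p, hg19) == 0
        assert lst_score(p, hg19, ScarConfig(lst_per_arm=False)) == 0  # gap > 3 Mb anyway
        abutting = profile(
            hg19,
            seg("chr1", a_end - 15 * MB + 1, a_end + MB, 2, 1),
            seg("chr1", a_end + MB + 1, a_end + 17 * MB, 3, 1),
        )
        assert lst_score(abutting, hg19) == 0  # spans centromere: not per-arm
        assert lst_score(abutting, hg19, ScarConfig(lst_per_arm=False)) == 1


# ---------------------------------------------------------------- composite

class TestHRDScore:
    def test_balanced_diploid_is_negative(self, hg19):
        r = hrd_score(diploid_profile(hg19), hg19)
        assert (r.loh, r.tai, r.lst, r.total) == (0, 0, 0, 0)
        assert not r.hrd_positive

    def test_total_is_sum_of_components(self, hg19):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = random_profile(hg19, rng)
            r = hrd_score(p, hg19)
            assert r.total == loh_score(p) + tai_score(p) + lst_score(p, hg19)
            assert r.hrd_positive == (r.total >= 38)

    def test_threshold_is_inclusive(self, hg19):
        p = diploid_profile(hg19)
        assert hrd_score(p, hg19, threshold=0).hrd_positive


# ------------------------------------------------- invariants & oracles

class TestCanonicalizationInvariance:
    def test_scores_invariant_to_segment_splitting(self, hg19):
        rng = np.random.default_rng(21)
        for _ in range(20):
            p = random_profile(hg19, rng, distinct_adjacent=True, min_len_mb=4)
            split_segs = []
            for s in p.segments:
                if s.length_bp > 2 * MB and rng.random() < 0.5:
                    mid = s.start_bp + s.length_bp // 2
                    split_segs.append(Segment(s.chrom, s.start_bp, mid, *s.state))
                    split_segs.append(Segment(s.chrom, mid + 1, s.end_bp, *s.state))
                else:
                    split_segs.append(s)
            q = SegmentProfile(p.sample_id, hg19, tuple(split_segs))
            assert loh_score(q) == loh_score(p)
            assert tai_score(q) == tai_score(p)
            assert lst_score(q, hg19) == lst_score(p, hg19)

    def test_empty_profile_scores_zero(self, hg19):
        p = SegmentProfile("empty", hg19, ())
        assert hrd_score(p, hg19).total == 0


class TestOracleEquivalence:
    def test_loh_and_tai_match_brute_force(self, hg19):
        rng = np.random.default_rng(99)
        for _ in range(200):
            p = random_profile(hg19, rng, distinct_adjacent=True)
            assert loh_score(p) == oracle_loh(p, hg19)
            assert tai_score(p) == oracle_tai(p, hg19)

    def test_lst_matches_brute_force_on_presmoothed_profiles(self, hg19):
        rng = np.random.default_rng(101)
        for _ in range(200):
            p = random_profile(hg19, rng, distinct_adjacent=True, min_len_mb=4)
            assert lst_score(p, hg19) == oracle_lst_no_smoothing_needed(p, hg19)
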