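"""Genomic-scar scores: LOH, TAI, LST and the composite HRD score.

Homologous recombination deficiency leaves three quantifiable copy-number
"scars" in a tumour genome, each counted from the allele-specific segment
profile:

* **LOH** — segments of loss of heterozygosity (mCN = 0, tCN > 0) at least
  15 Mb long that do not span essentially the whole chromosome.
* **TAI** — allelic-imbalance segments (mCN != tCN - mCN) extending to a
  telomeric end of a chromosome.
* **LST** — large-scale state transitions: copy-number breakpoints between
  adjacent segments both at least 10 Mb long separated by at most 3 Mb,
  after small-segment smoothing.

The HRD score is their sum; a sample is HRD-positive when the score
reaches the calibrated threshold (38 by default, compared inclusively).

Profiles are canonicalized before counting (abutting equal-state segments
are fused), so scores are invariant to input segment order and to
splitting a segment into equal-state pieces.  Sex chromosomes are excluded
by default because allele-specific copy number on X/Y depends on sex.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome import (
    GenomeBuild,
    P_ARM,
    Q_ARM,
    Segment,
    SegmentProfile,
    arm_of,
    merge_equal_state,
)

__all__ = ["ScarConfig", "HRDResult", "loh_score", "tai_score", "lst_score", "hrd_score"]

DEFAULT_THRESHOLD = 38


@dataclass(frozen=True)
class ScarConfig:
    """Tunable parameters of the three scar counters (lengths in bp)."""

    loh_min_len_bp: int = 15_000_000
    lst_min_seg_bp: int = 10_000_000
    lst_max_gap_bp: int = 3_000_000
    lst_smooth_bp: int = 3_000_000
    lst_per_arm: bool = True
    tai_exclude_centromere_crossing: bool = True
    tai_min_len_bp: int = 0
    autosomes_only: bool = True
    whole_chrom_fraction: float = 0.90

    def __post_init__(self) -> None:
        for name in ("loh_min_len_bp", "lst_min_seg_bp", "lst_max_gap_bp", "lst_smooth_bp", "tai_min_len_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.whole_chrom_fraction <= 1):
            raise ValueError("whole_chrom_fraction must be in (0, 1]")


@dataclass(frozen=True)
class HRDResult:
    """The three scar counts, their sum, and the call at a threshold."""

    sample_id: str
    loh: int
    tai: int
    lst: int
    total: int
    hrd_positive: bool
    threshold: int

    def __post_init__(self) -> None:
        if self.total != self.loh + self.tai + self.lst:
            raise ValueError("total must equal loh + tai + lst")
        if self.hrd_positive != (self.total >= self.threshold):
            raise ValueError("hrd_positive inconsistent with total and threshold")


def _scored_chromosomes(profile: SegmentProfile, config: ScarConfig) -> dict[str, list[Segment]]:
    """Per-chromosome canonical segment lists restricted to scored chromosomes."""
    canon = merge_equal_state(profile, max_gap_bp=0)
    by_chrom = canon.by_chromosome()
    if config.autosomes_only:
        by_chrom = {c: segs for c, segs in by_chrom.items() if profile.build[c].is_autosome}
    return by_chrom


def loh_score(profile: SegmentProfile, config: ScarConfig = ScarConfig()) -> int:
    """Count long LOH segments: length >= 15 Mb, mCN = 0, tCN > 0.

    Segments covering at least ``whole_chrom_fraction`` of their chromosome
    (whole-chromosome LOH) are excluded — whole-chromosome loss is a
    ploidy/aneuploidy event, not a recombination scar.
    """
    count = 0
    for chrom, segs in _scored_chromosomes(profile, config).items():
        chrom_len = profile.build[chrom].length_bp
        for seg in segs:
            if (
                seg.mcn == 0
                and seg.tcn > 0
                and seg.length_bp >= config.loh_min_len_bp
                and seg.length_bp < config.whole_chrom_fraction * chrom_len
            ):
                count += 1
    return count


def tai_score(profile: SegmentProfile, config: ScarConfig = ScarConfig()) -> int:
    """Count allelic-imbalance segments reaching a telomeric chromosome end.

    Covered territory never reaches the literal telomere repeats, so a
    segment "reaches" the p (q) telomere iff it is the first (last) segment
    of its chromosome in the profile.  Segments spanning the centromere are
    excluded by default.
    """
    count = 0
    for segs in _scored_chromosomes(profile, config).values():
        for i, seg in enumerate(segs):
            if i != 0 and i != len(segs) - 1:
                continue
            if seg.is_balanced or seg.length_bp < config.tai_min_len_bp:
                continue
            if (
                config.tai_exclude_centromere_crossing
                and arm_of(seg, profile.build) not in (P_ARM, Q_ARM)
            ):
                continue
            count += 1
    return count


def _smooth(segs: list[Segment], config: ScarConfig) -> list[Segment]:
    """LST preprocessing: fuse equal states across small gaps, then
    iteratively drop sub-3 Mb segments (shortest first), re-fusing newly
    adjacent equal states, until every remaining segment is at least
    ``lst_smooth_bp`` long."""

    def fuse(items: list[Segment]) -> list[Segment]:
        out: list[Segment] = []
        for seg in items:
            if out:
                prev = out[-1]
                gap = seg.start_bp - prev.end_bp - 1
                if seg.state == prev.state and gap <= config.lst_max_gap_bp:
                    out[-1] = replace(prev, end_bp=seg.end_bp)
                    continue
            out.append(seg)
        return out

    segs = fuse(segs)
    while True:
        short = [s for s in segs if s.length_bp < config.lst_smooth_bp]
        if not short:
            return segs
        victim = min(short, key=lambda s: (s.length_bp, s.start_bp))
        segs = fuse([s for s in segs if s is not victim])


def lst_score(
    profile: SegmentProfile, build: GenomeBuild | None = None, config: ScarConfig = ScarConfig()
) -> int:
    """Count large-scale state transitions.

    A transition is an ordered adjacent pair of same-chromosome segments
    with different (tCN, mCN) state, both at least ``lst_min_seg_bp`` long,
    separated by at most ``lst_max_gap_bp``.  Sub-``lst_smooth_bp`` segments
    are smoothed away first so that small interstitial calls do not mask
    flanking transitions.  With ``lst_per_arm`` both members of a pair must
    lie on the same arm; pairs involving centromere-spanning segments are
    never counted in that mode.
    """
    build = build or profile.build
    count = 0
    for segs in _scored_chromosomes(profile, config).values():
        smooth = _smooth(list(segs), config)
        for a, b in zip(smooth, smooth[1:]):
            if a.state == b.state:
                continue
            if a.length_bp < config.lst_min_seg_bp or b.length_bp < config.lst_min_seg_bp:
                continue
            if b.start_bp - a.end_bp - 1 > config.lst_max_gap_bp:
                continue
            if config.lst_per_arm:
                arm_a, arm_b = arm_of(a, build), arm_of(b, build)
                if arm_a != arm_b or arm_a not in (P_ARM, Q_ARM):
                    continue
            count += 1
    return count


def hrd_score(
    profile: SegmentProfile,
    build: GenomeBuild | None = None,
    config: ScarConfig = ScarConfig(),
    threshold: int = DEFAULT_THRESHOLD,
) -> HRDResult:
    """LOH + TAI + LST and the positive/negative call at ``threshold``."""
    build = build or profile.build
    loh = loh_score(profile, config)
    tai = tai_score(profile, config)
    lst = lst_score(profile, build, config)
    total = loh + tai + lst
    return HRDResult(
        sample_id=profile.sample_id,
        loh=loh,
        tai=tai,
        lst=lst,
        total=total,
        hrd_positive=total >= threshold,
        threshold=threshold,
    )
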