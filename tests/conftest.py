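import numpy as np
import pytest

from hrdscar.genome import GenomeBuild, Segment, SegmentProfile, load_hg19

MB = 1_000_000


@pytest.fixture(scope="session")
def hg19() -> GenomeBuild:
    return load_hg19()


def seg(chrom, start, end, tcn, mcn) -> Segment:
    return Segment(chrom, start, end, tcn, mcn)


def profile(build: GenomeBuild, *segments: Segment, sample_id: str = "s1") -> SegmentProfile:
    return SegmentProfile(sample_id, build, tuple(segments))


def diploid_profile(build: GenomeBuild, sample_id: str = "s1") -> SegmentProfile:
    """One balanced (2,1) segment covering each autosome."""
    segs = tuple(Segment(c.name, 1, c.length_bp, 2, 1) for c in build.autosomes)
    return SegmentProfile(sample_id, build, segs)


_STATES = [(0, 0), (1, 0), (2, 0), (2, 1), (3, 1), (3, 0), (4, 1), (4, 2), (5, 2)]


def random_profile(
    build: GenomeBuild,
    rng: np.random.Generator,
    min_len_mb: int = 1,
    max_len_mb: int = 60,
    gap_choices_mb: tuple[int, ...] = (0, 0, 1, 4, 6),
    distinct_adjacent: bool = False,
    sample_id: str = "rand",
) -> SegmentProfile:
    """Random multi-chromosome profile; states and breakpoints arbitrary.

    With ``distinct_adjacent`` consecutive segments always change state, so
    the profile is already canonical (no fusable neighbours).
    """
    segs = []
    for c in build.autosomes:
        if rng.random() < 0.2:  # some chromosomes uncovered
            continue
        pos = 1 + int(rng.integers(0, 3)) * MB
        prev_state = None
        while True:
            length = int(rng.integers(min_len_mb, max_len_mb + 1)) * MB
            if pos + length - 1 > c.length_bp:
                break
            state = _STATES[rng.integers(0, len(_STATES))]
            if distinct_adjacent:
                while state == prev_state:
                    state = _STATES[rng.integers(0, len(_STATES))]
            segs.append(Segment(c.name, pos, pos + length - 1, *state))
            prev_state = state
            pos += length + int(rng.choice(gap_choices_mb)) * MB
            if rng.random() < 0.15:  # leave the rest of the chromosome uncovered
                break
    return SegmentProfile(sample_id, build, tuple(segs))
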