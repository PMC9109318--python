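"""Genome builds and allele-specific copy-number segment profiles.

The substrate for every scar score is a per-sample collection of
allele-specific copy-number segments: genomic intervals annotated with a
total copy number (tCN) and a minor-allele copy number (mCN), as produced
by allele-specific copy-number callers such as PureCN.  This module holds
the in-memory model (:class:`Segment`, :class:`SegmentProfile`,
:class:`GenomeBuild`), TSV readers/writers for SEG-like segment tables,
and the small amount of genome arithmetic (arm assignment, equal-state
merging) the scores depend on.

Coordinates are 1-based inclusive internally, following the SEG-file
convention; the reader can convert 0-based half-open input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pandas as pd

__all__ = [
    "Arm",
    "Chromosome",
    "GenomeBuild",
    "Segment",
    "SegmentProfile",
    "SegmentTableError",
    "SegmentValidationError",
    "arm_of",
    "load_hg19",
    "merge_equal_state",
    "read_genome_build",
    "read_segment_table",
    "write_segment_table",
]


class SegmentTableError(ValueError):
    """A segment table could not be parsed (missing/unmappable columns)."""


class SegmentValidationError(ValueError):
    """Parsed rows violate a segment invariant (order, overlap, mCN > tCN/2)."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    centromere_start_bp: int
    centromere_end_bp: int
    is_autosome: bool

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not (0 < self.centromere_start_bp < self.centromere_end_bp < self.length_bp):
            raise ValueError(
                f"{self.name}: centromere interval must satisfy "
                "0 < start < end < chromosome length"
            )


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and centromere intervals of one reference assembly."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in build")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    def __getitem__(self, chrom: str) -> Chromosome:
        try:
            return self._by_name[chrom]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} in build {self.name!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name  # type: ignore[attr-defined]

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if c.is_autosome)


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (1-based inclusive coordinates).

    ``mCN`` is the minor-allele copy count, so ``mCN <= tCN - mCN`` always;
    allelic balance means ``mCN == tCN - mCN``.
    """

    chrom: str
    start_bp: int
    end_bp: int
    tcn: int
    mcn: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.chrom}:{self.start_bp}-{self.end_bp}: start > end")
        if self.tcn < 0 or self.mcn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.mcn > self.tcn - self.mcn:
            raise ValueError(
                f"mCN={self.mcn} exceeds major allele count tCN-mCN={self.tcn - self.mcn}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.tcn, self.mcn)

    @property
    def is_balanced(self) -> bool:
        return self.mcn == self.tcn - self.mcn


# Arm labels: "p", "q", or "spans_centromere".
Arm = str
P_ARM: Arm = "p"
Q_ARM: Arm = "q"
SPANS_CENTROMERE: Arm = "spans_centromere"


@dataclass(frozen=True)
class SegmentProfile:
    """Ordered, non-overlapping segments of one sample on one genome build."""

    sample_id: str
    build: GenomeBuild
    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        canon = tuple(sorted(self.segments, key=lambda s: (_chrom_rank(s.chrom, self.build), s.start_bp)))
        object.__setattr__(self, "segments", canon)
        self._validate()

    def _validate(self) -> None:
        for seg in self.segments:
            if seg.chrom not in self.build:
                raise SegmentValidationError(
                    f"sample {self.sample_id!r}: segment on unknown chromosome {seg.chrom!r}"
                )
            if seg.end_bp > self.build[seg.chrom].length_bp:
                raise SegmentValidationError(
                    f"sample {self.sample_id!r}: {seg.chrom}:{seg.start_bp}-{seg.end_bp} "
                    f"extends past chromosome length {self.build[seg.chrom].length_bp}"
                )
        for a, b in zip(self.segments, self.segments[1:]):
            if a.chrom == b.chrom and b.start_bp <= a.end_bp:
                raise SegmentValidationError(
                    f"sample {self.sample_id!r}: overlapping segments "
                    f"{a.chrom}:{a.start_bp}-{a.end_bp} and {b.chrom}:{b.start_bp}-{b.end_bp}"
                )

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def __len__(self) -> int:
        return len(self.segments)


def _chrom_rank(chrom: str, build: GenomeBuild) -> int:
    for i, c in enumerate(build.chromosomes):
        if c.name == chrom:
            return i
    return len(build.chromosomes)


def arm_of(segment: Segment, build: GenomeBuild) -> Arm:
    """Assign a segment to the p arm, the q arm, or ``spans_centromere``.

    A segment is on p iff it ends at or before the centromere start, on q
    iff it starts at or after the centromere end; anything overlapping the
    centromere interval spans it.
    """
    chrom = build[segment.chrom]
    if segment.end_bp <= chrom.centromere_start_bp:
        return P_ARM
    if segment.start_bp >= chrom.centromere_end_bp:
        return Q_ARM
    return SPANS_CENTROMERE


def merge_equal_state(profile: SegmentProfile, max_gap_bp: int = 0) -> SegmentProfile:
    """Fuse same-chromosome neighbours with identical (tCN, mCN) state.

    Two consecutive segments are fused when the gap between them is at most
    ``max_gap_bp``; the fused segment spans from the first start to the last
    end (covering the gap).  Idempotent.  With ``max_gap_bp == 0`` only
    abutting segments fuse and covered territory is unchanged.
    """
    merged: list[Segment] = []
    for seg in profile.segments:
        if merged:
            prev = merged[-1]
            gap = seg.start_bp - prev.end_bp - 1
            if seg.chrom == prev.chrom and seg.state == prev.state and gap <= max_gap_bp:
                merged[-1] = replace(prev, end_bp=seg.end_bp)
                continue
        merged.append(seg)
    return SegmentProfile(profile.sample_id, profile.build, tuple(merged))


_DEFAULT_COLUMNS: Mapping[str, str] = {
    "sample": "sample",
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "tCN": "tCN",
    "mCN": "mCN",
}


def read_segment_table(
    source: str | Path | TextIO,
    build: GenomeBuild,
    columns: Mapping[str, str] | None = None,
    zero_based: bool = False,
) -> dict[str, SegmentProfile]:
    """Read a SEG-like TSV into one :class:`SegmentProfile` per sample.

    Parameters
    ----------
    source
        Path or open text stream of a tab-separated table.
    build
        Genome build the coordinates refer to; unknown chromosomes are an
        error, never silently dropped.
    columns
        Maps the canonical names ``sample, chrom, start, end, tCN, mCN`` to
        the column names actually present.
    zero_based
        If true, input coordinates are 0-based half-open and are converted
        to the internal 1-based inclusive convention.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(source, sep="\t", comment="#", dtype={colmap["chrom"]: str})
    missing = [k for k, v in colmap.items() if v not in df.columns]
    if missing:
        raise SegmentTableError(
            "segment table is missing column(s): "
            + ", ".join(f"{colmap[k]!r} (for {k})" for k in missing)
        )
    profiles: dict[str, SegmentProfile] = {}
    for sample_id, rows in df.groupby(colmap["sample"], sort=True):
        segments = []
        for idx, row in rows.iterrows():
            start = int(row[colmap["start"]])
            end = int(row[colmap["end"]])
            if zero_based:
                start += 1  # 0-based half-open -> 1-based inclusive
            try:
                segments.append(
                    Segment(
                        chrom=str(row[colmap["chrom"]]),
                        start_bp=start,
                        end_bp=end,
                        tcn=int(row[colmap["tCN"]]),
                        mcn=int(row[colmap["mCN"]]),
                    )
                )
            except ValueError as exc:
                raise SegmentValidationError(f"row {idx}: {exc}") from exc
        profiles[str(sample_id)] = SegmentProfile(str(sample_id), build, tuple(segments))
    return profiles


def write_segment_table(
    profiles: Iterable[SegmentProfile], dest: str | Path | TextIO | None = None
) -> str:
    """Serialize profiles to the canonical TSV dialect; returns the text.

    Output round-trips bit-stably through :func:`read_segment_table`.
    """
    rows = [
        {
            "sample": p.sample_id,
            "chrom": s.chrom,
            "start": s.start_bp,
            "end": s.end_bp,
            "tCN": s.tcn,
            "mCN": s.mcn,
        }
        for p in profiles
        for s in p.segments
    ]
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "tCN", "mCN"])
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


def read_genome_build(source: str | Path | TextIO, name: str = "custom") -> GenomeBuild:
    """Read a build TSV with columns ``chrom, length, cen_start, cen_end``."""
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    required = {"chrom", "length", "cen_start", "cen_end"}
    missing = required - set(df.columns)
    if missing:
        raise SegmentTableError(f"genome build file missing column(s): {sorted(missing)}")
    chroms = tuple(
        Chromosome(
            name=row.chrom,
            length_bp=int(row.length),
            centromere_start_bp=int(row.cen_start),
            centromere_end_bp=int(row.cen_end),
            is_autosome=row.chrom not in ("chrX", "chrY", "X", "Y"),
        )
        for row in df.itertuples()
    )
    return GenomeBuild(name=name, chromosomes=chroms)


def load_hg19() -> GenomeBuild:
    """The bundled hg19 build (UCSC chromosome lengths, acen-band centromeres)."""
    ref = resources.files("hrdscar.data").joinpath("hg19_build.tsv")
    with ref.open("r") as fh:
        return read_genome_build(fh, name="hg19")
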