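"""Allele-specific copy-number segment profiles.

A profile is one sample's ordered list of segments, each carrying a total
copy number and a minor-allele copy number.  This module reads and writes
the SEG-like tab-separated dialect (1-based inclusive coordinates on disk,
0-based half-open in memory), validates profiles against a genome model,
and provides the two preprocessing operations the large-scale state
transition (LST) score requires: coalescing equal-state neighbours and
iterative removal of sub-threshold interlopers ("smoothing and filtering").

Uncovered gaps between segments are tolerated and never invented; all
operations preserve the covered territory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .genome import GenomeModel

__all__ = [
    "Segment",
    "SegmentProfile",
    "SegmentFormatError",
    "read_segments",
    "write_segments",
    "profiles_to_frame",
    "merge_equal_neighbors",
    "filter_small_variants",
]


class SegmentFormatError(ValueError):
    """Raised for malformed or inconsistent segment tables."""


@dataclass(frozen=True, slots=True)
class Segment:
    """One constant-copy-number interval (0-based half-open).

    ``minor_cn`` is the copy count of the less abundant parental allele, so
    ``minor_cn <= total_cn - minor_cn`` always holds.  Allelic imbalance
    means the two alleles differ (``total_cn != 2 * minor_cn``); LOH means
    the minor allele is absent (``minor_cn == 0``).
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SegmentFormatError(
                f"{self.chrom}: empty/inverted interval [{self.start}, {self.end})"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise SegmentFormatError(f"{self.chrom}: negative copy number")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise SegmentFormatError(
                f"{self.chrom}: minor_cn {self.minor_cn} exceeds major allele "
                f"for total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1

    @property
    def has_allelic_imbalance(self) -> bool:
        return self.total_cn - self.minor_cn != self.minor_cn


@dataclass(frozen=True)
class SegmentProfile:
    """One sample's segments, sorted and non-overlapping per chromosome."""

    sample_id: str
    segments: tuple[Segment, ...]

    def by_chromosome(self) -> Iterator[tuple[str, list[Segment]]]:
        """Yield (chrom, segments) preserving first-appearance chromosome order."""
        groups: dict[str, list[Segment]] = {}
        for seg in self.segments:
            groups.setdefault(seg.chrom, []).append(seg)
        yield from groups.items()

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)

    def validate(self, genome: GenomeModel | None = None) -> "SegmentProfile":
        """Check sortedness, non-overlap and (optionally) genome bounds."""
        for chrom, segs in self.by_chromosome():
            if genome is not None:
                if chrom not in genome:
                    raise SegmentFormatError(
                        f"sample {self.sample_id}: unknown chromosome {chrom!r}"
                    )
                if segs[-1].end > genome[chrom].length:
                    raise SegmentFormatError(
                        f"sample {self.sample_id}: segment ending at {segs[-1].end} "
                        f"exceeds {chrom} length {genome[chrom].length}"
                    )
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise SegmentFormatError(
                        f"sample {self.sample_id}: overlapping segments on {chrom} "
                        f"at [{a.start},{a.end}) and [{b.start},{b.end})"
                    )
        return self

    @classmethod
    def from_segments(
        cls,
        sample_id: str,
        segments: Iterable[Segment],
        genome: GenomeModel | None = None,
    ) -> "SegmentProfile":
        """Build a normalized profile: sort by (chromosome order, start)."""
        segs = list(segments)
        if genome is not None:
            order = {name: i for i, name in enumerate(genome.names)}
            segs.sort(key=lambda s: (order.get(s.chrom, len(order)), s.start))
        else:
            segs.sort(key=lambda s: (s.chrom, s.start))
        return cls(sample_id, tuple(segs)).validate(genome)


_SEG_COLUMNS = ("sample", "chrom", "start", "end", "total_cn", "minor_cn")


def read_segments(path: str | Path, genome: GenomeModel) -> list[SegmentProfile]:
    """Read SEG-like TSV (1-based inclusive) into normalized profiles.

    Columns: ``sample chrom start end total_cn minor_cn``.  Copy numbers
    must be integers; allele orientation is enforced on read
    (``minor_cn := min(allele counts)``).  One profile is returned per
    sample, in order of first appearance.
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in _SEG_COLUMNS if c not in table.columns]
    if missing:
        raise SegmentFormatError(f"{path}: missing columns {missing}")
    profiles: dict[str, list[Segment]] = {}
    for i, row in enumerate(table.itertuples(index=False)):
        for col in ("total_cn", "minor_cn"):
            value = getattr(row, col)
            if float(value) != int(value):
                raise SegmentFormatError(
                    f"{path}: sample {row.sample}, row {i + 1}: "
                    f"non-integer {col} {value}"
                )
        total = int(row.total_cn)
        minor = min(int(row.minor_cn), total - int(row.minor_cn))
        try:
            seg = Segment(
                chrom=str(row.chrom),
                start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
                end=int(row.end),
                total_cn=total,
                minor_cn=minor,
            )
        except SegmentFormatError as exc:
            raise SegmentFormatError(
                f"{path}: sample {row.sample}, row {i + 1}: {exc}"
            ) from exc
        profiles.setdefault(str(row.sample), []).append(seg)
    out = []
    for sample_id, segs in profiles.items():
        try:
            out.append(SegmentProfile.from_segments(sample_id, segs, genome))
        except SegmentFormatError as exc:
            raise SegmentFormatError(f"{path}: {exc}") from exc
    return out


def profiles_to_frame(profiles: Iterable[SegmentProfile]) -> pd.DataFrame:
    """Flatten profiles to the on-disk dialect (1-based inclusive)."""
    rows = [
        (p.sample_id, s.chrom, s.start + 1, s.end, s.total_cn, s.minor_cn)
        for p in profiles
        for s in p.segments
    ]
    return pd.DataFrame(rows, columns=list(_SEG_COLUMNS))


def write_segments(profiles: Iterable[SegmentProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def _merge_run(segs: list[Segment], gap_tolerance: int) -> list[Segment]:
    merged: list[Segment] = []
    for seg in segs:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.state == seg.state
            and seg.start - prev.end <= gap_tolerance
        ):
            merged[-1] = replace(prev, end=seg.end)
        else:
            merged.append(seg)
    return merged


def merge_equal_neighbors(
    profile: SegmentProfile, gap_tolerance: int = 0
) -> SegmentProfile:
    """Coalesce adjacent same-state segments separated by at most gap_tolerance.

    Idempotent.  The merged segment spans both inputs (closing the gap, if
    any, which is why the default tolerance is 0: by default no territory
    is invented).
    """
    out: list[Segment] = []
    for _, segs in profile.by_chromosome():
        out.extend(_merge_run(segs, gap_tolerance))
    return SegmentProfile(profile.sample_id, tuple(out))


def _filter_chromosome(
    segs: list[Segment], min_len: int, gap_tolerance: int
) -> list[Segment]:
    segs = _merge_run(segs, gap_tolerance)
    while True:
        removed = False
        for i, seg in enumerate(segs):
            if seg.length >= min_len:
                continue
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i < len(segs) - 1 else None
            if left is None and right is None:
                continue  # lone segment: nothing to absorb it
            if left is None:
                segs[i + 1] = replace(right, start=seg.start)
            elif right is None:
                segs[i - 1] = replace(left, end=seg.end)
            else:
                if seg.state == left.state or seg.state == right.state:
                    # equal-state neighbour separated by a gap wider than the
                    # tolerance: not an interloper, leave it alone
                    continue
                if left.length >= right.length:  # ties go to the left flank
                    segs[i - 1] = replace(left, end=seg.end)
                else:
                    segs[i + 1] = replace(right, start=seg.start)
            del segs[i]
            removed = True
            break
        if not removed:
            return segs
        segs = _merge_run(segs, gap_tolerance)


def filter_small_variants(
    profile: SegmentProfile, min_len: int = 3_000_000, gap_tolerance: int = 0
) -> SegmentProfile:
    """Iteratively absorb segments shorter than ``min_len`` into their flanks.

    An interior short segment whose state differs from both neighbours is
    removed and its interval assigned to the longer flank (left on ties);
    terminal short segments are absorbed into their single neighbour.
    Equal-state neighbours are re-coalesced after each removal, and the
    process repeats until stable.  Covered territory is conserved and the
    operation is idempotent on its own output.
    """
    if min_len <= 0:
        raise ValueError(f"min_len must be positive, got {min_len}")
    out: list[Segment] = []
    for _, segs in profile.by_chromosome():
        out.extend(_filter_chromosome(list(segs), min_len, gap_tolerance))
    return SegmentProfile(profile.sample_id, tuple(out))
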