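"""Chromosome geometry: lengths, centromeres, arms, telomere ends.

Every genomic-scar statistic needs to know where a chromosome ends, where
its centromere sits, and which arm an interval belongs to.  The model is
deliberately minimal: an ordered list of chromosomes, each with a length
and a centromere interval.  All coordinates are 0-based half-open
internally; input files use the 1-based inclusive SEG convention and are
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "GenomeModel",
    "IntervalClass",
    "GenomeFormatError",
    "load_genome",
    "classify_interval",
]


class GenomeFormatError(ValueError):
    """Raised when a genome table violates the expected format or invariants."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: total length and centromere interval, in base pairs.

    The p-arm is ``[0, cen_start)`` and the q-arm ``[cen_end, length)``;
    both must be non-empty.
    """

    name: str
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenomeFormatError(f"{self.name}: non-positive length {self.length}")
        if not (0 < self.cen_start < self.cen_end < self.length):
            raise GenomeFormatError(
                f"{self.name}: centromere [{self.cen_start}, {self.cen_end}) must lie "
                f"strictly inside (0, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (0, self.cen_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.cen_end, self.length)


@dataclass(frozen=True)
class GenomeModel:
    """Ordered collection of chromosomes with unique names."""

    chromosomes: tuple[ChromosomeSpec, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenomeFormatError(f"duplicate chromosome names: {dupes}")
        object.__setattr__(self, "_index", {c.name: c for c in self.chromosomes})

    @classmethod
    def from_specs(cls, specs: Iterable[ChromosomeSpec]) -> "GenomeModel":
        return cls(tuple(specs))

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> ChromosomeSpec:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def arms(self) -> list[tuple[str, str, int, int]]:
        """All (chrom, arm, start, end) tuples, in chromosome order, p before q."""
        out = []
        for c in self.chromosomes:
            out.append((c.name, "p", *c.p_arm))
            out.append((c.name, "q", *c.q_arm))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.names,
                "length": [c.length for c in self.chromosomes],
                "cen_start": [c.cen_start for c in self.chromosomes],
                "cen_end": [c.cen_end for c in self.chromosomes],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class IntervalClass:
    """Arm assignment and telomere contact of a genomic interval."""

    arm: str  # "p", "q", or "crosses_centromere"
    touches_p_telomere: bool
    touches_q_telomere: bool


_REQUIRED_COLUMNS = ("chrom", "length", "cen_start", "cen_end")


def load_genome(path: str | Path) -> GenomeModel:
    """Read a genome model from a tab-separated table.

    The file must have a header row ``chrom length cen_start cen_end`` and
    one row per chromosome.  Row order is preserved.  Invalid rows raise
    :class:`GenomeFormatError` naming the offending row.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise GenomeFormatError(f"{path}: missing columns {missing}")
    specs = []
    for i, row in table.iterrows():
        try:
            specs.append(
                ChromosomeSpec(
                    name=str(row["chrom"]),
                    length=int(row["length"]),
                    cen_start=int(row["cen_start"]),
                    cen_end=int(row["cen_end"]),
                )
            )
        except (GenomeFormatError, ValueError) as exc:
            raise GenomeFormatError(f"{path}: row {i + 1}: {exc}") from exc
    return GenomeModel.from_specs(specs)


def classify_interval(
    genome: GenomeModel,
    chrom: str,
    start: int,
    end: int,
    telomere_tolerance: int = 0,
) -> IntervalClass:
    """Assign an interval to an arm and flag telomere contact.

    An interval *crosses the centromere* iff it has material strictly on
    both sides of the centromere interval; half-open adjacency (interval
    ending at ``cen_start`` or starting at ``cen_end``) is not crossing.
    Otherwise the interval is assigned to the arm containing its start.
    Telomere flags are true when the interval reaches within
    ``telomere_tolerance`` bp of position 0 (p) or the chromosome length (q).
    """
    spec = genome[chrom]
    if not (0 <= start < end <= spec.length):
        raise ValueError(
            f"{chrom}: invalid interval [{start}, {end}) for length {spec.length}"
        )
    if start < spec.cen_start and end > spec.cen_end:
        arm = "crosses_centromere"
    elif start < spec.cen_start:
        arm = "p"
    else:
        arm = "q"
    return IntervalClass(
        arm=arm,
        touches_p_telomere=start <= telomere_tolerance,
        touches_q_telomere=end >= spec.length - telomere_tolerance,
    )
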