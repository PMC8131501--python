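"""Genomic-scar statistics: LOH, TAI, LST, and their sum, the HRD score.

Homologous recombination deficiency (HRD) leaves three quantifiable scar
patterns in an allele-specific copy-number profile:

* **LOH** — count of loss-of-heterozygosity regions (minor allele absent,
  at least one copy retained) longer than 15 Mb but shorter than the whole
  chromosome.
* **TAI** — telomeric allelic imbalance: count of allelic-imbalance
  regions that extend to a subtelomere without crossing the centromere.
* **LST** — large-scale state transitions: count of breakpoints (change
  in copy number or allelic content) between adjacent segments each of at
  least 10 Mb, after smoothing and removing sub-3-Mb small-scale variants.

The HRD score is the sum of the three; a sample whose score exceeds the
configured cutoff (default 57, a minimum-log-rank-p optimum in serous
ovarian cancer) is classified HRD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .genome import GenomeModel
from .segments import (
    Segment,
    SegmentProfile,
    filter_small_variants,
    merge_equal_neighbors,
)

__all__ = [
    "ScarConfig",
    "ScarResult",
    "loh_score",
    "tai_score",
    "lst_score",
    "hrd_score",
    "classify_hrd",
    "score_profiles",
]

HRD = "HRD"
NON_HRD = "non-HRD"


@dataclass(frozen=True)
class ScarConfig:
    """Length thresholds (bp) and the HRD classification cutoff.

    ``loh_min_len``: LOH regions must be strictly longer than this.
    ``lst_min_seg``: both segments flanking an LST breakpoint must span at
    least this.  ``lst_filter_len``: variants strictly shorter than this
    are smoothed away before LST counting, and breakpoint gaps must be
    strictly smaller.  ``tai_min_len``: minimum telomeric-imbalance region
    length (no minimum by default).  ``telomere_tolerance``: how close to
    the chromosome end a segment must reach to count as telomeric (0 after
    profile normalization).
    """

    loh_min_len: int = 15_000_000
    lst_min_seg: int = 10_000_000
    lst_filter_len: int = 3_000_000
    tai_min_len: int = 0
    hrd_cutoff: float = 57
    telomere_tolerance: int = 0

    def __post_init__(self) -> None:
        for name in ("loh_min_len", "lst_min_seg", "lst_filter_len", "tai_min_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hrd_cutoff < 0:
            raise ValueError("hrd_cutoff must be >= 0")


@dataclass(frozen=True)
class ScarResult:
    """Per-sample scar counts, HRD score (= loh + tai + lst) and status."""

    sample_id: str
    loh: int
    tai: int
    lst: int
    hrd: int
    status: str


def classify_hrd(hrd: float, cfg: ScarConfig = ScarConfig()) -> str:
    """HRD iff the score strictly exceeds the cutoff; equal scores are non-HRD."""
    if hrd < 0:
        raise ValueError("HRD score must be non-negative")
    return HRD if hrd > cfg.hrd_cutoff else NON_HRD


def loh_score(
    profile: SegmentProfile, genome: GenomeModel, cfg: ScarConfig = ScarConfig()
) -> int:
    """Count interstitial LOH regions longer than ``loh_min_len``.

    Contiguous segments with minor_cn 0 (and at least one retained copy)
    are coalesced into maximal LOH regions regardless of total copy number
    — LOH is an allelic state, not a copy state.  A region spanning the
    whole chromosome is excluded.
    """
    count = 0
    for chrom, segs in profile.by_chromosome():
        chrom_len = genome[chrom].length
        run_start = run_end = None
        runs: list[tuple[int, int]] = []
        for seg in segs:
            if seg.is_loh:
                if run_end is not None and seg.start == run_end:
                    run_end = seg.end
                else:
                    if run_end is not None:
                        runs.append((run_start, run_end))
                    run_start, run_end = seg.start, seg.end
            else:
                if run_end is not None:
                    runs.append((run_start, run_end))
                    run_start = run_end = None
        if run_end is not None:
            runs.append((run_start, run_end))
        for start, end in runs:
            if end - start > cfg.loh_min_len and end - start < chrom_len:
                count += 1
    return count


def tai_score(
    profile: SegmentProfile, genome: GenomeModel, cfg: ScarConfig = ScarConfig()
) -> int:
    """Count telomere-anchored allelic-imbalance regions per chromosome end.

    For each telomere (p and q separately) the maximal run of contiguous
    allelic-imbalance segments anchored at that telomere is examined; it
    counts if it does not cross the centromere and is at least
    ``tai_min_len`` long.  A chromosome therefore contributes at most 2,
    and whole-chromosome imbalance contributes 0.
    """
    merged = merge_equal_neighbors(profile)
    count = 0
    tol = cfg.telomere_tolerance
    for chrom, segs in merged.by_chromosome():
        spec = genome[chrom]
        # p-telomere: run grows rightward from position 0
        if segs and segs[0].start <= tol and segs[0].has_allelic_imbalance:
            end = segs[0].end
            for prev, seg in zip(segs, segs[1:]):
                if seg.start == prev.end and seg.has_allelic_imbalance:
                    end = seg.end
                else:
                    break
            crosses = end > spec.cen_end  # run starts in p, crossing means exiting
            if not crosses and end - segs[0].start >= cfg.tai_min_len:
                count += 1
        # q-telomere: run grows leftward from the chromosome end
        if segs and segs[-1].end >= spec.length - tol and segs[-1].has_allelic_imbalance:
            start = segs[-1].start
            for nxt, seg in zip(segs[::-1], segs[-2::-1]):
                if seg.end == nxt.start and seg.has_allelic_imbalance:
                    start = seg.start
                else:
                    break
            crosses = start < spec.cen_start
            if not crosses and segs[-1].end - start >= cfg.tai_min_len:
                count += 1
    return count


def _split_at_arms(segs: list[Segment], cen_start: int, cen_end: int):
    """Clip a chromosome's segments to its p and q arms (centromere dropped)."""
    p_arm: list[Segment] = []
    q_arm: list[Segment] = []
    for seg in segs:
        if seg.start < cen_start:
            p_arm.append(replace(seg, end=min(seg.end, cen_start)))
        if seg.end > cen_end:
            q_arm.append(replace(seg, start=max(seg.start, cen_end)))
    return p_arm, q_arm


def lst_score(
    profile: SegmentProfile, genome: GenomeModel, cfg: ScarConfig = ScarConfig()
) -> int:
    """Count large-scale state transitions, per arm, after smoothing.

    Each arm is processed independently (a transition at the centromere is
    never counted): segments are clipped to the arm, equal-state neighbours
    merged, variants shorter than ``lst_filter_len`` absorbed, and a
    breakpoint is counted whenever two consecutive segments differ in
    state, each spans at least ``lst_min_seg``, and the uncovered gap
    between them is smaller than ``lst_filter_len``.
    """
    count = 0
    for chrom, segs in profile.by_chromosome():
        spec = genome[chrom]
        for arm_segs in _split_at_arms(list(segs), spec.cen_start, spec.cen_end):
            if len(arm_segs) < 2:
                continue
            arm_profile = SegmentProfile(profile.sample_id, tuple(arm_segs))
            smoothed = filter_small_variants(arm_profile, cfg.lst_filter_len)
            segs_s = smoothed.segments
            for a, b in zip(segs_s, segs_s[1:]):
                if (
                    a.state != b.state
                    and a.length >= cfg.lst_min_seg
                    and b.length >= cfg.lst_min_seg
                    and b.start - a.end < cfg.lst_filter_len
                ):
                    count += 1
    return count


def hrd_score(
    profile: SegmentProfile, genome: GenomeModel, cfg: ScarConfig = ScarConfig()
) -> ScarResult:
    """Compute all three scars and classify HRD status."""
    loh = loh_score(profile, genome, cfg)
    tai = tai_score(profile, genome, cfg)
    lst = lst_score(profile, genome, cfg)
    hrd = loh + tai + lst
    return ScarResult(
        sample_id=profile.sample_id,
        loh=loh,
        tai=tai,
        lst=lst,
        hrd=hrd,
        status=classify_hrd(hrd, cfg),
    )


def score_profiles(
    profiles: Iterable[SegmentProfile],
    genome: GenomeModel,
    cfg: ScarConfig = ScarConfig(),
) -> pd.DataFrame:
    """Score many profiles; returns columns sample, loh, tai, lst, hrd, status."""
    results = [hrd_score(p, genome, cfg) for p in profiles]
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "loh": [r.loh for r in results],
            "tai": [r.tai for r in results],
            "lst": [r.lst for r in results],
            "hrd": [r.hrd for r in results],
            "status": [r.status for r in results],
        }
    )
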