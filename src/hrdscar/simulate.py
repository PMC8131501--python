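"""Truth-known synthetic cohorts: scar profiles, survival, expression.

The generator builds segment profiles whose LOH/TAI/LST counts are known
*by construction*, never by running the scorer — events are placed on
distinct chromosome arms with buffer geometry that provably prevents any
event from contributing to another statistic:

* **LOH event** — an interstitial minor-allele-absent region of 16–20 Mb
  flanked by 4–8 Mb buffer segments of a third state.  The buffers are
  shorter than the 10 Mb large-segment bound, so no state transition
  qualifies for LST, and a balanced margin keeps the telomeres clean.
* **TAI event** — a telomere-anchored 3/1 imbalance of 5–9 Mb that stays
  on its arm: too short for LST, minor allele retained, so only TAI sees it.
* **LST chain** — `c` transitions realized as `c+1` alternating balanced
  blocks (2/1 | 4/2) of ≥ 10.5 Mb tiling an arm: balanced everywhere, so
  neither LOH nor TAI is touched.

Everything else is a diploid heterozygous 2/1 background.  On top of the
profiles, the cohort generator draws exponential survival with a planted
group hazard ratio and negative-binomial expression counts with planted
differentially expressed and prognostic genes, emulating a tumor cohort
with allele-specific SNP-array calls, follow-up, and bulk RNA-seq.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ChromosomeSpec, GenomeModel
from .scars import HRD, NON_HRD
from .screen import ExpressionMatrix, tpm_normalize
from .segments import Segment, SegmentProfile, write_segments

__all__ = [
    "toy_genome",
    "simulate_scar_profile",
    "simulate_survival",
    "simulate_expression",
    "simulate_cohort",
    "CohortBundle",
    "write_bundle",
]

MB = 1_000_000
BACKGROUND = (2, 1)  # diploid heterozygous
LST_STATE = (4, 2)  # balanced gain used in LST chains
BUFFER_STATE = (3, 1)  # imbalanced buffer flanking LOH events
LOH_STATE = (2, 0)  # copy-neutral LOH


def toy_genome(
    n_chromosomes: int = 22,
    length: int = 200 * MB,
    cen_start: int = 95 * MB,
    cen_end: int = 100 * MB,
) -> GenomeModel:
    """A uniform toy genome: 22 chromosomes of 200 Mb, centromere at 95–100 Mb."""
    return GenomeModel.from_specs(
        ChromosomeSpec(f"chr{i + 1}", length, cen_start, cen_end)
        for i in range(n_chromosomes)
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _loh_blocks(rng, arm_start, arm_end):
    """Foreign blocks for one LOH event: buffer | LOH 16–20 Mb | buffer."""
    b1 = int(rng.integers(4 * MB, 8 * MB + 1))
    b2 = int(rng.integers(4 * MB, 8 * MB + 1))
    loh = int(rng.integers(16 * MB, 20 * MB + 1))
    unit = b1 + loh + b2
    margin = 10 * MB  # balanced background on both sides, inside the arm
    lo, hi = arm_start + margin, arm_end - margin - unit
    start = int(rng.integers(lo, hi + 1))
    return [
        (start, start + b1, *BUFFER_STATE),
        (start + b1, start + b1 + loh, *LOH_STATE),
        (start + b1 + loh, start + unit, *BUFFER_STATE),
    ]


def _tai_blocks(rng, arm_start, arm_end, at_p_telomere):
    """One telomere-anchored 5–9 Mb imbalanced block."""
    ln = int(rng.integers(5 * MB, 9 * MB + 1))
    if at_p_telomere:
        return [(arm_start, arm_start + ln, *BUFFER_STATE)]
    return [(arm_end - ln, arm_end, *BUFFER_STATE)]


def _lst_blocks(rng, arm_start, arm_end, n_transitions):
    """`n_transitions` breakpoints: alternating balanced blocks tiling the arm."""
    n_blocks = n_transitions + 1
    min_block = 10 * MB + MB // 2
    arm_len = arm_end - arm_start
    slack = arm_len - n_blocks * min_block
    if slack < 0:
        raise ValueError("arm too short for requested LST transitions")
    cuts = np.sort(rng.integers(0, slack + 1, size=n_blocks - 1))
    bounds = [arm_start]
    for i, c in enumerate(cuts):
        bounds.append(arm_start + (i + 1) * min_block + int(c))
    bounds.append(arm_end)
    blocks = []
    for i in range(n_blocks):
        state = BACKGROUND if i % 2 == 0 else LST_STATE
        if state != BACKGROUND:  # background blocks are filled in later anyway
            blocks.append((bounds[i], bounds[i + 1], *state))
    return blocks


def _assemble_profile(
    sample_id: str, genome: GenomeModel, foreign: dict[str, list]
) -> SegmentProfile:
    """Fill every chromosome with 2/1 background around the foreign blocks."""
    segments: list[Segment] = []
    for spec in genome:
        blocks = sorted(foreign.get(spec.name, ()))
        pos = 0
        for start, end, total, minor in blocks:
            if start > pos:
                segments.append(Segment(spec.name, pos, start, *BACKGROUND))
            segments.append(Segment(spec.name, start, end, total, minor))
            pos = end
        if pos < spec.length:
            segments.append(Segment(spec.name, pos, spec.length, *BACKGROUND))
    return SegmentProfile(sample_id, tuple(segments))


def simulate_scar_profile(
    genome: GenomeModel,
    planted: tuple[int, int, int],
    seed=0,
    sample_id: str = "S1",
    lst_per_arm: int = 1,
) -> tuple[SegmentProfile, dict]:
    """Generate a profile with exactly ``planted`` = (LOH, TAI, LST) scars.

    Events occupy distinct arms chosen at random; LST transitions may be
    chained up to ``lst_per_arm`` per arm (each chain of ``c`` breakpoints
    consumes one arm).  Raises if the genome has too few arms.
    """
    loh_n, tai_n, lst_n = (int(v) for v in planted)
    if min(loh_n, tai_n, lst_n) < 0:
        raise ValueError("planted counts must be non-negative")
    if lst_per_arm < 1:
        raise ValueError("lst_per_arm must be >= 1")
    rng = _rng(seed)
    arms = genome.arms()
    n_chains = math.ceil(lst_n / lst_per_arm)
    needed = loh_n + tai_n + n_chains
    if needed > len(arms):
        raise ValueError(
            f"planted events need {needed} arms, genome has only {len(arms)}"
        )
    picked = rng.permutation(len(arms))[:needed]
    foreign: dict[str, list] = {}
    cursor = 0

    def take():
        nonlocal cursor
        arm = arms[picked[cursor]]
        cursor += 1
        return arm

    for _ in range(loh_n):
        chrom, _, a0, a1 = take()
        foreign.setdefault(chrom, []).extend(_loh_blocks(rng, a0, a1))
    for _ in range(tai_n):
        chrom, arm, a0, a1 = take()
        foreign.setdefault(chrom, []).extend(_tai_blocks(rng, a0, a1, arm == "p"))
    remaining = lst_n
    for _ in range(n_chains):
        chrom, _, a0, a1 = take()
        c = min(lst_per_arm, remaining)
        remaining -= c
        foreign.setdefault(chrom, []).extend(_lst_blocks(rng, a0, a1, c))

    profile = _assemble_profile(sample_id, genome, foreign)
    truth = {"loh": loh_n, "tai": tai_n, "lst": lst_n, "hrd": loh_n + tai_n + lst_n}
    return profile, truth


def simulate_survival(
    group,
    hr: float = 0.49,
    baseline_rate: float = 0.03,
    censor_rate: float = 0.01,
    seed=0,
    linear_predictor=None,
    sample_ids=None,
) -> pd.DataFrame:
    """Exponential survival with a planted hazard ratio between groups.

    Per-subject hazard is ``baseline_rate × hr**group × exp(lp)`` events
    per month; censoring is an independent exponential with rate
    ``censor_rate``.  Returns columns ``sample time event``.
    """
    if hr <= 0 or baseline_rate <= 0 or censor_rate < 0:
        raise ValueError("hr and baseline_rate must be positive, censor_rate >= 0")
    rng = _rng(seed)
    g = np.asarray(group, dtype=float)
    lp = np.zeros_like(g) if linear_predictor is None else np.asarray(linear_predictor)
    hazard = baseline_rate * hr**g * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=g.size)
    else:
        censor_time = np.full(g.size, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(g.size)]
    return pd.DataFrame({"sample": list(sample_ids), "time": time, "event": event})


def simulate_expression(
    n_genes: int,
    groups: pd.Series,
    de_spec: dict[int, float] | None = None,
    dispersion: float = 0.15,
    seed=0,
    base_mean_range: tuple[float, float] = (5.0, 2000.0),
    length_range: tuple[int, int] = (500, 50_000),
    size_factor_sd: float = 0.15,
) -> tuple[ExpressionMatrix, dict]:
    """Negative-binomial counts with planted group effects.

    Per-gene base means are log-uniform over ``base_mean_range``; the mean
    for gene *g* in sample *s* is ``base_g × 2^(lfc_g × group_s) × sf_s``
    with log-normal per-sample size factors, and counts are drawn from a
    negative binomial with the given dispersion (variance m + φm²).  Gene
    lengths are drawn once per gene, log-uniform over ``length_range``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    de_spec = dict(de_spec or {})
    for idx in de_spec:
        if not 0 <= idx < n_genes:
            raise ValueError(f"DE gene index {idx} out of range")
    rng = _rng(seed)
    samples = list(groups.index)
    g = groups.to_numpy(dtype=float)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    lo, hi = base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    lengths = np.exp(
        rng.uniform(np.log(length_range[0]), np.log(length_range[1]), size=n_genes)
    ).astype(int)
    lfc = np.zeros(n_genes)
    for idx, effect in de_spec.items():
        lfc[idx] = effect
    sf = np.exp(rng.normal(0.0, size_factor_sd, size=len(samples)))
    mean = base[:, None] * 2.0 ** (lfc[:, None] * g[None, :]) * sf[None, :]
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        n_param = 1.0 / dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mean))
    em = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series(lengths.astype(float), index=genes),
        "counts",
    )
    truth = {
        "de_genes": {genes[i]: float(v) for i, v in de_spec.items()},
        "dispersion": dispersion,
    }
    return em, truth


@dataclass
class CohortBundle:
    """Everything a pipeline run needs, plus the generating truth."""

    genome: GenomeModel
    profiles: list[SegmentProfile]
    clinical: pd.DataFrame
    counts: ExpressionMatrix
    truth: dict = field(repr=False)


def _split_scar_counts(total: int) -> tuple[int, int, int]:
    """Deterministically split a target HRD score into (LOH, TAI, LST)."""
    tai = min(12, round(0.2 * total))
    loh = min(12, round(0.25 * total))
    return loh, tai, total - loh - tai


def simulate_cohort(
    genome: GenomeModel | None = None,
    n_samples: int = 348,
    hrd_fraction: float = 0.5,
    hr: float = 0.49,
    n_genes: int = 500,
    de_spec: dict[int, float] | None = None,
    prognostic_spec: dict[int, float] | None = None,
    threshold: float = 57.0,
    gap_halfwidth: int = 3,
    score_spread: float = 4.0,
    max_score: int = 90,
    baseline_rate: float = 0.03,
    censor_rate: float = 0.01,
    dispersion: float = 0.15,
    lst_per_arm: int = 6,
    seed: int = 0,
) -> CohortBundle:
    """Generate a joint cohort: segments, survival, expression, and truth.

    Planted HRD scores are drawn from well-separated status-conditional
    distributions straddling the classification ``threshold``: each group's
    scores sit adjacent to a dead zone of ``± gap_halfwidth`` around the
    threshold, receding from it with Poisson(``score_spread``) tails
    (non-HRD at ``threshold − gap − Pois``, HRD at ``threshold + gap +
    Pois``, clipped to [0, ``max_score``]).  Totals are split into
    (LOH, TAI, LST) and realized as segment profiles.  Survival hazard is
    ``baseline × hr^{HRD} × exp(Σ β_g z_g)`` where *z_g* is the realized
    standardized log2(TPM+1) of each prognostic gene, so planted prognostic
    genes are predictive on exactly the scale the screen tests.
    Differential-expression effects apply between the HRD and non-HRD
    groups.  Identical seeds give identical bundles.
    """
    rng = np.random.default_rng(seed)
    genome = toy_genome() if genome is None else genome
    n_hrd = round(hrd_fraction * n_samples)
    status = np.array([1] * n_hrd + [0] * (n_samples - n_hrd))
    rng.shuffle(status)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    low_edge = int(round(threshold - gap_halfwidth))
    high_edge = int(round(threshold + gap_halfwidth))
    totals = np.where(
        status == 1,
        np.minimum(high_edge + rng.poisson(score_spread, size=n_samples), max_score),
        np.maximum(low_edge - rng.poisson(score_spread, size=n_samples), 0),
    )
    profiles = []
    planted = []
    for sid, total in zip(sample_ids, totals):
        loh, tai, lst = _split_scar_counts(int(total))
        profile, _ = simulate_scar_profile(
            genome, (loh, tai, lst), seed=rng, sample_id=sid, lst_per_arm=lst_per_arm
        )
        profiles.append(profile)
        planted.append({"sample": sid, "loh": loh, "tai": tai, "lst": lst,
                        "hrd": int(total)})

    group_series = pd.Series(status, index=sample_ids)
    counts, expr_truth = simulate_expression(
        n_genes, group_series, de_spec=de_spec, dispersion=dispersion, seed=rng
    )

    prognostic_spec = dict(prognostic_spec or {})
    lp = np.zeros(n_samples)
    prognostic_truth = {}
    if prognostic_spec:
        log_tpm = np.log2(tpm_normalize(counts).data + 1.0)
        for idx, beta in prognostic_spec.items():
            gene = counts.genes[idx]
            x = log_tpm.loc[gene].to_numpy()
            z = (x - x.mean()) / x.std()
            lp += beta * z
            prognostic_truth[gene] = float(beta)

    clinical = simulate_survival(
        status,
        hr=hr,
        baseline_rate=baseline_rate,
        censor_rate=censor_rate,
        seed=rng,
        linear_predictor=lp,
        sample_ids=sample_ids,
    )

    truth = {
        "seed": seed,
        "hr": hr,
        "hrd_threshold_gap": [low_edge, high_edge],
        "samples": planted,
        "status": {sid: (HRD if s else NON_HRD) for sid, s in zip(sample_ids, status)},
        "expression": expr_truth,
        "prognostic_genes": prognostic_truth,
    }
    return CohortBundle(genome, profiles, clinical, counts, truth)


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the standard files: segments, genome, clinical, counts, lengths, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": outdir / "segments.tsv",
        "genome": outdir / "genome.tsv",
        "clinical": outdir / "clinical.tsv",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "truth": outdir / "truth.json",
    }
    write_segments(bundle.profiles, paths["segments"])
    bundle.genome.write(paths["genome"])
    bundle.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    bundle.counts.data.to_csv(paths["counts"], sep="\t", index_label="gene")
    bundle.counts.lengths.rename("length").to_csv(
        paths["lengths"], sep="\t", index_label="gene"
    )
    paths["truth"].write_text(json.dumps(bundle.truth, indent=1))
    return paths
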