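"""End-to-end orchestration: score → cutoff → screen → signature → risk.

The pipeline mirrors the discovery workflow for HRD-associated prognostic
transcripts: compute per-sample genomic-scar HRD scores, choose (or fix)
the survival-optimal classification cutoff, contrast the extreme score
cohorts for differential expression, screen the DEGs by univariate Cox,
select a signature by penalized Cox, and stratify the cohort by the
median risk score.  Every stage writes its table to the output directory,
and a machine-readable summary records the resolved configuration, seed,
versions, and headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import load_genome
from .scars import ScarConfig, score_profiles
from .screen import (
    ScreenThresholds,
    differential_expression,
    penalized_signature_selection,
    read_counts,
    risk_stratify,
    select_extreme_cohorts,
    tpm_normalize,
    univariate_prognostic_screen,
)
from .segments import read_segments
from .survival import optimal_cutoff, read_clinical

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]

log = logging.getLogger("hrdscar")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    ``fixed_cutoff`` switches the HRD classification from the per-cohort
    minimum-p scan (the default) to a fixed score threshold, e.g. 57.
    """

    segments: str = "segments.tsv"
    genome: str = "genome.tsv"
    clinical: str = "clinical.tsv"
    counts: str = "counts.tsv"
    lengths: str = "lengths.tsv"
    outdir: str = "hrdscar_out"
    scar: ScarConfig = field(default_factory=ScarConfig)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    fixed_cutoff: float | None = None
    min_group_fraction: float = 0.1
    extreme_fraction: float = 0.2
    cox_alpha: float = 0.05
    lasso_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if isinstance(data.get("scar"), dict):
            data["scar"] = ScarConfig(**data["scar"])
        if isinstance(data.get("thresholds"), dict):
            data["thresholds"] = ScreenThresholds(**data["thresholds"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorate


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dictionary (also written to
    ``outdir/summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def done(stage: str, **info):
        summary["stages"].append(stage)
        summary[stage] = info
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))

    # --- scoring -----------------------------------------------------------
    @_stage("score")
    def stage_score():
        genome = load_genome(config.genome)
        profiles = read_segments(config.segments, genome)
        scores = score_profiles(profiles, genome, config.scar)
        scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        return genome, scores

    genome, scores = stage_score()
    done("score", n_samples=len(scores), mean_hrd=float(scores["hrd"].mean()))

    clinical = read_clinical(config.clinical)
    clin_idx = clinical.set_index("sample")
    aligned = scores[scores["sample"].isin(clin_idx.index)].set_index("sample")
    t = clin_idx.loc[aligned.index, "time"].to_numpy(float)
    e = clin_idx.loc[aligned.index, "event"].to_numpy(int)

    # --- cutoff ------------------------------------------------------------
    @_stage("cutoff")
    def stage_cutoff():
        if config.fixed_cutoff is not None:
            return float(config.fixed_cutoff), None
        scan = optimal_cutoff(
            aligned["hrd"].to_numpy(float), t, e, config.min_group_fraction
        )
        scan.scan.to_csv(outdir / "cutoff_scan.tsv", sep="\t", index=False)
        return scan.optimal_cutoff, scan

    cutoff, scan = stage_cutoff()
    status = np.where(aligned["hrd"] > cutoff, "HRD", "non-HRD")
    pd.DataFrame({"sample": aligned.index, "hrd": aligned["hrd"], "status": status}).to_csv(
        outdir / "hrd_status.tsv", sep="\t", index=False
    )
    done(
        "cutoff",
        cutoff=float(cutoff),
        source="fixed" if config.fixed_cutoff is not None else "min_p_scan",
        min_p=None if scan is None else scan.min_p,
        n_hrd=int((status == "HRD").sum()),
    )

    # --- extremes + differential expression --------------------------------
    @_stage("extremes")
    def stage_extremes():
        return select_extreme_cohorts(aligned["hrd"], config.extreme_fraction)

    high_ids, low_ids = stage_extremes()
    done("extremes", n_high=len(high_ids), n_low=len(low_ids))

    @_stage("differential_expression")
    def stage_de():
        counts = read_counts(config.counts, config.lengths)
        de = differential_expression(counts, high_ids, low_ids, config.thresholds)
        de.to_csv(outdir / "differential_expression.tsv", sep="\t", index_label="gene")
        return counts, de

    counts, de = stage_de()
    degs = list(de.index[de["passes_de"]])
    n_up = int((de.loc[degs, "log2_fc"] > 0).sum())
    done("differential_expression", n_de=len(degs), n_up=n_up, n_down=len(degs) - n_up)

    # --- prognostic screen --------------------------------------------------
    tpm = tpm_normalize(counts)
    if not degs:
        done("cox_screen", n_candidates=0, note="no DEGs; downstream stages skipped")
        return summary

    @_stage("cox_screen")
    def stage_cox():
        table = univariate_prognostic_screen(tpm, clinical, degs, config.cox_alpha)
        table.to_csv(outdir / "cox_screen.tsv", sep="\t", index_label="gene")
        return table

    cox_table = stage_cox()
    candidates = list(cox_table.index[cox_table["prognostic"]])
    done("cox_screen", n_candidates=len(candidates), candidates=candidates)
    if not candidates:
        return summary

    # --- penalized selection and risk stratification ------------------------
    @_stage("signature_selection")
    def stage_select():
        return penalized_signature_selection(
            tpm, clinical, candidates, n_folds=config.lasso_folds, seed=config.seed
        )

    selection = stage_select()
    signature = selection.genes
    done(
        "signature_selection",
        signature=signature,
        best_alpha=selection.best_alpha,
        coefficients={g: float(c) for g, c in selection.coefficients.items()},
    )
    if not signature:
        return summary
    risk = selection.risk_scores(tpm)

    @_stage("risk_stratification")
    def stage_risk():
        strat = risk_stratify(risk, clinical)
        pd.DataFrame(
            {"sample": risk.index, "risk_score": risk.to_numpy(), "group": strat.groups}
        ).to_csv(outdir / "risk_groups.tsv", sep="\t", index=False)
        return strat

    strat = stage_risk()
    done(
        "risk_stratification",
        hr=strat.cox.hr,
        ci95=[strat.cox.ci95_low, strat.cox.ci95_high],
        logrank_p=strat.logrank.p,
    )
    return summary
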