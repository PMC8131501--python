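"""HRD-associated prognostic-gene screen.

The screen mirrors a now-common biomarker-discovery cascade in bulk
transcriptomics of tumor cohorts:

1. rank samples by HRD score and take the top and bottom 20% as the
   contrast cohorts;
2. normalize counts to transcripts per million (TPM);
3. keep expressed genes (mean TPM > 1 in at least one group) in the top
   75% of variability (median absolute deviation of log2(TPM+1));
4. per-gene two-group test with Benjamini–Hochberg adjustment and a
   fold-change threshold → differentially expressed genes (DEGs);
5. univariate Cox screen of the DEGs against overall survival (raw
   p < 0.05);
6. L1-penalized (lasso) Cox selection with the penalty chosen by 10-fold
   cross-validated partial-likelihood deviance → the gene signature;
7. median split of the resulting risk score → risk groups, log-rank test
   and hazard ratio.

The per-gene test is a Wilcoxon rank-sum on log2(TPM+1): deterministic and
assumption-light.  Count-model (negative-binomial) machinery would change
individual p-values but not the cascade structure, so survivor counts are
not expected to match any particular count-based analysis gene for gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .survival import CoxResult, LogrankResult, cox_partial_loglik, fit_cox_univariate, logrank_test

__all__ = [
    "ExpressionMatrix",
    "ScreenThresholds",
    "SignatureSelection",
    "RiskStratification",
    "read_counts",
    "tpm_normalize",
    "select_extreme_cohorts",
    "mad_filter",
    "bh_adjust",
    "differential_expression",
    "univariate_prognostic_screen",
    "penalized_signature_selection",
    "risk_stratify",
    "feature_correlation",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample expression table with gene lengths and a unit tag."""

    data: pd.DataFrame  # genes in rows, samples in columns
    lengths: pd.Series  # gene length in bp, aligned to data.index
    unit: str = "counts"  # "counts" or "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.lengths.index.equals(self.data.index):
            raise ValueError("gene lengths must align with the expression index")
        if (self.lengths.to_numpy() <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        data = self.data
        lengths = self.lengths
        if genes is not None:
            data = data.loc[genes]
            lengths = lengths.loc[genes]
        if samples is not None:
            data = data[list(samples)]
        return ExpressionMatrix(data, lengths, self.unit)


def read_counts(counts_path: str | Path, lengths_path: str | Path) -> ExpressionMatrix:
    """Read a gene × sample count TSV (first column ``gene``) and a
    ``gene length`` TSV into a counts matrix."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without length: {list(missing[:5])} ...")
    return ExpressionMatrix(counts, lengths.loc[counts.index].astype(float), "counts")


def tpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million: length-normalize, then scale columns to 1e6.

    TPM_g = (count_g / length_g) / Σ_g (count_g / length_g) × 10⁶, so every
    column sums to 10⁶ and the result is invariant to per-sample count
    scaling.
    """
    if counts.unit != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    rate = counts.data.div(counts.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total signal: {list(zero.index)}")
    tpm = rate.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, counts.lengths, "TPM")


def select_extreme_cohorts(
    scores: pd.Series, fraction: float = 0.2
) -> tuple[list[str], list[str]]:
    """Top/bottom ``fraction`` of samples by score → (high_ids, low_ids).

    k = ceil(fraction × n) per group; boundary ties are broken by sample-id
    order for determinism.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores)
    k = int(np.ceil(fraction * n))
    if 2 * k > n:
        raise ValueError(f"cohort of {n} too small for fraction {fraction}")
    order = scores.loc[sorted(scores.index)].sort_values(kind="stable")
    ids = list(order.index)
    return ids[-k:], ids[:k]


def mad_filter(tpm: ExpressionMatrix, keep_fraction: float = 0.75) -> pd.Index:
    """Keep the most variable genes by MAD of log2(TPM+1) across samples.

    The top ``keep_fraction`` of genes by MAD rank are kept; ties at the
    boundary are kept, so the result may slightly exceed the fraction.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    if tpm.data.empty:
        raise ValueError("empty expression matrix")
    log = np.log2(tpm.data + 1.0)
    mad = (log.sub(log.median(axis=1), axis=0)).abs().median(axis=1)
    k = int(np.ceil(keep_fraction * len(mad)))
    threshold = np.sort(mad.to_numpy())[::-1][k - 1]
    return mad.index[mad >= threshold]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ScreenThresholds:
    """DEG cascade thresholds: fold change, adjusted p, abundance, MAD keep."""

    fc: float = 1.5
    adj_p: float = 0.05
    min_tpm: float = 1.0
    mad_keep: float = 0.75
    abundance_rule: str = "either"  # mean TPM > min_tpm in "either" or "both" groups


def differential_expression(
    counts: ExpressionMatrix,
    high_ids,
    low_ids,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> pd.DataFrame:
    """Run the DEG filter cascade between the high- and low-score cohorts.

    Cascade order: (1) abundance — mean TPM > ``min_tpm`` in at least one
    group (or both, per ``abundance_rule``); (2) MAD variability filter on
    the survivors; (3) Wilcoxon rank-sum on log2(TPM+1) with BH adjustment
    over the tested genes; (4) |mean log2(TPM+1) difference| > log2(fc).
    The returned frame records, per gene, every statistic and which filter
    (if any) it failed.
    """
    high_ids, low_ids = list(high_ids), list(low_ids)
    if set(high_ids) & set(low_ids):
        raise ValueError("high and low cohorts overlap")
    if min(len(high_ids), len(low_ids)) < 3:
        raise ValueError("each cohort needs at least 3 samples")
    em = counts if counts.unit == "TPM" else tpm_normalize(counts)
    em = em.subset(samples=high_ids + low_ids)
    tpm_high = em.data[high_ids]
    tpm_low = em.data[low_ids]

    out = pd.DataFrame(index=em.genes)
    out["mean_tpm_high"] = tpm_high.mean(axis=1)
    out["mean_tpm_low"] = tpm_low.mean(axis=1)
    log_high = np.log2(tpm_high + 1.0)
    log_low = np.log2(tpm_low + 1.0)
    out["log2_fc"] = log_high.mean(axis=1) - log_low.mean(axis=1)

    if thresholds.abundance_rule == "both":
        out["passes_abundance"] = (out["mean_tpm_high"] > thresholds.min_tpm) & (
            out["mean_tpm_low"] > thresholds.min_tpm
        )
    else:
        out["passes_abundance"] = (out["mean_tpm_high"] > thresholds.min_tpm) | (
            out["mean_tpm_low"] > thresholds.min_tpm
        )

    abundant = out.index[out["passes_abundance"]]
    kept = mad_filter(em.subset(genes=abundant), thresholds.mad_keep)
    out["passes_mad"] = out.index.isin(kept) & out["passes_abundance"]

    out["p"] = np.nan
    out["adj_p"] = np.nan
    tested = out.index[out["passes_mad"]]
    if len(tested):
        res = stats.mannwhitneyu(
            log_high.loc[tested].to_numpy(),
            log_low.loc[tested].to_numpy(),
            axis=1,
            alternative="two-sided",
        )
        out.loc[tested, "p"] = res.pvalue
        out.loc[tested, "adj_p"] = bh_adjust(res.pvalue)
    out["passes_p"] = out["adj_p"] < thresholds.adj_p
    out["passes_fc"] = out["log2_fc"].abs() > np.log2(thresholds.fc)
    out["passes_de"] = (
        out["passes_abundance"] & out["passes_mad"] & out["passes_p"] & out["passes_fc"]
    )
    out["direction"] = np.where(out["log2_fc"] > 0, "up_in_high", "down_in_high")

    def first_failure(row):
        for name in ("abundance", "mad", "p", "fc"):
            if not row[f"passes_{name}"]:
                return name
        return ""

    out["filter_failed"] = out.apply(first_failure, axis=1)
    return out


def univariate_prognostic_screen(
    tpm: ExpressionMatrix,
    clinical: pd.DataFrame,
    genes=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene univariate Cox fit of log2(TPM+1) against overall survival.

    Returns the per-gene statistics with a ``prognostic`` flag for raw
    p < ``alpha`` (no multiplicity correction at this stage, by design: the
    penalized selection downstream is the gatekeeper).  Constant genes are
    skipped with a warning.
    """
    genes = tpm.genes if genes is None else pd.Index(genes)
    samples = [s for s in tpm.samples if s in set(clinical["sample"])]
    clin = clinical.set_index("sample").loc[samples]
    t = clin["time"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    log = np.log2(tpm.data.loc[genes, samples] + 1.0)
    rows = []
    for gene in genes:
        x = log.loc[gene].to_numpy()
        if np.ptp(x) == 0:
            warnings.warn(f"gene {gene}: constant expression, skipped", stacklevel=2)
            continue
        res = fit_cox_univariate(t, e, x)
        rows.append(
            (gene, res.beta, res.hr, res.ci95_low, res.ci95_high, res.p, res.converged)
        )
    out = pd.DataFrame(
        rows, columns=["gene", "beta", "hr", "ci95_low", "ci95_high", "p", "converged"]
    ).set_index("gene")
    out["prognostic"] = (out["p"] < alpha) & out["converged"]
    return out


@dataclass(frozen=True)
class SignatureSelection:
    """Lasso–Cox selection result: the signature and its provenance."""

    genes: list[str]
    coefficients: pd.Series  # nonzero coefficients, on standardized log2(TPM+1)
    best_alpha: float
    cv_path: pd.DataFrame = field(repr=False)  # alpha, cv partial log-likelihood
    means: pd.Series = field(repr=False)
    scales: pd.Series = field(repr=False)

    def risk_scores(self, tpm: ExpressionMatrix) -> pd.Series:
        """Linear predictor Σ coef_g · z_g on new samples (z = standardized
        log2(TPM+1) using the training means/scales)."""
        log = np.log2(tpm.data.loc[self.coefficients.index] + 1.0)
        z = log.sub(self.means, axis=0).div(self.scales, axis=0)
        return z.mul(self.coefficients, axis=0).sum(axis=0)


def penalized_signature_selection(
    tpm: ExpressionMatrix,
    clinical: pd.DataFrame,
    candidate_genes,
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "1se",
) -> SignatureSelection:
    """L1-penalized Cox selection over the candidate genes.

    The coordinate-descent path is delegated to scikit-survival's Coxnet
    solver; the penalty is assessed by ``n_folds``-fold cross-validated
    partial-likelihood deviance (Verweij–van Houwelingen form: the
    held-out contribution is the full-data partial log-likelihood minus
    the training-set one, both evaluated at the training coefficients).
    With ``rule="min"`` the deviance-minimizing penalty is used; the
    default ``rule="1se"`` takes the strongest penalty whose deviance is
    within one standard error of the minimum — the parsimonious choice
    that reliably collapses a one-signal candidate set to that single
    gene.  Genes with nonzero coefficients at the chosen penalty form the
    signature.  Fold assignment is seed-controlled.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    candidate_genes = list(candidate_genes)
    if len(candidate_genes) < 1:
        raise ValueError("no candidate genes")
    samples = [s for s in tpm.samples if s in set(clinical["sample"])]
    if len(samples) < n_folds:
        raise ValueError(f"{len(samples)} samples < {n_folds} folds")
    clin = clinical.set_index("sample").loc[samples]
    t = clin["time"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    log = np.log2(tpm.data.loc[candidate_genes, samples] + 1.0).T  # samples × genes
    means = log.mean(axis=0)
    scales = log.std(axis=0, ddof=0).replace(0.0, 1.0)
    X = ((log - means) / scales).to_numpy()
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    if rule not in ("min", "1se"):
        raise ValueError(f"unknown rule {rule!r}")
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=50, alpha_min_ratio=0.01)
    with warnings.catch_warnings():
        # the strongest path penalties legitimately zero out every coefficient
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        path.fit(X, y)
        alphas = path.alphas_  # descending

        # a fold may truncate the tail of the path; missing entries stay NaN
        # and those alphas are dropped below
        fold_dev = np.full((n_folds, len(alphas)), np.nan)
        folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for k, (train, _test) in enumerate(folds.split(X)):
            model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, fit_baseline_model=False
            )
            model.fit(X[train], y[train])
            for j in range(model.coef_.shape[1]):
                beta = model.coef_[:, j]
                if np.max(np.abs(beta)) > 8:
                    # near-separation blow-up at a vanishing penalty: the
                    # held-out deviance is meaningless there
                    fold_dev[k, j] = np.nan
                    continue
                fold_dev[k, j] = -2.0 * (
                    cox_partial_loglik(X, t, e, beta)
                    - cox_partial_loglik(X[train], t[train], e[train], beta)
                )
    valid = np.isfinite(fold_dev).all(axis=0)
    fold_dev = fold_dev[:, valid]
    alphas = alphas[valid]
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        best = i_min
    else:
        within = np.flatnonzero(mean_dev <= mean_dev[i_min] + se_dev[i_min])
        best = int(within[0])  # alphas descend: first index = strongest penalty
    best_alpha = float(alphas[best])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[best_alpha], fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        final.fit(X, y)
    coefs = pd.Series(final.coef_[:, 0], index=candidate_genes)
    nonzero = coefs[coefs != 0.0]
    return SignatureSelection(
        genes=list(nonzero.index),
        coefficients=nonzero,
        best_alpha=best_alpha,
        cv_path=pd.DataFrame(
            {"alpha": alphas, "cv_deviance": mean_dev, "cv_deviance_se": se_dev}
        ),
        means=means.loc[nonzero.index],
        scales=scales.loc[nonzero.index],
    )


@dataclass(frozen=True)
class RiskStratification:
    """Median-split risk groups with log-rank test and hazard ratio."""

    groups: pd.Series  # "high" / "low" per sample
    logrank: LogrankResult
    cox: CoxResult  # binary high-vs-low covariate

    @property
    def hr(self) -> float:
        return self.cox.hr


def risk_stratify(
    risk_scores: pd.Series, clinical: pd.DataFrame
) -> RiskStratification:
    """Dichotomize at the median risk score (ties → low) and test survival.

    Reports the two-group log-rank test and a Cox fit on the binary group
    indicator (high = 1), so the hazard ratio is high-risk vs low-risk.
    """
    scores = risk_scores.astype(float)
    if scores.nunique() < 2:
        raise ValueError("all risk scores are equal")
    clin = clinical.set_index("sample").loc[scores.index]
    t = clin["time"].to_numpy(float)
    e = clin["event"].to_numpy(int)
    median = float(scores.median())
    high = (scores > median).to_numpy()
    groups = pd.Series(np.where(high, "high", "low"), index=scores.index)
    lr = logrank_test(t[~high], e[~high], t[high], e[high])
    cox = fit_cox_univariate(t, e, high.astype(float))
    return RiskStratification(groups=groups, logrank=lr, cox=cox)


def feature_correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need aligned 1-d vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
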