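"""Survival statistics: Kaplan–Meier, log-rank, univariate Cox, min-p cutoff.

These are the building blocks of the HRD survival analysis: the
product-limit estimator for plotting, the two-group log-rank chi-square
test, a single-covariate Cox proportional-hazards fit (Breslow tie
handling, Newton–Raphson), and the optimal-cutoff search that scans
dichotomization thresholds and picks the one minimizing the log-rank
p-value — the procedure behind the HRD-score cutoff of 57.

All functions accept plain sequences/arrays of durations and binary event
indicators (1 = event observed, 0 = censored), aligned by position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KaplanMeierEstimate",
    "LogrankResult",
    "CoxResult",
    "CutoffScan",
    "km_estimate",
    "logrank_test",
    "fit_cox_univariate",
    "cox_partial_loglik",
    "optimal_cutoff",
    "read_clinical",
]


def _as_survival_arrays(durations, events):
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("durations and events must be 1-d and aligned")
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (event)")
    return t, e


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Right-continuous product-limit step function; S(0) = 1."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t+) at each event time

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), "right")
        surv = np.concatenate([[1.0], self.survival])
        return surv[idx]


def km_estimate(durations, events) -> KaplanMeierEstimate:
    """Kaplan–Meier product-limit estimator.

    With no censoring this equals the empirical survival function; steps
    occur only at observed event times.
    """
    t, e = _as_survival_arrays(durations, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    at_risk = n - np.searchsorted(t, event_times, "left")
    deaths = np.array([np.sum((t == u) & (e == 1)) for u in event_times])
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KaplanMeierEstimate(event_times=event_times, survival=surv)


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    observed_minus_expected: float  # O - E for the first group
    variance: float


def logrank_test(
    durations_a, events_a, durations_b, events_b
) -> LogrankResult:
    """Two-group log-rank test.

    Observed-minus-expected events are accumulated over the pooled distinct
    event times with the hypergeometric variance; the statistic is
    (O−E)²/V, referred to a chi-square with 1 df.  Symmetric in the group
    labels.
    """
    ta, ea = _as_survival_arrays(durations_a, events_a)
    tb, eb = _as_survival_arrays(durations_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    if e.sum() == 0:
        raise ValueError("log-rank test requires at least one event")

    event_times = np.unique(t[e == 1])
    # at-risk counts: subjects with t >= u
    n_all = np.array([np.sum(t >= u) for u in event_times], dtype=float)
    n_a = np.array([np.sum(ta >= u) for u in event_times], dtype=float)
    d_all = np.array([np.sum((t == u) & (e == 1)) for u in event_times], dtype=float)
    d_a = np.array(
        [np.sum((ta == u) & (ea == 1)) for u in event_times], dtype=float
    )
    if n_a[0] == 0 or n_a[0] == n_all[0]:
        raise ValueError("a group has no subjects at risk at the first event time")

    expected = d_all * n_a / n_all
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_all
            * (n_a / n_all)
            * (1.0 - n_a / n_all)
            * (n_all - d_all)
            / np.where(n_all > 1, n_all - 1.0, np.inf)
        )
    o_minus_e = float(np.sum(d_a - expected))
    v = float(np.nansum(var))
    if v <= 0:
        # no variability in group membership over the risk sets
        return LogrankResult(0.0, 1.0, o_minus_e, v)
    chi2 = o_minus_e**2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, o_minus_e, v)


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate proportional-hazards fit (Breslow tie handling)."""

    beta: float
    se: float
    hr: float
    ci95_low: float
    ci95_high: float
    p: float
    converged: bool
    n: int
    n_events: int


def _breslow_sums(t, e, x):
    """Per-distinct-event-time risk-set ingredients, processed once.

    Returns (event times order irrelevant): for each distinct event time u,
    d_u (number of events), sum of x over events at u, and the index into
    the descending-time ordering where the risk set for u begins.
    """
    order = np.argsort(-t, kind="stable")
    t_d, e_d, x_d = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])[::-1]  # descending
    # risk set for u = all subjects with t >= u = prefix of descending order
    risk_end = np.searchsorted(-t_d, -event_times, "right")
    d = np.array([np.sum((t == u) & (e == 1)) for u in event_times], dtype=float)
    sx = np.array([np.sum(x[(t == u) & (e == 1)]) for u in event_times])
    return t_d, x_d, event_times, risk_end, d, sx


def _cox_loglik_grad_info(beta, x_d, risk_end, d, sx):
    r = np.exp(beta * x_d)
    s0 = np.cumsum(r)[risk_end - 1]
    s1 = np.cumsum(r * x_d)[risk_end - 1]
    s2 = np.cumsum(r * x_d**2)[risk_end - 1]
    loglik = float(np.sum(beta * sx - d * np.log(s0)))
    mean = s1 / s0
    grad = float(np.sum(sx - d * mean))
    info = float(np.sum(d * (s2 / s0 - mean**2)))
    return loglik, grad, info


def fit_cox_univariate(
    durations, events, covariate, tol: float = 1e-8, max_iter: int = 100
) -> CoxResult:
    """Maximize the single-covariate Cox partial likelihood by Newton iteration.

    Ties are handled with the Breslow approximation.  The covariate is
    standardized internally for numerical stability (results are reported
    on the input scale); iteration stops when the standardized |gradient|
    falls below ``tol``.  Monotone likelihood (complete separation) is
    detected by blow-up of the standardized coefficient and flagged via
    ``converged=False`` rather than silently returned.
    """
    t, e = _as_survival_arrays(durations, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate must align with durations")
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate carries no information")
    scale = x.std()
    z = (x - x.mean()) / scale

    _, x_d, _, risk_end, d, sx = _breslow_sums(t, e, z)
    beta = 0.0
    loglik, grad, info = _cox_loglik_grad_info(beta, x_d, risk_end, d, sx)
    diverged = False
    for _ in range(max_iter):
        if abs(grad) < tol or diverged:
            break
        step = grad / info if info > 0 else np.sign(grad)
        # step-halving to keep the likelihood increasing
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik_grad_info(
                new_beta, x_d, risk_end, d, sx
            )
            if new_ll >= loglik - 1e-12:
                break
            step /= 2.0
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        # a standardized log-hazard-ratio this large means the partial
        # likelihood is monotone (separation): the MLE does not exist
        if abs(beta) > 8:
            diverged = True
    converged = abs(grad) < tol and not diverged

    beta = beta / scale  # back to the input covariate scale
    info = info * scale**2
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    with np.errstate(over="ignore"):
        hr_, lo_, hi_ = np.exp([beta, beta - half, beta + half])
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(hr_),
        ci95_low=float(lo_),
        ci95_high=float(hi_),
        p=p,
        converged=converged,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def cox_partial_loglik(X, durations, events, beta) -> float:
    """Multivariate Cox partial log-likelihood (Breslow ties) at ``beta``.

    Evaluation only — used for cross-validated deviance when choosing a
    penalty, not for fitting.
    """
    t, e = _as_survival_arrays(durations, events)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    order = np.argsort(-t, kind="stable")
    t_d, eta_d = t[order], eta[order]
    event_times = np.unique(t[e == 1])[::-1]
    risk_end = np.searchsorted(-t_d, -event_times, "right")
    log_s0 = np.log(np.cumsum(np.exp(eta_d)))[risk_end - 1]
    d = np.array([np.sum((t == u) & (e == 1)) for u in event_times], dtype=float)
    s_eta = np.array([np.sum(eta[(t == u) & (e == 1)]) for u in event_times])
    return float(np.sum(s_eta - d * log_s0))


@dataclass(frozen=True)
class CutoffScan:
    """Result of the minimum-p log-rank cutoff search."""

    scan: pd.DataFrame  # columns: cutoff, n_low, n_high, statistic, p
    optimal_cutoff: float
    min_p: float

    @property
    def n_candidates(self) -> int:
        return len(self.scan)


def optimal_cutoff(
    scores, durations, events, min_group_fraction: float = 0.1
) -> CutoffScan:
    """Scan dichotomization cutoffs and return the one with minimal log-rank p.

    Candidates are midpoints between consecutive distinct observed scores,
    restricted so that each side of the split retains at least
    ``min_group_fraction`` of the samples.  Ties in p go to the smaller
    cutoff.  The full scan table is retained for plotting.  No
    multiple-testing correction is applied: the reported minimum p is
    optimistic, as is standard for minimum-p cutpoint selection.
    """
    s = np.asarray(scores, dtype=float)
    t, e = _as_survival_arrays(durations, events)
    if s.shape != t.shape:
        raise ValueError("scores must align with survival records")
    if not (0 < min_group_fraction <= 0.5):
        raise ValueError("min_group_fraction must be in (0, 0.5]")
    distinct = np.unique(s)
    if distinct.size < 2:
        raise ValueError("cutoff search requires at least two distinct scores")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = s.size
    rows = []
    for c in candidates:
        high = s > c
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_low, n_high) < min_group_fraction * n:
            continue
        try:
            res = logrank_test(t[~high], e[~high], t[high], e[high])
        except ValueError:
            continue
        rows.append((float(c), n_low, n_high, res.statistic, res.p))
    if not rows:
        raise ValueError("no candidate cutoff satisfies the group-size constraint")
    scan = pd.DataFrame(rows, columns=["cutoff", "n_low", "n_high", "statistic", "p"])
    best = int(np.argmin(scan["p"].to_numpy()))  # first minimum -> smaller cutoff
    return CutoffScan(
        scan=scan,
        optimal_cutoff=float(scan.loc[best, "cutoff"]),
        min_p=float(scan.loc[best, "p"]),
    )


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with columns ``sample time event``."""
    table = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in ("sample", "time", "event") if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table
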