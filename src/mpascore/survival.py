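"""Cox models, Kaplan-Meier estimation and hazard-ratio scans over score cutoffs.

The Cox partial likelihood is maximized by Newton-Raphson with the Breslow
convention for tied event times; with Breslow ties, duplicating every record
leaves the coefficient unchanged, which makes scan results stable under
replicated inputs.  Confidence intervals and per-term p-values are Wald-type
(exp(beta +- 1.96 se)); a log-rank p-value is additionally reported for
dichotomous terms.

Two scans summarize how the hazard ratio depends on where a continuous score
is cut: the threshold scan dichotomizes at each percentile from the 10th to
the 90th, and the sliding-window scan compares a moving percentile window
(default width 30, step 2, so window centers run from 15 to 85) against the
rest of the cohort or, after an algebraic change of reference, against the
cohort as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .expression import ClinicalTable
from .evaluate import median_classify

__all__ = [
    "CoxFit",
    "KMEstimate",
    "KMScanResult",
    "km_estimate",
    "cox_fit",
    "median_dichotomize",
    "km_threshold_scan",
    "sliding_window_scan",
    "binomial_death_test",
    "multivariate_survival_report",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood maximization fails (e.g. separation)."""


@dataclass(frozen=True)
class CoxFit:
    """Result of a proportional-hazards fit (Breslow ties, Wald inference)."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool = True
    logrank_p: dict[str, float] = field(default_factory=dict)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - Z_95 * self.se)
        hi = np.exp(self.beta + Z_95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "beta": self.beta,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p,
                "logrank_p": [self.logrank_p.get(t, np.nan) for t in self.terms],
            }
        )


# ---------------------------------------------------------------------------
# Breslow partial likelihood
# ---------------------------------------------------------------------------

def _breslow_ll(beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood, gradient and Hessian under Breslow ties.

    ``x`` is (n, p).  Records are processed in decreasing time order so the
    risk set at each event time is a prefix; tied times share the prefix
    running through the whole tie group.
    """
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]
    eta = xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)

    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w[:, None] * xs, axis=0)
    xouter = np.einsum("ni,nj->nij", xs, xs)
    cum2 = np.cumsum(w[:, None, None] * xouter, axis=0)

    # last index of each tie group (prefix sums must include all tied records)
    n = len(ts)
    last = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        last[i : j + 1] = j
        i = j + 1

    ev = es == 1
    li = last[ev]
    d0 = cum0[li]
    ll = float(np.sum(eta[ev]) - np.sum(np.log(d0) + shift))
    m1 = cum1[li] / d0[:, None]
    grad = xs[ev].sum(axis=0) - m1.sum(axis=0)
    m2 = cum2[li] / d0[:, None, None]
    hess = -(m2 - np.einsum("ni,nj->nij", m1, m1)).sum(axis=0)
    return ll, grad, hess


def _newton_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 60, tol: float = 1e-9):
    beta = np.zeros(x.shape[1])
    # separation guard on the scale-free effect size |beta_j| * sd(x_j):
    # 20 log-hazard units per covariate sd only arises from a monotone likelihood
    sd = x.std(axis=0)
    ll, grad, hess = _breslow_ll(beta, x, time, event)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            return beta, hess, ll, False
        new_beta = beta + step
        new_ll, new_grad, new_hess = _breslow_ll(new_beta, x, time, event)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _breslow_ll(new_beta, x, time, event)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta) * sd) > 20:
            return beta, hess, ll, False
    converged = bool(np.max(np.abs(grad)) < 1e-6 and np.max(np.abs(beta) * sd) <= 20)
    return beta, hess, ll, converged


def _check_design(x: np.ndarray, terms: Sequence[str]) -> None:
    sds = x.std(axis=0)
    for t, s in zip(terms, sds):
        if s == 0:
            raise ValueError(f"constant covariate {t!r}")
    if x.shape[1] > 1:
        xc = (x - x.mean(axis=0)) / sds
        corr = xc.T @ xc / len(x)
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                if abs(corr[i, j]) > 1.0 - 1e-10:
                    raise ValueError(f"collinear covariates: {terms[i]!r} and {terms[j]!r}")
        if np.linalg.matrix_rank(xc) < x.shape[1]:
            raise ValueError(f"collinear covariate set: {tuple(terms)}")


def _fit_arrays(time: np.ndarray, event: np.ndarray, x: np.ndarray,
                terms: Sequence[str], logrank: bool = True) -> CoxFit:
    if event.sum() < 2:
        raise ValueError("Cox fit requires >= 2 events")
    if not np.isfinite(x).all():
        raise ValueError("covariates must be finite")
    _check_design(x, terms)
    beta, hess, ll, converged = _newton_cox(x, time, event)
    if converged:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(x.shape[1], np.nan)
    lr: dict[str, float] = {}
    if logrank and converged:
        for k, t in enumerate(terms):
            vals = np.unique(x[:, k])
            if len(vals) == 2:
                mask = x[:, k] == vals[1]
                res = logrank_test(time[mask], time[~mask], event[mask], event[~mask])
                lr[t] = float(res.p_value)
    return CoxFit(
        terms=tuple(terms), beta=beta, se=se, loglik=ll,
        n=len(time), n_events=int(event.sum()), converged=converged, logrank_p=lr,
    )


def cox_fit(tbl: ClinicalTable, terms: Sequence[str]) -> CoxFit:
    """Proportional-hazards fit of the named covariates (Breslow ties).

    Raises on constant or collinear covariates and flags non-convergence
    (e.g. monotone likelihood under perfect separation) instead of reporting
    meaningless standard errors.
    """
    if isinstance(terms, str):
        terms = [terms]
    x = np.column_stack([np.asarray(tbl.covariate(t), dtype=float) for t in terms])
    return _fit_arrays(tbl.time, tbl.event, x, terms)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve with the median survival time."""

    survival: pd.Series  # S(t) at the observed times, step function
    median: float | None

    def at(self, t: float) -> float:
        s = self.survival[self.survival.index <= t]
        return float(s.iloc[-1]) if len(s) else 1.0


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate; median is the first t with S(t) <= 0.5."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if len(t) == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    surv = kmf.survival_function_.iloc[:, 0]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(survival=surv, median=median)


def median_dichotomize(scores: Sequence[float]) -> np.ndarray:
    """High/low labels at the cohort median (strictly above = high, ties low)."""
    return median_classify(np.asarray(scores, dtype=float), "high_is_positive")


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMScanResult:
    """Hazard ratios along a grid of score cutoffs or windows."""

    mode: str  # "threshold" or "window"
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _indicator_fit_row(time, event, indicator) -> dict | None:
    n_in = int(indicator.sum())
    ev_in = int(event[indicator].sum())
    ev_out = int(event[~indicator].sum())
    if n_in == 0 or n_in == len(indicator) or ev_in < 2 or ev_out < 2:
        return None
    fit = _fit_arrays(time, event, indicator.astype(float)[:, None], ["group"], logrank=False)
    if not fit.converged:
        return None
    ci = fit.ci95[0]
    return {
        "hr": float(fit.hr[0]), "ci_low": float(ci[0]), "ci_high": float(ci[1]),
        "p": float(fit.p[0]), "n_in": n_in, "n_events_in": ev_in,
    }


def km_threshold_scan(
    tbl: ClinicalTable,
    scores: Sequence[float],
    lo_pct: float = 10,
    hi_pct: float = 90,
    step_pct: float = 5,
) -> KMScanResult:
    """HR(high vs low) as the dichotomization threshold moves across percentiles.

    The grid runs inclusively from ``lo_pct`` to ``hi_pct``; at each position
    the cohort is split at that score percentile (strictly above = high) and
    a univariate Cox fit of the indicator gives the HR.  Positions where
    either side has fewer than 2 events are reported as nulls.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) != len(tbl):
        raise ValueError("scores and clinical table differ in length")
    grid = np.arange(lo_pct, hi_pct + step_pct / 2.0, step_pct)
    rows = []
    for q in grid:
        thr = np.percentile(s, q)
        high = s > thr
        res = _indicator_fit_row(tbl.time, tbl.event, high)
        row = {"position_pct": float(q)}
        if res is None:
            row.update({"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                        "n_high": int(high.sum()), "n_low": int((~high).sum()),
                        "n_events_high": int(tbl.event[high].sum())})
        else:
            row.update({"hr": res["hr"], "ci_low": res["ci_low"], "ci_high": res["ci_high"],
                        "p": res["p"], "n_high": res["n_in"],
                        "n_low": len(s) - res["n_in"], "n_events_high": res["n_events_in"]})
        rows.append(row)
    return KMScanResult(mode="threshold", table=pd.DataFrame(rows))


def sliding_window_scan(
    tbl: ClinicalTable,
    scores: Sequence[float],
    window_pct: float = 30,
    step_pct: float = 2,
    comparator: str = "population",
) -> KMScanResult:
    """HR of a sliding percentile window of the score against the cohort.

    Windows ``[q, q + window_pct]`` advance by ``step_pct`` from 0 until the
    window reaches 100, reported at their median position (defaults: centers
    15, 17, ..., 85).  The membership indicator is fitted over all records;
    ``comparator="remainder"`` reports that HR directly (window vs everyone
    outside it), while the default ``"population"`` re-references it to the
    cohort-average hazard via h_pop = h / (f h + 1 - f) with f the window
    fraction, applied to the HR and its CI endpoints.
    """
    if comparator not in ("population", "remainder"):
        raise ValueError("comparator must be 'population' or 'remainder'")
    if window_pct <= 0 or window_pct >= 100:
        raise ValueError("window_pct must be in (0, 100)")
    if window_pct + step_pct > 100:
        raise ValueError("window_pct + step_pct must not exceed 100")
    s = np.asarray(scores, dtype=float)
    if len(s) != len(tbl):
        raise ValueError("scores and clinical table differ in length")

    starts = np.arange(0.0, 100.0 - window_pct + step_pct / 2.0, step_pct)
    rows = []
    for q in starts:
        lo = np.percentile(s, q)
        hi = np.percentile(s, q + window_pct)
        member = (s >= lo) & (s <= hi) if q == 0 else (s > lo) & (s <= hi)
        res = _indicator_fit_row(tbl.time, tbl.event, member)
        row = {"position_pct": float(q + window_pct / 2.0),
               "window_lo_pct": float(q), "window_hi_pct": float(q + window_pct)}
        if res is None:
            row.update({"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                        "n_in": int(member.sum()),
                        "n_events_in": int(tbl.event[member].sum())})
        else:
            f = res["n_in"] / len(s)
            vals = {k: res[k] for k in ("hr", "ci_low", "ci_high")}
            if comparator == "population":
                vals = {k: v / (f * v + (1.0 - f)) for k, v in vals.items()}
            row.update({**vals, "p": res["p"], "n_in": res["n_in"],
                        "n_events_in": res["n_events_in"]})
        rows.append(row)
    return KMScanResult(mode="window", table=pd.DataFrame(rows))


def binomial_death_test(tbl: ClinicalTable, groups: Sequence[bool]) -> float:
    """Exact two-sided binomial test of the death share in the high group.

    Tests k = deaths among high-group members out of K total deaths against
    the null proportion p0 = (high-group size) / (cohort size).
    """
    g = np.asarray(groups, dtype=bool)
    if len(g) != len(tbl):
        raise ValueError("groups and clinical table differ in length")
    deaths = tbl.event == 1
    K = int(deaths.sum())
    if K == 0:
        raise ValueError("no deaths: binomial test undefined")
    k = int((deaths & g).sum())
    p0 = g.sum() / len(g)
    return float(stats.binomtest(k, K, p0, alternative="two-sided").pvalue)


def multivariate_survival_report(tbl: ClinicalTable, terms: Sequence[str]) -> CoxFit:
    """Joint Cox fit of a score plus clinical covariates.

    String/categorical covariates are expanded into indicator terms
    (first level as reference); collinear terms raise with the offending
    pair named.
    """
    cols = []
    names: list[str] = []
    for t in terms:
        v = tbl.data[t]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, prefix=t, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(t)
    x = np.column_stack(cols)
    return _fit_arrays(tbl.time, tbl.event, x, names)
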