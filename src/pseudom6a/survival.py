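"""Univariate Cox proportional-hazards screening, risk/protective
classification, Kaplan-Meier curves and log-rank tests.

The single-covariate Cox fit maximizes the Efron-corrected partial
likelihood by damped Newton iteration; the scalar score and information are
written out explicitly, which keeps the solver transparent and lets tests
compare it against a grid-search maximizer of the same likelihood and
against an independent library fit.  By default the covariate is z-scored
before fitting, so beta is a log hazard ratio per standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


class NonIdentifiableError(ValueError):
    """Constant covariate: the partial likelihood carries no information."""


@dataclass
class CoxResult:
    gene_id: str
    beta: float
    hr: float
    se: float
    p_value: float
    classification: str = "not significant"
    separation: bool = False
    n_events: int = 0


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: int
    value: float

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _as_arrays(records) -> tuple:
    if isinstance(records, pd.DataFrame):
        t = records["time"].to_numpy(dtype=float)
        d = records["event"].to_numpy(dtype=int)
        x = records["value"].to_numpy(dtype=float)
    else:
        t = np.array([r.time for r in records], dtype=float)
        d = np.array([r.event for r in records], dtype=int)
        x = np.array([r.value for r in records], dtype=float)
    return t, d, x


def efron_loglik(beta: float, time: np.ndarray, event: np.ndarray,
                 x: np.ndarray) -> float:
    """Efron-corrected log partial likelihood for one covariate."""
    ll, _, _ = _efron_derivatives(beta, time, event, x)
    return ll


def _efron_derivatives(beta, time, event, x):
    order = np.argsort(time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    theta = np.exp(beta * xv)
    n = len(t)
    # suffix sums over the risk set (all with time >= t_i)
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum((theta * xv)[::-1])[::-1]
    s2 = np.cumsum((theta * xv * xv)[::-1])[::-1]
    ll = grad = info = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(d[i:j]) + i
        m = len(ev)
        if m:
            td = theta[ev]
            xd = xv[ev]
            D0, D1, D2 = td.sum(), (td * xd).sum(), (td * xd * xd).sum()
            ll += float(beta * xd.sum())
            grad += float(xd.sum())
            for l in range(m):
                f = l / m
                r0 = s0[i] - f * D0
                r1 = s1[i] - f * D1
                r2 = s2[i] - f * D2
                ll -= float(np.log(r0))
                mean_x = r1 / r0
                grad -= float(mean_x)
                info += float(r2 / r0 - mean_x**2)
        i = j
    return float(ll), float(grad), float(info)


def cox_univariate(records, gene_id: str = "", standardize: bool = True,
                   tol: float = 1e-8, max_iter: int = 50,
                   beta_cap: float = 10.0) -> CoxResult:
    """Single-covariate Cox fit (Efron ties, damped Newton, Wald p).

    Raises NonIdentifiableError for a constant covariate.  A monotone
    likelihood (perfect separation) is flagged and beta capped at
    +/- ``beta_cap``.
    """
    import warnings

    time, event, x = _as_arrays(records)
    if event.sum() < 2:
        raise ValueError("need >= 2 events")
    if np.ptp(x) == 0:
        raise NonIdentifiableError(f"{gene_id or 'covariate'} is constant")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=0)

    beta = 0.0
    ll, grad, info = _efron_derivatives(beta, time, event, x)
    converged = False
    separation = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = grad / info
        # dampen: halve until the log-likelihood does not decrease
        new_beta = beta + step
        for _ in range(30):
            new_ll, new_grad, new_info = _efron_derivatives(new_beta, time, event, x)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        if abs(new_beta) > beta_cap:
            separation = True
            beta = float(np.sign(new_beta) * beta_cap)
            ll, grad, info = _efron_derivatives(beta, time, event, x)
            warnings.warn(
                f"{gene_id or 'covariate'}: monotone likelihood, "
                f"beta capped at {beta}", stacklevel=2)
            break
        delta = abs(new_beta - beta)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if delta < tol:
            converged = True
            break
    se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(gene_id, float(beta), float(np.exp(beta)), float(se), p,
                     separation=separation, n_events=int(event.sum()))


def classify_prognostic(result: CoxResult, alpha: float = 0.05) -> str:
    """risk iff HR > 1 and p < alpha; protective iff HR < 1 and p < alpha."""
    if result.p_value < alpha and result.hr > 1.0:
        cls = "risk"
    elif result.p_value < alpha and result.hr < 1.0:
        cls = "protective"
    else:
        cls = "not significant"
    result.classification = cls
    return cls


def cox_screen(expression_logcpm: pd.DataFrame, survival: pd.DataFrame,
               alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene univariate Cox screen over a cohort.

    ``expression_logcpm``: genes x samples; ``survival``: sample_id, time,
    event.  Genes with a constant covariate are reported as not significant
    with NaN beta.
    """
    surv = survival.set_index("sample_id")
    cols = [s for s in expression_logcpm.columns if s in surv.index]
    t = surv.loc[cols, "time"].to_numpy()
    d = surv.loc[cols, "event"].to_numpy()
    rows = []
    for gene_id in expression_logcpm.index:
        x = expression_logcpm.loc[gene_id, cols].to_numpy(dtype=float)
        try:
            res = cox_univariate(
                pd.DataFrame({"time": t, "event": d, "value": x}),
                gene_id=gene_id,
            )
            classify_prognostic(res, alpha)
        except (NonIdentifiableError, ValueError):
            res = CoxResult(gene_id, float("nan"), float("nan"), float("nan"),
                            1.0, "not significant")
        rows.append(
            {"gene_id": gene_id, "beta": res.beta, "hr": res.hr, "se": res.se,
             "p_value": res.p_value, "classification": res.classification}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank

def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate: one row per distinct event time."""
    order = np.argsort(time, kind="stable")
    t, d = np.asarray(time, float)[order], np.asarray(event, int)[order]
    out = []
    surv = 1.0
    at_risk = len(t)
    i = 0
    while i < len(t):
        j = i
        while j < len(t) and t[j] == t[i]:
            j += 1
        deaths = int(d[i:j].sum())
        if deaths:
            surv *= 1.0 - deaths / at_risk
            out.append({"time": float(t[i]), "n_at_risk": at_risk,
                        "n_events": deaths, "survival": surv})
        at_risk -= j - i
        i = j
    return pd.DataFrame(out, columns=["time", "n_at_risk", "n_events", "survival"])


def km_logrank(records, split: str = "median") -> dict:
    """Median (or mean) split of the covariate into high/low groups, KM
    curves per group and the two-group log-rank test.

    Uses the standard expected-events chi-square; the statistic is invariant
    to swapping group labels.
    """
    time, event, x = _as_arrays(records)
    cut = np.median(x) if split == "median" else np.mean(x)
    high = x > cut
    if high.all() or (~high).all():
        raise ValueError("split produced an empty group")
    groups = {"high": high, "low": ~high}
    curves = {name: km_curve(time[mask], event[mask])
              for name, mask in groups.items()}
    # log-rank via lifelines (oracle-checked against a hand computation)
    from lifelines.statistics import logrank_test

    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    return {
        "curves": curves,
        "chi2": float(lr.test_statistic),
        "p_value": float(lr.p_value),
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }
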