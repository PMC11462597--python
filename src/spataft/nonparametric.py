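"""Nonparametric preliminaries: Kaplan-Meier curves, log-rank comparison,
Cox proportional-hazards fit with the global Schoenfeld test, and
descriptive mortality tables.

These are the screening analyses run before the parametric spatial model:
KM/log-rank to display and test group survival differences, and the global
Schoenfeld residual test whose rejection of proportional hazards motivates
the accelerated failure time formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "CoxFit",
    "cox_ph_fit",
    "schoenfeld_global_test",
    "mortality_table",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # distinct times with >= 1 death
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    deaths: np.ndarray

    @property
    def failure(self) -> np.ndarray:
        """Cumulative failure 1 - S, the form often plotted for mortality."""
        return 1.0 - self.survival

    def evaluate(self, t: float) -> float:
        """S(t) with S = 1 before the first death."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def median(self) -> float:
        """Smallest event time with S <= 0.5 (inf if never reached)."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.event_times[below[0]]) if below.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
            }
        )


def _validate_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(np.int64)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Tie convention: deaths precede censorings at equal times, i.e. a
    subject censored at t is still in the risk set of deaths at t.
    """
    times, events = _validate_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    uniq = np.unique(t[d == 1])
    n = t.size
    at_risk = np.empty(uniq.size, dtype=np.int64)
    deaths = np.empty(uniq.size, dtype=np.int64)
    for k, u in enumerate(uniq):
        at_risk[k] = int((t >= u).sum())
        deaths[k] = int(((t == u) & (d == 1)).sum())
    surv = np.cumprod(1.0 - deaths / at_risk) if uniq.size else np.empty(0)
    return KMCurve(event_times=uniq, survival=surv, at_risk=at_risk, deaths=deaths)


def logrank_test(times, events, group_labels) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi-square, df, p).

    Observed-minus-expected deaths per group accumulated over event times,
    with the hypergeometric covariance of the per-time death split.
    """
    times, events = _validate_surv(times, events)
    groups = np.asarray(group_labels)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    gidx = np.searchsorted(labels, groups)

    event_times = np.unique(times[events == 1])
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = times >= u
        n_t = int(at_risk.sum())
        d_t = int(((times == u) & (events == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(times == u) & (events == 1)], minlength=k).astype(float)
        p = n_g / n_t
        OmE += d_g - d_t * p
        if n_t > 1:
            mult = d_t * (n_t - d_t) / (n_t - 1)
            V += mult * (np.diag(p) - np.outer(p, p))
    # drop last group: covariance of the free k-1 components
    z = OmE[:-1]
    Vm = V[:-1, :-1]
    stat = float(z @ np.linalg.pinv(Vm) @ z)
    df = k - 1
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class CoxFit:
    """Newton-Raphson maximum of the Breslow partial likelihood."""

    coef: np.ndarray
    loglik: float
    information: np.ndarray  # observed information at the maximum
    schoenfeld: np.ndarray  # one row per death, columns = covariates
    schoenfeld_times: np.ndarray
    n_events: int
    separation_flag: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(np.linalg.inv(self.information)))


def _cox_quantities(beta, t, d, X):
    """Breslow log partial likelihood, gradient, information and per-death
    risk-set means, computed by suffix sums over descending time order."""
    n, p = X.shape
    order = np.argsort(-t, kind="stable")
    ts, ds, Xs = t[order], d[order], X[order]
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    logshift = eta.max()
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    # risk set of time t = all with time >= t = prefix in descending order;
    # tied times share the risk set closed at the last equal element
    last_eq = np.searchsorted(-ts, -ts, side="right") - 1
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    means = []
    mean_times = []
    for i in np.flatnonzero(ds == 1):
        j = last_eq[i]
        s0, s1, s2 = S0[j], S1[j], S2[j]
        xbar = s1 / s0
        ll += eta[i] - (np.log(s0) + logshift)
        grad += Xs[i] - xbar
        info += s2 / s0 - np.outer(xbar, xbar)
        means.append(xbar)
        mean_times.append(ts[i])
        # schoenfeld residual for this death is Xs[i] - xbar
    resid = np.array([Xs[i] - m for i, m in zip(np.flatnonzero(ds == 1), means)])
    return ll, grad, info, resid, np.array(mean_times)


def cox_ph_fit(times, events, design, *, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Fit the Cox model by Newton-Raphson on the Breslow partial likelihood.

    ``design`` may have zero columns (null model): the fit then just
    reports the null log partial likelihood.  Monotone likelihood
    (separation) is flagged when coefficients diverge.
    """
    times, events = _validate_surv(times, events)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != times.size:
        X = X.T
    n, p = X.shape
    if p and np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(p)
    ll, grad, info, resid, rtimes = _cox_quantities(beta, times, events, X)
    if p == 0:
        return CoxFit(beta, float(ll), info, resid, rtimes, int(events.sum()))
    separation = False
    for _ in range(max_iter):
        step = np.linalg.solve(info, grad)
        # step-halving to guarantee ascent
        for half in range(30):
            cand = beta + step / (2**half)
            ll_new = _cox_quantities(cand, times, events, X)[0]
            if ll_new >= ll - 1e-12:
                break
        beta, ll_prev = cand, ll
        ll, grad, info, resid, rtimes = _cox_quantities(beta, times, events, X)
        if np.abs(grad).max() < tol:
            break
        if np.abs(beta).max() > 20:
            separation = True
            warnings.warn("possible monotone likelihood (separation)", stacklevel=2)
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})"
        )
    return CoxFit(beta, float(ll), info, resid, rtimes, int(events.sum()), separation)


def schoenfeld_global_test(
    fit: CoxFit, *, transform: str = "identity"
) -> tuple[float, float]:
    """Global proportional-hazards score test on the Schoenfeld residuals.

    Tests zero correlation between the residuals and (transformed) event
    time across all covariates jointly; chi-square on p degrees of freedom.
    Transforms: "identity" (default), "log", "rank".
    """
    if fit.coef.size == 0:
        raise ValueError("global PH test needs at least one covariate")
    d = fit.n_events
    if d < 2:
        raise ValueError("too few events for the PH test")
    if transform == "identity":
        g = fit.schoenfeld_times.astype(float)
    elif transform == "log":
        g = np.log(fit.schoenfeld_times)
    elif transform == "rank":
        g = stats.rankdata(fit.schoenfeld_times)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    z = gc @ fit.schoenfeld  # p-vector
    denom = float(gc @ gc)
    stat = float(d * z @ np.linalg.solve(fit.information, z) / denom)
    p = float(stats.chi2.sf(stat, fit.coef.size))
    return stat, p


def _pct(x: float) -> float:
    """Round half-up to 2 decimals (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FactorMortalitySummary:
    """Per-level alive/died counts with row percentages and the Pearson
    chi-square test of association between the factor and mortality."""

    factor: str
    table: pd.DataFrame  # index = levels; columns alive, died, alive_pct, died_pct
    chi2: float | None
    df: int | None
    p_value: float | None


def mortality_table(cohort, factor: str) -> FactorMortalitySummary:
    """Mortality distribution by one baseline characteristic.

    Rows are factor levels with alive/died counts and row percentages
    (rounded half-up to 2 decimals); the chi-square is Pearson's without
    continuity correction.  Pass factor="overall" for the whole-cohort row.
    Empty levels are omitted.
    """
    events = cohort.events
    if factor == "overall":
        values = np.array(["Overall"] * len(cohort))
    else:
        raw = cohort.covariate(factor)
        if all(v is None for v in raw):
            raise KeyError(f"factor {factor!r} not present in cohort")
        values = np.array([v if v is not None else "not_stated" for v in raw])
    levels = pd.unique(values)
    rows = {}
    for lvl in levels:
        mask = values == lvl
        died = int(events[mask].sum())
        alive = int(mask.sum()) - died
        tot = alive + died
        rows[lvl] = {
            "alive": alive,
            "died": died,
            "alive_pct": _pct(100.0 * alive / tot),
            "died_pct": _pct(100.0 * died / tot),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    chi2 = df = p = None
    if len(levels) >= 2:
        counts = table[["alive", "died"]].to_numpy()
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
            chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
            chi2, p, df = float(chi2), float(p), int(df)
    else:
        warnings.warn(
            f"factor {factor!r} has a single level; chi-square omitted", stacklevel=2
        )
    return FactorMortalitySummary(factor=factor, table=table, chi2=chi2, df=df, p_value=p)
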