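"""Model comparison criteria and goodness of fit for the fitted AFT models.

DIC, WAIC and LPML are computed from the stored posterior draws; smaller
DIC/WAIC and larger LPML indicate a better model.  Frailties are treated
as parameters (conditional criteria), the convention for frailty survival
models.  Cox-Snell residuals r = -log S(t | fitted) check calibration:
under a correct model the uncensored residuals are unit exponential, so
their Nelson-Aalen cumulative hazard against the residuals is a line of
slope one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .aft_model import AFTModelSpec, SpatialFrailty, build_region_index, log_survival
from .mcmc import MCMCConfig, PosteriorChains, Priors, _pointwise_ll
from .mcmc import fit as mcmc_fit

logger = logging.getLogger(__name__)

__all__ = [
    "pointwise_loglik_matrix",
    "dic",
    "waic",
    "lpml",
    "ComparisonRow",
    "compare_models",
    "cox_snell",
]


def pointwise_loglik_matrix(chains: PosteriorChains, cohort, graph=None) -> np.ndarray:
    """(S, n) matrix of per-draw, per-record censored log-likelihoods."""
    X = cohort.design if cohort.design is not None else np.empty((len(cohort), 0))
    logt = np.log(cohort.times)
    events = cohort.events
    region_index = None
    if chains.spatial:
        if graph is None:
            raise ValueError("spatial chains need the adjacency graph")
        region_index = build_region_index(cohort, graph)
    S = chains.n_stored
    out = np.empty((S, len(cohort)))
    for s in range(S):
        eta = chains.mu[s] + (X @ chains.beta[s] if X.shape[1] else 0.0)
        if chains.spatial:
            eta = eta + chains.W[s][region_index]
        out[s] = _pointwise_ll(chains.family, logt, events, eta, float(chains.rho[s]))
    return out


def _plugin_loglik(chains: PosteriorChains, cohort, graph=None) -> float:
    """Log-likelihood at the posterior means of (mu, beta, log rho, W)."""
    X = cohort.design if cohort.design is not None else np.empty((len(cohort), 0))
    eta = chains.mu.mean() + (X @ chains.beta.mean(axis=0) if X.shape[1] else 0.0)
    if chains.spatial:
        region_index = build_region_index(cohort, graph)
        eta = eta + chains.W.mean(axis=0)[region_index]
    rho_hat = float(np.exp(chains.log_rho.mean()))
    ll = _pointwise_ll(chains.family, np.log(cohort.times), cohort.events, eta, rho_hat)
    return float(ll.sum())


def dic(
    chains: PosteriorChains, cohort, graph=None, *, ll_matrix: np.ndarray | None = None
) -> tuple[float, float]:
    """Deviance information criterion: DIC = mean deviance + p_D, with
    p_D = mean deviance - deviance at the posterior means."""
    if ll_matrix is None:
        ll_matrix = pointwise_loglik_matrix(chains, cohort, graph)
    dev_draws = -2.0 * ll_matrix.sum(axis=1)
    bad = np.flatnonzero(~np.isfinite(dev_draws))
    if bad.size:
        raise FloatingPointError(f"non-finite deviance at draw indices {bad[:10].tolist()}")
    dev_bar = float(dev_draws.mean())
    dev_hat = -2.0 * _plugin_loglik(chains, cohort, graph)
    p_d = dev_bar - dev_hat
    return dev_bar + p_d, p_d


def waic(
    chains: PosteriorChains, cohort, graph=None, *, ll_matrix: np.ndarray | None = None
) -> tuple[float, float]:
    """Widely applicable information criterion: -2(lppd - p_WAIC), with
    lppd from per-record log-mean-exp and p_WAIC the per-record posterior
    variance of the log-likelihood."""
    if ll_matrix is None:
        ll_matrix = pointwise_loglik_matrix(chains, cohort, graph)
    if not np.isfinite(ll_matrix).all():
        raise FloatingPointError("non-finite pointwise log-likelihoods")
    S = ll_matrix.shape[0]
    lppd = float((special.logsumexp(ll_matrix, axis=0) - np.log(S)).sum())
    p_waic = float(ll_matrix.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), p_waic


def lpml(
    chains: PosteriorChains, cohort, graph=None, *, ll_matrix: np.ndarray | None = None
) -> float:
    """Log pseudo marginal likelihood: sum of log conditional predictive
    ordinates, CPO_i = harmonic mean of the per-draw likelihoods, computed
    in log space as -logmeanexp(-ll)."""
    if ll_matrix is None:
        ll_matrix = pointwise_loglik_matrix(chains, cohort, graph)
    S = ll_matrix.shape[0]
    log_cpo = -(special.logsumexp(-ll_matrix, axis=0) - np.log(S))
    if not np.isfinite(log_cpo).all():
        raise FloatingPointError("non-finite CPO after stabilization")
    return float(log_cpo.sum())


@dataclass
class ComparisonRow:
    label: str
    family: str
    spatial: bool
    dic: float
    p_d: float
    waic: float
    p_waic: float
    lpml: float
    error: str | None = None


def compare_models(
    cohort,
    graph,
    candidates: list[dict],
    *,
    config: MCMCConfig | None = None,
    priors: Priors | None = None,
) -> tuple[list[ComparisonRow], PosteriorChains | None]:
    """Fit each candidate model and rank by DIC (all criteria reported).

    ``candidates`` entries are {"label", "family", "spatial"}; all share
    the same seed policy via ``config.seed`` so differences reflect the
    models, not the random streams.  A failing fit is recorded in its row
    and the comparison continues.  Returns (rows sorted by DIC, chains of
    the best model).
    """
    if not candidates:
        raise ValueError("candidate grid is empty")
    rows: list[ComparisonRow] = []
    chains_by_label: dict[str, PosteriorChains] = {}
    for cand in candidates:
        label = cand.get("label") or f"{cand['family']}{'+spatial' if cand.get('spatial') else ''}"
        try:
            chains = mcmc_fit(
                cohort,
                graph if cand.get("spatial") else None,
                family=cand["family"],
                spatial=bool(cand.get("spatial")),
                priors=priors,
                config=config,
            )
            ll_m = pointwise_loglik_matrix(chains, cohort, graph if cand.get("spatial") else None)
            d, p_d = dic(chains, cohort, graph, ll_matrix=ll_m)
            w, p_w = waic(chains, cohort, graph, ll_matrix=ll_m)
            l = lpml(chains, cohort, graph, ll_matrix=ll_m)
            if p_d < 0 or p_w < 0:
                logger.warning("negative effective parameters in %s (p_D=%.2f)", label, p_d)
            rows.append(ComparisonRow(label, cand["family"], bool(cand.get("spatial")),
                                      d, p_d, w, p_w, l))
            chains_by_label[label] = chains
        except Exception as exc:  # keep comparing remaining candidates
            logger.warning("candidate %s failed: %s", label, exc)
            rows.append(ComparisonRow(label, cand.get("family", "?"),
                                      bool(cand.get("spatial")),
                                      float("nan"), float("nan"), float("nan"),
                                      float("nan"), float("nan"), error=str(exc)))
    ok = [r for r in rows if r.error is None]
    ok.sort(key=lambda r: r.dic)
    failed = [r for r in rows if r.error is not None]
    best = chains_by_label.get(ok[0].label) if ok else None
    return ok + failed, best


@dataclass
class CoxSnellResult:
    """Cox-Snell residuals with their Nelson-Aalen diagnostic series."""

    residuals: np.ndarray
    events: np.ndarray
    na_times: np.ndarray  # sorted uncensored+censored residuals at events
    na_cumhaz: np.ndarray  # Nelson-Aalen cumulative hazard of the residuals
    slope: float  # through-origin slope of cumhaz vs residual


def cox_snell(chains: PosteriorChains, cohort, graph=None) -> CoxSnellResult:
    """Cox-Snell residuals r = -log S(t | posterior-mean parameters).

    Censored survival times yield censored residuals.  The Nelson-Aalen
    cumulative hazard of the residuals plotted against the residuals
    should follow the 45-degree line when the model fits; the fitted
    through-origin least-squares slope summarises it.
    """
    X = cohort.design if cohort.design is not None else np.empty((len(cohort), 0))
    eta = chains.mu.mean() + (X @ chains.beta.mean(axis=0) if X.shape[1] else 0.0)
    if chains.spatial:
        region_index = build_region_index(cohort, graph)
        eta = eta + chains.W.mean(axis=0)[region_index]
    rho_hat = float(np.exp(chains.log_rho.mean()))
    r = -log_survival(cohort.times, chains.family, eta, rho_hat)
    d = cohort.events

    order = np.argsort(r, kind="stable")
    rs, ds = r[order], d[order]
    n = rs.size
    uniq = np.unique(rs[ds == 1])
    cumhaz = np.empty(uniq.size)
    h = 0.0
    for k, u in enumerate(uniq):
        at_risk = (rs >= u).sum()
        deaths = ((rs == u) & (ds == 1)).sum()
        h += deaths / at_risk
        cumhaz[k] = h
    # through-origin LS slope of cumhaz on residual at event residuals
    slope = float((uniq @ cumhaz) / (uniq @ uniq)) if uniq.size else float("nan")
    return CoxSnellResult(residuals=r, events=d, na_times=uniq, na_cumhaz=cumhaz, slope=slope)
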