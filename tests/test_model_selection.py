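import math

import numpy as np
import pytest
from scipy import stats

from spataft import MCMCConfig, compare_models, cox_snell, dic, lpml, waic
from spataft.mcmc import PosteriorChains, Priors

from conftest import make_cohort, scipy_oracle


def fake_chains(family="weibull", mu=None, log_rho=None, beta=None, W=None,
                tau2=None, region_ids=None, design_columns=()):
    S = len(mu)
    return PosteriorChains(
        family=family,
        design_columns=tuple(design_columns),
        mu=np.asarray(mu, dtype=float),
        beta=np.asarray(beta, dtype=float) if beta is not None else np.empty((S, 0)),
        log_rho=np.asarray(log_rho, dtype=float) if log_rho is not None else np.zeros(S),
        W=np.asarray(W, dtype=float) if W is not None else None,
        tau2=np.asarray(tau2, dtype=float) if tau2 is not None else None,
        region_ids=region_ids,
        acceptance={},
        config=MCMCConfig(burn_in=1, monitor=max(S, 1), thin=1),
    )


@pytest.fixture
def toy_cohort():
    return make_cohort([1.5, 3.0, 0.8, 6.0, 2.2], [1, 1, 0, 1, 0])


@pytest.fixture
def toy_draws():
    rng = np.random.default_rng(0)
    return fake_chains(
        family="weibull",
        mu=rng.normal(1.0, 0.2, 400),
        log_rho=rng.normal(0.0, 0.1, 400),
    )


class TestDic:
    def test_degenerate_posterior(self, toy_cohort):
        chains = fake_chains(mu=np.full(300, 1.2), log_rho=np.zeros(300))
        d, p_d = dic(chains, toy_cohort)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        dist = scipy_oracle("weibull", 1.2, 1.0)
        dev = -2 * sum(
            dist.logpdf(r.time) if r.event else dist.logsf(r.time)
            for r in toy_cohort.records
        )
        assert d == pytest.approx(dev, abs=1e-9)

    def test_two_pass_bruteforce_oracle(self, toy_cohort, toy_draws):
        d, p_d = dic(toy_draws, toy_cohort)
        devs = []
        for mu_s, lr_s in zip(toy_draws.mu, toy_draws.log_rho):
            dist = scipy_oracle("weibull", mu_s, math.exp(lr_s))
            devs.append(
                -2 * sum(
                    dist.logpdf(r.time) if r.event else dist.logsf(r.time)
                    for r in toy_cohort.records
                )
            )
        dev_bar = np.mean(devs)
        dist_hat = scipy_oracle(
            "weibull", toy_draws.mu.mean(), math.exp(toy_draws.log_rho.mean())
        )
        dev_hat = -2 * sum(
            dist_hat.logpdf(r.time) if r.event else dist_hat.logsf(r.time)
            for r in toy_cohort.records
        )
        assert p_d == pytest.approx(dev_bar - dev_hat, abs=1e-10)
        assert d == pytest.approx(dev_bar + (dev_bar - dev_hat), abs=1e-10)

    def test_irrelevant_covariate_raises_dic(self, grid_8x10):
        # null simulation: adding a pure-noise covariate should not be
        # rewarded by DIC in most seeds
        from spataft import FactorSpec, SimulationScenario, encode_design, simulate_cohort
        from spataft.mcmc import fit

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sc = SimulationScenario(
                graph=grid_8x10, n_per_region=np.array([6] * 80),
                beta=np.array([]), mu=2.0, rho=1.0, family="weibull",
                tau2=1e-6, seed=seed,
            )
            cohort, _ = simulate_cohort(sc)
            rng = np.random.default_rng(1000 + seed)
            noise = rng.integers(0, 2, len(cohort))
            cov_cohort = make_cohort(
                cohort.times, cohort.events,
                regions=cohort.region_ids,
                covariates={"junk": ["a" if z else "b" for z in noise]},
                factors=[FactorSpec("junk", ("b", "a"), "b")],
            )
            cfg = MCMCConfig(burn_in=500, monitor=2000, thin=1, seed=seed)
            ch0 = fit(cohort, None, family="weibull", config=cfg)
            ch1 = fit(cov_cohort, None, family="weibull", config=cfg)
            d0, _ = dic(ch0, cohort)
            d1, _ = dic(ch1, cov_cohort)
            wins += d1 > d0
        assert wins >= 7


class TestWaic:
    def test_identical_draws_zero_penalty(self, toy_cohort):
        chains = fake_chains(mu=np.full(200, 0.9), log_rho=np.zeros(200))
        w, p_w = waic(chains, toy_cohort)
        assert p_w == pytest.approx(0.0, abs=1e-12)

    def test_streaming_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        ll = rng.normal(-2.0, 0.6, size=(1000, 5))
        w, p_w = waic(None, None, ll_matrix=ll)
        lppd = 0.0
        p_pen = 0.0
        S = ll.shape[0]
        for i in range(5):
            col = ll[:, i]
            m = col.max()
            lppd += m + math.log(math.fsum(math.exp(v - m) for v in col) / S)
            mean = math.fsum(col) / S
            p_pen += math.fsum((v - mean) ** 2 for v in col) / (S - 1)
        assert w == pytest.approx(-2 * (lppd - p_pen), abs=1e-8)
        assert p_w == pytest.approx(p_pen, abs=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        ll = rng.normal(-1.0, 0.5, size=(300, 7))
        perm = rng.permutation(300)
        assert waic(None, None, ll_matrix=ll) == pytest.approx(
            waic(None, None, ll_matrix=ll[perm])
        )
        assert lpml(None, None, ll_matrix=ll) == pytest.approx(
            lpml(None, None, ll_matrix=ll[perm])
        )


class TestLpml:
    def test_identical_draws(self, toy_cohort):
        chains = fake_chains(mu=np.full(150, 1.1), log_rho=np.zeros(150))
        from spataft.model_selection import pointwise_loglik_matrix

        ll = pointwise_loglik_matrix(chains, toy_cohort)
        assert lpml(chains, toy_cohort) == pytest.approx(ll[0].sum(), abs=1e-9)

    def test_jensen_bound_vs_lppd(self):
        rng = np.random.default_rng(7)
        ll = rng.normal(-2.0, 1.0, size=(500, 9))
        from scipy.special import logsumexp

        lppd = (logsumexp(ll, axis=0) - np.log(500)).sum()
        assert lpml(None, None, ll_matrix=ll) <= lppd + 1e-12

    def test_conjugate_normal_loo_predictive(self):
        # lognormal family, rho pinned at 1, all events: y = log t with a
        # N(0, sigma0^2) prior on mu gives closed-form leave-one-out
        # predictive N(y_i; m_-i, 1 + v_-i), times the 1/t_i Jacobian
        t = np.array([1.2, 2.5, 0.7, 4.0])
        y = np.log(t)
        cohort = make_cohort(t, [1, 1, 1, 1])
        sigma0_sq = 100.0
        n = 4
        v = 1.0 / (n + 1.0 / sigma0_sq)
        m = v * y.sum()
        rng = np.random.default_rng(8)
        S = 40_000
        chains = fake_chains(
            family="lognormal", mu=rng.normal(m, np.sqrt(v), S), log_rho=np.zeros(S)
        )
        from spataft.model_selection import pointwise_loglik_matrix

        ll = pointwise_loglik_matrix(chains, cohort)
        log_cpo = np.empty(n)
        from scipy.special import logsumexp

        log_cpo = -(logsumexp(-ll, axis=0) - np.log(S))
        for i in range(n):
            v_i = 1.0 / ((n - 1) + 1.0 / sigma0_sq)
            m_i = v_i * (y.sum() - y[i])
            closed = stats.norm.logpdf(y[i], m_i, np.sqrt(1 + v_i)) - y[i]
            assert log_cpo[i] == pytest.approx(closed, abs=0.03)


class TestCompareModels:
    def test_single_candidate(self, small_spatial_cohort, grid_8x10):
        cohort, _, _ = small_spatial_cohort
        rows, best = compare_models(
            cohort, grid_8x10, [{"family": "weibull", "spatial": False}],
            config=MCMCConfig(burn_in=100, monitor=200, thin=1, seed=0),
        )
        assert len(rows) == 1
        assert rows[0].error is None
        assert np.isfinite(rows[0].dic)
        assert best is not None

    def test_failed_candidate_recorded(self, small_spatial_cohort, grid_8x10):
        cohort, _, _ = small_spatial_cohort
        rows, best = compare_models(
            cohort, grid_8x10,
            [{"family": "not-a-family", "spatial": False},
             {"family": "weibull", "spatial": False}],
            config=MCMCConfig(burn_in=100, monitor=200, thin=1, seed=0),
        )
        assert len(rows) == 2
        errors = [r for r in rows if r.error is not None]
        assert len(errors) == 1
        assert best is not None


class TestCoxSnell:
    def _simulate(self, family, rho, seed, n=1500, censor=None):
        from spataft import SimulationScenario, grid_queen_adjacency, simulate_cohort

        g = grid_queen_adjacency(5, 6)
        sc = SimulationScenario(
            graph=g, n_per_region=np.array([n // 30] * 30),
            beta=np.array([]), mu=2.0, rho=rho, family=family,
            tau2=1e-8, censor_fraction=censor, seed=seed,
        )
        cohort, _ = simulate_cohort(sc)
        return cohort

    def test_truth_chains_give_exponential_residuals(self):
        cohort = self._simulate("weibull", 0.8, seed=1)
        chains = fake_chains(mu=np.full(200, 2.0), log_rho=np.full(200, np.log(0.8)))
        res = cox_snell(chains, cohort)
        unc = res.residuals[res.events == 1]
        assert stats.kstest(unc, "expon").pvalue > 0.01
        assert 0.85 <= res.slope <= 1.15

    def test_censored_records_yield_censored_residuals(self):
        cohort = self._simulate("weibull", 0.8, seed=2, censor=0.35)
        chains = fake_chains(mu=np.full(100, 2.0), log_rho=np.full(100, np.log(0.8)))
        res = cox_snell(chains, cohort)
        assert (res.events == cohort.events).all()
        # Nelson-Aalen handles censoring: slope still near one
        assert 0.85 <= res.slope <= 1.15

    def test_misspecified_weibull_on_heavy_tailed_data(self):
        from spataft.mcmc import fit

        rejected = 0
        for seed in range(3):
            cohort = self._simulate("loglogistic", 1.5, seed=10 + seed, n=900)
            chains = fit(cohort, None, family="weibull",
                         config=MCMCConfig(burn_in=300, monitor=400, thin=1, seed=seed))
            res = cox_snell(chains, cohort)
            p = stats.kstest(res.residuals[res.events == 1], "expon").pvalue
            rejected += p < 0.01
        assert rejected >= 2
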