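# spataft

Bayesian spatial accelerated-failure-time (AFT) survival analysis for
small-area disease mapping — censored Weibull / log-normal / log-logistic
likelihoods with intrinsic-CAR region frailties, Metropolis-within-Gibbs
inference, DIC/WAIC/LPML model comparison, and the standard nonparametric
preliminaries (Kaplan-Meier, log-rank, Cox-Schoenfeld proportional-hazards
check, Cox-Snell goodness of fit).

It is written for epidemiologists analysing registry survival cohorts
georeferenced to administrative regions (for example cancer mortality over
a state's local government areas) who want region-level unexplained-risk
maps alongside covariate effects.  Because such registry data are usually
access restricted, the package ships a first-class synthetic-cohort
generator that reproduces the statistical structure of this kind of study
— contiguity-correlated frailties, censored AFT event times, realistic
categorical covariate mixes — so the entire pipeline is testable and
demonstrable end to end.

## Model

For patient *j* in region *i*:

```
log T_ij = mu + beta' x_ij + W_i + rho * eps_ij
```

with right-censored `T_ij`, `eps` standard minimum-Gumbel / normal /
logistic (giving Weibull, log-normal, log-logistic baselines), and the
frailties `W = (W_1..W_R)` carrying an intrinsic conditional
autoregressive prior over the region adjacency graph (queen contiguity):
`W_i | W_-i ~ N(mean of neighbours, tau2 / m_i)`, constrained to sum to
zero per graph component.  Effects are reported as hazard-direction
ratios `exp(-beta/rho)` (AHR, with 95% credible interval) next to time
ratios `exp(beta)`.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from spataft import (MCMCConfig, effect_table, km_estimate,
                     registry_scenario, simulate_cohort, summarize_frailty)
from spataft.mcmc import fit
from spataft.model_selection import cox_snell, dic

scenario = registry_scenario(seed=1, n_total=79 * 40)   # 79 regions
cohort, W_true = simulate_cohort(scenario)
print(f"n = {len(cohort)}, events = {cohort.n_events} "
      f"(censored {1 - cohort.n_events/len(cohort):.1%})")
print(f"KM median survival: {km_estimate(cohort.times, cohort.events).median():.1f} months")

chains = fit(cohort, scenario.graph, family="loglogistic",
             config=MCMCConfig(burn_in=1000, monitor=2000, thin=2, seed=2))
tab = effect_table(chains.beta, chains.rho, list(chains.design_columns))
print(tab[["covariate", "AHR", "AHR_lo", "AHR_hi", "significant"]].round(2))
print(f"tau2 posterior median: {np.median(chains.tau2):.3f}")
d, p_d = dic(chains, cohort, scenario.graph)
print(f"DIC = {d:.1f} (p_D = {p_d:.1f})")
print(f"Cox-Snell slope: {cox_snell(chains, cohort, scenario.graph).slope:.3f}")
```

prints (about a minute on one CPU):

```
n = 3160, events = 2017 (censored 36.2%)
KM median survival: 5.3 months
         covariate  AHR  AHR_lo  AHR_hi  significant
        sex=Female 0.78    0.68    0.88         True
     smoking=Never 0.64    0.52    0.76         True
smoking=Not stated 1.13    0.79    1.62        False
         ecog=Poor 1.65    1.38    1.96         True
   ecog=Not stated 1.09    0.94    1.24        False
    stage=Stage II 2.12    1.58    3.02         True
   stage=Stage III 2.60    2.04    3.43         True
    stage=Stage IV 6.40    5.15    8.03         True
  stage=Not stated 2.46    1.92    3.13         True
tau2 posterior median: 0.067
DIC = 12016.4 (p_D = 22.7)
Cox-Snell slope: 1.003
```

Reading the output: the cohort emulates a lung-cancer registry (36%
administratively censored, short median survival driven by the 45%
stage-IV mix).  The fitted AHRs recover the generating effects — female
sex and never-smoking protective (AHR < 1, intervals excluding 1),
advanced stage sharply harmful — `rho` and `mu` are absorbed into the
ratios, `tau2` is the spatial frailty variance, and a Cox-Snell slope
near one says the fitted family matches the data-generating one.
`summarize_frailty(chains)` then gives per-region posterior means,
credible intervals and exceedance probabilities `Pr(W_i > 0)`, exported
by `export_choropleth_table` as a CSV joinable to any polygon layer for
mapping.

The same pipeline is scriptable from the shell:

```
spataft simulate --seed 1 --out cohort.csv --adjacency graph.txt
spataft describe --cohort cohort.csv --factor sex
spataft fit --cohort cohort.csv --adjacency graph.txt --spatial \
        --family loglogistic --seed 2 --out chains.npz
spataft compare --cohort cohort.csv --adjacency graph.txt --out grid.tsv
spataft diagnose --chains chains.npz --cohort cohort.csv --adjacency graph.txt --out resid.csv
spataft report --chains chains.npz --out frailty_map.csv
```

Every subcommand writes a JSON provenance stub (inputs, seed, version) so
any artifact can be regenerated from it.  The scaled-down sampler
schedule is the CLI default; `--full-schedule` selects the full
burn 5000 / monitor 10,000 / thin 4 protocol.

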