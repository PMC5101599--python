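# feroxmr

Hierarchical Bayesian Jolly–Seber (JS) superpopulation analysis of sparse
angling mark–recapture data, built around the 16-year (1994–2009) Loch
Rannoch Ferox Trout tagging study: 69 individual trout, 80 retained
encounters, 11 inter-annual recaptures.

Ferox Trout are large, long-lived, piscivorous Brown Trout (*Salmo trutta*)
whose abundance is notoriously hard to estimate because angling is the only
practical capture method and annual catches are tiny. `feroxmr` is for
fisheries scientists and quantitative ecologists who want to fit (or
stress-test) an open-population abundance model on data this sparse: it
estimates annual abundance, survival, catchability and recruitment, checks
model adequacy with a posterior predictive check, and derives the
conservation quantities managers ask for (interval mortality, density,
effective population size).

## The model

Observed capture histories `y_i` (one binary vector over the `T = 16`
annual occasions per fish) are augmented with all-zero pseudo-individuals
to a fixed size `M = 1000`. For augmented individual `i`:

    w_i      ~ Bernoulli(psi)            inclusion in the superpopulation
    entry e_i ~ Categorical(b_1..b_T)    b_1 = rho1, b_t = (1-rho1)/(T-1)
    survival  z_{i,t+1} = 1 given z_{i,t}=1 with probability S
    detection y_{i,t} ~ Bernoulli(w_i * z_{i,t} * p)

with independent Uniform(0,1) priors on `psi` (inclusion), `S` (annual
survival), `p` (annual capture probability) and `rho1` (probability of
recruiting before the first occasion). Equal entry probabilities after the
first occasion encode constant expected annual recruitment. Derived
quantities are computed per posterior draw from conditionally sampled
latent states: abundance `N_t = sum_i w_i z_{i,t}`, recruitment `B_t`, and
the annual mean recruitment `B`.

Inference marginalises the latent states analytically (a sum over entry and
death occasions), leaving a 4-parameter posterior sampled by adaptive
random-walk Metropolis-within-Gibbs on the logit scale — 5 chains of 1e5
iterations, half burn-in, thinned to at least 10,000 draws, convergence
gated on the Brooks–Gelman–Rubin diagnostic (R̂ ≤ 1.05). An independent
data-augmentation Gibbs sampler (conjugate Beta updates given sampled
latent states) is provided as a cross-check and agrees with the marginal
sampler on all quantities.

## Worked example

```python
from feroxmr import (
    load_rannoch_table, reconstruct_histories,
    ModelConfig, McmcSettings, run_mcmc, summarize,
)

matrix = reconstruct_histories(load_rannoch_table(), 7)   # 69 fish, 80 encounters
config = ModelConfig(T=16, M=1000)
sample = run_mcmc(matrix, config, McmcSettings(n_iterations=20_000, rng_seed=7))
print(summarize(sample).table.round(3).loc[["psi", "S", "p", "rho1", "B", "N_1994", "N_2009"]])
```

prints

```
           mean   lower    upper   rhat      n
psi       0.365   0.197    0.655  1.013  10000
S         0.747   0.583    0.900  1.005  10000
p         0.073   0.026    0.154  1.012  10000
rho1      0.320   0.143    0.601  1.003  10000
B        16.406   8.198   30.402  1.008  10000
N_1994  118.184  39.000  272.000  1.010  10000
N_2009   74.624  31.000  162.000  1.011  10000
```

Annual survival is about 0.75, so interval mortality `1 - S` is about 0.25;
a single experienced angler caught roughly 7% of the available fish each
year; abundance declines from roughly 118 fish (wide 95% CRI) at the start
of the study to roughly 75 by 2009 — about 0.05 fish per hectare once the
shallow west end of the loch is excluded (1,600 ha effective area), and an
effective population size of ~19 under the usual salmonid rule
`Ne ≈ 0.25 × spawners`. Wide credible intervals are the honest price of 80
encounters in 16 years.

The same pipeline is available from the shell:

```sh
feroxmr fit --seed 1 --output-dir out/        # summary.csv, draws.csv, figure
feroxmr simulate --seed 2 --output-dir sim/   # synthetic study files
feroxmr recover --replicates 50 --iterations 20000 --output-dir rec/
```

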