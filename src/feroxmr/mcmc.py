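"""Multi-chain MCMC for the Jolly-Seber superpopulation model.

Fitting protocol: several chains started at independent random draws from
the priors, each run for a fixed number of iterations with the first half
discarded as burn-in and the remainder thinned so that at least 10,000
draws are retained overall; convergence is declared when the
Brooks-Gelman-Rubin potential scale reduction factor satisfies
``R-hat <= 1.05`` for every monitored parameter. Point estimates are
posterior means and 95% credible intervals the 2.5% and 97.5% empirical
quantiles (linear interpolation).

Two samplers target the same posterior:

* ``method="marginal"`` (default) -- adaptive random-walk
  Metropolis-within-Gibbs on logit-transformed ``(psi, S, p, rho1)`` over
  the marginalised likelihood. Proposal scales adapt toward a 44%
  acceptance rate during burn-in and are frozen afterwards. All chains are
  advanced in lockstep so each likelihood evaluation is one batched array
  operation. Latent abundance/recruitment trajectories are realised for
  the retained draws by exact conditional sampling.
* ``method="augmented"`` -- the classic data-augmentation Gibbs sampler:
  latent inclusion/entry/death states given parameters, then conjugate
  Beta updates for each parameter given the latent states (uniform(0,1)
  priors only). Kept as an independent cross-check of the marginal path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .encounters import CaptureHistoryMatrix
from .model import (
    ConfigError,
    HistoryClasses,
    ModelConfig,
    PARAM_NAMES,
    dataset_loglik_batched,
    latent_trajectories,
    _cell_grid,
    _cell_weights,
    _loglik_rows,
)

__all__ = [
    "McmcSettings",
    "PosteriorSample",
    "FitSummary",
    "run_mcmc",
    "rhat",
    "summarize",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class McmcSettings:
    """Chain count, length, burn-in, thinning and seed."""

    n_chains: int = 5
    n_iterations: int = 100_000
    burn_in: float = 0.5
    thin: Optional[int] = None  # None: stride chosen to retain >= min_retained
    min_retained: int = 10_000
    rng_seed: int = 0
    adapt_target: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ConfigError("need at least two chains for convergence diagnosis")
        if not 0.0 < self.burn_in < 1.0:
            raise ConfigError("burn_in must be a fraction in (0, 1)")
        if self.thin is not None and self.thin < 1:
            raise ConfigError("thin stride must be >= 1")

    @property
    def n_burn(self) -> int:
        return int(self.n_iterations * self.burn_in)

    def stride(self) -> int:
        if self.thin is not None:
            return self.thin
        kept = (self.n_iterations - self.n_burn) * self.n_chains
        return max(1, math.ceil(kept / self.min_retained))


@dataclass
class PosteriorSample:
    """Retained posterior draws, indexed by (chain, draw).

    ``params`` has shape (n_chains, n_draws, 4) in canonical parameter
    order; ``N`` and ``B`` (if present) hold the per-draw latent abundance
    and recruitment trajectories, shape (n_chains, n_draws, T).
    """

    params: np.ndarray
    years: tuple[int, ...]
    N: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[0] * self.params.shape[1]

    def chain_values(self, name: str) -> np.ndarray:
        """Draws of one scalar quantity, shape (n_chains, n_draws_per_chain)."""
        if name in PARAM_NAMES:
            return self.params[:, :, PARAM_NAMES.index(name)]
        if name == "B":
            if self.B is None:
                raise KeyError("latent recruitment draws not attached")
            return self.B[:, :, 1:].mean(axis=2)
        if name.startswith("N_"):
            if self.N is None:
                raise KeyError("latent abundance draws not attached")
            year = int(name[2:])
            if year not in self.years:
                raise KeyError(f"no occasion labelled {year}")
            return self.N[:, :, self.years.index(year)]
        raise KeyError(f"unknown quantity {name!r}")

    def values(self, name: str) -> np.ndarray:
        """Draws of one scalar quantity, flattened across chains."""
        return self.chain_values(name).reshape(-1)

    def quantity_names(self) -> list[str]:
        names = list(PARAM_NAMES)
        if self.B is not None:
            names.append("B")
        if self.N is not None:
            names += [f"N_{y}" for y in self.years]
        return names

    def to_frame(self) -> pd.DataFrame:
        """All draws as a tidy DataFrame (chain, draw, one column per quantity)."""
        C, R = self.params.shape[:2]
        data: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(C), R),
            "draw": np.tile(np.arange(R), C),
        }
        for name in self.quantity_names():
            data[name] = self.values(name)
        return pd.DataFrame(data)

    def write_draws(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FitSummary:
    """Posterior summary table plus the convergence verdict."""

    table: pd.DataFrame  # index: quantity; columns: mean, lower, upper, rhat, n
    converged: bool
    rhat_variant: str

    def __getitem__(self, quantity: str) -> pd.Series:
        return self.table.loc[quantity]


def rhat(chains: np.ndarray, split: bool = True) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws). With ``split=True`` each chain
    is halved first (the split-chain variant, which also flags trending
    chains). Returns ``nan`` when every chain has zero internal variance
    (the diagnostic is undefined).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ConfigError("need >=2 chains and >=4 draws per chain")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    within = chains.var(axis=1, ddof=1)
    W = within.mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return math.nan
    var_hat = (n - 1) / n * W + B / n
    return math.sqrt(var_hat / W)


def summarize(
    sample: PosteriorSample,
    quantities: Optional[Sequence[str]] = None,
    split_rhat: bool = True,
) -> FitSummary:
    """Posterior mean, 95% credible interval and R-hat per quantity."""
    if sample.n_draws == 0:
        raise ConfigError("empty posterior sample")
    names = list(quantities) if quantities is not None else sample.quantity_names()
    rows = []
    for name in names:
        per_chain = sample.chain_values(name)
        flat = per_chain.reshape(-1)
        rows.append(
            {
                "mean": flat.mean(),
                "lower": np.quantile(flat, 0.025),
                "upper": np.quantile(flat, 0.975),
                "rhat": (
                    rhat(per_chain, split=split_rhat)
                    if per_chain.shape[0] >= 2 and per_chain.shape[1] >= 4
                    else math.nan
                ),
                "n": flat.size,
            }
        )
    table = pd.DataFrame(rows, index=names)
    finite = table["rhat"].to_numpy()
    converged = bool(np.all(np.nan_to_num(finite, nan=np.inf) <= RHAT_THRESHOLD))
    return FitSummary(table, converged, "split" if split_rhat else "classic")


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _logit(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip((u - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return np.log(frac) - np.log1p(-frac)

def _from_logit(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * expit(x)

def _log_jacobian(x: np.ndarray) -> np.ndarray:
    # d theta / d x = (hi - lo) sigma(x)(1 - sigma(x)); constant factor drops
    return -x - 2.0 * np.logaddexp(0.0, -x)


def _run_marginal(
    classes: HistoryClasses,
    config: ModelConfig,
    settings: McmcSettings,
) -> np.ndarray:
    """Adaptive RWM-within-Gibbs over the marginal likelihood.

    Returns retained draws, shape (n_chains, n_kept, 4). Chains advance in
    lockstep; each of the four per-iteration parameter updates evaluates
    the batched likelihood once for all chains.
    """
    rng = np.random.default_rng(np.random.SeedSequence(settings.rng_seed))
    C = settings.n_chains
    bounds = config.prior_bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]

    def logpost(x: np.ndarray) -> np.ndarray:
        theta = _from_logit(x, lo, hi)
        return _loglik_rows(theta, classes) + _log_jacobian(x).sum(axis=-1)

    # overdispersed starts: draw from the priors until the posterior is finite
    x = np.empty((C, 4))
    lp = np.full(C, -np.inf)
    for _ in range(100):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        draw = lo + (hi - lo) * rng.uniform(size=(int(bad.sum()), 4))
        x[bad] = _logit(draw, lo, hi)
        lp[bad] = logpost(x[bad])
    else:
        raise ConfigError("could not initialise chains at finite log-posterior")

    log_scale = np.full((C, 4), math.log(0.5))
    n_burn, stride = settings.n_burn, settings.stride()
    kept: list[np.ndarray] = []
    for it in range(settings.n_iterations):
        for j in range(4):
            prop = x.copy()
            prop[:, j] = x[:, j] + np.exp(log_scale[:, j]) * rng.standard_normal(C)
            lp_prop = logpost(prop)
            accept = np.log(rng.uniform(size=C)) < lp_prop - lp
            x[accept] = prop[accept]
            lp[accept] = lp_prop[accept]
            if it < n_burn:  # Robbins-Monro adaptation, frozen after burn-in
                step = (it + 1) ** -0.6
                log_scale[:, j] += step * (accept.astype(float) - settings.adapt_target)
        if it >= n_burn and (it - n_burn) % stride == 0:
            kept.append(_from_logit(x, lo, hi).copy())
    if not kept:
        raise ConfigError("no draws retained; increase n_iterations or reduce thinning")
    return np.stack(kept, axis=1)  # (C, n_kept, 4)


def _run_augmented(
    classes: HistoryClasses,
    config: ModelConfig,
    settings: McmcSettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Data-augmentation Gibbs sampler (uniform(0,1) priors required).

    Alternates exact conditional latent-state sampling (aggregated to
    (entry, last-alive) cell counts per history class) with conjugate Beta
    updates for psi, S, p and rho1. Returns (draws, N, B) for the retained
    iterations.
    """
    if np.any(config.prior_bounds() != np.array([[0.0, 1.0]] * 4)):
        raise ConfigError("the augmented Gibbs path supports uniform(0,1) priors only")
    rng = np.random.default_rng(np.random.SeedSequence(settings.rng_seed))
    C = settings.n_chains
    T, M = classes.T, classes.M
    n_obs = classes.n_observed
    n_det = int((classes.counts * classes.k).sum())
    e_idx, d_idx = _cell_grid(T)
    alive_mask = (np.arange(T)[None, :] >= e_idx[:, None]) & (
        np.arange(T)[None, :] <= d_idx[:, None]
    )
    n_burn, stride = settings.n_burn, settings.stride()
    draws, Ns, Bs = [], [], []
    for _c in range(C):
        theta = rng.uniform(size=4)
        chain_draws, chain_N, chain_B = [], [], []
        for it in range(settings.n_iterations):
            weights = _cell_weights(theta[None, :], T)[0]
            psi, S, p, _rho1 = theta
            q = 1.0 - p
            cell_counts = np.zeros(e_idx.size, dtype=np.int64)
            for f, l, cnt in zip(classes.f, classes.l, classes.counts):
                pr = np.where((e_idx <= f) & (d_idx >= l), weights, 0.0)
                cell_counts += rng.multinomial(int(cnt), pr / pr.sum())
            n_incl_zero = 0
            if classes.n_zero:
                pr1 = weights * q
                total1 = psi * pr1.sum()
                p_incl = total1 / ((1.0 - psi) + total1)
                n_incl_zero = rng.binomial(classes.n_zero, p_incl)
                if n_incl_zero:
                    cell_counts_zero = rng.multinomial(n_incl_zero, pr1 / pr1.sum())
                    cell_counts += cell_counts_zero
            n_incl = n_obs + n_incl_zero
            # sufficient statistics of the complete data
            survived = int((cell_counts * (d_idx - e_idx)).sum())
            died = int(cell_counts[d_idx < T - 1].sum())
            alive_occasions = survived + n_incl
            entered_first = int(cell_counts[e_idx == 0].sum())
            theta = np.array(
                [
                    rng.beta(1 + n_incl, 1 + M - n_incl),
                    rng.beta(1 + survived, 1 + died),
                    rng.beta(1 + n_det, 1 + alive_occasions - n_det),
                    rng.beta(1 + entered_first, 1 + n_incl - entered_first),
                ]
            )
            if it >= n_burn and (it - n_burn) % stride == 0:
                chain_draws.append(theta.copy())
                chain_N.append(cell_counts @ alive_mask)
                B_t = np.bincount(e_idx, weights=cell_counts, minlength=T)
                chain_B.append(B_t)
        draws.append(np.stack(chain_draws))
        Ns.append(np.stack(chain_N))
        Bs.append(np.stack(chain_B))
    return np.stack(draws), np.stack(Ns).astype(float), np.stack(Bs).astype(float)


def run_mcmc(
    matrix: CaptureHistoryMatrix,
    config: ModelConfig,
    settings: McmcSettings,
    method: str = "marginal",
    sample_latents: bool = True,
) -> PosteriorSample:
    """Fit the model and return retained posterior draws from all chains.

    Deterministic for fixed settings and seed. With ``sample_latents`` the
    per-draw abundance (``N_t``) and recruitment (``B_t``) trajectories are
    attached (the augmented sampler produces them as a by-product; the
    marginal sampler realises them by conditional sampling afterwards).
    """
    classes = HistoryClasses.from_matrix(matrix, config)
    if method == "marginal":
        params = _run_marginal(classes, config, settings)
        N = B = None
        if sample_latents:
            rng = np.random.default_rng(np.random.SeedSequence([settings.rng_seed, 1]))
            C, R = params.shape[:2]
            N_flat, B_flat = latent_trajectories(classes, params.reshape(-1, 4), rng)
            N = N_flat.reshape(C, R, -1)
            B = B_flat.reshape(C, R, -1)
    elif method == "augmented":
        params, N, B = _run_augmented(classes, config, settings)
        if not sample_latents:
            N = B = None
    else:
        raise ConfigError(f"unknown sampling method {method!r}")
    meta = {
        "method": method,
        "settings": settings,
        "M": config.M,
        "n_observed": classes.n_observed,
    }
    return PosteriorSample(params, tuple(matrix.years), N=N, B=B, meta=meta)
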