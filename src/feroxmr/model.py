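"""Hierarchical Bayesian Jolly-Seber superpopulation model.

The model follows the standard state-space formulation with parameter-expanded
data augmentation. The observed capture histories are padded with all-zero
pseudo-individuals up to a fixed augmented size ``M``; each augmented
individual is a genuine member of the superpopulation with inclusion
probability ``psi`` (zero-inflation). An included individual recruits at
occasion ``t`` with entry probability ``b_t``, where ``b_1 = rho1`` and the
remaining mass is spread evenly over occasions ``2..T`` (constant expected
annual recruitment), survives each annual interval with constant probability
``S``, never re-enters after death, and while alive is detected at each
occasion with constant capture probability ``p``. Priors on
``(psi, S, p, rho1)`` are independent uniforms, by default on (0, 1).

Two equivalent likelihood computations are provided:

* :func:`individual_marginal_loglik` / :func:`dataset_loglik` marginalise
  the latent inclusion, entry and death variables analytically -- a sum over
  at most ``1 + T*(T+1)/2`` latent paths per individual. This is the fast
  inference path (four free parameters).
* :func:`sample_latent_states` draws the latent states from their exact
  conditional distribution given data and parameters, which realises the
  per-draw abundance and recruitment trajectories and powers the augmented
  Gibbs sampler used for cross-validation.

Because survival and capture probabilities are constant, the marginal
probability of a capture history depends only on its first detection, last
detection and number of detections; histories are therefore grouped into
equivalence classes (:class:`HistoryClasses`) and the log-likelihood is
evaluated with a handful of vectorised array operations, batched over an
arbitrary leading shape of parameter vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .encounters import CaptureHistoryMatrix, MalformedDataError

__all__ = [
    "ModelConfig",
    "ParameterVector",
    "EntrySchedule",
    "LatentState",
    "HistoryClasses",
    "ConfigError",
    "entry_schedule",
    "individual_marginal_loglik",
    "dataset_loglik",
    "sample_latent_states",
]

PARAM_NAMES = ("psi", "S", "p", "rho1")

_TINY = 1e-300  # floor before taking logs; avoids 0*inf in degenerate corners


class ConfigError(ValueError):
    """Raised for invalid model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Augmentation size, number of occasions and prior bounds.

    ``priors`` maps each of ``psi, S, p, rho1`` to uniform bounds within
    [0, 1]; unlisted parameters default to uniform(0, 1).
    """

    T: int
    M: int = 1000
    priors: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ConfigError("need at least T=2 occasions")
        if self.M < 0:
            raise ConfigError("augmented size M must be non-negative")
        for name, (lo, hi) in self.priors.items():
            if name not in PARAM_NAMES:
                raise ConfigError(f"unknown parameter {name!r}")
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigError(f"prior bounds for {name} must satisfy 0 <= lo < hi <= 1")

    def prior_bounds(self) -> np.ndarray:
        """(4, 2) array of lower/upper prior bounds in canonical order."""
        out = np.empty((4, 2))
        for j, name in enumerate(PARAM_NAMES):
            out[j] = self.priors.get(name, (0.0, 1.0))
        return out


@dataclass(frozen=True)
class ParameterVector:
    """One point in parameter space: (psi, S, p, rho1), each in (0, 1)."""

    psi: float
    S: float
    p: float
    rho1: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} outside the open unit interval")

    def as_array(self) -> np.ndarray:
        return np.array([self.psi, self.S, self.p, self.rho1])


@dataclass(frozen=True)
class EntrySchedule:
    """Per-occasion entry probabilities b and conditional entry probabilities gamma."""

    b: np.ndarray
    gamma: np.ndarray


@dataclass(frozen=True)
class LatentState:
    """Realised inclusion and alive indicators for all M augmented individuals.

    ``z`` rows are single contiguous alive runs (no re-entry after death);
    detections can occur only where ``w[i] * z[i, t] == 1``.
    """

    w: np.ndarray  # (M,) 0/1 inclusion
    z: np.ndarray  # (M, T) 0/1 alive

    @property
    def entry_occasions(self) -> np.ndarray:
        """First alive occasion per individual; -1 for excluded individuals."""
        out = np.where(self.z.any(axis=1), self.z.argmax(axis=1), -1)
        return np.where(self.w == 1, out, -1)


def entry_schedule(rho1: float, T: int) -> EntrySchedule:
    """Entry probabilities under constant expected annual recruitment.

    ``b_1 = rho1`` and ``b_t = (1 - rho1)/(T - 1)`` for ``t >= 2``;
    ``gamma_t = b_t / (1 - sum_{s<t} b_s)`` is the conditional probability
    of entering at ``t`` given not yet entered (``gamma_T = 1``).
    """
    if T < 2:
        raise ConfigError("need at least T=2 occasions")
    if not 0.0 < rho1 < 1.0:
        raise ConfigError("rho1 must lie strictly inside (0, 1)")
    b = np.full(T, (1.0 - rho1) / (T - 1))
    b[0] = rho1
    remaining = 1.0 - np.concatenate(([0.0], np.cumsum(b)[:-1]))
    gamma = np.clip(b / np.maximum(remaining, _TINY), 0.0, 1.0)
    gamma[-1] = 1.0
    return EntrySchedule(b, gamma)


# ---------------------------------------------------------------------------
# Marginalised likelihood
# ---------------------------------------------------------------------------

def individual_marginal_loglik(
    history: np.ndarray,
    theta: ParameterVector,
    config: ModelConfig,
) -> float:
    """Log marginal probability of one augmented individual's history.

    Sums the complete-data probability over all admissible latent paths
    (inclusion w, entry occasion e, last-alive occasion d): an included
    individual enters with probability ``b_e``, survives ``d - e`` intervals
    and dies before the next occasion unless ``d = T``, and is detected at
    each alive occasion independently with probability ``p``. The all-zero
    history additionally receives the excluded-individual mass ``1 - psi``.

    This is the readable reference implementation; :func:`dataset_loglik`
    evaluates the same law through the vectorised class machinery.
    """
    y = np.asarray(history)
    if y.shape != (config.T,) or not np.isin(y, (0, 1)).all():
        raise MalformedDataError("history must be a binary vector of length T")
    T = config.T
    psi, S, p, rho1 = theta.psi, theta.S, theta.p, theta.rho1
    b = entry_schedule(rho1, T).b

    det = np.flatnonzero(y)
    total = 0.0
    if det.size:
        first, last = det[0], det[-1]
        e_max, d_min = first, last
    else:
        total += 1.0 - psi
        e_max, d_min = T - 1, 0
    for e in range(e_max + 1):
        for d in range(max(d_min, e), T):
            pr = b[e] * S ** (d - e) * ((1.0 - S) if d < T - 1 else 1.0)
            for t in range(e, d + 1):
                pr *= p if y[t] else (1.0 - p)
            total += psi * pr
    return math.log(total) if total > 0.0 else -math.inf


@dataclass(frozen=True)
class HistoryClasses:
    """Capture histories grouped by (first, last, count) sufficient statistics.

    With constant S and p the marginal probability of a history depends only
    on its first detection occasion ``f``, last detection occasion ``l`` and
    detection count ``k``; the all-zero augmented histories form one class
    of size ``n_zero``.
    """

    T: int
    M: int
    f: np.ndarray  # (K,) first detection occasion per class
    l: np.ndarray  # (K,) last detection occasion per class
    k: np.ndarray  # (K,) detections per class
    counts: np.ndarray  # (K,) individuals per class
    n_zero: int

    @classmethod
    def from_matrix(cls, matrix: CaptureHistoryMatrix, config: ModelConfig) -> "HistoryClasses":
        if matrix.n_occasions != config.T:
            raise ConfigError("matrix occasions do not match model config")
        if matrix.n_individuals > config.M:
            raise ConfigError(
                f"augmented size M={config.M} smaller than n={matrix.n_individuals}"
            )
        tally: dict[tuple[int, int, int], int] = {}
        for row in matrix.y:
            det = np.flatnonzero(row)
            key = (int(det[0]), int(det[-1]), int(det.size))
            tally[key] = tally.get(key, 0) + 1
        keys = sorted(tally)
        f = np.array([key[0] for key in keys], dtype=np.int64)
        l = np.array([key[1] for key in keys], dtype=np.int64)
        k = np.array([key[2] for key in keys], dtype=np.int64)
        counts = np.array([tally[key] for key in keys], dtype=np.int64)
        return cls(config.T, config.M, f, l, k, counts, config.M - matrix.n_individuals)

    @property
    def n_observed(self) -> int:
        return int(self.counts.sum())


def _entry_b(theta: np.ndarray, T: int) -> np.ndarray:
    """Entry probabilities for a (..., 4) parameter array -> (..., T)."""
    rho1 = theta[..., 3]
    b = np.broadcast_to(((1.0 - rho1) / (T - 1))[..., None], theta.shape[:-1] + (T,)).copy()
    b[..., 0] = rho1
    return b


def _class_log_probs(theta: np.ndarray, classes: HistoryClasses) -> tuple[np.ndarray, np.ndarray]:
    """Batched log class probabilities.

    Returns ``(logP, logP0)`` where ``logP[..., j]`` is the log marginal
    probability of one individual in observed class ``j`` and ``logP0`` that
    of an all-zero augmented history, for ``theta`` of shape ``(..., 4)``.
    """
    T = classes.T
    psi = np.maximum(theta[..., 0], _TINY)
    S = theta[..., 1]
    p = np.maximum(theta[..., 2], _TINY)
    q = np.maximum(1.0 - theta[..., 2], _TINY)
    b = _entry_b(theta, T)

    x = S * q  # per-interval survive-and-miss factor
    idx = np.arange(T)
    expo = idx[None, :] - idx[:, None]  # d - e
    pow_x = np.where(expo >= 0, x[..., None, None] ** np.maximum(expo, 0), 0.0)
    m = np.broadcast_to((1.0 - S)[..., None], S.shape + (T,)).copy()
    m[..., T - 1] = 1.0
    A = pow_x * m[..., None, :]  # (..., e, d): m_d * x^(d-e), zero for d < e
    # suffix sums over d, then pick d >= max(e, l)
    cum = np.flip(np.cumsum(np.flip(A, axis=-1), axis=-1), axis=-1)
    max_el = np.maximum(idx[:, None], idx[None, :])  # (e, l)
    R = cum[..., idx[:, None], max_el]  # (..., e, l)
    H = np.cumsum(b[..., :, None] * R, axis=-2)  # (..., f, l): sum_{e<=f} b_e R[e, l]

    with np.errstate(divide="ignore"):
        logH = np.log(np.maximum(H[..., classes.f, classes.l], 0.0))
        logP = (
            np.log(psi)[..., None]
            + classes.k * np.log(p)[..., None]
            + (1 - classes.k) * np.log(q)[..., None]
            + logH
        )
        P0 = (1.0 - psi) + psi * q * H[..., T - 1, 0]
        logP0 = np.log(np.maximum(P0, 0.0))
    return logP, logP0


def dataset_loglik_batched(theta: np.ndarray, classes: HistoryClasses) -> np.ndarray:
    """Dataset log-likelihood for parameters of shape (..., 4) -> (...)."""
    theta = np.asarray(theta, dtype=float)
    logP, logP0 = _class_log_probs(theta, classes)
    with np.errstate(invalid="ignore"):
        ll = (classes.counts * logP).sum(axis=-1) + classes.n_zero * logP0
    return np.where(np.isnan(ll), -np.inf, ll)


try:  # fast scalar kernel for the samplers; the array path remains the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _loglik_kernel(theta, f, l, k, counts, n_zero, T):  # pragma: no cover
        B = theta.shape[0]
        out = np.empty(B)
        K = f.shape[0]
        b = np.empty(T)
        cum = np.empty((T, T))
        for i in range(B):
            psi, S, p, rho1 = theta[i, 0], theta[i, 1], theta[i, 2], theta[i, 3]
            q = 1.0 - p
            x = S * q
            b[0] = rho1
            for t in range(1, T):
                b[t] = (1.0 - rho1) / (T - 1)
            for e in range(T):
                acc = 0.0
                for d in range(T - 1, e - 1, -1):
                    m_d = 1.0 if d == T - 1 else 1.0 - S
                    acc += m_d * x ** (d - e)
                    cum[e, d] = acc
            ll = 0.0
            logpsi = np.log(psi)
            logp = np.log(p)
            logq = np.log(q)
            ok = True
            for j in range(K):
                P = 0.0
                for e in range(f[j] + 1):
                    d0 = l[j] if l[j] > e else e
                    P += b[e] * cum[e, d0]
                if P <= 0.0:
                    ok = False
                    break
                term = logpsi + k[j] * logp + np.log(P)
                if k[j] != 1:
                    term += (1 - k[j]) * logq
                ll += counts[j] * term
            if not ok:
                out[i] = -np.inf
                continue
            if n_zero > 0:
                s0 = 0.0
                for e in range(T):
                    s0 += b[e] * cum[e, e]
                P0 = (1.0 - psi) + psi * q * s0
                ll += n_zero * np.log(P0)
            out[i] = ll if not np.isnan(ll) else -np.inf
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _loglik_rows(theta2d: np.ndarray, classes: HistoryClasses) -> np.ndarray:
    """Dataset log-likelihood for a (R, 4) parameter block (sampler hot path)."""
    theta2d = np.ascontiguousarray(theta2d, dtype=float)
    if _HAVE_NUMBA:
        return _loglik_kernel(
            theta2d,
            classes.f,
            classes.l,
            classes.k,
            classes.counts,
            classes.n_zero,
            classes.T,
        )
    return dataset_loglik_batched(theta2d, classes)


def dataset_loglik(
    matrix: CaptureHistoryMatrix,
    theta: ParameterVector,
    config: ModelConfig,
) -> float:
    """Log-likelihood of the augmented dataset at one parameter vector.

    Equal to the sum of :func:`individual_marginal_loglik` over the observed
    rows plus ``M - n`` copies of the all-zero history term.
    """
    classes = HistoryClasses.from_matrix(matrix, config)
    return float(dataset_loglik_batched(theta.as_array(), classes))


# ---------------------------------------------------------------------------
# Conditional latent-state sampling
# ---------------------------------------------------------------------------

def _cell_grid(T: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (entry e, last-alive d) cell index arrays with d >= e."""
    e, d = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
    mask = d >= e
    return e[mask], d[mask]


def _cell_weights(theta: np.ndarray, classes_T: int) -> np.ndarray:
    """Unnormalised (e, d) path weights b_e * m_d * (S q)^(d-e), batched.

    Shape ``theta`` (..., 4) -> (..., n_cells). The detection-position
    factor ``p^k q^(1-k)`` is constant within a history's admissible cells
    and therefore cancels from conditional cell probabilities.
    """
    T = classes_T
    S = theta[..., 1]
    q = 1.0 - theta[..., 2]
    b = _entry_b(theta, T)
    e_idx, d_idx = _cell_grid(T)
    x = np.maximum(S * q, 0.0)
    w = b[..., e_idx] * (x[..., None] ** (d_idx - e_idx))
    m_last = np.where(d_idx == T - 1, 1.0, (1.0 - S)[..., None])
    return w * m_last


def sample_latent_states(
    matrix: CaptureHistoryMatrix,
    theta: ParameterVector,
    config: ModelConfig,
    rng_seed: int | np.random.Generator = 0,
) -> LatentState:
    """Draw (w, z) from their exact conditional law given data and parameters.

    Observed individuals have ``w = 1`` and an alive run bracketing their
    detections; the entry/death pair is drawn from its discrete conditional.
    The ``M - n`` all-zero augmented individuals are excluded with
    probability ``(1 - psi) / P0`` and otherwise receive a never-detected
    alive run.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    classes_check = HistoryClasses.from_matrix(matrix, config)  # validates n <= M
    T, M, n = config.T, config.M, matrix.n_individuals
    del classes_check
    e_idx, d_idx = _cell_grid(T)
    weights = _cell_weights(theta.as_array(), T)  # (n_cells,)
    q = 1.0 - theta.p

    w = np.zeros(M, dtype=np.int8)
    z = np.zeros((M, T), dtype=np.int8)
    for i, row in enumerate(matrix.y):
        det = np.flatnonzero(row)
        first, last = det[0], det[-1]
        admissible = (e_idx <= first) & (d_idx >= last)
        pr = np.where(admissible, weights, 0.0)
        cell = rng.choice(pr.size, p=pr / pr.sum())
        w[i] = 1
        z[i, e_idx[cell] : d_idx[cell] + 1] = 1

    if M > n:
        # all-zero individuals: cell weights already carry q^(d-e) through
        # the (S q) factor; one more q covers nondetection at the entry year
        pr1 = weights * q
        total1 = theta.psi * pr1.sum()
        p_incl = total1 / ((1.0 - theta.psi) + total1)
        for i in range(n, M):
            if rng.random() < p_incl:
                cell = rng.choice(pr1.size, p=pr1 / pr1.sum())
                w[i] = 1
                z[i, e_idx[cell] : d_idx[cell] + 1] = 1
    return LatentState(w, z)


def latent_trajectories(
    classes: HistoryClasses,
    theta_draws: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw abundance and recruitment from conditional latent sampling.

    For ``theta_draws`` of shape (R, 4), samples the latent (entry,
    last-alive) cells of every augmented individual conditionally on the
    data, aggregated by history class, and returns ``(N, B)`` where
    ``N[r, t]`` counts included individuals alive at occasion ``t`` and
    ``B[r, t]`` those entering at occasion ``t``.
    """
    theta_draws = np.asarray(theta_draws, dtype=float)
    R = theta_draws.shape[0]
    T = classes.T
    e_idx, d_idx = _cell_grid(T)
    ncell = e_idx.size
    alive_mask = (np.arange(T)[None, :] >= e_idx[:, None]) & (
        np.arange(T)[None, :] <= d_idx[:, None]
    )  # (ncell, T)
    entry_mask = np.zeros((ncell, T))
    entry_mask[np.arange(ncell), e_idx] = 1.0

    weights = _cell_weights(theta_draws, T)  # (R, ncell)
    N = np.zeros((R, T))
    B = np.zeros((R, T))
    for f, l, cnt in zip(classes.f, classes.l, classes.counts):
        admissible = (e_idx <= f) & (d_idx >= l)
        pr = np.where(admissible, weights, 0.0)
        pr = pr / pr.sum(axis=1, keepdims=True)
        cells = rng.multinomial(int(cnt), pr)  # (R, ncell)
        N += cells @ alive_mask
        B += cells @ entry_mask
    if classes.n_zero:
        q = 1.0 - theta_draws[:, 2]
        psi = theta_draws[:, 0]
        pr1 = weights * q[:, None]
        total1 = psi * pr1.sum(axis=1)
        p_incl = total1 / ((1.0 - psi) + total1)
        n_incl = rng.binomial(classes.n_zero, p_incl)  # (R,)
        pr = pr1 / pr1.sum(axis=1, keepdims=True)
        cells = rng.multinomial(n_incl, pr)
        N += cells @ alive_mask
        B += cells @ entry_mask
    return N, B
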