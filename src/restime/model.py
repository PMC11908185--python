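"""Hyperexponential mixture model and its conjugate conditional posteriors.

The waiting-time density is a K-term exponential mixture

    p(t | pi, lambda) = sum_k pi_k lambda_k exp(-lambda_k t),

with a Dirichlet prior on the weights pi, independent Gamma priors on the
rates lambda_k, and a categorical latent indicator z_n attaching each
observed residence time t_n to one component.  Conjugacy gives closed-form
conditional posteriors: the weights remain Dirichlet with concentrations
gamma_k + Omega_k and each rate remains Gamma with shape alpha_k + Omega_k
and rate beta_k + T_k, where Omega_k counts the events assigned to
component k and T_k is their total duration.  The hyperparameters thus act
as pseudo-counts, which is why order-one values suffice for the event
counts (~1e4-1e5) this model is aimed at.

Setting gamma_k = 1/K approximates a Dirichlet-process prior for large K:
components not supported by the data keep negligible posterior weight, so
a finite K well above the expected number of processes behaves like an
infinite mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Hyperparameters",
    "MixtureState",
    "SufficientStats",
    "mixture_pdf",
    "mixture_survival",
    "indicator_probs",
    "sufficient_stats",
    "weights_posterior_params",
    "rate_posterior_params",
]

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True, eq=False)
class Hyperparameters:
    """Prior hyperparameters for a K-component mixture.

    alpha, beta parameterize the Gamma prior on each rate (shape, rate);
    beta carries units of ns (conjugate to a rate in 1/ns), so changing
    the time unit rescales beta.  gamma holds the Dirichlet
    concentrations of the weight prior.
    """

    K: int
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name in ("alpha", "beta", "gamma"):
            v = np.broadcast_to(np.asarray(getattr(self, name), float), (self.K,)).copy()
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
            object.__setattr__(self, name, v)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Hyperparameters) and self.K == other.K
                and np.array_equal(self.alpha, other.alpha)
                and np.array_equal(self.beta, other.beta)
                and np.array_equal(self.gamma, other.gamma))

    def __hash__(self) -> int:
        return hash((self.K, self.alpha.tobytes(), self.beta.tobytes(),
                     self.gamma.tobytes()))

    @classmethod
    def default(cls, K: int = 15, alpha: float = 1.0, beta: float = 3.0) -> "Hyperparameters":
        """Broad, diffuse priors: alpha=1, beta=3 ns, gamma_k=1/K."""
        return cls(K=K, alpha=np.full(K, alpha), beta=np.full(K, beta),
                   gamma=np.full(K, 1.0 / K))


@dataclass(frozen=True)
class MixtureState:
    """One point (pi, lambda) in the mixture parameter space."""

    weights: np.ndarray
    rates: np.ndarray  # 1/ns

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        lam = np.asarray(self.rates, float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "rates", lam)
        if w.shape != lam.shape or w.ndim != 1:
            raise ValueError("weights and rates must be 1-d and the same length")
        if abs(w.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("weights must sum to 1")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(lam <= 0):
            raise ValueError("rates must be positive")

    @property
    def K(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class SufficientStats:
    """Per-component event counts Omega_k and total durations T_k (ns)."""

    omega_k: np.ndarray
    t_k: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.omega_k, float)
        t = np.asarray(self.t_k, float)
        object.__setattr__(self, "omega_k", o)
        object.__setattr__(self, "t_k", t)
        if o.shape != t.shape:
            raise ValueError("omega_k and t_k must have the same shape")
        if np.any(t < 0) or np.any(o < 0):
            raise ValueError("sufficient statistics must be non-negative")
        if np.any((o == 0) & (t > 0)):
            raise ValueError("T_k must be 0 for empty components")


def mixture_pdf(t, state: MixtureState):
    """Density of the hyperexponential mixture at time(s) t (1/ns)."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.einsum(
        "k,k,...k->...",
        state.weights, state.rates,
        np.exp(-np.multiply.outer(t, state.rates)),
    )
    return out if out.ndim else float(out)


def mixture_survival(t, state: MixtureState):
    """Model survival probability S(t) = sum_k pi_k exp(-lambda_k t)."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.exp(-np.multiply.outer(t, state.rates)) @ state.weights
    return out if out.ndim else float(out)


def indicator_probs(t_n: float, state: MixtureState) -> np.ndarray:
    """Conditional posterior of the indicator for one event.

    p(z_n = k) is proportional to pi_k lambda_k exp(-lambda_k t_n).
    Computed in log space with a max shift so that large lambda_k * t_n
    (flicker components applied to long events) never underflows to an
    all-zero vector.
    """
    if t_n <= 0:
        raise ValueError("t_n must be positive")
    with np.errstate(divide="ignore"):
        logp = np.log(state.weights) + np.log(state.rates) - state.rates * t_n
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def sufficient_stats(z, t, K: int) -> SufficientStats:
    """Count events and accumulate durations per component.

    ``z`` holds 0-based component labels, one per event.
    """
    z = np.asarray(z)
    t = np.asarray(t, float)
    if z.shape != t.shape:
        raise ValueError("z and t must have the same length")
    if z.size and (z.min() < 0 or z.max() >= K):
        raise ValueError(f"indicator label out of range [0, {K})")
    omega_k = np.bincount(z, minlength=K).astype(float)
    t_k = np.bincount(z, weights=t, minlength=K)
    return SufficientStats(omega_k=omega_k, t_k=t_k)


def weights_posterior_params(stats: SufficientStats, hp: Hyperparameters) -> np.ndarray:
    """Dirichlet concentrations of the weights posterior: gamma_k + Omega_k."""
    if stats.omega_k.size != hp.K:
        raise ValueError("stats and hyperparameters disagree on K")
    return hp.gamma + stats.omega_k


def rate_posterior_params(k: int, stats: SufficientStats, hp: Hyperparameters) -> tuple:
    """(shape, rate) of the Gamma posterior for rate k.

    An empty component falls back to its prior (alpha_k, beta_k).
    """
    if not 0 <= k < hp.K:
        raise ValueError(f"component index {k} out of range [0, {hp.K})")
    return float(hp.alpha[k] + stats.omega_k[k]), float(hp.beta[k] + stats.t_k[k])
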