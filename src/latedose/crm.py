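"""Time-to-event continual reassessment method (one- and two-parameter).

Both variants weight each patient's binary DLT contribution by the
fraction of follow-up observed, ``w = u/S`` (``w = 1`` once a DLT is
seen), giving the working likelihood

    L = prod_i  (w_i F(d_i))^{y_i} (1 - w_i F(d_i))^{1 - y_i}.

The one-parameter model uses the power ("empiric") curve
``F(d, beta) = d^{exp(beta)}`` on a skeleton of prior per-dose guesses
with a N(0, sigma^2) prior on ``beta``; its posterior mean is obtained
by one-dimensional quadrature.  The two-parameter variant uses a
logistic curve in the physical dose, ``F(d) = expit(a0 + a1 d)`` with
normal priors on ``a0`` and ``log a1`` (so the fitted curve is always
increasing); its posterior is computed on a dense two-dimensional grid,
which for two parameters is exact to quadrature tolerance and fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .dataset import ToxDataset

__all__ = [
    "CrmPrior",
    "Crm2Prior",
    "titecrm_weight",
    "titecrm_fit",
    "titecrm_curve",
    "titecrm_next_dose",
    "titecrm_posterior_draws",
    "titecrm2_fit",
    "Crm2Posterior",
]

_BETA_GRID = np.linspace(-10.0, 10.0, 2001)


@dataclass(frozen=True)
class CrmPrior:
    """Skeleton (per-dose prior guesses) and prior variance of beta."""

    skeleton: tuple[float, ...]
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        sk = self.skeleton
        if any(not 0.0 < p < 1.0 for p in sk):
            raise ValueError("skeleton values must lie in (0, 1)")
        if any(b <= a for a, b in zip(sk, sk[1:])):
            raise ValueError("skeleton must be strictly increasing")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class Crm2Prior:
    """Normal priors on the logistic intercept a0 and log-slope log(a1)."""

    mu_a0: float = -1.0
    var_a0: float = 1.0 / 0.3
    mu_loga1: float = float(np.log(0.2))
    var_loga1: float = 1.0 / 0.3

    def __post_init__(self) -> None:
        if self.var_a0 <= 0 or self.var_loga1 <= 0:
            raise ValueError("prior variances must be positive")


def titecrm_weight(u: int, S: int, dlt: bool) -> float:
    """Follow-up weight u/S, or 1 once a DLT has been observed."""
    if not 0 <= u <= S:
        raise ValueError(f"cycles observed must lie in 0..{S}, got {u}")
    return 1.0 if dlt else u / S


def _weighted_data(data: ToxDataset, prior: CrmPrior, one_cycle: bool = False):
    """(skeleton value, weight, y) arrays; optionally restricted to cycle 1.

    The one-cycle restriction refits the same likelihood on cycle-1 data
    with S = 1: every patient with at least one observed cycle has
    weight 1 and the event is a DLT in cycle 1.
    """
    d, w, y = [], [], []
    for rec in data.records:
        if one_cycle:
            if rec.cycles_observed < 1:
                continue
            d.append(prior.skeleton[rec.dose])
            w.append(1.0)
            y.append(int(rec.dlt_cycle == 1))
        else:
            d.append(prior.skeleton[rec.dose])
            w.append(titecrm_weight(rec.cycles_observed, data.n_cycles, rec.dlt))
            y.append(int(rec.dlt))
    return np.array(d), np.array(w), np.array(y)


def _loglik_grid(beta, d, w, y):
    """Log-likelihood of the weighted one-parameter model on a beta grid."""
    if d.size == 0:
        return np.zeros_like(beta)
    expb = np.exp(beta)[:, None]
    F = np.power(d[None, :], expb)
    G = np.clip(w[None, :] * F, 1e-300, 1 - 1e-12)
    ll = y[None, :] * np.log(G) + (1 - y[None, :]) * np.log1p(-G)
    return ll.sum(axis=1)


def titecrm_fit(
    data: ToxDataset, prior: CrmPrior, one_cycle: bool = False
) -> float:
    """Posterior mean of beta by dense one-dimensional quadrature."""
    d, w, y = _weighted_data(data, prior, one_cycle)
    beta = _BETA_GRID
    logpost = _loglik_grid(beta, d, w, y) - 0.5 * beta**2 / prior.sigma2
    logpost -= logpost.max()
    weights = np.exp(logpost)
    return float(np.sum(beta * weights) / np.sum(weights))


def titecrm_curve(prior: CrmPrior, beta_hat: float) -> np.ndarray:
    """Fitted per-dose DLT probabilities ``skeleton ** exp(beta_hat)``."""
    return np.power(np.array(prior.skeleton), np.exp(beta_hat))


def titecrm_next_dose(
    beta_hat: float,
    prior: CrmPrior,
    tau: float,
    admissible,
) -> int | None:
    """Admissible dose minimizing |F(d_j, beta_hat) - tau|; ties go low."""
    admissible = np.asarray(admissible, dtype=bool)
    if not admissible.any():
        return None
    dist = np.abs(titecrm_curve(prior, beta_hat) - tau)
    dist = np.where(admissible, dist, np.inf)
    return int(np.argmin(dist))


def titecrm_posterior_draws(
    data: ToxDataset, prior: CrmPrior, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Posterior draws of beta from the quadrature grid."""
    d, w, y = _weighted_data(data, prior)
    logpost = _loglik_grid(_BETA_GRID, d, w, y) - 0.5 * _BETA_GRID**2 / prior.sigma2
    p = np.exp(logpost - logsumexp(logpost))
    p /= p.sum()
    return rng.choice(_BETA_GRID, size=n_draws, p=p)


def titecrm_tail_probability(
    data: ToxDataset, prior: CrmPrior, dose: int, tau_cycle1: float,
    one_cycle: bool = True, below: bool = False,
) -> float:
    """Posterior P(F(dose) > tau_cycle1) under the cycle-1-restricted fit.

    With ``below=True`` returns P(F(dose) <= tau_cycle1) instead.  Used
    by the lowest-dose-unsafe / highest-dose-safe stopping rules.
    """
    d, w, y = _weighted_data(data, prior, one_cycle=one_cycle)
    beta = _BETA_GRID
    logpost = _loglik_grid(beta, d, w, y) - 0.5 * beta**2 / prior.sigma2
    p = np.exp(logpost - logsumexp(logpost))
    p /= p.sum()
    F = np.power(prior.skeleton[dose], np.exp(beta))
    mask = F <= tau_cycle1 if below else F > tau_cycle1
    return float(p[mask].sum())


# ---------------------------------------------------------------------------
# Two-parameter logistic variant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Crm2Posterior:
    """Grid posterior summary of the two-parameter logistic model."""

    mean_a0: float
    mean_a1: float
    grid_a0: np.ndarray
    grid_loga1: np.ndarray
    weights: np.ndarray  # normalized joint posterior on the grid

    def curve(self, dose_values) -> np.ndarray:
        """Fitted DLT probabilities at the posterior means."""
        return expit(self.mean_a0 + self.mean_a1 * np.asarray(dose_values))

    def draws(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Joint draws of (a0, a1), shape (n_draws, 2)."""
        flat = self.weights.ravel()
        idx = rng.choice(flat.size, size=n_draws, p=flat)
        i0, i1 = np.unravel_index(idx, self.weights.shape)
        return np.column_stack(
            [self.grid_a0[i0], np.exp(self.grid_loga1[i1])]
        )

    def tail_probability(
        self, dose_value: float, tau_cycle1: float, below: bool = False
    ) -> float:
        F = expit(
            self.grid_a0[:, None] + np.exp(self.grid_loga1)[None, :] * dose_value
        )
        mask = F <= tau_cycle1 if below else F > tau_cycle1
        return float(self.weights[mask].sum())


def titecrm2_fit(
    data: ToxDataset,
    prior: Crm2Prior,
    one_cycle: bool = False,
    n_nodes: int = 121,
    half_width: float = 6.0,
) -> Crm2Posterior:
    """Grid posterior of (a0, log a1) for the weighted logistic model.

    The grid spans ``half_width`` prior standard deviations around each
    prior mean, which covers the posterior in this weakly informative
    setting; posterior means are grid expectations.
    """
    s0 = float(np.sqrt(prior.var_a0))
    s1 = float(np.sqrt(prior.var_loga1))
    a0 = np.linspace(prior.mu_a0 - half_width * s0, prior.mu_a0 + half_width * s0, n_nodes)
    la1 = np.linspace(
        prior.mu_loga1 - half_width * s1, prior.mu_loga1 + half_width * s1, n_nodes
    )
    logprior = (
        -0.5 * (a0[:, None] - prior.mu_a0) ** 2 / prior.var_a0
        - 0.5 * (la1[None, :] - prior.mu_loga1) ** 2 / prior.var_loga1
    )
    x, w, y = [], [], []
    for rec in data.records:
        if one_cycle:
            if rec.cycles_observed < 1:
                continue
            x.append(rec.dose_value)
            w.append(1.0)
            y.append(int(rec.dlt_cycle == 1))
        else:
            x.append(rec.dose_value)
            w.append(titecrm_weight(rec.cycles_observed, data.n_cycles, rec.dlt))
            y.append(int(rec.dlt))
    loglik = np.zeros_like(logprior)
    if x:
        xv = np.array(x)
        wv = np.array(w)
        yv = np.array(y)
        eta = a0[:, None, None] + np.exp(la1)[None, :, None] * xv[None, None, :]
        G = np.clip(wv * expit(eta), 1e-300, 1 - 1e-12)
        loglik = (yv * np.log(G) + (1 - yv) * np.log1p(-G)).sum(axis=2)
    logpost = logprior + loglik
    logpost -= logpost.max()
    weights = np.exp(logpost)
    weights /= weights.sum()
    mean_a0 = float(np.sum(weights * a0[:, None]))
    mean_a1 = float(np.sum(weights * np.exp(la1)[None, :]))
    return Crm2Posterior(mean_a0, mean_a1, a0, la1, weights)
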