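"""Interval-censored survival dose-finding (cloglog discrete-hazard model).

The conditional probability of a DLT in cycle ``s`` at dose ``d_j``
(given no earlier DLT) follows the complementary-log-log model

    log(-log(1 - pi_{j,s})) = gamma_s + theta * log d_j,

fitted by maximizing the interval-censored likelihood

    L = prod_{j,s} pi_{j,s}^{r_{j,s}} (1 - pi_{j,s})^{q_{j,s}},

where ``r`` counts DLTs in cycle ``s`` and ``q`` DLT-free completions of
cycle ``s``.  Prior information enters as fractional pseudo-patients on
the lowest and highest doses, anchored at cycle-1 rates ``pi_1*`` and
``pi_J*`` with per-cycle rates decreasing by scaling the cycle hazard
(``-log(1 - pi*_s) = -log(1 - pi*_1) * decay^{s-1}``), which is exactly
representable by the cloglog model, so the pseudo-data-only fit
reproduces the anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dataset import ToxDataset

__all__ = [
    "IcsdpPrior",
    "IcsdpFit",
    "icsdp_pseudo_data",
    "icsdp_fit",
    "icsdp_total_prob",
    "icsdp_next_dose",
]


@dataclass(frozen=True)
class IcsdpPrior:
    """Pseudo-data anchors: cycle-1 DLT rates at the extreme doses."""

    pi1: float  # anchor at the lowest dose
    piJ: float  # anchor at the highest dose
    n0: float  # pseudo-patients per anchor dose (non-integer allowed)
    decay: float = 1 / 3  # per-cycle hazard scaling of the anchors

    def __post_init__(self) -> None:
        if not 0.0 < self.pi1 <= self.piJ < 1.0:
            raise ValueError("require 0 < pi1 <= piJ < 1")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")


def _anchor_rate(pi1_cycle1: float, s: int, decay: float) -> float:
    """Conditional anchor rate in cycle s, hazard scaled by decay^(s-1)."""
    lam = -np.log1p(-pi1_cycle1)
    return float(-np.expm1(-lam * decay ** (s - 1)))


def icsdp_pseudo_data(
    prior: IcsdpPrior, n_doses: int, n_cycles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo event/survivor counts ``(r0, q0)`` of shape (J, S).

    ``n0`` pseudo-patients enter at each anchor dose; in cycle ``s`` the
    survivors of cycle ``s-1`` split into events at the decayed anchor
    rate and survivors.
    """
    r0 = np.zeros((n_doses, n_cycles))
    q0 = np.zeros((n_doses, n_cycles))
    for j, anchor in ((0, prior.pi1), (n_doses - 1, prior.piJ)):
        at_risk = prior.n0
        for s in range(1, n_cycles + 1):
            rate = _anchor_rate(anchor, s, prior.decay)
            r0[j, s - 1] = at_risk * rate
            q0[j, s - 1] = at_risk * (1.0 - rate)
            at_risk = q0[j, s - 1]
    return r0, q0


@dataclass(frozen=True)
class IcsdpFit:
    gamma: np.ndarray  # per-cycle intercepts
    theta: float  # log-dose slope
    cov: np.ndarray | None  # asymptotic covariance of (gamma..., theta)
    converged: bool
    dose_values: tuple[float, ...]
    n_cycles: int

    def conditional_probs(self, dose_values=None) -> np.ndarray:
        """pi[j, s] on the fitted model."""
        dv = np.asarray(dose_values if dose_values is not None else self.dose_values)
        eta = self.gamma[None, :] + self.theta * np.log(dv)[:, None]
        return -np.expm1(-np.exp(eta))

    def total_probs(self, dose_values=None) -> np.ndarray:
        """rho_j = P(DLT within S cycles) per dose."""
        pi = self.conditional_probs(dose_values)
        return 1.0 - np.prod(1.0 - pi, axis=1)

    def mtd_value(self, tau: float) -> float:
        """Continuous dose at which the fitted rho attains tau.

        rho(d) = 1 - exp(-d^theta * sum_s exp(gamma_s)) inverts in
        closed form.
        """
        total_haz = np.exp(self.gamma).sum()
        target = -np.log1p(-tau)
        return float((target / total_haz) ** (1.0 / self.theta))


def _nll(params, logd, r, q):
    gamma = params[:-1]
    theta = params[-1]
    eta = gamma[None, :] + theta * logd[:, None]
    eta = np.clip(eta, -30.0, 30.0)
    lam = np.exp(eta)
    log_surv = -lam  # log(1 - pi)
    log_pi = np.log(-np.expm1(-lam) + 1e-300)
    return -np.sum(r * log_pi + q * log_surv)


def icsdp_fit(
    data: ToxDataset | None,
    prior: IcsdpPrior,
    dose_values=None,
    n_cycles: int | None = None,
    previous: IcsdpFit | None = None,
) -> IcsdpFit:
    """Maximize the pseudo-data-augmented likelihood.

    On optimizer failure the previous fit is returned flagged as
    non-converged (the trial engine then retains the current dose).
    """
    if data is not None:
        dose_values = data.dose_values
        n_cycles = data.n_cycles
    dv = np.asarray(dose_values, dtype=float)
    S = int(n_cycles)
    r0, q0 = icsdp_pseudo_data(prior, dv.size, S)
    if data is not None:
        r_obs, q_obs = data.interval_counts()
        r, q = r0 + r_obs, q0 + q_obs
    else:
        r, q = r0, q0
    logd = np.log(dv)
    x0 = np.concatenate([np.full(S, np.log(-np.log(0.8))), [1.0]])
    res = optimize.minimize(_nll, x0, args=(logd, r, q), method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    # BFGS can report precision loss at a perfectly good optimum; accept
    # any finite solution with a near-zero gradient
    grad_ok = np.isfinite(res.fun) and float(
        np.max(np.abs(res.jac))
    ) < 1e-3 * (1.0 + abs(res.fun))
    converged = bool(res.success or grad_ok)
    if not converged and previous is not None:
        return IcsdpFit(previous.gamma, previous.theta, previous.cov,
                        False, tuple(dv), S)
    cov = None
    try:
        cov = np.asarray(res.hess_inv)
    except Exception:
        cov = None
    return IcsdpFit(res.x[:-1].copy(), float(res.x[-1]), cov,
                    converged, tuple(dv), S)


def icsdp_total_prob(conditional_probs) -> float:
    """Whole-follow-up DLT probability from per-cycle conditional rates."""
    pi = np.asarray(conditional_probs, dtype=float)
    return float(1.0 - np.prod(1.0 - pi))


def icsdp_next_dose(rho, tau: float, admissible) -> int | None:
    """Admissible dose maximizing the gain 1/(tau - rho)^2; ties go low.

    Maximizing the gain is equivalent to minimizing |tau - rho|, with an
    exact hit (infinite gain) selecting that dose.
    """
    rho = np.asarray(rho, dtype=float)
    admissible = np.asarray(admissible, dtype=bool)
    if not admissible.any():
        return None
    dist = np.where(admissible, np.abs(rho - tau), np.inf)
    return int(np.argmin(dist))
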