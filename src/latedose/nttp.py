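"""Quasi-continuous toxicity-score design (normalized total toxicity profile).

The per-cycle nTTP scores are modeled with a Bayesian linear mixed
model

    y_{i,s} = beta0 + beta1 * x_i + beta2 * s + gamma_i + eps_{i,s},

with dose value ``x_i``, patient effect ``gamma_i ~ N(0, sigma_g^2)``
and error ``eps ~ N(0, sigma_e^2)``.  Normal priors are placed on the
coefficients and IG(0.001, 0.001) priors on both variance components;
every full conditional is conjugate, so the posterior is sampled by a
Gibbs sampler.  Cycles after a DLT contribute nothing (the patient has
left the study); the DLT cycle contributes its observed score.

Dose selection minimizes the distance of the posterior mean cycle-1
score ``E[beta0 + beta1 d + beta2]`` from the cycle-1 score target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ToxDataset

__all__ = ["NttpPrior", "NttpPosterior", "nttp_fit", "nttp_next_dose"]


@dataclass(frozen=True)
class NttpPrior:
    mu_beta0: float = 0.1
    var_beta0: float = 100.0
    mu_beta1: float = 0.5
    var_beta1: float = 100.0
    mu_beta2: float = 0.0
    var_beta2: float = 10.0
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def __post_init__(self) -> None:
        if min(self.var_beta0, self.var_beta1, self.var_beta2) <= 0:
            raise ValueError("prior variances must be positive")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_beta0, self.mu_beta1, self.mu_beta2])

    @property
    def precision(self) -> np.ndarray:
        return np.diag(1.0 / np.array([self.var_beta0, self.var_beta1, self.var_beta2]))


@dataclass(frozen=True)
class NttpPosterior:
    """Posterior draws of (beta0, beta1, beta2, sigma_g^2, sigma_e^2)."""

    beta: np.ndarray  # (n_draws, 3)
    sigma_g2: np.ndarray
    sigma_e2: np.ndarray

    @property
    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    def cycle1_means(self, dose_values) -> np.ndarray:
        """Posterior mean cycle-1 score per dose."""
        b = self.beta_mean
        return b[0] + b[1] * np.asarray(dose_values, dtype=float) + b[2]

    def mtd_draws(self, tau_nttp: float, lo: float, hi: float) -> np.ndarray:
        """Per-draw continuous dose whose cycle-1 score equals the target.

        Draws with a non-positive dose slope carry no dose-toxicity
        signal and are returned as NaN.
        """
        b0, b1, b2 = self.beta[:, 0], self.beta[:, 1], self.beta[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (tau_nttp - b0 - b2) / b1
        d = np.where(b1 > 1e-8, d, np.nan)
        return np.clip(d, lo, hi)


def nttp_fit(
    data: ToxDataset,
    prior: NttpPrior,
    n_draws: int = 1000,
    n_burn: int = 500,
    seed: int = 0,
) -> NttpPosterior:
    """Gibbs sampler for the linear mixed model on observed scores."""
    rows_x, rows_s, rows_y, rows_pid = [], [], [], []
    pid_map: dict[int, int] = {}
    for rec in data.records:
        if rec.cycles_observed < 1:
            continue
        pid = pid_map.setdefault(rec.patient, len(pid_map))
        for s in range(1, rec.cycles_observed + 1):
            rows_x.append(rec.dose_value)
            rows_s.append(float(s))
            rows_y.append(rec.nttp[s - 1])
            rows_pid.append(pid)
    if not rows_y:
        raise ValueError("at least one observed cycle is required")
    X = np.column_stack([np.ones(len(rows_y)), np.array(rows_x), np.array(rows_s)])
    y = np.array(rows_y)
    pid = np.array(rows_pid)
    n_pat = len(pid_map)
    counts = np.bincount(pid, minlength=n_pat).astype(float)

    rng = np.random.default_rng(int(seed) % (2**31))
    beta = prior.mean.copy()
    gamma = np.zeros(n_pat)
    sig_g2, sig_e2 = 0.01, 0.01
    XtX = X.T @ X
    a0, b0v = prior.ig_shape, prior.ig_scale

    keep_beta = np.empty((n_draws, 3))
    keep_g2 = np.empty(n_draws)
    keep_e2 = np.empty(n_draws)
    for it in range(n_burn + n_draws):
        # coefficients
        resid_target = y - gamma[pid]
        prec = XtX / sig_e2 + prior.precision
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ resid_target / sig_e2 + prior.precision @ prior.mean)
        beta = rng.multivariate_normal(mean, cov, method="cholesky")
        # patient effects
        resid = y - X @ beta
        prec_g = counts / sig_e2 + 1.0 / sig_g2
        mean_g = np.bincount(pid, weights=resid, minlength=n_pat) / sig_e2 / prec_g
        gamma = mean_g + rng.standard_normal(n_pat) / np.sqrt(prec_g)
        # variance components
        sig_g2 = 1.0 / rng.gamma(a0 + n_pat / 2.0, 1.0 / (b0v + 0.5 * np.sum(gamma**2)))
        err = resid - gamma[pid]
        sig_e2 = 1.0 / rng.gamma(a0 + y.size / 2.0, 1.0 / (b0v + 0.5 * np.sum(err**2)))
        if it >= n_burn:
            keep_beta[it - n_burn] = beta
            keep_g2[it - n_burn] = sig_g2
            keep_e2[it - n_burn] = sig_e2
    return NttpPosterior(keep_beta, keep_g2, keep_e2)


def nttp_next_dose(cycle1_means, tau_nttp: float, admissible) -> int | None:
    """Admissible dose minimizing |E(nTTP, cycle 1) - target|; ties go low."""
    means = np.asarray(cycle1_means, dtype=float)
    admissible = np.asarray(admissible, dtype=bool)
    if not admissible.any():
        return None
    dist = np.where(admissible, np.abs(means - tau_nttp), np.inf)
    return int(np.argmin(dist))
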