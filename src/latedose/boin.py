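"""Bayesian optimal interval (BOIN) boundaries and the time-to-event rule.

The BOIN family escalates/de-escalates by comparing the estimated DLT
rate at the current dose with two fixed boundaries ``lambda_e < lambda_d``
derived from the target ``tau`` and the indifference interval
``(tau_1, tau_2)``.  The time-to-event variant makes decisions while some
patients' follow-up is incomplete by imputing each pending patient's
residual DLT risk from a Beta posterior weighted by observed follow-up
(standardized total follow-up time, STFT).  With no pending patients the
rule reduces exactly to the complete-data BOIN comparison of the
observed rate with the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["IntervalSpec", "BetaPrior", "Move", "boin_thresholds", "titeboin_decision"]


class Move(str, Enum):
    ESCALATE = "escalate"
    STAY = "stay"
    DEESCALATE = "de-escalate"
    SUSPEND = "suspend"


@dataclass(frozen=True)
class IntervalSpec:
    """Target DLT probability with its indifference interval."""

    tau: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tau1 < self.tau < self.tau2 < 1.0:
            raise ValueError(
                f"require 0 < tau1 < tau < tau2 < 1, got "
                f"({self.tau1}, {self.tau}, {self.tau2})"
            )

    @classmethod
    def from_epsilons(cls, tau: float, eps1: float, eps2: float) -> "IntervalSpec":
        return cls(tau, tau - eps1, tau + eps2)

    @property
    def eps1(self) -> float:
        return self.tau - self.tau1

    @property
    def eps2(self) -> float:
        return self.tau2 - self.tau


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on the DLT probability at a dose."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta prior shapes must be positive")


def boin_thresholds(interval: IntervalSpec) -> tuple[float, float]:
    """Closed-form BOIN escalation/de-escalation boundaries.

    ``lambda_e`` is the likelihood-ratio boundary between ``tau_1`` and
    ``tau``; ``lambda_d`` between ``tau`` and ``tau_2``:

        lambda_e = log((1-tau1)/(1-tau)) / log(tau (1-tau1) / (tau1 (1-tau)))
        lambda_d = log((1-tau)/(1-tau2)) / log(tau2 (1-tau) / (tau (1-tau2)))
    """
    t, t1, t2 = interval.tau, interval.tau1, interval.tau2
    lam_e = np.log((1 - t1) / (1 - t)) / np.log(t * (1 - t1) / (t1 * (1 - t)))
    lam_d = np.log((1 - t) / (1 - t2)) / np.log(t2 * (1 - t) / (t * (1 - t2)))
    return float(lam_e), float(lam_d)


def titeboin_decision(
    summary: dict,
    thresholds: tuple[float, float],
    prior: BetaPrior,
    n_cycles: int = 3,
) -> Move:
    """Escalation move at the current dose given an interim summary.

    Parameters
    ----------
    summary
        Mapping with keys ``n`` (treated), ``dlt`` (observed DLTs),
        ``complete`` (DLT-free with full follow-up), ``pending``
        (DLT-free, incomplete) and ``stft`` (summed follow-up fraction of
        the pending patients), as produced by
        :meth:`latedose.dataset.ToxDataset.pending_summary`.
    thresholds
        ``(lambda_e, lambda_d)`` from :func:`boin_thresholds`.
    prior
        Beta prior used for the pending-outcome imputation.

    Notes
    -----
    Observed DLTs alone can force de-escalation (``m/n >= lambda_d``)
    regardless of pending data.  Otherwise each pending patient with
    follow-up fraction ``w`` contributes an imputed residual DLT
    probability ``p(1-w) / (1 - p w)`` (a uniform-within-follow-up
    hazard), with ``p`` the Beta posterior mean under follow-up
    weighting, and the imputed rate is compared with the boundaries.
    A dose with no observed information suspends accrual.
    """
    lam_e, lam_d = thresholds
    n, m = summary["n"], summary["dlt"]
    c, pend, stft = summary["complete"], summary["pending"], summary["stft"]
    if n <= 0:
        raise ValueError("decision requires at least one treated patient")
    if m / n >= lam_d:
        return Move.DEESCALATE
    if pend == 0:
        rate = m / n
    else:
        exposure = m + c + stft
        if exposure <= 0.0:
            return Move.SUSPEND
        p_hat = (prior.alpha + m) / (prior.alpha + prior.beta + exposure)
        # imputed residual risk for pending patients (mean follow-up fraction)
        w = stft / pend
        imputed = pend * p_hat * (1.0 - w) / (1.0 - p_hat * w)
        rate = (m + imputed) / n
    if rate <= lam_e:
        return Move.ESCALATE
    if rate >= lam_d:
        return Move.DEESCALATE
    return Move.STAY
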