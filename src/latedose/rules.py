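"""Enforcement and stopping rules for the simulated dose-finding trials.

Two rule settings are supported.  Setting 1 activates only the k-fold
dose-rise enforcement, the sufficient-information stop and the
maximum-patients stop; setting 2 additionally activates the hard-safety
exclusion, the lowest-dose-unsafe / highest-dose-safe posterior stops
and the precision (CV of the MTD) stop.  All probability comparisons use
strict inequalities, so boundary equality never triggers a rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import ToxDataset

__all__ = [
    "RuleConfig",
    "hard_safety_boundary",
    "apply_hard_safety",
    "k_fold_check",
    "sufficient_information_stop",
    "safety_posterior_stop",
    "precision_stop",
]

#: MAD-to-standard-deviation consistency constant for a normal sample.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and counts of the enforcement/stopping rules."""

    setting: int = 1
    tau_cycle1: float = 0.3
    hard_safety_threshold: float = 0.95
    posterior_threshold: float = 0.80
    k_fold: float = 2.0
    sufficient_information_n: int = 9
    precision_cv: float = 0.30
    precision_activation_n: int = 9
    max_patients: int = 30

    def __post_init__(self) -> None:
        if self.setting not in (1, 2):
            raise ValueError("setting must be 1 or 2")
        for thr in (self.hard_safety_threshold, self.posterior_threshold):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if min(self.sufficient_information_n, self.precision_activation_n,
               self.max_patients) <= 0:
            raise ValueError("rule counts must be positive")

    @property
    def hard_safety_active(self) -> bool:
        return self.setting == 2

    @property
    def posterior_stops_active(self) -> bool:
        return self.setting == 2

    @property
    def precision_active(self) -> bool:
        return self.setting == 2


def hard_safety_boundary(
    n: int, tau_cycle1: float = 0.3, threshold: float = 0.95
) -> int | None:
    """Minimal cycle-1 DLT count that excludes a dose with ``n`` observed.

    Under a Beta(1, 1) prior, the smallest ``r <= n`` such that
    ``P(p1 > tau_cycle1 | r of n) > threshold``; None when no count
    qualifies.  For ``tau_cycle1=0.3`` and threshold 0.95 this yields the
    familiar 3/3, 4/6, 5/9 exclusion triples.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    for r in range(n + 1):
        if stats.beta.sf(tau_cycle1, 1 + r, 1 + n - r) > threshold:
            return r
    return None


def apply_hard_safety(data: ToxDataset, config: RuleConfig) -> set[int]:
    """Doses (0-based) excluded by the hard-safety rule, upward-closed.

    A dose whose cycle-1 DLT count reaches the Beta-posterior boundary is
    excluded along with every higher dose.
    """
    n, dlt = data.cycle1_counts()
    excluded: set[int] = set()
    for j in range(data.n_doses):
        bound = hard_safety_boundary(
            int(n[j]), config.tau_cycle1, config.hard_safety_threshold
        )
        if bound is not None and dlt[j] >= bound:
            excluded.update(range(j, data.n_doses))
            break
    return excluded


def k_fold_check(
    proposed_value: float, highest_tried_value: float, k: float = 2.0
) -> bool:
    """True when the proposed dose is within a k-fold rise of the highest tried."""
    return proposed_value <= k * highest_tried_value + 1e-12


def sufficient_information_stop(n_treated_at_recommended: int, limit: int = 9) -> bool:
    """Stop when the recommended dose already carries ``limit`` patients."""
    return n_treated_at_recommended >= limit


def safety_posterior_stop(
    prob_lowest_unsafe: float | None,
    prob_highest_safe: float | None,
    config: RuleConfig,
    lowest_has_cohort: bool,
    highest_has_cohort: bool,
) -> tuple[bool, bool]:
    """(lowest-dose-unsafe, highest-dose-safe) stop flags.

    The probabilities are the design-family one-cycle model's posterior
    ``P(p1 > tau_cycle1)`` at the lowest dose and ``P(p1 <= tau_cycle1)``
    at the highest dose; a flag is inactive until a full cohort has been
    assigned to the respective dose.
    """
    low = (
        lowest_has_cohort
        and prob_lowest_unsafe is not None
        and prob_lowest_unsafe > config.posterior_threshold
    )
    high = (
        highest_has_cohort
        and prob_highest_safe is not None
        and prob_highest_safe > config.posterior_threshold
    )
    return bool(low), bool(high)


def precision_stop(
    mtd_draws, config: RuleConfig, n_with_one_cycle: int
) -> bool:
    """Stop when the MTD posterior is precisely located.

    CV = 1.4826 * MAD(draws) / median(draws) on the physical dose scale;
    the rule activates once ``precision_activation_n`` patients have at
    least one observed cycle and never fires on a non-positive median.
    """
    if n_with_one_cycle < config.precision_activation_n:
        return False
    draws = np.asarray(mtd_draws, dtype=float)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        return False
    med = float(np.median(draws))
    if med <= 0:
        return False
    mad = float(np.median(np.abs(draws - med)))
    cv = MAD_SCALE * mad / med
    return cv < config.precision_cv
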