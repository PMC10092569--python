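"""Isotonic-regression final MTD selection for the interval designs.

After all follow-up has completed, per-dose posterior mean DLT
probabilities are smoothed by a monotone (pool-adjacent-violators) fit
weighted by the number treated, and the treated, admissible dose whose
isotonic estimate is closest to the target is recommended; ties break
toward the lower dose.
"""

from __future__ import annotations

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .boin import BetaPrior

__all__ = ["pava", "isotonic_mtd"]


def pava(values, weights) -> np.ndarray:
    """Weighted isotonic (non-decreasing) least-squares fit."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    x = np.arange(values.size)
    iso = IsotonicRegression(increasing=True)
    return iso.fit_transform(x, values, sample_weight=weights)


def isotonic_mtd(
    n_treated,
    n_dlt,
    prior: BetaPrior,
    tau: float,
    admissible=None,
    tie: str = "directional",
) -> int | None:
    """Final recommended 0-based dose index, or None.

    Only doses with at least one treated patient participate in the
    isotonic fit; the recommendation is restricted to the treated,
    admissible doses.  Exact ties in the distance to the target are
    common because pooled isotonic estimates coincide; the default
    directional rule (as in the cited interval designs' selection)
    takes the highest tied dose when the tied estimates sit below the
    target and the lowest otherwise, while ``tie="lower"`` always takes
    the lowest tied dose.
    """
    n_treated = np.asarray(n_treated, dtype=float)
    n_dlt = np.asarray(n_dlt, dtype=float)
    treated = n_treated > 0
    if admissible is None:
        admissible = np.ones_like(treated, dtype=bool)
    else:
        admissible = np.asarray(admissible, dtype=bool)
    candidates = treated & admissible
    if not candidates.any():
        return None
    post_mean = (prior.alpha + n_dlt[treated]) / (
        prior.alpha + prior.beta + n_treated[treated]
    )
    iso = pava(post_mean, n_treated[treated])
    est = np.full(n_treated.size, np.nan)
    est[treated] = iso
    dist = np.where(candidates, np.abs(est - tau), np.inf)
    best = float(dist.min())
    tied = np.flatnonzero(np.abs(dist - best) <= 1e-12)
    if tie == "lower" or tied.size == 1:
        return int(tied[0])
    below = est[tied] < tau
    if below.all():
        return int(tied[-1])
    return int(tied[0])
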