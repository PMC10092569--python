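"""Keyboard (mTPI2-type) interval decisions and the rolling variant.

The unit interval is tiled with keys of width ``eps1 + eps2`` anchored at
the target key ``[tau1, tau2)``; keys extend outward from the target key
and the two end keys absorb the remainders.  The key with the largest
posterior Beta mass determines the move: a strongest key below the
target key escalates, the target key stays, and a strongest key above
de-escalates.

The time-to-event variant evaluates the same rule on "effective"
binomial data in which DLT-free patients with incomplete follow-up
contribute fractionally (their observed follow-up fraction ``u/S``),
while DLTs always count fully.  The rolling variant (R-mTPI2) instead
applies a rule cascade on complete observations and best/worst-case
imputations of the pending outcomes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .boin import BetaPrior, IntervalSpec, Move

__all__ = [
    "key_edges",
    "keyboard_effective_counts",
    "keyboard_decision",
    "rmtpi2_decision",
]


def key_edges(interval: IntervalSpec) -> tuple[np.ndarray, int]:
    """Edges of the keys tiling [0, 1] and the index of the target key.

    Keys of width ``tau2 - tau1`` are laid outward from the target key
    ``[tau1, tau2)``; partial keys at the ends absorb the remainders.
    """
    width = interval.tau2 - interval.tau1
    lower = [interval.tau1]
    while lower[-1] - width > 1e-12:
        lower.append(lower[-1] - width)
    upper = [interval.tau2]
    while upper[-1] + width < 1.0 - 1e-12:
        upper.append(upper[-1] + width)
    edges = np.array([0.0] + sorted(lower) + sorted(upper) + [1.0])
    edges = np.unique(np.clip(edges, 0.0, 1.0))
    target = int(np.searchsorted(edges, interval.tau1, side="left"))
    return edges, target


def keyboard_effective_counts(summary: dict, n_cycles: int = 3) -> tuple[float, float]:
    """Effective (n, events) at a dose from an interim summary.

    Completed patients and DLTs count fully; each pending DLT-free
    patient contributes their follow-up fraction to the effective sample
    size and nothing to the events.
    """
    n_eff = summary["dlt"] + summary["complete"] + summary["stft"]
    return float(n_eff), float(summary["dlt"])


def keyboard_decision(
    n_eff: float, events: float, prior: BetaPrior, interval: IntervalSpec
) -> Move:
    """Move from the posterior key masses under Beta(alpha+y, beta+n-y)."""
    if n_eff <= 0:
        raise ValueError("decision requires positive effective sample size")
    if events < 0 or events > n_eff + 1e-9:
        raise ValueError("events must lie in [0, n_eff]")
    a = prior.alpha + events
    b = prior.beta + max(n_eff - events, 0.0)
    edges, target = key_edges(interval)
    cdf = stats.beta.cdf(edges, a, b)
    masses = np.diff(cdf)
    strongest = int(np.argmax(masses))
    if strongest < target:
        return Move.ESCALATE
    if strongest == target:
        return Move.STAY
    return Move.DEESCALATE


def rmtpi2_decision(
    summary: dict,
    prior: BetaPrior,
    interval: IntervalSpec,
    consecutive_at_dose: int = 0,
    consecutive_limit: int = 6,
) -> Move:
    """Rolling keyboard rule cascade at the current dose.

    1. With no pending patients the move is the plain keyboard decision
       on the complete counts.
    2. Observed DLTs alone force de-escalation when even the best case
       (all pending patients DLT-free) de-escalates.
    3. If the best-case and worst-case imputations (pending all
       non-DLT / all DLT) agree, that move is taken.
    4. Otherwise enrollment may continue at the current dose while fewer
       than ``consecutive_limit`` patients have been assigned to it
       consecutively without interruption; beyond that, accrual is
       suspended until more follow-up accumulates.  The limit is a
       configurable rule constant.
    """
    n, m, pend = summary["n"], summary["dlt"], summary["pending"]
    if pend == 0:
        return keyboard_decision(float(n), float(m), prior, interval)
    best = keyboard_decision(float(n), float(m), prior, interval)
    worst = keyboard_decision(float(n), float(m + pend), prior, interval)
    if best == worst:
        return best
    if best == Move.DEESCALATE:
        return Move.DEESCALATE
    if consecutive_at_dose < consecutive_limit:
        return Move.STAY
    return Move.SUSPEND
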