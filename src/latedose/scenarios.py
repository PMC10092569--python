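"""Toxicity scenarios for multi-cycle dose-finding simulations.

A scenario is defined by the per-dose probability of a dose-limiting
toxicity (DLT) in the first treatment cycle, together with a per-cycle
hazard decay factor.  The conditional probability of a DLT in cycle ``s``
(given no DLT earlier) is ``p1 * decay**(s-1)``, reflecting a risk that
decreases over successive cycles of the same treatment.  The cumulative
DLT probability through cycle ``s`` is therefore

    p_s = 1 - prod_{k<=s} (1 - p1 * decay**(k-1)).

With ``p1 = 0.3`` and ``decay = 1/3`` over three cycles this gives the
whole-follow-up probability ``p3 = 0.391``, which is the default target
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ScenarioSpec",
    "cumulative_dlt_probability",
    "DEFAULT_DOSE_VALUES",
    "builtin_scenario",
    "BUILTIN_SCENARIOS",
]

#: Dose grid of the motivating radiopharmaceutical trial, in MBq.
DEFAULT_DOSE_VALUES: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5, 6.0, 7.0)


def cumulative_dlt_probability(p1: float, s: int, decay: float = 1 / 3) -> float:
    """Cumulative probability of DLT in cycles 1..s.

    Parameters
    ----------
    p1
        Probability of a DLT in cycle 1, in [0, 1].
    s
        Cycle index (1-based); ``s=1`` returns ``p1``.
    decay
        Multiplicative per-cycle decay of the conditional DLT hazard.

    Returns
    -------
    float
        ``p_s``, non-decreasing in ``s`` and bounded by 1.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"p1 must be a probability, got {p1!r}")
    if s < 1:
        raise ValueError(f"cycle index must be >= 1, got {s!r}")
    if decay < 0:
        raise ValueError(f"decay must be non-negative, got {decay!r}")
    surv = 1.0
    for k in range(1, int(s) + 1):
        surv *= 1.0 - p1 * decay ** (k - 1)
    return 1.0 - surv


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth of a simulated trial.

    Attributes
    ----------
    dose_values
        Strictly increasing physical dose quantities (MBq).
    p1
        Per-dose probability of DLT in cycle 1.
    decay
        Per-cycle conditional-hazard decay factor.
    n_cycles
        Number of follow-up cycles ``S``.
    name
        Optional label.
    truth
        Label of the correct trial outcome: a 1-based MTD dose index,
        ``"all_unsafe"`` (correct outcome is stopping for safety) or
        ``"all_safe"`` (correct outcome is stopping because the highest
        dose is clearly below target).
    """

    dose_values: tuple[float, ...]
    p1: tuple[float, ...]
    decay: float = 1 / 3
    n_cycles: int = 3
    name: str = ""
    truth: int | str | None = None

    def __post_init__(self) -> None:
        dv = tuple(float(d) for d in self.dose_values)
        p1 = tuple(float(p) for p in self.p1)
        object.__setattr__(self, "dose_values", dv)
        object.__setattr__(self, "p1", p1)
        if len(dv) != len(p1):
            raise ValueError("dose_values and p1 must have equal length")
        if any(d2 <= d1 for d1, d2 in zip(dv, dv[1:])):
            raise ValueError("dose_values must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in p1):
            raise ValueError("p1 entries must be probabilities")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def n_doses(self) -> int:
        return len(self.dose_values)

    def cumulative(self, dose: int) -> np.ndarray:
        """Cumulative DLT probabilities ``(p_1, ..., p_S)`` at 0-based dose."""
        return np.array(
            [
                cumulative_dlt_probability(self.p1[dose], s, self.decay)
                for s in range(1, self.n_cycles + 1)
            ]
        )

    def total_dlt_probability(self, dose: int) -> float:
        """Whole-follow-up DLT probability ``p_S`` at 0-based dose index."""
        return cumulative_dlt_probability(self.p1[dose], self.n_cycles, self.decay)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dose_values": list(self.dose_values),
            "p1": list(self.p1),
            "decay": self.decay,
            "n_cycles": self.n_cycles,
            "truth": self.truth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            dose_values=tuple(d["dose_values"]),
            p1=tuple(d["p1"]),
            decay=float(d.get("decay", 1 / 3)),
            n_cycles=int(d.get("n_cycles", 3)),
            name=str(d.get("name", "")),
            truth=d.get("truth"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sc(name: str, p1: Sequence[float], truth) -> ScenarioSpec:
    return ScenarioSpec(
        dose_values=DEFAULT_DOSE_VALUES, p1=tuple(p1), name=name, truth=truth
    )


#: Library of scenarios.  Scenario D and the calibration scenarios
#: (P.S.1-P.S.6) follow the published study configuration; scenarios A, B,
#: C, E and F are synthetic stand-ins matching the described qualitative
#: shapes (the study reports them only graphically).
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    # lowest dose on target, linear increase
    "A": _sc("A", (0.30, 0.35, 0.40, 0.45, 0.50, 0.55), truth=1),
    # fourth dose on target, nonlinear increase (synthetic stand-in)
    "B": _sc("B", (0.10, 0.15, 0.25, 0.30, 0.35, 0.55), truth=4),
    # all doses unsafe (synthetic stand-in)
    "C": _sc("C", (0.40, 0.45, 0.50, 0.55, 0.60, 0.65), truth="all_unsafe"),
    # cliff: three safe doses then three very unsafe doses
    "D": _sc("D", (0.05, 0.05, 0.05, 0.80, 0.80, 0.80), truth=3),
    # calibration scenarios
    "P.S.1": _sc("P.S.1", (0.300, 0.400, 0.450, 0.500, 0.550, 0.600), truth=1),
    "P.S.2": _sc("P.S.2", (0.050, 0.070, 0.100, 0.150, 0.200, 0.300), truth=6),
    "P.S.3": _sc("P.S.3", (0.100, 0.200, 0.300, 0.400, 0.500, 0.600), truth=3),
    "P.S.4": _sc("P.S.4", (0.150, 0.200, 0.250, 0.300, 0.350, 0.400), truth=4),
    "P.S.5": _sc("P.S.5", (0.400, 0.450, 0.500, 0.550, 0.600, 0.650), truth="all_unsafe"),
    "P.S.6": _sc("P.S.6", (0.070, 0.090, 0.110, 0.130, 0.150, 0.170), truth="all_safe"),
}


def builtin_scenario(name: str) -> ScenarioSpec:
    """Look up a scenario from the built-in library by name."""
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(BUILTIN_SCENARIOS)}"
        ) from None
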