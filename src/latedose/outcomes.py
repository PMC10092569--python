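"""Latent-variable generation of per-cycle toxicity outcomes.

Each simulated patient carries a single latent toxicity variable
``z ~ Uniform(0, 1)`` that determines their outcome on *every* dose and
cycle.  Writing ``v = 1 - z``, the patient experiences a DLT in cycle
``s`` on a given dose exactly when ``p_{s-1} < v <= p_s``, where ``p_s``
is the cumulative DLT probability of that dose through cycle ``s``
(half-open-interval convention, so every ``v <= p_S`` maps to exactly one
DLT cycle).  Smaller ``v`` means a more toxic outcome, so the same
patient is weakly more toxic on higher doses whenever ``p1`` is monotone
in dose.

The maximum observed grade per cycle is likewise a deterministic
function of ``z``: the survivor region of ``v`` is partitioned into
grade bands with masses given by :func:`cycle1_grade_distribution`
(cycle 1) and its survivor-scaled analogue in later cycles, ordered so
that larger ``v`` maps to a lower grade.  A cycle in which a DLT occurs
receives grade 4 in the lower half of its DLT band and grade 3 in the
upper half, matching the equal split of the grade-3 and grade-4 masses.

Three toxicity types (renal, hematological, neurological) with grades
0-4 give 125 grade/type combinations; conditional on the maximum grade,
the combination is uniform over all combinations attaining that maximum,
selected by an auxiliary uniform that is independent of ``z``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .scenarios import ScenarioSpec

__all__ = [
    "GradeDistribution",
    "cycle1_grade_distribution",
    "later_cycle_grade_masses",
    "dlt_cycle",
    "grade_type_combination",
    "combinations_with_max_grade",
    "NttpWeights",
    "load_default_weights",
    "nttp_value",
    "expected_cycle1_nttp",
    "PatientOutcome",
    "simulate_patient",
    "patient_streams",
]

N_TYPES = 3
N_GRADES = 5  # grades 0..4


@dataclass(frozen=True)
class GradeDistribution:
    """Masses of each maximum grade 0..4 for one cycle (may be sub-stochastic)."""

    mass: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if any(m < -1e-12 for m in self.mass):
            raise ValueError("grade masses must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.mass))

    def __getitem__(self, g: int) -> float:
        return self.mass[g]


def cycle1_grade_distribution(p1: float) -> GradeDistribution:
    """Distribution of the maximum observed grade in cycle 1.

    The construction ties the grade distribution to the cycle-1 DLT
    probability ``p1``: grades 3 and 4 (the DLT grades) each receive mass
    ``p1/2``, and the sub-DLT grades fill the remainder piecewise so that
    low grades vanish as ``p1`` grows.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"p1 must be a probability, got {p1!r}")
    g4 = g3 = p1 / 2.0
    g2 = (1.0 - p1) if p1 > 0.5 else p1
    if 0.4 < p1 < 0.5:
        g1 = 1.0 - 2.0 * p1
    elif p1 <= 0.4:
        g1 = p1 / 2.0
    else:
        g1 = 0.0
    g0 = (1.0 - 2.5 * p1) if p1 <= 0.4 else 0.0
    return GradeDistribution((g0, g1, g2, g3, g4))


def later_cycle_grade_masses(
    p1: float, s: int, decay: float = 1 / 3
) -> GradeDistribution:
    """Sub-stochastic grade masses for cycle ``s`` >= 2.

    Cycle-1 masses are scaled by the survivor fraction ``1 - p_{s-1}``;
    the total mass is the probability of still being on study at the
    start of cycle ``s``.
    """
    from .scenarios import cumulative_dlt_probability

    if s < 2:
        raise ValueError("use cycle1_grade_distribution for s=1")
    base = cycle1_grade_distribution(p1)
    surv = 1.0 - cumulative_dlt_probability(p1, s - 1, decay)
    return GradeDistribution(tuple(surv * m for m in base.mass))


def dlt_cycle(latent: float, scenario: ScenarioSpec, dose: int) -> int | None:
    """Cycle (1-based) in which the patient experiences a DLT, or None.

    Uses the half-open convention ``p_{s-1} < 1-z <= p_s``.
    """
    if not 0.0 < latent < 1.0:
        raise ValueError(f"latent must lie in (0, 1), got {latent!r}")
    v = 1.0 - latent
    p = scenario.cumulative(dose)
    if v > p[-1]:
        return None
    # first s with v <= p_s
    return int(np.searchsorted(p, v, side="left")) + 1


def _combo_table() -> list[list[tuple[int, int, int]]]:
    by_max: list[list[tuple[int, int, int]]] = [[] for _ in range(N_GRADES)]
    for a in range(N_GRADES):
        for b in range(N_GRADES):
            for c in range(N_GRADES):
                by_max[max(a, b, c)].append((a, b, c))
    return by_max


#: combinations of (renal, hematological, neurological) grades grouped by
#: maximum grade, in lexicographic order (deterministic indexing).
_COMBOS_BY_MAX = _combo_table()


def combinations_with_max_grade(g: int) -> list[tuple[int, int, int]]:
    """All grade triples whose maximum is exactly ``g``."""
    return list(_COMBOS_BY_MAX[g])


def grade_type_combination(max_grade: int, aux_uniform: float) -> tuple[int, int, int]:
    """Grade triple with the given maximum, uniform over such triples.

    ``aux_uniform`` in [0, 1) indexes the lexicographically ordered list
    of combinations whose maximum grade is exactly ``max_grade``.
    """
    combos = _COMBOS_BY_MAX[max_grade]
    idx = min(int(aux_uniform * len(combos)), len(combos) - 1)
    return combos[idx]


# ---------------------------------------------------------------------------
# nTTP: normalized total toxicity profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NttpWeights:
    """Severity weights per toxicity type and grade, with a normalizer.

    ``matrix`` has one row per type (renal, hematological, neurological)
    and one column per grade 0..4.  The nTTP of a grade triple is the
    Euclidean norm of the selected weights divided by ``normalizer``;
    with the default normalizer (the norm of the worst row-wise weights)
    the score lies in [0, 1].
    """

    matrix: tuple[tuple[float, ...], ...]
    normalizer: float

    def __post_init__(self) -> None:
        if len(self.matrix) != N_TYPES or any(len(r) != N_GRADES for r in self.matrix):
            raise ValueError("weight matrix must be 3 types x 5 grades")
        for row in self.matrix:
            if any(b < a for a, b in zip(row, row[1:])):
                raise ValueError("weights must be non-decreasing in grade")
        if self.normalizer <= 0:
            raise ValueError("normalizer must be positive")

    @classmethod
    def from_matrix(cls, matrix: Sequence[Sequence[float]]) -> "NttpWeights":
        m = tuple(tuple(float(x) for x in row) for row in matrix)
        norm = float(np.sqrt(sum(max(row) ** 2 for row in m)))
        return cls(m, norm)

    @classmethod
    def from_csv(cls, path, normalizer: float | None = None) -> "NttpWeights":
        with open(path) as fh:
            rows = list(csv.reader(fh))
        body = [r for r in rows[1:] if r]
        matrix = [[float(x) for x in r[1:6]] for r in body[:N_TYPES]]
        if normalizer is None:
            return cls.from_matrix(matrix)
        return cls(tuple(tuple(r) for r in matrix), float(normalizer))


def load_default_weights() -> NttpWeights:
    """Package-default severity weights (shipped as a small CSV)."""
    path = resources.files("latedose").joinpath("data/nttp_weights.csv")
    with resources.as_file(path) as p:
        return NttpWeights.from_csv(p)


def nttp_value(grade_triple: Sequence[int], weights: NttpWeights) -> float:
    """Normalized total toxicity profile of one cycle's grade triple."""
    if weights is None:
        raise ValueError("an nTTP weight table must be configured")
    if len(grade_triple) != N_TYPES:
        raise ValueError("expected one grade per toxicity type")
    ssq = 0.0
    for t, g in enumerate(grade_triple):
        if not 0 <= g <= 4:
            raise ValueError(f"grades must lie in 0..4, got {g!r}")
        ssq += weights.matrix[t][g] ** 2
    return float(np.sqrt(ssq) / weights.normalizer)


def expected_cycle1_nttp(p1: float, weights: NttpWeights) -> float:
    """Expected cycle-1 nTTP at a dose with cycle-1 DLT probability ``p1``.

    Averages the uniform-within-maximum-grade combination mechanism
    against the cycle-1 maximum-grade distribution.  Used to derive the
    default nTTP target from the cycle-1 DLT target.
    """
    dist = cycle1_grade_distribution(p1)
    total = 0.0
    for g in range(N_GRADES):
        combos = _COMBOS_BY_MAX[g]
        mean_g = float(np.mean([nttp_value(c, weights) for c in combos]))
        total += dist[g] * mean_g
    return total


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientOutcome:
    """Realized outcomes of one patient on one dose.

    ``dlt_cycle`` is 1-based or None; lists cover only the cycles the
    patient remains on study (outcomes are undefined after a DLT).
    """

    latent: float
    dose: int
    dlt_cycle: int | None
    max_grades: tuple[int, ...]
    grade_triples: tuple[tuple[int, int, int], ...]
    nttp: tuple[float, ...]

    @property
    def cycles_on_study(self) -> int:
        return len(self.max_grades)

    def dlt_by(self, cycles_observed: int) -> bool:
        return self.dlt_cycle is not None and self.dlt_cycle <= cycles_observed


def _max_grade_for_cycle(
    v: float, p_prev: float, p_cur: float, base: GradeDistribution, had_dlt: bool
) -> int:
    """Maximum grade in a cycle, deterministically from ``v = 1 - z``.

    DLT cycle: grade 4 in the lower half of the band ``(p_prev, p_cur]``,
    grade 3 above (matching the equal grade-3/4 masses).  Non-DLT cycle:
    the survivor region ``(p_cur, 1]`` is split among grades 2, 1, 0 in
    proportion to the cycle-1 masses, with larger ``v`` giving a lower
    grade.
    """
    if had_dlt:
        mid = p_prev + 0.5 * (p_cur - p_prev)
        return 4 if v <= mid else 3
    width = 1.0 - p_cur
    if width <= 0.0:
        return 2
    sub = base[0] + base[1] + base[2]
    if sub <= 0.0:
        return 2
    # thresholds measured downwards from v = 1
    t0 = 1.0 - width * base[0] / sub
    t1 = 1.0 - width * (base[0] + base[1]) / sub
    if v > t0:
        return 0
    if v > t1:
        return 1
    return 2


def simulate_patient(
    latent: float,
    aux_uniforms: Sequence[float],
    scenario: ScenarioSpec,
    dose: int,
    weights: NttpWeights | None = None,
) -> PatientOutcome:
    """Full per-cycle outcome of a patient with latent ``z`` on a dose.

    ``aux_uniforms`` supplies one uniform per cycle for the grade/type
    combination draw; it must have length ``scenario.n_cycles``.
    """
    if weights is None:
        weights = load_default_weights()
    if len(aux_uniforms) < scenario.n_cycles:
        raise ValueError("need one auxiliary uniform per cycle")
    v = 1.0 - latent
    p = scenario.cumulative(dose)
    base = cycle1_grade_distribution(scenario.p1[dose])
    dc = dlt_cycle(latent, scenario, dose)
    n_obs = dc if dc is not None else scenario.n_cycles
    grades: list[int] = []
    triples: list[tuple[int, int, int]] = []
    scores: list[float] = []
    for s in range(1, n_obs + 1):
        p_prev = 0.0 if s == 1 else float(p[s - 2])
        g = _max_grade_for_cycle(v, p_prev, float(p[s - 1]), base, had_dlt=(dc == s))
        triple = grade_type_combination(g, aux_uniforms[s - 1])
        grades.append(g)
        triples.append(triple)
        scores.append(nttp_value(triple, weights))
    return PatientOutcome(
        latent=latent,
        dose=dose,
        dlt_cycle=dc,
        max_grades=tuple(grades),
        grade_triples=tuple(triples),
        nttp=tuple(scores),
    )


def patient_streams(
    base_seed: int, replicate: int, n_patients: int, n_cycles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Latent and auxiliary uniforms for one simulated trial replicate.

    The latent variables come from a stream keyed by (seed, replicate)
    and the auxiliary grade/type uniforms from independent per-patient
    streams, so that the sequence of patients (and their outcomes on any
    dose) is identical across designs and the empirical benchmark for a
    common base seed.

    Returns ``(latents, aux)`` with shapes ``(n,)`` and ``(n, S)``.
    """
    lat_rng = np.random.default_rng([int(base_seed), int(replicate), 0])
    latents = lat_rng.uniform(size=n_patients)
    # keep strictly inside (0, 1)
    latents = np.clip(latents, 1e-12, 1 - 1e-12)
    aux = np.empty((n_patients, n_cycles))
    for i in range(n_patients):
        rng_i = np.random.default_rng([int(base_seed), int(replicate), 1, i])
        aux[i] = rng_i.uniform(size=n_cycles)
    return latents, aux
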