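"""Rolling-enrollment trial simulation and operating characteristics.

A cohort enters at the start of every treatment cycle (weeks 0, 6, 12,
...), so each interim decision sees complete follow-up only for cohorts
enrolled at least ``S`` cycles earlier and partial follow-up for the
rest.  The engine builds the observable dataset at each cycle boundary
(no future leakage by construction), asks the design for the next
cohort's dose, applies the enforcement rules (hard-safety exclusions,
k-fold dose-rise cap), evaluates the stopping rules of the active
setting, and enrolls or suspends.  When enrollment stops, already
enrolled patients complete their follow-up; the final recommendation is
then computed from the complete data with the design's own final
selection rule (none after a safety stop).

The trial duration is the week at which the last enrolled patient
completes follow-up or experiences a DLT; a configuration flag instead
truncates the clock at the stopping decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PatientRecord, ToxDataset
from .designs import SUSPEND, DecisionContext, Design
from .outcomes import NttpWeights, load_default_weights, patient_streams, simulate_patient
from .rules import (
    RuleConfig,
    apply_hard_safety,
    k_fold_check,
    precision_stop,
    safety_posterior_stop,
    sufficient_information_stop,
)
from .scenarios import ScenarioSpec

__all__ = [
    "TrialConfig",
    "TrialResult",
    "OperatingCharacteristics",
    "run_trial",
    "observable_dataset",
    "simulate_ocs",
    "correct_outcome",
]

STOP_REASONS = (
    "sufficient_information",
    "lowest_unsafe",
    "highest_safe",
    "precision",
    "hard_safety",
    "maximum_patients",
)

_CATEGORY = {0: 1, 1: 1, 2: 2, 3: 3, 4: 3}  # max grade -> 3-level category


@dataclass(frozen=True)
class TrialConfig:
    cohort_size: int = 3
    max_patients: int = 30
    n_cycles: int = 3
    cycle_weeks: float = 6.0
    tau: float = 0.391
    rules: RuleConfig = field(default_factory=RuleConfig)
    truncate_duration_at_stop: bool = False
    max_boundaries: int = 200  # hard cap against pathological suspension loops

    def __post_init__(self) -> None:
        if self.max_patients % self.cohort_size != 0:
            raise ValueError("max_patients must be divisible by cohort_size")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass(frozen=True)
class TrialResult:
    recommendation: int | None  # 0-based dose index
    n_patients: int
    duration_weeks: float
    allocation: np.ndarray  # patients per dose
    stop_reasons: tuple[str, ...]
    patient_doses: np.ndarray  # assigned dose per patient
    patient_latents: np.ndarray
    n_interims: int

    def __post_init__(self) -> None:
        if self.allocation.sum() != self.n_patients:
            raise ValueError("allocation must sum to enrolled patients")


@dataclass
class _TrialState:
    """Mutable bookkeeping of one simulated trial."""

    doses: list[int] = field(default_factory=list)  # per patient
    enroll_boundary: list[int] = field(default_factory=list)  # per patient
    excluded: set[int] = field(default_factory=set)
    highest_tried: float = 0.0
    consecutive_at_current: int = 0
    design_state: dict = field(default_factory=dict)


def observable_dataset(
    scenario: ScenarioSpec,
    doses: list[int],
    enroll_boundary: list[int],
    boundary: int,
    latents: np.ndarray,
    aux: np.ndarray,
    weights: NttpWeights,
    _cache: dict | None = None,
) -> ToxDataset:
    """Data observable at a cycle boundary (week ``6 * boundary``).

    A patient enrolled at boundary ``e`` has ``min(boundary - e, S)``
    cycles observed, cut short at their DLT cycle; patients enrolled at
    the current boundary contribute nothing yet.
    """
    records = []
    S = scenario.n_cycles
    for i, (dose, e) in enumerate(zip(doses, enroll_boundary)):
        elapsed = boundary - e
        if elapsed < 1:
            continue
        key = (i, dose)
        if _cache is not None and key in _cache:
            out = _cache[key]
        else:
            out = simulate_patient(latents[i], aux[i], scenario, dose, weights)
            if _cache is not None:
                _cache[key] = out
        u = min(elapsed, S, out.cycles_on_study)
        dlt_cycle = out.dlt_cycle if (out.dlt_cycle or S + 1) <= u else None
        records.append(
            PatientRecord(
                patient=i,
                dose=dose,
                dose_value=scenario.dose_values[dose],
                cycles_observed=u,
                dlt_cycle=dlt_cycle,
                categories=tuple(_CATEGORY[g] for g in out.max_grades[:u]),
                max_grades=out.max_grades[:u],
                nttp=out.nttp[:u],
            )
        )
    return ToxDataset(tuple(records), S, scenario.dose_values)


def _fit_seed(base_seed: int, replicate: int, interim: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(replicate), 7, int(interim)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_trial(
    design: Design,
    scenario: ScenarioSpec,
    config: TrialConfig,
    base_seed: int,
    replicate: int = 0,
    weights: NttpWeights | None = None,
) -> TrialResult:
    """Simulate one trial of one design on one scenario."""
    if weights is None:
        weights = load_default_weights()
    rules = config.rules
    N, S = config.max_patients, config.n_cycles
    latents, aux = patient_streams(base_seed, replicate, N, S)
    st = _TrialState()
    cache: dict = {}

    def enroll(dose: int, boundary: int) -> None:
        for _ in range(config.cohort_size):
            st.doses.append(dose)
            st.enroll_boundary.append(boundary)
        st.highest_tried = max(st.highest_tried, scenario.dose_values[dose])

    # first cohort always starts at the lowest dose
    enroll(0, 0)
    st.consecutive_at_current = config.cohort_size
    current = 0
    stop_reasons: list[str] = []
    safety_stop = False
    boundary = 0
    interim = 0

    while boundary < config.max_boundaries:
        boundary += 1
        data = observable_dataset(
            scenario, st.doses, st.enroll_boundary, boundary, latents, aux,
            weights, _cache=cache,
        )
        interim += 1
        treated = data.treated_per_dose()

        # --- enforcement: hard safety exclusion (setting 2) ------------
        if rules.hard_safety_active:
            st.excluded |= apply_hard_safety(data, rules)
            if 0 in st.excluded:
                stop_reasons.append("hard_safety")
                safety_stop = True
                break
        admissible = np.array(
            [j not in st.excluded for j in range(scenario.n_doses)]
        )

        # --- design proposal -------------------------------------------
        ctx = DecisionContext(
            data=data,
            current_dose=current,
            admissible=admissible,
            tau=config.tau,
            n_enrolled=len(st.doses),
            interim=interim,
            fit_seed=_fit_seed(base_seed, replicate, interim),
            consecutive_at_current=st.consecutive_at_current,
            state=st.design_state,
        )
        proposal = design.propose(ctx)

        # --- engine overrides ------------------------------------------
        if proposal != SUSPEND:
            j = int(proposal)
            if not admissible[j]:
                lower = [i for i in range(j, -1, -1) if admissible[i]]
                if not lower:
                    stop_reasons.append("hard_safety")
                    safety_stop = True
                    break
                j = lower[0]
            # k-fold rise cap on the physical dose value
            while j > 0 and not k_fold_check(
                scenario.dose_values[j], st.highest_tried, rules.k_fold
            ):
                j -= 1
            if not admissible[j]:
                cands = [i for i in range(j + 1) if admissible[i]]
                if not cands:
                    stop_reasons.append("hard_safety")
                    safety_stop = True
                    break
                j = max(cands)
        else:
            j = None

        # --- stopping rules --------------------------------------------
        triggered: list[str] = []
        if rules.posterior_stops_active:
            lo_has = treated[0] >= config.cohort_size
            hi_has = treated[-1] >= config.cohort_size
            p_lo = (
                design.cycle1_tail_prob(data, 0, rules.tau_cycle1, below=False)
                if lo_has else None
            )
            p_hi = (
                design.cycle1_tail_prob(
                    data, scenario.n_doses - 1, rules.tau_cycle1, below=True
                )
                if hi_has else None
            )
            low, high = safety_posterior_stop(p_lo, p_hi, rules, lo_has, hi_has)
            if low:
                triggered.append("lowest_unsafe")
            if high:
                triggered.append("highest_safe")
        if rules.precision_active and design.model_based:
            draws = design.mtd_draws(ctx)
            if draws is not None and precision_stop(
                draws, rules, n_with_one_cycle=data.n_patients
            ):
                triggered.append("precision")
        if j is not None and sufficient_information_stop(
            int(treated[j]), rules.sufficient_information_n
        ):
            triggered.append("sufficient_information")
        if len(st.doses) >= N:
            triggered.append("maximum_patients")

        if triggered:
            stop_reasons.extend(triggered)
            safety_stop = any(
                r in ("lowest_unsafe", "highest_safe", "hard_safety")
                for r in triggered
            )
            break

        # --- enroll or suspend -----------------------------------------
        if j is None:
            continue  # accrual suspended for one cycle
        if j == current:
            st.consecutive_at_current += config.cohort_size
        else:
            st.consecutive_at_current = config.cohort_size
        enroll(j, boundary)
        current = j

    # --- wind down: follow-up completes, final recommendation ----------
    doses_arr = np.array(st.doses, dtype=int)
    completion = np.empty(len(st.doses))
    for i in range(len(st.doses)):
        out = cache.get((i, st.doses[i])) or simulate_patient(
            latents[i], aux[i], scenario, st.doses[i], weights
        )
        cycles = out.dlt_cycle if out.dlt_cycle is not None else S
        completion[i] = (st.enroll_boundary[i] + cycles) * config.cycle_weeks
    duration = float(completion.max()) if completion.size else 0.0
    if config.truncate_duration_at_stop:
        duration = min(duration, boundary * config.cycle_weeks)

    if safety_stop:
        recommendation = None
    else:
        final_boundary = max(st.enroll_boundary) + S + 1 if st.doses else 0
        final_data = observable_dataset(
            scenario, st.doses, st.enroll_boundary, final_boundary,
            latents, aux, weights, _cache=cache,
        )
        admissible = np.array(
            [i not in st.excluded for i in range(scenario.n_doses)]
        )
        recommendation = design.final_select(final_data, admissible, config.tau)

    allocation = np.bincount(doses_arr, minlength=scenario.n_doses)
    return TrialResult(
        recommendation=recommendation,
        n_patients=len(st.doses),
        duration_weeks=duration,
        allocation=allocation,
        stop_reasons=tuple(stop_reasons),
        patient_doses=doses_arr,
        patient_latents=latents[: len(st.doses)],
        n_interims=interim,
    )


def correct_outcome(result: TrialResult, scenario: ScenarioSpec) -> bool:
    """Whether the trial reached the correct conclusion for its scenario.

    With a true MTD, the correct outcome is recommending it.  When all
    doses are unsafe, it is stopping for safety (lowest-dose-unsafe or
    hard safety) without a recommendation; when all doses are below
    target, it is stopping because the highest dose is clearly safe.
    """
    truth = scenario.truth
    if truth is None:
        raise ValueError(f"scenario {scenario.name!r} carries no truth label")
    if truth == "all_unsafe":
        return result.recommendation is None and any(
            r in ("lowest_unsafe", "hard_safety") for r in result.stop_reasons
        )
    if truth == "all_safe":
        return "highest_safe" in result.stop_reasons
    return result.recommendation == int(truth) - 1


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated results over simulated replicates of one design."""

    design: str
    scenario: str
    n_sims: int
    pcs: float
    mean_patients: float
    sd_patients: float
    mean_duration: float
    sd_duration: float
    mean_allocation: np.ndarray
    recommendation_pct: np.ndarray  # index 0 = no dose, then doses 1..J
    stop_reason_pct: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "design": self.design,
            "scenario": self.scenario,
            "n_sims": self.n_sims,
            "pcs": self.pcs,
            "mean_patients": self.mean_patients,
            "sd_patients": self.sd_patients,
            "mean_duration": self.mean_duration,
            "sd_duration": self.sd_duration,
        }
        for j, a in enumerate(self.mean_allocation):
            rows[f"alloc_d{j + 1}"] = a
        for j, p in enumerate(self.recommendation_pct):
            rows[f"rec_{'none' if j == 0 else f'd{j}'}"] = p
        for k, v in self.stop_reason_pct.items():
            rows[f"stop_{k}"] = v
        return pd.DataFrame([rows])


def simulate_ocs(
    design: Design,
    scenario: ScenarioSpec,
    n_sims: int,
    base_seed: int,
    config: TrialConfig,
    weights: NttpWeights | None = None,
) -> OperatingCharacteristics:
    """Operating characteristics over independent seeded replicates.

    Replicate ``r`` draws its patients from streams keyed by
    ``(base_seed, r)``, so every design (and the empirical benchmark)
    sees the same sequence of latent toxicity variables for a common
    base seed.
    """
    if weights is None:
        weights = load_default_weights()
    J = scenario.n_doses
    pats, durs = np.empty(n_sims), np.empty(n_sims)
    alloc = np.zeros(J)
    rec = np.zeros(J + 1)
    reasons = {k: 0 for k in STOP_REASONS}
    correct = 0
    for r in range(n_sims):
        res = run_trial(design, scenario, config, base_seed, r, weights)
        pats[r], durs[r] = res.n_patients, res.duration_weeks
        alloc += res.allocation
        rec[0 if res.recommendation is None else res.recommendation + 1] += 1
        for reason in set(res.stop_reasons):
            reasons[reason] += 1
        if scenario.truth is not None and correct_outcome(res, scenario):
            correct += 1
    return OperatingCharacteristics(
        design=design.name,
        scenario=scenario.name,
        n_sims=n_sims,
        pcs=100.0 * correct / n_sims,
        mean_patients=float(pats.mean()),
        sd_patients=float(pats.std(ddof=1)) if n_sims > 1 else 0.0,
        mean_duration=float(durs.mean()),
        sd_duration=float(durs.std(ddof=1)) if n_sims > 1 else 0.0,
        mean_allocation=alloc / n_sims,
        recommendation_pct=100.0 * rec / n_sims,
        stop_reason_pct={k: 100.0 * v / n_sims for k, v in reasons.items()},
    )
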