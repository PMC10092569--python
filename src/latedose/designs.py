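"""Uniform decision interface wrapping the eight escalation designs.

Each design object is stateless across trials; per-trial scratch (the
initial-escalation flag, previous fits used as fallbacks) lives in the
``state`` dict of the :class:`DecisionContext` that the trial engine
passes to every call.  A design proposes the dose for the next cohort
(0-based index) or asks for an accrual suspension; the engine then
applies enforcement rules and stopping checks.

Beyond proposals, designs expose the hooks the stopping rules need:
a one-cycle model for the lowest-dose-unsafe / highest-dose-safe rules
(the design family's own cycle-1 estimate where it has one, a
Beta-binomial otherwise) and, for model-based designs, posterior draws
of the MTD on the physical dose scale for the precision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .boin import BetaPrior, IntervalSpec, Move, boin_thresholds, titeboin_decision
from .crm import (
    Crm2Prior,
    CrmPrior,
    titecrm2_fit,
    titecrm_fit,
    titecrm_next_dose,
    titecrm_posterior_draws,
    titecrm_tail_probability,
)
from .dataset import ToxDataset
from .icsdp import IcsdpFit, IcsdpPrior, icsdp_fit, icsdp_next_dose
from .isotonic import isotonic_mtd
from .keyboard import keyboard_decision, keyboard_effective_counts, rmtpi2_decision
from .nttp import NttpPrior, nttp_fit, nttp_next_dose
from .outcomes import NttpWeights
from .pomm import (
    POMM_SWITCH_SUBJECTS,
    PommPrior,
    pomm_dlt_probabilities,
    pomm_initial_fit,
    pomm_mixed_fit,
    pomm_next_dose,
)

__all__ = [
    "DecisionContext",
    "SUSPEND",
    "Design",
    "TiteCrmDesign",
    "TiteCrm2Design",
    "IcsdpDesign",
    "PommDesign",
    "NttpDesign",
    "TiteBoinDesign",
    "TiteKeyboardDesign",
    "RollingMtpi2Design",
]

SUSPEND = "suspend"


@dataclass
class DecisionContext:
    data: ToxDataset
    current_dose: int
    admissible: np.ndarray  # bool per dose (hard-safety exclusions applied)
    tau: float
    n_enrolled: int
    interim: int
    fit_seed: int
    consecutive_at_current: int
    state: dict[str, Any] = field(default_factory=dict)

    @property
    def dose_values(self) -> tuple[float, ...]:
        return self.data.dose_values


class Design:
    """Base class: shared glue for moves and Beta-binomial rule models."""

    name: str = ""
    model_based: bool = False

    # -- proposals ----------------------------------------------------

    def propose(self, ctx: DecisionContext):
        raise NotImplementedError

    def final_select(self, data: ToxDataset, admissible, tau: float):
        raise NotImplementedError

    # -- stopping-rule hooks ------------------------------------------

    def cycle1_tail_prob(
        self, data: ToxDataset, dose: int, tau_cycle1: float, below: bool
    ) -> float | None:
        """P(p1 at `dose` exceeds tau_cycle1) -- or is below, if `below`."""
        return self._beta_binomial_tail(data, dose, tau_cycle1, below)

    def mtd_draws(self, ctx: DecisionContext, n_draws: int = 1000):
        """Posterior MTD draws on the dose scale (model-based designs)."""
        return None

    # -- helpers -------------------------------------------------------

    _rule_beta_prior = BetaPrior(1.0, 1.0)

    def _beta_binomial_tail(
        self, data: ToxDataset, dose: int, tau_cycle1: float, below: bool
    ) -> float:
        n, dlt = data.cycle1_counts()
        a = self._rule_beta_prior.alpha + dlt[dose]
        b = self._rule_beta_prior.beta + n[dose] - dlt[dose]
        tail = stats.beta.sf(tau_cycle1, a, b)
        return float(1.0 - tail) if below else float(tail)

    @staticmethod
    def _move_to_dose(move: Move, ctx: DecisionContext):
        if move == Move.SUSPEND:
            return SUSPEND
        j = ctx.current_dose
        if move == Move.ESCALATE:
            return min(j + 1, ctx.data.n_doses - 1)
        if move == Move.DEESCALATE:
            # de-escalation from the lowest dose means staying there
            return max(j - 1, 0)
        return j

    @staticmethod
    def _interp_extrap(x, xp, fp) -> np.ndarray:
        """Piecewise-linear map with linear extrapolation at both ends.

        Used to carry continuous MTD solutions from a model's working
        scale to the physical dose scale without saturating at the grid
        ends (saturation would artificially shrink the spread of the
        draws that the precision stopping rule measures).
        """
        x = np.asarray(x, dtype=float)
        xp = np.asarray(xp, dtype=float)
        fp = np.asarray(fp, dtype=float)
        out = np.interp(x, xp, fp)
        lo = x < xp[0]
        hi = x > xp[-1]
        out[lo] = fp[0] + (x[lo] - xp[0]) * (fp[1] - fp[0]) / (xp[1] - xp[0])
        out[hi] = fp[-1] + (x[hi] - xp[-1]) * (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        return out


def _initial_escalation(ctx: DecisionContext) -> int | None:
    """One-level escalation until the first DLT is observed anywhere.

    Returns the proposed dose while the initial phase is active, else
    None.  Only one observed cycle is required before each step, in line
    with the per-cycle rolling enrollment.
    """
    if ctx.state.get("initial_done", False):
        return None
    if any(rec.dlt for rec in ctx.data.records):
        ctx.state["initial_done"] = True
        return None
    return min(ctx.current_dose + 1, ctx.data.n_doses - 1)


# ---------------------------------------------------------------------------
# model-based designs
# ---------------------------------------------------------------------------


class TiteCrmDesign(Design):
    """One-parameter TITE-CRM on a skeleton of prior guesses."""

    name = "tite-crm"
    model_based = True

    def __init__(self, prior: CrmPrior, tau: float):
        self.prior = prior
        self.tau = tau

    def _best_dose(self, data: ToxDataset, admissible, tau: float):
        beta_hat = titecrm_fit(data, self.prior)
        return titecrm_next_dose(beta_hat, self.prior, tau, admissible)

    def propose(self, ctx: DecisionContext):
        step = _initial_escalation(ctx)
        if step is not None:
            return step
        dose = self._best_dose(ctx.data, ctx.admissible, ctx.tau)
        return dose if dose is not None else SUSPEND

    def final_select(self, data, admissible, tau):
        return self._best_dose(data, admissible, tau)

    def cycle1_tail_prob(self, data, dose, tau_cycle1, below):
        return titecrm_tail_probability(
            data, self.prior, dose, tau_cycle1, one_cycle=True, below=below
        )

    def mtd_draws(self, ctx, n_draws: int = 1000):
        rng = np.random.default_rng(ctx.fit_seed)
        beta = titecrm_posterior_draws(ctx.data, self.prior, n_draws, rng)
        # continuous MTD on the skeleton scale, mapped to physical doses
        with np.errstate(over="ignore"):
            d_star = self.tau ** (1.0 / np.exp(beta))
        sk = np.array(self.prior.skeleton)
        dv = np.array(ctx.dose_values)
        return self._interp_extrap(d_star, sk, dv)


class TiteCrm2Design(Design):
    """Two-parameter logistic TITE-CRM on the physical dose values."""

    name = "tite-crm2"
    model_based = True

    def __init__(self, prior: Crm2Prior, tau: float):
        self.prior = prior
        self.tau = tau

    def _best_dose(self, data, admissible, tau):
        post = titecrm2_fit(data, self.prior)
        curve = post.curve(data.dose_values)
        dist = np.where(np.asarray(admissible, bool), np.abs(curve - tau), np.inf)
        if not np.isfinite(dist).any():
            return None
        return int(np.argmin(dist))

    def propose(self, ctx):
        step = _initial_escalation(ctx)
        if step is not None:
            return step
        dose = self._best_dose(ctx.data, ctx.admissible, ctx.tau)
        return dose if dose is not None else SUSPEND

    def final_select(self, data, admissible, tau):
        return self._best_dose(data, admissible, tau)

    def cycle1_tail_prob(self, data, dose, tau_cycle1, below):
        post = titecrm2_fit(data, self.prior, one_cycle=True)
        return post.tail_probability(data.dose_values[dose], tau_cycle1, below)

    def mtd_draws(self, ctx, n_draws: int = 1000):
        rng = np.random.default_rng(ctx.fit_seed)
        post = titecrm2_fit(ctx.data, self.prior)
        ab = post.draws(n_draws, rng)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_star = (logit(self.tau) - ab[:, 0]) / ab[:, 1]
        return np.asarray(d_star, dtype=float)


class IcsdpDesign(Design):
    """Interval-censored survival design with pseudo-data prior."""

    name = "icsdp"
    model_based = True

    def __init__(self, prior: IcsdpPrior, tau: float):
        self.prior = prior
        self.tau = tau

    def _fit(self, data: ToxDataset, state: dict) -> IcsdpFit:
        fit = icsdp_fit(data, self.prior, previous=state.get("icsdp_fit"))
        state["icsdp_fit"] = fit
        return fit

    def propose(self, ctx):
        had_previous = "icsdp_fit" in ctx.state
        fit = self._fit(ctx.data, ctx.state)
        if not fit.converged and had_previous:
            return ctx.current_dose  # retain dose on a flagged fit
        rho = fit.total_probs()
        dose = icsdp_next_dose(rho, ctx.tau, ctx.admissible)
        return dose if dose is not None else SUSPEND

    def final_select(self, data, admissible, tau):
        fit = icsdp_fit(data, self.prior)
        return icsdp_next_dose(fit.total_probs(), tau, admissible)

    def _param_draws(self, fit: IcsdpFit, n_draws, rng):
        if fit.cov is None:
            return np.tile(np.concatenate([fit.gamma, [fit.theta]]), (n_draws, 1))
        mean = np.concatenate([fit.gamma, [fit.theta]])
        cov = 0.5 * (fit.cov + fit.cov.T) + 1e-10 * np.eye(mean.size)
        try:
            return rng.multivariate_normal(mean, cov, size=n_draws,
                                           method="cholesky")
        except np.linalg.LinAlgError:
            return np.tile(mean, (n_draws, 1))

    def cycle1_tail_prob(self, data, dose, tau_cycle1, below):
        fit = icsdp_fit(data, self.prior)
        rng = np.random.default_rng(12345)
        draws = self._param_draws(fit, 2000, rng)
        eta = draws[:, 0] + draws[:, -1] * np.log(data.dose_values[dose])
        pi1 = -np.expm1(-np.exp(np.clip(eta, -30, 30)))
        frac = float(np.mean(pi1 > tau_cycle1))
        return 1.0 - frac if below else frac

    def mtd_draws(self, ctx, n_draws: int = 1000):
        fit = self._fit(ctx.data, ctx.state)
        rng = np.random.default_rng(ctx.fit_seed)
        draws = self._param_draws(fit, n_draws, rng)
        target = -np.log1p(-self.tau)
        total_haz = np.exp(draws[:, :-1]).sum(axis=1)
        theta = draws[:, -1]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            d_star = np.where(theta > 1e-6,
                              (target / total_haz) ** (1.0 / theta), np.nan)
        return np.asarray(d_star, dtype=float)


class PommDesign(Design):
    """Proportional-odds mixed-model design on toxicity categories."""

    name = "pomm"
    model_based = True

    def __init__(self, prior: PommPrior, tau: float, tau_cycle1: float):
        self.prior = prior
        self.tau = tau
        self.tau_cycle1 = tau_cycle1

    def _phase2(self, data: ToxDataset) -> bool:
        return data.n_patients >= POMM_SWITCH_SUBJECTS

    def _best_dose(self, data, admissible, tau, state=None):
        state = state if state is not None else {}
        if self._phase2(data):
            fit = pomm_mixed_fit(data, self.prior, previous=state.get("pomm_fit"))
            state["pomm_fit"] = fit
            probs = pomm_dlt_probabilities(fit, data.dose_values, data.n_cycles)
            return pomm_next_dose(probs, tau, admissible)
        fit = pomm_initial_fit(data, self.prior, fallback=state.get("pomm_init"))
        state["pomm_init"] = fit
        probs = fit.dlt_prob(data.dose_values)
        return pomm_next_dose(probs, self.tau_cycle1, admissible)

    def propose(self, ctx):
        dose = self._best_dose(ctx.data, ctx.admissible, ctx.tau, ctx.state)
        return dose if dose is not None else SUSPEND

    def final_select(self, data, admissible, tau):
        return self._best_dose(data, admissible, tau)

    def cycle1_tail_prob(self, data, dose, tau_cycle1, below):
        if not self._phase2(data):
            # the initial GLM is a point fit; use the Beta-binomial check
            return self._beta_binomial_tail(data, dose, tau_cycle1, below)
        fit = pomm_mixed_fit(data, self.prior)
        rng = np.random.default_rng(12345)
        draws = fit.draws(500, rng)
        d = data.dose_values[dose]
        a2 = draws[:, 0] + np.exp(draws[:, 1])
        p3 = 1.0 - expit(a2 - draws[:, 2] * d - draws[:, 3] * 1.0)
        frac = float(np.mean(p3 > tau_cycle1))
        return 1.0 - frac if below else frac

    def mtd_draws(self, ctx, n_draws: int = 400):
        if not self._phase2(ctx.data):
            return None
        fit = ctx.state.get("pomm_fit") or pomm_mixed_fit(ctx.data, self.prior)
        rng = np.random.default_rng(ctx.fit_seed)
        draws = fit.draws(n_draws, rng)
        dv = np.array(ctx.dose_values)
        s = np.arange(1, ctx.data.n_cycles + 1)
        a2 = draws[:, 0] + np.exp(draws[:, 1])
        # survival through all cycles for each draw x dose
        eta = (a2[:, None, None] - draws[:, 2, None, None] * dv[None, :, None]
               - draws[:, 3, None, None] * s[None, None, :])
        surv = expit(eta).prod(axis=2)
        p_dlt = 1.0 - surv
        idx = np.argmin(np.abs(p_dlt - self.tau), axis=1)
        return dv[idx].astype(float)


class NttpDesign(Design):
    """Linear mixed-model design on the normalized total toxicity profile."""

    name = "nttp"
    model_based = True

    def __init__(self, prior: NttpPrior, tau_nttp: float, weights: NttpWeights,
                 n_draws: int = 1000, n_burn: int = 500):
        self.prior = prior
        self.tau_nttp = tau_nttp
        self.weights = weights
        self.n_draws = n_draws
        self.n_burn = n_burn

    def _fit(self, data, seed):
        return nttp_fit(data, self.prior, self.n_draws, self.n_burn, seed)

    def propose(self, ctx):
        post = self._fit(ctx.data, ctx.fit_seed)
        ctx.state["nttp_post"] = post
        dose = nttp_next_dose(
            post.cycle1_means(ctx.dose_values), self.tau_nttp, ctx.admissible
        )
        return dose if dose is not None else SUSPEND

    def final_select(self, data, admissible, tau):
        post = self._fit(data, seed=1)
        return nttp_next_dose(
            post.cycle1_means(data.dose_values), self.tau_nttp, admissible
        )

    # the score model has no DLT-probability scale; the safety rules use
    # the Beta-binomial default from the base class.

    def mtd_draws(self, ctx, n_draws: int = 1000):
        post = ctx.state.get("nttp_post")
        if post is None:
            post = self._fit(ctx.data, ctx.fit_seed)
        return post.mtd_draws(self.tau_nttp, ctx.dose_values[0],
                              ctx.dose_values[-1])


# ---------------------------------------------------------------------------
# model-assisted designs
# ---------------------------------------------------------------------------


class _IntervalDesign(Design):
    model_based = False

    #: neutral prior for the final isotonic selection, decoupled from the
    #: (possibly asymmetric) escalation prior
    selection_prior = BetaPrior(1.0, 1.0)

    def __init__(self, interval: IntervalSpec, prior: BetaPrior):
        self.interval = interval
        self.prior = prior
        self._rule_beta_prior = prior

    def final_select(self, data, admissible, tau):
        return isotonic_mtd(
            data.treated_per_dose(), data.dlt_per_dose(),
            self.selection_prior, tau, admissible,
        )


class TiteBoinDesign(_IntervalDesign):
    """Time-to-event Bayesian optimal interval design."""

    name = "tite-boin"

    def __init__(self, interval, prior):
        super().__init__(interval, prior)
        self.thresholds = boin_thresholds(interval)

    def propose(self, ctx):
        summary = ctx.data.pending_summary(ctx.current_dose)
        move = titeboin_decision(summary, self.thresholds, self.prior,
                                 ctx.data.n_cycles)
        return self._move_to_dose(move, ctx)


class TiteKeyboardDesign(_IntervalDesign):
    """Time-to-event keyboard (mTPI2) design on effective binomial data.

    ``suspend_pending_frac``: accrual is suspended when more than this
    fraction of the patients at the current dose are DLT-free with
    incomplete follow-up (None disables suspension).
    """

    name = "tite-mtpi2"

    def __init__(self, interval, prior, suspend_pending_frac: float | None = 0.5):
        super().__init__(interval, prior)
        self.suspend_pending_frac = suspend_pending_frac

    def propose(self, ctx):
        summary = ctx.data.pending_summary(ctx.current_dose)
        if (
            self.suspend_pending_frac is not None
            and summary["n"] > 0
            and summary["pending"] / summary["n"] > self.suspend_pending_frac
        ):
            return SUSPEND
        n_eff, events = keyboard_effective_counts(summary, ctx.data.n_cycles)
        if n_eff <= 0:
            return SUSPEND
        move = keyboard_decision(n_eff, events, self.prior, self.interval)
        return self._move_to_dose(move, ctx)


class RollingMtpi2Design(_IntervalDesign):
    """Rolling keyboard design with best/worst-case imputation cascade."""

    name = "r-mtpi2"

    def __init__(self, interval, prior, consecutive_limit: int = 6):
        super().__init__(interval, prior)
        self.consecutive_limit = consecutive_limit

    def propose(self, ctx):
        summary = ctx.data.pending_summary(ctx.current_dose)
        move = rmtpi2_decision(
            summary, self.prior, self.interval,
            consecutive_at_dose=ctx.consecutive_at_current,
            consecutive_limit=self.consecutive_limit,
        )
        return self._move_to_dose(move, ctx)
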