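"""Proportional-odds mixed-model design on three-level toxicity categories.

Toxicity in each cycle is categorized as 1 (grade <= 1), 2 (grade 2) or
3 (grade >= 3, a DLT).  For the first 15 subjects a plain logistic model
on the cycle-1 DLT indicator guides escalation toward the cycle-1
target; from subject 16 a proportional-odds mixed model over all cycles
is used:

    logit P(Y_{i,s} <= k | d_j) = alpha_k - beta1 d_j - beta2 s - u_i,

with patient effect ``u_i ~ N(0, sigma0^2)`` and k = 1, 2.  Dose
selection minimizes the distance of the whole-follow-up DLT probability
of a median patient (u = 0), ``1 - prod_s P(Y <= 2 | d, s, 0)``, from
the target.  A DLT cycle contributes its category-3 term to the
likelihood and later cycles contribute nothing (the patient has left the
study), which is the interval-censored handling of DLTs.

Prior information is a small set of fractional pseudo-observations on
every dose and cycle (total weight ``n0`` spread evenly), anchored at
per-dose cycle-1 DLT rates and grade-2/DLT ratios.  The fit is a
penalized maximum likelihood (the pseudo-data act as the prior) with a
Laplace approximation supplying posterior draws, and the patient random
effect integrated out by Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit

from .dataset import ToxDataset

__all__ = [
    "PommPrior",
    "PommInitialFit",
    "PommMixedFit",
    "pomm_initial_fit",
    "pomm_mixed_fit",
    "pomm_dlt_probabilities",
    "pomm_next_dose",
    "POMM_SWITCH_SUBJECTS",
]

#: the mixed model takes over from this many enrolled subjects onward
POMM_SWITCH_SUBJECTS = 16

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass(frozen=True)
class PommPrior:
    """Per-dose anchors and total pseudo-observation weight."""

    p1_anchor: tuple[float, ...]  # cycle-1 DLT rates, increasing in dose
    grade2_ratio: tuple[float, ...]  # p1G2 / p1 per dose
    n0: float = 2.0
    decay: float = 1 / 3

    def __post_init__(self) -> None:
        pa = self.p1_anchor
        if any(not 0.0 < p < 1.0 for p in pa):
            raise ValueError("anchors must lie in (0, 1)")
        if any(b <= a for a, b in zip(pa, pa[1:])):
            raise ValueError("anchors must be increasing in dose")
        if len(self.grade2_ratio) != len(pa):
            raise ValueError("one grade-2 ratio per dose required")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")


def _pseudo_cells(prior: PommPrior, dose_values, n_cycles: int):
    """(dose_value, cycle, category weights[3], cell weight) pseudo rows."""
    J = len(dose_values)
    w_cell = prior.n0 / (J * n_cycles)
    cells = []
    for j, d in enumerate(dose_values):
        for s in range(1, n_cycles + 1):
            scale = prior.decay ** (s - 1)
            c3 = prior.p1_anchor[j] * scale
            c2 = prior.grade2_ratio[j] * prior.p1_anchor[j] * scale
            c1 = max(1.0 - c2 - c3, 1e-9)
            cells.append((float(d), s, np.array([c1, c2, c3]), w_cell))
    return cells


# ---------------------------------------------------------------------------
# initial phase: weighted logistic on cycle-1 DLT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PommInitialFit:
    b0: float
    b1: float
    converged: bool

    def dlt_prob(self, dose_values) -> np.ndarray:
        return expit(self.b0 + self.b1 * np.asarray(dose_values))


def pomm_initial_fit(
    data: ToxDataset | None,
    prior: PommPrior,
    dose_values=None,
    fallback: PommInitialFit | None = None,
) -> PommInitialFit:
    """Weighted ML logistic fit of cycle-1 DLT vs dose value.

    Pseudo-observations contribute fractional event/non-event weights at
    every dose (weight ``n0 / J`` each, matching the cycle-1 anchors);
    they keep the fit identifiable when all observed outcomes agree.
    """
    if data is not None:
        dose_values = data.dose_values
    dv = np.asarray(dose_values, dtype=float)
    x, y, w = [], [], []
    w0 = prior.n0 / dv.size
    for j, d in enumerate(dv):
        x += [d, d]
        y += [1.0, 0.0]
        w += [w0 * prior.p1_anchor[j], w0 * (1.0 - prior.p1_anchor[j])]
    if data is not None:
        for rec in data.records:
            if rec.cycles_observed >= 1:
                x.append(rec.dose_value)
                y.append(float(rec.dlt_cycle == 1))
                w.append(1.0)
    x, y, w = map(np.array, (x, y, w))

    def nll(b):
        eta = b[0] + b[1] * x
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return -np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p)))

    res = optimize.minimize(nll, np.array([-1.0, 0.3]), method="BFGS")
    if not res.success and fallback is not None:
        return PommInitialFit(fallback.b0, fallback.b1, False)
    return PommInitialFit(float(res.x[0]), float(res.x[1]), bool(res.success))


# ---------------------------------------------------------------------------
# main phase: proportional-odds mixed model
# ---------------------------------------------------------------------------


def _unpack(params):
    a1 = params[0]
    a2 = a1 + np.exp(params[1])  # enforce alpha1 < alpha2
    b1, b2 = params[2], params[3]
    sigma0 = np.exp(params[4])
    return a1, a2, b1, b2, sigma0


def _category_logprobs(a1, a2, b1, b2, d, s, u):
    """log P(Y = k) for k=1,2,3 at dose value d, cycle s, effect u."""
    eta1 = a1 - b1 * d - b2 * s - u
    eta2 = a2 - b1 * d - b2 * s - u
    c1 = expit(eta1)
    c2 = expit(eta2)
    p = np.stack([c1, c2 - c1, 1.0 - c2])
    return np.log(np.clip(p, 1e-300, 1.0))


def _pack_patients(patients):
    """Flatten ragged patient-cycle observations into arrays."""
    d, s, cat, pid = [], [], [], []
    for i, (dose, cycles, cats) in enumerate(patients):
        for cyc, k in zip(cycles, cats):
            d.append(dose)
            s.append(float(cyc))
            cat.append(k - 1)
            pid.append(i)
    return (np.array(d), np.array(s), np.array(cat, dtype=int),
            np.array(pid, dtype=int), len(patients))


def _nll(params, pdata, cells):
    a1, a2, b1, b2, sigma0 = _unpack(params)
    d, s, cat, pid, n_pat = pdata
    total = 0.0
    if n_pat:
        u = sigma0 * _GH_NODES  # N(0, sigma0^2) quadrature points
        base = -b1 * d - b2 * s  # (obs,)
        eta1 = a1 + base[:, None] - u[None, :]
        eta2 = a2 + base[:, None] - u[None, :]
        c1 = expit(eta1)
        c2 = expit(eta2)
        k = cat[:, None]
        p = np.where(k == 0, c1, np.where(k == 1, c2 - c1, 1.0 - c2))
        lp = np.log(np.clip(p, 1e-300, 1.0))
        ll = np.zeros((n_pat, u.size))
        np.add.at(ll, pid, lp)  # sum each patient's cycles per node
        m = ll.max(axis=1, keepdims=True)
        total += float(
            np.sum(m[:, 0] + np.log(np.sum(_GH_WEIGHTS * np.exp(ll - m), axis=1)))
        )
    for d0, s0, cat_w, w_cell in cells:
        lp = _category_logprobs(a1, a2, b1, b2, d0, float(s0), 0.0)
        total += w_cell * float(np.dot(cat_w, lp))
    return -total


def _fd_hessian(fun, x, eps=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                4 * eps * eps
            )
    return H


@dataclass(frozen=True)
class PommMixedFit:
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    sigma0: float
    params: np.ndarray  # unconstrained MAP parameters
    cov: np.ndarray | None  # Laplace covariance on the unconstrained scale
    converged: bool

    def category_probs(self, dose_value: float, cycle: int, u: float = 0.0):
        lp = _category_logprobs(
            self.alpha1, self.alpha2, self.beta1, self.beta2,
            dose_value, float(cycle), u,
        )
        return np.exp(lp)

    def draws(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Laplace draws on the unconstrained parameter scale."""
        if self.cov is None:
            return np.tile(self.params, (n_draws, 1))
        try:
            L = np.linalg.cholesky(self.cov + 1e-10 * np.eye(self.params.size))
        except np.linalg.LinAlgError:
            return np.tile(self.params, (n_draws, 1))
        z = rng.standard_normal((n_draws, self.params.size))
        return self.params[None, :] + z @ L.T


def pomm_mixed_fit(
    data: ToxDataset,
    prior: PommPrior,
    previous: PommMixedFit | None = None,
) -> PommMixedFit:
    """Penalized ML fit of the proportional-odds mixed model."""
    patients = []
    for rec in data.records:
        if rec.cycles_observed >= 1:
            patients.append(
                (rec.dose_value, list(range(1, rec.cycles_observed + 1)),
                 list(rec.categories))
            )
    pdata = _pack_patients(patients)
    cells = _pseudo_cells(prior, data.dose_values, data.n_cycles)
    x0 = np.array([0.0, 0.5, 0.3, 0.1, np.log(0.5)])
    if previous is not None:
        x0 = previous.params.copy()
    res = optimize.minimize(
        _nll, x0, args=(pdata, cells), method="BFGS",
        options={"maxiter": 400, "gtol": 1e-6},
    )
    ok = bool(res.success) or res.fun < _nll(x0, pdata, cells)
    if not ok and previous is not None:
        return PommMixedFit(
            previous.alpha1, previous.alpha2, previous.beta1, previous.beta2,
            previous.sigma0, previous.params, previous.cov, False,
        )
    a1, a2, b1, b2, s0 = _unpack(res.x)
    cov = None
    try:
        H = _fd_hessian(lambda p: _nll(p, pdata, cells), res.x)
        cov = np.linalg.inv(H + 1e-8 * np.eye(H.shape[0]))
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    return PommMixedFit(a1, a2, b1, b2, s0, res.x.copy(), cov, ok)


def pomm_dlt_probabilities(
    fit: PommMixedFit, dose_values, n_cycles: int
) -> np.ndarray:
    """Whole-follow-up DLT probability per dose for a median patient."""
    out = np.empty(len(dose_values))
    for j, d in enumerate(dose_values):
        surv = 1.0
        for s in range(1, n_cycles + 1):
            p = fit.category_probs(float(d), s)
            surv *= 1.0 - p[2]
        out[j] = 1.0 - surv
    return out


def pomm_next_dose(probs, tau: float, admissible) -> int | None:
    """Admissible dose minimizing |P(DLT) - tau|; ties go low."""
    probs = np.asarray(probs, dtype=float)
    admissible = np.asarray(admissible, dtype=bool)
    if not admissible.any():
        return None
    dist = np.where(admissible, np.abs(probs - tau), np.inf)
    return int(np.argmin(dist))
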