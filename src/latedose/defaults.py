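"""Shipped design hyper-parameters from the prior-calibration procedure.

Each design's prior was calibrated (grid search maximizing the geometric
mean of correct-selection proportions over the calibration scenarios)
separately for rule setting 1 (minimal rules) and setting 2 (full rules);
these values are shipped as defaults.  The overall DLT-probability target
is 0.391 across three cycles, equivalent to a cycle-1 target of 0.3 under
the per-cycle hazard decay of 1/3.
"""

from __future__ import annotations

import numpy as np

from .boin import BetaPrior, IntervalSpec
from .crm import Crm2Prior, CrmPrior
from .icsdp import IcsdpPrior
from .nttp import NttpPrior
from .outcomes import NttpWeights, expected_cycle1_nttp, load_default_weights
from .pomm import PommPrior

__all__ = [
    "TAU",
    "TAU_CYCLE1",
    "default_design",
    "DESIGN_NAMES",
]

TAU = 0.391
TAU_CYCLE1 = 0.3

DESIGN_NAMES = (
    "tite-crm",
    "tite-crm2",
    "icsdp",
    "pomm",
    "nttp",
    "tite-boin",
    "tite-mtpi2",
    "r-mtpi2",
)

_CRM_SKELETON = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
_POMM_ANCHORS = (0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
# grade-2/DLT ratio anchors per dose (linear ramp across the grid)
_POMM_G2_RATIOS = (0.20, 0.30, 0.40, 0.50, 0.60, 0.70)

_BOIN_INTERVAL = IntervalSpec(TAU, 0.3128, 0.5083)
_MTPI2_INTERVAL = IntervalSpec(TAU, 0.3519, 0.5474)


def default_design(name: str, setting: int = 1, tau: float = TAU,
                   weights: NttpWeights | None = None):
    """Construct a design with its calibrated hyper-parameters.

    Parameters
    ----------
    name
        One of :data:`DESIGN_NAMES`.
    setting
        Rule setting (1 or 2); a few designs carry different calibrated
        priors per setting.
    tau
        Whole-follow-up DLT-probability target.
    weights
        nTTP weight table (nTTP design only); package default if None.
    """
    from .designs import (
        IcsdpDesign,
        NttpDesign,
        PommDesign,
        RollingMtpi2Design,
        TiteBoinDesign,
        TiteCrm2Design,
        TiteCrmDesign,
        TiteKeyboardDesign,
    )

    if setting not in (1, 2):
        raise ValueError("setting must be 1 or 2")
    name = name.lower()
    if name == "tite-crm":
        return TiteCrmDesign(CrmPrior(_CRM_SKELETON, sigma2=1.0), tau=tau)
    if name == "tite-crm2":
        return TiteCrm2Design(
            Crm2Prior(mu_a0=-1.0, var_a0=1 / 0.3,
                      mu_loga1=float(np.log(0.2)), var_loga1=1 / 0.3),
            tau=tau,
        )
    if name == "icsdp":
        if setting == 1:
            prior = IcsdpPrior(pi1=0.2, piJ=0.4, n0=6.0)
        else:
            prior = IcsdpPrior(pi1=0.2, piJ=0.3, n0=4.0)
        return IcsdpDesign(prior, tau=tau)
    if name == "pomm":
        return PommDesign(
            PommPrior(_POMM_ANCHORS, _POMM_G2_RATIOS, n0=2.0),
            tau=tau, tau_cycle1=TAU_CYCLE1,
        )
    if name == "nttp":
        w = weights if weights is not None else load_default_weights()
        if setting == 1:
            prior = NttpPrior(0.1, 100.0, 0.5, 100.0, 0.0, 10.0)
        else:
            prior = NttpPrior(0.05, 10.0, 0.1, 10.0, 0.0, 10.0)
        return NttpDesign(prior, tau_nttp=expected_cycle1_nttp(TAU_CYCLE1, w),
                          weights=w)
    if name == "tite-boin":
        beta = BetaPrior(0.1, 0.9) if setting == 1 else BetaPrior(1.0, 1.0)
        return TiteBoinDesign(_BOIN_INTERVAL, beta)
    if name == "tite-mtpi2":
        return TiteKeyboardDesign(_MTPI2_INTERVAL, BetaPrior(1.0, 1.0))
    if name == "r-mtpi2":
        return RollingMtpi2Design(_MTPI2_INTERVAL, BetaPrior(1.0, 1.0))
    raise ValueError(f"unknown design {name!r}; available: {DESIGN_NAMES}")
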