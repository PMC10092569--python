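import numpy as np
import pytest
import statsmodels.api as sm

from latedose import Crm2Prior, CrmPrior, titecrm2_fit, titecrm_fit, titecrm_next_dose, titecrm_weight
from latedose.crm import titecrm_tail_probability

from conftest import DOSES, make_dataset, make_record

SKELETON = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
PRIOR = CrmPrior(SKELETON, sigma2=1.0)


@pytest.mark.parametrize(
    "u, S, dlt, expected",
    [(1, 3, False, 1 / 3), (3, 3, False, 1.0), (1, 3, True, 1.0), (0, 3, False, 0.0)],
)
def test_titecrm_weight(u, S, dlt, expected):
    assert titecrm_weight(u, S, dlt) == pytest.approx(expected)
    with pytest.raises(ValueError):
        titecrm_weight(4, 3, False)


def _quadrature_oracle(records, n_nodes=100_001, one_cycle=False):
    """Dense-trapezoid posterior mean of beta, written independently."""
    beta = np.linspace(-10, 10, n_nodes)
    log_post = -0.5 * beta**2  # sigma2 = 1
    for rec in records:
        d = SKELETON[rec.dose]
        w = 1.0 if rec.dlt else rec.cycles_observed / 3
        G = w * d ** np.exp(beta)
        y = 1 if rec.dlt else 0
        log_post += y * np.log(G + 1e-300) + (1 - y) * np.log(1 - G)
    log_post -= log_post.max()
    p = np.exp(log_post)
    return np.trapezoid(beta * p, beta) / np.trapezoid(p, beta)


def test_fit_empty_data_returns_prior_mean():
    assert titecrm_fit(make_dataset([]), PRIOR) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize(
    "records",
    [
        [make_record(0, 5, 3)],  # full follow-up, no DLT at skeleton 0.30
        [make_record(0, 3, 1, dlt_cycle=1), make_record(1, 2, 3)],
        [make_record(i, i % 4, 1 + i % 3) for i in range(9)],
        [make_record(0, 3, 2, dlt_cycle=2), make_record(1, 3, 3), make_record(2, 4, 1)],
    ],
)
def test_fit_matches_dense_quadrature_oracle(records):
    ds = make_dataset(records)
    assert titecrm_fit(ds, PRIOR) == pytest.approx(_quadrature_oracle(records), abs=1e-6)


def test_zero_weight_patient_is_likelihood_neutral():
    base = [make_record(0, 2, 3)]
    with_w0 = base + [make_record(1, 4, 0)]
    assert titecrm_fit(make_dataset(base), PRIOR) == pytest.approx(
        titecrm_fit(make_dataset(with_w0), PRIOR), abs=1e-12
    )


def test_fit_invariant_to_patient_order():
    records = [make_record(i, i % 5, 1 + (i % 3), dlt_cycle=None) for i in range(8)]
    records[3] = make_record(3, 3, 1, dlt_cycle=1)
    shuffled = [records[i] for i in (5, 0, 7, 3, 1, 6, 2, 4)]
    assert titecrm_fit(make_dataset(records), PRIOR) == pytest.approx(
        titecrm_fit(make_dataset(shuffled), PRIOR), abs=1e-12
    )


def test_next_dose_criterion():
    # beta = 0: skeleton itself, target 0.391 -> dose 6 has the closest value
    assert titecrm_next_dose(0.0, PRIOR, 0.391, [True] * 6) == 5
    # admissibility restricts the argmin
    assert titecrm_next_dose(0.0, PRIOR, 0.391, [True] * 3 + [False] * 3) == 2
    assert titecrm_next_dose(0.0, PRIOR, 0.391, [False] * 6) is None
    # exact tie in |F - tau| breaks to the lower dose
    prior = CrmPrior((0.2, 0.4), sigma2=1.0)
    assert titecrm_next_dose(0.0, prior, 0.3, [True, True]) == 0


def test_complete_data_reduction_equals_standard_crm():
    # with every weight equal to 1 the fit is the standard CRM likelihood
    records = [make_record(i, 2 + (i % 2), 3, dlt_cycle=3 if i == 0 else None)
               for i in range(6)]
    records[0] = make_record(0, 2, 1, dlt_cycle=1)  # DLT weight is 1 anyway
    ds = make_dataset(records)
    assert titecrm_fit(ds, PRIOR) == pytest.approx(_quadrature_oracle(records), abs=1e-6)


def test_cycle1_restricted_tail_probability():
    # 3/3 cycle-1 DLTs at the lowest dose: the one-cycle model must see
    # the dose as very likely above a 0.3 cycle-1 target
    records = [make_record(i, 0, 1, dlt_cycle=1) for i in range(3)]
    p = titecrm_tail_probability(make_dataset(records), PRIOR, 0, 0.3)
    assert p > 0.8
    # and the complement identity
    below = titecrm_tail_probability(make_dataset(records), PRIOR, 0, 0.3, below=True)
    assert p + below == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# two-parameter variant
# ---------------------------------------------------------------------------

PRIOR2 = Crm2Prior()


def test_crm2_prior_recovery_without_data():
    post = titecrm2_fit(make_dataset([]), PRIOR2)
    assert post.mean_a0 == pytest.approx(PRIOR2.mu_a0, abs=0.02)
    lognormal_mean = np.exp(PRIOR2.mu_loga1 + PRIOR2.var_loga1 / 2)
    assert post.mean_a1 == pytest.approx(lognormal_mean, rel=0.05)


def test_crm2_strong_data_curve_crosses_target():
    # 30 clean patients at dose 1.5 and 30 all-DLT at dose 7.0
    records = [make_record(i, 0, 3) for i in range(30)]
    records += [make_record(30 + i, 5, 1, dlt_cycle=1) for i in range(30)]
    post = titecrm2_fit(make_dataset(records), PRIOR2)
    curve = post.curve(DOSES)
    assert curve[0] < 0.391 < curve[-1]
    assert np.all(np.diff(curve) > 0)  # a1 > 0 by construction


def test_crm2_complete_data_matches_ml_logistic_oracle():
    # weight-1 data reduce to a binary logistic likelihood; with 200
    # patients the weakly informative prior leaves the implied MTD
    # estimate within a quarter MBq of the ML fit
    rng = np.random.default_rng(42)
    records = []
    true_a0, true_a1 = -2.0, 0.45
    for i in range(200):
        dose = int(rng.integers(0, 6))
        p = 1 / (1 + np.exp(-(true_a0 + true_a1 * DOSES[dose])))
        dlt = bool(rng.uniform() < p)
        records.append(make_record(i, dose, 1 if dlt else 3, dlt_cycle=1 if dlt else None))
    ds = make_dataset(records)
    post = titecrm2_fit(ds, PRIOR2)
    X = sm.add_constant([r.dose_value for r in records])
    y = [int(r.dlt) for r in records]
    ml = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    tau = 0.391
    mtd_ml = (np.log(tau / (1 - tau)) - ml.params[0]) / ml.params[1]
    mtd_post = (np.log(tau / (1 - tau)) - post.mean_a0) / post.mean_a1
    assert mtd_post == pytest.approx(mtd_ml, abs=0.25)


def test_crm2_selected_dose_stable_and_deterministic():
    records = [make_record(i, i % 4, 1 + i % 3) for i in range(12)]
    ds = make_dataset(records)
    c1 = titecrm2_fit(ds, PRIOR2).curve(DOSES)
    c2 = titecrm2_fit(ds, PRIOR2).curve(DOSES)
    assert np.array_equal(c1, c2)
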