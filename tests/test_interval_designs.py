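import numpy as np
import pytest
from scipy import integrate, stats

from latedose import BetaPrior, IntervalSpec, Move, boin_thresholds, titeboin_decision
from latedose.isotonic import isotonic_mtd, pava
from latedose.keyboard import (
    key_edges,
    keyboard_decision,
    keyboard_effective_counts,
    rmtpi2_decision,
)

BOIN_IV = IntervalSpec(0.391, 0.3128, 0.5083)
MTPI2_IV = IntervalSpec(0.391, 0.3519, 0.5474)
FLAT = BetaPrior(1.0, 1.0)
BOIN_PRIOR = BetaPrior(0.1, 0.9)


def summary(n, dlt, complete, pending, stft):
    return {"n": n, "dlt": dlt, "complete": complete, "pending": pending, "stft": stft}


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------


def test_boin_thresholds_calibrated_interval():
    lam_e, lam_d = boin_thresholds(BOIN_IV)
    assert round(lam_d, 4) == 0.4492
    # the printed escalation boundary is reproduced to the rounding of
    # the printed interval bounds (residual ~2e-4)
    assert abs(lam_e - 0.3512) < 5e-4
    assert BOIN_IV.tau1 < lam_e < BOIN_IV.tau < lam_d < BOIN_IV.tau2


def test_boin_thresholds_against_symbolic_oracle():
    # frozen values from an independent 30-digit evaluation of the
    # closed forms at (tau, tau1, tau2) = (0.3, 0.18, 0.42)
    lam_e, lam_d = boin_thresholds(IntervalSpec(0.3, 0.18, 0.42))
    assert lam_e == pytest.approx(0.23649068523646799, abs=1e-12)
    assert lam_d == pytest.approx(0.35851946464092984, abs=1e-12)


def test_boin_thresholds_reject_degenerate_interval():
    with pytest.raises(ValueError):
        IntervalSpec(0.3, 0.3, 0.5)


# ---------------------------------------------------------------------------
# TITE-BOIN
# ---------------------------------------------------------------------------


def test_titeboin_complete_data_is_plain_boin():
    thr = boin_thresholds(BOIN_IV)
    assert titeboin_decision(summary(3, 0, 3, 0, 0.0), thr, BOIN_PRIOR) == Move.ESCALATE
    assert titeboin_decision(summary(3, 3, 0, 0, 0.0), thr, BOIN_PRIOR) == Move.DEESCALATE
    # 2/5 = 0.40 sits between lambda_e = 0.3512 and lambda_d = 0.4492
    assert titeboin_decision(summary(5, 2, 3, 0, 0.0), thr, BOIN_PRIOR) == Move.STAY


def test_titeboin_pending_imputation_fixture():
    # hand trace: 3 treated, 0 DLT, 1 complete, 2 pending with one cycle
    # each (STFT = 2/3).  Posterior mean p = (1+0)/(2+1+2/3) = 0.2727;
    # each pending patient has mean follow-up fraction w = 1/3 and
    # imputed residual risk p(1-w)/(1-p w) = 0.2000; the imputed rate
    # (0 + 2*0.2000)/3 = 0.1333 is below lambda_e = 0.3512 -> escalate.
    thr = boin_thresholds(BOIN_IV)
    move = titeboin_decision(summary(3, 0, 1, 2, 2 / 3), thr, FLAT)
    assert move == Move.ESCALATE
    # same counts but two observed DLTs already clear lambda_d on the
    # observed rate alone -> de-escalate irrespective of pending data
    move = titeboin_decision(summary(3, 2, 0, 1, 1 / 3), thr, FLAT)
    assert move == Move.DEESCALATE


def test_titeboin_requires_treated_patients():
    with pytest.raises(ValueError):
        titeboin_decision(summary(0, 0, 0, 0, 0.0), boin_thresholds(BOIN_IV), FLAT)


# ---------------------------------------------------------------------------
# keyboard / mTPI2
# ---------------------------------------------------------------------------


def test_key_edges_tile_unit_interval():
    edges, target = key_edges(MTPI2_IV)
    assert edges[0] == 0.0 and edges[-1] == 1.0
    assert np.all(np.diff(edges) > 0)
    assert edges[target] == pytest.approx(MTPI2_IV.tau1)
    assert edges[target + 1] == pytest.approx(MTPI2_IV.tau2)
    inner = np.diff(edges)[1:-1]
    assert inner == pytest.approx(np.full(inner.size, MTPI2_IV.tau2 - MTPI2_IV.tau1))


def test_keyboard_effective_counts():
    assert keyboard_effective_counts(summary(6, 1, 5, 0, 0.0)) == (6.0, 1.0)
    # one pending patient at u/S = 1/3 adds 1/3 effective, no events
    n_eff, ev = keyboard_effective_counts(summary(4, 1, 2, 1, 1 / 3))
    assert n_eff == pytest.approx(1 + 2 + 1 / 3)
    assert ev == 1.0


def _keyboard_oracle(n_eff, events, prior, interval):
    """Strongest-key search via direct numerical integration of the
    posterior density (independent of the betainc-based implementation)."""
    a, b = prior.alpha + events, prior.beta + n_eff - events
    edges, target = key_edges(interval)
    masses = [
        integrate.quad(lambda p: stats.beta.pdf(p, a, b), lo, hi, limit=200)[0]
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    strongest = int(np.argmax(masses))
    return (Move.ESCALATE if strongest < target
            else Move.STAY if strongest == target else Move.DEESCALATE)


@pytest.mark.parametrize(
    "n_eff, events",
    [(3, 0), (3, 3), (6, 2), (6, 3), (9, 4), (4.333, 1), (2.667, 0), (7.5, 3)],
)
def test_keyboard_decision_matches_mass_oracle(n_eff, events):
    got = keyboard_decision(float(n_eff), float(events), FLAT, MTPI2_IV)
    assert got == _keyboard_oracle(n_eff, events, FLAT, MTPI2_IV)


def test_keyboard_symmetric_posterior_stays():
    tau = (MTPI2_IV.tau1 + MTPI2_IV.tau2) / 2
    iv = IntervalSpec(tau, MTPI2_IV.tau1, MTPI2_IV.tau2)
    # posterior mean placed mid-key, large n: mass concentrates there
    assert keyboard_decision(40.0, 40.0 * tau, FLAT, iv) == Move.STAY


# ---------------------------------------------------------------------------
# rolling mTPI2
# ---------------------------------------------------------------------------


def test_rmtpi2_agreement_cases():
    # best and worst case agree -> that move (here: escalate with a
    # single pending among many clean completions)
    assert rmtpi2_decision(summary(9, 0, 8, 1, 2 / 3), FLAT, MTPI2_IV) == Move.ESCALATE
    # all observed DLT -> both cases de-escalate
    assert rmtpi2_decision(summary(4, 3, 0, 1, 1 / 3), FLAT, MTPI2_IV) == Move.DEESCALATE


def test_rmtpi2_no_pending_reduces_to_keyboard():
    for n in range(1, 13):
        for m in range(n + 1):
            s = summary(n, m, n - m, 0, 0.0)
            assert rmtpi2_decision(s, FLAT, MTPI2_IV) == keyboard_decision(
                float(n), float(m), FLAT, MTPI2_IV
            )


def test_rmtpi2_disagreement_falls_through_to_consecutive_rule():
    # 3 clean complete + 3 pending: best case 0/6 escalates, worst case
    # 3/6 does not -> consecutive-assignment rule decides
    s = summary(6, 0, 3, 3, 1.0)
    assert keyboard_decision(6.0, 0.0, FLAT, MTPI2_IV) == Move.ESCALATE
    assert keyboard_decision(6.0, 3.0, FLAT, MTPI2_IV) != Move.ESCALATE
    assert rmtpi2_decision(s, FLAT, MTPI2_IV, consecutive_at_dose=3) == Move.STAY
    assert rmtpi2_decision(s, FLAT, MTPI2_IV, consecutive_at_dose=6) == Move.SUSPEND


# ---------------------------------------------------------------------------
# shared properties
# ---------------------------------------------------------------------------


def test_zero_pending_reduction_exhaustive():
    """All three time-to-event rules equal their complete-data
    counterparts for every (n <= 12, m) with no pending patients."""
    thr = boin_thresholds(BOIN_IV)
    lam_e, lam_d = thr
    for n in range(1, 13):
        for m in range(n + 1):
            s = summary(n, m, n - m, 0, 0.0)
            rate = m / n
            expected = (Move.ESCALATE if rate <= lam_e
                        else Move.DEESCALATE if rate >= lam_d else Move.STAY)
            assert titeboin_decision(s, thr, BOIN_PRIOR) == expected
            kb = keyboard_decision(float(n), float(m), FLAT, MTPI2_IV)
            n_eff, ev = keyboard_effective_counts(s)
            assert keyboard_decision(n_eff, ev, FLAT, MTPI2_IV) == kb
            assert rmtpi2_decision(s, FLAT, MTPI2_IV) == kb


_RANK = {Move.ESCALATE: 0, Move.STAY: 1, Move.DEESCALATE: 2, Move.SUSPEND: 1}


def test_decision_monotone_in_dlt_count():
    # adding a DLT (all else fixed) never softens the move
    thr = boin_thresholds(BOIN_IV)
    for n in range(1, 10):
        for m in range(n):
            for pend in range(0, n - m):
                comp = n - m - pend
                s0 = summary(n, m, comp, pend, pend * 0.5)
                s1 = summary(n, m + 1, comp - 1 if comp else comp,
                             pend if comp else pend - 1,
                             (pend if comp else pend - 1) * 0.5)
                if s1["complete"] < 0 or s1["pending"] < 0:
                    continue
                assert _RANK[titeboin_decision(s1, thr, BOIN_PRIOR)] >= _RANK[
                    titeboin_decision(s0, thr, BOIN_PRIOR)
                ]
                e0 = keyboard_effective_counts(s0)
                e1 = keyboard_effective_counts(s1)
                assert _RANK[keyboard_decision(e1[0], e1[1], FLAT, MTPI2_IV)] >= _RANK[
                    keyboard_decision(e0[0], e0[1], FLAT, MTPI2_IV)
                ]


def test_decision_table_is_pure():
    rows1 = [
        keyboard_decision(float(n), float(m), FLAT, MTPI2_IV).value
        for n in range(1, 13) for m in range(n + 1)
    ]
    rows2 = [
        keyboard_decision(float(n), float(m), FLAT, MTPI2_IV).value
        for n in range(1, 13) for m in range(n + 1)
    ]
    assert rows1 == rows2


# ---------------------------------------------------------------------------
# isotonic final selection
# ---------------------------------------------------------------------------


def _pava_oracle(values, weights):
    """Max-min formula for weighted isotonic regression (independent of
    the pool-adjacent-violators implementation)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    n = values.size
    out = np.empty(n)
    for i in range(n):
        best = -np.inf
        for a in range(i + 1):
            worst = np.inf
            for b in range(i, n):
                seg = slice(a, b + 1)
                worst = min(worst, np.average(values[seg], weights=weights[seg]))
            best = max(best, worst)
        out[i] = best
    return out


def test_pava_matches_maxmin_oracle_small_instances():
    rng = np.random.default_rng(0)
    grid = np.round(np.arange(0, 1.01, 0.1), 1)
    # exhaustive over 3 doses, sampled over 4 and 5 doses
    for v in np.stack(np.meshgrid(grid, grid, grid), -1).reshape(-1, 3):
        w = np.ones(3)
        assert pava(v, w) == pytest.approx(_pava_oracle(v, w), abs=1e-9)
    for size in (4, 5):
        for _ in range(120):
            v = rng.choice(grid, size)
            w = rng.integers(1, 7, size).astype(float)
            assert pava(v, w) == pytest.approx(_pava_oracle(v, w), abs=1e-9)


def test_pava_pools_violators():
    assert pava([0.5, 0.2], [3, 3]) == pytest.approx([0.35, 0.35])
    assert pava([0.1, 0.2, 0.3], [3, 3, 3]) == pytest.approx([0.1, 0.2, 0.3])


def test_isotonic_mtd_selection():
    # monotone raw rates: nearest to tau
    assert isotonic_mtd([9, 9, 9], [0, 3, 7], FLAT, 0.391) == 1
    # single treated dose
    assert isotonic_mtd([0, 3, 0], [0, 1, 0], FLAT, 0.391) == 1
    # no treated dose
    assert isotonic_mtd([0, 0], [0, 0], FLAT, 0.391) is None
    # admissibility restricts the choice
    assert isotonic_mtd([9, 9, 9], [0, 3, 7], FLAT, 0.391,
                        admissible=[True, False, False]) == 0


def test_isotonic_mtd_tie_rules():
    # all-clean doses tie exactly below target: directional rule takes
    # the highest tied dose, the "lower" mode the lowest
    n, y = [3, 3, 3], [0, 0, 0]
    assert isotonic_mtd(n, y, FLAT, 0.391) == 2
    assert isotonic_mtd(n, y, FLAT, 0.391, tie="lower") == 0
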