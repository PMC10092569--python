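import numpy as np
import pytest
from hypothesis import given, strategies as st

from latedose import (
    ScenarioSpec,
    cycle1_grade_distribution,
    dlt_cycle,
    grade_type_combination,
    later_cycle_grade_masses,
    nttp_value,
    patient_streams,
    simulate_patient,
)
from latedose.outcomes import NttpWeights, combinations_with_max_grade
from latedose.scenarios import cumulative_dlt_probability


@pytest.mark.parametrize(
    "p1, expected",
    [
        (0.3, (0.25, 0.15, 0.3, 0.15, 0.15)),
        (0.6, (0.0, 0.0, 0.4, 0.3, 0.3)),
        (0.4, (0.0, 0.2, 0.4, 0.2, 0.2)),
    ],
)
def test_cycle1_grade_distribution_examples(p1, expected):
    dist = cycle1_grade_distribution(p1)
    assert dist.mass == pytest.approx(expected, abs=1e-12)


@given(p1=st.floats(0.0, 1.0))
def test_grade_masses_conserve_probability(p1):
    dist = cycle1_grade_distribution(p1)
    assert sum(dist.mass) == pytest.approx(1.0, abs=1e-12)
    # DLT consistency: P(max grade >= 3 in cycle 1) equals p1 exactly
    assert dist[3] + dist[4] == pytest.approx(p1, abs=1e-12)
    assert dist[3] == pytest.approx(dist[4])


def test_grade_masses_sum_on_fine_grid():
    for p1 in np.linspace(0.0, 1.0, 501):
        assert abs(sum(cycle1_grade_distribution(p1).mass) - 1.0) < 1e-12


def test_later_cycle_masses_scaled_by_survivors():
    base = np.array(cycle1_grade_distribution(0.3).mass)
    s2 = np.array(later_cycle_grade_masses(0.3, 2).mass)
    assert s2 == pytest.approx(0.7 * base)
    assert s2.sum() == pytest.approx(0.7)
    s3 = np.array(later_cycle_grade_masses(0.3, 3).mass)
    assert s3 == pytest.approx((1 - 0.37) * base)
    # no attrition when p1 = 0
    assert later_cycle_grade_masses(0.0, 2).mass == cycle1_grade_distribution(0.0).mass
    with pytest.raises(ValueError):
        later_cycle_grade_masses(0.3, 1)


@pytest.fixture(scope="module")
def sc3():
    return ScenarioSpec(dose_values=(1.0, 2.0), p1=(0.3, 0.6), n_cycles=3)


@pytest.mark.parametrize(
    "latent, expected",
    [(0.9, 1), (0.5, None), (0.65, 2), (0.61, 3)],
)
def test_dlt_cycle_interval_lookup(latent, expected, sc3):
    # cumulative probabilities at dose 0 are (0.3, 0.37, 0.391)
    assert dlt_cycle(latent, sc3, 0) == expected


def test_dlt_cycle_marginals_match_increments(sc3):
    # vectorized interval lookup over 1e6 uniforms, cross-checked against
    # the scalar implementation on a subsample
    rng = np.random.default_rng(7)
    z = rng.uniform(size=1_000_000)
    p = sc3.cumulative(0)
    cyc = np.searchsorted(p, 1 - z, side="left") + 1
    cyc[1 - z > p[-1]] = 0  # no DLT
    for i in rng.choice(z.size, 500, replace=False):
        assert dlt_cycle(z[i], sc3, 0) == (int(cyc[i]) or None)
    expected = np.array([p[0], p[1] - p[0], p[2] - p[1]])
    for s in (1, 2, 3):
        freq = np.mean(cyc == s)
        se = np.sqrt(expected[s - 1] * (1 - expected[s - 1]) / z.size)
        assert abs(freq - expected[s - 1]) < 3 * se


def test_shared_latent_coupling_monotone_in_dose(sc3):
    # the same latent is weakly more toxic on the higher dose
    for z in np.linspace(0.01, 0.99, 197):
        lo = dlt_cycle(z, sc3, 0) or 99
        hi = dlt_cycle(z, sc3, 1) or 99
        assert hi <= lo


def test_grade_type_combination_counts():
    assert sum(len(combinations_with_max_grade(g)) for g in range(5)) == 125
    assert len(combinations_with_max_grade(4)) == 5**3 - 4**3 == 61
    assert combinations_with_max_grade(0) == [(0, 0, 0)]
    assert grade_type_combination(0, 0.73) == (0, 0, 0)


@given(g=st.integers(0, 4), u=st.floats(0.0, 0.999999))
def test_grade_type_combination_max_property(g, u):
    triple = grade_type_combination(g, u)
    assert max(triple) == g


def test_grade_type_combination_uniform():
    # index mapping hits every combination with equal width
    combos = combinations_with_max_grade(2)
    picks = {grade_type_combination(2, (i + 0.5) / len(combos)) for i in range(len(combos))}
    assert picks == set(combos)


def test_nttp_values(weights):
    assert nttp_value((0, 0, 0), weights) == 0.0
    # hand evaluation: sqrt(1.0^2 + 0.75^2) / sqrt(1.5^2 + 1.5^2 + 1.0^2)
    assert nttp_value((3, 2, 0), weights) == pytest.approx(1.25 / np.sqrt(5.5), abs=1e-12)
    with pytest.raises(ValueError):
        nttp_value((5, 0, 0), weights)
    with pytest.raises(ValueError):
        nttp_value((1, 1, 1), None)


@given(
    a=st.tuples(*[st.integers(0, 4)] * 3),
    bump=st.tuples(*[st.integers(0, 2)] * 3),
)
def test_nttp_monotone_in_each_grade(a, bump, weights):
    b = tuple(min(4, x + d) for x, d in zip(a, bump))
    assert nttp_value(a, weights) <= nttp_value(b, weights) + 1e-12


def test_nttp_weights_validation():
    with pytest.raises(ValueError):
        NttpWeights.from_matrix([[0, 1, 0.5, 2, 3]] * 3)  # not monotone
    w = NttpWeights.from_matrix([[0, 1, 2, 3, 4]] * 3)
    assert nttp_value((4, 4, 4), w) == pytest.approx(1.0)


def test_simulate_patient_invariants(weights):
    sc = ScenarioSpec(dose_values=(1.0, 2.0, 3.0), p1=(0.2, 0.5, 0.8))
    lat, aux = patient_streams(3, 0, 400, 3)
    for z, a in zip(lat, aux):
        for dose in range(3):
            out = simulate_patient(z, a, sc, dose, weights)
            assert out.cycles_on_study <= sc.n_cycles
            if out.dlt_cycle is not None:
                assert out.cycles_on_study == out.dlt_cycle
                assert out.max_grades[-1] >= 3
            # DLT in cycle s iff max grade >= 3 in that cycle
            for s, g in enumerate(out.max_grades, start=1):
                assert (g >= 3) == (out.dlt_cycle == s)
            assert all(0.0 <= v <= 1.0 for v in out.nttp)
            assert len(out.grade_triples) == out.cycles_on_study
            for g, t in zip(out.max_grades, out.grade_triples):
                assert max(t) == g


def test_simulate_patient_grade_marginals(weights):
    # realized cycle-1 maximum grades reproduce the analytic distribution
    sc = ScenarioSpec(dose_values=(1.0,), p1=(0.3,))
    lat, aux = patient_streams(11, 0, 40_000, 3)
    grades = np.array(
        [simulate_patient(z, a, sc, 0, weights).max_grades[0] for z, a in zip(lat, aux)]
    )
    dist = cycle1_grade_distribution(0.3)
    for g in range(5):
        freq = np.mean(grades == g)
        se = np.sqrt(dist[g] * (1 - dist[g]) / grades.size)
        assert abs(freq - dist[g]) < 3.5 * se


def test_patient_streams_deterministic():
    a = patient_streams(5, 2, 30, 3)
    b = patient_streams(5, 2, 30, 3)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = patient_streams(5, 3, 30, 3)
    assert not np.array_equal(a[0], c[0])
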