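"""Unit and property tests for the age-structured population simulator."""

import heapq
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdgcycle import (
    CellPopulation,
    ParameterError,
    PopulationModelParams,
    advance,
    build_composition_matrix,
    draw_cycle_length,
    infer_cycle_length_from_growth,
    init_synchronized_population,
    malthusian_rate,
    snapshot_age_fractions,
)

T_S = 34.25  # default stalked-daughter birth age, min


# ---------------------------------------------------------------- parameters


@pytest.mark.parametrize(
    "kwargs",
    [
        {"mean_cycle_length": -1.0},
        {"stalked_offset_fraction": 1.0},
        {"cycle_length_cv": -0.1},
        {"interval_width": 0.0},
        {"n_intervals": 5},  # 5 * 20 < 137: intervals do not cover the cycle
        {"measurement_times": (0.0, 20.0, 20.0)},
        {"measurement_times": (-5.0, 20.0)},
        {"harvest_age_max": 137.0},  # >= mean cycle length
        {"n_cells": 0},
        {"stalked_offset_mode": "sideways"},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ParameterError):
        PopulationModelParams(**kwargs)


def test_default_derived_quantities():
    p = PopulationModelParams()
    assert p.stalked_offset == pytest.approx(0.25 * 137.0)
    assert p.harvest_age_max == pytest.approx(p.stalked_offset)
    np.testing.assert_allclose(p.interval_edges, np.arange(8) * 20.0)
    assert len(p.measurement_times) == 10


# ---------------------------------------------------------- cycle-length draw


def test_cycle_length_degenerate_cv_is_exact(rng):
    p = PopulationModelParams(cycle_length_cv=0.0)
    assert all(draw_cycle_length(p, rng) == 137.0 for _ in range(5))


def test_cycle_length_truncated_normal_moments(rng):
    """The sample mean matches the analytic truncated-normal moment; the
    truncation removes <2% of mass, so the mean stays within ~1.5% of t_C;
    every draw exceeds t_S."""
    from scipy import stats

    p = PopulationModelParams()
    draws = np.array([draw_cycle_length(p, rng) for _ in range(2_000)])
    assert np.all(draws > T_S)
    # vectorized path for the tight moment check
    from cdgcycle.population_model import _draw_cycle_lengths

    big = _draw_cycle_lengths(p, rng, 100_000)
    assert np.all(big > T_S)
    sd = 0.35 * 137.0
    a = (T_S - 137.0) / sd
    truncated = stats.truncnorm(a, np.inf, loc=137.0, scale=sd)
    assert stats.norm.cdf(a) < 0.02  # rejected mass
    mc_sigma = truncated.std() / math.sqrt(big.size)
    assert big.mean() == pytest.approx(truncated.mean(), abs=3 * mc_sigma)
    assert truncated.mean() == pytest.approx(137.0, rel=0.015)


# ------------------------------------------------------------ initialization


def test_init_synchronized_limit_all_age_zero(rng):
    p = PopulationModelParams(harvest_age_max=0.0, n_cells=100)
    pop = init_synchronized_population(p, rng)
    assert np.all(pop.internal_ages == 0.0)
    assert pop.elapsed_real_time == 0.0


def test_init_harvest_window_uniform_moment(rng):
    p = PopulationModelParams(n_cells=100_000)
    pop = init_synchronized_population(p, rng)
    assert pop.internal_ages.mean() == pytest.approx(T_S / 2, rel=0.01)
    assert np.all(pop.internal_ages < T_S + 1e-12)  # all in swarmer phase


# -------------------------------------------------------------------- advance


def test_advance_without_division(rng):
    p = PopulationModelParams(cycle_length_cv=0.0)
    pop = CellPopulation(np.array([0.0]), np.array([137.0]))
    out = advance(pop, 100.0, p, rng)
    assert len(out) == 1
    assert out.internal_ages[0] == pytest.approx(100.0)
    assert out.elapsed_real_time == pytest.approx(100.0)


def test_advance_hand_traced_division(rng):
    """One cell dividing at t=137 within a 140-min step leaves two daughters
    that have each aged the residual 3 minutes."""
    p = PopulationModelParams(cycle_length_cv=0.0)
    pop = CellPopulation(np.array([0.0]), np.array([137.0]))
    out = advance(pop, 140.0, p, rng)
    assert len(out) == 2
    assert sorted(out.internal_ages) == pytest.approx([3.0, T_S + 3.0])


def test_advance_rejects_nonpositive_dt(rng):
    p = PopulationModelParams()
    pop = CellPopulation(np.array([0.0]), np.array([137.0]))
    with pytest.raises(ParameterError):
        advance(pop, 0.0, p, rng)


def _event_queue_simulate(founders, t_c, t_s, times):
    """Exact event-driven oracle for cv=0: returns sorted ages per time.

    Each cell is (birth_real_time, birth_age); it divides when
    birth_age + (t - birth_real_time) reaches t_c, producing daughters of
    birth age 0 and t_s at the division instant.
    """
    heap = []  # (division_time, birth_time, birth_age)
    for age in founders:
        heapq.heappush(heap, (t_c - age, 0.0, age))
    results = {}
    for t in times:
        while heap and heap[0][0] <= t:
            div_time, _, _ = heapq.heappop(heap)
            heapq.heappush(heap, (div_time + t_c, div_time, 0.0))
            heapq.heappush(heap, (div_time + (t_c - t_s), div_time, t_s))
        results[t] = np.sort(
            np.array([age + (t - birth) for _, birth, age in heap])
        )
    return results


def test_step_advance_matches_event_queue_oracle(rng):
    """Step-based advance reproduces the exact event-driven simulation's
    population size and sorted ages over 10 cycles for cv=0 founders."""
    p = PopulationModelParams(cycle_length_cv=0.0, n_cells=10)
    founders = np.linspace(0.0, 30.0, 10)
    times = [137.0 * k for k in range(1, 11)]
    oracle = _event_queue_simulate(founders, 137.0, T_S, times)

    pop = CellPopulation(founders.copy(), np.full(10, 137.0))
    now = 0.0
    for t in times:
        # deliberately awkward step size to exercise mid-step divisions
        while now < t:
            dt = min(19.0, t - now)
            pop = advance(pop, dt, p, rng)
            now += dt
        assert len(pop) == oracle[t].size
        np.testing.assert_allclose(
            np.sort(pop.internal_ages), oracle[t], atol=1e-8
        )


# ------------------------------------------------------------------ snapshots


def test_snapshot_synchronized_start():
    pop = CellPopulation(np.zeros(50), np.full(50, 137.0))
    frac = snapshot_age_fractions(pop, np.arange(8) * 20.0)
    np.testing.assert_allclose(frac, [1, 0, 0, 0, 0, 0, 0])


def test_snapshot_uniform_shift_analytic(rng):
    """cv=0 population advanced 40 min without divisions: ages uniform on
    [40, 74.25], so intervals 3 and 4 hold 20/34.25 and 14.25/34.25 of the
    mass (within 3-sigma binomial error at n=1e5)."""
    p = PopulationModelParams(cycle_length_cv=0.0, n_cells=100_000)
    pop = advance(init_synchronized_population(p, rng), 40.0, p, rng)
    frac = snapshot_age_fractions(pop, p.interval_edges)
    p3 = 20.0 / T_S
    sigma = math.sqrt(p3 * (1 - p3) / 100_000)
    assert abs(frac[2] - p3) < 3 * sigma
    assert abs(frac[3] - (1 - p3)) < 3 * sigma
    assert frac.sum() == pytest.approx(1.0, abs=1e-12)


def test_snapshot_clamps_old_cells():
    pop = CellPopulation(np.array([10.0, 150.0, 400.0]), np.full(3, 500.0))
    frac = snapshot_age_fractions(pop, np.arange(8) * 20.0)
    assert frac[0] == pytest.approx(1 / 3)
    assert frac[6] == pytest.approx(2 / 3)  # ages >= 140 land in interval 7


def test_snapshot_empty_population_raises():
    pop = CellPopulation(np.array([]), np.array([]))
    with pytest.raises(ParameterError):
        snapshot_age_fractions(pop, np.arange(8) * 20.0)


# --------------------------------------------------------- composition matrix


def test_composition_matrix_synchronized_deterministic_rows():
    p = PopulationModelParams(
        cycle_length_cv=0.0, harvest_age_max=0.0, n_cells=1_000, seed=7
    )
    F = build_composition_matrix(p)
    np.testing.assert_allclose(F.values[0], [1, 0, 0, 0, 0, 0, 0])
    # at m=120 all cells are exactly 120 min old -> interval 7 ([120, 140))
    row_120 = F.values[list(p.measurement_times).index(120.0)]
    np.testing.assert_allclose(row_120, [0, 0, 0, 0, 0, 0, 1])


def test_composition_matrix_shape_and_partition(default_params):
    F = build_composition_matrix(default_params)
    assert F.values.shape == (10, 7)
    np.testing.assert_allclose(F.values.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(F.values >= 0)


def test_composition_matrix_seed_reproducibility():
    p = PopulationModelParams(n_cells=2_000, seed=99)
    F1 = build_composition_matrix(p)
    F2 = build_composition_matrix(p)
    np.testing.assert_array_equal(F1.values, F2.values)


def test_composition_matrix_csv_round_trip(default_params, tmp_path):
    F = build_composition_matrix(default_params)
    path = tmp_path / "f.csv"
    F.to_csv(path)
    G = type(F).from_csv(path)
    np.testing.assert_allclose(G.values, F.values, atol=1e-12)
    np.testing.assert_allclose(G.row_times, F.row_times)
    np.testing.assert_allclose(G.interval_edges, F.interval_edges)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    mean=st.floats(60.0, 200.0),
    frac=st.floats(0.0, 0.5),
    cv=st.floats(0.0, 0.5),
    seed=st.integers(0, 2**31 - 1),
)
def test_composition_rows_always_partition(mean, frac, cv, seed):
    """Every row of the composition matrix is a probability vector, for any
    parameters and seed."""
    p = PopulationModelParams(
        mean_cycle_length=mean,
        stalked_offset_fraction=frac,
        cycle_length_cv=cv,
        n_intervals=int(np.ceil(mean / 20.0)),
        measurement_times=(0.0, 60.0, 120.0, 180.0),
        n_cells=300,
        seed=seed,
    )
    F = build_composition_matrix(p)
    assert np.all(F.values >= 0) and np.all(F.values <= 1)
    np.testing.assert_allclose(F.values.sum(axis=1), 1.0, atol=1e-9)


# ------------------------------------------------- growth-rate relation


def test_malthusian_rate_symmetric_closed_form():
    assert malthusian_rate(137.0, 0.0) == pytest.approx(
        math.log(2) / 137.0, rel=1e-12
    )


def test_malthusian_rate_pinned_asymmetric_value():
    """Root of 1 = e^(-137 l) + e^(-102.75 l), frozen from an independent
    bisection oracle."""
    assert malthusian_rate(137.0, T_S) == pytest.approx(
        5.823666518043952e-3, rel=1e-9
    )


def test_malthusian_rate_increasing_in_stalked_offset():
    rates = [malthusian_rate(137.0, t_s) for t_s in (0.0, 10.0, 34.25, 60.0)]
    assert all(b > a for a, b in zip(rates, rates[1:]))


def test_malthusian_rate_invalid_offsets():
    with pytest.raises(ParameterError):
        malthusian_rate(137.0, 137.0)
    with pytest.raises(ParameterError):
        malthusian_rate(137.0, -1.0)


def test_infer_cycle_length_round_trips():
    assert infer_cycle_length_from_growth(
        math.log(2) / 137.0, 0.0
    ) == pytest.approx(137.0, abs=1e-6)
    rate = malthusian_rate(137.0, T_S)
    assert infer_cycle_length_from_growth(rate, 0.25) == pytest.approx(
        137.0, abs=1e-4
    )


def test_infer_cycle_length_monotone_in_rate():
    rate = malthusian_rate(137.0, T_S)
    assert infer_cycle_length_from_growth(
        2 * rate, 0.25
    ) < infer_cycle_length_from_growth(rate, 0.25)
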