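"""Egg development, nestling growth, predation and the annual cycle."""

import math

import numpy as np
import pytest

from alauda.agents import (
    Brood,
    Clutch,
    continuous_incubation_days,
    daily_predation,
    daily_requirement,
    incubation_step,
    nestling_daily_step,
    plan_foraging,
    season_cycle,
)
from alauda.params import SkylarkParams


# ------------------------------------------------------------- incubation

@pytest.mark.parametrize("ambient", [-5.0, 10.0, 25.8, 36.1])
def test_uninterrupted_incubation_lasts_exactly_the_minimum(params, ambient):
    """With zero trips the degree-day model hatches at 10.2 days for any
    ambient temperature (the eggs never leave the incubated state)."""
    days = continuous_incubation_days(params, ambient_c=ambient)
    assert days == pytest.approx(params.MINDAYSTOHATCH, abs=1e-9)


def test_trips_at_egg_temperature_cause_no_delay(params):
    """Ambient equal to EGGTEMP: no gradient, trips cost no development."""
    clutch = Clutch(4, lay_day=0, inc_start_day=0)
    req = params.development_requirement()
    days = 0
    while not clutch.hatched:
        incubation_step(clutch, 30, params.EGGTEMP, params)
        days += 1
    # development rate equals the uninterrupted rate
    assert clutch.development >= req
    assert days == math.ceil(params.MINDAYSTOHATCH)


def _numeric_trip_development(ambient, trip_minutes, params, dt_s=0.01):
    """Brute-force integration of the off-nest cooling ODE."""
    k = params.COOLING_RATE_EGGS
    temp = params.EGGTEMP
    acc = 0.0
    t = 0.0
    dt_h = dt_s / 3600.0
    while t < trip_minutes / 60.0:
        acc += max(0.0, temp - params.MD_THRESHOLD) * dt_h
        temp += -k * (temp - ambient) * dt_h
        t += dt_h
    return acc


@pytest.mark.parametrize("ambient", [0.0, 10.0, 20.0, 30.0])
def test_closed_form_trip_cooling_matches_numeric_integration(params, ambient):
    from alauda.agents import _trip_development_degc_hours

    closed = _trip_development_degc_hours(ambient, params.TRIPLENGTH / 60.0, params)
    numeric = _numeric_trip_development(ambient, params.TRIPLENGTH, params)
    assert closed == pytest.approx(numeric, rel=1e-3)


def test_interrupted_incubation_is_delayed_but_bounded(params):
    """30 trips/day at 10 degC ambient: hatch after 10.2 but by day 17."""
    clutch = Clutch(4, lay_day=0, inc_start_day=0)
    days = 0
    while not clutch.hatched and days < 30:
        incubation_step(clutch, 30, 10.0, params)
        days += 1
    assert clutch.hatched
    assert params.MINDAYSTOHATCH < days <= 17


def test_development_is_monotone_in_trips(params):
    gains = []
    for trips in [0, 10, 20, 40]:
        c = Clutch(4, lay_day=0, inc_start_day=0)
        gains.append(incubation_step(c, trips, 5.0, params))
    assert all(g1 > g2 for g1, g2 in zip(gains, gains[1:]))


def test_too_many_trips_rejected(params):
    c = Clutch(4, lay_day=0, inc_start_day=0)
    with pytest.raises(ValueError):
        incubation_step(c, 200, 10.0, params)


# ------------------------------------------------------------- foraging plan

def test_trip_count_is_the_requirement_ceiling(params):
    # requirement exactly one trip's intake -> 1 trip
    assert plan_foraging(0.53, 0.53, 80) == (1, pytest.approx(0.53))
    # fixed scenario: ceil(2.65 / 0.53) = 5 trips
    trips, intake = plan_foraging(2.65, 0.53, 80)
    assert trips == 5 and intake == pytest.approx(2.65)
    # nothing to gain -> no trips, full deficit day
    assert plan_foraging(2.65, 0.0, 80) == (0, 0.0)
    # cap binds
    assert plan_foraging(100.0, 0.5, 10)[0] == 10


def test_cold_weather_adds_thermoregulation_surcharge(params):
    base = daily_requirement(params.thermoreg_threshold_c, params)
    cold = daily_requirement(params.thermoreg_threshold_c - 8.0, params)
    assert base == pytest.approx(params.adult_food_need)
    assert cold == pytest.approx(params.adult_food_need + 8.0 * params.thermoreg_slope)


# ------------------------------------------------------------- nestlings

def test_unlimited_food_gives_maximum_growth(params):
    rng = np.random.default_rng(0)
    brood = Brood(n=4, hatch_day=0)
    m0 = brood.masses[0]
    nestling_daily_step(brood, 1e6, params, rng)
    assert brood.masses[0] == pytest.approx(m0 + 4.54)


def test_starvation_kills_after_the_configured_days(params):
    rng = np.random.default_rng(0)
    brood = Brood(n=4, hatch_day=0)
    outcomes = [nestling_daily_step(brood, 0.0, params, rng)
                for _ in range(params.starvation_days_to_death)]
    assert outcomes[-1] == "starved"
    assert not brood.alive


def test_nest_leaving_frequency_matches_binomial_oracle(params):
    """First-eligible-day leaving ~ Binomial(n, 0.23) within 3 sigma."""
    n = 10_000
    rng = np.random.default_rng(123)
    left = 0
    for _ in range(n):
        brood = Brood(n=4, hatch_day=0, age_days=params.min_nest_leave_age - 1)
        if nestling_daily_step(brood, 1e6, params, rng) == "left":
            left += 1
    p = 0.23
    sigma = math.sqrt(n * p * (1 - p))
    assert abs(left - n * p) < 3 * sigma


def test_brood_always_leaves_by_the_maximum_age(params):
    rng = np.random.default_rng(0)
    brood = Brood(n=4, hatch_day=0)
    outcome = None
    for _ in range(params.max_nestling_age):
        outcome = nestling_daily_step(brood, 1e6, params, rng)
        if outcome == "left":
            break
    assert outcome == "left"
    assert params.min_nest_leave_age <= brood.age_days <= params.max_nestling_age


# ------------------------------------------------------------- predation

def test_zero_probability_always_survives():
    rng = np.random.default_rng(0)
    assert all(daily_predation(0.0, rng) for _ in range(1000))


def test_predation_survival_matches_closed_form():
    """p = 0.035/day over 11 days: survival ~ 0.965^11 ~ 0.676."""
    n = 100_000
    rng = np.random.default_rng(7)
    p = 0.035
    days = 11
    survived = sum(
        all(daily_predation(p, rng) for _ in range(days)) for _ in range(n)
    )
    expect = (1 - p) ** days
    sigma = math.sqrt(n * expect * (1 - expect))
    assert abs(survived - n * expect) < 3 * sigma


def test_same_seed_gives_identical_fate_sequence():
    rng_a, rng_b = np.random.default_rng(5), np.random.default_rng(5)
    a = [daily_predation(0.3, rng_a) for _ in range(100)]
    b = [daily_predation(0.3, rng_b) for _ in range(100)]
    assert a == b


def test_higher_clutch_mortality_weakly_increases_predated_fraction():
    days = 11
    n = 20_000
    fractions = []
    for prob in [0.01, 0.035, 0.08]:
        rng = np.random.default_rng(99)
        lost = sum(
            not all(daily_predation(prob, rng) for _ in range(days))
            for _ in range(n)
        )
        fractions.append(lost / n)
    assert fractions == sorted(fractions)


# ------------------------------------------------------------- annual cycle

def test_total_return_mortality_removes_everyone(params):
    rng = np.random.default_rng(0)
    p = params.replace(ADULTRETURNMORT=100)
    adults, _ = season_cycle(1000, 0, p, rng)
    assert adults == 0


def test_return_survival_matches_binomial_oracle(params):
    """1000 adults at 35% mortality: ~650 return, within 3 sigma."""
    rng = np.random.default_rng(11)
    n = 1000
    totals = [season_cycle(n, 0, params, rng)[0] for _ in range(100)]
    p = 0.65
    sigma = math.sqrt(n * p * (1 - p))
    for t in totals:
        assert abs(t - n * p) < 4 * sigma  # individual draws
    assert abs(np.mean(totals) - n * p) < 3 * sigma / math.sqrt(100)


def test_juvenile_survival_is_independent_of_adults(params):
    rng = np.random.default_rng(3)
    adults, juveniles = season_cycle(500, 0, params, rng)
    assert juveniles == 0
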