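"""Skylark agent physiology and behaviour primitives.

Scalar, side-effect-light functions for habitat scoring, foraging
accessibility, rain hindrance, food intake, degree-day egg development
with trip-interrupted incubation, nestling growth, daily predation and
the between-season return-mortality step.  The simulation engine applies
vectorised equivalents of the per-cell functions; these scalar forms are
the reference definitions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import ElementType, VegetationState
from .params import SkylarkParams

#: Height bands (cm) of the habitat-score piecewise definition.
BARE_MAX_CM = 3.0
CROP_BAND_MAX_CM = 110.0
TALL_BAND_MAX_CM = 200.0
TALLVEG_BAND_MAX_CM = 300.0


def habitat_score_cell(
    veg: VegetationState,
    params: SkylarkParams,
    element_type: ElementType = ElementType.FIELD,
    tramlines_open: bool = False,
    has_scrapes: bool = False,
) -> float:
    """Quality score per m^2 of one cell.

    Piecewise in vegetation height: bare earth (< 3 cm) is good open
    habitat; the 3 cm - 1.1 m crop band is the baseline score reduced by
    power laws in height and density above their thresholds; taller
    vegetation scores negatively and hedgerow/woodland strongly so.
    Patchiness, open tramlines and scrapes add premiums.
    """
    h = veg.height_cm
    if element_type in (ElementType.HEDGEROW, ElementType.WOODLAND) or h > TALLVEG_BAND_MAX_CM:
        base = params.HQHEDGE
    elif element_type in (ElementType.ROAD, ElementType.BUILDING, ElementType.WATER):
        return 0.0
    elif h < BARE_MAX_CM:
        base = params.HQBAREEARTH
    elif h <= CROP_BAND_MAX_CM:
        f_h = min(1.0, (h / params.HEIGHTCONST_C) ** params.HEIGHTCONST_B)
        d = veg.density
        f_d = 1.0 if d <= 0 else min(1.0, (d / params.DENSITYCONST_C) ** params.DENSITYCONST_B)
        base = params.q0_crop_score * f_h * f_d
    elif h <= TALL_BAND_MAX_CM:
        base = params.HQTALL
    else:
        base = params.HQTALLVEG
    if veg.is_patchy and h < TALL_BAND_MAX_CM:
        base += params.PATCHYPREMIUM
    if tramlines_open:
        base += params.TRAMLINEPREMIUM
    if has_scrapes:
        base += params.SKSCRAPESPREMIUM
    return base


def foraging_accessibility(
    veg: VegetationState,
    params: SkylarkParams,
    enhanced: bool = False,
) -> float:
    """Fraction of food physically accessible in [0, 1].

    Accessibility declines linearly with height and density above their
    thresholds; open tramlines or scrapes (``enhanced``) reduce the
    resulting hindrance by the TRAMLINE_FORAGING proportion.
    """
    h, d = veg.height_cm, veg.density
    a_h = 1.0
    if h > params.HEIGHTCONST_C:
        a_h = min(1.0, max(0.0, 1.0 + params.HINDCONSTH_B * (h - params.HEIGHTCONST_C)))
    a_d = 1.0
    if d > params.DENSITYCONST_C:
        a_d = min(1.0, max(0.0, 1.0 + params.HINDCONSTD_B * (d - params.DENSITYCONST_C)))
    hindrance = 1.0 - a_h * a_d
    if enhanced:
        hindrance *= 1.0 - params.TRAMLINE_FORAGING
    return 1.0 - hindrance


def rain_hindrance(precipitation_mm: float, params: SkylarkParams) -> float:
    """Fraction of foraging lost to rain; 1 at/above MAXFEEDRAIN mm/day."""
    if precipitation_mm < 0:
        raise ValueError("precipitation must be >= 0")
    if precipitation_mm == 0:
        return 0.0
    if precipitation_mm >= params.MAXFEEDRAIN:
        return 1.0
    return min(1.0, (precipitation_mm / params.MAXFEEDRAIN) ** params.RAINHINDPOW)


def foraging_intake(
    food_access_pairs,
    precipitation_mm: float,
    minutes: float,
    params: SkylarkParams,
) -> float:
    """Food units extracted in ``minutes`` of foraging.

    ``food_access_pairs`` iterates over (insect_food, accessibility) for
    the cells available to the forager.  The best cells are used first;
    without depletion this is the best instantaneous rate times time.
    """
    if minutes < 0:
        raise ValueError("minutes must be >= 0")
    rh = rain_hindrance(precipitation_mm, params)
    if rh >= 1.0 or minutes == 0:
        return 0.0
    best = max((f * a for f, a in food_access_pairs), default=0.0)
    return best * params.EXTRACTION_RATE * (1.0 - rh) * minutes


# ----------------------------------------------------------------------
# Egg development
# ----------------------------------------------------------------------

@dataclass
class Clutch:
    n_eggs: int
    lay_day: int                      # absolute day the first egg was laid
    inc_start_day: int | None = None  # absolute day incubation began
    development: float = 0.0          # accumulated degC-days above threshold
    alive: bool = True
    hatched: bool = False
    stage: str = "clutch"


def _trip_development_degc_hours(
    ambient_c: float, trip_hours: float, params: SkylarkParams
) -> float:
    """Closed-form degC-hours above threshold during one off-nest bout.

    Egg temperature decays exponentially from EGGTEMP toward ambient at
    rate COOLING_RATE_EGGS per hour; rewarming on return is instant.
    """
    e, m, k = params.EGGTEMP, params.MD_THRESHOLD, params.COOLING_RATE_EGGS
    dt0 = e - ambient_c
    if k <= 0:
        return max(0.0, e - m) * trip_hours
    if ambient_c >= m:
        # temperature stays above threshold for the whole bout
        return (ambient_c - m) * trip_hours + dt0 * (1.0 - math.exp(-k * trip_hours)) / k
    if dt0 <= m - ambient_c:   # egg starts at or below threshold
        return 0.0
    t_cross = math.log(dt0 / (m - ambient_c)) / k
    t = min(trip_hours, t_cross)
    return (ambient_c - m) * t + dt0 * (1.0 - math.exp(-k * t)) / k


def incubation_step(
    clutch: Clutch,
    n_trips: int,
    ambient_c: float,
    params: SkylarkParams,
) -> float:
    """Advance one day of incubation; returns degC-days of development gained.

    The day is split into incubated time (egg at EGGTEMP) and ``n_trips``
    off-nest bouts of TRIPLENGTH minutes each, cooling toward ambient.
    Development accrues as the integral of the positive temperature
    excess over MD_THRESHOLD; the clutch hatches when accumulated
    development reaches MINDAYSTOHATCH x (EGGTEMP - MD_THRESHOLD).
    """
    trip_hours = params.TRIPLENGTH / 60.0
    off_hours = n_trips * trip_hours
    if off_hours > 24.0:
        raise ValueError("trips exceed the day length")
    on_hours = 24.0 - off_hours
    degc_hours = max(0.0, params.EGGTEMP - params.MD_THRESHOLD) * on_hours
    if n_trips > 0:
        degc_hours += n_trips * _trip_development_degc_hours(ambient_c, trip_hours, params)
    gained = degc_hours / 24.0
    clutch.development += gained
    if clutch.development >= params.development_requirement():
        clutch.hatched = True
    return gained


def continuous_incubation_days(
    params: SkylarkParams, ambient_c: float = 15.0, max_days: int = 1000
) -> float:
    """Fractional incubation length with zero trips (uninterrupted).

    Runs the daily development step and interpolates the hatch instant
    within the hatch day; equals MINDAYSTOHATCH by construction of the
    development requirement.
    """
    clutch = Clutch(n_eggs=4, lay_day=0, inc_start_day=0)
    req = params.development_requirement()
    for day in range(1, max_days + 1):
        before = clutch.development
        gained = incubation_step(clutch, 0, ambient_c, params)
        if clutch.hatched:
            if gained <= 0:
                return float(day)
            return (day - 1) + (req - before) / gained
    raise RuntimeError("no hatch within max_days (development threshold too high)")


# ----------------------------------------------------------------------
# Nestlings and broods
# ----------------------------------------------------------------------

@dataclass
class Brood:
    n: int
    hatch_day: int
    age_days: int = 0
    masses: list = field(default_factory=list)
    poor_growth_days: int = 0
    alive: bool = True
    left_nest: bool = False
    stage: str = "nestling"

    def __post_init__(self):
        if not self.masses:
            self.masses = [2.0] * self.n   # hatchling mass, g


def nestling_daily_step(
    brood: Brood,
    food_delivered: float,
    params: SkylarkParams,
    rng: np.random.Generator,
) -> str | None:
    """One day of nestling growth; returns "left", "starved" or None.

    Each nestling grows by min(PEMAX, assimilation x equal food share).
    Persistent growth below a configured fraction of PEMAX kills the
    brood ("other" mortality).  From the minimum nest-leaving age the
    brood leaves with the daily NESTLEAVECHANCE probability, and always
    by the maximum nestling age.
    """
    if not brood.alive or brood.left_nest:
        return None
    share = food_delivered / brood.n if brood.n else 0.0
    growth = min(params.PEMAX, params.assimilation_efficiency * share)
    brood.masses = [m + growth for m in brood.masses]
    if growth < params.starvation_growth_fraction * params.PEMAX:
        brood.poor_growth_days += 1
    else:
        brood.poor_growth_days = 0
    brood.age_days += 1
    if brood.poor_growth_days >= params.starvation_days_to_death:
        brood.alive = False
        return "starved"
    if brood.age_days >= params.min_nest_leave_age:
        if (
            brood.age_days >= params.max_nestling_age
            or rng.random() < params.nest_leave_daily()
        ):
            brood.left_nest = True
            return "left"
    return None


def daily_predation(daily_prob: float, rng: np.random.Generator) -> bool:
    """One day of nest predation risk; True means the nest survives."""
    if daily_prob <= 0.0:
        return True
    return rng.random() >= daily_prob


# ----------------------------------------------------------------------
# Adults
# ----------------------------------------------------------------------

class BirdState(enum.Enum):
    ARRIVING = "arriving"
    TERRITORY_SEARCH = "territory_search"
    PRE_BREEDING = "pre_breeding"
    EGG_LAYING = "egg_laying"
    INCUBATING = "incubating"
    CARING_YOUNG = "caring_young"
    POST_BREEDING = "post_breeding"
    DEPARTED = "departed"


@dataclass
class Skylark:
    bird_id: int
    sex: str                          # "M" or "F"
    state: BirdState = BirdState.ARRIVING
    arrival_doy: int = 0
    territory_id: int | None = None
    deficit_days: int = 0
    attempts: int = 0


def daily_requirement(
    mean_temp_c: float, params: SkylarkParams, brood_demand: float = 0.0
) -> float:
    """Adult daily food requirement: maintenance + cold surcharge + brood."""
    surcharge = max(0.0, params.thermoreg_threshold_c - mean_temp_c) * params.thermoreg_slope
    return params.adult_food_need + surcharge + brood_demand


def plan_foraging(
    requirement: float, intake_per_trip: float, max_trips: int
) -> tuple[int, float]:
    """Trips taken and food obtained for a daily requirement.

    The bird takes ceil(requirement / intake-per-trip) trips, capped by
    the trip budget; when foraging yields nothing it stays put (0 trips).
    """
    if intake_per_trip <= 0.0 or requirement <= 0.0:
        return 0, 0.0
    trips = min(max_trips, math.ceil(requirement / intake_per_trip - 1e-12))
    return trips, trips * intake_per_trip


def season_cycle(
    n_adults: int,
    n_juveniles: int,
    params: SkylarkParams,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Overwinter/return survival applied between breeding seasons.

    Returns (returning adults, returning first-years); each individual
    survives independently with 1 - mortality.
    """
    ad = int(rng.binomial(n_adults, params.adult_return_survival())) if n_adults else 0
    jv = int(rng.binomial(n_juveniles, params.juvenile_return_survival())) if n_juveniles else 0
    return ad, jv
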