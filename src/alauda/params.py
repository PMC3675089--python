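"""Model parameters for the skylark simulation.

The thirty named, fitted parameters (upper-case fields) are the single
source of truth for calibration and for the one-at-a-time sensitivity
harness; every one of them can be overridden individually.  The
lower-case fields are structural design constants of this implementation
(energetics bookkeeping, breeding calendar, territory geometry) that the
published parameter set does not cover.

Units follow field convention: heights in cm, densities on a 0-100
arbitrary scale, temperatures in degrees Celsius, precipitation in
mm/day, food in arbitrary units (the extraction rate is per unit food
per m^2 per minute), scores in quality units per m^2, areas in m^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterator

import yaml


@dataclass
class SkylarkParams:
    # --- Energetics ---
    #: Rate of food extraction, per arbitrary unit food m^-2 minute^-1.
    EXTRACTION_RATE: float = 0.00053
    #: Linear decrease of foraging accessibility per cm of vegetation height
    #: above HEIGHTCONST_C (negative slope).
    HINDCONSTH_B: float = -0.025
    #: Linear decrease of foraging accessibility per density unit above
    #: DENSITYCONST_C (negative slope).
    HINDCONSTD_B: float = -0.22
    #: Precipitation (mm/day) at which foraging is prevented entirely.
    MAXFEEDRAIN: float = 4.7
    #: Maximum nestling growth rate, g/day.
    PEMAX: float = 4.54
    #: Power of the curve relating feeding hindrance to rainfall.
    RAINHINDPOW: float = 4
    #: Proportional reduction of foraging hindrance on fields with open
    #: tramlines or skylark scrapes.
    TRAMLINE_FORAGING: float = 0.45
    # --- Mortality ---
    #: Overwinter + return mortality for adults, percent.
    ADULTRETURNMORT: float = 35
    #: Daily clutch predation probability, as an integer scaled by
    #: ``predation_prob_scale`` (350 -> 0.035/day at the default scale).
    CLUTCH_MORT_PROB: float = 350
    #: Overwinter + return mortality for birds fledged the previous
    #: season, percent.
    JUVRETURNMORT: float = 35.0
    #: Daily nestling predation probability, scaled like CLUTCH_MORT_PROB.
    NEST_MORT_PROB: float = 23
    # --- Reproduction ---
    #: Cooling rate of unincubated eggs, degC h^-1 per degC of
    #: egg-to-ambient gradient.
    COOLING_RATE_EGGS: float = 3
    #: Egg temperature while incubated, degC.
    EGGTEMP: float = 36.1
    #: Threshold temperature for physiological egg development, degC.
    MD_THRESHOLD: float = 25.8
    #: Minimum incubation time at optimal (uninterrupted) incubation, days.
    MINDAYSTOHATCH: float = 10.2
    #: Daily probability (percent) of leaving the nest once the minimum
    #: nest-leaving age is reached.
    NESTLEAVECHANCE: float = 23
    #: Duration of one female feeding trip off the nest, minutes.
    TRIPLENGTH: float = 10.5
    # --- Territory quality ---
    #: Exponent for habitat-score reduction with vegetation density above
    #: DENSITYCONST_C (3 cm - 1.1 m vegetation band).
    DENSITYCONST_B: float = -0.26
    #: Exponent for habitat-score reduction with vegetation height above
    #: HEIGHTCONST_C (3 cm - 1.1 m vegetation band).
    HEIGHTCONST_B: float = -0.22
    #: Quality score/m^2 of habitat with vegetation below 3 cm.
    HQBAREEARTH: float = 3
    #: Quality score/m^2 of hedgerows, woodland and other objects > 3 m.
    HQHEDGE: float = -250
    #: Quality score/m^2 for vegetation between 1.1 m and 2 m.
    HQTALL: float = -2
    #: Quality score/m^2 for vegetation between 2 m and 3 m.
    HQTALLVEG: float = -10
    #: Minimum total territory score for female acceptance.
    MINFEMACCEPTSCORE: float = 300000
    #: Extra score/m^2 for patchy, accessible habitat under 2 m.
    PATCHYPREMIUM: float = 47
    #: Extra score/m^2 for fields provided with skylark scrapes.
    SKSCRAPESPREMIUM: float = 0.24
    #: Extra score/m^2 for fields with open tramlines.
    TRAMLINEPREMIUM: float = 6
    #: Density threshold above which density reduces quality/accessibility.
    DENSITYCONST_C: float = 10
    #: Height threshold (cm) above which height reduces quality/accessibility.
    HEIGHTCONST_C: float = 38.0
    #: Days that tramlines remain open after the operation that made them.
    TRAMLINE_DECAYTIME: float = 21

    # --- Design constants: habitat & territory geometry ---
    #: Baseline quality score/m^2 for crop vegetation in the 3 cm - 1.1 m
    #: band before the height/density power-law reductions.
    q0_crop_score: float = 40.0
    #: Territory area, m^2 (square block).
    territory_area_m2: float = 10000.0
    #: An occupied territory may split when its total score reaches this
    #: multiple of MINFEMACCEPTSCORE and both halves stay acceptable.
    split_threshold_multiplier: float = 2.0
    #: Scale applied to CLUTCH_MORT_PROB / NEST_MORT_PROB to obtain a
    #: daily probability (printed values are bare integers).
    predation_prob_scale: float = 1e-4
    #: Scale applied to the percent-valued mortality/behaviour parameters.
    percent_scale: float = 1e-2

    # --- Design constants: energetics ---
    #: Adult daily maintenance requirement, food units/day.
    adult_food_need: float = 2.5
    #: Extra requirement per degC below the cold threshold, units/degC/day.
    thermoreg_slope: float = 0.05
    #: Mean daily temperature below which thermoregulation costs accrue, degC.
    thermoreg_threshold_c: float = 10.0
    #: Grams of nestling growth per food unit assimilated.
    assimilation_efficiency: float = 0.7
    #: Minutes of daylight available for foraging per adult per day.
    daylight_foraging_minutes: float = 840.0
    #: Cap on feeding trips per day while incubating.
    max_incubation_trips: int = 40
    #: Consecutive days of energy shortfall before a nest is abandoned.
    deficit_days_to_abandon: int = 3
    #: Fraction of PEMAX below which a nestling-day counts as failed growth.
    starvation_growth_fraction: float = 0.25
    #: Consecutive failed-growth days before nestlings die ("other").
    starvation_days_to_death: int = 3

    # --- Design constants: reproduction calendar ---
    #: Possible clutch sizes, drawn uniformly.
    clutch_sizes: tuple = (3, 4, 5)
    #: Vegetation height window (cm) suitable for nest initiation.
    nest_height_window_cm: tuple = (10.0, 60.0)
    #: Minimum nestling age (days) before the brood may leave the nest.
    min_nest_leave_age: int = 7
    #: Age (days) at which a brood still in the nest leaves regardless.
    max_nestling_age: int = 11
    #: Age (days post-hatch) at which young become independent.
    independence_age: int = 30
    #: Daily survival of pre-fledglings (out of nest, still dependent).
    prefledgling_daily_survival: float = 0.985
    #: Arrival window (day-of-year, inclusive): mid-March to mid-April.
    arrival_start_doy: int = 75
    arrival_end_doy: int = 105
    #: Last day-of-year a new breeding attempt may be initiated (31 July).
    last_initiation_doy: int = 212
    #: End of the field season (departure), day-of-year.
    season_end_doy: int = 273

    def replace(self, **overrides: Any) -> "SkylarkParams":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    # -- probability helpers keeping the printed scales in one place --

    def clutch_predation_daily(self) -> float:
        return min(1.0, self.CLUTCH_MORT_PROB * self.predation_prob_scale)

    def nestling_predation_daily(self) -> float:
        return min(1.0, self.NEST_MORT_PROB * self.predation_prob_scale)

    def adult_return_survival(self) -> float:
        return max(0.0, 1.0 - self.ADULTRETURNMORT * self.percent_scale)

    def juvenile_return_survival(self) -> float:
        return max(0.0, 1.0 - self.JUVRETURNMORT * self.percent_scale)

    def nest_leave_daily(self) -> float:
        return min(1.0, self.NESTLEAVECHANCE * self.percent_scale)

    def development_requirement(self) -> float:
        """Degree-days (above MD_THRESHOLD) required for hatching."""
        return self.MINDAYSTOHATCH * (self.EGGTEMP - self.MD_THRESHOLD)

    # -- serialisation --

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clutch_sizes"] = list(self.clutch_sizes)
        d["nest_height_window_cm"] = list(self.nest_height_window_cm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SkylarkParams":
        d = dict(d)
        for key in ("clutch_sizes", "nest_height_window_cm"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SkylarkParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: The thirty named fitted parameters, in published order.
TABLE_PARAMETERS: tuple = (
    "EXTRACTION_RATE", "HINDCONSTH_B", "HINDCONSTD_B", "MAXFEEDRAIN",
    "PEMAX", "RAINHINDPOW", "TRAMLINE_FORAGING", "ADULTRETURNMORT",
    "CLUTCH_MORT_PROB", "JUVRETURNMORT", "NEST_MORT_PROB",
    "COOLING_RATE_EGGS", "EGGTEMP", "MD_THRESHOLD", "MINDAYSTOHATCH",
    "NESTLEAVECHANCE", "TRIPLENGTH", "DENSITYCONST_B", "HEIGHTCONST_B",
    "HQBAREEARTH", "HQHEDGE", "HQTALL", "HQTALLVEG", "MINFEMACCEPTSCORE",
    "PATCHYPREMIUM", "SKSCRAPESPREMIUM", "TRAMLINEPREMIUM",
    "DENSITYCONST_C", "HEIGHTCONST_C", "TRAMLINE_DECAYTIME",
)

#: Parameters whose fitted values are printed as small integers; the
#: sensitivity protocol perturbs these by +-1/2/4/8 instead of percentages.
INTEGER_PARAMETERS: frozenset = frozenset({
    "RAINHINDPOW", "ADULTRETURNMORT", "NEST_MORT_PROB", "COOLING_RATE_EGGS",
    "NESTLEAVECHANCE", "HQBAREEARTH", "HQTALL", "HQTALLVEG",
    "PATCHYPREMIUM", "TRAMLINEPREMIUM", "DENSITYCONST_C",
    "TRAMLINE_DECAYTIME",
})
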