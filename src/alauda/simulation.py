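"""The daily simulation loop: weather -> farming -> vegetation/insects ->
skylark agents, over a sequence of 365-day years.

Population dynamics are emergent: males acquire territories scored from
the day's vegetation, females accept and breed, reproduction is driven
by degree-day egg development and energetics-limited provisioning, and
mortality arises from predation draws, starvation, farm operations and
overwinter return losses.  The run emits a structured event log and a
daily population table from which all observation protocols can be
computed.

Per-polygon vegetation, insect and habitat-score updates are vectorised
over the polygon table; they implement exactly the scalar per-cell
functions in :mod:`alauda.agents` (cross-checked by the test suite).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from dataclasses import replace as veg_replace

import numpy as np
import pandas as pd

from .agents import (
    BirdState,
    Brood,
    Clutch,
    Skylark,
    daily_predation,
    daily_requirement,
    incubation_step,
    nestling_daily_step,
    plan_foraging,
    rain_hindrance,
    season_cycle,
)
from .farming import CropPlan, Farm, apply_operation, default_crop_plans, step_farm_day
from .landscape import DEFAULT_CURVES, ElementType, InsectParams, LandscapeGrid
from .params import SkylarkParams
from .territory import Territory, TerritoryManager
from .weather import DAYS_PER_YEAR

#: Days after a failed or finished attempt before a new nest is started.
RENEST_DELAY_DAYS = 5
#: Minimum pre-fledgling age (days post-hatch) assumed independent when
#: the season ends before the nominal independence age.
SEASON_END_INDEPENDENCE_AGE = 15

EVENT_COLUMNS = ["year", "doy", "kind", "agent", "value", "polygon", "row", "col", "cause"]


@dataclass
class Pair:
    pair_id: int
    male: Skylark
    female: Skylark
    territory: Territory
    nest_id: str | None = None
    nest_poly: int | None = None      # polygon index of the active nest
    clutch: Clutch | None = None
    eggs_laid: int = 0
    brood: Brood | None = None
    next_attempt_day: int = 0
    stage: str | None = None          # exposed to farm-operation destruction

    @property
    def nest_stage(self) -> str | None:
        # presence-based: terminal events always clear the references, so
        # a still-referenced brood/clutch is the active nest stage even if
        # its alive flag was just cleared by the step that killed it
        if self.brood is not None and not self.brood.left_nest:
            return "nestling"
        if self.clutch is not None and not self.clutch.hatched:
            return "clutch"
        return None


@dataclass
class SimResult:
    events: pd.DataFrame
    daily: pd.DataFrame
    years: int
    seed: int


class Simulation:
    """One reproducible run over a landscape, farm set and weather series."""

    def __init__(
        self,
        grid: LandscapeGrid,
        farms: list[Farm],
        weather: pd.DataFrame,
        params: SkylarkParams | None = None,
        seed: int = 0,
        plans: dict[str, CropPlan] | None = None,
        insects: InsectParams | None = None,
        initial_pairs: int = 10,
    ):
        self.grid = grid
        # private copies: a run must not mutate the caller's objects, so
        # repeated runs from the same scenario are independent
        self.polys = copy.deepcopy(grid.polygons)
        self.farms = copy.deepcopy(farms)
        self.params = params or SkylarkParams()
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.plans = plans or default_crop_plans()
        self.insects = insects or InsectParams()
        self.initial_pairs = int(initial_pairs)
        self._validate_config()
        self._setup_polygon_arrays()
        self._weather_temp = weather["mean_temp"].to_numpy(dtype=float)
        self._weather_rain = weather["precipitation"].to_numpy(dtype=float)
        self.events: list[tuple] = []
        self.daily_rows: list[tuple] = []

    # ------------------------------------------------------------------
    # setup
    # ------------------------------------------------------------------

    def _validate_config(self) -> None:
        field_ids = [f for farm in self.farms for f in farm.field_ids]
        if len(set(field_ids)) != len(field_ids):
            raise ValueError("a field may belong to only one farm")
        for farm in self.farms:
            if not farm.rotation:
                raise ValueError(f"farm {farm.farm_id} has no rotation assigned")
            for f in farm.field_ids:
                if f not in self.grid.index_of:
                    raise ValueError(f"farm {farm.farm_id} references unknown field {f}")
            for crop in farm.rotation:
                if crop not in self.plans:
                    raise ValueError(
                        f"farm {farm.farm_id} rotation uses unknown crop {crop!r}"
                    )

    def _setup_polygon_arrays(self) -> None:
        polys = self.polys
        n = len(polys)
        self.n_poly = n
        et = [p.element_type for p in polys]
        self.hedge_like = np.array(
            [e in (ElementType.HEDGEROW, ElementType.WOODLAND) for e in et]
        )
        self.zero_score = np.array(
            [e in (ElementType.ROAD, ElementType.BUILDING, ElementType.WATER) for e in et]
        )
        self.field_like = np.array(
            [e in (ElementType.FIELD, ElementType.PERMANENT_GRASS, ElementType.FIELD_MARGIN)
             for e in et]
        )
        self.coef = np.array([self.insects.element_coefficients.get(e, 0.0) for e in et])
        self.patchy = np.array([p.veg.is_patchy for p in polys])
        self.scrapes = np.array([p.has_scrapes for p in polys])
        self.always_open = np.array([p.tramlines_always_open for p in polys])
        self.tram_until = np.full(n, -np.inf)
        self.knock_factor = np.ones(n)
        self.knock_day = np.full(n, -np.inf)
        self.has_curve = np.zeros(n, dtype=bool)
        self.t_base = np.zeros(n)
        self.t_scale = np.ones(n)
        self.g_rate = np.zeros(n)
        self.b_max = np.ones(n)
        self.h_max = np.zeros(n)
        self.d_max = np.zeros(n)
        self.growing = np.zeros(n, dtype=bool)
        self.biomass = np.zeros(n)
        self.height = np.zeros(n)
        self.density = np.zeros(n)
        for i, p in enumerate(polys):
            self.biomass[i] = p.veg.biomass
            self.height[i] = p.veg.height_cm
            self.density[i] = p.veg.density
            if p.growth_curve is not None:
                c = DEFAULT_CURVES[p.growth_curve]
                self.has_curve[i] = True
                self.t_base[i], self.t_scale[i] = c.t_base_c, c.t_scale_c
                self.g_rate[i], self.b_max[i] = c.rate, c.biomass_max
                self.h_max[i], self.d_max[i] = c.height_max_cm, c.density_max
                if p.element_type != ElementType.FIELD:
                    self.growing[i] = True  # non-crop vegetation grows from day one
        self.insect_food = np.zeros(n)
        self.mgr = TerritoryManager(self.grid, self.params)
        self._cell_area = self.grid.cell_size**2

    # ------------------------------------------------------------------
    # vectorised daily landscape updates
    # ------------------------------------------------------------------

    def _grow_vegetation(self, mean_temp: float) -> None:
        tf = np.maximum(0.0, mean_temp - self.t_base) / self.t_scale
        mask = self.has_curve & self.growing & (self.biomass > 0) & (tf > 0)
        if mask.any():
            b = self.biomass[mask]
            b = np.minimum(
                self.b_max[mask],
                b + self.g_rate[mask] * b * (1 - b / self.b_max[mask]) * tf[mask],
            )
            self.biomass[mask] = b
            frac = b / self.b_max[mask]
            self.height[mask] = self.h_max[mask] * frac
            self.density[mask] = np.minimum(100.0, self.d_max[mask] * frac)

    def _update_insects(self, doy: int, day: int) -> None:
        env = self.insects.envelope(doy)
        sat = np.where(
            self.biomass > 0,
            self.biomass / (self.biomass + self.insects.biomass_halfsat),
            0.0,
        )
        food = env * self.coef * sat * self.insects.food_max
        rec = self.insects.recovery_days
        mult = np.ones_like(food)
        active = np.isfinite(self.knock_day) & (day - self.knock_day < rec)
        if active.any():
            dt = day - self.knock_day[active]
            f = self.knock_factor[active]
            mult[active] = f + (1 - f) * dt / rec
        self.insect_food = food * mult

    def _tramlines_open(self, day: int) -> np.ndarray:
        return self.always_open | (day < self.tram_until)

    def _habitat_scores(self, day: int) -> np.ndarray:
        """Per-polygon quality score per m^2 (vectorised habitat_score_cell)."""
        p = self.params
        h, d = self.height, self.density
        with np.errstate(divide="ignore"):
            f_h = np.minimum(
                1.0, np.where(h > 0, h / p.HEIGHTCONST_C, 1.0) ** p.HEIGHTCONST_B
            )
            f_d = np.where(
                d > 0, np.minimum(1.0, (d / p.DENSITYCONST_C) ** p.DENSITYCONST_B), 1.0
            )
        base = np.select(
            [
                self.hedge_like | (h > 300.0),
                self.zero_score,
                h < 3.0,
                h <= 110.0,
                h <= 200.0,
            ],
            [p.HQHEDGE, 0.0, p.HQBAREEARTH, p.q0_crop_score * f_h * f_d, p.HQTALL],
            default=p.HQTALLVEG,
        )
        base = base + p.PATCHYPREMIUM * (self.patchy & (h < 200.0))
        base = base + p.TRAMLINEPREMIUM * self._tramlines_open(day)
        base = base + p.SKSCRAPESPREMIUM * self.scrapes
        return np.where(self.zero_score, 0.0, base)

    def _accessibility(self, day: int) -> np.ndarray:
        """Per-polygon foraging accessibility (vectorised)."""
        p = self.params
        a_h = np.clip(
            1.0 + p.HINDCONSTH_B * np.maximum(0.0, self.height - p.HEIGHTCONST_C), 0.0, 1.0
        )
        a_d = np.clip(
            1.0 + p.HINDCONSTD_B * np.maximum(0.0, self.density - p.DENSITYCONST_C), 0.0, 1.0
        )
        hindrance = 1.0 - a_h * a_d
        enhanced = self._tramlines_open(day) | self.scrapes
        hindrance = np.where(enhanced, hindrance * (1.0 - p.TRAMLINE_FORAGING), hindrance)
        return 1.0 - hindrance

    # ------------------------------------------------------------------
    # event helper
    # ------------------------------------------------------------------

    def _emit(self, kind, agent="", value=np.nan, polygon=-1, row=-1, col=-1, cause=""):
        self.events.append(
            (self._year, self._doy, kind, agent, value, polygon, row, col, cause)
        )

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------

    def run(self, years: int) -> SimResult:
        if years * DAYS_PER_YEAR > len(self._weather_temp):
            raise ValueError("weather series shorter than the requested run")
        p = self.params
        rng = self.rng
        self._next_bird = 1
        self._next_pair = 1
        n_males = n_females = self.initial_pairs

        for year_index in range(years):
            self._year = year_index + 1
            for farm in self.farms:
                farm.start_year(year_index)
            self._start_season(n_males, n_females, rng)
            juveniles = 0

            for doy in range(1, DAYS_PER_YEAR + 1):
                self._doy = doy
                day = year_index * DAYS_PER_YEAR + doy - 1
                self._day = day
                temp = float(self._weather_temp[day])
                rain = float(self._weather_rain[day])

                if 80 <= doy <= 300:
                    self._farming_step(doy, day, rain, rng)

                self._grow_vegetation(temp)
                self._update_insects(doy, day)

                if p.arrival_start_doy <= doy <= p.season_end_doy:
                    juveniles = self._skylark_step(doy, day, temp, rain, juveniles, rng)

                if doy == p.season_end_doy:
                    juveniles = self._end_season(juveniles)

            surv_m, _ = season_cycle(n_males, 0, p, rng)
            surv_f, surv_j = season_cycle(n_females, juveniles, p, rng)
            j_m = int(rng.binomial(surv_j, 0.5)) if surv_j else 0
            n_males = surv_m + j_m
            n_females = surv_f + (surv_j - j_m)

        events = pd.DataFrame(self.events, columns=EVENT_COLUMNS)
        daily = pd.DataFrame(
            self.daily_rows,
            columns=["year", "doy", "n_pairs", "n_territories", "n_floaters",
                     "n_juveniles"],
        )
        return SimResult(events=events, daily=daily, years=years, seed=self.seed)

    # ------------------------------------------------------------------
    # per-season state
    # ------------------------------------------------------------------

    def _start_season(self, n_males: int, n_females: int, rng) -> None:
        p = self.params
        arrivals_m = np.sort(
            rng.integers(p.arrival_start_doy, p.arrival_end_doy + 1, n_males)
        )
        arrivals_f = np.sort(
            rng.integers(p.arrival_start_doy, p.arrival_end_doy + 1, n_females)
        )
        self._pending_males = [
            Skylark(self._next_bird + i, "M", arrival_doy=int(d))
            for i, d in enumerate(arrivals_m)
        ]
        self._next_bird += n_males
        self._pending_females = [
            Skylark(self._next_bird + i, "F", arrival_doy=int(d))
            for i, d in enumerate(arrivals_f)
        ]
        self._next_bird += n_females
        self.floaters: list[Skylark] = []
        self.unmated_females: list[Skylark] = []
        self.unmated_holders: list[Skylark] = []
        self.holder_territories: dict[int, Territory] = {}
        self.pairs: list[Pair] = []
        self.prefledglings: list[list] = []   # [count, age_days]
        self.nests_by_poly: dict[int, Pair] = {}

    def _farming_step(self, doy: int, day: int, rain: float, rng) -> None:
        p = self.params
        for farm in self.farms:
            for fid, op in step_farm_day(farm, doy, rain, rng, self.plans):
                idx = self.grid.index_of[fid]
                poly = self.polys[idx]
                # sync the polygon's vegetation from the vectorised state
                # before the operation mutates it
                poly.veg = veg_replace(
                    poly.veg,
                    height_cm=float(self.height[idx]),
                    density=float(self.density[idx]),
                    biomass=float(self.biomass[idx]),
                )
                nest_pair = self.nests_by_poly.get(idx)
                nests = []
                if nest_pair is not None and nest_pair.nest_stage is not None:
                    nest_pair.stage = nest_pair.nest_stage
                    nests = [nest_pair]
                destroyed = apply_operation(op, poly, day, p, nests=nests, rng=rng)
                self.biomass[idx] = poly.veg.biomass
                self.height[idx] = poly.veg.height_cm
                self.density[idx] = poly.veg.density
                self.growing[idx] = poly.growing
                if poly.tramlines_open_until is not None:
                    self.tram_until[idx] = poly.tramlines_open_until
                self.knock_factor[idx] = poly.knockdown_factor
                if poly.knockdown_day is not None:
                    self.knock_day[idx] = poly.knockdown_day
                self._emit("operation", f"F{farm.farm_id}", polygon=fid,
                           cause=op.kind.value)
                for victim in destroyed:
                    self._fail_nest(victim, "other")

    def _skylark_step(self, doy, day, temp, rain, juveniles, rng) -> int:
        p = self.params
        score_vec = self._habitat_scores(day)
        access_vec = self._accessibility(day)
        rh = rain_hindrance(rain, p)
        rate_vec = self.insect_food * access_vec * p.EXTRACTION_RATE * (1.0 - rh)

        # arrivals
        while self._pending_males and self._pending_males[0].arrival_doy <= doy:
            m = self._pending_males.pop(0)
            m.state = BirdState.TERRITORY_SEARCH
            self.floaters.append(m)
            self._emit("arrival", f"M{m.bird_id}")
        while self._pending_females and self._pending_females[0].arrival_doy <= doy:
            f = self._pending_females.pop(0)
            self.unmated_females.append(f)
            self._emit("arrival", f"F{f.bird_id}")

        # territory acquisition (floaters retry daily, shuffled)
        if self.floaters:
            remaining: list[Skylark] = []
            holders_by_id = {pr.male.bird_id: pr for pr in self.pairs}
            for i in rng.permutation(len(self.floaters)):
                male = self.floaters[int(i)]
                territory, split_info = self.mgr.try_acquire(male.bird_id, score_vec)
                if territory is None:
                    remaining.append(male)
                    continue
                male.territory_id = territory.territory_id
                male.state = BirdState.PRE_BREEDING
                r, c = territory.centre
                self._emit("territory_acquired", f"M{male.bird_id}",
                           polygon=territory.centre_poly, row=r, col=c)
                if split_info is not None:
                    old_owner, kept = split_info
                    self._emit("territory_split", f"M{old_owner}",
                               polygon=kept.centre_poly,
                               row=kept.centre[0], col=kept.centre[1])
                    holder_pair = holders_by_id.get(old_owner)
                    if holder_pair is not None:
                        holder_pair.territory = kept
                        holder_pair.male.territory_id = kept.territory_id
                    elif old_owner in self.holder_territories:
                        self.holder_territories[old_owner] = kept
                self.unmated_holders.append(male)
                self.holder_territories[male.bird_id] = territory
            self.floaters = remaining

        # pairing
        if self.unmated_females and self.unmated_holders:
            still: list[Skylark] = []
            for female in self.unmated_females:
                best_male, best_score = None, -np.inf
                for m in self.unmated_holders:
                    s = self.holder_territories[m.bird_id].score(score_vec, self._cell_area)
                    if s > best_score:
                        best_male, best_score = m, s
                if best_male is None or best_score < p.MINFEMACCEPTSCORE:
                    still.append(female)
                    continue
                t = self.holder_territories.pop(best_male.bird_id)
                self.unmated_holders.remove(best_male)
                female.state = BirdState.PRE_BREEDING
                female.territory_id = t.territory_id
                pair = Pair(self._next_pair, best_male, female, t)
                self._next_pair += 1
                self.pairs.append(pair)
                r, c = t.centre
                self._emit("pair_formed", f"P{pair.pair_id}",
                           polygon=t.centre_poly, row=r, col=c)
            self.unmated_females = still

        # territory maintenance: a territory whose score has fallen below
        # the acceptance threshold is given up once no nest is active
        # (this, not energetics, drives the mid-season declines on
        # maturing crops; score premiums for tramlines/scrapes delay it)
        for pair in list(self.pairs):
            if pair.nest_stage is not None or pair.brood is not None:
                continue
            if pair.territory.score(score_vec, self._cell_area) < p.MINFEMACCEPTSCORE:
                self._emit("territory_abandoned", f"P{pair.pair_id}",
                           polygon=pair.territory.centre_poly)
                self._emit("pair_end", f"P{pair.pair_id}")
                self.mgr.release(pair.territory)
                pair.female.state = BirdState.DEPARTED
                pair.male.state = BirdState.DEPARTED
        self.pairs = [pr for pr in self.pairs if pr.female.state != BirdState.DEPARTED]
        for male in list(self.unmated_holders):
            t = self.holder_territories[male.bird_id]
            if t.score(score_vec, self._cell_area) < p.MINFEMACCEPTSCORE:
                self.mgr.release(t)
                del self.holder_territories[male.bird_id]
                self.unmated_holders.remove(male)
                male.state = BirdState.DEPARTED
                self._emit("territory_abandoned", f"M{male.bird_id}")

        # pair behaviour
        for pair in list(self.pairs):
            if pair.female.state != BirdState.DEPARTED:
                self._pair_step(pair, temp, rate_vec, rng)
        self.pairs = [pr for pr in self.pairs if pr.female.state != BirdState.DEPARTED]

        # pre-fledgling cohorts
        for cohort in self.prefledglings:
            cohort[0] = int(rng.binomial(cohort[0], p.prefledgling_daily_survival))
            cohort[1] += 1
            if cohort[0] > 0 and cohort[1] >= p.independence_age:
                juveniles += cohort[0]
                self._emit("fledge_independent", value=cohort[0])
                cohort[0] = 0
        self.prefledglings = [c for c in self.prefledglings if c[0] > 0]

        self.daily_rows.append(
            (self._year, doy, len(self.pairs), len(self.mgr.territories),
             len(self.floaters), juveniles)
        )
        return juveniles

    def _end_season(self, juveniles: int) -> int:
        for pair in self.pairs:
            if pair.nest_stage is not None:
                self._fail_nest(pair, "other")
            self._emit("pair_end", f"P{pair.pair_id}")
            self.mgr.release(pair.territory)
        for m in list(self.unmated_holders):
            self.mgr.release(self.holder_territories.pop(m.bird_id))
        for cohort in self.prefledglings:
            if cohort[1] >= SEASON_END_INDEPENDENCE_AGE:
                juveniles += cohort[0]
        self.pairs = []
        self.floaters = []
        self.unmated_females = []
        self.unmated_holders = []
        self.prefledglings = []
        self.nests_by_poly.clear()
        return juveniles

    # ------------------------------------------------------------------
    # pair behaviour
    # ------------------------------------------------------------------

    def _fail_nest(self, pair: Pair, cause: str) -> None:
        """Record loss of the active clutch or brood and reset the pair."""
        stage = pair.nest_stage
        if stage == "clutch":
            pair.clutch.alive = False
            self._emit("clutch_fate", pair.nest_id, cause=cause)
        elif stage == "nestling":
            pair.brood.alive = False
            self._emit("brood_fate", pair.nest_id, cause=cause)
        if pair.nest_poly is not None:
            self.nests_by_poly.pop(pair.nest_poly, None)
        pair.clutch = None
        pair.brood = None
        pair.nest_poly = None
        pair.nest_id = None
        if pair.female.state not in (BirdState.DEPARTED, BirdState.POST_BREEDING):
            pair.female.state = BirdState.PRE_BREEDING
        pair.female.deficit_days = 0
        pair.next_attempt_day = self._day + RENEST_DELAY_DAYS

    def _nest_site_index(self, pair: Pair) -> int | None:
        """Polygon index of the best nest site in the territory, if any."""
        lo, hi = self.params.nest_height_window_cm
        counts = pair.territory.poly_counts
        ok = self.field_like & (self.height >= lo) & (self.height <= hi) & (counts > 0)
        if not ok.any():
            return None
        return int(np.argmax(np.where(ok, counts, 0)))

    def _pair_step(self, pair: Pair, temp: float, rate_vec: np.ndarray, rng) -> None:
        p = self.params
        female = pair.female
        in_territory = pair.territory.poly_counts > 0
        best_rate = float(np.max(np.where(in_territory, rate_vec, 0.0)))
        intake_per_trip = best_rate * p.TRIPLENGTH
        state = female.state

        if state == BirdState.PRE_BREEDING:
            if self._doy <= p.last_initiation_doy and self._day >= pair.next_attempt_day:
                site = self._nest_site_index(pair)
                if site is not None:
                    pair.clutch = Clutch(
                        n_eggs=int(rng.choice(p.clutch_sizes)), lay_day=self._day
                    )
                    pair.eggs_laid = 1
                    pair.nest_poly = site
                    pair.nest_id = f"N{self._year}-{pair.pair_id}-{self._day}"
                    self.nests_by_poly[site] = pair
                    female.state = BirdState.EGG_LAYING
                    female.attempts += 1
                    self._emit("nest_started", pair.nest_id,
                               polygon=self.grid.polygons[site].poly_id)
            return

        if state == BirdState.EGG_LAYING:
            if not daily_predation(p.clutch_predation_daily(), rng):
                self._fail_nest(pair, "predated")
                return
            pair.eggs_laid += 1
            if pair.eggs_laid >= pair.clutch.n_eggs:
                pair.clutch.inc_start_day = self._day
                female.state = BirdState.INCUBATING
                female.deficit_days = 0
                self._emit("inc_start", pair.nest_id, value=pair.clutch.n_eggs)
                self._incubate_day(pair, temp, intake_per_trip)
            return

        if state == BirdState.INCUBATING:
            if not daily_predation(p.clutch_predation_daily(), rng):
                self._fail_nest(pair, "predated")
                return
            self._incubate_day(pair, temp, intake_per_trip)
            if (
                female.state == BirdState.INCUBATING
                and female.deficit_days >= p.deficit_days_to_abandon
            ):
                self._fail_nest(pair, "other")
            return

        if state == BirdState.CARING_YOUNG:
            brood = pair.brood
            if brood is None or not brood.alive or brood.left_nest:
                female.state = BirdState.PRE_BREEDING
                return
            if not daily_predation(p.nestling_predation_daily(), rng):
                self._fail_nest(pair, "predated")
                return
            demand = brood.n * p.PEMAX / p.assimilation_efficiency
            own = daily_requirement(temp, p)
            target = own + demand / 2.0
            cap = int(p.daylight_foraging_minutes // p.TRIPLENGTH)
            delivered = 0.0
            for _parent in range(2):       # both parents provision the brood
                _trips, intake = plan_foraging(target, intake_per_trip, cap)
                delivered += max(0.0, intake - own)
            outcome = nestling_daily_step(brood, delivered, p, rng)
            if outcome == "starved":
                self._fail_nest(pair, "other")
            elif outcome == "left":
                self._emit("nest_leave", pair.nest_id, value=brood.age_days)
                self._prefledge(pair)

    def _incubate_day(self, pair: Pair, temp: float, intake_per_trip: float) -> None:
        p = self.params
        female = pair.female
        req = daily_requirement(temp, p)
        trips, intake = plan_foraging(req, intake_per_trip, p.max_incubation_trips)
        if intake + 1e-12 < req:
            female.deficit_days += 1
        else:
            female.deficit_days = 0
        incubation_step(pair.clutch, trips, temp, p)
        if pair.clutch.hatched:
            inc_len = self._day - pair.clutch.inc_start_day + 1
            self._emit("hatch", pair.nest_id, value=inc_len)
            pair.brood = Brood(n=pair.clutch.n_eggs, hatch_day=self._day)
            female.state = BirdState.CARING_YOUNG
            female.deficit_days = 0

    def _prefledge(self, pair: Pair) -> None:
        """Brood leaves the nest; the male tends it, the female may renest."""
        brood = pair.brood
        self.prefledglings.append([brood.n, brood.age_days])
        if pair.nest_poly is not None:
            self.nests_by_poly.pop(pair.nest_poly, None)
        pair.brood = None
        pair.clutch = None
        pair.nest_poly = None
        pair.nest_id = None
        pair.female.state = BirdState.PRE_BREEDING
        pair.next_attempt_day = self._day + RENEST_DELAY_DAYS


def simulate(
    grid: LandscapeGrid,
    farms: list[Farm],
    weather: pd.DataFrame,
    params: SkylarkParams | None = None,
    years: int = 60,
    seed: int = 0,
    **kwargs,
) -> SimResult:
    """Run a full simulation and return the event log + daily state."""
    sim = Simulation(grid, farms, weather, params=params, seed=seed, **kwargs)
    return sim.run(years)
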