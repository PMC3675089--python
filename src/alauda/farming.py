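"""Farms, crop rotations and probabilistic daily farm operations.

Each crop has a management plan: an ordered list of operations, each
with an eligible day-of-year window, a daily attempt probability and a
weather gate (maximum precipitation).  Operations feed back on the
landscape (vegetation resets, insect knock-down, tramlines) and on
skylark nests (stage-specific destruction probabilities).

The published management library (tens of crops, tens of operations per
crop) is reduced here to a handful of parameterised plans; windows and
probabilities are illustrative defaults and are expected to be
overridden from scenario config where they matter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .landscape import DEFAULT_CURVES, ElementType, Polygon, VegetationState
from .params import SkylarkParams


class OpKind(enum.Enum):
    SOW = "sow"
    PLOUGH = "plough"
    HARROW = "harrow"
    MECHANICAL_WEED = "mechanical_weed"
    SPRAY_INSECTICIDE = "spray_insecticide"
    SPRAY_OTHER = "spray_other"
    HARVEST = "harvest"
    MOW = "mow"
    ROLL = "roll"


SPRAY_KINDS = frozenset({OpKind.SPRAY_INSECTICIDE, OpKind.SPRAY_OTHER})

#: Default per-stage nest destruction probabilities by operation kind:
#: soil-moving operations destroy nests outright, mowing nearly so,
#: spraying causes no direct destruction.
SOIL_KINDS = frozenset(
    {OpKind.PLOUGH, OpKind.HARROW, OpKind.SOW, OpKind.MECHANICAL_WEED, OpKind.HARVEST}
)


def default_nest_destruction(kind: OpKind) -> dict:
    if kind in SOIL_KINDS:
        return {"clutch": 1.0, "nestling": 1.0}
    if kind == OpKind.MOW:
        return {"clutch": 0.9, "nestling": 0.9}
    return {"clutch": 0.0, "nestling": 0.0}


@dataclass
class FarmOperation:
    kind: OpKind
    window: tuple[int, int]            # eligible day-of-year range, inclusive
    daily_prob: float = 0.3
    max_precip_mm: float = 5.0         # weather gate
    veg_reset: tuple | None = None     # (height_cm, density, biomass) or None
    insect_knockdown: float = 1.0      # multiplier applied to insect food
    nest_destruction: dict | None = None  # stage -> probability
    opens_tramlines: bool = False
    starts_growth: bool = False        # sowing
    stops_growth: bool = False         # harvest

    def __post_init__(self):
        if not 0.0 <= self.daily_prob <= 1.0:
            raise ValueError("daily_prob must lie in [0, 1]")
        if not 1 <= self.window[0] <= self.window[1] <= 365:
            raise ValueError("operation window must lie within the year")
        if self.nest_destruction is None:
            self.nest_destruction = default_nest_destruction(self.kind)


@dataclass
class CropPlan:
    crop_id: str
    operations: list[FarmOperation]
    growth_curve: str

    def __post_init__(self):
        starts = [op.window[0] for op in self.operations]
        if starts != sorted(starts):
            raise ValueError("operations must be ordered by window start")
        if self.growth_curve not in DEFAULT_CURVES:
            raise ValueError(f"unknown growth curve {self.growth_curve!r}")


def _barley_plan(crop_id: str = "spring_barley", organic: bool = False) -> CropPlan:
    ops = [
        FarmOperation(OpKind.PLOUGH, (85, 100), daily_prob=0.4,
                      veg_reset=(0.0, 0.0, 0.0)),
        FarmOperation(OpKind.SOW, (95, 115), daily_prob=0.4,
                      veg_reset=(0.0, 0.0, 1.0), starts_growth=True),
    ]
    if organic:
        ops.append(FarmOperation(OpKind.MECHANICAL_WEED, (125, 140), daily_prob=0.3))
    else:
        ops.append(FarmOperation(OpKind.SPRAY_OTHER, (135, 155), daily_prob=0.33,
                                 opens_tramlines=True))
        ops.append(FarmOperation(OpKind.SPRAY_INSECTICIDE, (160, 180), daily_prob=0.2,
                                 opens_tramlines=True, insect_knockdown=0.3))
    ops.append(FarmOperation(OpKind.HARVEST, (222, 245), daily_prob=0.4,
                             veg_reset=(5.0, 3.0, 10.0), stops_growth=True))
    return CropPlan(crop_id, ops, "spring_barley")


def default_crop_plans() -> dict[str, CropPlan]:
    plans = {
        "spring_barley": _barley_plan(),
        "spring_barley_organic": _barley_plan("spring_barley_organic", organic=True),
        "winter_wheat": CropPlan("winter_wheat", [
            FarmOperation(OpKind.SPRAY_OTHER, (120, 140), daily_prob=0.33,
                          opens_tramlines=True),
            FarmOperation(OpKind.SPRAY_INSECTICIDE, (150, 170), daily_prob=0.2,
                          opens_tramlines=True, insect_knockdown=0.3),
            FarmOperation(OpKind.HARVEST, (215, 240), daily_prob=0.4,
                          veg_reset=(5.0, 3.0, 10.0), stops_growth=True),
            FarmOperation(OpKind.PLOUGH, (255, 270), daily_prob=0.4,
                          veg_reset=(0.0, 0.0, 0.0)),
            FarmOperation(OpKind.SOW, (265, 290), daily_prob=0.4,
                          veg_reset=(0.0, 0.0, 2.0), starts_growth=True),
        ], "winter_wheat"),
        "grass_ley": CropPlan("grass_ley", [
            FarmOperation(OpKind.ROLL, (90, 105), daily_prob=0.3),
            FarmOperation(OpKind.MOW, (150, 165), daily_prob=0.4,
                          veg_reset=(8.0, 10.0, 30.0)),
            FarmOperation(OpKind.MOW, (200, 215), daily_prob=0.4,
                          veg_reset=(8.0, 10.0, 30.0)),
        ], "grass_ley"),
        "peas": CropPlan("peas", [
            FarmOperation(OpKind.PLOUGH, (90, 105), daily_prob=0.4,
                          veg_reset=(0.0, 0.0, 0.0)),
            FarmOperation(OpKind.SOW, (100, 120), daily_prob=0.4,
                          veg_reset=(0.0, 0.0, 1.0), starts_growth=True),
            FarmOperation(OpKind.SPRAY_OTHER, (140, 160), daily_prob=0.3,
                          opens_tramlines=True),
            FarmOperation(OpKind.HARVEST, (215, 235), daily_prob=0.4,
                          veg_reset=(5.0, 3.0, 10.0), stops_growth=True),
        ], "peas"),
    }
    return plans


class FarmType(enum.Enum):
    PIG = "pig"
    ARABLE = "arable"
    MIXED = "mixed"
    HOBBY = "hobby"
    ORGANIC_PIG = "organic_pig"
    ORGANIC_ARABLE = "organic_arable"
    ORGANIC_MIXED = "organic_mixed"


ORGANIC_TYPES = frozenset(
    {FarmType.ORGANIC_PIG, FarmType.ORGANIC_ARABLE, FarmType.ORGANIC_MIXED}
)


@dataclass
class Farm:
    farm_id: int
    farm_type: FarmType
    field_ids: list[int]
    rotation: list[str] = field(default_factory=list)
    phases: dict[int, int] = field(default_factory=dict)  # field id -> offset
    # per-year state, reset by start_year()
    current_crop: dict[int, str] = field(default_factory=dict)
    done_ops: dict[int, set] = field(default_factory=dict)

    @property
    def is_organic(self) -> bool:
        return self.farm_type in ORGANIC_TYPES

    def start_year(self, year_index: int) -> None:
        """Advance the rotation and clear the per-year operation state."""
        n = len(self.rotation)
        if n == 0:
            raise ValueError(f"farm {self.farm_id} has no rotation assigned")
        self.current_crop = {
            f: self.rotation[(year_index + self.phases.get(f, 0)) % n]
            for f in self.field_ids
        }
        self.done_ops = {f: set() for f in self.field_ids}


def assign_rotations(
    farms: list[Farm], crop_shares: dict[str, float]
) -> None:
    """Assign each farm a phased rotation matching long-run crop shares.

    ``crop_shares`` maps crop ids to target area fractions (sum <= 1;
    any remainder is filled with the first crop).  Because every field
    cycles through every rotation slot, the long-run mean annual area of
    each crop equals its share of rotation slots; phases are staggered
    per field only to spread crops evenly within years.
    """
    total = sum(crop_shares.values())
    if total > 1.0 + 1e-9 or any(v < 0 for v in crop_shares.values()):
        raise ValueError("crop shares must be non-negative and sum to <= 1")
    crops = list(crop_shares)
    for farm in farms:
        n_slots = max(len(farm.field_ids), len(crops), 1)
        # largest-remainder apportionment of rotation slots
        quotas = {c: crop_shares[c] / total * n_slots for c in crops} if total else {}
        slots = {c: int(np.floor(q)) for c, q in quotas.items()}
        leftover = n_slots - sum(slots.values())
        for c in sorted(crops, key=lambda c: quotas[c] - slots[c], reverse=True):
            if leftover <= 0:
                break
            slots[c] += 1
            leftover -= 1
        rotation: list[str] = []
        for c in crops:
            rotation.extend([c] * slots[c])
        if not rotation:
            raise ValueError("empty rotation")
        farm.rotation = rotation
        farm.phases = {f: i % len(rotation) for i, f in enumerate(farm.field_ids)}


def step_farm_day(
    farm: Farm,
    doy: int,
    precipitation: float,
    rng: np.random.Generator,
    plans: dict[str, CropPlan],
) -> list[tuple[int, FarmOperation]]:
    """Attempt today's operations; returns (field polygon id, op) pairs.

    An operation is eligible once all earlier operations in the plan are
    done or out of window; it fires with its daily probability when the
    weather gate allows, and is forced on the final eligible day so that
    rotations stay coherent across years.  Organic farms never spray.
    """
    executed = []
    for fid in farm.field_ids:
        plan = plans[farm.current_crop[fid]]
        done = farm.done_ops[fid]
        for i, op in enumerate(plan.operations):
            if i in done:
                continue
            if farm.is_organic and op.kind in SPRAY_KINDS:
                done.add(i)
                continue
            lo, hi = op.window
            if doy > hi:
                done.add(i)  # window missed (e.g. persistent rain)
                continue
            if doy < lo:
                break  # plan order: later ops wait
            blocked = any(
                j not in done and plan.operations[j].window[1] >= doy
                for j in range(i)
            )
            if blocked:
                break
            if precipitation > op.max_precip_mm:
                continue
            if doy == hi or rng.random() < op.daily_prob:
                done.add(i)
                executed.append((fid, op))
    return executed


def apply_operation(
    op: FarmOperation,
    polygon: Polygon,
    day: int,
    params: SkylarkParams,
    nests: list = (),
    rng: np.random.Generator | None = None,
) -> list:
    """Apply an operation's effects to a polygon; returns destroyed nests.

    ``nests`` are objects with a ``stage`` attribute ("clutch" or
    "nestling"); each is destroyed with the operation's per-stage
    probability (certain destruction needs no rng).
    """
    if op.veg_reset is not None:
        h, d, b = op.veg_reset
        polygon.veg = replace(polygon.veg, height_cm=h, density=d, biomass=b)
    if op.starts_growth:
        polygon.growing = True
        curve = DEFAULT_CURVES[polygon.growth_curve] if polygon.growth_curve else None
        if curve is not None:
            polygon.veg = replace(polygon.veg, biomass=curve.sown_biomass,
                                  crop_id=polygon.growth_curve)
    if op.stops_growth:
        polygon.growing = False
    if op.insect_knockdown < 1.0:
        polygon.knockdown_factor = op.insect_knockdown
        polygon.knockdown_day = day
    if op.opens_tramlines:
        polygon.tramlines_open_until = day + int(round(params.TRAMLINE_DECAYTIME))
    destroyed = []
    for nest in nests:
        p = op.nest_destruction.get(nest.stage, 0.0)
        if p >= 1.0 or (p > 0.0 and rng is not None and rng.random() < p):
            destroyed.append(nest)
    return destroyed
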