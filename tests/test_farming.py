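"""Farm operations, scheduling and rotations."""

import numpy as np
import pytest

from alauda.farming import (
    Farm,
    FarmOperation,
    FarmType,
    OpKind,
    apply_operation,
    assign_rotations,
    default_crop_plans,
    step_farm_day,
)
from alauda.landscape import ElementType, Polygon, VegetationState
from alauda.params import SkylarkParams
from alauda.farming import CropPlan


def _one_op_farm(op: FarmOperation, crop="test_crop"):
    plan = CropPlan(crop, [op], "spring_barley")
    farm = Farm(1, FarmType.ARABLE, field_ids=[10], rotation=[crop],
                phases={10: 0})
    farm.start_year(0)
    return farm, {crop: plan}


def test_certain_operation_fires_on_first_eligible_day():
    op = FarmOperation(OpKind.SOW, (100, 110), daily_prob=1.0)
    farm, plans = _one_op_farm(op)
    rng = np.random.default_rng(0)
    assert step_farm_day(farm, 99, 0.0, rng, plans) == []
    fired = step_farm_day(farm, 100, 0.0, rng, plans)
    assert fired == [(10, op)]
    # not-yet-done bookkeeping: never fires twice
    assert step_farm_day(farm, 101, 0.0, rng, plans) == []


def test_rain_above_gate_defers_operation():
    op = FarmOperation(OpKind.SOW, (100, 110), daily_prob=1.0, max_precip_mm=5.0)
    farm, plans = _one_op_farm(op)
    rng = np.random.default_rng(0)
    assert step_farm_day(farm, 100, 7.0, rng, plans) == []
    assert step_farm_day(farm, 101, 1.0, rng, plans) == [(10, op)]


def test_daily_firing_probability_matches_binomial_oracle():
    """p = 0.5 over a 2-day window: day-1 firing frequency ~ Binomial(n, 0.5)."""
    op = FarmOperation(OpKind.SOW, (100, 101), daily_prob=0.5)
    n = 10_000
    day1 = 0
    for seed in range(n):
        farm, plans = _one_op_farm(op)
        rng = np.random.default_rng(seed)
        if step_farm_day(farm, 100, 0.0, rng, plans):
            day1 += 1
    p = 0.5
    sigma = np.sqrt(n * p * (1 - p))
    assert abs(day1 - n * p) < 3 * sigma


def test_spray_opens_tramlines_for_the_decay_time():
    """TRAMLINE_DECAYTIME = 21 days after the operation."""
    params = SkylarkParams()
    poly = Polygon(10, ElementType.FIELD, veg=VegetationState(biomass=50.0))
    op = FarmOperation(OpKind.SPRAY_OTHER, (100, 120), opens_tramlines=True)
    apply_operation(op, poly, day=200, params=params)
    assert poly.tramlines_open_until == 221
    assert poly.tramlines_open(220) and not poly.tramlines_open(221)


def test_harvest_reset_is_idempotent_on_bare_polygon():
    params = SkylarkParams()
    op = FarmOperation(OpKind.HARVEST, (220, 240), veg_reset=(5.0, 3.0, 10.0),
                       stops_growth=True)
    poly = Polygon(10, ElementType.FIELD, veg=VegetationState())
    apply_operation(op, poly, 250, params)
    state1 = poly.veg
    apply_operation(op, poly, 251, params)
    assert poly.veg == state1


def test_certain_nest_destruction_destroys_every_nest():
    params = SkylarkParams()
    op = FarmOperation(OpKind.MECHANICAL_WEED, (100, 120),
                       nest_destruction={"clutch": 1.0, "nestling": 1.0})

    class Nest:
        def __init__(self, stage):
            self.stage = stage

    nests = [Nest("clutch"), Nest("clutch"), Nest("nestling")]
    poly = Polygon(10, ElementType.FIELD)
    destroyed = apply_operation(op, poly, 100, params, nests=nests)
    assert destroyed == nests


def test_spraying_never_destroys_nests_by_default():
    op = FarmOperation(OpKind.SPRAY_INSECTICIDE, (100, 120))
    assert op.nest_destruction == {"clutch": 0.0, "nestling": 0.0}


def test_organic_farms_never_spray():
    plans = default_crop_plans()
    farm = Farm(1, FarmType.ORGANIC_ARABLE, field_ids=[10],
                rotation=["spring_barley"], phases={10: 0})
    farm.start_year(0)
    rng = np.random.default_rng(1)
    executed = []
    for doy in range(80, 301):
        executed.extend(op.kind for _f, op in step_farm_day(farm, doy, 0.0, rng, plans))
    assert OpKind.SPRAY_INSECTICIDE not in executed
    assert OpKind.SPRAY_OTHER not in executed
    assert OpKind.SOW in executed and OpKind.HARVEST in executed


# ---------------------------------------------------------------- rotations

def test_single_crop_everywhere_every_year():
    farm = Farm(1, FarmType.ARABLE, field_ids=[1, 2, 3])
    assign_rotations([farm], {"spring_barley": 1.0})
    for year in range(5):
        farm.start_year(year)
        assert set(farm.current_crop.values()) == {"spring_barley"}


def test_two_crops_fifty_fifty_alternate_over_two_fields():
    farm = Farm(1, FarmType.ARABLE, field_ids=[1, 2])
    assign_rotations([farm], {"a_crop": 0.5, "b_crop": 0.5})
    for year in range(6):
        farm.start_year(year)
        assert sorted(farm.current_crop.values()) == ["a_crop", "b_crop"]


def test_three_crops_seven_fields_long_run_areas_match_targets():
    """21-year mean areas match targets within the largest single field."""
    areas = {1: 2.0, 2: 3.5, 3: 5.0, 4: 1.5, 5: 4.0, 6: 2.5, 7: 6.0}
    farm = Farm(1, FarmType.MIXED, field_ids=list(areas))
    shares = {"a": 0.45, "b": 0.35, "c": 0.20}
    assign_rotations([farm], shares)
    total = sum(areas.values())
    realised = {c: 0.0 for c in shares}
    years = 21
    for year in range(years):
        farm.start_year(year)
        for fid, crop in farm.current_crop.items():
            realised[crop] += areas[fid]
    for crop, share in shares.items():
        mean_area = realised[crop] / years
        assert abs(mean_area - share * total) <= max(areas.values())


def test_infeasible_targets_rejected():
    farm = Farm(1, FarmType.ARABLE, field_ids=[1])
    with pytest.raises(ValueError):
        assign_rotations([farm], {"a": 0.8, "b": 0.4})
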