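"""Habitat scoring, foraging accessibility and territory machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alauda.agents import (
    foraging_accessibility,
    foraging_intake,
    habitat_score_cell,
    rain_hindrance,
)
from alauda.landscape import ElementType, VegetationState
from alauda.params import SkylarkParams
from alauda.territory import TerritoryManager, evaluate_territory
from tests.conftest import uniform_grid


# ------------------------------------------------------------- cell scores

def test_bare_earth_scores_three_per_m2(params):
    veg = VegetationState(height_cm=2.0)
    assert habitat_score_cell(veg, params) == 3.0


def test_hedgerow_scores_minus_250(params):
    veg = VegetationState(height_cm=400.0)
    assert habitat_score_cell(veg, params, ElementType.HEDGEROW) == -250.0
    # very tall vegetation in any element scores like hedge
    assert habitat_score_cell(veg, params, ElementType.FIELD) == -250.0


def test_score_at_both_thresholds_equals_baseline(params):
    veg = VegetationState(height_cm=params.HEIGHTCONST_C, density=params.DENSITYCONST_C)
    assert habitat_score_cell(veg, params) == pytest.approx(params.q0_crop_score)


def test_power_law_reduction_at_double_height(params):
    """h = 76 cm, d <= 10, q0 = 40 -> 40 x (76/38)^(-0.22) ~ 34.34."""
    veg = VegetationState(height_cm=76.0, density=8.0)
    expect = 40.0 * (76.0 / 38.0) ** (-0.22)
    score = habitat_score_cell(veg, params)
    assert score == pytest.approx(expect)
    assert score == pytest.approx(34.34, abs=0.01)


def test_tall_vegetation_bands(params):
    assert habitat_score_cell(VegetationState(height_cm=150.0), params) == -2.0
    assert habitat_score_cell(VegetationState(height_cm=250.0), params) == -10.0


def test_premiums_are_additive(params):
    veg = VegetationState(height_cm=20.0, density=5.0, is_patchy=True)
    score = habitat_score_cell(veg, params, tramlines_open=True, has_scrapes=True)
    assert score == pytest.approx(40.0 + 47.0 + 6.0 + 0.24)


# ------------------------------------------------------------ accessibility

def test_accessibility_is_one_at_the_height_threshold(params):
    veg = VegetationState(height_cm=38.0, density=5.0)
    assert foraging_accessibility(veg, params) == 1.0


def test_accessibility_zero_at_forty_cm_above_threshold(params):
    """a_h = 1 + (-0.025)(78 - 38) = 0."""
    veg = VegetationState(height_cm=78.0, density=5.0)
    assert foraging_accessibility(veg, params) == pytest.approx(0.0)


def test_open_tramlines_recover_forty_five_percent(params):
    veg = VegetationState(height_cm=78.0, density=5.0)
    assert foraging_accessibility(veg, params, enhanced=True) == pytest.approx(0.45)


@settings(max_examples=100, derandomize=True)
@given(h=st.floats(0, 500), d=st.floats(0, 100), enhanced=st.booleans())
def test_accessibility_always_in_unit_interval(h, d, enhanced):
    veg = VegetationState(height_cm=h, density=d)
    a = foraging_accessibility(veg, SkylarkParams(), enhanced=enhanced)
    assert 0.0 <= a <= 1.0


# ------------------------------------------------------------ rain and intake

def test_rain_hindrance_endpoints_and_power(params):
    assert rain_hindrance(0.0, params) == 0.0
    assert rain_hindrance(4.7, params) == 1.0
    assert rain_hindrance(10.0, params) == 1.0
    assert rain_hindrance(2.35, params) == pytest.approx(0.5**4)


def test_foraging_intake_arithmetic(params):
    """100 units/m2, accessibility 1, 10 min -> 100 x 0.00053 x 10 = 0.53."""
    pairs = [(100.0, 1.0)]
    assert foraging_intake(pairs, 0.0, 10.0, params) == pytest.approx(0.53)
    assert foraging_intake(pairs, 0.0, 0.0, params) == 0.0
    assert foraging_intake(pairs, 5.0, 10.0, params) == 0.0  # rain gate


def test_foraging_uses_best_cells_first(params):
    pairs = [(50.0, 1.0), (100.0, 0.4), (80.0, 0.9)]
    # best product is 80 x 0.9 = 72
    assert foraging_intake(pairs, 0.0, 10.0, params) == pytest.approx(
        72.0 * params.EXTRACTION_RATE * 10.0
    )


# ------------------------------------------------------------- territories

def _score_vec(grid, value):
    return np.full(len(grid.polygons), float(value))


def test_uniform_bare_block_is_rejected(params, bare_grid):
    """10,000 m2 of bare earth at 3/m2 totals 30,000 < 300,000."""
    _rect, total, ok = evaluate_territory(
        bare_grid, (50, 50), _score_vec(bare_grid, 3.0), params
    )
    assert total == pytest.approx(30000.0)
    assert not ok


def test_all_hedge_block_is_rejected(params, bare_grid):
    _rect, total, ok = evaluate_territory(
        bare_grid, (50, 50), _score_vec(bare_grid, -250.0), params
    )
    assert total < 0 and not ok


def test_good_block_with_patchy_premium_is_accepted(params, bare_grid):
    """50/m2 over 10,000 m2 = 500,000 >= 300,000."""
    _rect, total, ok = evaluate_territory(
        bare_grid, (50, 50), _score_vec(bare_grid, 50.0), params
    )
    assert total == pytest.approx(500000.0)
    assert ok


def test_no_acceptable_candidates_leaves_all_males_floaters(params, bare_grid):
    mgr = TerritoryManager(bare_grid, params)
    t, _ = mgr.try_acquire(1, _score_vec(bare_grid, 3.0))
    assert t is None and len(mgr.territories) == 0


def test_single_block_excludes_second_male(params):
    # grid holds one full 100x100 m block; every other candidate overlaps it
    grid = uniform_grid(140, 140)
    mgr = TerritoryManager(grid, params)
    vec = _score_vec(grid, 50.0)
    t1, _ = mgr.try_acquire(1, vec)
    assert t1 is not None
    t2, _ = mgr.try_acquire(2, vec)
    assert t2 is None
    assert len(mgr.territories) == 1


def test_rich_block_splits_for_the_second_male(params):
    """score >= 2 x MINFEMACCEPTSCORE with split multiplier 2 -> two halves."""
    grid = uniform_grid(140, 140)
    mgr = TerritoryManager(grid, params)
    vec = _score_vec(grid, 65.0)   # 650,000 per full block; halves 325,000
    t1, _ = mgr.try_acquire(1, vec)
    t2, split_info = mgr.try_acquire(2, vec)
    assert t1 is not None and t2 is not None
    assert split_info is not None and split_info[0] == 1
    assert len(mgr.territories) == 2
    rects = [t.rect for t in mgr.territories.values()]
    assert not rects[0].overlaps(rects[1])


def test_concurrent_territories_never_overlap(params):
    grid = uniform_grid(300, 300)
    mgr = TerritoryManager(grid, params)
    vec = _score_vec(grid, 50.0)
    held = []
    for male in range(30):
        t, _ = mgr.try_acquire(male, vec)
        if t is not None:
            held.append(t)
    assert len(held) > 1
    for i, a in enumerate(held):
        for b in held[i + 1:]:
            assert not a.rect.overlaps(b.rect)
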