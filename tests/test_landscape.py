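"""Landscape structure, I/O, vegetation growth and insect food."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alauda.landscape import (
    DEFAULT_CURVES,
    ElementType,
    InsectParams,
    LandscapeGrid,
    Polygon,
    VegetationState,
    grids_equal,
    grow_vegetation,
    load_landscape,
    read_raster,
    save_landscape,
    update_insect_food,
    write_raster,
)
from tests.conftest import uniform_grid


# ---------------------------------------------------------------- structure

def test_single_polygon_identity():
    grid = uniform_grid(3, 3)
    assert len(grid.polygons) == 1
    assert grid.polygons[0].cell_count == 9
    assert grid.polygons[0].area_m2 == 9.0


def test_raster_id_absent_from_table_is_an_error():
    ids = np.array([[1, 2], [1, 1]])
    poly = Polygon(poly_id=1, element_type=ElementType.FIELD)
    with pytest.raises(ValueError, match="absent"):
        LandscapeGrid(ids, [poly])


def test_duplicate_polygon_ids_rejected():
    ids = np.ones((2, 2), dtype=int)
    polys = [Polygon(1, ElementType.FIELD), Polygon(1, ElementType.FIELD)]
    with pytest.raises(ValueError, match="duplicate"):
        LandscapeGrid(ids, polys)


def test_area_equals_cell_count_times_cell_area():
    ids = np.array([[1, 1, 2], [1, 2, 2]])
    polys = [Polygon(1, ElementType.FIELD), Polygon(2, ElementType.PERMANENT_GRASS)]
    grid = LandscapeGrid(ids, polys, cell_size=2.0)
    assert polys[0].cell_count == 3 and polys[0].area_m2 == 12.0
    assert polys[1].cell_count == 3 and polys[1].area_m2 == 12.0


def test_non_rectangular_raster_rejected(tmp_path):
    path = tmp_path / "r.txt"
    path.write_text("ncols 3 nrows 2 cellsize 1.0\n1 1 1\n1 1\n")
    with pytest.raises(ValueError):
        read_raster(path)


def test_landscape_write_read_round_trip(tmp_path):
    ids = np.array([[1, 1, 2], [3, 3, 2], [3, 3, 2]])
    polys = [
        Polygon(1, ElementType.FIELD, growth_curve="spring_barley", farm_id=1),
        Polygon(2, ElementType.HEDGEROW),
        Polygon(3, ElementType.FIELD, growth_curve="spring_barley", farm_id=1,
                has_scrapes=True, tramlines_always_open=True),
    ]
    grid = LandscapeGrid(ids, polys, cell_size=2.0)
    save_landscape(grid, tmp_path / "r.txt", tmp_path / "p.csv")
    back = load_landscape(tmp_path / "r.txt", tmp_path / "p.csv")
    assert grids_equal(grid, back)


# ---------------------------------------------------------------- growth

def _field(curve="spring_barley", biomass=10.0):
    c = DEFAULT_CURVES[curve]
    frac = biomass / c.biomass_max
    p = Polygon(
        1, ElementType.FIELD, growth_curve=curve, growing=True,
        veg=VegetationState(height_cm=c.height_max_cm * frac,
                            density=c.density_max * frac, biomass=biomass),
    )
    return p, c


def test_no_growth_at_base_temperature():
    p, c = _field()
    before = p.veg
    grow_vegetation(p, c.t_base_c)
    assert p.veg == before


def test_inert_elements_never_grow():
    p = Polygon(1, ElementType.ROAD, growth_curve="spring_barley",
                veg=VegetationState(biomass=5.0), growing=True)
    before = p.veg
    grow_vegetation(p, 25.0)
    assert p.veg == before


def test_logistic_trajectory_matches_brute_force_integration():
    """Daily growth follows the stated logistic with degree-day scaling."""
    b0 = 1.0
    p, c = _field(biomass=b0)
    p.veg = VegetationState(biomass=b0)
    temp = 15.0
    b = b0
    heights = []
    for _ in range(200):
        grow_vegetation(p, temp)
        tf = (temp - c.t_base_c) / c.t_scale_c
        b = min(c.biomass_max, b + c.rate * b * (1 - b / c.biomass_max) * tf)
        assert p.veg.biomass == pytest.approx(b, rel=1e-12)
        heights.append(p.veg.height_cm)
    assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))
    # reaches the configured maximum within the season
    assert p.veg.height_cm == pytest.approx(c.height_max_cm, rel=1e-3)


# ---------------------------------------------------------------- insects

def test_zero_biomass_means_zero_food():
    p = Polygon(1, ElementType.FIELD, veg=VegetationState(biomass=0.0))
    assert update_insect_food(p, doy=180, insects=InsectParams()) == 0.0


def test_food_is_linear_in_element_coefficient():
    ins = InsectParams()
    a = Polygon(1, ElementType.FIELD, veg=VegetationState(biomass=50.0))
    b = Polygon(2, ElementType.FIELD, veg=VegetationState(biomass=50.0))
    ins2 = InsectParams()
    ins2.element_coefficients = dict(ins.element_coefficients)
    ins2.element_coefficients[ElementType.FIELD] *= 2.0
    fa = update_insect_food(a, 180, ins)
    fb = update_insect_food(b, 180, ins2)
    assert fb == pytest.approx(2.0 * fa)


def test_midsummer_peak_is_the_series_maximum():
    ins = InsectParams()
    p = Polygon(1, ElementType.FIELD, veg=VegetationState(biomass=100.0))
    series = [update_insect_food(p, d, ins) for d in range(1, 366)]
    assert int(np.argmax(series)) + 1 == ins.peak_doy


@settings(max_examples=50, derandomize=True)
@given(b1=st.floats(0, 500), b2=st.floats(0, 500), doy=st.integers(1, 365))
def test_food_monotone_in_biomass(b1, b2, doy):
    ins = InsectParams()
    lo, hi = sorted([b1, b2])
    p_lo = Polygon(1, ElementType.FIELD, veg=VegetationState(biomass=lo))
    p_hi = Polygon(2, ElementType.FIELD, veg=VegetationState(biomass=hi))
    assert update_insect_food(p_lo, doy, ins) <= update_insect_food(p_hi, doy, ins) + 1e-12


def test_insecticide_knockdown_recovers_linearly():
    ins = InsectParams(recovery_days=10.0)
    p = Polygon(1, ElementType.FIELD, veg=VegetationState(biomass=100.0))
    base = update_insect_food(p, 180, ins)
    p.knockdown_factor = 0.3
    p.knockdown_day = 100
    assert update_insect_food(p, 180, ins, day=100) == pytest.approx(0.3 * base)
    assert update_insect_food(p, 180, ins, day=105) == pytest.approx(0.65 * base)
    assert update_insect_food(p, 180, ins, day=110) == pytest.approx(base)


def test_vegetation_state_invariants():
    with pytest.raises(ValueError):
        VegetationState(height_cm=-1.0).validate()
    with pytest.raises(ValueError):
        VegetationState(density=150.0).validate()
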