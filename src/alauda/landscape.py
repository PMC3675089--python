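"""Dynamic landscape: polygons on a raster grid, vegetation growth and
insect food biomass.

The landscape is a rectangular raster of square cells, each belonging to
exactly one polygon.  A polygon carries an element type (field,
hedgerow, ...), a vegetation state updated daily, and an insect food
density derived from season, element type and vegetation.  Raster and
polygon attributes are plain text (portable integer grid + CSV), so no
GIS dependency is needed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ElementType(enum.Enum):
    FIELD = "field"
    FIELD_MARGIN = "field_margin"
    HEDGEROW = "hedgerow"
    WOODLAND = "woodland"
    ROAD = "road"
    BUILDING = "building"
    WATER = "water"
    PERMANENT_GRASS = "permanent_grass"
    BARE = "bare"
    OTHER = "other"


#: Element types on which nothing grows.
INERT_ELEMENTS = frozenset(
    {ElementType.ROAD, ElementType.BUILDING, ElementType.WATER, ElementType.BARE}
)
#: Element types in which a territory centre / nest may sit.
FIELD_LIKE_ELEMENTS = frozenset(
    {ElementType.FIELD, ElementType.PERMANENT_GRASS, ElementType.FIELD_MARGIN}
)


@dataclass
class VegetationState:
    height_cm: float = 0.0
    density: float = 0.0        # arbitrary 0-100 scale
    biomass: float = 0.0        # arbitrary units / m^2
    is_patchy: bool = False
    crop_id: str | None = None

    def validate(self) -> None:
        if self.height_cm < 0 or self.biomass < 0:
            raise ValueError("vegetation height and biomass must be >= 0")
        if not 0 <= self.density <= 100:
            raise ValueError("vegetation density must lie in [0, 100]")


@dataclass
class GrowthCurve:
    """Logistic biomass growth with degree-day temperature scaling.

    Daily increment: db = rate * b * (1 - b/biomass_max) * tf with
    tf = max(0, T - t_base) / t_scale.  Height and density are monotone
    (linear) functions of biomass, capped at their maxima.
    """

    curve_id: str
    t_base_c: float = 5.0
    t_scale_c: float = 10.0
    rate: float = 0.15
    biomass_max: float = 300.0
    height_max_cm: float = 80.0
    density_max: float = 60.0
    sown_biomass: float = 1.0

    def step(self, veg: VegetationState, mean_temp_c: float) -> VegetationState:
        tf = max(0.0, mean_temp_c - self.t_base_c) / self.t_scale_c
        b = veg.biomass
        if b > 0 and tf > 0:
            b = min(self.biomass_max, b + self.rate * b * (1 - b / self.biomass_max) * tf)
        frac = b / self.biomass_max if self.biomass_max > 0 else 0.0
        return replace(
            veg,
            biomass=b,
            height_cm=self.height_max_cm * frac,
            density=min(100.0, self.density_max * frac),
        )


#: Built-in growth curves for the reduced crop/element set.
DEFAULT_CURVES: dict[str, GrowthCurve] = {
    c.curve_id: c
    for c in [
        GrowthCurve("spring_barley", rate=0.12, density_max=30.0),
        GrowthCurve("winter_wheat", rate=0.09, biomass_max=350.0,
                    height_max_cm=90.0, density_max=40.0, sown_biomass=2.0),
        GrowthCurve("grass_ley", rate=0.10, biomass_max=200.0,
                    height_max_cm=50.0, density_max=25.0, sown_biomass=5.0),
        GrowthCurve("permanent_grass", rate=0.08, biomass_max=180.0,
                    height_max_cm=40.0, density_max=25.0, sown_biomass=10.0),
        GrowthCurve("field_margin", rate=0.06, biomass_max=150.0,
                    height_max_cm=60.0, density_max=20.0, sown_biomass=10.0),
        GrowthCurve("maize", rate=0.12, biomass_max=500.0,
                    height_max_cm=220.0, density_max=50.0, sown_biomass=1.0),
        GrowthCurve("peas", rate=0.12, biomass_max=250.0,
                    height_max_cm=60.0, density_max=35.0, sown_biomass=1.0),
        GrowthCurve("set_aside", rate=0.07, biomass_max=160.0,
                    height_max_cm=55.0, density_max=25.0, sown_biomass=8.0),
    ]
}


@dataclass
class InsectParams:
    """Stand-in insect food biomass model.

    insect_food = seasonal triangular envelope x element coefficient x
    saturating function of vegetation biomass x food_max, multiplied by
    any active insecticide knock-down (see farming).
    """

    food_max: float = 200.0
    season_start_doy: int = 60
    peak_doy: int = 180
    season_end_doy: int = 300
    biomass_halfsat: float = 100.0
    recovery_days: float = 28.0   # linear recovery span after insecticide
    element_coefficients: dict = field(default_factory=lambda: {
        ElementType.FIELD: 1.0,
        ElementType.FIELD_MARGIN: 1.5,
        ElementType.PERMANENT_GRASS: 1.2,
        ElementType.HEDGEROW: 0.8,
        ElementType.WOODLAND: 0.5,
        ElementType.OTHER: 0.5,
        ElementType.BARE: 0.0,
        ElementType.ROAD: 0.0,
        ElementType.BUILDING: 0.0,
        ElementType.WATER: 0.0,
    })

    def envelope(self, doy: int) -> float:
        if doy <= self.season_start_doy or doy >= self.season_end_doy:
            return 0.0
        if doy <= self.peak_doy:
            return (doy - self.season_start_doy) / (self.peak_doy - self.season_start_doy)
        return (self.season_end_doy - doy) / (self.season_end_doy - self.peak_doy)


@dataclass
class Polygon:
    poly_id: int
    element_type: ElementType
    cell_count: int = 0
    area_m2: float = 0.0
    veg: VegetationState = field(default_factory=VegetationState)
    insect_food: float = 0.0
    growth_curve: str | None = None
    farm_id: int | None = None
    has_scrapes: bool = False
    tramlines_always_open: bool = False
    tramlines_open_until: int | None = None  # absolute simulation day, exclusive
    # insecticide knock-down bookkeeping
    knockdown_factor: float = 1.0
    knockdown_day: int | None = None
    growing: bool = False  # crops only grow between sowing and harvest

    def tramlines_open(self, day: int) -> bool:
        if self.tramlines_always_open:
            return True
        return self.tramlines_open_until is not None and day < self.tramlines_open_until

    def knockdown_multiplier(self, day: int, recovery_days: float) -> float:
        if self.knockdown_day is None:
            return 1.0
        dt = day - self.knockdown_day
        if dt >= recovery_days:
            return 1.0
        f = self.knockdown_factor
        return f + (1.0 - f) * dt / recovery_days


def grow_vegetation(
    polygon: Polygon,
    mean_temp_c: float,
    curves: dict[str, GrowthCurve] | None = None,
) -> VegetationState:
    """Advance a polygon's vegetation by one day; inert elements are no-ops."""
    if polygon.element_type in INERT_ELEMENTS:
        return polygon.veg
    if polygon.element_type == ElementType.FIELD and not polygon.growing:
        return polygon.veg
    curves = curves or DEFAULT_CURVES
    curve_id = polygon.growth_curve
    if curve_id is None:
        return polygon.veg
    curve = curves[curve_id]
    polygon.veg = curve.step(polygon.veg, mean_temp_c)
    return polygon.veg


def update_insect_food(
    polygon: Polygon, doy: int, insects: InsectParams, day: int | None = None
) -> float:
    """Recompute today's available insect food for a polygon, units/m^2."""
    coeff = insects.element_coefficients.get(polygon.element_type, 0.0)
    b = polygon.veg.biomass
    sat = b / (b + insects.biomass_halfsat) if b > 0 else 0.0
    food = insects.envelope(doy) * coeff * sat * insects.food_max
    if day is not None:
        food *= polygon.knockdown_multiplier(day, insects.recovery_days)
    polygon.insect_food = food
    return food


@dataclass
class Plot:
    """A named rectangular observation plot (cells, inclusive of origin)."""

    name: str
    row0: int
    col0: int
    nrows: int
    ncols: int

    def contains(self, row: int, col: int) -> bool:
        return (
            self.row0 <= row < self.row0 + self.nrows
            and self.col0 <= col < self.col0 + self.ncols
        )

    def area_m2(self, cell_size: float) -> float:
        return self.nrows * self.ncols * cell_size * cell_size


class LandscapeGrid:
    """Raster of cells mapping to polygons, plus the polygon table."""

    def __init__(
        self,
        ids: np.ndarray,
        polygons: list[Polygon],
        cell_size: float = 1.0,
        plots: list[Plot] | None = None,
    ):
        ids = np.asarray(ids)
        if ids.ndim != 2:
            raise ValueError("raster must be a 2-D integer grid")
        self.ids = ids.astype(np.int32)
        self.cell_size = float(cell_size)
        self.plots = list(plots or [])
        self.polygons = polygons
        self.index_of = {p.poly_id: i for i, p in enumerate(polygons)}
        if len(self.index_of) != len(polygons):
            raise ValueError("duplicate polygon ids in table")
        raster_ids = np.unique(self.ids)
        unknown = [int(i) for i in raster_ids if int(i) not in self.index_of]
        if unknown:
            raise ValueError(f"raster contains ids absent from the table: {unknown}")
        if self.ids.min() < 0:
            raise ValueError("raster ids must be non-negative")
        # dense index raster for fast lookups
        lut = np.full(int(self.ids.max()) + 1, -1, dtype=np.int32)
        for pid, idx in self.index_of.items():
            if 0 <= pid <= int(self.ids.max()):
                lut[pid] = idx
        self.index_raster = lut[self.ids]
        cell_area = self.cell_size**2
        counts = np.bincount(self.index_raster.ravel(), minlength=len(polygons))
        for p, c in zip(polygons, counts):
            p.cell_count = int(c)
            p.area_m2 = float(c) * cell_area

    @property
    def shape(self) -> tuple[int, int]:
        return self.ids.shape

    def polygon_at(self, row: int, col: int) -> Polygon:
        return self.polygons[self.index_raster[row, col]]

    def total_area_m2(self) -> float:
        return self.ids.size * self.cell_size**2


# ----------------------------------------------------------------------
# I/O: portable text raster + CSV polygon table (+ optional plots CSV)
# ----------------------------------------------------------------------

def write_raster(ids: np.ndarray, cell_size: float, path) -> None:
    ids = np.asarray(ids, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write(f"ncols {ids.shape[1]} nrows {ids.shape[0]} cellsize {cell_size}\n")
        np.savetxt(fh, ids, fmt="%d")


def read_raster(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 6 or header[0] != "ncols":
            raise ValueError("bad raster header")
        ncols, nrows, cell_size = int(header[1]), int(header[3]), float(header[5])
        ids = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    if ids.shape != (nrows, ncols):
        raise ValueError("non-rectangular raster or shape mismatch with header")
    return ids, cell_size


_TABLE_COLUMNS = [
    "poly_id", "element_type", "growth_curve", "farm_id",
    "has_scrapes", "tramlines_always_open", "is_patchy",
]


def write_polygon_table(polygons: list[Polygon], path) -> None:
    rows = []
    for p in polygons:
        rows.append({
            "poly_id": p.poly_id,
            "element_type": p.element_type.value,
            "growth_curve": p.growth_curve or "",
            "farm_id": "" if p.farm_id is None else p.farm_id,
            "has_scrapes": int(p.has_scrapes),
            "tramlines_always_open": int(p.tramlines_always_open),
            "is_patchy": int(p.veg.is_patchy),
        })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


#: Initial vegetation by element type (fields start bare until sown).
_INITIAL_VEG = {
    ElementType.HEDGEROW: VegetationState(400.0, 80.0, 400.0),
    ElementType.WOODLAND: VegetationState(1500.0, 90.0, 800.0),
    ElementType.PERMANENT_GRASS: VegetationState(20.0, 25.0, 90.0, is_patchy=True),
    ElementType.FIELD_MARGIN: VegetationState(25.0, 20.0, 75.0, is_patchy=True),
}


def initial_vegetation(element_type: ElementType, is_patchy: bool) -> VegetationState:
    veg = _INITIAL_VEG.get(element_type, VegetationState())
    return replace(veg, is_patchy=veg.is_patchy or is_patchy)


def read_polygon_table(path) -> list[Polygon]:
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"polygon table missing columns: {sorted(missing)}")
    if df["poly_id"].duplicated().any():
        raise ValueError("duplicate polygon ids in table")
    polys = []
    for row in df.itertuples(index=False):
        et = ElementType(row.element_type)
        patchy = bool(row.is_patchy)
        p = Polygon(
            poly_id=int(row.poly_id),
            element_type=et,
            veg=initial_vegetation(et, patchy),
            growth_curve=(str(row.growth_curve)
                          if isinstance(row.growth_curve, str) and row.growth_curve
                          else None),
            farm_id=None if pd.isna(row.farm_id) or row.farm_id == "" else int(row.farm_id),
            has_scrapes=bool(row.has_scrapes),
            tramlines_always_open=bool(row.tramlines_always_open),
        )
        polys.append(p)
    return polys


def write_plots(plots: list[Plot], path) -> None:
    pd.DataFrame(
        [(pl.name, pl.row0, pl.col0, pl.nrows, pl.ncols) for pl in plots],
        columns=["name", "row0", "col0", "nrows", "ncols"],
    ).to_csv(path, index=False)


def read_plots(path) -> list[Plot]:
    df = pd.read_csv(path)
    return [
        Plot(str(r.name), int(r.row0), int(r.col0), int(r.nrows), int(r.ncols))
        for r in df.itertuples(index=False)
    ]


def save_landscape(grid: LandscapeGrid, raster_path, table_path, plots_path=None) -> None:
    write_raster(grid.ids, grid.cell_size, raster_path)
    write_polygon_table(grid.polygons, table_path)
    if plots_path is not None:
        write_plots(grid.plots, plots_path)


def load_landscape(raster_path, table_path, plots_path=None) -> LandscapeGrid:
    """Load and validate a landscape; unknown raster ids are an error."""
    ids, cell_size = read_raster(raster_path)
    polygons = read_polygon_table(table_path)
    plots = read_plots(plots_path) if plots_path is not None else None
    return LandscapeGrid(ids, polygons, cell_size=cell_size, plots=plots)


def grids_equal(a: LandscapeGrid, b: LandscapeGrid) -> bool:
    """Structural equality (raster, cell size, polygon attributes, plots)."""
    if a.cell_size != b.cell_size or not np.array_equal(a.ids, b.ids):
        return False
    if a.plots != b.plots or len(a.polygons) != len(b.polygons):
        return False
    for pa, pb in zip(a.polygons, b.polygons):
        if (
            pa.poly_id != pb.poly_id
            or pa.element_type != pb.element_type
            or pa.growth_curve != pb.growth_curve
            or pa.farm_id != pb.farm_id
            or pa.has_scrapes != pb.has_scrapes
            or pa.tramlines_always_open != pb.tramlines_always_open
            or pa.veg.is_patchy != pb.veg.is_patchy
        ):
            return False
    return True
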