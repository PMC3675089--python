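"""Self-contained synthetic scenarios emulating the three study designs:
a multi-plot mixed farmland census landscape, an all-spring-barley
landscape for nest monitoring, and the two-field skylark-scrape
experiment.  A scenario bundles landscape, farms, weather, parameters
and observation protocol, and reproduces a run bit-for-bit from its
seed; it can be saved to and reloaded from a directory of plain-text
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .farming import Farm, FarmType, assign_rotations
from .landscape import (
    ElementType,
    LandscapeGrid,
    Plot,
    Polygon,
    initial_vegetation,
    load_landscape,
    save_landscape,
)
from .params import SkylarkParams
from .simulation import SimResult, simulate
from .weather import WeatherGenParams, generate_weather, read_weather, write_weather

#: Polygon ids reserved for the landscape matrix.
HEDGE_ID = 1
MARGIN_ID = 2
FIRST_FIELD_ID = 10


@dataclass
class Scenario:
    name: str
    grid: LandscapeGrid
    farms: list[Farm]
    weather: pd.DataFrame
    params: SkylarkParams
    seed: int
    years: int = 60
    initial_pairs: int = 10
    visit_doys: list[int] = dc_field(default_factory=list)
    window_years: int = 20
    extras: dict = dc_field(default_factory=dict)

    def run(self, years: int | None = None, seed: int | None = None) -> SimResult:
        return simulate(
            self.grid,
            self.farms,
            self.weather,
            params=self.params,
            years=years if years is not None else self.years,
            seed=self.seed if seed is None else seed,
            initial_pairs=self.initial_pairs,
        )

    # -- persistence ----------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_landscape(self.grid, d / "raster.txt", d / "polygons.csv", d / "plots.csv")
        write_weather(self.weather, d / "weather.csv")
        self.params.to_yaml(d / "params.yaml")
        farms_rows = []
        for f in self.farms:
            farms_rows.append({
                "farm_id": f.farm_id,
                "farm_type": f.farm_type.value,
                "field_ids": ";".join(str(i) for i in f.field_ids),
                "rotation": ";".join(f.rotation),
                "phases": ";".join(f"{k}:{v}" for k, v in f.phases.items()),
            })
        pd.DataFrame(farms_rows).to_csv(d / "farms.csv", index=False)
        manifest = {
            "name": self.name,
            "seed": self.seed,
            "years": self.years,
            "initial_pairs": self.initial_pairs,
            "visit_doys": list(map(int, self.visit_doys)),
            "window_years": self.window_years,
            "extras": self.extras,
        }
        with open(d / "scenario.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    @classmethod
    def load(cls, directory) -> "Scenario":
        d = Path(directory)
        with open(d / "scenario.yaml") as fh:
            manifest = yaml.safe_load(fh)
        grid = load_landscape(d / "raster.txt", d / "polygons.csv", d / "plots.csv")
        farms = []
        fdf = pd.read_csv(d / "farms.csv")
        for r in fdf.itertuples(index=False):
            phases = {}
            if isinstance(r.phases, str) and r.phases:
                phases = {
                    int(k): int(v)
                    for k, v in (item.split(":") for item in r.phases.split(";"))
                }
            farms.append(Farm(
                farm_id=int(r.farm_id),
                farm_type=FarmType(r.farm_type),
                field_ids=[int(i) for i in str(r.field_ids).split(";") if i],
                rotation=str(r.rotation).split(";") if isinstance(r.rotation, str) else [],
                phases=phases,
            ))
        return cls(
            name=manifest["name"],
            grid=grid,
            farms=farms,
            weather=read_weather(d / "weather.csv"),
            params=SkylarkParams.from_yaml(d / "params.yaml"),
            seed=int(manifest["seed"]),
            years=int(manifest["years"]),
            initial_pairs=int(manifest["initial_pairs"]),
            visit_doys=list(manifest.get("visit_doys", [])),
            window_years=int(manifest.get("window_years", 20)),
            extras=manifest.get("extras", {}),
        )


# ----------------------------------------------------------------------
# raster assembly helpers
# ----------------------------------------------------------------------

def _make_polygons(ids: np.ndarray, field_attrs: dict[int, dict]) -> list[Polygon]:
    """Polygon table for a raster: matrix ids plus per-field attributes."""
    present = np.unique(ids)
    polys = []
    for pid in present:
        pid = int(pid)
        if pid == HEDGE_ID:
            et, curve, patchy = ElementType.HEDGEROW, None, False
        elif pid == MARGIN_ID:
            et, curve, patchy = ElementType.FIELD_MARGIN, "field_margin", True
        else:
            attrs = field_attrs.get(pid, {})
            et = attrs.get("element_type", ElementType.FIELD)
            curve = attrs.get("growth_curve", "spring_barley")
            patchy = attrs.get("is_patchy", et == ElementType.PERMANENT_GRASS)
        p = Polygon(
            poly_id=pid,
            element_type=et,
            veg=initial_vegetation(et, patchy),
            growth_curve=curve,
            farm_id=field_attrs.get(pid, {}).get("farm_id"),
            has_scrapes=field_attrs.get(pid, {}).get("has_scrapes", False),
            tramlines_always_open=field_attrs.get(pid, {}).get(
                "tramlines_always_open", False
            ),
        )
        polys.append(p)
    return polys


def _weather_for(seed: int, years: int) -> pd.DataFrame:
    return generate_weather(years, seed=(seed + 7919) % (2**31), gen=WeatherGenParams())


# ----------------------------------------------------------------------
# fixture scenarios
# ----------------------------------------------------------------------

def make_all_barley(
    area_km2: float = 0.25,
    seed: int = 0,
    cell_size: float = 2.0,
    years: int = 60,
) -> Scenario:
    """An all-spring-barley landscape for the nest-monitoring protocol.

    A hedged square of the requested area split into four barley fields
    separated by field margins; a single arable farm grows spring barley
    everywhere, and nest records are collected over the last
    ``window_years`` of the run.
    """
    if area_km2 < 0.25:
        raise ValueError("area must be at least 0.25 km^2")
    side = int(round(math.sqrt(area_km2 * 1e6) / cell_size))
    ids = np.full((side, side), MARGIN_ID, dtype=np.int32)
    ids[:2, :] = HEDGE_ID
    ids[-2:, :] = HEDGE_ID
    ids[:, :2] = HEDGE_ID
    ids[:, -2:] = HEDGE_ID
    inner0, inner1 = 2, side - 2
    mid = side // 2
    gap = 1  # margin strip half-width (cells)
    field_attrs: dict[int, dict] = {}
    fid = FIRST_FIELD_ID
    field_ids = []
    for r0, r1 in ((inner0, mid - gap), (mid + gap, inner1)):
        for c0, c1 in ((inner0, mid - gap), (mid + gap, inner1)):
            ids[r0:r1, c0:c1] = fid
            field_attrs[fid] = {"growth_curve": "spring_barley", "farm_id": 1}
            field_ids.append(fid)
            fid += 1
    polys = _make_polygons(ids, field_attrs)
    grid = LandscapeGrid(ids, polys, cell_size=cell_size,
                         plots=[Plot("all", 0, 0, side, side)])
    farm = Farm(farm_id=1, farm_type=FarmType.ARABLE, field_ids=field_ids)
    assign_rotations([farm], {"spring_barley": 1.0})
    area_ha = area_km2 * 100
    return Scenario(
        name="all_barley",
        grid=grid,
        farms=[farm],
        weather=_weather_for(seed, years),
        params=SkylarkParams(),
        seed=seed,
        years=years,
        initial_pairs=max(4, int(round(area_ha / 2.5))),
        visit_doys=list(range(105, 210, 15)),
        window_years=20,
    )


def make_scrape_experiment(
    seed: int = 0,
    n_scrapes: int = 100,
    cell_size: float = 2.0,
    years: int = 60,
) -> Scenario:
    """The two-field scrape experiment: a 22 ha spring-barley field with
    scrapes (tramlines kept open) and a 35 ha control without.

    With ``n_scrapes`` = 0 the first field loses its scrape flag and
    open tramlines, making the two fields identical apart from area.
    Weekly census dates span the breeding season.
    """
    # field cell counts chosen for exact areas at the default cell size
    f1_rows, f1_cols = 250, 220      # 55,000 cells x 4 m^2 = 22 ha
    f2_rows, f2_cols = 250, 350      # 87,500 cells x 4 m^2 = 35 ha
    gap = 3
    nrows = f1_rows + 4
    ncols = 2 + f1_cols + gap + f2_cols + 2
    ids = np.full((nrows, ncols), MARGIN_ID, dtype=np.int32)
    ids[:2, :] = HEDGE_ID
    ids[-2:, :] = HEDGE_ID
    ids[:, :2] = HEDGE_ID
    ids[:, -2:] = HEDGE_ID
    scrape_id, control_id = FIRST_FIELD_ID, FIRST_FIELD_ID + 1
    ids[2:2 + f1_rows, 2:2 + f1_cols] = scrape_id
    c0 = 2 + f1_cols + gap
    ids[2:2 + f2_rows, c0:c0 + f2_cols] = control_id
    with_scrapes = n_scrapes > 0
    field_attrs = {
        scrape_id: {"farm_id": 1, "has_scrapes": with_scrapes,
                    "tramlines_always_open": with_scrapes},
        control_id: {"farm_id": 1},
    }
    polys = _make_polygons(ids, field_attrs)
    plots = [
        Plot("scrape_field", 2, 2, f1_rows, f1_cols),
        Plot("control_field", 2, c0, f2_rows, f2_cols),
    ]
    grid = LandscapeGrid(ids, polys, cell_size=cell_size, plots=plots)
    farm = Farm(farm_id=1, farm_type=FarmType.ARABLE,
                field_ids=[scrape_id, control_id])
    assign_rotations([farm], {"spring_barley": 1.0})
    return Scenario(
        name="scrape_experiment",
        grid=grid,
        farms=[farm],
        weather=_weather_for(seed, years),
        params=SkylarkParams(),
        seed=seed,
        years=years,
        initial_pairs=24,
        visit_doys=list(range(105, 205, 7)),
        window_years=20,
        extras={"scrape_field": scrape_id, "control_field": control_id,
                "n_scrapes": n_scrapes},
    )


def make_bjerringbro_like(
    plot_count: int = 16,
    mean_field_ha: float = 3.9,
    seed: int = 0,
    fields_per_plot: int = 4,
    cell_size: float = 4.0,
    years: int = 60,
) -> Scenario:
    """A multi-plot mixed-farmland census landscape.

    ``plot_count`` square plots of ``fields_per_plot`` fields each, with
    per-plot field sizes varying around ``mean_field_ha`` (overall mean
    within a few percent), hedged plot boundaries and margin strips.
    Plots are assigned round-robin to pig/arable/mixed/hobby farms with
    a mixed rotation; the census protocol visits each plot eight times
    per season.
    """
    if plot_count < 1:
        raise ValueError("plot count must be >= 1")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(0.7, 1.3, plot_count)
    factors = factors / factors.mean()   # exact mean field area across plots
    field_m2 = factors * mean_field_ha * 10000.0
    field_side = np.maximum(4, np.round(np.sqrt(field_m2) / cell_size)).astype(int)

    per_row = math.ceil(math.sqrt(plot_count))
    fdim = 2  # fields per plot edge (2x2 layout)
    margin = 1
    tile = int(field_side.max()) * fdim + margin * (fdim + 1) + 2  # + hedge ring
    nrows = ncols = per_row * tile
    ids = np.full((nrows, ncols), MARGIN_ID, dtype=np.int32)
    plots = []
    field_attrs: dict[int, dict] = {}
    farm_fields: dict[int, list[int]] = {}
    n_farms = min(4, plot_count)
    fid = FIRST_FIELD_ID
    for pi in range(plot_count):
        pr, pc = divmod(pi, per_row)
        r0, c0 = pr * tile, pc * tile
        ids[r0:r0 + tile, c0:c0 + 1] = HEDGE_ID
        ids[r0:r0 + tile, c0 + tile - 1:c0 + tile] = HEDGE_ID
        ids[r0:r0 + 1, c0:c0 + tile] = HEDGE_ID
        ids[r0 + tile - 1:r0 + 1 + tile, c0:c0 + tile] = HEDGE_ID
        side = int(field_side[pi])
        farm_id = pi % n_farms + 1
        for fr in range(fdim):
            for fc in range(fdim):
                rr = r0 + 1 + margin + fr * (side + margin)
                cc = c0 + 1 + margin + fc * (side + margin)
                if fr * fdim + fc >= fields_per_plot:
                    continue
                ids[rr:rr + side, cc:cc + side] = fid
                field_attrs[fid] = {"farm_id": farm_id}
                farm_fields.setdefault(farm_id, []).append(fid)
                fid += 1
        plots.append(Plot(f"plot{pi + 1:02d}", r0 + 1, c0 + 1, tile - 2, tile - 2))
    polys = _make_polygons(ids, field_attrs)
    grid = LandscapeGrid(ids, polys, cell_size=cell_size, plots=plots)
    types = [FarmType.PIG, FarmType.ARABLE, FarmType.MIXED, FarmType.HOBBY]
    farms = [
        Farm(farm_id=k, farm_type=types[(k - 1) % len(types)], field_ids=flds)
        for k, flds in sorted(farm_fields.items())
    ]
    assign_rotations(farms, {
        "spring_barley": 0.4, "winter_wheat": 0.25, "grass_ley": 0.25, "peas": 0.1,
    })
    visit_doys = np.linspace(105, 208, 8).round().astype(int).tolist()
    return Scenario(
        name="bjerringbro_like",
        grid=grid,
        farms=farms,
        weather=_weather_for(seed, years),
        params=SkylarkParams(),
        seed=seed,
        years=years,
        initial_pairs=plot_count * 3,
        visit_doys=visit_doys,
        window_years=20,
    )
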