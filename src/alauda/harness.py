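"""Runners that map a parameter set to the six pattern statistics.

The guided-fitting and sensitivity harnesses need a function from a
:class:`~alauda.params.SkylarkParams` to the six fit statistics.  With
no field data deposited, the reference patterns are synthesised by a
baseline run of the fitted (default) parameter set on a miniature
two-field scenario; a runner then measures how far a perturbed
parameter set moves the model away from those baseline patterns.  By
construction the baseline scores zero on every statistic, which is the
natural reference point for one-at-a-time sensitivity.

Common random numbers (the same seed for every run) are used so that
parameter effects are not swamped by sampling noise.
"""

from __future__ import annotations

import numpy as np

from .observe import map_territories, monitor_nests, seasonal_series
from .params import SkylarkParams
from .pom import (
    density_series_fit,
    regression_origin,
    scaled_r2_fit,
    scaled_slope_fit,
    ssd_distribution_fit,
)
from .scenarios import Scenario, make_scrape_experiment


def make_miniature_scenario(seed: int = 0, years: int = 3) -> Scenario:
    """A scaled-down scrape-experiment scenario for cheap repeated runs."""
    scenario = make_scrape_experiment(seed=seed, years=years)
    # shrink the two fields to ~1/8 area by cropping the raster
    ids = scenario.grid.ids[:96, :]
    from .landscape import LandscapeGrid, Plot

    plots = [
        Plot("scrape_field", 2, 2, 92, 220),
        Plot("control_field", 2, 225, 92, 350),
    ]
    polys = scenario.grid.polygons
    grid = LandscapeGrid(np.ascontiguousarray(ids), polys,
                         cell_size=scenario.grid.cell_size, plots=plots)
    scenario.grid = grid
    scenario.years = years
    scenario.initial_pairs = 12
    return scenario


def _patterns(scenario: Scenario, years: int):
    """Run a scenario and extract the model-side pattern vectors."""
    result = scenario.run(years=years)
    events = result.events
    censuses = map_territories(
        events, scenario.grid.plots, scenario.visit_doys,
        cell_size=scenario.grid.cell_size, window_years=None,
    )
    densities = np.array([c.mean_density_per_ha for c in censuses])
    _records, hatch, leave = monitor_nests(events, window_years=None)
    series = {
        name: seasonal_series(
            events, scenario.extras[name], scenario.visit_doys, window_years=None
        )["mean_pairs"].to_numpy()
        for name in ("scrape_field", "control_field")
    }
    return densities, hatch.to_numpy(), leave.to_numpy(), series


def pattern_runner(seed: int = 0, years: int = 3):
    """Build a runner: SkylarkParams -> dict of the six statistics.

    The reference patterns come from a baseline run with default
    parameters on the miniature scenario; the baseline therefore scores
    exactly zero on all six statistics.
    """
    scenario = make_miniature_scenario(seed=seed, years=years)
    base_params = SkylarkParams()
    scenario.params = base_params
    obs_dens, obs_hatch, obs_leave, obs_series = _patterns(scenario, years)
    if not obs_dens.any():
        raise RuntimeError("baseline miniature run produced no pairs in any plot")
    for name in ("scrape_field", "control_field"):
        if not obs_series[name].any():
            raise RuntimeError(f"baseline series for {name} is all zero")

    def runner(params: SkylarkParams) -> dict:
        scenario.params = params
        dens, hatch, leave, series = _patterns(scenario, years)
        b, r2 = regression_origin(obs_dens, dens)
        return {
            "bjerringbro_slope": scaled_slope_fit(b, 1.0),
            "bjerringbro_r2": scaled_r2_fit(r2, 1.0),
            "hatch_fit": ssd_distribution_fit(obs_hatch, hatch)[1],
            "nest_leaving_fit": ssd_distribution_fit(obs_leave, leave)[1],
            "density_no_scrapes": density_series_fit(
                obs_series["control_field"], series["control_field"]
            ),
            "density_with_scrapes": density_series_fit(
                obs_series["scrape_field"], series["scrape_field"]
            ),
        }

    return runner
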