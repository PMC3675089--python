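"""Pattern-oriented model fitting: the six fit statistics, their scaling
to [0, 1], the weighted overall statistic, and the one-at-a-time
sensitivity harness.

Pattern set 1 compares modelled and observed plot pair densities by a
regression forced through the origin (slope and a general R^2).  Pattern
set 2 compares binned proportion distributions of incubation length and
nest-leaving day (plus failure causes) by summed squared difference.
Pattern set 3 compares per-date pair counts on two fields, scaled by the
score an extinct population would get.  The overall statistic is a
weighted mean of per-set means (sets 1 and 2 weighted double); lower is
better and 0 is a perfect fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .params import INTEGER_PARAMETERS, SkylarkParams

SIX_STATISTICS = (
    "bjerringbro_slope",
    "bjerringbro_r2",
    "hatch_fit",
    "nest_leaving_fit",
    "density_no_scrapes",
    "density_with_scrapes",
)

#: Percentage perturbations for continuous parameters and absolute steps
#: for small-integer parameters in the sensitivity protocol.
PERCENT_STEPS = (0.05, 0.10, 0.20, 0.40)
INTEGER_STEPS = (1, 2, 4, 8)
#: A parameter is insensitive if no perturbation moves the overall
#: statistic by more than this.
INSENSITIVITY_CUTOFF = 0.1


# ----------------------------------------------------------------------
# core statistics
# ----------------------------------------------------------------------

def regression_origin(x, y) -> tuple[float, float]:
    """Slope and R^2 of a linear regression forced through the origin.

    b = sum(xy)/sum(x^2); R^2 = 1 - SS_err/SS_tot with SS_tot taken
    about the mean of y (the general coefficient of determination, so
    R^2 may be negative for a poor through-origin fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValueError("all-zero x: slope undefined")
    b = float(x @ y) / sxx
    ss_err = float(((y - b * x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_err / ss_tot if ss_tot > 0 else (1.0 if ss_err == 0 else -np.inf)
    return b, r2


def ssd_distribution_fit(observed, modelled) -> tuple[float, float]:
    """Summed squared difference between two proportion vectors.

    Returns (raw SSD, scaled to [0, 1]); the scale constant is the
    maximum attainable SSD of 2 (two disjoint point masses).
    """
    p = np.asarray(observed, dtype=float)
    q = np.asarray(modelled, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions have mismatched bins")
    raw = float(((p - q) ** 2).sum())
    return raw, raw / 2.0


def density_series_fit(observed, modelled) -> float:
    """Per-date pair-count fit scaled by the extinct-population score.

    SSD(model, observed) / SSD(0, observed), clamped to [0, 1]; an
    extinct population (model = 0 everywhere) scores exactly 1.
    """
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modelled, dtype=float)
    if obs.shape != mod.shape:
        raise ValueError("observed and modelled series have mismatched dates")
    denom = float((obs**2).sum())
    if denom == 0.0:
        raise ValueError("observed series is all zero; scaling undefined")
    return min(1.0, float(((obs - mod) ** 2).sum()) / denom)


def scaled_slope_fit(b: float, m_slope: float) -> float:
    """|1 - b| / M, clamped to [0, 1]; M is the slope range over stable runs."""
    if m_slope <= 0:
        raise ValueError("M must be positive")
    return min(1.0, abs(1.0 - b) / m_slope)


def scaled_r2_fit(r2: float, m_r2: float) -> float:
    """(M - R^2) / M with M the best observed R^2, clamped to [0, 1]."""
    if m_r2 <= 0:
        raise ValueError("M must be positive")
    return min(1.0, max(0.0, (m_r2 - r2) / m_r2))


def overall_fit(stats: dict, weights=(2.0, 2.0, 1.0)) -> float:
    """Weighted mean of per-pattern-set means; lower is better.

    Sets: 1 = (bjerringbro_slope, bjerringbro_r2), 2 = (hatch_fit,
    nest_leaving_fit), 3 = (density_no_scrapes, density_with_scrapes).
    """
    for name in SIX_STATISTICS:
        v = stats[name]
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    s1 = (stats["bjerringbro_slope"] + stats["bjerringbro_r2"]) / 2.0
    s2 = (stats["hatch_fit"] + stats["nest_leaving_fit"]) / 2.0
    s3 = (stats["density_no_scrapes"] + stats["density_with_scrapes"]) / 2.0
    w = np.asarray(weights, dtype=float)
    return float((w @ [s1, s2, s3]) / w.sum())


@dataclass
class FitReport:
    slope: float
    r2: float
    m_slope: float
    m_r2: float
    statistics: dict = field(default_factory=dict)
    overall: float = np.nan

    def as_series(self) -> pd.Series:
        out = {"slope": self.slope, "r2": self.r2,
               "M_slope": self.m_slope, "M_r2": self.m_r2}
        out.update(self.statistics)
        out["overall"] = self.overall
        return pd.Series(out)


def fit_report(
    plot_obs,
    plot_mod,
    hatch_obs,
    hatch_mod,
    leave_obs,
    leave_mod,
    series_obs_no,
    series_mod_no,
    series_obs_with,
    series_mod_with,
    m_slope: float = 1.0,
    m_r2: float = 1.0,
    weights=(2.0, 2.0, 1.0),
) -> FitReport:
    """Assemble the six statistics and the overall fit from raw patterns."""
    b, r2 = regression_origin(plot_obs, plot_mod)
    stats = {
        "bjerringbro_slope": scaled_slope_fit(b, m_slope),
        "bjerringbro_r2": scaled_r2_fit(r2, m_r2),
        "hatch_fit": ssd_distribution_fit(hatch_obs, hatch_mod)[1],
        "nest_leaving_fit": ssd_distribution_fit(leave_obs, leave_mod)[1],
        "density_no_scrapes": density_series_fit(series_obs_no, series_mod_no),
        "density_with_scrapes": density_series_fit(series_obs_with, series_mod_with),
    }
    return FitReport(
        slope=b, r2=r2, m_slope=m_slope, m_r2=m_r2,
        statistics=stats, overall=overall_fit(stats, weights),
    )


# ----------------------------------------------------------------------
# observed-pattern data
# ----------------------------------------------------------------------

@dataclass
class PatternData:
    """Observed pattern vectors for one pattern set (1, 2 or 3)."""

    set_id: int
    vectors: dict = field(default_factory=dict)

    def validate_proportions(self, tol: float = 1e-9) -> None:
        for name, vec in self.vectors.items():
            if name.endswith("_proportions"):
                total = float(np.sum(vec))
                if abs(total - 1.0) > tol:
                    raise ValueError(f"{name} sums to {total}, expected 1")


def load_annual_pairs(path=None) -> pd.DataFrame:
    """Annual pair counts for the scrape field (columns year, pairs).

    With no path, loads the packaged observed counts for the scrape
    field in the four years after scrapes were provided.
    """
    if path is None:
        path = resources.files("alauda.data") / "scrape_field_pairs_observed.csv"
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"year", "pairs"} <= set(df.columns):
        raise ValueError("annual pairs file needs columns year, pairs")
    return df


def load_proportions(path) -> pd.Series:
    """A binned proportion vector (columns bin, proportion)."""
    df = pd.read_csv(path, dtype={"bin": str})
    s = pd.Series(df["proportion"].to_numpy(), index=df["bin"])
    if abs(float(s.sum()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return s


def load_plot_densities(path) -> pd.DataFrame:
    """Per-plot observed densities (columns plot, density_per_ha)."""
    df = pd.read_csv(path)
    if not {"plot", "density_per_ha"} <= set(df.columns):
        raise ValueError("plot density file needs columns plot, density_per_ha")
    return df


def load_date_series(path) -> pd.DataFrame:
    """Per-date pair counts (columns doy, pairs)."""
    df = pd.read_csv(path)
    if not {"doy", "pairs"} <= set(df.columns):
        raise ValueError("date series file needs columns doy, pairs")
    return df


# ----------------------------------------------------------------------
# sensitivity analysis
# ----------------------------------------------------------------------

def perturbation_values(name: str, value: float) -> list[float]:
    """The eight one-at-a-time test values for a parameter.

    Small-integer parameters are stepped by +-1, 2, 4, 8; all others by
    +-5, 10, 20, 40 percent of the fitted value.
    """
    if name in INTEGER_PARAMETERS:
        steps = [-s for s in reversed(INTEGER_STEPS)] + list(INTEGER_STEPS)
        return [value + s for s in steps]
    steps = [-s for s in reversed(PERCENT_STEPS)] + list(PERCENT_STEPS)
    return [value * (1.0 + s) for s in steps]


class RunnerError(RuntimeError):
    def __init__(self, parameter: str, cause: Exception):
        super().__init__(f"simulation runner failed for parameter {parameter}: {cause}")
        self.parameter = parameter


def sensitivity_scan(
    runner,
    params: SkylarkParams,
    parameter_names,
    weights=(2.0, 2.0, 1.0),
) -> pd.DataFrame:
    """One-at-a-time sensitivity scan.

    ``runner`` maps a SkylarkParams to a dict of the six statistics.
    Each parameter is perturbed at its eight protocol values with all
    others at fitted values; the table records the six statistics, the
    overall statistic, the deviation from the baseline overall, and the
    insensitivity classification (max |deviation| <= 0.1).
    """
    base_stats = runner(params)
    base_overall = overall_fit(base_stats, weights)
    rows = []
    for name in parameter_names:
        fitted = getattr(params, name)
        for value in perturbation_values(name, fitted):
            try:
                stats = runner(params.replace(**{name: value}))
            except Exception as exc:   # noqa: BLE001 - annotate and re-raise
                raise RunnerError(name, exc) from exc
            overall = overall_fit(stats, weights)
            row = {"parameter": name, "value": value,
                   "fitted_value": fitted, **stats,
                   "overall": overall,
                   "deviation": abs(overall - base_overall)}
            rows.append(row)
    df = pd.DataFrame(rows)
    max_dev = df.groupby("parameter", sort=False)["deviation"].transform("max")
    df["max_deviation"] = max_dev
    df["insensitive"] = max_dev <= INSENSITIVITY_CUTOFF
    return df


def fit_scan(
    runner,
    base: SkylarkParams,
    param_grid: dict,
    n_random: int = 0,
    seed: int = 0,
    weights=(2.0, 2.0, 1.0),
) -> pd.DataFrame:
    """Scripted stand-in for guided fitting: scan parameter combinations
    and rank them by the overall statistic (ascending; best first).

    ``param_grid`` maps parameter names to candidate value lists.  With
    ``n_random`` > 0, random combinations are drawn from the grid;
    otherwise the full product is evaluated (keep grids small).
    """
    names = list(param_grid)
    rng = np.random.default_rng(seed)
    if n_random > 0:
        combos = [
            tuple(param_grid[n][rng.integers(len(param_grid[n]))] for n in names)
            for _ in range(n_random)
        ]
    else:
        from itertools import product

        combos = list(product(*(param_grid[n] for n in names)))
    rows = []
    for combo in combos:
        p = base.replace(**dict(zip(names, combo)))
        stats = runner(p)
        rows.append({**dict(zip(names, combo)), **stats,
                     "overall": overall_fit(stats, weights)})
    return pd.DataFrame(rows).sort_values("overall", kind="stable").reset_index(drop=True)
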