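"""Virtual-ecologist observation protocols.

These functions reduce a simulation event log to the same data
structures a field campaign produces, so that model and field data are
measured identically: repeated territory mapping of plots (pairs whose
territory centre lies inside the plot on a visit date), nest monitoring
(incubation length / nestling period or failure cause), and a per-date
seasonal series of pair counts for a single field.

Long runs discard a burn-in: by convention statistics use only the last
``window_years`` of the run (20 of 60 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Plot

HATCH_BINS = list(range(9, 18))       # incubation length, days
LEAVE_BINS = list(range(6, 12))       # nestling period, days
FATE_BINS = ["predated", "other"]


def _window_years(events: pd.DataFrame, window_years: int | None) -> np.ndarray:
    years = np.sort(events["year"].unique())
    if window_years is not None and window_years < len(years):
        years = years[-window_years:]
    return years


def pair_intervals(events: pd.DataFrame) -> pd.DataFrame:
    """Mated-pair occupancy intervals from pair_formed / pair_end events.

    Returns one row per pair-year: year, pair id, centre row/col, centre
    polygon, start doy (inclusive) and end doy (exclusive).
    """
    formed = events[events["kind"] == "pair_formed"]
    ended = events[events["kind"] == "pair_end"].set_index(["year", "agent"])["doy"]
    rows = []
    for r in formed.itertuples(index=False):
        end = ended.get((r.year, r.agent), 366)
        rows.append((r.year, r.agent, int(r.row), int(r.col), int(r.polygon),
                     int(r.doy), int(end)))
    return pd.DataFrame(
        rows, columns=["year", "pair", "row", "col", "polygon", "start", "end"]
    )


@dataclass
class PlotCensus:
    plot: Plot
    area_ha: float
    visit_doys: list[int]
    #: per-year visit counts, shape (n_years, n_visits)
    counts: np.ndarray
    years: np.ndarray

    @property
    def seasonal_max(self) -> np.ndarray:
        """Per-year maximum pairs over visits."""
        return self.counts.max(axis=1) if self.counts.size else np.zeros(0)

    @property
    def mean_seasonal_max(self) -> float:
        return float(self.seasonal_max.mean()) if self.counts.size else 0.0

    @property
    def mean_density_per_ha(self) -> float:
        return self.mean_seasonal_max / self.area_ha


def map_territories(
    events: pd.DataFrame,
    plots: list[Plot],
    visit_doys: list[int],
    cell_size: float = 1.0,
    window_years: int | None = None,
) -> list[PlotCensus]:
    """Repeat territory mapping: count mated pairs with the territory
    centre inside each plot on each visit date."""
    years = _window_years(events, window_years)
    intervals = pair_intervals(events)
    intervals = intervals[intervals["year"].isin(years)]
    out = []
    for plot in plots:
        counts = np.zeros((len(years), len(visit_doys)), dtype=int)
        inside = intervals[
            intervals.apply(lambda r: plot.contains(r["row"], r["col"]), axis=1)
        ] if len(intervals) else intervals
        for yi, year in enumerate(years):
            sub = inside[inside["year"] == year]
            for vi, doy in enumerate(visit_doys):
                counts[yi, vi] = int(
                    ((sub["start"] <= doy) & (doy < sub["end"])).sum()
                )
        out.append(
            PlotCensus(
                plot=plot,
                area_ha=plot.area_m2(cell_size) / 10000.0,
                visit_doys=list(visit_doys),
                counts=counts,
                years=years,
            )
        )
    return out


@dataclass
class NestRecord:
    nest_id: str
    year: int
    incubation_days: int | None = None    # set iff the clutch hatched
    clutch_fate: str | None = None        # "predated" | "other" if it did not
    nestling_days: int | None = None      # set iff the brood left the nest
    brood_fate: str | None = None


def nest_records(events: pd.DataFrame, window_years: int | None = None) -> list[NestRecord]:
    years = set(_window_years(events, window_years))
    keep = events[events["kind"].isin(
        ["hatch", "clutch_fate", "nest_leave", "brood_fate"]
    )]
    records: dict[str, NestRecord] = {}
    for r in keep.itertuples(index=False):
        if r.year not in years:
            continue
        rec = records.setdefault(r.agent, NestRecord(nest_id=r.agent, year=int(r.year)))
        if r.kind == "hatch":
            rec.incubation_days = int(r.value)
        elif r.kind == "clutch_fate":
            rec.clutch_fate = r.cause
        elif r.kind == "nest_leave":
            rec.nestling_days = int(r.value)
        elif r.kind == "brood_fate":
            rec.brood_fate = r.cause
    return list(records.values())


def _distribution(values, fates, bins) -> pd.Series:
    """Proportion vector over duration bins + the two fate categories.

    Durations outside the bin range are clipped into the nearest bin.
    """
    labels = [str(b) for b in bins] + FATE_BINS
    counts = dict.fromkeys(labels, 0)
    for v in values:
        b = min(max(int(v), bins[0]), bins[-1])
        counts[str(b)] += 1
    for f in fates:
        counts[f] += 1
    total = sum(counts.values())
    props = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return pd.Series(props, index=labels)


def monitor_nests(
    events: pd.DataFrame, window_years: int | None = 20
) -> tuple[list[NestRecord], pd.Series, pd.Series]:
    """Nest monitoring protocol over the post-burn-in window.

    Returns (records, hatch distribution, nest-leaving distribution);
    each distribution is a proportion vector over day bins (9-17 for
    incubation, 6-11 for nest leaving) plus the predated/other fates,
    normalised to sum to 1.
    """
    records = nest_records(events, window_years)
    hatch = _distribution(
        [r.incubation_days for r in records if r.incubation_days is not None],
        [r.clutch_fate for r in records if r.clutch_fate is not None],
        HATCH_BINS,
    )
    # only nests that hatched enter the nestling-period distribution
    leave = _distribution(
        [r.nestling_days for r in records if r.nestling_days is not None],
        [r.brood_fate for r in records if r.brood_fate is not None],
        LEAVE_BINS,
    )
    return records, hatch, leave


def seasonal_series(
    events: pd.DataFrame,
    field_polygon: int,
    visit_doys: list[int],
    window_years: int | None = 20,
) -> pd.DataFrame:
    """Mean pairs on a field per visit date over the window years.

    A pair belongs to the field if its territory centre polygon is the
    field; means are taken over the post-burn-in years.
    """
    years = _window_years(events, window_years)
    intervals = pair_intervals(events)
    intervals = intervals[
        intervals["year"].isin(years) & (intervals["polygon"] == field_polygon)
    ]
    means = []
    for doy in visit_doys:
        per_year = [
            int(((intervals["year"] == y)
                 & (intervals["start"] <= doy)
                 & (doy < intervals["end"])).sum())
            for y in years
        ]
        means.append(float(np.mean(per_year)) if len(per_year) else 0.0)
    return pd.DataFrame({"doy": visit_doys, "mean_pairs": means})
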