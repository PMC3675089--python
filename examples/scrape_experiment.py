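"""The two-field skylark-scrape experiment.

A 22 ha spring-barley field with scrapes (tramlines kept open) and a
35 ha control field are censused weekly; the run shows the qualitative
pattern of interest: pair numbers collapse on the control field once the
maturing crop closes, but persist on the scrape field.
"""

from alauda import make_scrape_experiment
from alauda.observe import seasonal_series

scenario = make_scrape_experiment(seed=2)
result = scenario.run(years=30)

print("mean pairs per census date (last 20 years):")
print(f"{'day':>5} {'with scrapes':>13} {'control':>9}")
series = {
    name: seasonal_series(result.events, scenario.extras[name],
                          scenario.visit_doys, window_years=20)
    for name in ("scrape_field", "control_field")
}
for i, doy in enumerate(scenario.visit_doys):
    s = series["scrape_field"]["mean_pairs"][i]
    c = series["control_field"]["mean_pairs"][i]
    print(f"{doy:>5} {s:>13.2f} {c:>9.2f}")

print(
    "\nBoth fields fill once the crop emerges; the control field (no\n"
    "scrapes, tramlines allowed to close) loses its territories when the\n"
    "crop grows tall and dense, while the scrape field retains them."
)
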