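"""From raw ring widths to a site chronology.

Generates pseudo-observed rings for 12 trees (ontogenetic trend x model
signal x noise), detrends each with the 60-year 50%-cutoff smoothing
spline, averages with the robust biweight mean, and reports how well the
chronology tracks the generating signal.
"""

import numpy as np

from ringcast import (
    SyntheticSiteSpec,
    VSLiteParameters,
    build_chronology,
    generate_climate,
    generate_pseudo_observed_rings,
    simulate,
)

climate = generate_climate(SyntheticSiteSpec(site_id="demo", seed=1, years=(1892, 2020)))
truth = VSLiteParameters()
trees = generate_pseudo_observed_rings(climate, truth, n_trees=12, noise_sd=0.05, seed=2)
chron = build_chronology(trees, site_id="demo", min_trees=5)

sim = simulate(climate, truth)
window = (chron.years >= 1961) & (chron.years <= 2020)
signal = sim.trw_proxy[1:][(sim.years[1:] >= 1961) & (sim.years[1:] <= 2020)]
r = np.corrcoef(chron.index[window], signal)[0, 1]

print(f"trees: {len(trees)}, chronology years: {chron.years[0]}-{chron.years[-1]}")
print(f"index mean: {chron.index.mean():.3f} (ratio detrending centres it near 1)")
print(f"sample depth 1961-2020: {chron.sample_depth[window].min()}")
print(f"correlation with the generating growth signal, 1961-2020: r = {r:.3f}")
print()
print("the spline removes the age trend (and any variance slower than the")
print("60-yr cutoff); what remains is the climate-driven year-to-year signal.")
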