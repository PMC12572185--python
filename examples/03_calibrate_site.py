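"""Random-search calibration of the growth model at one site.

Draws 10,000 parameter vectors inside ecologically plausible bounds,
simulates each, and keeps the one whose ring-width proxy correlates best
with the observed (here: synthetic) chronology over 1961-2020.
"""

from ringcast import (
    SyntheticSiteSpec,
    VSLiteParameters,
    build_chronology,
    generate_climate,
    generate_pseudo_observed_rings,
    random_search_calibrate,
)

climate = generate_climate(SyntheticSiteSpec(site_id="demo", seed=1, years=(1892, 2020)))
truth = VSLiteParameters()
trees = generate_pseudo_observed_rings(climate, truth, n_trees=12, noise_sd=0.05, seed=2)
chron = build_chronology(trees, site_id="demo")

result = random_search_calibrate(chron, climate, n_draws=10_000, seed=42)

print(f"calibration window: {result.calibration_window}, draws: {result.n_draws}")
print(f"best r = {result.r:.3f}  (t({result.df}) = {result.t_stat:.2f}, p = {result.p_value:.2e})")
print(f"95% CI of r: [{result.ci95[0]:.2f}, {result.ci95[1]:.2f}]")
print("recovered / true parameters:")
for name in ("t1", "t2", "t3", "t4", "m1", "m2", "w", "mcap"):
    print(f"  {name:>4}: {getattr(result.best_params, name):7.3f}   {getattr(truth, name):7.3f}")
print()
print("with a clean target the search recovers the response thresholds the")
print("forcing actually visits; parameters the climate never exercises (for")
print("instance a heat limb never reached) remain unidentified - as expected.")
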