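"""Flower strips versus off-field habitat on a synthetic landscape.

Generates a seeded synthetic landscape (target-crop fields plus small
off-field elements), sweeps the flower-strip and off-field mitigation
scenarios over a presence-probability grid with the recruitment-limited
colony model, and compares how much managed habitat area each scenario
needs for the dilution reached at 90% of candidate hive sites.

Runs in about half a minute at this problem size.
"""

from beeforage import (
    BeeParameters,
    ExposureConfig,
    OILSEED_RAPE,
    SimulationConfig,
    SyntheticLandscapeParams,
    area_efficiency,
    generate_synthetic_landscape,
    run_assessment,
)

params = SyntheticLandscapeParams(extent=3000, n_target=15, n_alternative=0,
                                  n_offfield=120)
ls = generate_synthetic_landscape(params, seed=202)
print(ls.summary(), "\n")

bee = BeeParameters.default()
cfg = SimulationConfig(model="rl")
exp = ExposureConfig(C_P=1.0, reference=OILSEED_RAPE)
common = dict(realizations=4, site_sample_fraction=0.04, master_seed=99)

strips = run_assessment(ls, "flower_strips", bee, cfg, exp,
                        p_grid=[0.0, 0.5, 1.0], variant={"width": 1.0}, **common)
off = run_assessment(ls, "off_field", bee, cfg, exp,
                     p_grid=[0.5, 1.0], variant={"quality_mult": 1.0}, **common)

df = area_efficiency({"off_field": off, "flower_strips": strips})
print(df.to_string(index=False))
ratio = df.attrs["matched_area_ratio"]
if isinstance(ratio, tuple):
    print(f"\nmatched-dilution area ratio (off-field / strips): > {ratio[0]:.1f} (bound)")
else:
    print(f"\nmatched-dilution area ratio (off-field / strips): {ratio:.1f}")

print(
    "\np90 is the dilution factor reached at 90% of candidate hive sites"
    "\n(lower = stronger dilution).  Strips achieve a given p90 with far"
    "\nless managed area because they sit on the very fields the hives"
    "\nborder, while off-field elements are scattered across the landscape."
)
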