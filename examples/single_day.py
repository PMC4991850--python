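"""One foraging day under the two colony models.

Builds a small in-memory landscape — a treated oilseed-rape field next to
the hive, a second field further out, and a dozen small clover patches —
and simulates a 10-hour day with the single-optimal (SO) and the
recruitment-limited (RL) model, printing deliveries and the dilution
factor of the hypothetical pesticide at the hive entrance.
"""

from beeforage import (
    BeeParameters,
    CLOVER,
    ExposureConfig,
    OILSEED_RAPE,
    Patch,
    SimulationConfig,
    dilution_factor,
    patches_for_sugar_fraction,
    simulate_day,
)

bee = BeeParameters.default()
exp = ExposureConfig(C_P=1.0, reference=OILSEED_RAPE)  # 1 ug chemical / mg nectar


def build_patches():
    patches = [
        Patch(id="home-field", rt=OILSEED_RAPE, A=2e5, D=12.5, treated=True, C=exp.C_P),
        Patch(id="far-field", rt=OILSEED_RAPE, A=1e5, D=800.0),
    ]
    for k in range(12):
        patches.append(
            Patch(id=f"clover-{k:02d}", rt=CLOVER, A=500.0, D=150.0 + 120.0 * k)
        )
    return patches


for model in ("so", "rl"):
    res = simulate_day(build_patches(), bee, SimulationConfig(model=model))
    phi = dilution_factor(res, exp, bee)
    print(f"\n{model.upper()} model:")
    print(f"  sugar delivered      : {res.total_sugar / 1000:8.1f} g")
    print(f"  exploited patches    : {len(res.exploited_patches)}")
    print(f"  patches for 90% sugar: {patches_for_sugar_fraction(res, 0.9)}")
    print(f"  dilution factor phi_m: {phi:.3f}")

print(
    "\nphi_m = 1 means the nectar stream is as contaminated as the treated"
    "\nfield itself; smaller values mean foraging effort was diverted to"
    "\nuntreated patches.  The SO colony locks onto the single best patch"
    "\neach hour, the RL colony spreads effort over several good patches,"
    "\nwhich is why its dilution is stronger here."
)
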