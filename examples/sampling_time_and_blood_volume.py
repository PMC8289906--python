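"""Effect of imprecise blood-draw timing and unmeasured blood volume.

Blood draws nominally at 6 h often happen anywhere in 6 +/- 3 h, and at
36 h anywhere in 36 +/- 12 h; total blood volume differs by sex (means
4,750 ml women / 5,320 ml men) and is rarely corrected for.  Both
uncertainties translate directly into spread in the measured level.
"""

from tbikinetics import blood_volume_uncertainty, get_preset, time_uncertainty

print("Draw-time jitter (D0 = 400,000 pg, nominal kinetics):")
for nominal_t, hw in [(6.0, 3.0), (36.0, 12.0)]:
    for name in ("GFAP", "UCH-L1", "tau", "NF-L"):
        s = time_uncertainty(get_preset(name), nominal_t, hw, n=2000, seed=4).summary()
        print(
            f"  {name:7s} at {nominal_t:4.0f}±{hw:.0f} h: "
            f"mean={s['mean']:7.2f} sd={s['sd']:6.2f} pg/ml"
        )

print("\nBlood-volume uncertainty (GFAP at 6 h, Vd ~ Normal(sex mean, 10%)):")
for sex in ("female", "male"):
    s = blood_volume_uncertainty(get_preset("GFAP"), sex, 6.0, n=2000, seed=1).summary()
    print(f"  {sex:6s}: mean={s['mean']:6.2f} sd={s['sd']:5.2f} pg/ml")

print(
    "\nNF-L's 6-h level is barely moved by timing error (slow absorption),"
    "\nwhile the other biomarkers shift by several pg/ml; ignoring sex-specific"
    "\nblood volume alone spreads the same injury over ~±20% in level."
)
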