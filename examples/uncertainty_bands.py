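"""How uncertainty in the rate constants propagates to predicted levels.

Monte Carlo bands (mean +/- 2*delta, delta = output SD over 1,000 draws
of one rate constant from its lognormal with shape 0.2): absorption-rate
uncertainty widens the band during the rising phase, elimination-rate
uncertainty during the falling phase.  Joint uncertainty in all four
inputs is summarised by the Pearson correlation of each input with the
output at 5 h and 50 h.
"""

import numpy as np

from tbikinetics import get_preset, joint_uncertainty, single_param_band

preset = get_preset("GFAP")
grid = np.arange(0.0, 120.0, 0.5)
for which in ("ka", "ke"):
    band = single_param_band(preset, which, grid, sigma=0.2, n=1000, seed=5)
    t_widest = grid[np.argmax(band.width())]
    print(
        f"GFAP {which}-band: widest at t={t_widest:5.1f} h "
        f"(width {band.width().max():6.2f} pg/ml); mean peaks at "
        f"t={grid[np.argmax(band.mean)]:5.1f} h"
    )

joint = joint_uncertainty(preset, time_points=(5.0, 50.0), n=1000, seed=3)
print("\nPearson correlation of each input with the predicted level:")
print(joint.correlations.round(3).to_string())
print(
    "\nThe ka-band is widest before the ~23 h peak and the ke-band after it;"
    "\nD0 and Vd dominate the output at both times, ka only early, ke only late."
)
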