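"""Which inputs drive the predicted level, and when?

Partial correlation coefficients (PCC) between each model input and the
predicted level over a Monte Carlo ensemble (N=1000; lognormal spread 0.3
on the released amount D0, 0.1 on blood volume and the rate constants).
The released amount always pushes levels up, blood volume always down;
the absorption rate matters early and the elimination rate late, with
the hand-over (crossover) occurring near the biomarker's peak time.
"""

import numpy as np

from tbikinetics import get_preset, pcc_over_time, rate_crossover_time

for name, grid in [("GFAP", np.arange(1.0, 51.0, 1.0)), ("NF-L", np.arange(1.0, 701.0, 7.0))]:
    result = pcc_over_time(get_preset(name), grid, n=1000, seed=1)
    i_early, i_late = 0, len(grid) - 1
    print(f"{name}: significance band |gamma| < {result.threshold:.4f} (alpha={result.alpha})")
    for inp in ("D0", "Vd", "ka", "ke"):
        g = result.pcc[inp]
        print(f"  gamma({inp:2s}) early={g[i_early]:+.3f}  late={g[i_late]:+.3f}")
    print(f"  ka/ke influence crossover at ~{rate_crossover_time(result):.0f} h\n")

print(
    "gamma near +1/-1 means the input dominates the predicted level at that"
    "\ntime; NF-L's slower kinetics shift its crossover ~10x later than GFAP's."
)
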