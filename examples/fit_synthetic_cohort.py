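"""Estimate the amount released at impact from four sparse timed levels.

Generates a synthetic concussion cohort (known ground truth: per-subject
released amount D0 and blood volume, jittered true draw times recorded
only as nominal schedule hours, 20% multiplicative assay noise), then
inverts the kinetic model by closed-form least squares to recover each
subject's D0, and reports the recovery error.
"""

import numpy as np

from tbikinetics import CohortConfig, fit_cohort, generate_cohort, get_preset, truth_report

config = CohortConfig(
    n_subjects=200, biomarkers=("GFAP",), noise_sigma=0.2, fixed_vd=5000.0, seed=13
)
table = generate_cohort(config)
print(f"cohort: {config.n_subjects} subjects x 4 timepoints = {len(table)} measurements")

fits, curves = fit_cohort(table, get_preset("GFAP"))
merged = fits.merge(truth_report(table), on=["subject_id", "biomarker"])
rel_err = (merged["D0_hat_pg"] - merged["true_D0_pg"]) / merged["true_D0_pg"]
print(f"median |relative error| of D0_hat: {np.median(np.abs(rel_err)):.3f}")
print(f"mean relative bias:                {rel_err.mean():+.3f}")
print(f"first subjects:\n{merged.head(3)[['subject_id', 'D0_hat_pg', 'true_D0_pg']].to_string(index=False)}")

print(
    "\nWith the correct kinetics, 20% assay noise and true draw times jittered"
    "\naround the recorded nominal hours, the released amount is recovered to"
    "\nwithin ~10-15% for a typical subject and with little systematic bias —"
    "\nsupporting D0 as a time-independent severity measure."
)
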