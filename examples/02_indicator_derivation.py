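"""Derive the six indicators from raw survey measurements.

Missing-aware OR logic: an indicator is 1 as soon as any criterion is
met, 0 only when every criterion is observed to fail, missing otherwise.
"""

import numpy as np

from ncdprev import (
    derive_bmi_category,
    derive_diabetes,
    derive_hypertension,
)

NA = np.nan

sbp = [150, 139, 120, NA]
dbp = [80, 89, NA, NA]
med = [0, 0, 0, 1]
print("hypertension (sbp, dbp, medication):")
for s, d, m, out in zip(sbp, dbp, med, derive_hypertension(sbp, dbp, med)):
    print(f"  sbp={s!s:>4} dbp={d!s:>4} med={m} -> {out}")
# 150/80 exceeds the systolic cut-off -> 1; 139/89 fails all criteria
# with everything observed -> 0; 120/NA cannot rule out the diastolic
# criterion -> nan; medication alone suffices -> 1.

print("\nBMI category for 80 kg at 1.60 m:",
      derive_bmi_category(160.0, 80.0)[0], "(31.2 kg/m^2 -> obese)")

print("\ndiabetes in a wave without HbA1c measurements (1997):")
for m, h in ((1, NA), (0, NA)):
    out = derive_diabetes(m, h, wave_year=1997)[0]
    print(f"  medication={m} hba1c=NA -> {out}")
# Medication confirms diabetes; without it the HbA1c criterion is
# undecidable, so the cell stays missing and is left to the imputation
# engine rather than biased to 0.
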