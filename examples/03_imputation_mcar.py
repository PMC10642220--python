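"""Chained-equations imputation under MCAR deletion.

Deletes 30% of one binary indicator completely at random and checks
that the pooled prevalence over m completed datasets recovers the
pre-deletion value.
"""

import numpy as np
import pandas as pd

from ncdprev import ImputationSpec, MiceConfig, run_chain

rng = np.random.default_rng(42)
frames = []
for year in (1997, 2002, 2007, 2012, 2017):
    n = 2000
    frames.append(pd.DataFrame({
        "year": year,
        "sex": rng.integers(0, 2, n),
        "age": rng.integers(25, 65, n),
        "smoking": (rng.random(n) < 0.30).astype(float),
    }))
frame = pd.concat(frames, ignore_index=True)
truth = frame["smoking"].mean()

deleted = frame.copy()
deleted.loc[rng.random(len(frame)) < 0.30, "smoking"] = np.nan

spec = ImputationSpec("smoking", "logistic", ("age", "sex", "year"))
completed = run_chain(deleted, [spec], MiceConfig(m=20, iterations=10, seed=7))

pooled = np.mean([f["smoking"].mean() for f in completed.frames])
between = completed.imputed_cell_means("smoking").var()
print(f"pre-deletion prevalence : {truth:.4f}")
print(f"pooled prevalence (m=20): {pooled:.4f}")
print(f"between-imputation variance of imputed-cell mean: {between:.2e}")
# The pooled estimate sits within Monte-Carlo error of the pre-deletion
# value (MCAR neutrality); the positive between-imputation variance
# shows parameter uncertainty is propagated (proper imputation).
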