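"""Taguchi L9 screening of dissolution conditions.

Builds the 9-run orthogonal array over product, medium, apparatus and
rotation speed, simulates six replicate tablets per run, and runs the
main-effects ANOVA on Q%2h / Q%12h / Q%24h.  Product and apparatus drive
release; medium and speed are nulls.
"""

import numpy as np
import pandas as pd

from dissopk import doe_anova, l9_design, make_study_fixture, simulate_dissolution
from dissopk.datasets import DOE_RUNS

design = l9_design()
print(design.decode().to_string(index=False))

fixture = make_study_fixture(seed=1)
rng = np.random.default_rng(1)
rows = []
for run_no, method in enumerate(fixture.methods, start=1):
    product = DOE_RUNS.loc[run_no - 1, "product"]
    prof = simulate_dissolution(fixture.products[product], method, n_units=6, seed=rng)
    tgrid = np.concatenate(([0.0], prof.times))
    for unit in range(prof.n_units):
        qgrid = np.concatenate(([0.0], prof.q[unit]))
        rows.append({"run": run_no, "unit": unit + 1,
                     "q2h": np.interp(2.0, tgrid, qgrid),
                     "q12h": np.interp(12.0, tgrid, qgrid),
                     "q24h": np.interp(24.0, tgrid, qgrid)})

table = doe_anova(design, pd.DataFrame(rows))
pivot = table[table.term != "residual"].pivot(index="term", columns="response", values="p")
print("\nANOVA p-values per response:")
print(pivot.round(4).to_string())
print("\nproduct and apparatus are significant (p < 0.05) at every time")
print("point; rotation speed is not — the pattern that justifies fixing")
print("the medium and speed when selecting the biopredictive method.")
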