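"""Level-A IVIVC: deconvolve, correlate, convolve, classify.

Simulates the "observed" reference plasma curve, mechanistically
deconvolves it to the fraction released in vivo, correlates that with the
in vitro profile of each apparatus condition, convolves back and computes
the Cmax/AUC prediction errors that decide which condition is
biopredictive.
"""

import numpy as np

from dissopk import (
    AbsorptionParams,
    DispositionParams,
    MethodFixture,
    classify_biopredictive,
    convolve_predict,
    deconvolve_fabs,
    derive_disposition,
    fit_ivivc,
    make_study_fixture,
    pk_metrics,
    prediction_error,
    simulate_dissolution,
    simulate_observed_plasma,
)
from dissopk.dissolution import WeibullParams, weibull_release
from dissopk.ivivc import OralKernel
from dissopk.synthetic import REFERENCE_RELEASE, effective_release

fixture = make_study_fixture(seed=1)
d = derive_disposition(fixture.disposition)
a = fixture.absorption

# "observed" reference curve: forward simulation of the in vivo release
t_rel = np.arange(0.25, 36.01, 0.25)
frac = weibull_release(t_rel, REFERENCE_RELEASE) / 100.0
observed = simulate_observed_plasma(fixture.disposition, a, (t_rel, frac))
obs_metrics = pk_metrics(observed)
print(f"observed: Cmax = {obs_metrics.cmax_ng_ml:.1f} ng/mL, "
      f"Tmax = {obs_metrics.tmax_h:.1f} h, AUC(0-t) = {obs_metrics.auc_0t:.0f} ng*h/mL\n")

kernel = OralKernel.from_cat(d, a)
fabs = deconvolve_fabs(observed, d, dose_mg=a.dose_mg, kernel=kernel)

print(f"{'condition':<22} {'r^2':>6} {'PE Cmax':>8} {'PE AUC':>8}  biopredictive")
for apparatus in ("basket", "paddle_sinker", "paddle"):
    method = MethodFixture(medium="0.9% NaCl", apparatus=apparatus, speed_rpm=50)
    for product in ("Reference", "Generic #1", "Generic #2"):
        fdiss = simulate_dissolution(
            fixture.products[product], method, n_units=1, seed=0, noise_cv=0.0
        )
        model = fit_ivivc(fabs, fdiss)
        pred = convolve_predict(model, fdiss, d, dose_mg=a.dose_mg,
                                t_grid=observed.times_h, kernel=kernel)
        pm = pk_metrics(pred)
        pe_c = prediction_error(obs_metrics.cmax_ng_ml, pm.cmax_ng_ml)
        pe_a = prediction_error(obs_metrics.auc_0t, pm.auc_0t)
        label = f"{apparatus}/{product}"
        print(f"{label:<22} {model.r_squared:>6.3f} {pe_c:>8.2f} {pe_a:>8.2f}  "
              f"{classify_biopredictive(pe_c, pe_a)}")

print("\nThe paddle+sinker condition carries the smallest worst-case |PE|")
print("across products, which is why it is selected as biopredictive.")
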