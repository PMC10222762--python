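"""Oral PK simulation: disposition, enterocyte trapping, Tmax sensitivity.

Derives the hybrid two-compartment constants from the published
desvenlafaxine parameters, simulates an immediate-release 100 mg dose
through the CAT absorption chain, and shows how the fraction unbound in
the enterocytes (Fuent) delays Tmax — the behaviour of a lysosomotropic
weak base.
"""

from dissopk import (
    AbsorptionParams,
    DispositionParams,
    derive_disposition,
    lysosome_trapping_ratio,
    pk_metrics,
    psa_fuent,
    simulate_oral_cat,
)

d = derive_disposition(DispositionParams())
print(f"Vc = {d.vc_l_kg:.4f} L/kg, k10 = {d.k10_1_h:.4f} 1/h")
print(f"alpha = {d.alpha_1_h:.4f} 1/h, beta = {d.beta_1_h:.4f} 1/h")
print(f"terminal half-life = {d.t_half_beta_h:.2f} h (reported: 9.7 h)\n")

a = AbsorptionParams(dose_mg=100.0)
profile = simulate_oral_cat(d, a, t_end_h=48.0)
m = pk_metrics(profile, terminal_rate_1_h=d.beta_1_h)
print(f"IR 100 mg: Cmax = {m.cmax_ng_ml:.1f} ng/mL at Tmax = {m.tmax_h:.2f} h "
      f"(observed window 2-4 h), AUC(0-inf) = {m.auc_0inf:.0f} ng*h/mL\n")

print("Tmax vs fraction unbound in enterocytes (Fuent):")
for fuent, tmax in psa_fuent(d, a, [0.01, 0.02, 0.05, 0.1, 0.5, 1.0]):
    marker = "  <- model value" if fuent == a.fuent else ""
    print(f"  Fuent = {fuent:>5.2f}: Tmax = {tmax:.2f} h{marker}")

print("\nlysosome/cytosol trapping ratio (pKa 9.18, cytosol pH 7.0):")
print(f"  lysosomal pH 4.0: {lysosome_trapping_ratio(9.18, 4.0, 7.0):7.0f}x  (~10^3)")
print(f"  lysosomal pH 6.5: {lysosome_trapping_ratio(9.18, 6.5, 7.0):7.1f}x  (< 10)")
print("\nLow Fuent (2%) slows enterocyte exit and reproduces the late Tmax")
print("seen for a BCS class I drug that is trapped in acidic organelles.")
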