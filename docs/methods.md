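# Methods

This note documents the models, parameter choices and numerical decisions
behind `dissopk`, and what the synthetic study fixture does and does not
emulate.

## Tablet geometry

Tablets are idealised as cylinders (round) or rectangular prisms (square);
SA/V follows algebraically (cylinder SA/V ≡ 2/t + 2/r).  Batch summaries
report the mean of per-tablet SA/V ratios with the sample (n−1) SD, which
is the quantity a physical characterisation of n = 12 units reports; the
ratio-of-means alternative (SA/V evaluated at mean dimensions) is also
implemented and typically agrees within ~0.05%.  Swelling and erosion of
the hydrated matrix are out of scope — SA/V is a *initial-state* covariate
of release rate, not a time-resolved geometry.

## Dissolution model and specifications

ER matrix release is represented by the Weibull function
F(t) = fmax(1 − exp(−(t/td)^b)).  It is an empirical saturating model, not
a mechanistic gel-layer description; it is chosen because HPMC-matrix
profiles are smooth, monotone and asymptote below 100%, and because its
three parameters separate extent (fmax), time scale (td) and shape (b).
Profiles are interpolated linearly between sampling points (monotone, no
overshoot), with Q(0) ≡ 0 and no extrapolation beyond the last sample.

Specification windows are checked against the mean of replicate units, the
convention of dissolution testing.  Boundary semantics follow the
pharmacopeial reading: a first-hour "< 20%" limit is strict, ranges and
"not less than" limits are inclusive.  Derived specifications
(floor(min − margin), ceil(max + margin), clipped to [0, 100], first point
upper-only, last point lower-only) use inclusive bounds throughout so that
every profile used to derive a window is guaranteed to pass it; the margin
(default 2%) and rounding step (default 1%) are free parameters, as no
standard rule exists for widening windows beyond the observed span.

## Two-compartment disposition

Parameterised by Cl, Vss, K12, K21 (per kg; default body weight 70 kg —
the shipped AUC values are consistent with dose/Cl at ~70 kg, and the
simulation weight is configurable).  Derived constants:
Vc = Vss/(1 + K12/K21), k10 = Cl/Vc, and α, β the roots of
s² − (k10+K12+K21)s + k10·K21.  The unit impulse response (UIR)

    C(t) = D/(Vc·BW) · [(α−K21)/(α−β) e^{−αt} + (K21−β)/(α−β) e^{−βt}]

is the convolution kernel for IV input; its analytic AUC is D/(Cl·BW),
which the tests use as a closed-form oracle.  A repeated root (α = β) is
refused with a pointer to perturb K12/K21; it cannot arise from the
shipped constants.

## Oral absorption (open CAT chain)

Commercial ACAT physiology (absorption scale factors, regional pH) is
proprietary, so absorption is an open compartmental absorption-and-transit
chain: an undissolved depot releasing per a supplied cumulative release
function (bolus for IR), gastric emptying ks = 2.8 h⁻¹ (fasted),
n = 7 intestinal transit compartments at kt = 7/3.32 ≈ 2.11 h⁻¹, lumen →
enterocyte uptake ka = 2·Peff/R with R = 1.75 cm (≈ 2.55 h⁻¹ for
Peff = 6.2×10⁻⁴ cm/s), and enterocyte → portal exit kent = kent0·Fuent.
Drug reaching the end of the chain is lost to the colon; a bioavailability
fraction F (default 1) splits the enterocyte exit.

The enterocyte step encodes the drug's lysosomotropic behaviour: with
Fuent = 2% and kent0 = 35 h⁻¹ (calibrated so the simulated IR Tmax falls
in the observed 2–4 h window at 100 mg), systemic appearance is delayed
without changing extent.  The closed-form pH-partition ratio
(1 + 10^{pKa−pH_lyso})/(1 + 10^{pKa−pH_cyto}) stands in for a kinetic
cell-compartment simulation; it is an equilibrium statement only.

Solubility is not rate-limiting (BCS class I) and no saturation check is
applied by default.  The diffusion coefficient is stored in cm²/s, the
standard unit for that quantity.

Numerics: the system is linear and time-invariant, so it is propagated by
an exact matrix-exponential step (`expm` of the augmented generator) on a
uniform grid (default 0.05 h) with piecewise-constant release rates per
step.  Columns of the generator sum to zero over the state space including
sink states, so mass is conserved to machine precision and dose linearity
is exact — both are asserted in tests.  Tmax ties take the earliest grid
time.

## IVIVC

Deconvolution is posed as non-negative least squares for a
piecewise-constant input rate on the observation grid, against an exact
convolution matrix.  Two kernels are available:

* the **analytic UIR** (default): the recovered input is the cumulative
  fraction *absorbed into the central compartment*; the interval integrals
  of the biexponential are closed-form, so deconvolve/convolve are mutual
  inverses to machine precision on noise-free staircase data;
* the **oral impulse-response kernel**: the unit-dose IR simulation of the
  full CAT + disposition system, integrated by cumulative trapezoid.  With
  this kernel the recovered input is the fraction *released in vivo* — the
  mechanistic route, and the one the pipeline uses.  The distinction
  matters: against the plain UIR, in vivo release is confounded with the
  absorption-chain lag (~1.5 h here), which systematically penalises the
  dissolution condition that actually matches the in vivo release.

An optional Tikhonov ridge stabilises deconvolution of noisy curves
(default 0; the shipped workflow deconvolves a noise-free stand-in).

The Level-A correlation is a straight line Fabs = a·Fdiss + c at matched
times, with an optional single time-scale factor (t_vivo = m·t_vitro)
profiled out by bounded scalar search; the model form is a deliberate
minimal choice, selection between scaled/unscaled being left to r².
Predictions clip the correlated input to [0, 1] and enforce monotonicity
before convolution.  Prediction error uses the convention
PE% = 100·(observed − predicted)/observed, rounded half-up to two decimals
for reporting; biopredictiveness requires |PE| ≤ 10 for both Cmax and
AUC(0-t), inclusive at the boundary.  Method ranking orders conditions by
worst-case |PE| across products, ties broken lexically by (apparatus,
speed).

## Virtual bioequivalence

Subjects are drawn log-normally (mean-corrected, so the expectation equals
the population value) around Cl and Vss (between-subject CV 25% each) and
an absorption time-scale (CV 15%).  Each subject receives test and
reference with identical parameters (crossover); an independent mean-1
log-normal residual (within-subject CV 18%) multiplies each
administration's Cmax and AUC.  The within-subject default was chosen — a
realistic intra-subject Cmax CV for an oral product — so that a test
product whose release-rate differs from the reference by the magnitude the
fastest generic shows lands near the 0.80–1.25 boundary and fails a
realistic fraction of trials, while self-equivalence still passes > 90% of
trials; with a 10% residual every product passes every trial and the
design loses all discrimination.  Period and sequence effects are not
generated and therefore not modelled; the 90% CI is a paired t-interval on
log metrics, equivalent to TOST at the 5% level, and the pass boundary is
inclusive.  The master seed spawns per-trial child seeds
(`numpy.random.SeedSequence`), all recorded, so any trial is re-runnable.

## Synthetic study fixture

No raw dissolution or plasma data are deposited, so the fixture generates
stand-ins with the *established effect structure* rather than fitted
curves:

* products carry the published mean dimensions and SDs; release speeds up
  with SA/V through td_eff = td / (hydro · (SA/V ÷ 8.479)^s) with
  sensitivity s = 2 (a higher-SA/V tablet of the same formulation
  dissolves proportionally faster; s = 2 makes the fastest product ~24%
  faster than the reference, the magnitude needed for the VBE gradient);
* the apparatus hydrodynamic multipliers are 0.8 (basket, low
  hydrodynamics), 0.75 (paddle without sinker, tablet adhesion) and 1.0
  (paddle with sinker).  These are calibration constants: they must be
  strong enough that the screening ANOVA flags the apparatus and the
  convolution separates conditions, yet weak enough that the
  product × apparatus interaction (which an L9 aliases onto the medium and
  speed columns) stays below the replicate noise — multipliers of 0.6/0.5
  make the null speed factor spuriously significant at the early time
  point in almost every realisation;
* medium and rotation speed are generated as exact nulls, encoding the
  screening conclusion;
* replicate noise is tablet-dominated: a per-unit log-normal multiplier
  (CV 3%), a per-unit additive offset (SD 1.5% of label) and per-point
  jitter (SD 0.3%), all scaled to one CV knob (zero CV gives identical
  units); within-unit monotonicity is restored by cumulative maximum.
  The additive component reflects that assay error does not vanish at low
  % dissolved;
* the reference release (fmax 95%, td 7.1 h, b 0.9) places the reference
  profile inside the proposed specification windows; the "observed"
  plasma curve is the forward CAT simulation of that release (a stand-in
  for an unpublished volunteer study), with optional residual noise;
* an external-validation product ("Generic #3") has dimensions close to
  the reference and is excluded from the DoE.

What passing tests on this fixture show: that the *workflow* — screening,
mechanistic deconvolution, PE classification, VBE discrimination,
specification setting — behaves correctly and reproduces the qualitative
findings (SA/V ordering, apparatus/product significance, paddle+sinker
selection, the pass-count gradient).  What they do not show: agreement
with any real product's measured profiles or trial counts, which depend on
data and population settings that are not public.  Reported trial counts
(7/10, 9/10, 10/10) are therefore treated as an ordering property, never
as numeric targets.

## Problem sizes and determinism

The default study uses 6 units × 9 runs for the DoE, 25 subjects × 10
trials per VBE, a 0.05 h ODE grid, 0.25 h deconvolution grid and 0.5 h
VBE convolution grid — sizes chosen so a full pipeline run completes in a
few seconds while grid-halving changes headline metrics by ≪ 1%.
Statistical properties in the test suite use 200–1000 replications.  Every
stochastic step is driven by a named seed derived from the config's master
seed, and a fixed config reproduces the report byte for byte.

## Known limitations

* The CAT chain is a deliberate simplification of regional gut physiology:
  no pH-dependent solubility/permeability profile, bile salts, or food
  effects; predicted absolute Cmax/AUC are anchors, not validated values.
* Level-A IVIVC assumes a time-invariant linear release→absorption map;
  site-dependent absorption would break it.
* The VBE population varies three parameters only; correlations between
  parameters and demographic covariates are not modelled.
* Specification derivation is min/max-with-margin, not a safe-space
  analysis linking windows to predicted exposure bounds.
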