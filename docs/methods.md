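# Methods

`glycobind` analyzes the binding kinetics and affinity of galectin-3
(Gal-3) interacting with multivalent neo-glycoproteins — bovine serum
albumin carrying m copies of a synthetic poly-LacNAc-type glycan — from
three kinds of data: surface plasmon resonance (SPR) sensorgrams, ELISA
dose-response curves, and mean molecular-dynamics interaction energies.
This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic-data generator does and does
not emulate.

## Kinetic models and forward simulation

An SPR sensorgram R(t) (response units, RU, proportional to bound mass)
is driven by an analyte injection at concentration C (association phase,
duration `t_assoc`) followed by a buffer wash (dissociation, `t_dissoc`).
Units are fixed package-wide: time s, concentration M, response RU,
ka M⁻¹s⁻¹, kd s⁻¹.

**1:1 Langmuir** (A + L ⇌ AL): during association

    R(t) = Req (1 − e^−(ka C + kd) t),   Req = ka C Rmax / (ka C + kd),

and R(t) = R(t_assoc) e^−kd (t − t_assoc) afterwards. KD = kd/ka.

**Heterogeneous ligand**: two independent immobilized site classes; the
response is the sum of two 1:1 terms with (ka1, kd1, Rmax1) and
(ka2, kd2, Rmax2).

**Bivalent analyte**: sequential two-point attachment with shared
capacity Rmax, integrated numerically with the conventional statistical
factors (two equivalent ways to make the first contact, two bonds to
break in the final detachment):

    dR1/dt = 2 ka1 C (Rmax − R1 − R2) − kd1 R1 − ka2 R1 (Rmax − R1 − R2) + 2 kd2 R2
    dR2/dt = ka2 R1 (Rmax − R1 − R2) − 2 kd2 R2,     R = R1 + R2,

where ka2 is in RU⁻¹s⁻¹ (second attachment happens on the surface).
With ka2 = 0 this reduces to a 1:1 model with association rate 2·ka1;
the factor is part of the convention, not a bug.

**Heterogeneous analyte**: two analyte species at C_A, C_B competing for
one capacity, dRi/dt = kai Ci (Rmax − R1 − R2) − kdi Ri.

The two closed-form kinds are evaluated analytically (with `expm1` for
small exponents); the two others are integrated with SciPy's LSODA at
rtol 1e-8 / atol 1e-10, split exactly at the phase boundary. LSODA's
automatic stiffness switching is required because the fitter explores
rate corners (ka ~ 1e9 M⁻¹s⁻¹) where explicit Runge–Kutta steps collapse.
Closed forms agree with independent adaptive integration to better than
1e-6 of the trace scale over the tested parameter sweep
(ka ∈ [1e4, 1e7], kd ∈ [1e-5, 1e-2], C ∈ [1e-11, 1e-6]).

Default schedule: `t_assoc` = 120 s, `t_dissoc` = 600 s, `dt` = 0.5 s.
The long dissociation window is what makes kd ≈ 1e-4 s⁻¹ (a 5% decay
over 600 s) identifiable at all.

## Referencing

Double referencing subtracts, in one pass, the interspot trace (sensor
regions exposed to analyte flow but carrying no ligand: drift and bulk
refractive-index offsets) and a blank zero-concentration injection:
corrected = raw − interspot − blank. The blank is assumed already
interspot-corrected, so each systematic term is removed exactly once.
Grids must match exactly; no resampling is attempted, because
interpolation would smooth kinetic information silently. Baseline zeroing
subtracts the mean over a pre-injection window (samples at negative
times) and requires at least two samples there.

## Global fitting

All curves of a titration share one surface, so rate constants and
capacities are fitted globally across concentrations by trust-region
least squares on the pooled residuals. Choices that matter:

- **Parameterization**: log10(ka), log10(kd) with linear capacities
  (rates span decades; log space stabilizes the Jacobian). Optional
  per-curve additive offsets.
- **Bounds**: ka ∈ [1e2, 1e9] M⁻¹s⁻¹, kd ∈ [1e-6, 1] s⁻¹, Rmax ∈
  (0, 10 × max |R|] — the physically plausible biosensor range containing
  every regime used here; bivalent ka2 ∈ [1e-8, 1e2] RU⁻¹s⁻¹.
- **Multistart**: `n_starts` Latin-hypercube draws over the bounds
  (seeded, default 8) plus one heuristic start: kd from the log-linear
  slope of the highest-concentration dissociation tail, then a coarse
  log-spaced ka line search in which the capacity is solved linearly
  (the 1:1 trace is linear in Rmax at fixed rates).
- **Errors**: standard errors from the Jacobian-based covariance at the
  optimum with σ² = RSS/dof, transformed from log to natural scale. A
  singular covariance yields NaN errors; the fit is still returned.
  KD = kd/ka is always recomputed from the estimates, with the
  first-order ratio propagation se_KD = KD √((se_ka/ka)² + (se_kd/kd)²).
- **Weighting**: unweighted least squares; SPR noise is
  response-independent to first order.
- **Model selection**: candidates are ranked by AICc on the pooled
  residuals (k = free parameters + 1 for the noise variance); ties within
  ΔAICc < 2 resolve to the fewer-parameter model. Candidates are fitted
  in order of increasing complexity and each two-site candidate receives
  an extra start at the nested simpler optimum with the second capacity
  zeroed, which guarantees the nested model never outscores its superset
  on RSS. AICc is a quantitative stand-in for the qualitative
  "reasonable fit" judgment used when such data are evaluated by eye.

Two-site fits are label-symmetric; consumers should order sites by KD
before comparing to ground truth.

## ELISA

Direct (saturation) design: S(c) = background + Smax·c/(Kd + c), one-site
specific binding — appropriate for a single-CRD lectin titrated over an
immobilized excess of multivalent ligand, and it preserves the
half-saturation meaning of an apparent Kd. A warning is attached when the
fitted Kd falls more than 100-fold outside the sampled range.

Competitive design: four-parameter logistic
S(i) = bottom + (top − bottom)/(1 + (i/IC50)^hill) with the Hill slope
free within [0.3, 5]: multivalent inhibitors plausibly give hill ≠ 1 and
fixing it would be an unverifiable assumption. IC50 is reported in the
unit of the input concentrations.

Multivalency is quantified as relative potency
rp = IC50(monovalent glycan)/IC50(neo-glycoprotein), both converted to
nM before the ratio, and rp/m (potency per presented glycan); rp/m > 1
is the operational signature of a cluster glycoside effect.

## Linear interaction energy

ΔG_bind = α·Δ⟨V_LJ⟩ + β·Δ⟨V_el⟩ between bound and free ligand states,
with defaults α = 0.181 and β = 0.3. When energy trajectories are given
instead of averages, the mean is taken over the final 10 ns window
(configurable), where the complex is assumed equilibrated. The module is
deliberately arithmetic-only: running or parsing the underlying
simulations is out of scope.

## Synthetic data: what it emulates and what it does not

The generator emulates a parallel-injection titration: per concentration,
model trace + linear drift·t + square bulk pulse during the injection +
i.i.d. Gaussian noise; an interspot channel with the same systematics and
independent noise but no binding; and one blank injection under the same
noise law, provided interspot-corrected. Defaults: noise sd 0.5 RU (SPR)
and 0.02 absorbance units (ELISA) — no noise figures are reported for
the original instruments, so these were chosen once to make recovery
nontrivial but stable; drift and bulk default to 0 and are enabled
explicitly where referencing is exercised. Concentration ladders default
to five two-fold dilutions from 250 pM (sub-nanomolar regime of the
immobilized-lectin orientation) or from 250 nM (the 16–250 nM range of
the reversed orientation and the ASF standard). A fixed seed makes every
generated dataset byte-identical.

Not emulated: mass-transport limitation, regeneration-cycle carryover,
spikes/air bubbles, non-Gaussian or response-dependent noise,
plate-layout effects, and instrument-vendor binary formats. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every instrument
artifact.

## Scope of the reported rate constants

The experimentally fitted rate constants of the original ligand series
come from instrument sensorgrams that were never deposited; without that
instrument data they cannot be recomputed here. They enter this package
only as **generator parameters** (the regimes at which synthetic
titrations are produced and refitted) and as inputs to derived-quantity
checks: KD = kd/ka per compound, fold differences between compounds, and
relative potencies from the reported IC50 columns.

## Problem sizes and determinism

Stochastic checks use five-curve titrations sampled at dt = 1.5 s
(481 points per curve), 100 replicates per kinetic regime or selection
scenario and 200 per ELISA assay, with replicate seeds drawn from a
single `SeedSequence`; single-start fits (the heuristic start) are used
inside replicate loops, the full multistart elsewhere. These sizes give
stable rates while keeping the whole battery in the minutes range on one
core. Every random draw in the package flows through an explicit integer
seed.

## Known limitations

- Conformational-change (two-state) and mass-transport-limited models
  are not implemented.
- Equilibrium-only (steady-state) affinity analysis is out of scope; the
  `equilibrium_response` helper exists for closed-form kinds only.
- Fit standard errors are asymptotic (local curvature); for strongly
  correlated parameters (e.g., ka–Rmax at low saturation) they can be
  optimistic. Reported ± values are fit standard errors and labeled as
  such, regardless of how published ± values were produced.
- The bivalent-analyte second-step rate is expressed in response units,
  so its numerical value depends on the surface capacity scale.
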