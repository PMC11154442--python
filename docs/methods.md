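# Methods

## Transport model

The package describes steady-state transport of a single neutral-solute
surrogate for a protein through two layers in series.

**Polarization layer.** Rejected solute accumulates in a stagnant film of
thickness δ_pol on the retentate side. The flux balance
J = v_w·c − D_i·dc/dx (friction-free, bulk diffusivity D_i) integrates to
the closed-form film expression with Peclet number
Pe_d = v_w·δ_pol/D_i = v_w/k_dbl, where k_dbl = D_i/δ_pol is the film
mass-transfer coefficient.

**Membrane active layer.** Inside the pores the solute advects with
hindrance factor K_c and diffuses with hindered diffusivity K_d·D_m over
thickness δ_mem; the corresponding Peclet number is
Pe_m = K_c·δ_mem·v_w/(K_d·D_m) = v_w/k_m. At each pore mouth the internal
concentration jumps by the partition coefficient Φ (steric, electrostatic
and affinity exclusion lumped together).

Eliminating the internal concentrations gives the observed rejection

    R_obs = 1 − (1−σ) / [(1−σ) + e^(−Pe_d)·(1 − e^(−Pe_m))·σ],    σ = 1 − K_c·Φ

and, when pore transport is advection-dominated (Pe_m → ∞),

    R_obs = 1 − (1−σ) / [(1−σ) + e^(−Pe_d)·σ].

σ is the rejection plateau at vanishing flux (a thermodynamic quantity);
k_dbl sets how fast polarization erodes the rejection as flux rises (a
kinetic one). The model's key assumptions: steady state, a single solute,
constant bulk concentration, flux-independent k_dbl (no "suction"
correction), no cake layer or limiting-flux behaviour, and no explicit
electrostatics — charge effects enter only through the fitted or supplied
Φ/σ. Partition coefficients can be estimated sterically from radii with
the Ferry form (1 − r_s/r_p)², optionally weighted by a Boltzmann factor
exp(−E_T/kT) for a user-supplied interaction energy (Smith–Deen form);
E_T is a scalar input, not itself a function of ionic strength. Hindrance
factors K_c, K_d are direct inputs — no correlation in r_s/r_p is built
in, since the fitting workflow lumps them into σ and k_m anyway.

## Numerical oracle

`solve_profile_numeric` solves the same two-layer problem without the
closed-form algebra: it shoots on the permeate concentration c_p (uniform
flux J = v_w·c_p), integrates both layer ODEs with an adaptive Runge–Kutta
scheme (relative tolerance 1e-12), applies the partition jump at each pore
mouth, and exploits the fact that the exit mismatch is affine in c_p to
land on the root in one secant step, polishing until the closed-form layer
fluxes agree with J to relative 1e-10 (200-iteration cap, convergence
failure raises with diagnostics). Agreement of its rejection with the
closed form (relative error ≤ 1e-6 over random parameter sets with Pe in
[0.1, 5]) is the package's structural self-check; forward error grows like
e^Pe·rtol, so the oracle is exercised in the physically relevant moderate-Pe
range.

Numerical conventions in the closed forms: x increases from retentate to
permeate and fluxes toward the permeate are positive; e^(−Pe) is taken as
exactly 0 for Pe > 709 (past double underflow) so the formulas assume their
analytic limits instead of producing 0/0; the layer-flux expressions are
singular at Pe = 0 and return a flagged diffusive limit there; σ outside
[0, 1] warns by default (`strict=True` raises), because unbounded fits of
near-complete-rejection data legitimately land marginally above 1.

## Mass-transfer correlations

Five literature Sherwood power laws Sh = A·Re^m·Sc^n are provided
(Schock–Miquel, Graetz–Leveque, Harriott–Hamilton, Bandini–Morelli, Shi),
with k_dbl = Sh·D/d_h and the spacer-filled-channel hydraulic diameter
d_h = 4ε/(2/h + (1−ε)·S_v,p). Exponents are kept exactly as published —
Graetz–Leveque with 0.33 literally, Bandini–Morelli with exactly 1/3 — and
a `third_exponents` switch normalises the cube roots for users who prefer
consistency over fidelity. Published flow-regime ranges are advisory
warnings, not errors: in protein ultrafiltration (Sc > 10⁴, strong
permeation) every one of these correlations is used out of its derivation
regime, and they are known to underestimate k_dbl there. The defaults
profile (ρ = 997 kg/m³, η = 0.89 mPa·s, D = 6.0e-11 m²/s at 25 °C) is a
convenience for dilute aqueous BSA, not a measured property set; spacer
porosity and specific surface must come from the user's module.

## Estimation

Fits minimise the unweighted sum of squared rejection residuals with
`scipy.optimize.least_squares` (trust-region reflective; gradient, step and
function tolerances 1e-12, iteration cap 500 per parameter). Rate
coefficients are optimised as log k, which keeps them positive without
bounds and conditions the problem across the 1e-6 m/s scale; σ is
unbounded by default with an optional [0, 1] clamp. Initialisation is
deterministic and scale-free: σ₀ = max observed R_obs (its own low-flux
limit), k₀ = median flux (placing the corresponding Pe near 1). Duplicate
assays are fitted as individual observations, preserving residual degrees
of freedom.

Uncertainties are linearized: the residual Jacobian at the optimum is
mapped to natural units by the chain rule (∂r/∂k = (∂r/∂log k)/k), the
covariance is s²(JᵀJ)⁻¹ (pseudo-inverse for degenerate directions), and
95% intervals use t quantiles at the residual df. Coverage of the σ
interval is 90–99% under Gaussian rejection noise of sd 0.01 at n = 10
(checked by Monte Carlo in the test suite). Adjusted r² follows the
standard definition 1 − (SS_res/(n−p))/(SS_tot/(n−1)) and may be negative;
it is NaN with a warning when the data carry no variance.

Nested models are compared with F = ((SS₁−SS₂)/(df₁−df₂))/(SS₂/df₂) and the
upper-tail p of F(df₁−df₂, df₂); a richer model that fails to improve the
fit in finite precision yields F ≤ 0, reported as computed with p = 1.

**A calibration caveat.** For the regular nested pair — σ-only (k_dbl
frozen at truth) versus the two-parameter advection fit — the test's type-I
error sits at the nominal 5% (measured 4.5% over 1000 null replicates).
Comparing the advection model against the *general* model is not a regular
problem: the extra parameter enters only through e^(−Pe_m) ∈ (0, 1), whose
null value 0 is the boundary k_m → 0 of the parameter space, and its local
effect is nearly collinear with k_dbl. The classical F reference then
overstates the achievable improvement under the null and the test is
conservative (measured type-I ≈ 1–3% at α = 0.05). Practically this means
a significant p-value against the general model is trustworthy, while a
non-significant one is even weaker evidence for pore diffusion than its
face value suggests.

## Synthetic-data generator

The generator emulates a pilot-scale crossflow study: 0.5% (w/v) protein,
six solution conditions (pH 7 at 0/0.08/0.15/0.2 M NaCl; pH 4.9 at 0/0.2 M),
five transmembrane pressures (0.2, 0.5, 0.8, 1.5, 3 bar), crossflow
0.167 m/s, duplicate concentration assays per point. Flux follows a linear
clean-membrane law v_w = L_p·TMP with default permeability 5e-6 m/s/bar,
chosen to span Pe_d ≈ 0.14–2.0 at the default k_dbl — the regime where
polarization visibly bends the rejection curve; no limiting-flux plateau is
modelled, consistent with the model's no-cake-layer assumption. True
rejections come from the forward model; noise enters where measurement
error actually arises — as independent multiplicative Gaussian perturbations
(default relative sd 1%) on the retentate and permeate concentration
readings — and R_obs is recomputed from the noisy pair. To first order this
gives sd(R_obs) ≈ √2·sd·(1−R): heteroscedastic in R, like a real assay, and
exactly zero at σ = 1 where the permeate is empty. Default ground-truth
sieving coefficients (0.9993, 0.9935, 0.9686, 0.9646 at pH 7 with rising
salt; 0.9977, 0.9916 at pH 4.9) and the shared k_dbl = 7.34e-6 m/s are
representative of near-complete BSA rejection relaxing with ionic strength.
Everything is deterministic given the seed.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: retentate concentration drift over the
pressure staircase, flux decline from fouling or adsorption, the
flux-dependence of k_dbl (suction effect), protein oligomerization
responding to pH/ionic strength, and assay-specific error structure beyond
multiplicative Gaussian noise. Parameter-recovery and calibration results
are statements about the model class under its own assumptions.

## Problem sizes

The verification suite uses 100 random parameter draws for the
oracle-equivalence check, 1000 null replicates for F-test calibration,
500 replicates for CI coverage, and 10⁴ replicates for the noise-propagation
check — sizes at which the Monte-Carlo error is several times smaller than
the acceptance bands being tested.

## Known limitations

* Single-solute, neutral-surrogate model: coupled multi-ion/multi-protein
  transport, Donnan or Poisson–Boltzmann partitioning are out of scope.
* k_dbl is flux-independent; at high permeation rates the suction effect
  makes this an underestimate of the true mass transfer.
* The F test against the general model is conservative (boundary null; see
  above).
* Unweighted least squares: the generator's own noise model is
  heteroscedastic in R, so on strongly varying rejections a weighted fit
  would be more efficient; weights are deliberately not implemented.
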