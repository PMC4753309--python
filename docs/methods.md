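# Methods

This note records the models behind `ferromat`, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want to know.

## Accretion and biomass kinetics

Fe(III)-oxide accretion and total community DNA on deployed substrates
are modelled as first-order growth, x(t) = x₀·e^{kt} with t in days.
`fit_exponential` minimises Σ(xᵢ − x₀e^{ktᵢ})² with
`scipy.optimize.curve_fit`, initialised deterministically by log-linear
regression on the positive points; `se_k` comes from the Jacobian-based
covariance and `p_value_k` from a two-sided Wald t-test of k = 0 on
n − 2 residual degrees of freedom (the convention of standard
nonlinear-regression summaries).

Raw-scale least squares assumes additive, homoscedastic error. Replicate
slide extractions typically have error proportional to the signal, and
under such multiplicative (lognormal) noise the raw-scale Wald interval
undercovers badly (we measure ~77% instead of 95% on simulated series;
an HC1 sandwich interval is worse at n = 11). `fit_exponential` therefore
also offers `error_model="multiplicative"`: ordinary least squares of
ln x on t, which is the exact likelihood under constant-CV noise and
whose t-interval has nominal coverage (measured 96% over 200 simulated
seasons). The raw-scale fit remains the default; the multiplicative fit
is the recommended choice whenever scatter grows with the mean.

Censored (below-detection) points are excluded by default; a documented
option substitutes half the detection limit. Apparent lag is the time
for the fitted curve to reach a detection limit, ln(limit/x₀)/k — a
reparameterisation of the exponential, not a separate lag mechanism.
Vertical growth converts mm/month to μm/day with a 30-day month.
Endpoint comparisons use the pooled-variance two-sample t-test (Student
form), with Welch's correction behind a flag.

## O₂ reaction–diffusion slab model

The mat is a homogeneous slab of thickness L_f (cm) with effective O₂
diffusivity D_e (cm²/s), bulk interface concentration C₀ (μM), and a
no-flux bottom boundary. The dimensionless steady state depends only on
the Thiele modulus φ = √(k₁L_f²/D_e):

- first-order consumption: u(ζ) = cosh(φ(1−ζ))/cosh(φ), computed in
  log space so φ of several hundred does not overflow `cosh`;
- zero-order consumption: u(ζ) = φ²ζ²/2 − φ²ζ + 1, clipped at 0 below
  the anoxic point.

Both satisfy u(0) = 1 and zero bottom gradient. Both kinetic orders are
implemented and selectable; the cosh solution is the default for
generation and fitting because φ² = k₁L_f²/D_e is dimensionally a
first-order group (the quadratic is retained as the zero-order analogue).
φ > 1 classifies a profile as diffusion limited, φ < 1 as reaction
limited (φ is nonnegative by definition, so the threshold sits at the
point where reaction and diffusion time scales balance).

`estimate_flux` applies Fick's first law with the near-interface
gradient taken as the OLS slope through the first three grid points
(OLS rather than a two-point difference, for electrode-noise
robustness; the window is configurable). Unit bookkeeping
(μM → μmol cm⁻³, μm → cm) is centralised in `constants`. Note the
estimator's discretization bias on steep profiles: on the OSP-2013
default slab (decay length L_f/φ ≈ 217 μm) a 10-μm grid gives a
three-point OLS gradient ~4.5% below the analytic surface gradient —
the factor is (1 − e^{−2a})/(2a) with a = φ·Δz/L_f. The flux test
therefore checks convergence to the closed form
C₀√(D_e·k₁)·tanh(φ) as the grid is refined (<1% at 2-μm spacing).

Only φ is identifiable from a normalised profile shape, so
`fit_profile` takes L_f and D_e as explicit inputs, fits log φ by
Levenberg–Marquardt (positivity for free; started at φ = 1), and
back-computes k₁ = φ²D_e/L_f². Flat profiles short-circuit to φ = 0.
Penetration depth is the linearly interpolated first crossing of the
0.3 μM detection limit, absent if never crossed.

The per-site slab defaults are solved, not asserted: given D_e
(4.5×10⁻⁵ cm²/s, a configurable effective diffusivity for O₂ in a
porous mat at 70–75 °C) and the site's bulk O₂, the pair (k₁, L_f) is
obtained by inverting the closed-form surface flux
J = D_e·C₀·φ·tanh(φ)/L_f and φ² = k₁L_f²/D_e against the site's
measured flux and Thiele modulus (OSP: J = 1.14×10⁻⁴ μmol cm⁻² s⁻¹,
φ = 28 → L_f = 0.608 cm, k₁ = 0.0955 s⁻¹). These defaults honour the
flux and φ constraints; they do not also reproduce the measured ~950 μm
penetration depth (the default profile goes anoxic at ~1130 μm), which
would require the unpublished raw profiles to pin down jointly.

## Colonization rates

A sterile slide has zero cells at deployment, so areal density vs time
is regressed through the origin: rate = Σtᵢd̄ᵢ/Σtᵢ², with d̄ᵢ the mean
density over fields at time tᵢ. The reported spread is the sample SD of
per-field slopes dᵢ/tᵢ, reflecting between-field heterogeneity rather
than a formal slope standard error. With one time point the estimator
reduces to density/time. Morphotype labels are free strings; the
rod↔*Hydrogenobaculum* and coccus↔archaea identifications established
microscopically are metadata, not enforced.

## Community succession

Counts are divided by per-taxon 16S rRNA gene copy numbers (default 1;
*Hydrogenobaculum* carries two) before per-sample normalisation.
Bray-Curtis dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed on proportions
(post correction) to match relative-abundance figures; clustering is
agglomerative with complete linkage by default (average available),
labels sorted first so tie-breaking is deterministic. Dendrograms
serialise to Newick with branch lengths equal to merge-height
differences; merge heights are monotone for both linkages
(ultrametric trees).

Decline rates are OLS slopes of percentage vs day, sign-flipped so
decline is positive; extrapolation is linear and floored at 0%. The
window over which a decline is averaged is the caller's choice.

Primer-bias diagnostics divide amplicon proportions by
random-metagenome reference proportions per shared sample and taxon.
Taxa missing from one table are flagged `absent` rather than given a
0 or ∞ ratio — amplicon dropout (e.g. a single 515F primer mismatch in
Crenarchaeota) is evidence of bias, not of absence.

The four-stage classifier is a rule cascade over a mat snapshot:
stage IV at depth ≥ 5 mm (mature mats are 0.5–2 cm); stage III at
depth ≥ 2 mm or heterotroph fraction ≥ 0.25 (heterotrophs establish and
O₂ gradients appear at 2–4 mm); stage II once Fe(III)-oxide is visible
(7–30 days); else stage I. Thresholds are anchored to qualitative field
ranges and exposed in `StageThresholds`; monotonicity in depth holds by
construction.

## Geochemistry

Areal loading = concentration × extraction volume / molar mass / slide
area (mg L⁻¹ → μmol cm⁻²); molar ratios cancel volume and area and are
reported both per time point and as mean ± se across time points, since
a ratio series can legitimately be read either way. Molar masses are
packaged constants (Fe 55.845, As 74.922, P 30.974, W 183.84 g/mol …),
overridable. The Reynolds helper Re = vL/ν takes the characteristic
length and kinematic viscosity explicitly.

## Synthetic data

The generators emulate the five input types with per-site defaults
equal to the study values: Fe rate constants 0.05/0.047 day⁻¹ (OSP/
Beowulf), DNA 0.028/0.043 day⁻¹, rod colonization 3.7×10⁶/6.8×10⁶ and
coccus 9.2×10⁵/8.6×10⁵ cells cm⁻² day⁻¹, bulk O₂ 55/44 μM, As:Fe
0.5/0.67, P:Fe 0.01, W:Fe 0.002. Values the study does not state were
fixed once as field-plausible: Fe x₀ = 0.5/0.3 μmol cm⁻² (chosen so the
day-70 instantaneous rate is ~0.9 μmol cm⁻² day⁻¹), DNA x₀ = 2/1
ng cm⁻², detection limit 0.05 μmol cm⁻², SEM field area 10⁻⁴ cm²
(integer expected counts at integer days, keeping noiseless round-trips
exact), extraction volume 0.05 L over 18.75 cm² of slide (half of one
2.5 × 7.5 cm face), lognormal CV 0.2 for accretion/DNA, gaussian
electrode noise sd = 0.02·C₀, Dirichlet concentration 200, and a
community trajectory in which the rod lithoautotroph starts at 0.85 on
day 4 and declines 1%/day (floor 0.01), the Fe(II)-oxidizer holds 0.15,
and ≥4 heterotroph taxa share the remainder with relative weights
rising logistically around day 45 (site-specific weights follow the
mature-mat surveys). Compositions sum to 1 exactly; noise draws are
bit-reproducible given a seed; no global random state is used.

What the generators do **not** emulate: replicate structure and serial
correlation of real field seasons (each point is independent),
depth-limitation of late growth (pure exponentials), electrode response
smearing, compositional zero-inflation from sequencing depth, or any
2-D/3-D mat geometry (microterracettes). Passing round-trip tests
therefore demonstrates estimator correctness under the assumed error
models, not robustness to everything real slides do.

## Problem sizes

Default analyses use 11-point series over 0–70 days, ~600-point
profiles at 10-μm spacing, 4 fields × 4 time points of counts, 7-sample
community tables and 9-point extraction series; stochastic checks use
200 seeds (CI coverage) and 100 seeds (Poisson rate recovery). All
sizes are configurable.
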