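# Methods

## Scope and data

The package post-processes pulsatile vascular flow simulations; it does
not solve the Navier–Stokes equations. Its empirical substrate is a
packaged set of result tables from a factorial study of seven
patient-specific abdominal aortic aneurysms, each simulated under five
blood rheologies (Casson `Cs`, Carreau–Yasuda `CY`, Herschel–Bulkley
`HB`, Newtonian `N`, Power law `P`) and three inlet velocity profiles
(Parabolic, Plug, Womersley), giving a balanced 5 × 3 design with n = 7
geometries per cell and fourteen response variables. Table values are
stored exactly as printed (same decimal places) because they are the
reproduction substrate; all statistics recomputed here therefore inherit
the printed rounding, which the test tolerances absorb.

Everything upstream of those tables (segmentation, meshing, the finite
volume solver) is out of scope. Synthetic generators with analytic ground
truth replace the solver wherever per-element or per-cell fields are
needed.

## Physical constants

Blood density ρ = 1050 kg/m³ and the Newtonian reference viscosity
μ = 0.00345 Pa·s. The density is not printed in the study tables; it is
the value for which `α = R√(ωρ/μ)` reproduces all seven tabulated
Womersley numbers to two decimals (the other common literature value,
1060 kg/m³, does not). The cycle-mean inlet speed Ū = 0.0647 m/s is
back-computed from the tabulated mean Reynolds numbers `Re = 2ρŪR/μ`; the
peak/mean ratio 4.483 is the tabulated peak/mean Reynolds ratio. The
cardiac period is 1 s, sampled at 200 uniform steps (0.005 s).

## Cardiac waveform generator

The per-cycle mean-velocity curve of the study is only published as a
figure, so the generator uses a deterministic raised-cosine-power pulse
`b(t) = cos²ᵐ(π(t − t_p)/T)` — a trigonometric polynomial with m
harmonics (default m = 8, peak at 0.15 T) whose cycle average
`C(2m, m)/4ᵐ` is known in closed form. Rescaling `u = Ū(1 + A(b − b̄))`
fixes the mean and the peak exactly; on any grid with more than 2m
samples the discrete mean is exact because trigonometric polynomials
integrate exactly under the rectangle rule. The peak/mean ratio is
capped at `4ᵐ/C(2m, m)` (≈ 5.09 for m = 8) so the flow never reverses;
requesting more is a parameter error rather than a silent negative-flow
waveform. The generator reproduces the study's operating point (mean
0.0647 m/s, peak ratio 4.483) but not secondary features of a measured
waveform (dicrotic notch, early-diastolic reversal), so tests passing on
it certify the numerics, not physiological fidelity.

## Womersley profile construction

Fourier coefficients come from the FFT of the uniformly sampled waveform
(`u(t) = c₀ + Σₙ Re[cₙ e^{inωt}]`, 14 modes by default). Mode 0 is steady
Poiseuille flow carrying c₀. For mode n the annular shape is

    (1 − J₀(Λₙ r/R)/J₀(Λₙ)) / (1 − 2 J₁(Λₙ)/(Λₙ J₀(Λₙ))),
    Λₙ = α √n i³ᐟ²,

whose disc average is exactly 1; scaling it by cₙ makes the profile's
cross-sectional mean reproduce the waveform mode by mode. This
flow-rate-based calibration replaces the unpublished per-mode pressure
gradient — it is the only closed constraint consistent with all three
profiles sharing equal mean values. √n is applied symmetrically in both
Bessel arguments (the standard form). The Womersley number is always
evaluated with the Newtonian reference viscosity, matching the study's
case table, regardless of which rheology a simulation used. Non-finite
Bessel ratios (extreme α) raise a numeric error rather than propagate.
With the default band-limited waveform the 14-mode reconstruction is
exact and the disc-averaged profile tracks the waveform to < 0.01% of
peak, well inside the 0.5% contract asserted in the tests.

## Rheology

Parameters are the study's table values. The Carreau–Yasuda exponent is
implemented as `(n − 1)/a` so viscosity falls from μ₀ to μ∞
(shear-thinning); the source prints `(1 − n)/a`, which would make the
model shear-thickening and contradict both its own parameters and the
cited behaviour. Casson is the standard apparent-viscosity form
`μ = (√k + √(τ₀/γ̇))²`. Casson, Herschel–Bulkley and Power-law diverge as
γ̇ → 0 and are capped at a configurable μ_max (default 10 Pa·s), the
usual solver-style regularization; the cap never binds for
Carreau–Yasuda or Newtonian. The claim that all models converge to the
Newtonian case above 100 s⁻¹ is treated as qualitative: with these
parameters Cs and CY are still a few percent above μ∞ at 100 s⁻¹
(within 1% by 10⁵ s⁻¹, which is what the tests assert) and HB/P fall
below it.

## WSS indices

Time integrals use the periodic rectangle rule on the uniform grid
(equivalent to the periodic trapezoid rule there). OSI is clipped to
[0, 0.5]; an identically zero magnitude integral yields NaN
("undefined"), not 0.5. RRT uses the proportionality constant 1, which
matches the magnitudes of the packaged summary tables; OSI = 0.5 yields
+inf, which counts as "above threshold" in the thrombus-prone
percentage but is excluded from averages and maxima. Summary averages
are area-weighted by default — the source does not say — with an
unweighted mode behind a flag for sensitivity checks. Threshold
percentages use strict inequalities.

## Plane flow metrics

The "top 15% peak-systolic velocity" band is read as
speed ≥ 85% of the plane maximum (threshold-on-magnitude): this makes
dispersion a meaningful breadth measure (uniform flow ⇒ 100%). The
alternative reading — top 15% of plane area ranked by speed — is
available as `band_mode="quantile"`. The band centroid is area-weighted;
velocity-weighting is available via flag. Both metrics are invariant
under rigid motions of the plane and uniform speed rescaling, which the
tests verify. Synthetic planes are square-grid tessellations of a disc;
their recorded ground truth (jet offset, Gaussian band area) is the
continuum value, so tessellated results match it only to grid
resolution (≲ 1% at the default 101 cells across).

## Grid convergence

Relative errors are fine-grid-referenced, `e_ij = 100|f_i − f_j|/f_i`,
which reproduces the magnitude scale of the published verification
table. With the order p estimated from the same triplet, the diagnostic
`GCI₂₃/(rᵖ GCI₁₂)` reduces algebraically to `f₁/f₂` — its deviation
from 1 measures the relative fine–medium solution change and tends to 0
in the asymptotic range. All three published diagnostic ratios
(1.0010, 1.0019, 1.0101) are reproduced to four decimals. The published
p for the residence-time row is recovered within 0.005 from the printed
4-decimal solutions; the other two rows' printed orders are not
recoverable from their own printed values (they were evidently computed
at full precision) and are documented as rounding-limited rather than
"corrected".

## Robust factorial statistics

Cell locations are 20% trimmed means (`g = ⌊0.2 n⌋` dropped per tail);
the trim proportion is the robust-ANOVA literature's default and is the
value that reproduces the study's post hoc estimates exactly. Squared
standard errors are `(n − 1)s²_w/(h(h − 1))` with winsorized variance
`s²_w` and effective size `h = n − 2g`. Main effects and interaction are
Johansen-type quadratic-form tests on Kronecker-structured contrast
matrices, with the small-sample-corrected chi-square critical value.
p-values are located by scanning the significance level over the grid
1/1000 … 999/1000 until the statistic crosses the corrected critical
value — the convention of the WRS family of robust procedures — so
reported p-values live in [0.001, 0.999], and the 0.999 entries in the
reproduced matrix are genuine scan caps, not display artifacts. With
trim = 0 the machinery reduces to the classical Welch/Johansen
heteroscedastic ANOVA on means (cross-checked in the tests). Degenerate
all-constant designs return a zero statistic (pseudo-inverse) and the
cap p-value.

Post hoc contrasts are Yuen-type: each factor level's location is the
pooled 20% trimmed mean of all observations at that level (n = 35 for
inlet levels, n = 21 for rheology levels), compared pairwise in
alphabetical order (first minus second) with Welch–Satterthwaite degrees
of freedom. Pooling reproduces the published estimates exactly; the
alternative convention (average of per-cell trimmed means) does not and
is kept behind `pooled=False`. Families are adjusted with the Hochberg
step-up method (via statsmodels); confidence intervals are widened to
the per-comparison level `α/rank` implied by each comparison's Hochberg
rank when ranked by decreasing raw p. The exact critical-value
construction behind the published intervals is not recoverable from the
text, so interval endpoints are best-effort while point estimates and
adjusted p-values are the reproduction surface. The repeated use of the
same seven geometries across cells is ignored, exactly as in the
source's between-subjects analysis. Evidence labels follow the
p < 0.005 (strong) / 0.005–0.05 (weak) convention.

The synthetic factorial generator draws
`y = μ + aᵢ + bⱼ + (ab)ᵢⱼ + ε` with per-cell Gaussian noise scales and
optional gross-error contamination (noise inflated by a multiplier with
a given probability). It emulates the balanced design and
heteroscedastic, outlier-prone errors of the study but not the
between-geometry correlation structure of real AAA responses.

## Problem sizes and calibration

The null-calibration experiment uses 500 replicates of the study's own
design (5 × 3 cells, n = 7, standard normal errors) and checks the 5%
rejection rate of all three tests within three binomial standard errors
(±0.029). A 2000-replicate pilot gave rates between 0.038 and 0.062, so
the procedure is near-nominal at this cell size — slightly conservative
for the inlet main effect, slightly liberal for the interaction, as
expected for trimmed tests at n = 7. The OSI range property is checked
over 1000 random synthetic fields; index-refinement checks compare 200-
vs 400-step time grids.

## Known limitations

- Fixture-driven statistics inherit the printed rounding of the source
  tables; agreement tolerances (±0.002 on p-values, ±0.005 on
  percentage contrasts) reflect that, not algorithmic uncertainty.
- The waveform, WSS and plane generators are band-limited analytic
  constructions; they exercise the estimators' correctness, not their
  behaviour on noisy solver output.
- Confidence-interval endpoints for post hoc contrasts follow a
  documented but non-unique multiplicity convention (see above).
- No patient geometry handling: profiles are defined on circular
  inlets, planes are supplied (or generated) as cell tables.
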