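# Methods

## Problem and models

The package estimates microvascular leakage parameters of the abdominal
aortic aneurysm (AAA) vessel wall from dynamic contrast-enhanced MRI. A
dynamic spoiled-gradient-echo series S(x, t) is converted to gadolinium
concentration C_t(x, t), which is then described by one of three
tracer-kinetic solutions of the two-compartment exchange problem between
blood plasma and the extravascular extracellular space (EES):

* **Patlak** — C_t = K^trans ∫₀ᵗ C_p dτ + v_p C_p. Assumes negligible
  backflux from the EES over the scan duration; linear in (K^trans, v_p).
* **Tofts** — C_t = K^trans (C_p ∗ e^(−k_ep t)), k_ep = K^trans/v_e.
  Assumes negligible intravascular contribution.
* **Extended Tofts** — Tofts plus v_p C_p.

K^trans (min⁻¹) lumps flow, permeability and surface area; v_p and v_e are
volume fractions. At vessel-wall kinetics (K^trans ≲ 0.2 min⁻¹, an ~8 min
acquisition, no visible contrast reflux) the backflux term is barely
identifiable, which is why the model comparison itself — fit error,
parameter uncertainty, repeatability — is the scientific question the
pipeline answers.

## Signal model

Steady-state SPGR (Ernst) equation with both relaxivities:

S = scale · sin α (1 − E1)/(1 − cos α E1) · e^(−TE·R2),
E1 = e^(−TR·R1), R1 = 1/T1₀ + r1 C, R2 = 1/T2₀ + r2 C.

Defaults: TR/TE = 13/1.5 ms, α = 35°, fixed pre-contrast T1₀/T2₀ =
900/30 ms (the T2 vs T2* distinction is collapsed into the 30 ms
constant), r1 = 5.2 and r2 = 6.1 L·mmol⁻¹·s⁻¹ (gadobutrol at 1.5 T,
literature values — the defaults are config-overridable). The TE·R2 decay
factor can be disabled (`include_t2=False`); it is on by default.

Conversion to concentration fixes `scale` from the mean of the
pre-injection baseline samples (C = 0 assumed there) and inverts each
sample by bracketed Brent root-finding over C ∈ [−0.5, C_max] mM. Negative
concentrations from noise are kept so residuals stay unbiased. C_max is
the location of the signal maximum (≈16 mM with the defaults): beyond it
the T2 loss overtakes the T1 shortening and the equation stops being
injective, so saturated samples are clamped there and flagged rather than
silently mis-inverted. Inversion is exact to the Brent tolerance
(|ΔC| ≤ 1e−14), giving ≤1e−8 mM roundtrip error over the working range.

## Arterial input function

Parker functional form: two Gaussians (A_n mM·min, T_n, σ_n min) plus a
sigmoid-gated exponential washout (α mM, β min⁻¹, steepness s min⁻¹,
centre τ min), all shifted by an onset time t0 and zero before it. The
shipped population parameter set (A₁ = 0.40, T₁ = 0.8, σ₁ = 0.55,
A₂ = 0.30, T₂ = 1.8, σ₂ = 0.85, α = 0.90, β = 0.16, s = 3.5, τ = 0.65)
is tuned to a slow 0.5 mL/s venous injection — broad Gaussians (σ ≥ 0.5
min), peak ≈1 mM, weak first-pass peak. It is a documented stand-in, not a
measured population value, and is fully overridable.

`fit_aif` builds a generalized AIF from high-temporal-resolution lumen
curves: each curve is fitted individually (trust-region least squares,
t0 held fixed — the onset is a designed discontinuity with no usable
gradient), non-convergent curves are excluded with a warning, and the
Parker form is re-fitted to the pointwise mean of the fitted curves on a
1 s grid. Curve-averaging was chosen over parameter-averaging because the
mean of Parker curves is itself near-Parker while parameter means are not
guaranteed to be. No hematocrit correction is applied by default;
C_p = C_b/(1−Hct) is available behind a flag-style option upstream of the
fit by scaling curves.

## Numerics of the forward models

Time is seconds at the I/O boundary and minutes inside the kinetics (one
conversion constant). The AIF is evaluated analytically on a uniform
internal grid (default 0.5 s). The Patlak integral is the cumulative
trapezoid on that grid; the Tofts convolution uses the exact closed form
for a piecewise-linear C_p against the exponential kernel, advanced as a
first-order IIR recursion (`scipy.signal.lfilter`), with series expansions
of the interval weights for k_ep·Δ < 1e−4. Model values at acquisition
times are linear interpolations of the grid solution.

A Parker AIF jumps from 0 to a finite value at t0, which a
piecewise-linear representation cannot express; the input is therefore
decomposed as C_p = (continuous part) + jump·H(t−t0) and the step's
convolution with both kernels is added in closed form. With this the
forward models agree with 100×-oversampled brute-force quadrature to
better than 0.01% over the vessel-wall parameter range (the test suite
asserts 0.1%).

Jacobians are analytic. For the Tofts branch the k_ep sensitivity needs
the companion convolution with kernel u·e^(−k_ep u) (= −∂I/∂k_ep),
computed by the same recursion; the parameterization is (K^trans, v_e), as
those are the reported quantities.

## Fitting

`PkCurveFit` is a scikit-learn style estimator (fit/predict,
get_params/set_params, trailing-underscore fitted attributes). Patlak is
solved by linear least squares (projected onto the box if a bound is
violated). Tofts and Extended Tofts use bounded trust-region least squares
with analytic Jacobians — damped Gauss–Newton; a pure projected
Gauss–Newton loop is available (`optimizer="gauss_newton"`) and agrees
with the default on well-posed problems. Box constraints:
K^trans ∈ [0, 5] min⁻¹, v_p ∈ [0, 1], v_e ∈ [1e−3, 1] (the lower v_e bound
keeps k_ep finite). Deterministic initialization (K^trans = 0.01, v_p =
0.01, v_e = 0.2); an optional deterministic multi-start jitters the start
geometrically. Convergence: relative step tolerance 1e−8, at most 200
iterations/evaluations. An all-zero curve short-circuits to K^trans = 0
(and v_p = 0) with fit error 0 by convention.

Relative fit error: 100·RMS(C_t − C_tfit)/max|C_t|. Peak normalization is
the default and is recorded with the result; mean-|C_t| normalization is
available because the in-vivo convention cannot be pinned down. Parameter
uncertainty: Cov = s²(JᵀJ)⁻¹ with s² = SSR/(n−p) (unscaled covariance
optional), u_i = 100·√Cov_ii/|θ̂_i|; parameters below 1e−12 in magnitude
report u = ∞ rather than raising. Monte-Carlo simulations in the test
suite confirm the covariance-based K^trans uncertainty tracks the
replicate scatter within 20% under Gaussian noise.

Voxel-wise fitting converts and fits every wall voxel independently and
averages parameters over converged voxels (maps carry NaN elsewhere);
ROI-based fitting averages the voxel concentrations per time point first
and fits once. For Patlak the two commute exactly (linearity); for the
Tofts branch they differ, which the suite asserts on a two-region phantom.
Scans with more than 20% non-converged wall voxels are flagged poor
quality — an automatic proxy for the manual image-quality exclusions done
in practice.

## Synthetic data

The generator emulates a cardiac-gated 1.5 T vessel-wall protocol: 25
dynamics at a nominal 18 s interval with optional Gaussian interval jitter
(gating), contrast injected at the start of dynamic 6, annular wall
phantom (default ring radii 6–9 voxels on a 32×32 grid) with lumen voxels
carrying the blood curve, wall voxels the tissue kinetics, and everything
else a constant baseline (1000 a.u. — only ratios enter the conversion).
Default true parameters sit in the vessel-wall regime (K^trans = 0.043
min⁻¹, v_p = 0.01, v_e = 0.2; fixture grids span K^trans 0.01–0.10, v_p
0.005–0.05, v_e 0.1–0.4).

Noise is additive Gaussian on the magnitude signal — at wall SNR the
Rician floor is negligible and Gaussian keeps estimator calibration
analytic; a Rician option exists. The default noise sd (130 a.u.) is a
calibration choice: wall SNR is rarely reported, and this level puts
single-voxel fit errors in the mid-teens-to-twenties percent range typical
of vessel-wall studies.

Scan-rescan cohorts draw subject-level K^trans log-normally (mean 0.043
min⁻¹, between-subject CV 40% — log-normal guarantees positivity) and
perturb each scan through a mean-one log-normal factor with the
within-subject CV (default 22%). Maximal aneurysm diameter is linear in
the subject's true K^trans (intercept 43 mm, slope 150 mm·min, residual sd
5 mm), chosen to give a cohort mean diameter near 49 ± 6 mm and a moderate
positive rank correlation with K^trans.

What the phantom does **not** model: motion and breathing displacement,
pulsation artifacts, partial-volume effects at the thin wall,
intraluminal-thrombus enhancement (none is simulated; thrombus does not
enhance), B1/flip-angle error, and spatially correlated physiological
noise. The last point matters for interpretation: in the phantom, ROI
averaging shrinks noise ~1/√n so ROI-based fit errors are far smaller than
voxel-level ones, whereas in vivo coherent fluctuations keep ROI-level
errors high. Passing tests therefore validate the estimators and their
calibration, not the in-vivo error budget.

## Reproducibility statistics

* **Within-subject CV**: per-subject within SD of a scan pair is
  |x₁−x₂|/√2; the overall within-subject SD pools them as the root mean
  within-variance (standard repeatability convention, near-unbiased), and
  CV = 100·pooled SD/grand mean. Arithmetic-mean pooling is available as
  an option; note its expectation is √(2/π) ≈ 0.80 of the generative σ,
  so the RMS form is the default.
* **ICC**: one-way random-effects single-measurement ICC(1,1) =
  (MSB − MSW)/(MSB + (k−1)MSW) — the standard scan-rescan agreement form
  when scan order carries no meaning; two-way absolute-agreement ICC(A,1)
  is available.
* **Wilcoxon signed-rank** (paired model comparisons): zero differences
  dropped; for n ≤ 25 the exact null pmf of the positive rank sum is built
  by dynamic programming over (doubled) mid-ranks, so ties are handled
  exactly; larger n uses the normal approximation with tie and continuity
  corrections. Two-sided p = 2·min(tails), capped at 1.
* **Spearman ρ**: Pearson correlation of mid-ranks; p from the t
  approximation with n−2 df (adequate at cohort sizes), exact pairing
  permutation available for n ≤ 10. Exactly monotone data snap to ±1.

The comparison report (pydantic-validated schema) is a pure function of
the tidy per-fit table: per-model mean ± SD of K^trans, fit error and
K^trans uncertainty; pairwise Wilcoxon tests and win fractions (ties count
0.5; tests suppressed below 5 common subjects); cross-model Spearman of
K^trans; K^trans-vs-diameter Spearman; and the ICC/CV table when at least
3 subjects have rescans.

## Known limitations

* The population AIF parameters are a plausibility-tuned stand-in, not a
  fitted population value.
* Fixed pre-contrast T1/T2 and no B1 correction: absolute K^trans scales
  inherit any error in those constants.
* No spatial regularization or motion correction; masks must already be
  aligned to the dynamic series.
* Only the three compared models are implemented — no 2CXM or
  tissue-homogeneity models.
* The acceptance pipeline uses a 24×24 single-slice phantom with ~90 wall
  voxels per scan to keep a full 10-subject × 2-scan × 3-model × 2-mode
  analysis in the minutes range; geometry is configurable.
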