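# Methods

## Radiance model and its assumptions

The simulator and the retrieval share one physical picture. For a Lambertian
scene, top-of-atmosphere radiance in the far-red is

    L(λ) = ρ(λ)/π · I_sc(λ) · μ0 · A(λ) + F_s · h_F(λ) · A(λ)

with ρ the effective surface reflectance, I_sc the solar irradiance, μ0 the
cosine of the solar zenith angle, F_s the fluorescence amplitude, h_F the
normalized emission shape, and A the ground-to-sensor transmittance. Two
deliberate simplifications:

* **Path reflectance, spherical albedo and two-way transmittance are folded
  into ρ.** In a window free of telluric lines these terms are spectrally
  smooth and cannot be separated from surface reflectance by any fit; the
  simulator therefore exposes a single smooth effective-reflectance
  polynomial (values validated to [0, 1]; zero is allowed so that a
  pure-fluorescence scene is expressible).
* **A ≡ 1 unless O2-like contamination is requested.** The retrieval window
  (771–778 nm by default) contains only Fraunhofer lines, where transmittance
  is unity to a very good approximation. `o2_depth > 0` injects narrow
  absorption lines at 769.2–770.7 nm that the retrieval deliberately does
  not model; this reproduces the degradation seen when a retrieval window
  reaches into an oxygen band.

Instrument line-shape convolution is folded into the widths of the
Gaussian absorption lines rather than applied as a separate convolution
operator: the retrieval never inverts the line shape, so an explicit ISRF
stage would add a parameter with no observable consequence.

## What the simulator emulates — and what it does not

Real non-fluorescent archives (bare soil, water) vary from scene to scene in
brightness, spectral slope, viewing geometry, and — crucially for a 7 nm
window — in high-frequency structure: spectral-calibration/Doppler shifts
and instrument line-shape changes displace and reshape the solar lines. The
generator draws, per scene:

| parameter | default draw | role |
| --- | --- | --- |
| reflectance polynomial (quadratic in normalized λ) | c0 ~ U(0.10, 0.55), c1 ~ U(−0.08, 0.08), c2 ~ U(−0.04, 0.04) | smooth variability |
| μ0 | U(0.3, 0.9) | brightness/geometry |
| spectral shift | U(−0.01, 0.01) nm (~1/4 channel) | calibration/Doppler stand-in |
| line-width scale | U(0.92, 1.08) | ISRF variability stand-in |
| SNR | constant 300 (configurable, affine in radiance) | sensor noise |

These choices give the training matrix about five patterns above the noise
floor, so BIC-selected model sizes cluster at nv = 5 on scenes drawn from the
same population — the behaviour the method is designed around. The continuum
scale (~1200 radiance units, i.e. mW m⁻² sr⁻¹ nm⁻¹-class) makes typical TOA
radiance ~60–120 and fluorescence amplitudes of 0–1.5 about a 1% additive
signal, which is the physically relevant regime.

A subtle identifiability constraint shapes these defaults: cross-scene
variation in *line depth* produces training patterns that mimic Fraunhofer
in-filling (a depth reduction is locally indistinguishable from an additive
smooth term), and a basis containing such patterns absorbs the fluorescence
signal almost completely. Shift- and width-type variability instead produces
derivative-shaped patterns, which are nearly orthogonal to in-filling. Real
solar line depths are stable; depth-like variability belongs to telluric
features, which the clean window excludes. The `line_scale` field exists for
experiments but defaults to 1 and is not jittered.

What the simulator does **not** contain: real solar line lists or telluric
line physics, radiative-transfer-based transmittance, canopy-model emission
spectra (the Gaussian h_F stands in for the far-red emission peak),
correlated (non-white) detector noise, and cross-track/footprint geometry.
Passing tests therefore demonstrate the estimator's statistical behaviour
under its own model assumptions plus the listed perturbations — not
performance on real granules.

## Numerical choices

* **Polynomial coordinate.** The wavelength polynomial multiplies v_1 on
  λ̂ = (λ − mid(window))/width(window). Raw nm near 775 would make the
  polynomial columns nearly collinear; the affine change rescales the a_i
  but leaves the fitted F_s untouched.
* **Weighting and RSS convention.** Weights are ϖ = SNR/L per channel.
  The residual sum of squares is Σ(ϖ r)² — dimensionless, the standard
  chi-square when ϖ is a reciprocal 1σ uncertainty. The alternative Σ ϖ r²
  is available behind `rss_squared_weights=False`. Channels with
  non-positive radiance get weight 0 (excluded from fit and RSS) and are
  logged; a strict mode raises instead.
* **BIC ties and degenerate fits.** Ties break toward the smaller nv
  (parsimony). A numerically perfect fit (RSS below 1e−24 of the weighted
  signal) has no finite BIC and is treated as −∞, again resolved toward the
  smaller candidate. Candidates that fail (e.g. nv larger than the basis)
  are recorded and skipped; only if all fail does selection raise.
* **Refit after selection.** The winning candidate is refit; with a
  deterministic solver this equals the candidate fit, but the order is
  explicit.
* **Sign convention of singular vectors.** Each vector is flipped so its
  inner product with the mean training spectrum is ≥ 0 (ties: largest
  element positive), making bases reproducible across linear-algebra
  backends. No mean-centering and no normalization are applied before the
  SVD: v_1 itself is the multiplicative carrier of the spectrum shape and
  must retain radiance units.
* **Uncertainty.** The reported 1σ on F_s is the square root of the h_F
  coefficient variance from the weighted-least-squares covariance with
  residual-based variance rescaling (RSS_w/(n−k)). On scenes whose
  non-fluorescent part lies in the basis span this is calibrated to a few
  percent; under basis mismatch it understates the total error (see
  limitations).
* **Negative retrievals are reported, never clipped** — clipping would bias
  ensemble means.
* **Windows are half-open** [λ_min, λ_max) on channel centers, so adjacent
  windows partition the grid unambiguously.

## Study sizes and experiment design

Test-suite and acceptance-script experiments use synthetic archives of
400–6000 training scenes (standing in for archives of several thousand real
soil/water spectra) and Monte-Carlo ensembles of 100–500 scenes; these sizes
were chosen so every sampling distribution involved is well resolved. The
emission-width and spectral-window sweeps are run at SNR 1500 rather than
the nominal 300: a sensitivity analysis should resolve the effect of the
swept parameter above the sensor-noise floor, which full-orbit averaging
achieves for the satellite analysis and a higher SNR achieves at desk scale.
Model-selection experiments use scenes constructed from exactly five basis
patterns (leading pattern at the radiance scale, the others at ~1.5% of it,
i.e. a few times the detection threshold implied by the BIC penalty), so
the generating complexity is known exactly.

## Known limitations

* **Basis mismatch inflates scatter beyond the reported 1σ.** With a finite,
  noisy training archive the fitted singular vectors carry estimation error;
  scenes then have a deterministic out-of-span component whose projection on
  the fluorescence direction adds scene-level error that the per-sounding
  covariance cannot see. It shrinks with training-archive size
  (≈ 1/√n_train) and is the dominant error source at SNR ≳ 1000.
* **The emission-width R² ordering is not resolvable here.** At a
  mis-specified width σ the retrieval error is, to excellent approximation,
  a pure rescaling of the estimate (signal and noise scale together with the
  norm of the in-fill direction), and the squared Pearson correlation is
  invariant under rescaling. The only true σ-dependence of R² against truth
  is the tiny misalignment (1 − cos²) between in-fill directions, of order
  1e−3 at σ = 20 and 1e−4 elsewhere — far below the sampling noise of any
  feasible ensemble. RMSE and bias, by contrast, identify the generating
  σ = 30 sharply and robustly, and are the meaningful width diagnostics in
  this setting. Orderings of correlation-type metrics across widths require
  nonlinear real-data effects this simulator does not model.
* A single Gaussian centered at 740 nm represents only the far-red emission
  peak; the red peak near 685 nm and double-peaked shapes are out of scope
  (the center is configurable).
* No atmospheric correction: windows containing real O2 or water-vapour
  features require a transmittance estimate this package does not provide;
  the window sweep quantifies exactly this failure mode.
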