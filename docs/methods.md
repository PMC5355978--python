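# Methods

This note documents the model implemented by `tieredpol`: its assumptions,
parameters, numerical methods and limitations. The model chain has three
stages — optics, transduction, opponent coding — plus a synthetic spectral
generator used only to exercise the exact spectral pipeline.

## Optical model

Skylight focused by a facet lens of F-ratio `F` enters the distal tip of
R7's rhabdomere (diameter `D_r`). The in-band photon flux is

    N_i = (π/4)² F⁻² D_r² ∫ L(λ) dλ,    λ ∈ [300, 412] nm,

where `L(λ)` is the sky's photon radiance. The integration window is the
absorption band of the pair's UV rhodopsin (peak 335 nm); absorption
outside it is negligible. Spectral irradiance input (W m⁻² nm⁻¹) is
converted to photon radiance by dividing by π sr (Lambertian sky) and the
quantal energy `hc/λ`. In practice `N_i` is treated as a free intensity
parameter: every downstream result is expressed as a function of it.

Partially polarized light of degree `d` and angle `θ` (measured from R7's
microvillar axis) is decomposed into components parallel and perpendicular
to R7's microvilli, `N∥ = N_i (1 + d cos 2θ)/2` and
`N⊥ = N_i (1 − d cos 2θ)/2`. The microvillar membrane is dichroic: the
peak absorption coefficients `k∥ = 2kδ/(δ+1)` and `k⊥ = 2k/(δ+1)` are
derived from the unpolarized mean `k = (k∥+k⊥)/2` and the dichroic ratio
`δ = k∥/k⊥`, so both identities hold exactly.

**Monochromatic absorption** at the peak wavelength follows Beer–Lambert
per component; R8 receives what R7 transmits, with its dichroic axes
swapped because its microvilli are orthogonal.

**Broadband absorption** cannot be a single exponential, because off-peak
wavelengths are absorbed more slowly and come to dominate the transmitted
light (spectral self-screening). The fraction of in-band photons absorbed
by a rhabdomere of optical depth `κ = k(λmax)·l` is modelled as

    Fa(κ) = (1 − e^(−κ)) (c0 + c1 κ + c2 κ²),

with canonical coefficients `(0.4697838, 0.05512361, −0.00291346)` valid
for `κ ∈ [0, 7.5]` (an unpolarized optical depth of a 1 mm rhabdomere).
The `(1 − e^(−κ))` factor guarantees `Fa(0) = 0` and, crucially, a finite
slope at zero: a vanishingly short photoreceptor then keeps its intrinsic
polarization sensitivity `δ`, which a pure polynomial fit would violate.
Beyond `κ ≈ 9.5` the fitted quadratic turns over and the form becomes
non-physical, so evaluation outside the validity range raises an error
rather than returning a decreasing absorptance. Tiered absorption uses
stacked optical depths: the pair as a whole absorbs
`Fa(κ∥7 + κ⊥8) N∥ + Fa(κ⊥7 + κ∥8) N⊥`, and R8's share is the difference
between the pair total and R7 alone. This keeps photon bookkeeping exact
(absorbed + transmitted = incident per component) and makes segment
decompositions telescope.

**Polarization sensitivity** is the max/min ratio of transduction rates
under fully polarized light. Whenever `l7` or `l8` is below 10⁻⁶ µm the
ratio is evaluated analytically (dichroic ratio, filtered closed form
`δ e^((k∥−k⊥) l7)`, or the derivative ratio `δ Fa′(κ⊥7)/Fa′(κ∥7)`),
never as a 0/0 numerical quotient.

**Birefringence** is ignored in the absorption model; the helper
`birefringence_phase` confirms the justification: with `Δn ≤ 10⁻³` a 60 µm
rhabdomere accumulates ≈1.13 rad of retardation, under a fifth of a
wavelength.

## Transduction-unit saturation

Each microvillus produces at most one quantum bump per dead time `t_d`.
The rhabdomere is divided into thin segments (default 1 µm; light entering
a segment has been filtered by those above it, via differences of `Fa` at
stacked depths). With `n_m` microvilli per segment absorbing `A_s`
photons/s, the number of photons absorbed per microvillus per dead time is
Poisson with mean `ν = A_s t_d / n_m`; the count transduced over a window
`τ` (an integer multiple of `t_d`, enforced) is binomial with
`n_m τ/t_d` trials and success probability `1 − e^(−ν)`:

    mean = (1 − e^(−ν)) n_m τ/t_d,   variance = e^(−ν) (1 − e^(−ν)) n_m τ/t_d.

Segment moments add because microvilli transduce independently. For
`ν ≪ 1` both moments converge to the Poisson value `A_s τ` (relative
deviation ~ν); saturation becomes noticeable above ~10⁴ transduced
photons/s. Without saturation, quantum efficiency is taken as 1 and counts
are Poisson with mean `A τ`.

Defaults: 360 microvilli/µm (9×10⁴ along 250 µm, the blowfly value,
assumed for both tiers), `t_d = 30` ms, `τ = 90 ms = 3 t_d`. A
non-integer number of segments leaves a final partial segment with
proportionally fewer microvilli.

## Opponent unit and noise budget

Each receptor's signal is its contrast `q(θ) = M(θ)/M_bg`, normalized to
the transduction of unpolarized background light of the same intensity;
without saturation `q(θ) = 1 + d (PS−1)/(PS+1) cos 2(θ − θmax)`. The
opponent output is `Q(θ) = q7(θ) − q8(θ)`, with signal range
`ΔQ = Δq7 + Δq8` in the unsaturated case. The noise variance per window is

    σ_Q²(θ) = Var(q7) + Var(q8) + 2 σ_in²/τ,

with photon terms `M(θ)/(M_bg² τ)` (Poisson) or
`Var(M^(τ))/(M_bg^(τ))²` (binomial, when saturation is on — the same
generalization is applied to the background normalization, since the
transducing machinery defines the background response too). The intrinsic
term is contrast-referred Gaussian noise of variance `σ_in²` per 1 s of
integration, entering once per receptor; the default
`σ_in² = 5×10⁻⁵` makes intrinsic noise dominate above ~10⁶ photons/s and
photon noise below, as observed in neurons postsynaptic to fly
photoreceptors. Setting it ten times higher (5×10⁻⁴) models a sparser
synaptic array.

**Discriminable angles.** A difference in polarization angle is counted as
just noticeable when it moves `Q` by one noise standard deviation. Because
noise varies over the stimulus space, ΔS is a Riemannian path sum over
`θ ∈ [0°, 90°]` on a 900-step grid (0.1°), with the noise evaluated at the
left node of each step; refining to 1800 steps changes ΔS by <0.1%.

**Mutual information.** The angle prior is uniform on [0°, 90°) and the
channel Gaussian, `Q | θ ~ N(Q(θ), σ_Q²(θ))`, so
`I(Q;θ) = h(Q) − h(Q|θ)` in bits. `f(Q)` is the angle-marginalized
mixture, computed by trapezoidal quadrature on 513 angle nodes and a
2001-point `Q` grid spanning the mixture mean ±8σ; doubling both grids
changes the result by <0.1%, and a seeded Monte-Carlo plug-in estimator
(10⁶ samples, 60×60 bins) agrees to <0.05 bits.

**Discriminability curves** use the analytic derivative of the closed-form
`Q(θ)` when saturation is off, central finite differences (0.01°)
otherwise; the gradient vanishes at 0° and 90°, where discriminability is
reported as 0 rather than raising.

## Sweeps and optimization

Length-fraction sweeps run `l8/l` over [0.01, 0.99] at 0.01 steps; optima
are located by grid search followed by bounded golden-section refinement
to 10⁻³ in the bracketing interval, with ties broken toward smaller `l8/l`
(argmax of the first maximum). Fractions are reported to two decimals,
lengths to the nearest 5 µm (20 µm for the broad saturated signal-range
optimum, whose peak is nearly flat). Total-length sweeps cover 20–300 µm
in 5 µm steps with the pair split equally. The SNR-optimal single-receptor
length is found on a 1 µm grid over [1, 400] µm; the degree of
polarization, window and photon flux only scale the SNR curve, so the
argmax is theirs-invariant (asserted in tests). Headline optima are
computed with saturation off; both switches are exposed, and saturation
shifts the optima only slightly while lowering every metric.

These grid sizes keep the complete study (all sweeps, both metrics, four
intensities) under a minute on one core.

## Synthetic spectral inputs

The exact spectral pipeline — absorptance by wavelength integration and
the polynomial fit — needs a sky spectrum and a pigment absorbance curve.
Since the study's measured irradiance is not available, `tieredpol.sky`
generates synthetic stand-ins:

* **Sky:** photon radiance of a 6500 K blackbody modulated by a Rayleigh
  `λ⁻⁴` law on a 1 nm grid over 300–412 nm, renormalized to an arbitrary
  peak value (absolute intensity is a free parameter downstream), with
  optional seeded log-normal noise.
* **Template:** a two-sided band in log-wavelength, equal to 1 at 335 nm
  and to 0.01 exactly at 300 and 412 nm, with flank exponent 2.24. The
  exponent is the one free shape parameter; it was calibrated once so that
  the synthetic pipeline's fitted absorptance reproduces the canonical
  `Fa(κ)` curve (within 2.4% for `κ ≤ 3`), making the stand-in a faithful
  surrogate for the original spectral conditions. Any tabulated template
  can be substituted.

What the synthetic path does **not** emulate: absolute Pretoria-summer
radiance (so the printed bright-day flux of 1.6×10⁷ photons/s is not
reproduced here — intensity is always supplied explicitly), Fraunhofer
structure, time-of-day spectral shifts, and the slight width overestimate
of real UV-rhodopsin bands. Tests that pass on the synthetic path
therefore validate the machinery and the robustness of the optima to the
spectral stand-in, not the absolute calibration of any particular sky.

## Degenerate inputs and numerical conventions

* Zero-length receptors: absorption 0; PS via analytic limits; contrast
  undefined (zero background) raises a degenerate-geometry error.
* `τ` must be a positive integer multiple of `t_d` when saturation is on.
* All spectral integrals are trapezoidal on the native grid (1 nm for
  generated spectra); delta-function fixtures are scaled so their
  trapezoidal integral is exact including at window edges.
* The absorptance fit minimizes *relative* error (weighted least squares
  on the quadratic factor) over ≥50 samples; the achieved maximum relative
  error is recorded on the model and flagged if above 1%.

## Known limitations

* Waveguide mode structure, rhabdomere twist, the longitudinal pupil and
  metarhodopsin photochemistry are outside the model; the pupil in
  particular would extend the unsaturated regime to brighter skies.
* Bump latency and shape dynamics are collapsed into fixed-window counts;
  time-varying stimuli are not modelled.
* The opponent unit confounds polarization angle with degree of
  polarization; all metrics are computed at fixed `d` (default 0.1).
* A single ommatidium is modelled; pooling across the dorsal rim and
  higher-order polarization neurons are not.
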