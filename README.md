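# tieredpol

Biophysical model of skylight-polarization coding by the tiered R7/R8
photoreceptor pair in the fly dorsal rim area (DRA).

In most flies the polarization-sensitive photoreceptors R7 and R8 stack
their rhabdomeres into a single waveguide, the central rhabdomere pair
(CRP): R7 sits on top and filters the light reaching R8, whose microvilli
are orthogonal to R7's. The pair therefore forms two orthogonal
polarization analysers that share one limited resource — the CRP's total
length `l`. This package models the complete chain from sky photons to
coding performance and asks how that resource should be divided:

1. **Optics.** Dichroic Beer–Lambert absorption in the two tiers. For
   fully polarized light at the 335 nm absorption peak, R7's polarization
   sensitivity (max/min transduction ratio) is
   `PS7 = (1 − e^(−k∥ l7)) / (1 − e^(−k⊥ l7))` and R8's is boosted by R7's
   filtering. Broadband skylight is handled through the absorptance
   function `Fa(κ) = (1 − e^(−κ))(c0 + c1 κ + c2 κ²)` of the optical depth
   `κ = k(λmax)·l`, so no spectral data file is needed.
2. **Transduction.** Each microvillus is a transduction unit with a dead
   time `t_d`; per 1 µm segment the photon count per integration window
   `τ` is binomial with success probability `1 − e^(−ν)`,
   `ν = A_s t_d / n_m`. This captures the saturation of transduction at
   high light levels and the underdispersion (Fano factor `e^(−ν)`) of the
   resulting counts.
3. **Opponent coding.** An opponent unit outputs the difference of the two
   contrast signals, `Q(θ) = q7(θ) − q8(θ)`, with photon noise from each
   receptor plus contrast-referred intrinsic noise `2σ_in²/τ`. Coding
   ability is measured as the number of discriminable polarization angles
   ΔS (a Riemannian sum of one-noise-SD just-noticeable differences over
   0–90°) and as the mutual information `I(Q; θ)` for a uniform angle
   prior.

The model's central result: photon noise favours an equal split of the CRP
(`l8/l ≈ 0.5`), while intrinsic noise favours a shorter R8 (down to
`l8/l ≈ 0.33` in bright light) — a range that brackets the R8 fractions
measured across fly species.

## Worked example

```python
import tieredpol as tp

dichroic = tp.DichroicAbsorption()            # k = 0.0075 µm⁻¹, δ = 10
pair = tp.TieredPairGeometry(100.0, 0.5)      # 100 µm CRP, equal split

ps7 = tp.polarization_sensitivity(7, pair, dichroic, "monochromatic")
ps8 = tp.polarization_sensitivity(8, pair, dichroic, "monochromatic")
print(f"PS7 = {ps7:.1f}, PS8 = {ps8:.1f}")

model = tp.OpponentModel(pair, dichroic, tp.OpponentConfig(
    total_flux=1e5, degree=0.1, sigma_in_sq=5e-5, tau_ms=90.0))
print(f"discriminable angles = {model.discriminable_angles():.2f}")
print(f"mutual information  = {model.mutual_information():.2f} bits")

best = tp.optimal_length_fraction("delta_s", ni=3e6, sigma_in_sq=5e-5)
print(f"optimal R8 fraction at Ni=3e6: {best.argmax:.2f}")
```

prints

```
PS7 = 7.5, PS8 = 13.9
discriminable angles = 6.20
mutual information  = 1.17 bits
optimal R8 fraction at Ni=3e6: 0.33
```

Self-screening pulls R7's sensitivity below its intrinsic dichroic ratio
of 10 while R7's filtering pushes R8's above it; at 10⁵ photons s⁻¹ the
opponent unit resolves about six polarization angles (≈1.2 bits per 90 ms
window); and in bright light, where intrinsic noise dominates, the optimal
R8 share of the CRP drops to one third.

A command-line interface exposes the sweeps
(`tieredpol sweep-fraction`, `tieredpol sweep-length`, `tieredpol optimum`,
`tieredpol mi`, `tieredpol species`, `tieredpol make-sky`,
`tieredpol run-study`), writing tidy CSVs plus a JSON manifest. All
parameters can be set from a TOML file (see `tieredpol.config`).

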