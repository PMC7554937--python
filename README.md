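# flavokin

Pre-steady-state kinetic analysis for flavoenzyme catalysis: global
spectral deconvolution of multiwavelength stopped-flow data, hyperbolic
binding/hydride-transfer rate laws, and kinetic-isotope-effect (KIE)
thermal analysis — with seeded synthetic-data generators so every stage
is testable without instrument data.

## Who this is for

Enzymologists analysing photodiode-array stopped-flow transients of
flavin-dependent oxidoreductases (and similar chromophoric enzymes).
A rapid-mixing experiment yields an absorbance matrix D(t, λ); the
questions are: how many kinetic species does it contain, what are their
rate constants and spectra, how do the observed rates depend on substrate
concentration and temperature, and what do H/D isotope contrasts say
about hydrogen tunneling?

## The models

**Sequential mechanism.** Transients are described as an irreversible
first-order chain A → B → … → Z with rate constants k₁…k_{n−1}.
Populations follow the closed-form Bateman solution (with a stable
confluent evaluation when rates coincide), and the observation model is
bilinear: D = C(k)·S, where C holds the fractional populations and S the
species-associated spectra.

**Global fitting.** `fit_sequential` minimizes ‖D − C(k)·S‖² over log k
with S eliminated analytically at each step (variable projection);
`select_model` picks the minimal adequate number of steps by BIC plus a
2% floor on each step's share of the band-I (≈450 nm) amplitude change.

**Scalar rate laws.**
`fit_hyperbolic` fits k_obs = k·[S]/([S] + K_d), the single-site
binding-then-transfer law; `fit_exponential` fits monophasic traces
signal = offset + amplitude·(1 − e^{−kt}).

**Isotope and activation analysis.** KIE = k_H/k_D with first-order
error propagation; Arrhenius (ln k vs 1/T → A, E_a), isotope contrasts
ΔE_a = E_aD − E_aH and A_H/A_D, the KIE(T) profile
(A_H/A_D)·e^{−(E_aH−E_aD)/RT}, and Eyring (ln(k/T) vs 1/T → ΔH‡, ΔS‡).

**Flavin utilities.** FAD occupancy from an (A280, A450) pair using
ε₂₈₀(protein) = 47,900, ε₂₈₀(FAD) = 22,000 and ε₄₅₀ = 11,300 M⁻¹cm⁻¹,
and a semiquinone-signature screen of deconvolved spectra.

## Worked example

```python
import flavokin as fk

ts = fk.simulate_stopped_flow(fk.scenario_preset("nadh_2step", seed=7))
chosen, fits = fk.select_model(ts, max_steps=4)
fit = fits[chosen - 1]
print(chosen, fit.rates, fit.amplitude_fractions)
```

Running `python examples/01_global_spectral_fit.py` prints:

```
simulated 150 spectra x 77 wavelengths, noise sd 0.0018 AU
estimated spectral rank: 3
chosen mechanism: 2 step(s) (A -> B -> C)
  k_obs step 1:   77.375 +/- 0.883 s^-1
  k_obs step 2:    8.949 +/- 0.199 s^-1
band-I amplitude fractions per step: [0.751, 0.249]
rate-exchange ambiguous: True
```

The simulated enzyme (7.5 µM, true rates 78 and 8.9 s⁻¹, 2% band-I
noise) is correctly resolved into a three-species, two-step chain; the
fast phase carries ~75% of the flavin band-I bleach and the slow phase
the remaining ~25%. The ambiguity flag records that exchanging k₁/k₂
refits the spectra with an identical residual, so rates are reported in
chain order. The other scripts in `examples/` walk through the
hyperbolic binding law, the KIE/Arrhenius/Eyring analysis and the
re-oxidation + FAD-occupancy utilities.

A thin CLI mirrors the library for shell use:

```bash
flavokin simulate --scenario nadh_2step --seed 7 --out d.csv
flavokin fit d.csv --max-steps 4 --out fit.json
flavokin kie --kh 78 --kd 44
```

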