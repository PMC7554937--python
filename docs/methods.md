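# Methods

## Sequential-chain forward model

Transient spectral kinetics are modelled as an irreversible first-order
chain A → B → … → Z. "Species" here are spectral species: distributions
of enzyme states resolvable by their spectra, not necessarily single
chemical intermediates. The model is deliberately restricted:

* **Irreversibility is hard-coded.** Reverse steps are out of scope; the
  very slow reverse hydride transfer is handled separately as a
  single-exponential re-oxidation fit, not as a reverse rate inside the
  chain.
* **Fractional populations.** Concentrations are normalized to total 1;
  the absolute scale (total chromophore, µM) is a single multiplier in
  the bilinear observation model D = scale · C · S.
* **Units are fixed** package-wide: seconds, s⁻¹, nm, µM, AU. Conversion
  happens only at I/O boundaries.

Populations use the closed-form Bateman solution. When any two rates
agree to better than one part in 10⁶ the generic formula cancels
catastrophically, so those mechanisms are evaluated through the matrix
exponential of the bidiagonal rate matrix, which realises the confluent
t·e^{−kt} limits stably for arbitrary multiplicity. The split point
(relative gap 10⁻⁶) keeps both branches comfortably inside their
accurate regimes; the test suite checks both branches against an
independent numerical ODE integration, including rates equal to eight
significant digits.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, as pure
functions of (parameters, seed):

* **Flavin-like spectra.** Gaussian bands at 449 nm (band-I), shoulders
  at 422/475 nm and a 375 nm band, scaled so the oxidized band-I peak is
  11,300 M⁻¹cm⁻¹. Reduction bleaches band-I down a ladder chosen to
  split the total bleach 75/25 (three species) or 75/23/2 (four
  species), mirroring the amplitude partition of the fast and slow
  hydride-transfer phases; the final, hydroquinone-like species retains
  ≤ 5% of band-I. Each reduced species also carries a weak signature
  band on the 505–545 nm edge so the spectra are mutually linearly
  independent (rank-revealing) without touching the 440–460 nm window
  used for amplitude accounting or the semiquinone screening regions.
  Band shapes are Gaussians in wavelength with fixed widths; this is
  cosmetic — recovery tests need smooth, distinct spectra, not
  spectroscopic fidelity.
* **Stopped-flow acquisition.** The noiseless bilinear model on a
  logarithmic time grid (multi-decade kinetics from ~10² s⁻¹ down to
  ~10⁻³ s⁻¹ need log sampling), truncated below the dead time (default
  1.5 ms, a typical stopped-flow figure), plus i.i.d. Gaussian noise per
  (time, wavelength) entry. The default noise is 2% of the simulated
  band-I peak (≈ 0.0017 AU at 7.5 µM enzyme), a homoscedastic
  approximation to photodiode-array shot + read noise.
* **Rate tables.** Hyperbolic k_obs(c) and Arrhenius k(T) values with
  multiplicative Gaussian noise (fractional SD), the simplest model
  consistent with ±-style replicate errors; draws are redrawn if
  non-positive.
* **Exponential traces.** Rising convention (re-oxidation followed at
  450 nm), offset + amplitude·(1 − e^{−kt}) + Gaussian noise.

Not emulated: mixing artifacts, photobleaching, baseline drift,
heteroscedastic detector noise, NADH's own 340 nm absorbance (the
analysis window is the flavin region), and instrument nonlinearity.
Passing recovery tests therefore demonstrate estimator correctness and
statistical efficiency under idealized noise, not robustness to
instrument systematics.

## Global fitting

`fit_sequential` minimizes ‖D − C(k)S‖² by variable projection: for each
trial k the spectra S are the exact linear least-squares solution, and a
trust-region optimizer works on the remaining nonlinear problem in
log k (positivity without constraints). Choices that matter:

* **Initialization** from the time grid: rates log-spaced between
  1/(10·t_max) and 10/t_min, with two decade-shifted fallback starts
  used when the first start does not converge to an evidently good fit.
* **Weighting:** unweighted across wavelengths (homoscedastic noise
  model).
* **Spectra are unconstrained** in sign by default, matching standard
  global-analysis practice; fitted spectra can dip slightly negative in
  noise.
* **Standard errors** come from the Gauss–Newton covariance at the
  optimum (s²·(JᵀJ)⁻¹ with the variable-projection Jacobian), scaled to
  the rate parameters.
* **Identifiability:** for chains with free spectra, exchanging two rate
  constants can leave the residual unchanged (the classic exchange
  degeneracy). Rates are reported in chain order — fast phase first as
  initialized — and the result carries an `exchange_ambiguous` flag set
  when swapping k₁/k₂ changes the residual by < 10⁻³ relative.
* **Dead time:** species A is the post-mixing state at the first
  observed time; no back-extrapolation before the dead time is
  attempted.

`estimate_rank` counts singular values above the operator norm of an
i.i.d. Gaussian noise matrix, sd·(√n_t + √n_λ), with the noise sd either
supplied or estimated robustly from second differences along the
wavelength axis.

**Model selection.** The data never announce their step count; the rule
used is: accept an added step only if (i) the BIC (Gaussian residuals)
improves and (ii) every step in the larger model carries more than 2% of
the total band-I amplitude change. The amplitude floor encodes the
judgment that a step explaining < 2% of the observable signal is not an
adequate basis for a mechanistic claim, however much it may polish the
residual. Amplitude shares are computed from the mean spectra in the
440–460 nm window as |m_i − m_{i+1}| normalized by the sum of absolute
step changes, so non-monotone (re-oxidation) sequences still sum to 1.

## Scalar fits

* `fit_hyperbolic`: unweighted nonlinear least squares of
  k·c/(c + K_d), initialized at 1.2·max(k_obs) and the median
  concentration. Designs that cannot constrain both parameters (fewer
  than three distinct concentrations, or all concentrations ≫ or ≪ the
  fitted K_d) are flagged `underdetermined` with inflated standard
  errors rather than raised — the roughly concentration-dependent slow
  phase is handled by the same model with wide errors, no special case.
* `fit_exponential`: rate initialized from the half-rise time;
  amplitude sign free so bleaching traces fit without a separate mode.
  Flags: amplitude indistinguishable from zero (rate unidentifiable),
  and residual sd > 5× the point-to-point noise (systematic lack of
  monophasic fit).

## Isotope and activation analysis

Arrhenius and Eyring fits are ordinary least squares in the linearized
variables (ln k or ln(k/T) vs 1/T_K), unweighted by default. Constants:
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, k_B = 1.3806×10⁻²³ J·K⁻¹,
h = 6.626×10⁻³⁴ J·s; T_K = T_°C + 273.15. Energies are reported in
kcal/mol and entropies in cal/(mol·K). Two temperatures interpolate
exactly with a zero covariance (no residual degrees of freedom).

Derived quantities — KIE, ΔE_a = E_aD − E_aH, A_H/A_D and the KIE(T)
profile — propagate the (ln A, E_a) covariance of each regression;
isotope datasets are independent, so cross-covariances are zero. The
KIE(T) profile is flat exactly when E_aH = E_aD, in which case it equals
A_H/A_D everywhere. KIEs measured at equimolar rather than saturating
substrate are marked with an explicit `apparent` flag carried from
metadata, never inferred.

## Flavin utilities

FAD occupancy inverts the two-wavelength construction exactly:
fad = A450/ε₄₅₀, protein = (A280 − ε₂₈₀(FAD)·fad)/ε₂₈₀(protein),
occupancy = fad/protein (all in molar units internally, reported in µM).
The assumption that bound FAD keeps free-FAD spectral properties is
inherited from the measurement convention, not modelled. Readings where
the FAD absorbance exceeds what the 280 nm reading allows are rejected.

The semiquinone screen compares the 550–650 nm mean (blue-neutral
semiquinone band) and the 375–400 nm elevation over the oxidized
reference (red-anionic hint) against 10% of the reference band-I
amplitude. The thresholds are package defaults calibrated on the
generator (false-positive rate < 5% under 2%-of-band-I noise); the
anionic flag is labelled a hint because such subtle changes are
suggestive, not diagnostic. Both tests are relative to band-I, so the
screen is invariant to uniform scaling; missing wavelength coverage
yields a partial result with coverage flags rather than an error.

## Problem sizes and determinism

Recovery experiments use 150-point logarithmic time grids over 77
wavelengths (360–550 nm), 50-seed replicate sets for spectral and trace
recoveries and 100-seed sets for binding-law recoveries — enough for
stable means at the stated noise levels while keeping the whole suite
and the benchmark script in the seconds-to-minutes range on one CPU.
All randomness flows through explicit integer seeds; there is no global
random state, and every generator is bit-reproducible given its seed.

## Known limitations

* Reversible, branched and explicitly bimolecular mechanisms are out of
  scope; binding is folded into observed rates.
* Rotational/exchange ambiguity in the bilinear factorization is
  flagged, not resolved.
* The homoscedastic noise model understates reality at high absorbance;
  a weighted fit mode is the natural extension.
* The KIE error model is first-order propagation; strongly skewed rate
  uncertainties would need resampling.
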