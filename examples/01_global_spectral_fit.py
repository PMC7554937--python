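"""Deconvolve a biphasic flavin-bleaching transient into kinetic species.

Simulates a photodiode-array stopped-flow acquisition of an oxidized
flavoenzyme (7.5 µM) reduced in two sequential first-order steps
(78 and 8.9 s^-1), then recovers the rates, species spectra and per-step
band-I amplitude split by variable-projection global fitting with
automatic model selection.
"""

import flavokin as fk

ts = fk.simulate_stopped_flow(fk.scenario_preset("nadh_2step", seed=7))
print(f"simulated {ts.times.size} spectra x {ts.wavelengths.size} wavelengths, "
      f"noise sd {ts.meta['noise_sd_AU']:.4f} AU")

print("estimated spectral rank:", fk.estimate_rank(ts))

chosen, fits = fk.select_model(ts, max_steps=4)
fit = fits[chosen - 1]
print(f"chosen mechanism: {chosen} step(s) "
      f"(A -> B{' -> C' if chosen >= 2 else ''})")
for i, (k, se) in enumerate(zip(fit.rates, fit.rate_se), start=1):
    print(f"  k_obs step {i}: {k:8.3f} +/- {se:.3f} s^-1")
print("band-I amplitude fractions per step:",
      [round(float(f), 3) for f in fit.amplitude_fractions])
print("rate-exchange ambiguous:", fit.exchange_ambiguous)

# The first rate is the fast hydride-transfer phase carrying ~75% of the
# band-I bleach; the second is the slower phase with the remaining ~25%.
# The exchange flag reminds you that swapping k1/k2 refits the spectra
# with an identical residual - rates are reported in chain order.
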