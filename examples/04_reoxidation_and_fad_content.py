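"""Slow re-oxidation kinetics and FAD occupancy from two absorbances.

Part 1 fits a monophasic rising 450 nm trace (the hydroquinone enzyme
re-oxidized by NAD+ over 35 min, k = 0.0025 s^-1) and compares forward
and reverse hydride-transfer rates.  Part 2 computes protein
concentration and FAD occupancy from a single (A280, A450) pair.
"""

import numpy as np

import flavokin as fk

# --- re-oxidation trace -------------------------------------------------
t = np.arange(0.0, 2101.0, 5.0)  # 0-35 min, every 5 s
_, y = fk.simulate_exponential_trace(0.0025, 0.08, 0.02, t,
                                     noise_sd=0.0008, seed=3)
fit = fk.fit_exponential(t, y)
print(f"re-oxidation rate: {fit.rate:.5f} +/- {fit.rate_se:.5f} s^-1 (truth 0.0025)")
print(f"forward/reverse fold change: {fk.fold_change(78.0, fit.rate):,.0f}")
# A ratio of ~3e4 shows the reductive half-reaction equilibrium lies
# almost completely toward the reduced enzyme.

# --- FAD occupancy ------------------------------------------------------
A280, A450 = fk.fad_absorbances(20.0, 0.98)  # construct a 20 µM, 98% holo sample
res = fk.fad_content(A280, A450)
print(f"A280 = {A280:.3f}, A450 = {A450:.3f} ->")
print(f"  protein {res.protein_conc:.1f} uM, FAD {res.fad_conc:.1f} uM, "
      f"occupancy {res.fraction_bound:.2f} mol FAD / mol monomer")
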