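"""Synthetic stopped-flow and rate-table generators.

Everything the analysis pipeline consumes can be generated here: flavin-like
multiwavelength bleaching kinetics, hyperbolic k_obs-vs-concentration tables,
Arrhenius temperature series and single-exponential re-oxidation traces.
Every generator is a pure function of its parameters and a mandatory seed.

The flavin spectra emulate the visible bands of an oxidized FAD cofactor:
main band-I centred at 449 nm with shoulders at 422 and 475 nm and a
near-UV band at 375 nm.  Reduction to the hydroquinone bleaches band-I to
a few percent of its oxidized amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .globalfit import SpectralTimeSeries
from .mechanism import (
    SequentialMechanism,
    SpeciesSpectrumSet,
    chain_concentrations,
    predict_absorbance,
)

#: Molar band-I extinction of protein-bound oxidized FAD, AU/µM (1 cm path).
BAND_I_EXTINCTION_PER_UM = 11300e-6

# Visible-band centres (nm), Gaussian sigmas (nm) and amplitudes relative to
# band-I for the oxidized species.  Widths are cosmetic: recovery tests need
# smooth, distinct, rank-revealing spectra, not spectroscopic fidelity.
_BANDS = (
    # (centre, sigma, relative amplitude)
    (449.0, 16.0, 1.00),
    (422.0, 11.0, 0.45),
    (475.0, 11.0, 0.38),
    (375.0, 18.0, 0.55),
)

# Band-I amplitude ladders (fraction of oxidized) chosen so that successive
# steps split the total band-I bleach 75/25 (three species) and 75/23/2
# (four species), mirroring the amplitude partition of the fast and slow
# hydride-transfer phases.
_AMPLITUDE_LADDERS = {
    2: (1.0, 0.05),
    3: (1.0, 1.0 - 0.75 * 0.95, 0.05),
    4: (1.0, 1.0 - 0.75 * 0.98, 1.0 - 0.98 * (0.75 + 0.23), 0.02),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterisation of one simulated stopped-flow experiment."""

    name: str
    mechanism: SequentialMechanism
    spectra: SpeciesSpectrumSet
    total_conc: float  # µM
    time_grid: np.ndarray  # s
    dead_time: float = 1.5e-3  # s
    noise_sd: float = 0.0  # AU
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dead_time < 0:
            raise InvalidInputError("dead_time must be >= 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.total_conc <= 0:
            raise InvalidInputError("total_conc must be positive")


def make_flavin_spectra(n_species: int, wavelengths) -> SpeciesSpectrumSet:
    """Build a ladder of flavin-like spectra from oxidized to hydroquinone.

    Species 1 is the oxidized cofactor (band-I peak at 449 nm); the last
    species is hydroquinone-like with band-I bleached to <= 5% of oxidized;
    intermediates carry distinct band-I amplitudes splitting the total
    bleach 75/25 (or 75/23/2).  A weak reduced-state feature near 405 nm
    grows as band-I bleaches, keeping the set full-rank.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if n_species not in _AMPLITUDE_LADDERS:
        raise InvalidInputError("n_species must be 2, 3 or 4")
    if wl.min() > 400.0 or wl.max() < 500.0:
        raise InvalidInputError(
            "wavelength grid must cover the flavin band-I region (400-500 nm)"
        )
    ladder = _AMPLITUDE_LADDERS[n_species]
    oxidized = np.zeros_like(wl)
    for centre, sigma, rel in _BANDS:
        oxidized += rel * np.exp(-0.5 * ((wl - centre) / sigma) ** 2)
    # Each reduced species carries a weak signature band on the
    # long-wavelength edge (505-545 nm), at a species-specific centre so
    # the set is full-rank; the band-I window (440-460 nm) and the
    # semiquinone screening regions stay untouched.
    rows = []
    for j, amp in enumerate(ladder):
        signature = np.exp(-0.5 * ((wl - (505.0 + 12.0 * j)) / 12.0) ** 2)
        rows.append(amp * oxidized + 0.08 * (1.0 - amp) * signature)
    matrix = BAND_I_EXTINCTION_PER_UM * np.asarray(rows)
    return SpeciesSpectrumSet(wavelengths=wl, matrix=matrix)


def simulate_stopped_flow(scenario: SyntheticScenario) -> SpectralTimeSeries:
    """Forward-simulate one photodiode-array stopped-flow acquisition.

    The bilinear noiseless model is evaluated on the scenario time grid
    restricted to t >= dead_time, then i.i.d. Gaussian noise of sd
    ``noise_sd`` is added per matrix entry.  The generating truth is
    recorded in the metadata for recovery tests.
    """
    t = np.asarray(scenario.time_grid, dtype=float)
    t = t[t >= scenario.dead_time]
    if t.size < 2:
        raise InvalidInputError("time grid has fewer than 2 points past dead time")
    profile = chain_concentrations(scenario.mechanism, t)
    clean = predict_absorbance(profile, scenario.spectra, scale=scenario.total_conc)
    rng = np.random.default_rng(scenario.seed)
    noisy = clean + rng.normal(0.0, scenario.noise_sd, size=clean.shape) \
        if scenario.noise_sd > 0 else clean
    meta = {
        "scenario": scenario.name,
        "dead_time_s": scenario.dead_time,
        "total_conc_uM": scenario.total_conc,
        "noise_sd_AU": scenario.noise_sd,
        "seed": scenario.seed,
        "true_rates_per_s": list(scenario.mechanism.rates),
        **scenario.meta,
    }
    return SpectralTimeSeries(
        times=t, wavelengths=scenario.spectra.wavelengths, absorbance=noisy, meta=meta
    )


def hyperbolic_kobs(k_lim: float, Kd: float, conc) -> np.ndarray:
    """Single-site binding-then-transfer rate law k_obs = k·c/(c + Kd)."""
    c = np.asarray(conc, dtype=float)
    return k_lim * c / (c + Kd)


def simulate_kobs_table(
    k_lim: float,
    Kd: float,
    concentrations,
    cv: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
):
    """Noisy replicate table of observed rates vs substrate concentration.

    Each replicate draws k_obs = model × (1 + N(0, cv)), redrawn if
    non-positive (truncation).  Returns parallel arrays
    (concentration_uM, k_obs_per_s, replicate).
    """
    if k_lim <= 0 or Kd <= 0:
        raise InvalidInputError("k_lim and Kd must be positive")
    if cv < 0:
        raise InvalidInputError("cv must be >= 0")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    model = hyperbolic_kobs(k_lim, Kd, c)
    concs, kobs, reps = [], [], []
    for r in range(n_rep):
        for ci, mi in zip(c, model):
            val = mi
            if cv > 0:
                val = mi * (1.0 + rng.normal(0.0, cv))
                while val <= 0:
                    val = mi * (1.0 + rng.normal(0.0, cv))
            concs.append(ci)
            kobs.append(val)
            reps.append(r)
    return np.asarray(concs), np.asarray(kobs), np.asarray(reps)


#: Gas constant in kcal·mol^-1·K^-1.
R_KCAL = 1.9872e-3


def simulate_temperature_series(
    A: float, Ea: float, temps_C, cv: float = 0.0, seed: int = 0
):
    """Arrhenius rates k = A·exp(-Ea/(R·T_K)) with multiplicative noise.

    ``Ea`` in kcal/mol; temperatures in °C (converted to kelvin
    internally); returns (temperature_C, k_per_s) arrays.
    """
    if A <= 0 or Ea < 0:
        raise InvalidInputError("A must be positive and Ea non-negative")
    temps = np.asarray(temps_C, dtype=float)
    if np.any(temps < -10) or np.any(temps > 60):
        raise InvalidInputError("temperatures outside the sensible -10..60 °C range")
    rng = np.random.default_rng(seed)
    k = A * np.exp(-Ea / (R_KCAL * (temps + 273.15)))
    if cv > 0:
        noisy = k * (1.0 + rng.normal(0.0, cv, size=k.shape))
        while np.any(noisy <= 0):
            bad = noisy <= 0
            noisy[bad] = k[bad] * (1.0 + rng.normal(0.0, cv, size=int(bad.sum())))
        k = noisy
    return temps, k


def simulate_exponential_trace(
    rate: float,
    amplitude: float,
    offset: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Monophasic rising trace: signal = offset + amplitude·(1 − e^{−rate·t}).

    The rising convention matches re-oxidation followed at 450 nm; a
    bleaching trace is obtained with negative amplitude.
    """
    if rate <= 0:
        raise InvalidInputError("rate must be positive")
    t = np.asarray(times, dtype=float)
    signal = offset + amplitude * (1.0 - np.exp(-rate * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return t, signal


def log_time_grid(t_min: float, t_max: float, n: int = 150) -> np.ndarray:
    """Logarithmic acquisition grid covering multi-decade kinetics."""
    if not (0 < t_min < t_max):
        raise InvalidInputError("need 0 < t_min < t_max")
    return np.geomspace(t_min, t_max, n)


def scenario_preset(
    name: str, seed: int = 0, noise_sd: float | None = None
) -> SyntheticScenario:
    """Named scenario presets for the conditions studied in the pipeline.

    ``nadh_2step``  — 1:1 NADH reduction, rates 78 and 8.9 s^-1.
    ``dic_2step``   — dicoumarol-inhibited reduction, 0.034 and 0.0065 s^-1.
    ``nadph_2step`` — 1:1 NADPH reduction, 261 and 7.8 s^-1.
    """
    wl = np.arange(360.0, 551.0, 2.5)
    presets = {
        "nadh_2step": dict(rates=(78.0, 8.9), t_min=1.5e-3, t_max=60.0),
        "dic_2step": dict(rates=(0.034, 0.0065), t_min=0.1, t_max=800.0),
        "nadph_2step": dict(rates=(261.0, 7.8), t_min=1.5e-3, t_max=10.0),
    }
    if name not in presets:
        raise InvalidInputError(
            f"unknown scenario {name!r}; choose from {sorted(presets)}"
        )
    p = presets[name]
    spectra = make_flavin_spectra(3, wl)
    total_conc = 7.5
    if noise_sd is None:
        # 2% of the simulated band-I peak absorbance
        noise_sd = 0.02 * total_conc * spectra.matrix[0].max()
    return SyntheticScenario(
        name=name,
        mechanism=SequentialMechanism(p["rates"]),
        spectra=spectra,
        total_conc=total_conc,
        time_grid=log_time_grid(p["t_min"], p["t_max"], 150),
        dead_time=1.5e-3,
        noise_sd=noise_sd,
        seed=seed,
    )
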