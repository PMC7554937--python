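"""Forward model for irreversible sequential kinetic mechanisms.

A sequential mechanism is a chain of irreversible first-order conversions
between spectral species,

    A --k1--> B --k2--> ... --k_{n-1}--> Z,

the standard minimal description of multiphasic stopped-flow transients.
Species populations follow the Bateman equations; the observed absorbance
matrix is the bilinear product of the population profile with a set of
species spectra.  All times are in seconds, rates in s^-1, wavelengths in
nm and concentrations in µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .exceptions import InvalidInputError, InvalidMechanismError

# Pairwise relative rate gaps below this switch to the confluent
# (matrix-exponential) evaluation to avoid catastrophic cancellation in
# the Bateman denominators.
_DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class SequentialMechanism:
    """An irreversible first-order chain with ``len(rates) + 1`` species.

    Parameters
    ----------
    rates
        First-order rate constants (s^-1) along the chain, in step order.
        May be empty, describing a single unreactive species.
    """

    rates: tuple[float, ...]

    def __init__(self, rates) -> None:
        rates = tuple(float(k) for k in np.atleast_1d(np.asarray(rates, dtype=float))) if np.size(rates) else ()
        for k in rates:
            if not np.isfinite(k) or k <= 0.0:
                raise InvalidMechanismError(
                    f"all rate constants must be positive and finite, got {k!r}"
                )
        object.__setattr__(self, "rates", rates)

    @property
    def n_species(self) -> int:
        return len(self.rates) + 1

    @property
    def n_steps(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Fractional species populations on a time grid.

    ``matrix`` has shape (n_times, n_species); every row sums to 1
    (closed system) and the first species starts at fraction 1.
    """

    times: np.ndarray
    matrix: np.ndarray

    @property
    def n_species(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class SpeciesSpectrumSet:
    """Per-species spectra on a strictly increasing wavelength grid (nm).

    ``matrix`` has shape (n_species, n_wavelengths) in absorbance units
    per µM of total chromophore (1 cm path).  Non-negativity is enforced
    for generated spectra only; fitted spectra are unconstrained.
    """

    wavelengths: np.ndarray = field(repr=False)
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if wl.ndim != 1 or wl.size < 2:
            raise InvalidInputError("wavelength grid must be 1-D with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if m.shape[1] != wl.size:
            raise InvalidInputError(
                f"spectra matrix has {m.shape[1]} columns for {wl.size} wavelengths"
            )
        if not np.all(np.isfinite(m)):
            raise InvalidInputError("spectra must be finite everywhere")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "matrix", m)

    @property
    def n_species(self) -> int:
        return self.matrix.shape[0]


def _validate_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise InvalidInputError("times must be a 1-D array")
    if t.size and (np.any(~np.isfinite(t)) or np.any(t < 0)):
        raise InvalidInputError("times must be finite and non-negative")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    return t


def _bateman_distinct(rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Closed-form Bateman populations for pairwise-distinct rates."""
    n = rates.size + 1
    out = np.empty((t.size, n))
    E = np.exp(-np.outer(t, rates))  # (n_times, n_steps)
    out[:, 0] = E[:, 0] if rates.size else 1.0
    for j in range(1, n - 1):
        ks = rates[: j + 1]
        # c_j(t) = (prod_{i<j} k_i) * sum_i exp(-k_i t) / prod_{l!=i} (k_l - k_i)
        coef = np.prod(ks[:-1])
        acc = np.zeros(t.size)
        for i in range(j + 1):
            denom = np.prod(np.delete(ks, i) - ks[i])
            acc += E[:, i] / denom
        out[:, j] = coef * acc
    if n > 1:
        out[:, -1] = 1.0 - out[:, :-1].sum(axis=1)
    return out


def _chain_expm(rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Populations via the matrix exponential of the bidiagonal rate matrix.

    Exact for arbitrary rate degeneracy (computes the confluent t^m e^{-kt}
    limits implicitly); used when Bateman denominators would cancel.
    """
    n = rates.size + 1
    K = np.zeros((n, n))
    K[np.arange(n - 1), np.arange(n - 1)] = -rates
    K[np.arange(1, n), np.arange(n - 1)] += rates
    out = np.empty((t.size, n))
    for i, ti in enumerate(t):
        out[i] = expm(K * ti)[:, 0]
    out[:, -1] = 1.0 - out[:, :-1].sum(axis=1)
    return out


def chain_concentrations(mech: SequentialMechanism, times) -> ConcentrationProfile:
    """Solve the irreversible chain for fractional populations.

    Uses the closed-form Bateman solution; rate sets with near-equal
    entries (relative gap below 1e-6) are routed through a confluent
    matrix-exponential evaluation, which realises the repeated-root
    t·e^{-kt} limits without cancellation.
    """
    t = _validate_times(times)
    rates = np.asarray(mech.rates, dtype=float)
    if rates.size == 0:
        return ConcentrationProfile(times=t, matrix=np.ones((t.size, 1)))
    degenerate = False
    if rates.size > 1:
        ks = np.sort(rates)
        gaps = np.diff(ks) / ks[1:]
        degenerate = bool(np.any(gaps < _DEGENERACY_RTOL))
    matrix = _chain_expm(rates, t) if degenerate else _bateman_distinct(rates, t)
    return ConcentrationProfile(times=t, matrix=matrix)


def predict_absorbance(
    profile: ConcentrationProfile,
    spectra: SpeciesSpectrumSet,
    scale: float = 1.0,
) -> np.ndarray:
    """Bilinear observation model: D = scale · C · S.

    Parameters
    ----------
    profile
        Fractional populations, shape (n_times, n_species).
    spectra
        Species spectra in AU/µM, shape (n_species, n_wavelengths).
    scale
        Total chromophore concentration in µM.

    Returns
    -------
    Absorbance matrix, shape (n_times, n_wavelengths), in AU.
    """
    if profile.matrix.shape[1] != spectra.matrix.shape[0]:
        raise InvalidInputError(
            f"profile has {profile.matrix.shape[1]} species, "
            f"spectra have {spectra.matrix.shape[0]}"
        )
    return float(scale) * (profile.matrix @ spectra.matrix)
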