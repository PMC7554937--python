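"""Flavoprotein spectral utilities.

Two small, self-contained analyses:

* FAD occupancy from a two-wavelength absorbance reading.  The monomer
  extinction at 280 nm is modelled as the intrinsic protein coefficient
  plus the bound-FAD contribution scaled by occupancy; the 450 nm
  absorbance reports the FAD concentration directly.  Bound FAD is
  assumed spectrally similar to free FAD.
* Semiquinone screening of deconvolved species spectra.  A stabilized
  blue-neutral semiquinone shows a broad red-shifted band (550-650 nm);
  traces of the red-anionic semiquinone show up as a relative elevation
  near 375-400 nm.  The anionic test is reported as a hint, never a
  detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .mechanism import SpeciesSpectrumSet

#: Intrinsic protein extinction at 280 nm, M^-1 cm^-1 (from sequence).
EPS280_PROTEIN = 47900.0
#: Bound-FAD contribution at 280 nm, M^-1 cm^-1 per occupancy unit.
EPS280_FAD = 22000.0
#: FAD extinction at 450 nm, M^-1 cm^-1.
EPS450_FAD = 11300.0


@dataclass(frozen=True)
class FlavinContentResult:
    protein_conc: float  # µM monomer
    fad_conc: float  # µM
    fraction_bound: float  # mol FAD per mol monomer


def fad_content(A280: float, A450: float, pathlength: float = 1.0) -> FlavinContentResult:
    """Protein concentration and FAD occupancy from A280/A450.

    Solves, in molar units:
        fad = A450 / (ε450 · l)
        protein = (A280/l − ε280_FAD · fad) / ε280_protein
        fraction_bound = fad / protein
    Raises when the FAD absorbance exceeds what the 280 nm reading allows
    (implied protein concentration ≤ 0).
    """
    if A280 <= 0 or A450 < 0 or pathlength <= 0:
        raise InvalidInputError("need A280 > 0, A450 >= 0, pathlength > 0")
    fad_M = A450 / (EPS450_FAD * pathlength)
    protein_M = (A280 / pathlength - EPS280_FAD * fad_M) / EPS280_PROTEIN
    if protein_M <= 0:
        raise InvalidInputError(
            "FAD absorbance exceeds what the 280 nm reading allows "
            "(implied protein concentration <= 0)"
        )
    return FlavinContentResult(
        protein_conc=protein_M * 1e6,
        fad_conc=fad_M * 1e6,
        fraction_bound=fad_M / protein_M,
    )


def fad_absorbances(
    protein_conc_uM: float, fraction_bound: float, pathlength: float = 1.0
) -> tuple[float, float]:
    """Forward construction (A280, A450) from occupancy; inverse of fad_content."""
    p = protein_conc_uM * 1e-6
    f = p * fraction_bound
    A450 = EPS450_FAD * f * pathlength
    A280 = (EPS280_PROTEIN * p + EPS280_FAD * f) * pathlength
    return A280, A450


@dataclass(frozen=True)
class SemiquinoneFlags:
    neutral_sq: bool
    anionic_sq_hint: bool
    neutral_covered: bool
    anionic_covered: bool


_NEUTRAL_REGION = (550.0, 650.0)
_ANIONIC_REGION = (375.0, 400.0)
_BAND_I_REGION = (430.0, 470.0)


def _region_mean(wl: np.ndarray, row: np.ndarray, region) -> float | None:
    keep = (wl >= region[0]) & (wl <= region[1])
    return float(row[keep].mean()) if keep.any() else None


def semiquinone_screen(
    spectra: SpeciesSpectrumSet,
    reference_index: int = 0,
    neutral_threshold: float = 0.10,
    anionic_threshold: float = 0.10,
) -> list[SemiquinoneFlags]:
    """Screen deconvolved species for semiquinone signatures.

    ``neutral_sq``: mean absorbance in 550-650 nm exceeds
    ``neutral_threshold`` × the band-I amplitude of the oxidized
    reference species.  ``anionic_sq_hint``: elevation of the 375-400 nm
    mean above the reference beyond the same scale.  Both comparisons are
    relative to the reference band-I amplitude, so the screen is
    invariant to uniform spectral scaling.  Missing wavelength coverage
    yields a partial result with the corresponding ``*_covered`` flag
    cleared instead of an error.
    """
    wl = spectra.wavelengths
    band = (wl >= _BAND_I_REGION[0]) & (wl <= _BAND_I_REGION[1])
    if not band.any():
        raise InvalidInputError("wavelength grid does not cover the band-I region")
    ref = spectra.matrix[reference_index]
    band_amp = float(ref[band].max())
    if band_amp <= 0:
        raise InvalidInputError("reference species has no band-I amplitude")
    ref_anionic = _region_mean(wl, ref, _ANIONIC_REGION)
    out = []
    for row in spectra.matrix:
        nm = _region_mean(wl, row, _NEUTRAL_REGION)
        am = _region_mean(wl, row, _ANIONIC_REGION)
        neutral_covered = nm is not None
        anionic_covered = am is not None and ref_anionic is not None
        neutral = bool(neutral_covered and nm > neutral_threshold * band_amp)
        anionic = bool(
            anionic_covered and (am - ref_anionic) > anionic_threshold * band_amp
        )
        out.append(
            SemiquinoneFlags(
                neutral_sq=neutral,
                anionic_sq_hint=anionic,
                neutral_covered=neutral_covered,
                anionic_covered=anionic_covered,
            )
        )
    return out
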