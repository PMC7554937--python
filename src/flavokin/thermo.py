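"""Kinetic-isotope-effect and activation analysis.

Primary H/D kinetic isotope effects are simple rate ratios,
KIE = k_H/k_D, with first-order error propagation.  The temperature
dependence of each isotope's observed rate is analysed two ways:

* Arrhenius: ln k = ln A − E_a/(R·T), giving the frequency factor A and
  activation energy E_a; isotope contrasts ΔE_a = E_aD − E_aH and
  A_H/A_D diagnose hydrogen tunneling (A_H/A_D near 1 with small ΔE_a is
  the signature of environmentally coupled tunneling).
* Eyring: ln(k/T) = ln(k_B/h) + ΔS‡/R − ΔH‡/(R·T), giving the activation
  enthalpy and entropy.

Both are unweighted linear regressions in the linearized variables, with
the (intercept, slope) covariance propagated into every derived quantity.
Energies are reported in kcal/mol and entropies in cal/(mol·K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

#: Gas constant, kcal·mol^-1·K^-1.
R_KCAL = 1.9872e-3
#: Gas constant, cal·mol^-1·K^-1.
R_CAL = 1.9872
#: Boltzmann constant, J·K^-1.
K_B = 1.3806e-23
#: Planck constant, J·s.
PLANCK_H = 6.626e-34

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class RateVsTemperature:
    """Observed rate constants vs temperature for one isotope and step."""

    temperatures_C: np.ndarray
    rates: np.ndarray
    errors: np.ndarray | None = None
    isotope: str = "H"
    step: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_C, dtype=float)
        k = np.asarray(self.rates, dtype=float)
        if t.shape != k.shape or t.ndim != 1:
            raise InvalidInputError("temperatures and rates must be matching 1-D arrays")
        if np.any(k <= 0):
            raise InvalidInputError("all rates must be positive")
        object.__setattr__(self, "temperatures_C", t)
        object.__setattr__(self, "rates", k)
        if self.errors is not None:
            e = np.asarray(self.errors, dtype=float)
            if e.shape != k.shape:
                raise InvalidInputError("errors must match rates in shape")
            object.__setattr__(self, "errors", e)

    @property
    def temperatures_K(self) -> np.ndarray:
        return self.temperatures_C + CELSIUS_OFFSET


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k = ln A − E_a/(R·T) regression result."""

    A: float  # s^-1
    Ea: float  # kcal/mol
    #: covariance of (ln A, E_a)
    cov: np.ndarray = field(repr=False)

    @property
    def Ea_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def lnA_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    def rate_at(self, temp_C: float) -> float:
        """Model rate at a temperature (°C)."""
        return self.A * np.exp(-self.Ea / (R_KCAL * (temp_C + CELSIUS_OFFSET)))


@dataclass(frozen=True)
class EyringFit:
    """ln(k/T) = ln(k_B/h) + ΔS‡/R − ΔH‡/(R·T) regression result."""

    dH: float  # kcal/mol
    dS: float  # cal/(mol K)
    #: covariance of (ΔS‡ [cal/mol/K], ΔH‡ [kcal/mol])
    cov: np.ndarray = field(repr=False)

    @property
    def dH_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def dS_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))


@dataclass(frozen=True)
class KIERecord:
    """One kinetic-isotope-effect value with propagated uncertainty."""

    kie: float
    sd: float
    step: str = ""
    temperature_C: float | None = None
    #: set when rates were measured at equimolar (non-saturating)
    #: conditions, so the KIE is apparent rather than intrinsic
    apparent: bool = False


def compute_kie(
    kH: float,
    kD: float,
    sd_H: float = 0.0,
    sd_D: float = 0.0,
    step: str = "",
    temperature_C: float | None = None,
    apparent: bool = False,
) -> KIERecord:
    """KIE = k_H/k_D with first-order error propagation."""
    if kH <= 0 or kD <= 0:
        raise InvalidInputError("rate constants must be positive")
    kie = kH / kD
    sd = kie * np.sqrt((sd_H / kH) ** 2 + (sd_D / kD) ** 2)
    return KIERecord(
        kie=float(kie), sd=float(sd), step=step,
        temperature_C=temperature_C, apparent=apparent,
    )


def _linear_fit(x: np.ndarray, y: np.ndarray):
    """OLS of y on x: returns (intercept, slope) and their covariance."""
    if np.unique(x).size < 2:
        raise InvalidInputError("need at least 2 distinct temperatures")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = x.size
    if n > 2:
        s2 = float(resid @ resid) / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
    else:
        cov = np.zeros((2, 2))  # exact interpolation: no residual dof
    return beta, cov


def fit_arrhenius(data: RateVsTemperature) -> ArrheniusFit:
    """Linear regression of ln k on 1/T_K; slope = −E_a/R."""
    x = 1.0 / data.temperatures_K
    y = np.log(data.rates)
    (intercept, slope), cov_is = _linear_fit(x, y)
    Ea = -slope * R_KCAL
    # transform (intercept, slope) covariance to (ln A, Ea)
    T = np.array([[1.0, 0.0], [0.0, -R_KCAL]])
    cov = T @ cov_is @ T.T
    return ArrheniusFit(A=float(np.exp(intercept)), Ea=float(Ea), cov=cov)


def fit_eyring(data: RateVsTemperature) -> EyringFit:
    """Linear regression of ln(k/T_K) on 1/T_K; slope = −ΔH‡/R."""
    x = 1.0 / data.temperatures_K
    y = np.log(data.rates / data.temperatures_K)
    (intercept, slope), cov_is = _linear_fit(x, y)
    dH = -slope * R_KCAL
    dS = (intercept - np.log(K_B / PLANCK_H)) * R_CAL
    T = np.array([[R_CAL, 0.0], [0.0, -R_KCAL]])
    cov = T @ cov_is @ T.T
    return EyringFit(dH=float(dH), dS=float(dS), cov=cov)


@dataclass(frozen=True)
class IsotopeContrast:
    """Arrhenius contrasts between an H and a D dataset."""

    delta_Ea: float  # E_aD − E_aH, kcal/mol
    delta_Ea_sd: float
    A_ratio: float  # A_H / A_D
    A_ratio_sd: float


def isotope_contrast(fitH: ArrheniusFit, fitD: ArrheniusFit) -> IsotopeContrast:
    """ΔE_a = E_aD − E_aH and A_H/A_D with covariance-propagated errors.

    The two isotope datasets are independent, so cross-covariances are
    zero; within each fit the (ln A, E_a) covariance is used.
    """
    delta = fitD.Ea - fitH.Ea
    delta_sd = np.sqrt(fitH.cov[1, 1] + fitD.cov[1, 1])
    ratio = fitH.A / fitD.A
    ratio_sd = ratio * np.sqrt(fitH.cov[0, 0] + fitD.cov[0, 0])
    return IsotopeContrast(
        delta_Ea=float(delta), delta_Ea_sd=float(delta_sd),
        A_ratio=float(ratio), A_ratio_sd=float(ratio_sd),
    )


def kie_temperature_profile(
    fitH: ArrheniusFit,
    fitD: ArrheniusFit,
    temps_C,
    step: str = "",
    apparent: bool = False,
) -> list[KIERecord]:
    """KIE(T) = (A_H/A_D)·exp(−(E_aH − E_aD)/(R·T_K)).

    Flat in temperature exactly when E_aH = E_aD, in which case the
    profile equals A_H/A_D everywhere.  Uncertainties propagate the
    (ln A, E_a) covariance of each fit.
    """
    temps = np.atleast_1d(np.asarray(temps_C, dtype=float))
    out = []
    for tc in temps:
        tk = tc + CELSIUS_OFFSET
        ln_kie = (np.log(fitH.A) - np.log(fitD.A)) - (fitH.Ea - fitD.Ea) / (
            R_KCAL * tk
        )
        g = np.array([1.0, -1.0 / (R_KCAL * tk)])  # d ln KIE / d(lnA, Ea)
        var = g @ fitH.cov @ g + g @ fitD.cov @ g
        kie = float(np.exp(ln_kie))
        out.append(
            KIERecord(
                kie=kie, sd=kie * float(np.sqrt(max(var, 0.0))),
                step=step, temperature_C=float(tc), apparent=apparent,
            )
        )
    return out
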