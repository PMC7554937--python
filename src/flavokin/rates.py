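"""Secondary fits on scalar rate data.

Two models cover the scalar analyses downstream of the global fits:

* the single-site binding-then-transfer rate law
  k_obs = k·[S] / ([S] + K_d), whose limit k houses the hydride- (or
  deuteride-) transfer rate constant and whose K_d is the substrate
  dissociation constant, and
* the monophasic exponential signal(t) = offset + amplitude·(1 − e^{−k·t})
  used for slow single-phase transitions such as enzyme re-oxidation.

Both are plain unweighted nonlinear least squares with deterministic,
data-derived initial values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InvalidInputError


@dataclass(frozen=True)
class HyperbolicFit:
    k_limit: float  # s^-1, limiting rate at saturation
    Kd: float  # µM
    k_limit_se: float
    Kd_se: float
    residual_ss: float
    underdetermined: bool = False
    message: str = ""


@dataclass(frozen=True)
class ExponentialFit:
    rate: float  # s^-1
    amplitude: float
    offset: float
    rate_se: float
    amplitude_se: float
    offset_se: float
    residual_ss: float
    flagged: bool = False
    message: str = ""


def _hyperbola(c, k, Kd):
    return k * c / (c + Kd)


def fit_hyperbolic(concentrations, k_obs) -> HyperbolicFit:
    """Fit the single-site binding-then-transfer law to (c, k_obs) pairs.

    Initialized at k0 = 1.2·max(k_obs), Kd0 = median concentration.  Fits
    with fewer than three distinct concentrations, or whose sampled
    concentrations all sit far above or far below the fitted K_d, are
    returned with an ``underdetermined`` flag and inflated standard
    errors rather than raised.
    """
    c = np.asarray(concentrations, dtype=float)
    k = np.asarray(k_obs, dtype=float)
    if c.shape != k.shape or c.ndim != 1:
        raise InvalidInputError("concentrations and k_obs must be matching 1-D arrays")
    if np.any(c <= 0) or np.any(k <= 0):
        raise InvalidInputError("concentrations and k_obs must be positive")
    n_distinct = np.unique(c).size
    p0 = (1.2 * k.max(), float(np.median(c)))
    flag = n_distinct < 3
    msg = "fewer than 3 distinct concentrations" if flag else ""
    try:
        popt, pcov = curve_fit(
            _hyperbola, c, k, p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
        )
        k_fit, kd_fit = popt
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    except RuntimeError as exc:  # non-convergence
        k_fit, kd_fit = p0
        perr = np.array([np.inf, np.inf])
        flag, msg = True, str(exc)
    if not np.all(np.isfinite(perr)):
        flag = True
        msg = msg or "singular covariance: parameters not jointly identifiable"
    elif c.min() > 10.0 * kd_fit or c.max() < 0.1 * kd_fit:
        flag = True
        msg = "concentration range does not bracket Kd; estimates weakly constrained"
    ss = float(np.sum((k - _hyperbola(c, k_fit, kd_fit)) ** 2))
    return HyperbolicFit(
        k_limit=float(k_fit), Kd=float(kd_fit),
        k_limit_se=float(perr[0]), Kd_se=float(perr[1]),
        residual_ss=ss, underdetermined=flag, message=msg,
    )


def _rising_exp(t, rate, amplitude, offset):
    return offset + amplitude * (1.0 - np.exp(-rate * t))


def fit_exponential(times, signal) -> ExponentialFit:
    """Fit a monophasic exponential to a kinetic trace.

    The rising convention (re-oxidation at 450 nm) is the default;
    bleaching traces are accommodated by a negative fitted amplitude.
    The rate is initialized from the time at which the trace crosses half
    of its apparent amplitude.  Traces with no resolvable amplitude, or
    systematic non-monotone structure beyond the noise, are flagged.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 5:
        raise InvalidInputError("need matching 1-D arrays with >= 5 points")
    offset0 = float(y[0])
    amp0 = float(y[-1] - y[0])
    noise_est = float(np.std(np.diff(y)) / np.sqrt(2.0)) if t.size > 2 else 0.0
    if abs(amp0) <= 3.0 * noise_est or amp0 == 0.0:
        return ExponentialFit(
            rate=np.nan, amplitude=amp0, offset=offset0,
            rate_se=np.inf, amplitude_se=np.inf, offset_se=np.inf,
            residual_ss=float(np.sum((y - y.mean()) ** 2)),
            flagged=True, message="amplitude indistinguishable from zero",
        )
    # half-rise time -> rate init (log-linearized tail equivalent)
    half = offset0 + 0.5 * amp0
    crossed = np.nonzero((y - half) * np.sign(amp0) >= 0)[0]
    t_half = t[crossed[0]] if crossed.size and t[crossed[0]] > 0 else t[t > 0][0]
    p0 = (np.log(2.0) / t_half, amp0, offset0)
    try:
        popt, pcov = curve_fit(
            _rising_exp, t, y, p0=p0,
            bounds=([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        flag, msg = False, ""
    except RuntimeError as exc:
        popt = np.asarray(p0)
        perr = np.array([np.inf, np.inf, np.inf])
        flag, msg = True, str(exc)
    resid = y - _rising_exp(t, *popt)
    ss = float(resid @ resid)
    # systematic lack of fit: residual sd far above the point-to-point noise
    if not flag and noise_est > 0 and np.std(resid) > 5.0 * noise_est:
        flag, msg = True, "trace deviates from monophasic shape beyond noise"
    return ExponentialFit(
        rate=float(popt[0]), amplitude=float(popt[1]), offset=float(popt[2]),
        rate_se=float(perr[0]), amplitude_se=float(perr[1]),
        offset_se=float(perr[2]), residual_ss=ss, flagged=flag, message=msg,
    )


def fold_change(k_ref: float, k_test: float) -> float:
    """Ratio k_ref / k_test, e.g. uninhibited over inhibited rate."""
    if k_ref <= 0 or k_test <= 0:
        raise InvalidInputError("rates must be positive")
    return k_ref / k_test
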