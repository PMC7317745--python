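"""Apparent exchange rate (AXR) estimation from filtered acquisitions.

A FEXSY experiment applies a fixed-amplitude first gradient pair — the
"filter" — which suppresses the fast-diffusing (extracellular) pool.  As
spins exchange during the mixing time the apparent diffusion coefficient of
the surviving magnetization recovers toward its equilibrium value.  The
standard mono-exponential parametrization is

    ADC(tm) = ADC_eq * (1 - sigma * exp(-AXR * tm)),

with filter efficiency ``sigma`` in [0, 1] and the apparent exchange rate
``AXR`` in 1/s.  The ADC at each mixing time comes from a through-origin
fit of -log(S/S0) against the encode b-value, where S0 is the zero-encode
signal after the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .acquisition import FexsyAcquisition
from .spectra import dei_permeability_curve

__all__ = ["AxrFit", "fit_adc", "fit_axr", "axr_from_fexsy",
           "axr_permeability_curve"]

AXR_BOUNDS = (0.0, 100.0)   # 1/s
#: Relative ADC(tm) spread below which the exchange rate is unidentifiable.
FLATNESS_TOL = 1e-6


@dataclass(frozen=True)
class AxrFit:
    """Filter-exchange fit result."""

    axr: float               # 1/s
    sigma: float             # filter efficiency in [0, 1]
    adc_eq: float            # m^2/s
    adc_per_tm: np.ndarray   # m^2/s
    tm_list: np.ndarray      # s
    covariance: np.ndarray   # parameter covariance (adc_eq, sigma, axr)
    residual: float          # RMS of the ADC fit, m^2/s


def fit_adc(signals, b) -> float:
    """Apparent diffusion coefficient: through-origin least-squares slope of
    ``-log(S/S0)`` against ``b`` (S0 = the b=0 point, which must be present).
    """
    signals = np.asarray(signals, float)
    b = np.asarray(b, float)
    if len(signals) < 3:
        raise ValueError("need at least 3 encode points")
    if not np.any(b == 0.0):
        raise ValueError("encode points must include b = 0")
    if np.any(signals <= 0):
        raise ValueError("signals must be positive to take logarithms")
    y = -np.log(signals / signals[np.argmin(b)])
    denom = float(np.sum(b * b))
    if denom == 0.0:
        raise ValueError("b-values do not vary")
    return float(np.sum(b * y) / denom)


def _model(tm, adc_eq, sigma, axr):
    return adc_eq * (1.0 - sigma * np.exp(-axr * tm))


def fit_axr(adc_per_tm, tm_list, axr_starts=(0.5, 2.0, 5.0, 10.0, 20.0,
                                             50.0)) -> AxrFit:
    """Nonlinear least-squares fit of the filter-exchange recovery model.

    Multi-start over ``axr_starts`` (deterministic); bounds AXR in [0, 100]
    1/s and sigma in [0, 1].  Raises if ADC(tm) is flat (sigma and AXR are
    then unidentifiable) or if no start converges.
    """
    adc = np.asarray(adc_per_tm, float)
    tm = np.asarray(tm_list, float)
    if len(adc) != len(tm) or len(np.unique(tm)) < 3:
        raise ValueError("need ADC values at >= 3 distinct mixing times")
    scale = float(np.mean(adc))
    if scale <= 0:
        raise ValueError("mean ADC must be positive")
    if np.ptp(adc) / scale < FLATNESS_TOL:
        raise ValueError(
            "ADC(tm) is flat: filter efficiency ~ 0, AXR unidentifiable"
        )
    best = None
    for start in axr_starts:
        p0 = (float(adc.max()), max(1e-3, 1.0 - adc.min() / adc.max()),
              float(start))
        try:
            popt, pcov = curve_fit(
                _model, tm, adc / scale,
                p0=(p0[0] / scale, p0[1], p0[2]),
                bounds=([0.0, 0.0, AXR_BOUNDS[0]],
                        [np.inf, 1.0, AXR_BOUNDS[1]]),
                maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.sqrt(np.mean(
            (_model(tm, *popt) - adc / scale) ** 2)))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise RuntimeError("AXR fit failed to converge from every start")
    popt, pcov, resid = best
    scale_vec = np.array([scale, 1.0, 1.0])
    return AxrFit(axr=float(popt[2]), sigma=float(popt[1]),
                  adc_eq=float(popt[0] * scale), adc_per_tm=adc, tm_list=tm,
                  covariance=pcov * np.outer(scale_vec, scale_vec),
                  residual=resid * scale)


def axr_from_fexsy(acq: FexsyAcquisition, drop_encode: int = 0) -> AxrFit:
    """Fit ADC at every mixing time of a FEXSY acquisition, then AXR.

    ``drop_encode`` discards that many of the strongest encode amplitudes
    before the ADC fits (the filter-saturated points, if desired).
    """
    n = len(acq.encode_G) - drop_encode
    if n < 3:
        raise ValueError("too few encode points after dropping")
    b = acq.b_encode[:n]
    adcs = [fit_adc(acq.signals[:n, j], b) for j in range(len(acq.tm_list))]
    return fit_axr(adcs, acq.tm_list)


def axr_permeability_curve(axr_values, permeabilities) -> float:
    """Spearman rank correlation of AXR against membrane permeability."""
    return dei_permeability_curve(axr_values, permeabilities)
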