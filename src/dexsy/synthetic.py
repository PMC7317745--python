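"""Synthetic ground-truth spectra and signal matrices.

A two-site equilibrium exchange picture (Karger-type) stands in for real
acquisitions: an intracellular pool (diffusivity ``D_intra``, fraction
``f_intra``) and an extracellular pool exchange at rate ``k_ex`` during the
mixing time, producing four spectral components — two diagonal (non-
exchanged) and two symmetric cross peaks.  The exchanged fraction after a
mixing time ``tm`` is ``f_ex = 1 - exp(-k_ex tm)`` and detailed balance
makes the two cross masses equal:

    wC = wD = f_intra (1 - f_intra) f_ex,

with the remaining mass split between the diagonal components in proportion
to the pool fractions.  This generator is synthetic plumbing for testing
the inversion/peak/DEI chain — it is not the random-walk simulation, and
its Gaussian signal noise is a high-SNR approximation (no Rician floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import (DexsySequence, SignalMatrix, b_value,
                          forward_signal)

__all__ = [
    "ExchangeGroundTruth",
    "make_ground_truth",
    "generate_dexsy_signal",
    "generate_fexsy_adc",
]


@dataclass(frozen=True)
class ExchangeGroundTruth:
    """Two-site exchange weights for a DEXSY experiment.

    ``weights`` = (wA, wB, wC, wD): extracellular diagonal, intracellular
    diagonal, and the two cross components; they are non-negative and sum
    to 1, with wC = wD by detailed balance.
    """

    D_intra: float
    D_extra: float
    f_intra: float
    k_ex: float
    tm: float
    weights: tuple

    @property
    def exchanged_fraction(self) -> float:
        return float(1.0 - np.exp(-self.k_ex * self.tm))

    @property
    def expected_dei(self) -> float:
        """Weight-ratio prediction (wC + wD) / (wA + wB)."""
        wA, wB, wC, wD = self.weights
        return (wC + wD) / (wA + wB)


def make_ground_truth(D_intra: float, D_extra: float, f_intra: float,
                      k_ex: float, tm: float) -> ExchangeGroundTruth:
    """Equilibrium two-site mixing weights after a mixing time ``tm``."""
    if not 0.0 < f_intra < 1.0:
        raise ValueError("f_intra must lie strictly between 0 and 1")
    if k_ex < 0 or tm < 0:
        raise ValueError("rates and times must be non-negative")
    if D_intra <= 0 or D_extra <= 0:
        raise ValueError("diffusivities must be positive")
    f_ex = 1.0 - np.exp(-k_ex * tm)
    wC = wD = f_intra * (1.0 - f_intra) * f_ex
    rest = 1.0 - wC - wD
    wB = rest * f_intra
    wA = rest * (1.0 - f_intra)
    return ExchangeGroundTruth(D_intra=D_intra, D_extra=D_extra,
                               f_intra=f_intra, k_ex=k_ex, tm=tm,
                               weights=(wA, wB, wC, wD))


def generate_dexsy_signal(truth: ExchangeGroundTruth, seq: DexsySequence,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> SignalMatrix:
    """Four-component DEXSY signal matrix, optionally with Gaussian noise.

    Noise is additive, zero-mean, iid per cell on the real channel; the
    matrix is renormalized so the (0, 0) cell is exactly 1.  The noise
    level is recorded in ``stderr`` so that downstream inversion can use
    the discrepancy principle.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    wA, wB, wC, wD = truth.weights
    D = np.array([truth.D_intra, truth.D_extra])
    # index 0 = intra, 1 = extra; rows: D1, cols: D2; C above the diagonal
    W = np.array([[wB, wC],
                  [wD, wA]])
    b1 = b_value(np.asarray(seq.G1, float), seq.delta, seq.Delta)
    b2 = b_value(np.asarray(seq.G2, float), seq.delta, seq.Delta)
    S = forward_signal(W, D, D, b1, b2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0.0, noise_sd, S.shape)
        S = S / S[0, 0]
    S[0, 0] = 1.0
    return SignalMatrix(
        values=S, G1=np.asarray(seq.G1, float), G2=np.asarray(seq.G2, float),
        delta=seq.delta, Delta=seq.Delta, tm=seq.tm,
        direction=seq.direction,
        stderr=np.full(S.shape, noise_sd) if noise_sd > 0 else None,
    )


def generate_fexsy_adc(adc_eq: float, sigma: float, axr: float, tm_list,
                       noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Per-tm apparent diffusion coefficients from the filter-exchange model
    ``ADC(tm) = ADC_eq (1 - sigma exp(-AXR tm))`` plus Gaussian noise."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    if adc_eq <= 0 or axr < 0 or noise_sd < 0:
        raise ValueError("invalid model parameters")
    tm_list = np.asarray(tm_list, float)
    adc = adc_eq * (1.0 - sigma * np.exp(-axr * tm_list))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        adc = adc + rng.normal(0.0, noise_sd, adc.shape)
    return adc
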