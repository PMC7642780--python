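"""Measurement noise model and the shared per-pixel probability model.

A pixel reading in photon units is X = (g_i * N + r) / g0 where N is a
Poisson count with the physical expectation n, g_i the true per-pixel gain
(ADU/photon, fixed across shots), g0 the nominal gain used for conversion and
r Gaussian readout noise in ADU. Approximating the compound distribution by a
normal with matched moments gives the likelihood used by the refinement:

    X ~ Normal(n, v(n)),   v(n) = sigma_r^2 + n + sigma_g^2 n^2

with sigma_g the relative gain-calibration error and sigma_r the readout
standard deviation after division by the nominal gain. The quadratic gain
term overtakes Poisson counting at n = 1/sigma_g^2 photons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NoiseParams:
    """Detector noise description. Defaults follow a CSPAD-like camera:
    28 ADU/photon nominal gain, 3% gain-calibration error, 3 ADU readout."""

    nominal_gain: float = 28.0
    sigma_g: float = 0.03
    sigma_r: float = 3.0 / 28.0

    def __post_init__(self):
        if self.nominal_gain <= 0:
            raise ValueError("nominal gain must be positive")
        if self.sigma_g < 0 or self.sigma_r < 0:
            raise ValueError("noise standard deviations must be non-negative")


def sample_gain_map(rng: np.random.Generator, shape, params: NoiseParams) -> np.ndarray:
    """Per-pixel gains g_i ~ Normal(g0, sigma_g * g0), resampled above zero.

    The truncation is a formality: at sigma_g = 3% a non-positive draw is a
    ~33-sigma event.
    """
    g = rng.normal(params.nominal_gain, params.sigma_g * params.nominal_gain, size=shape)
    while np.any(g <= 0):
        bad = g <= 0
        g[bad] = rng.normal(
            params.nominal_gain, params.sigma_g * params.nominal_gain, size=int(bad.sum())
        )
    return g


def apply_noise(
    rng: np.random.Generator,
    expected_photons: np.ndarray,
    gains: np.ndarray,
    params: NoiseParams,
) -> np.ndarray:
    """Observed pixel values in photon units: (g_i Poisson(n) + readout)/g0.

    Readout noise is applied in ADU and then divided by the nominal gain, so
    observed values can be negative where scattering is weak.
    """
    n = np.asarray(expected_photons, dtype=float)
    if np.any(n < 0):
        raise ValueError("expected photon counts must be non-negative")
    counts = rng.poisson(n).astype(float)
    readout_adu = rng.normal(0.0, params.sigma_r * params.nominal_gain, size=n.shape)
    return (np.asarray(gains) * counts + readout_adu) / params.nominal_gain


def model_variance(n, params: NoiseParams):
    """v(n) = sigma_r^2 + n + sigma_g^2 n^2; raises if non-positive."""
    n = np.asarray(n, dtype=float)
    v = params.sigma_r ** 2 + n + params.sigma_g ** 2 * n * n
    if np.any(v <= 0):
        raise ValueError("model variance is non-positive (invalid photon model)")
    return v


def gain_approx_breakpoint(params: NoiseParams) -> float:
    """Photon count where the gain-error variance equals the Poisson term."""
    if params.sigma_g == 0:
        return np.inf
    return 1.0 / params.sigma_g ** 2


def pixel_log_probability(X, n, params: NoiseParams):
    """Log of the normal density of X with mean n and variance v(n)."""
    v = model_variance(n, params)
    X = np.asarray(X, dtype=float)
    n = np.asarray(n, dtype=float)
    return -0.5 * np.log(2.0 * np.pi * v) - (X - n) ** 2 / (2.0 * v)
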