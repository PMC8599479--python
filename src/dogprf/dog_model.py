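"""Difference-of-Gaussians (DoG) receptive-field mathematics.

The centre-surround population receptive field is modelled as

    f(x, y) = exp(-r^2 / (2 sigma1^2)) - delta * exp(-r^2 / (2 sigma2^2)),

with r^2 = (x - x0)^2 + (y - y0)^2, an excitatory centre Gaussian of spread
``sigma1`` and an inhibitory surround Gaussian of spread ``sigma2`` whose
amplitude is modulated by ``delta``.  The filter's total (DC) energy is the
2D integral 2*pi*(sigma1^2 - delta*sigma2^2); the model is *DC balanced*
when this vanishes, i.e. when delta = (sigma1/sigma2)^2.  A balanced DoG is a
bandpass spatial filter that responds to contrast but is insensitive to
uniform luminance; a positively biased DoG is a lowpass filter that passes
the luminance (DC) component.

Two balance notions appear in this module and must not be confused:

* 2D balance (``balanced_delta``): delta = (sigma1/sigma2)^2, zero 2D
  integral.  This is the condition used throughout the fitting pipeline.
* 1D-section balance (``balanced_delta_1d``): delta = sigma1/sigma2, zero
  *1D* integral of the radial section of the kernel.  ``filter_signal``
  convolves 1D signals with the radial section, so only a 1D-balanced
  kernel annihilates a constant signal.  The two conditions coincide only
  in the degenerate limit sigma1 -> sigma2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import cached_property
from typing import NamedTuple

import numpy as np

from .errors import InputError, ParameterError

#: |bias| at or below this value (deg^2) counts as DC balanced.
BALANCE_TOL = 1e-6

#: The restricted model space for the surround amplitude.
DELTA_BOUNDS = (0.1, 0.9)


@dataclass(frozen=True)
class DoGParams:
    """Parameters (x0, y0, sigma1, sigma2, delta) of one DoG receptive field.

    Positions and spreads are in degrees of visual angle; ``delta`` is the
    dimensionless amplitude of the inhibitory surround.
    """

    x0: float
    y0: float
    sigma1: float
    sigma2: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ParameterError(
                f"Gaussian spreads must be positive, got sigma1={self.sigma1}, "
                f"sigma2={self.sigma2}"
            )

    @property
    def eccentricity(self) -> float:
        """Distance of the centre from fixation, degrees."""
        return math.hypot(self.x0, self.y0)

    @property
    def ratio(self) -> float:
        """sigma1 / sigma2."""
        return self.sigma1 / self.sigma2

    def in_restricted_space(self, delta_bounds: tuple[float, float] = DELTA_BOUNDS) -> bool:
        """True when the model is non-inverted and delta is inside the
        restricted space (sigma1 < sigma2, lo < delta < hi)."""
        lo, hi = delta_bounds
        return self.sigma1 < self.sigma2 and lo < self.delta < hi


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square sampling lattice for the visual field, centred on fixation.

    ``extent`` is the half-width in degrees; ``resolution`` the number of
    samples per axis.  An odd resolution places a sample exactly at (0, 0).
    """

    extent: float = 17.4
    resolution: int = 101

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ParameterError("grid extent must be positive")
        if self.resolution < 2:
            raise ParameterError("grid resolution must be at least 2")

    @property
    def cell_size(self) -> float:
        """Spacing between adjacent samples, degrees."""
        return 2.0 * self.extent / (self.resolution - 1)

    @property
    def cell_area(self) -> float:
        """Area represented by one sample, degrees^2."""
        return self.cell_size ** 2

    @cached_property
    def axis(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.resolution)

    @cached_property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrid arrays; Y increases upward along rows."""
        X, Y = np.meshgrid(self.axis, self.axis)
        return X, Y

    @cached_property
    def eccentricity(self) -> np.ndarray:
        X, Y = self.coords
        return np.hypot(X, Y)

    @cached_property
    def polar_angle(self) -> np.ndarray:
        """Polar angle in degrees, counter-clockwise from the +x axis."""
        X, Y = self.coords
        return np.degrees(np.arctan2(Y, X))


class BiasValue(NamedTuple):
    """DC bias sigma1^2 - delta*sigma2^2 (deg^2) and its classification."""

    value: float
    classification: str  # "balanced" | "positive" | "negative"


class BalancedCounterparts(NamedTuple):
    """The three single-parameter replacements that restore DC balance."""

    delta_variant: DoGParams
    sigma1_variant: DoGParams
    sigma2_variant: DoGParams


def evaluate_dog(params: DoGParams, grid: VisualFieldGrid) -> np.ndarray:
    """Evaluate the DoG at every sample of ``grid``.

    Returns a (resolution, resolution) array; the value at the centre is
    1 - delta.
    """
    X, Y = grid.coords
    r2 = (X - params.x0) ** 2 + (Y - params.y0) ** 2
    return np.exp(-r2 / (2.0 * params.sigma1 ** 2)) - params.delta * np.exp(
        -r2 / (2.0 * params.sigma2 ** 2)
    )


def balanced_delta(sigma1: float, sigma2: float) -> float:
    """Surround amplitude that makes the 2D DoG DC balanced: (sigma1/sigma2)^2."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ParameterError("sigmas must be positive")
    return (sigma1 / sigma2) ** 2


def balanced_delta_1d(sigma1: float, sigma2: float) -> float:
    """Surround amplitude that zeroes the *1D* integral of the radial
    section: sigma1/sigma2.  See the module docstring."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise ParameterError("sigmas must be positive")
    return sigma1 / sigma2


def balanced_sigma1(sigma2: float, delta: float) -> float:
    """Centre spread that balances the DoG at fixed (sigma2, delta):
    sigma2 * sqrt(delta)."""
    if sigma2 <= 0 or delta <= 0:
        raise ParameterError("sigma2 and delta must be positive")
    return sigma2 * math.sqrt(delta)


def bias(params: DoGParams, tol: float = BALANCE_TOL) -> BiasValue:
    """DC bias of the DoG: sigma1^2 - delta*sigma2^2 (deg^2).

    The 2D integral of the kernel is 2*pi times this value, so the sign of
    the bias is the sign of the filter's DC gain.
    """
    value = params.sigma1 ** 2 - params.delta * params.sigma2 ** 2
    if abs(value) <= tol:
        cls = "balanced"
    elif value > tol:
        cls = "positive"
    else:
        cls = "negative"
    return BiasValue(value, cls)


def balanced_counterparts(params: DoGParams) -> BalancedCounterparts:
    """For an arbitrary DoG, compute the three single-parameter replacements
    that would each make it DC balanced:

    * delta' = (sigma1/sigma2)^2, holding the sigmas,
    * sigma1' = sigma2*sqrt(delta), holding sigma2 and delta,
    * sigma2' = sigma1/sqrt(delta), holding sigma1 and delta.
    """
    if params.delta <= 0:
        raise ParameterError("delta must be positive to solve for the sigmas")
    d = balanced_delta(params.sigma1, params.sigma2)
    s1 = balanced_sigma1(params.sigma2, params.delta)
    s2 = params.sigma1 / math.sqrt(params.delta)
    return BalancedCounterparts(
        replace(params, delta=d),
        replace(params, sigma1=s1),
        replace(params, sigma2=s2),
    )


def frequency_response(params: DoGParams, frequencies: np.ndarray) -> np.ndarray:
    """Analytic radial amplitude spectrum of the DoG at the given spatial
    frequencies (cycles per degree).

    The 2D Fourier transform of a unit-amplitude isotropic Gaussian of
    spread sigma is 2*pi*sigma^2 * exp(-2*pi^2*sigma^2*f^2), so

        F(f) = 2*pi*sigma1^2*exp(-2*pi^2*sigma1^2*f^2)
             - delta*2*pi*sigma2^2*exp(-2*pi^2*sigma2^2*f^2).

    The returned spectrum is signed; F(0) = 2*pi*bias.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise InputError("frequencies must be non-negative")
    s1sq = params.sigma1 ** 2
    s2sq = params.sigma2 ** 2
    two_pi_sq = 2.0 * math.pi ** 2
    return 2.0 * math.pi * (
        s1sq * np.exp(-two_pi_sq * s1sq * f ** 2)
        - params.delta * s2sq * np.exp(-two_pi_sq * s2sq * f ** 2)
    )


def classify_filter(params: DoGParams, tol: float = BALANCE_TOL) -> str:
    """Classify the DoG's spatial-frequency behaviour.

    Returns "bandpass" for a balanced model (|bias| <= tol, inclusive),
    "lowpass" for a positively biased one, and "negative" for a negatively
    biased one (nonzero DC gain of negative sign, reported distinctly).
    Inverted models (sigma1 >= sigma2) are rejected.
    """
    if params.sigma1 >= params.sigma2:
        raise ParameterError(
            "inverted DoG (sigma1 >= sigma2) is outside the model space"
        )
    b = bias(params, tol)
    if b.classification == "balanced":
        return "bandpass"
    if b.classification == "positive":
        return "lowpass"
    return "negative"


def dog_kernel_1d(params: DoGParams, sampling: float, support_sigma: float = 8.0) -> np.ndarray:
    """Radial section of the DoG sampled at spacing 1/sampling, centred,
    truncated at ``support_sigma`` surround spreads."""
    if sampling <= 0:
        raise InputError("sampling rate must be positive")
    half = int(math.ceil(support_sigma * params.sigma2 * sampling))
    x = np.arange(-half, half + 1) / sampling
    return np.exp(-x ** 2 / (2.0 * params.sigma1 ** 2)) - params.delta * np.exp(
        -x ** 2 / (2.0 * params.sigma2 ** 2)
    )


def filter_signal(signal: np.ndarray, params: DoGParams, sampling: float) -> np.ndarray:
    """Circularly convolve a 1D signal with the radial section of the DoG.

    ``sampling`` is the number of signal samples per unit distance.  The
    kernel is used unnormalised, so the output mean equals the input mean
    times the kernel sum (the discrete 1D DC gain).  Only a 1D-balanced
    kernel (delta = sigma1/sigma2, see ``balanced_delta_1d``) has zero DC
    gain and therefore annihilates constants.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise InputError("signal must be a non-empty 1D array")
    kernel = dog_kernel_1d(params, sampling)
    if kernel.size > y.size:
        raise InputError(
            f"signal length {y.size} shorter than kernel support {kernel.size}"
        )
    half = kernel.size // 2
    padded = np.zeros_like(y)
    padded[: half + 1] = kernel[half:]
    if half:
        padded[-half:] = kernel[:half]
    return np.fft.irfft(np.fft.rfft(y) * np.fft.rfft(padded), n=y.size)
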