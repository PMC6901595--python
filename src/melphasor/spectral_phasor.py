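"""Spectral-emission phasor analysis.

Each pixel of a lambda-mode image carries counts in a small number of emission
channels (here 32 channels of 8.9 nm covering 410-696 nm).  The spectral
phasor transform maps the per-pixel spectrum I(lambda) to

    g = sum_c I(l_c) cos(2 pi n (l_c - l_i) / (l_max - l_min)) / sum_c I(l_c)
    s = likewise with sin

over channel centers l_c, with harmonic number n and initial wavelength l_i.
The phase angle relates to the center of mass of the emission spectrum (a red
shift moves the phasor counter-clockwise from (1, 0)); the modulus decreases
with spectral width, so an infinitely broad background sits at the origin.
Phasors obey vector addition: the phasor of a summed spectrum is the
intensity-weighted mean of the component phasors, which is what makes
cursor-based unmixing of overlapping spectra possible without reference
spectra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .flim_phasor import PhasorField

__all__ = [
    "SpectralStack",
    "SpectrumVector",
    "SpectralPhasorPoint",
    "PeakWavelength",
    "spectral_phasor_transform",
    "spectrum_phasor",
    "phase_modulus",
    "peak_wavelength_from_phasor",
]


def _channel_centers(lambda_min: float, channel_width: float, n: int) -> np.ndarray:
    # channel c spans [l_min + c*w, l_min + (c+1)*w); centers at +w/2
    return lambda_min + (np.arange(n) + 0.5) * channel_width


@dataclass
class SpectralStack:
    """Per-pixel spectral counts: ``counts[row, col, channel]``."""

    counts: np.ndarray
    lambda_min_nm: float = 410.0
    lambda_max_nm: float = 696.0
    channel_width_nm: float = 8.9
    lambda_i_nm: float | None = None   # initial wavelength; defaults to lambda_min
    harmonic: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("spectral stack must be rows x cols x channels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lambda_i_nm is None:
            self.lambda_i_nm = self.lambda_min_nm
        span = self.lambda_max_nm - self.lambda_min_nm
        covered = self.counts.shape[2] * self.channel_width_nm
        if covered < span - self.channel_width_nm:
            raise ValueError(
                "channels do not cover the wavelength range within one width"
            )

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def channel_centers_nm(self) -> np.ndarray:
        return _channel_centers(
            self.lambda_min_nm, self.channel_width_nm, self.n_channels
        )


@dataclass
class SpectrumVector:
    """A single spectrum with its wavelength-axis metadata."""

    counts: np.ndarray
    lambda_min_nm: float = 410.0
    lambda_max_nm: float = 696.0
    channel_width_nm: float = 8.9
    lambda_i_nm: float | None = None
    harmonic: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("spectrum must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lambda_i_nm is None:
            self.lambda_i_nm = self.lambda_min_nm

    @property
    def channel_centers_nm(self) -> np.ndarray:
        return _channel_centers(
            self.lambda_min_nm, self.channel_width_nm, self.counts.shape[0]
        )


class SpectralPhasorPoint(NamedTuple):
    g: float
    s: float


class PhaseModulus(NamedTuple):
    phi: float          # radians in [0, 2*pi)
    modulus: float
    degenerate: bool    # True at the origin, where phi is a convention


class PeakWavelength(NamedTuple):
    wavelength_nm: float
    aliased: bool       # True when the inverted wavelength leaves the axis range


def _angles(stack_like: SpectralStack | SpectrumVector) -> np.ndarray:
    span = stack_like.lambda_max_nm - stack_like.lambda_min_nm
    return (
        2.0
        * math.pi
        * stack_like.harmonic
        * (stack_like.channel_centers_nm - stack_like.lambda_i_nm)
        / span
    )


def spectral_phasor_transform(
    stack: SpectralStack, intensity_threshold: float = 0.0
) -> PhasorField:
    """Transform a spectral stack into a per-pixel phasor field.

    Zero-count pixels are always masked (the background convention puts an
    infinitely broad spectrum at the origin, not a measured pixel there); an
    optional intensity threshold masks dim pixels the same way as for FLIM.
    """
    if stack.harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    theta = _angles(stack)
    counts = stack.counts.astype(float)
    total = counts.sum(axis=2)
    mask = (total > 0) & (total >= intensity_threshold)
    if not mask.any():
        warnings.warn("no pixel carries spectral counts; empty mask", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(mask, counts @ np.cos(theta) / total, 0.0)
        s = np.where(mask, counts @ np.sin(theta) / total, 0.0)
    return PhasorField(
        g=g,
        s=s,
        intensity=total,
        mask=mask,
        harmonic=stack.harmonic,
        modality="spectral",
        meta={
            "lambda_min_nm": stack.lambda_min_nm,
            "lambda_max_nm": stack.lambda_max_nm,
            "lambda_i_nm": stack.lambda_i_nm,
            "channel_width_nm": stack.channel_width_nm,
        },
    )


def spectrum_phasor(spectrum: SpectrumVector) -> SpectralPhasorPoint:
    """Phasor of a single spectrum."""
    total = spectrum.counts.sum()
    if total <= 0:
        raise ValueError("cannot compute the phasor of an empty spectrum")
    theta = _angles(spectrum)
    g = float(spectrum.counts @ np.cos(theta) / total)
    s = float(spectrum.counts @ np.sin(theta) / total)
    return SpectralPhasorPoint(g, s)


def phase_modulus(g: float, s: float) -> PhaseModulus:
    """Phase angle in [0, 2*pi) measured counter-clockwise from (1, 0), and
    modulus sqrt(g^2 + s^2).  The origin has no defined phase; by convention
    phi = 0 with the degenerate flag set."""
    if not (math.isfinite(g) and math.isfinite(s)):
        raise ValueError("phasor coordinates must be finite")
    m = math.hypot(g, s)
    if m == 0.0:
        return PhaseModulus(0.0, 0.0, True)
    phi = math.atan2(s, g) % (2.0 * math.pi)
    return PhaseModulus(phi, m, False)


def peak_wavelength_from_phasor(
    phi: float, stack_like: SpectralStack | SpectrumVector | PhasorField
) -> PeakWavelength:
    """Invert a phase angle to the emission center-of-mass wavelength.

    lambda_hat = lambda_i + phi * (lambda_max - lambda_min) / (2 pi n).  For a
    narrow symmetric spectrum this equals its center of mass, hence (to within
    channel discretisation) its peak.  Angles that invert outside the
    wavelength axis are flagged as aliased but still returned.
    """
    if not 0.0 <= phi < 2.0 * math.pi:
        raise ValueError("phi must lie in [0, 2*pi)")
    if isinstance(stack_like, PhasorField):
        meta = stack_like.meta
        lam_i = meta["lambda_i_nm"]
        lam_min = meta["lambda_min_nm"]
        lam_max = meta["lambda_max_nm"]
        n = stack_like.harmonic
    else:
        lam_i = stack_like.lambda_i_nm
        lam_min = stack_like.lambda_min_nm
        lam_max = stack_like.lambda_max_nm
        n = stack_like.harmonic
    lam = lam_i + phi * (lam_max - lam_min) / (2.0 * math.pi * n)
    aliased = not (lam_min <= lam <= lam_max)
    return PeakWavelength(float(lam), aliased)
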