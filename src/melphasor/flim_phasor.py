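"""Lifetime (FLIM) phasor analysis.

Every pixel of a time-correlated single-photon-counting (TCSPC) image carries a
photon arrival-time histogram ``I(t)`` over one laser period ``T = 1/f``.  The
phasor transform maps that histogram to a point in the plane,

    g = sum_k I(t_k) cos(h*w*t_k) / sum_k I(t_k)
    s = sum_k I(t_k) sin(h*w*t_k) / sum_k I(t_k)

with ``w = 2*pi*f`` the angular repetition frequency and ``h`` the harmonic
number.  Single-exponential decays land on the *universal circle*
``(g - 1/2)^2 + s^2 = 1/4``; mixtures of two species fall on the chord joining
the two pure-species phasors, with the position along the chord giving the
intensity fraction of each species.  This module implements the transform, the
analytic single-exponential reference, reference-fluorophore calibration, the
median "E-filter", two-component fraction decomposition and a conventional
biexponential decay fit used for cross-checking average lifetimes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FLIMStack",
    "DecayHistogram",
    "PhasorPoint",
    "PhasorField",
    "CalibrationRef",
    "ExponentialFit",
    "EndmemberPair",
    "FractionMap",
    "FitError",
    "wrapped_decay_expectation",
    "flim_phasor_transform",
    "decay_phasor",
    "single_exp_phasor",
    "multi_exp_phasor",
    "calibrate",
    "efilter",
    "fraction_decompose",
    "fit_two_exponential",
]


class FitError(RuntimeError):
    """Raised when a decay fit fails to converge from every start."""


class PhasorPoint(NamedTuple):
    """A point in phasor space (both coordinates unitless)."""

    g: float
    s: float


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DecayHistogram:
    """Photon counts per time bin over one laser period.

    ``counts`` may be floats when the histogram is a noiseless expectation.
    """

    counts: np.ndarray          # (n_time_bins,)
    bin_width_ns: float
    rep_rate_hz: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("decay histogram must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("decay histogram counts must be non-negative")

    @property
    def period_ns(self) -> float:
        return 1e9 / self.rep_rate_hz

    @property
    def omega_ns(self) -> float:
        """Angular repetition frequency in rad/ns."""
        return 2.0 * math.pi * self.rep_rate_hz * 1e-9

    @property
    def bin_centers_ns(self) -> np.ndarray:
        n = self.counts.shape[0]
        return (np.arange(n) + 0.5) * self.bin_width_ns

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class FLIMStack:
    """Per-pixel decay histograms: ``counts[row, col, time_bin]``."""

    counts: np.ndarray
    bin_width_ns: float
    rep_rate_hz: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("FLIM stack must be rows x cols x time_bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        period_ns = 1e9 / self.rep_rate_hz
        if not math.isclose(
            self.counts.shape[2] * self.bin_width_ns, period_ns, rel_tol=1e-9
        ):
            raise ValueError(
                "n_time_bins * bin_width must equal one laser period 1/rep_rate"
            )

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def omega_ns(self) -> float:
        return 2.0 * math.pi * self.rep_rate_hz * 1e-9

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width_ns


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates for a FLIM or spectral image.

    Masked-out pixels carry no (g, s) claim; their coordinates are stored as
    0.0 purely as a fill value.  ``meta`` carries modality-specific axis
    information (e.g. the wavelength axis for spectral fields) so that
    downstream operations such as peak-wavelength inversion need no extra
    inputs.
    """

    g: np.ndarray               # (rows, cols)
    s: np.ndarray               # (rows, cols)
    intensity: np.ndarray       # (rows, cols) total counts per pixel
    mask: np.ndarray            # (rows, cols) bool, True = valid
    harmonic: int = 1
    modality: str = "flim"      # "flim" | "spectral"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.g.shape, self.s.shape, self.intensity.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("g, s, intensity and mask must share one shape")
        if self.modality not in ("flim", "spectral"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape

    def copy(self) -> "PhasorField":
        return PhasorField(
            g=self.g.copy(),
            s=self.s.copy(),
            intensity=self.intensity.copy(),
            mask=self.mask.copy(),
            harmonic=self.harmonic,
            modality=self.modality,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class EndmemberPair:
    """Two reference phasors between which mixtures distribute linearly."""

    a: PhasorPoint
    b: PhasorPoint
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if math.isclose(self.a.g, self.b.g) and math.isclose(self.a.s, self.b.s):
            raise ValueError("endmember phasors must be distinct")

    @property
    def length(self) -> float:
        return math.hypot(self.a.g - self.b.g, self.a.s - self.b.s)


@dataclass
class FractionMap:
    """Per-pixel fraction of endmember A and perpendicular residual."""

    f_a: np.ndarray
    residual: np.ndarray
    pair: EndmemberPair

    @property
    def f_b(self) -> np.ndarray:
        return 1.0 - self.f_a


# ---------------------------------------------------------------------------
# Analytic references
# ---------------------------------------------------------------------------


def single_exp_phasor(tau_ns: float, omega_ns: float, harmonic: int = 1) -> PhasorPoint:
    """Phasor of a single-exponential decay with lifetime ``tau_ns``.

    Lies exactly on the universal circle for every ``tau_ns > 0``:
    g = 1/(1+(h w tau)^2), s = h w tau/(1+(h w tau)^2).
    """
    if tau_ns <= 0:
        raise ValueError("lifetime must be positive")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    x = harmonic * omega_ns * tau_ns
    d = 1.0 + x * x
    return PhasorPoint(1.0 / d, x / d)


def multi_exp_phasor(
    components: Sequence[tuple[float, float]], omega_ns: float, harmonic: int = 1
) -> PhasorPoint:
    """Phasor of a multi-exponential decay given (tau_ns, amplitude) pairs.

    The phasor of a sum of decays is the intensity-weighted (a_i * tau_i)
    vector sum of the component phasors.
    """
    taus = np.array([t for t, _ in components], dtype=float)
    amps = np.array([a for _, a in components], dtype=float)
    if np.any(taus <= 0) or np.any(amps < 0):
        raise ValueError("components need tau > 0 and amplitude >= 0")
    weights = amps * taus
    weights = weights / weights.sum()
    pts = np.array([single_exp_phasor(t, omega_ns, harmonic) for t in taus])
    g, s = weights @ pts
    return PhasorPoint(float(g), float(s))


def wrapped_decay_expectation(
    components: Sequence[tuple[float, float]],
    n_bins: int,
    period_ns: float,
    irf_fwhm_ns: float = 0.0,
) -> np.ndarray:
    """Expected fraction of photons per time bin for a periodically excited
    multi-exponential decay (sums to 1).

    Under 80 MHz excitation a decay does not finish within one period; photons
    from earlier pulses pile up, so the steady-state profile within one period
    is exp(-t/tau)/(1 - exp(-T/tau)).  Each bin gets the exact integral of
    that profile.  An optional Gaussian instrument response is applied as a
    circular convolution over the period.
    """
    taus = np.array([t for t, _ in components], dtype=float)
    amps = np.array([a for _, a in components], dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    edges = np.linspace(0.0, period_ns, n_bins + 1)
    out = np.zeros(n_bins)
    for tau, amp in zip(taus, amps):
        if amp == 0.0:
            continue
        # integral of e^{-t/tau} over each bin / (1 - e^{-T/tau}); weight by
        # the photon yield amp*tau of the component
        decay = np.exp(-edges / tau)
        bin_int = (decay[:-1] - decay[1:]) / (1.0 - math.exp(-period_ns / tau))
        out += amp * tau * bin_int
    out = out / out.sum()
    if irf_fwhm_ns > 0:
        sigma = irf_fwhm_ns / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        centers = (edges[:-1] + edges[1:]) / 2.0
        # circular (periodic) Gaussian kernel sampled on the bin grid
        d = np.minimum(centers - centers[0], period_ns - (centers - centers[0]))
        kernel = np.exp(-0.5 * (d / sigma) ** 2)
        kernel /= kernel.sum()
        out = np.real(np.fft.ifft(np.fft.fft(out) * np.fft.fft(kernel)))
        out = np.clip(out, 0.0, None)
        out /= out.sum()
    return out


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------


def flim_phasor_transform(
    stack: FLIMStack, harmonic: int = 1, intensity_threshold: float = 20
) -> PhasorField:
    """Transform a FLIM stack into a per-pixel phasor field.

    Pixels whose total photon count falls below ``intensity_threshold`` (and
    all zero-count pixels) are masked out: below roughly 20 photons the shot
    noise makes the phasor position meaningless for cursor assignment.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    t = stack.bin_centers_ns
    phase = harmonic * stack.omega_ns * t
    cos_t = np.cos(phase)
    sin_t = np.sin(phase)
    counts = stack.counts.astype(float)
    total = counts.sum(axis=2)
    mask = (total >= intensity_threshold) & (total > 0)
    if not mask.any():
        warnings.warn(
            "every pixel is below the intensity threshold; empty phasor mask",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(mask, counts @ cos_t / total, 0.0)
        s = np.where(mask, counts @ sin_t / total, 0.0)
    return PhasorField(
        g=g, s=s, intensity=total, mask=mask, harmonic=harmonic, modality="flim"
    )


def decay_phasor(decay: DecayHistogram, harmonic: int = 1) -> PhasorPoint:
    """Phasor of a single decay histogram (sums over bin centers)."""
    total = decay.total
    if total <= 0:
        raise ValueError("cannot compute the phasor of an empty histogram")
    phase = harmonic * decay.omega_ns * decay.bin_centers_ns
    g = float(decay.counts @ np.cos(phase) / total)
    s = float(decay.counts @ np.sin(phase) / total)
    return PhasorPoint(g, s)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationRef:
    """Reference-fluorophore calibration for lifetime phasors.

    A solution of a fluorophore with known single-exponential lifetime
    ``tau_ref_ns`` (ATTO 488 in water by convention, ~4.1 ns) is imaged under
    the same conditions; the unique rotation + scale (about the origin, in
    polar form) mapping its measured phasor onto the analytic point
    ``single_exp_phasor(tau_ref)`` corrects the instrument phase delay and
    modulation loss of every pixel.
    """

    tau_ref_ns: float
    measured: PhasorPoint
    omega_ns: float
    harmonic: int = 1

    def __post_init__(self) -> None:
        m = math.hypot(self.measured.g, self.measured.s)
        if m <= 0:
            raise ValueError("measured reference phasor has zero modulus")
        target = single_exp_phasor(self.tau_ref_ns, self.omega_ns, self.harmonic)
        self.rotation = math.atan2(target.s, target.g) - math.atan2(
            self.measured.s, self.measured.g
        )
        self.scale = math.hypot(target.g, target.s) / m


def calibrate(field_in: PhasorField, ref: CalibrationRef) -> PhasorField:
    """Apply a reference calibration (rotation + scale) to every pixel."""
    z = (field_in.g + 1j * field_in.s) * ref.scale * np.exp(1j * ref.rotation)
    out = field_in.copy()
    out.g = np.where(field_in.mask, z.real, field_in.g)
    out.s = np.where(field_in.mask, z.imag, field_in.s)
    return out


# ---------------------------------------------------------------------------
# E-filter (median convolution)
# ---------------------------------------------------------------------------


def _masked_median_pass(img: np.ndarray, mask: np.ndarray, kernel: int) -> np.ndarray:
    """One median pass over unmasked pixels; border ring left untouched.

    The median of an even number of valid neighbors is the lower median, so
    the output is always one of the input values (deterministic tie-break).
    """
    r = kernel // 2
    out = img.copy()
    rows, cols = img.shape
    if rows <= 2 * r or cols <= 2 * r:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(img, (kernel, kernel))
    wmask = np.lib.stride_tricks.sliding_window_view(mask, (kernel, kernel))
    flat = windows.reshape(windows.shape[0], windows.shape[1], -1)
    fmask = wmask.reshape(flat.shape)
    vals = np.where(fmask, flat, np.inf)
    vals = np.sort(vals, axis=2)
    n_valid = fmask.sum(axis=2)
    idx = np.maximum(n_valid - 1, 0) // 2
    med = np.take_along_axis(vals, idx[..., None], axis=2)[..., 0]
    interior = mask[r:-r, r:-r] & (n_valid > 0)
    out[r:-r, r:-r] = np.where(interior, med, img[r:-r, r:-r])
    return out


def efilter(field_in: PhasorField, passes: int = 1, kernel: int = 3) -> PhasorField:
    """Median convolution filter on the g and s images (the "E-filter").

    Reduces the variance of phasor positions without reducing image
    resolution: g and s are median-filtered independently; intensities are
    untouched; pixels within the kernel radius of the image border are
    returned unfiltered; masked neighbors are excluded from each median.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be an odd integer >= 3")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    out = field_in.copy()
    for _ in range(passes):
        out.g = _masked_median_pass(out.g, out.mask, kernel)
        out.s = _masked_median_pass(out.s, out.mask, kernel)
    return out


# ---------------------------------------------------------------------------
# Two-component fraction decomposition
# ---------------------------------------------------------------------------


def fraction_decompose(field_in: PhasorField, pair: EndmemberPair) -> FractionMap:
    """Decompose each pixel phasor into fractions of two endmembers.

    The pixel phasor P is orthogonally projected onto the segment AB;
    f_A = |P' - B| / |A - B| (clipped to [0, 1]).  The perpendicular distance
    |P - P'| is reported per pixel: large residuals flag pixels that are not a
    two-species mixture (a third fluorophore, background) rather than being
    silently dropped.
    """
    a = np.array(pair.a)
    b = np.array(pair.b)
    ab = a - b
    denom = ab @ ab
    p = np.stack([field_in.g, field_in.s], axis=-1)
    t = (p - b) @ ab / denom          # unclipped projection coordinate
    proj = b + t[..., None] * ab
    residual = np.linalg.norm(p - proj, axis=-1)
    f_a = np.clip(t, 0.0, 1.0)
    f_a = np.where(field_in.mask, f_a, np.nan)
    residual = np.where(field_in.mask, residual, np.nan)
    return FractionMap(f_a=f_a, residual=residual, pair=pair)


# ---------------------------------------------------------------------------
# Two-exponential decay fit
# ---------------------------------------------------------------------------


@dataclass
class ExponentialFit:
    """Result of a biexponential fit a1*exp(-t/tau1) + a2*exp(-t/tau2).

    ``a1 + a2 = 1`` and ``tau1 <= tau2``.  ``tau_avg_intensity`` is the
    intensity-weighted average lifetime (a1*tau1^2 + a2*tau2^2) /
    (a1*tau1 + a2*tau2) reported alongside phasor positions for comparison
    with conventional fitting.
    """

    tau1_ns: float
    tau2_ns: float
    a1: float
    a2: float
    tau_avg_intensity_ns: float
    residual_norm: float

    @staticmethod
    def intensity_weighted_lifetime(
        taus: Sequence[float], amps: Sequence[float]
    ) -> float:
        taus = np.asarray(taus, dtype=float)
        amps = np.asarray(amps, dtype=float)
        return float((amps * taus**2).sum() / (amps * taus).sum())


_DEFAULT_STARTS: tuple[tuple[float, float], ...] = ((0.3, 2.0), (0.5, 3.0), (1.0, 4.0))


def fit_two_exponential(
    decay: DecayHistogram,
    starts: Sequence[tuple[float, float]] = _DEFAULT_STARTS,
) -> ExponentialFit:
    """Least-squares biexponential fit of a decay histogram.

    The model is the periodically wrapped, bin-integrated expectation of
    a1*exp(-t/tau1) + (1-a1)*exp(-t/tau2) scaled to the fitted amplitude.
    Several (tau1, tau2) starts are tried; the best residual wins, ties broken
    by the smaller tau1, so the result is deterministic.
    """
    counts = decay.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot fit an empty decay")
    n = counts.shape[0]
    period = decay.period_ns

    def model(params: np.ndarray) -> np.ndarray:
        tau1, tau2, a1, scale = params
        frac = wrapped_decay_expectation(
            [(tau1, a1), (tau2, 1.0 - a1)], n, period
        )
        return scale * frac

    def resid(params: np.ndarray) -> np.ndarray:
        return model(params) - counts

    best = None
    for tau1_0, tau2_0 in starts:
        try:
            res = least_squares(
                resid,
                x0=np.array([tau1_0, tau2_0, 0.5, total]),
                bounds=([1e-3, 1e-3, 0.0, 0.0], [50.0, 50.0, 1.0, np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if not res.success:
            continue
        cost = res.cost
        tau1 = min(res.x[0], res.x[1])
        if best is None or cost < best[0] - 1e-12 or (
            abs(cost - best[0]) <= 1e-12 and tau1 < best[1]
        ):
            best = (cost, tau1, res)
    if best is None:
        raise FitError("two-exponential fit did not converge from any start")
    res = best[2]
    tau1, tau2, a1, _ = res.x
    a2 = 1.0 - a1
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
    tau_avg = ExponentialFit.intensity_weighted_lifetime([tau1, tau2], [a1, a2])
    return ExponentialFit(
        tau1_ns=float(tau1),
        tau2_ns=float(tau2),
        a1=float(a1),
        a2=float(a2),
        tau_avg_intensity_ns=float(tau_avg),
        residual_norm=float(np.linalg.norm(res.fun)),
    )
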