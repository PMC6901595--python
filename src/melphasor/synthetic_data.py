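"""Synthetic melanocyte image generator with known ground truth.

Generates time-resolved (FLIM) and 32-channel spectral image stacks that
emulate heterogeneously pigmented choroidal melanocytes on a tissue
background, so the whole phasor pipeline can be exercised against a known
per-pixel answer.  Two melanin endmembers are mixed pixel by pixel:

* eumelanin-like - short lifetime (intensity-averaged ~1.3 ns), red-shifted
  emission peaking at 610 nm (the dark-hair / dark-cell signature);
* pheomelanin-like - longer lifetime (~2.1 ns), blue-shifted emission peaking
  at 589 nm (the red-hair / light-cell signature).

Decays are periodically wrapped at the 80 MHz repetition rate (a multi-ns
decay does not finish between pulses), spectra are channel-integrated
Gaussians on the 410-696 nm axis, mixing is by photon (intensity) fraction -
which is what phasor decomposition recovers - and noise is Poisson per bin.
Optional confounder species (free/bound NADH-like, collagen/elastin-like ECM,
heme-like porphyrin) can populate the background.  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erf

from .flim_phasor import DecayHistogram, FLIMStack, wrapped_decay_expectation
from .spectral_phasor import SpectralStack, SpectrumVector

__all__ = [
    "EndmemberSpec",
    "AcquisitionConfig",
    "SceneLayout",
    "GroundTruth",
    "EUMELANIN",
    "PHEOMELANIN",
    "NADH_LIKE",
    "ECM_LIKE",
    "HEME_LIKE",
    "expected_decay_fractions",
    "expected_spectrum_fractions",
    "generate_decay",
    "generate_spectrum",
    "generate_flim_stack",
    "generate_spectral_stack",
    "make_melanocyte_layout",
    "make_ramp_layout",
    "make_uniform_layout",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndmemberSpec:
    """A pure fluorophore species.

    ``lifetime_components`` are (tau_ns, amplitude) pairs of a
    multi-exponential decay; amplitudes are pre-exponential fractions summing
    to 1.  ``brightness`` is the mean expected photons per pixel this species
    contributes where it is present.
    """

    name: str
    lifetime_components: tuple[tuple[float, float], ...]
    spectrum_peak_nm: float
    spectrum_fwhm_nm: float
    brightness: float = 1000.0

    def __post_init__(self) -> None:
        taus = [t for t, _ in self.lifetime_components]
        amps = [a for _, a in self.lifetime_components]
        if any(t <= 0 for t in taus):
            raise ValueError(f"{self.name}: lifetimes must be positive")
        if any(a <= 0 for a in amps) or not math.isclose(sum(amps), 1.0, rel_tol=1e-9):
            raise ValueError(f"{self.name}: amplitudes must be positive and sum to 1")
        if self.spectrum_fwhm_nm < 0:
            raise ValueError(f"{self.name}: spectral width must be non-negative")
        if self.brightness < 0:
            raise ValueError(f"{self.name}: brightness must be non-negative")

    @property
    def tau_avg_intensity_ns(self) -> float:
        taus = np.array([t for t, _ in self.lifetime_components])
        amps = np.array([a for _, a in self.lifetime_components])
        return float((amps * taus**2).sum() / (amps * taus).sum())


# Amplitudes below are solved so the intensity-weighted average lifetimes hit
# the melanocyte values (1.3 ns dark/eumelanin-rich, 2.1 ns light/
# pheomelanin-rich); the hair-cortex counterparts are 1.7 and 2.4 ns.
EUMELANIN = EndmemberSpec(
    name="eumelanin",
    lifetime_components=((0.5, 0.8824), (2.5, 0.1176)),  # tau_avg ~ 1.3 ns
    spectrum_peak_nm=610.0,
    spectrum_fwhm_nm=60.0,
    brightness=2000.0,
)

PHEOMELANIN = EndmemberSpec(
    name="pheomelanin",
    lifetime_components=((1.0, 0.7105), (3.0, 0.2895)),  # tau_avg ~ 2.1 ns
    spectrum_peak_nm=589.0,
    spectrum_fwhm_nm=60.0,
    brightness=1200.0,
)

# Confounders are illustrative profiles of the background fluorophores a
# choroid field contains; their decay/spectral positions are distinct from
# the melanin chord so separation is testable.
NADH_LIKE = EndmemberSpec(
    name="nadh",
    lifetime_components=((0.4, 0.75), (3.4, 0.25)),
    spectrum_peak_nm=460.0,
    spectrum_fwhm_nm=70.0,
    brightness=150.0,
)

ECM_LIKE = EndmemberSpec(
    name="ecm",
    lifetime_components=((0.3, 0.5), (1.8, 0.5)),
    spectrum_peak_nm=490.0,
    spectrum_fwhm_nm=90.0,
    brightness=120.0,
)

HEME_LIKE = EndmemberSpec(
    name="heme",
    lifetime_components=((0.2, 0.9), (1.2, 0.1)),
    spectrum_peak_nm=612.0,
    spectrum_fwhm_nm=30.0,
    brightness=300.0,
)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry shared by the FLIM and spectral modalities.

    The time axis always spans exactly one laser period, so
    ``bin_width = 1 / (rep_rate * n_time_bins)`` by construction.
    """

    rep_rate_hz: float = 80e6
    n_time_bins: int = 256
    image_shape: tuple[int, int] = (128, 128)
    lambda_min_nm: float = 410.0
    lambda_max_nm: float = 696.0
    n_channels: int = 32
    channel_width_nm: float = 8.9
    harmonic: int = 1
    irf_fwhm_ps: float = 0.0

    def __post_init__(self) -> None:
        if self.rep_rate_hz <= 0 or self.n_time_bins < 2:
            raise ValueError("need a positive rep rate and >= 2 time bins")
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        if self.irf_fwhm_ps < 0:
            raise ValueError("IRF width must be non-negative")
        span = self.lambda_max_nm - self.lambda_min_nm
        if self.n_channels * self.channel_width_nm < span - self.channel_width_nm:
            raise ValueError(
                "n_channels x channel_width must span the wavelength range "
                "within one channel width"
            )

    @property
    def period_ns(self) -> float:
        return 1e9 / self.rep_rate_hz

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_time_bins

    @property
    def omega_ns(self) -> float:
        return 2.0 * math.pi * self.rep_rate_hz * 1e-9

    @property
    def channel_centers_nm(self) -> np.ndarray:
        return self.lambda_min_nm + (np.arange(self.n_channels) + 0.5) * (
            self.channel_width_nm
        )


# ---------------------------------------------------------------------------
# Expectations (noiseless building blocks; exposed for tests)
# ---------------------------------------------------------------------------


def expected_decay_fractions(spec: EndmemberSpec, acq: AcquisitionConfig) -> np.ndarray:
    """Expected fraction of a species' photons per time bin (sums to 1)."""
    return wrapped_decay_expectation(
        spec.lifetime_components,
        acq.n_time_bins,
        acq.period_ns,
        irf_fwhm_ns=acq.irf_fwhm_ps * 1e-3,
    )


def expected_spectrum_fractions(
    spec: EndmemberSpec, acq: AcquisitionConfig
) -> np.ndarray:
    """Expected fraction of a species' photons per spectral channel.

    Gaussian emission profile integrated over each 8.9 nm channel (exact erf
    differences) and renormalized over the detector range; a zero-width
    profile degenerates to a delta in the channel containing the peak.
    """
    if not acq.lambda_min_nm <= spec.spectrum_peak_nm <= acq.lambda_max_nm:
        raise ValueError(
            f"{spec.name}: spectrum peak {spec.spectrum_peak_nm} nm outside "
            f"[{acq.lambda_min_nm}, {acq.lambda_max_nm}] nm"
        )
    edges = acq.lambda_min_nm + np.arange(acq.n_channels + 1) * acq.channel_width_nm
    if spec.spectrum_fwhm_nm == 0.0:
        out = np.zeros(acq.n_channels)
        c = int(
            np.clip(
                (spec.spectrum_peak_nm - acq.lambda_min_nm) // acq.channel_width_nm,
                0,
                acq.n_channels - 1,
            )
        )
        out[c] = 1.0
        return out
    sigma = spec.spectrum_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    z = (edges - spec.spectrum_peak_nm) / (sigma * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    out = np.diff(cdf)
    return out / out.sum()


def _validate_mixture(
    endmembers: Sequence[tuple[EndmemberSpec, float]], total_photons: float
) -> None:
    fracs = [f for _, f in endmembers]
    if any(f < 0 for f in fracs):
        raise ValueError("photon fractions must be non-negative")
    if not math.isclose(sum(fracs), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("photon fractions must sum to 1")
    if total_photons < 0:
        raise ValueError("total_photons must be non-negative")


def _rng(seed: int) -> np.random.Generator:
    # counter-based bit generator: reproducible regardless of draw order
    return np.random.Generator(np.random.Philox(seed))


# ---------------------------------------------------------------------------
# Single-pixel generators
# ---------------------------------------------------------------------------


def generate_decay(
    endmembers: Sequence[tuple[EndmemberSpec, float]],
    total_photons: float,
    acq: AcquisitionConfig,
    seed: int,
    noiseless: bool = False,
) -> DecayHistogram:
    """Simulate one TCSPC decay histogram for a photon-fraction mixture.

    The mixture decay is the photon-fraction-weighted sum of the component
    decays (phasors of mixtures are sums of the independent phasors); counts
    are Poisson per bin unless ``noiseless`` asks for the expectation.
    """
    _validate_mixture(endmembers, total_photons)
    expect = np.zeros(acq.n_time_bins)
    for spec, frac in endmembers:
        if frac > 0:
            expect += frac * expected_decay_fractions(spec, acq)
    expect *= total_photons
    counts = expect if noiseless else _rng(seed).poisson(expect)
    return DecayHistogram(
        counts=counts, bin_width_ns=acq.bin_width_ns, rep_rate_hz=acq.rep_rate_hz
    )


def generate_spectrum(
    endmembers: Sequence[tuple[EndmemberSpec, float]],
    total_photons: float,
    acq: AcquisitionConfig,
    seed: int,
    noiseless: bool = False,
) -> SpectrumVector:
    """Simulate one 32-channel emission spectrum for an intensity mixture."""
    _validate_mixture(endmembers, total_photons)
    expect = np.zeros(acq.n_channels)
    for spec, frac in endmembers:
        if frac > 0:
            expect += frac * expected_spectrum_fractions(spec, acq)
    expect *= total_photons
    counts = expect if noiseless else _rng(seed).poisson(expect)
    return SpectrumVector(
        counts=counts,
        lambda_min_nm=acq.lambda_min_nm,
        lambda_max_nm=acq.lambda_max_nm,
        channel_width_nm=acq.channel_width_nm,
        harmonic=acq.harmonic,
    )


# ---------------------------------------------------------------------------
# Scene layouts
# ---------------------------------------------------------------------------


@dataclass
class SceneLayout:
    """Where the melanin is and how it is mixed.

    ``cell_masks`` labels melanocytes (0 = background tissue); ``f_eu`` is the
    per-pixel eumelanin photon fraction in [0, 1]; ``melanin_photons`` is the
    expected melanin photon budget per pixel (granules bright, soma dim,
    nucleus/background zero); ``granules`` lists melanosome disks
    (row, col, radius); ``background_species`` emit from background pixels.
    """

    cell_masks: np.ndarray
    f_eu: np.ndarray
    melanin_photons: np.ndarray
    granules: tuple[tuple[int, int, float], ...] = ()
    background_species: tuple[EndmemberSpec, ...] = ()

    def __post_init__(self) -> None:
        self.cell_masks = np.asarray(self.cell_masks)
        self.f_eu = np.asarray(self.f_eu, dtype=float)
        self.melanin_photons = np.asarray(self.melanin_photons, dtype=float)
        if not (
            self.cell_masks.shape == self.f_eu.shape == self.melanin_photons.shape
        ):
            raise ValueError("layout grids must share one shape")
        if np.any((self.f_eu < 0) | (self.f_eu > 1)):
            raise ValueError("f_eu must lie in [0, 1] everywhere")
        if np.any(self.melanin_photons < 0):
            raise ValueError("photon budgets must be non-negative")
        for r, c, _ in self.granules:
            if not (
                0 <= r < self.cell_masks.shape[0]
                and 0 <= c < self.cell_masks.shape[1]
            ) or self.cell_masks[r, c] == 0:
                raise ValueError("granules must lie inside a parent cell mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_masks.shape


@dataclass
class GroundTruth:
    """Known per-pixel answers for a generated scene."""

    fraction: np.ndarray        # eumelanin photon fraction f_eu
    species: np.ndarray         # 0 none, 1 melanin, 2+ background species
    expected_photons: np.ndarray
    seed: int


def _disk(shape: tuple[int, int], r0: float, c0: float, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def make_melanocyte_layout(
    shape: tuple[int, int] = (128, 128),
    n_cells: int = 4,
    seed: int = 0,
    f_eu_values: Sequence[float] | None = None,
    granules_per_cell: int = 45,
    granule_radius_px: tuple[float, float] = (1.0, 2.0),
    granule_photons: float = 4000.0,
    soma_photons: float = 200.0,
    background_species: Sequence[EndmemberSpec] = (),
) -> SceneLayout:
    """Lay out melanocytes with perinuclear and peripheral melanosomes.

    Each cell is a soma disk with a nucleus void; melanosome granules cluster
    densely in a perinuclear ring and sparsely along peripheral processes
    radiating from the soma, mirroring how pigment maps in cultured
    melanocytes.  Granule size and density are illustrative defaults (no
    published statistics constrain them) and fully configurable.  The
    eumelanin fraction is constant within a cell: one value per cell, spread
    evenly over [0.1, 0.9] unless ``f_eu_values`` is given.
    """
    rng = _rng(seed + 1_000_003)
    rows, cols = shape
    masks = np.zeros(shape, dtype=np.int32)
    f_map = np.zeros(shape, dtype=float)
    photons = np.zeros(shape, dtype=float)
    granules: list[tuple[int, int, float]] = []
    if f_eu_values is None:
        f_eu_values = np.linspace(0.1, 0.9, n_cells)
    if len(f_eu_values) != n_cells:
        raise ValueError("need one f_eu value per cell")

    # soma size scales down with the field of view so small test scenes fit
    soma_cap = min(14.0, max(3.0, min(rows, cols) / 5.0))
    for i in range(n_cells):
        soma_r = rng.uniform(0.75 * soma_cap, soma_cap)
        r0 = rng.uniform(soma_r + 1, rows - soma_r - 1)
        c0 = rng.uniform(soma_r + 1, cols - soma_r - 1)
        nucleus_r = soma_r * 0.4
        soma = _disk(shape, r0, c0, soma_r)
        nucleus = _disk(shape, r0, c0, nucleus_r)
        cell = soma.copy()
        # peripheral processes: thin rays outward from the soma
        for _ in range(rng.integers(2, 5)):
            ang = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(0.9, 1.8) * soma_cap
            for step in np.linspace(0, length, int(length * 2)):
                pr = int(round(r0 + (soma_r + step) * math.sin(ang)))
                pc = int(round(c0 + (soma_r + step) * math.cos(ang)))
                if 0 <= pr < rows and 0 <= pc < cols:
                    cell |= _disk(shape, pr, pc, 1.5)
        masks[cell & (masks == 0)] = i + 1
        this_cell = masks == i + 1
        f_map[this_cell] = f_eu_values[i]
        photons[this_cell & soma & ~nucleus] = soma_photons

        # granules: ~2/3 perinuclear, the rest scattered over the cell
        n_peri = int(granules_per_cell * 2 / 3)
        cell_pix = np.argwhere(this_cell)
        for k in range(granules_per_cell):
            if k < n_peri:
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(nucleus_r + 1, nucleus_r + 4)
                gr = int(round(r0 + rad * math.sin(ang)))
                gc = int(round(c0 + rad * math.cos(ang)))
            else:
                gr, gc = cell_pix[rng.integers(len(cell_pix))]
            if not (0 <= gr < rows and 0 <= gc < cols) or masks[gr, gc] != i + 1:
                continue
            g_rad = rng.uniform(*granule_radius_px)
            spot = _disk(shape, gr, gc, g_rad) & this_cell & ~nucleus
            photons[spot] = granule_photons
            granules.append((int(gr), int(gc), float(g_rad)))

    return SceneLayout(
        cell_masks=masks,
        f_eu=f_map,
        melanin_photons=photons,
        granules=tuple(granules),
        background_species=tuple(background_species),
    )


def make_ramp_layout(
    shape: tuple[int, int] = (64, 64),
    photons_per_pixel: float = 5000.0,
    background_species: Sequence[EndmemberSpec] = (),
) -> SceneLayout:
    """One flat cell whose eumelanin fraction ramps 0 -> 1 across columns."""
    rows, cols = shape
    f_map = np.tile(np.linspace(0.0, 1.0, cols), (rows, 1))
    return SceneLayout(
        cell_masks=np.ones(shape, dtype=np.int32),
        f_eu=f_map,
        melanin_photons=np.full(shape, float(photons_per_pixel)),
        background_species=tuple(background_species),
    )


def make_uniform_layout(
    shape: tuple[int, int],
    f_eu: float,
    photons_per_pixel: float,
    background_species: Sequence[EndmemberSpec] = (),
) -> SceneLayout:
    """A flat field with one mixing fraction everywhere."""
    return SceneLayout(
        cell_masks=np.ones(shape, dtype=np.int32),
        f_eu=np.full(shape, float(f_eu)),
        melanin_photons=np.full(shape, float(photons_per_pixel)),
        background_species=tuple(background_species),
    )


# ---------------------------------------------------------------------------
# Stack generators
# ---------------------------------------------------------------------------


def _scene_expectation(
    layout: SceneLayout,
    end_a: EndmemberSpec,
    end_b: EndmemberSpec,
    acq: AcquisitionConfig,
    per_species_profile,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected counts (rows, cols, bins) and species label map."""
    if layout.shape != acq.image_shape:
        raise ValueError(
            f"layout shape {layout.shape} != acquisition shape {acq.image_shape}"
        )
    p_a = per_species_profile(end_a, acq)
    p_b = per_species_profile(end_b, acq)
    f = layout.f_eu[..., None]
    mel = layout.melanin_photons[..., None]
    expect = mel * (f * p_a + (1.0 - f) * p_b)
    species = np.where(layout.melanin_photons > 0, 1, 0).astype(np.int32)
    bg = layout.cell_masks == 0
    for i, spec in enumerate(layout.background_species):
        p_bg = per_species_profile(spec, acq)
        expect[bg] += spec.brightness * p_bg
        species[bg & (species == 0)] = 2 + i
    return expect, species


def generate_flim_stack(
    layout: SceneLayout,
    end_a: EndmemberSpec,
    end_b: EndmemberSpec,
    acq: AcquisitionConfig,
    seed: int,
    noiseless: bool = False,
) -> tuple[FLIMStack, GroundTruth]:
    """Assemble a per-pixel FLIM stack from a scene layout.

    Pixels outside cells and granules carry only background-species photons;
    the ground-truth fraction map is the layout's f_eu.
    """
    expect, species = _scene_expectation(
        layout, end_a, end_b, acq, expected_decay_fractions
    )
    counts = expect if noiseless else _rng(seed).poisson(expect).astype(np.uint32)
    stack = FLIMStack(
        counts=counts, bin_width_ns=acq.bin_width_ns, rep_rate_hz=acq.rep_rate_hz
    )
    gt = GroundTruth(
        fraction=layout.f_eu.copy(),
        species=species,
        expected_photons=expect.sum(axis=2),
        seed=seed,
    )
    return stack, gt


def generate_spectral_stack(
    layout: SceneLayout,
    end_a: EndmemberSpec,
    end_b: EndmemberSpec,
    acq: AcquisitionConfig,
    seed: int,
    noiseless: bool = False,
    snr_scale: float = 1.0,
) -> tuple[SpectralStack, GroundTruth]:
    """Spectral twin of :func:`generate_flim_stack` (same layout, same f_eu).

    ``snr_scale < 1`` emulates the poorer photon budget of descanned spectral
    detection by scaling every pixel's expected counts.
    """
    if not 0 < snr_scale <= 1:
        raise ValueError("snr_scale must lie in (0, 1]")
    expect, species = _scene_expectation(
        layout, end_a, end_b, acq, expected_spectrum_fractions
    )
    expect = expect * snr_scale
    counts = expect if noiseless else _rng(seed).poisson(expect).astype(np.uint32)
    stack = SpectralStack(
        counts=counts,
        lambda_min_nm=acq.lambda_min_nm,
        lambda_max_nm=acq.lambda_max_nm,
        channel_width_nm=acq.channel_width_nm,
        harmonic=acq.harmonic,
    )
    gt = GroundTruth(
        fraction=layout.f_eu.copy(),
        species=species,
        expected_photons=expect.sum(axis=2),
        seed=seed,
    )
    return stack, gt
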