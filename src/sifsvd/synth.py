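"""Synthetic top-of-atmosphere (TOA) spectra for far-red SIF retrieval.

This module emulates what a grating spectrometer sees in the O2-A channel
(758–778 nm at 0.044 nm sampling): a smooth solar continuum carved by narrow
Fraunhofer-analogue absorption lines, scaled by a spectrally smooth effective
surface reflectance and the cosine of the solar zenith angle, plus an additive
chlorophyll-fluorescence term with a Gaussian emission shape peaking near
740 nm, and per-channel Gaussian sensor noise scaled by a signal-to-noise
model.  The noiseless radiance follows the Lambertian TOA model

    L(lambda) = rho(lambda)/pi * I_sc(lambda) * mu0 * A(lambda)
                + Fs * h_F(lambda) * A(lambda)

where ``A`` is an optional O2-like ground-to-sensor transmittance stand-in
(identically 1 by default, i.e. a Fraunhofer-only window).  Path reflectance,
spherical albedo and two-way transmittance are spectrally smooth in such a
window and are deliberately collapsed into the single effective-reflectance
polynomial: the retrieval cannot identify them separately, so the simulator
does not pretend to.

Instrument line-shape convolution is folded into the widths of the absorption
lines rather than applied as a separate convolution stage; the retrieval never
inverts the line shape, so an explicit ISRF operator would add nothing
testable.

All random draws take one explicit integer seed per operation; there is no
global random state anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("sifsvd.synth")

DEFAULT_SAMPLING_NM = 0.044
DEFAULT_GRID_BOUNDS = (758.0, 778.0)
DEFAULT_WINDOW = (771.0, 778.0)

#: Fraunhofer-analogue absorption lines (center nm, depth fraction, width nm).
#: Centers are spread over the O2-A channel with several lines inside the
#: 771–778 nm retrieval window; the 768.3–771.7 nm region is kept line-free so
#: that the optional O2-like contamination (see :func:`o2_absorption_shape`)
#: is the only structure there.
DEFAULT_FRAUNHOFER_LINES: tuple[tuple[float, float, float], ...] = (
    (758.8, 0.35, 0.07),
    (759.9, 0.22, 0.06),
    (761.2, 0.55, 0.09),
    (762.6, 0.18, 0.05),
    (763.9, 0.40, 0.08),
    (765.4, 0.28, 0.06),
    (766.7, 0.50, 0.10),
    (768.2, 0.15, 0.05),
    (771.8, 0.45, 0.08),
    (772.9, 0.30, 0.06),
    (773.8, 0.55, 0.09),
    (774.9, 0.20, 0.05),
    (775.9, 0.38, 0.07),
    (776.8, 0.25, 0.06),
    (777.5, 0.48, 0.08),
)

#: Narrow O2-like absorption lines confined to 769.2–770.7 nm, used as a
#: stand-in for unmodelled ground-to-sensor transmittance when a retrieval
#: window reaches below 771 nm.  (center nm, relative depth, width nm).
_O2_LINES: tuple[tuple[float, float, float], ...] = (
    (769.25, 0.80, 0.05),
    (769.55, 1.00, 0.05),
    (769.85, 0.95, 0.05),
    (770.15, 0.90, 0.05),
    (770.45, 0.75, 0.04),
    (770.70, 0.60, 0.04),
)


def _polyval_hat(coeffs: Sequence[float], lam_hat: np.ndarray) -> np.ndarray:
    """Evaluate a polynomial with ascending-order coefficients on lam_hat."""
    return np.polynomial.polynomial.polyval(lam_hat, np.asarray(coeffs, dtype=float))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SpectralGrid:
    """A strictly increasing wavelength axis shared by all spectra of a run.

    Parameters
    ----------
    wavelengths
        Channel-center wavelengths in nm, strictly increasing.
    sampling_step
        Nominal channel spacing in nm (0.044 nm for the O2-A channel).
    """

    wavelengths: np.ndarray
    sampling_step: float = DEFAULT_SAMPLING_NM

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength axis must be 1-D with at least 2 channels")
        if not np.all(np.diff(wl) > 0):
            bad = int(np.argmin(np.diff(wl)))
            raise ValueError(
                f"wavelengths must be strictly increasing (violation at index {bad}: "
                f"{wl[bad]:.6g} -> {wl[bad + 1]:.6g})"
            )
        object.__setattr__(self, "wavelengths", wl)
        if not self.sampling_step > 0:
            raise ValueError("sampling_step must be > 0")

    @classmethod
    def regular(
        cls,
        lo: float = DEFAULT_GRID_BOUNDS[0],
        hi: float = DEFAULT_GRID_BOUNDS[1],
        step: float = DEFAULT_SAMPLING_NM,
    ) -> "SpectralGrid":
        """Regular grid covering [lo, hi) at the given step (default 455 channels)."""
        n = int(round((hi - lo) / step))
        return cls(lo + step * np.arange(n), sampling_step=step)

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths.size)

    def normalized(self) -> np.ndarray:
        """Wavelengths mapped affinely to [-1/2, 1/2] over the grid extent."""
        wl = self.wavelengths
        return (wl - 0.5 * (wl[0] + wl[-1])) / (wl[-1] - wl[0])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with center in the half-open window [lo, hi)."""
        if not lo < hi:
            raise ValueError(f"window must satisfy lo < hi, got ({lo}, {hi})")
        return (self.wavelengths >= lo) & (self.wavelengths < hi)


@dataclasses.dataclass(frozen=True)
class SolarModel:
    """Smooth solar continuum with narrow absorption lines.

    ``continuum_coeffs`` are ascending polynomial coefficients in the
    normalized grid coordinate (see :meth:`SpectralGrid.normalized`), in
    radiance units (mW m-2 sr-1 nm-1 scale by default).  ``lines`` is a
    sequence of ``(center_nm, depth_fraction, width_nm)`` with depth in
    [0, 1) and width > 0.
    """

    continuum_coeffs: tuple[float, ...] = (1200.0, -60.0)
    lines: tuple[tuple[float, float, float], ...] = DEFAULT_FRAUNHOFER_LINES
    seed: int = 0

    def __post_init__(self) -> None:
        for center, depth, width in self.lines:
            if not (0.0 <= depth < 1.0):
                raise ValueError(f"line depth must be in [0, 1), got {depth} at {center} nm")
            if not width > 0:
                raise ValueError(f"line width must be > 0, got {width} at {center} nm")


@dataclasses.dataclass(frozen=True)
class SNRModel:
    """Per-channel signal-to-noise ratio, affine in radiance: SNR = offset + slope*L.

    The instrument noise model of the source data is not public; a constant
    SNR (slope = 0) is the configurable placeholder default.
    """

    offset: float = 300.0
    slope: float = 0.0

    def at(self, radiance: np.ndarray | float) -> np.ndarray:
        snr = self.offset + self.slope * np.asarray(radiance, dtype=float)
        if np.any(snr <= 0):
            raise ValueError("SNR model evaluates to a non-positive value")
        return snr


@dataclasses.dataclass(frozen=True)
class SceneTruth:
    """Ground-truth parameters of one simulated sounding.

    ``reflectance_coeffs`` are ascending polynomial coefficients of the
    effective surface reflectance in the normalized grid coordinate (values
    must stay within [0, 1] on the grid).  ``line_scale`` multiplies every
    Fraunhofer-analogue line depth; ``shift_nm`` and ``width_scale`` displace
    and widen the lines, standing in for the spectral-calibration / Doppler
    and instrument line-shape variability that gives real archives their
    high-frequency scene-to-scene structure.  ``o2_depth`` scales the O2-like
    absorption stand-in; 0 means a Fraunhofer-only window with
    ground-to-sensor transmittance identically 1.
    """

    reflectance_coeffs: tuple[float, ...] = (0.3,)
    mu0: float = 0.7
    fs_true: float = 0.8
    sigma_f: float = 30.0
    phi: float = 1.0
    center_f: float = 740.0
    o2_depth: float = 0.0
    line_scale: float = 1.0
    shift_nm: float = 0.0
    width_scale: float = 1.0
    snr: SNRModel = dataclasses.field(default_factory=SNRModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs_true >= 0:
            raise ValueError("fs_true must be >= 0")
        if not (0.0 < self.mu0 <= 1.0):
            raise ValueError("mu0 must be in (0, 1]")
        if not (0.0 <= self.o2_depth < 1.0):
            raise ValueError("o2_depth must be in [0, 1)")
        if not self.sigma_f > 0:
            raise ValueError("sigma_f must be > 0")
        if not self.phi > 0:
            raise ValueError("phi must be > 0")
        if not self.line_scale >= 0:
            raise ValueError("line_scale must be >= 0")
        if not self.width_scale > 0:
            raise ValueError("width_scale must be > 0")


@dataclasses.dataclass
class SceneSet:
    """A batch of simulated soundings sharing one grid and SNR model.

    ``spectra`` has shape (n_scenes, n_channels); ``fs_true`` holds the
    generating fluorescence amplitude per scene.  ``truths`` carries the full
    per-scene parameters where the generator had them (None for scenes built
    directly from basis patterns).
    """

    grid: SpectralGrid
    spectra: np.ndarray
    fs_true: np.ndarray
    snr: SNRModel | None = None
    truths: list[SceneTruth] | None = None

    def __len__(self) -> int:
        return int(self.spectra.shape[0])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def line_transmittance(
    wavelengths: np.ndarray,
    lines: Sequence[tuple[float, float, float]],
    depth_scale: float = 1.0,
    shift_nm: float = 0.0,
    width_scale: float = 1.0,
) -> np.ndarray:
    """Product of Gaussian absorption-line profiles, each 1 - d*exp(...).

    ``depth_scale`` multiplies every line depth; ``shift_nm`` displaces every
    line center (Doppler / spectral-calibration stand-in); ``width_scale``
    multiplies every line width (instrument line-shape stand-in).
    """
    if not width_scale > 0:
        raise ValueError("width_scale must be > 0")
    t = np.ones_like(wavelengths, dtype=float)
    for center, depth, width in lines:
        d = depth * depth_scale
        if not (0.0 <= d < 1.0):
            raise ValueError(
                f"scaled line depth must stay in [0, 1), got {d:.4g} at {center} nm"
            )
        w = width * width_scale
        t *= 1.0 - d * np.exp(-0.5 * ((wavelengths - center - shift_nm) / w) ** 2)
    return t


def make_solar_irradiance(
    grid: SpectralGrid,
    model: SolarModel,
    depth_scale: float = 1.0,
    shift_nm: float = 0.0,
    width_scale: float = 1.0,
) -> np.ndarray:
    """Solar irradiance on the grid: smooth continuum times line transmittances.

    Raises ``ValueError`` if the continuum is not strictly positive anywhere
    on the grid.
    """
    continuum = _polyval_hat(model.continuum_coeffs, grid.normalized())
    if np.any(continuum <= 0):
        raise ValueError("solar continuum must be strictly positive over the grid")
    return continuum * line_transmittance(
        grid.wavelengths, model.lines, depth_scale, shift_nm, width_scale
    )


def o2_absorption_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Unit-peak O2-like absorption shape confined to 769.2–770.7 nm."""
    shape = np.zeros_like(wavelengths, dtype=float)
    for center, depth, width in _O2_LINES:
        shape += depth * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    peak = shape.max()
    if peak > 0:
        shape /= peak
    return shape


def simulate_toa_radiance(
    grid: SpectralGrid, solar: SolarModel, truth: SceneTruth
) -> tuple[np.ndarray, SceneTruth]:
    """Noiseless TOA radiance for one sounding; echoes the truth used.

    Reflected term rho/pi * I_sc * mu0 plus additive fluorescence
    Fs * h_F(lambda; sigma, phi), both multiplied by the O2-like
    transmittance stand-in A(lambda) = 1 - o2_depth * shape (A = 1 by
    default).
    """
    from .forward import gaussian_hf  # local import to avoid a module cycle

    refl = _polyval_hat(truth.reflectance_coeffs, grid.normalized())
    if np.any(refl < 0) or np.any(refl > 1):
        raise ValueError("reflectance polynomial must stay within [0, 1] on the grid")
    isc = make_solar_irradiance(
        grid,
        solar,
        depth_scale=truth.line_scale,
        shift_nm=truth.shift_nm,
        width_scale=truth.width_scale,
    )
    absorption = 1.0 - truth.o2_depth * o2_absorption_shape(grid.wavelengths)
    hf = gaussian_hf(grid.wavelengths, truth.sigma_f, truth.phi, truth.center_f)
    radiance = (refl / np.pi * isc * truth.mu0 + truth.fs_true * hf) * absorption
    if np.any(radiance < 0):
        raise ValueError("simulated radiance is negative; scene configuration inconsistent")
    return radiance, truth


def add_noise(
    spectrum: np.ndarray, snr_model: SNRModel, seed: int
) -> np.ndarray:
    """Add zero-mean Gaussian noise with per-channel std L/SNR (Eq. un = L/SNR).

    A pure function of (spectrum, snr_model, seed).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    sigma = np.abs(spectrum) / snr_model.at(spectrum)
    rng = np.random.default_rng(seed)
    return spectrum + rng.normal(0.0, 1.0, size=spectrum.shape) * sigma


def default_reflectance_sampler(rng: np.random.Generator) -> tuple[float, ...]:
    """Quadratic effective-reflectance coefficients typical of soil/water scenes."""
    return (
        float(rng.uniform(0.10, 0.55)),
        float(rng.uniform(-0.08, 0.08)),
        float(rng.uniform(-0.04, 0.04)),
    )


def make_training_set(
    grid: SpectralGrid,
    solar: SolarModel,
    n_scenes: int,
    reflectance_sampler: Callable[[np.random.Generator], tuple[float, ...]] | None = None,
    seed: int = 0,
    snr: SNRModel | None = SNRModel(),
    mu0_range: tuple[float, float] = (0.3, 0.9),
    shift_range: tuple[float, float] = (-0.01, 0.01),
    width_scale_range: tuple[float, float] = (0.92, 1.08),
) -> np.ndarray:
    """Matrix of ``n_scenes`` non-fluorescent spectra (rows) on the grid.

    Every row is :func:`simulate_toa_radiance` with ``fs_true = 0`` and a
    reflectance drawn from the sampler; geometry (mu0), spectral shift and
    line width vary scene to scene.  ``snr=None`` yields noiseless rows.  A
    single-scene training set is rejected: the SVD of one spectrum cannot
    separate shape from variation.
    """
    if n_scenes < 2:
        raise ValueError("a training set needs n_scenes >= 2")
    sampler = reflectance_sampler or default_reflectance_sampler
    rng = np.random.default_rng(seed)
    rows = np.empty((n_scenes, grid.n_channels))
    coeff_draws = []
    for i in range(n_scenes):
        coeffs = tuple(sampler(rng))
        coeff_draws.append(coeffs)
        truth = SceneTruth(
            reflectance_coeffs=coeffs,
            mu0=float(rng.uniform(*mu0_range)),
            fs_true=0.0,
            shift_nm=float(rng.uniform(*shift_range)),
            width_scale=float(rng.uniform(*width_scale_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows[i], _ = simulate_toa_radiance(grid, solar, truth)
        if snr is not None:
            rows[i] = add_noise(rows[i], snr, truth.seed)
    if len(set(coeff_draws)) == 1:
        logger.warning(
            "degenerate reflectance sampler: all %d training scenes share one "
            "reflectance; the training matrix will be (nearly) rank deficient",
            n_scenes,
        )
    return rows


def make_scene_set(
    grid: SpectralGrid,
    solar: SolarModel,
    n_scenes: int,
    seed: int = 0,
    fs_range: tuple[float, float] = (0.0, 1.5),
    sigma_f: float = 30.0,
    phi: float = 1.0,
    snr: SNRModel | None = SNRModel(),
    reflectance_sampler: Callable[[np.random.Generator], tuple[float, ...]] | None = None,
    mu0_range: tuple[float, float] = (0.3, 0.9),
    shift_range: tuple[float, float] = (-0.01, 0.01),
    width_scale_range: tuple[float, float] = (0.92, 1.08),
    o2_depth_range: tuple[float, float] = (0.0, 0.0),
) -> SceneSet:
    """Batch of fluorescent soundings with known per-scene truth.

    Fluorescence amplitudes are drawn uniformly from ``fs_range`` (a
    degenerate range pins them); reflectance, geometry, spectral shift and
    line width vary as in :func:`make_training_set`.
    """
    sampler = reflectance_sampler or default_reflectance_sampler
    rng = np.random.default_rng(seed)
    spectra = np.empty((n_scenes, grid.n_channels))
    truths: list[SceneTruth] = []
    for i in range(n_scenes):
        truth = SceneTruth(
            reflectance_coeffs=tuple(sampler(rng)),
            mu0=float(rng.uniform(*mu0_range)),
            fs_true=float(rng.uniform(*fs_range)),
            sigma_f=sigma_f,
            phi=phi,
            o2_depth=float(rng.uniform(*o2_depth_range)),
            shift_nm=float(rng.uniform(*shift_range)),
            width_scale=float(rng.uniform(*width_scale_range)),
            snr=snr if snr is not None else SNRModel(),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        clean, _ = simulate_toa_radiance(grid, solar, truth)
        spectra[i] = clean if snr is None else add_noise(clean, snr, truth.seed)
        truths.append(truth)
    fs_true = np.array([t.fs_true for t in truths])
    return SceneSet(grid=grid, spectra=spectra, fs_true=fs_true, snr=snr, truths=truths)


def make_pattern_scenes(
    basis,
    n_scenes: int,
    n_patterns: int = 5,
    seed: int = 0,
    fs_range: tuple[float, float] = (0.0, 1.5),
    sigma_f: float = 30.0,
    phi: float = 1.0,
    snr: SNRModel | None = SNRModel(),
    radiance_scale: float = 100.0,
    pattern_frac: float = 0.015,
) -> SceneSet:
    """Scenes that contain exactly ``n_patterns`` spectral patterns plus SIF.

    Each non-fluorescent part is a linear combination of the first
    ``n_patterns`` singular vectors of ``basis``: the leading vector carries
    the radiance scale (about ``radiance_scale`` per channel), the remaining
    patterns enter with per-channel rms amplitude of about
    ``pattern_frac * radiance_scale`` (a few percent, typical of the
    scene-to-scene variability of real spectra) and random signs.  Useful for
    model-selection experiments where the generating pattern count must be
    known exactly.
    """
    from .forward import gaussian_hf

    if n_patterns < 1 or n_patterns > basis.n_vectors:
        raise ValueError("n_patterns must be within the basis size")
    rng = np.random.default_rng(seed)
    grid = basis.grid
    v = basis.vectors[:n_patterns]
    mean_v1 = float(np.mean(v[0]))
    if mean_v1 <= 0:
        raise ValueError("leading basis vector has non-positive mean; unrealistic basis")
    omega1_0 = radiance_scale / mean_v1
    beta = pattern_frac * radiance_scale * np.sqrt(grid.n_channels)
    hf = gaussian_hf(grid.wavelengths, sigma_f, phi)
    spectra = np.empty((n_scenes, grid.n_channels))
    fs_true = np.empty(n_scenes)
    for i in range(n_scenes):
        omega = np.zeros(n_patterns)
        omega[0] = omega1_0 * rng.uniform(0.9, 1.1)
        if n_patterns > 1:
            signs = rng.choice([-1.0, 1.0], size=n_patterns - 1)
            omega[1:] = signs * rng.uniform(0.5, 1.5, size=n_patterns - 1) * beta
        fs_true[i] = rng.uniform(*fs_range)
        clean = omega @ v + fs_true[i] * hf
        spectra[i] = (
            clean if snr is None else add_noise(clean, snr, int(rng.integers(0, 2**31 - 1)))
        )
    return SceneSet(grid=grid, spectra=spectra, fs_true=fs_true, snr=snr, truths=None)
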