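"""Off-axis hologram demodulation: carrier estimation, Fourier sideband
filtering, phase unwrapping and background-plane removal.

The measured quantity is the double-pass transmission phase

    φ(x, y) = 2 ∫ (2π/λ) [n_cell(x, y, z) − n_PBS] dz ,

imprinted on a spatial carrier fringe by the off-axis geometry:

    I(x, y) = A + B · cos(2π k·r + φ(x, y)) + noise .

Demodulation isolates one Fourier sideband, recentres it and takes the
complex argument, yielding φ wrapped to (−π, π]; unwrapping and a
least-squares background-plane subtraction recover the physical map.
The double-pass factor 2 is deliberately *not* divided out anywhere in
this module — downstream dry-mass integration uses the 4π denominator
that absorbs it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as _fft
from skimage.restoration import unwrap_phase as _unwrap_reliability

__all__ = [
    "Interferogram",
    "PhaseMap",
    "estimate_carrier",
    "reconstruct_phase",
    "unwrap_phase",
    "subtract_background",
    "phase_rmse",
]


@dataclass
class Interferogram:
    """Raw fringe-intensity image with acquisition metadata.

    Parameters
    ----------
    intensity : ndarray
        2-D non-negative fringe image (arbitrary counts).
    pixel_size : float
        Lateral sampling, µm/pixel.
    wavelength : float
        Source centre wavelength, µm.
    carrier_hint : tuple of float, optional
        Known carrier frequency (cycles/pixel along the two array axes);
        used instead of estimation when provided.
    """

    intensity: np.ndarray
    pixel_size: float
    wavelength: float
    carrier_hint: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite everywhere")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class PhaseMap:
    """2-D phase in radians with imaging metadata."""

    phase: np.ndarray
    pixel_size: float
    wavelength: float
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase must be a 2-D array")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite everywhere")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


def _fft_freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    f0 = np.fft.fftfreq(shape[0])[:, None]
    f1 = np.fft.fftfreq(shape[1])[None, :]
    return f0, f1


def estimate_carrier(ig: Interferogram, dc_radius: float = 0.05) -> np.ndarray:
    """Locate the off-axis carrier frequency from the Fourier spectrum.

    Returns the frequency (cycles/pixel along the two array axes) of the
    strongest spectral peak outside a DC exclusion disk of radius
    ``dc_radius`` cycles/pixel.  The sign is fixed to the half-plane with
    positive first component (positive second component on the boundary).

    Raises
    ------
    ValueError
        If the image is smaller than 64×64 or no peak exceeds 3× the
        median spectral magnitude outside DC ("no carrier detected").
    """
    img = ig.intensity
    if min(img.shape) < 64:
        raise ValueError("carrier estimation requires an image of at least 64x64 pixels")
    spec = np.abs(np.fft.fft2(img - img.mean()))
    f0, f1 = _fft_freq_grids(img.shape)
    outside_dc = np.hypot(f0, f1) > dc_radius
    floor = np.median(spec[outside_dc])
    masked = np.where(outside_dc, spec, 0.0)
    peak = masked.max()
    if peak <= 3.0 * floor:
        raise ValueError("no carrier detected: no spectral peak above 3x the median outside DC")
    i, j = np.unravel_index(int(np.argmax(masked)), img.shape)
    carrier = np.array([np.fft.fftfreq(img.shape[0])[i], np.fft.fftfreq(img.shape[1])[j]])
    if carrier[0] < 0 or (carrier[0] == 0 and carrier[1] < 0):
        carrier = -carrier
    return carrier


def reconstruct_phase(
    ig: Interferogram,
    carrier: np.ndarray | str = "auto",
    window_fraction: float = 0.5,
    soft_edge: float = 0.0,
) -> PhaseMap:
    """Demodulate an off-axis hologram into a wrapped phase map.

    One sideband is isolated with a circular window of radius
    ``window_fraction × |carrier|`` cycles/pixel, recentred by integer FFT
    bins and inverse-transformed; the output is the complex argument,
    wrapped to (−π, π].  Any sub-bin carrier residual appears as a gentle
    tilt that the background-subtraction stage removes.

    Parameters
    ----------
    carrier : array-like or "auto"
        Carrier frequency (cycles/pixel); "auto" uses :func:`estimate_carrier`
        or the interferogram's ``carrier_hint`` when present.
    window_fraction : float
        Sideband window radius as a fraction of the carrier magnitude.
        Must stay below 1 or the window reaches the DC term.
    soft_edge : float
        Fraction of the window radius over which a raised-cosine edge
        tapers the hard window (0 = hard window).
    """
    if isinstance(carrier, str):
        if carrier != "auto":
            raise ValueError("carrier must be a 2-vector or 'auto'")
        carrier = (
            np.asarray(ig.carrier_hint, dtype=float)
            if ig.carrier_hint is not None
            else estimate_carrier(ig)
        )
    carrier = np.asarray(carrier, dtype=float)
    cmag = float(np.hypot(*carrier))
    if cmag <= 0:
        raise ValueError("carrier magnitude must be positive")
    radius = window_fraction * cmag
    if radius >= cmag - 1.0 / max(ig.intensity.shape):
        raise ValueError(
            "sideband window overlaps the DC term; use a larger carrier frequency "
            "or a smaller window_fraction"
        )

    img = ig.intensity
    n0, n1 = img.shape
    spec = np.fft.fft2(img)
    # recentre the +carrier sideband on the zero bin (integer-bin shift)
    shift0 = int(round(carrier[0] * n0))
    shift1 = int(round(carrier[1] * n1))
    spec = np.roll(spec, (-shift0, -shift1), axis=(0, 1))
    f0, f1 = _fft_freq_grids(img.shape)
    dist = np.hypot(f0, f1)
    if soft_edge > 0:
        inner = radius * (1.0 - soft_edge)
        win = np.clip((radius - dist) / (radius - inner + 1e-300), 0.0, 1.0)
        win = 0.5 - 0.5 * np.cos(np.pi * win)
    else:
        win = (dist <= radius).astype(float)
    field = np.fft.ifft2(spec * win)
    return PhaseMap(
        phase=np.angle(field),
        pixel_size=ig.pixel_size,
        wavelength=ig.wavelength,
        background_corrected=False,
    )


def _unwrap_lsq(wrapped: np.ndarray) -> np.ndarray:
    """Weighted-free least-squares unwrapping via DCT Poisson solve."""

    def wrap(a: np.ndarray) -> np.ndarray:
        return (a + np.pi) % (2 * np.pi) - np.pi

    d0 = wrap(np.diff(wrapped, axis=0))
    d1 = wrap(np.diff(wrapped, axis=1))
    rho = np.zeros_like(wrapped)
    rho[:-1, :] += d0
    rho[1:, :] -= d0
    rho[:, :-1] += d1
    rho[:, 1:] -= d1
    m, n = wrapped.shape
    dct = _fft.dctn(rho, type=2, norm="ortho")
    i = np.arange(m)[:, None]
    j = np.arange(n)[None, :]
    denom = 2.0 * (np.cos(np.pi * i / m) + np.cos(np.pi * j / n) - 2.0)
    denom[0, 0] = 1.0
    sol = dct / denom
    sol[0, 0] = 0.0
    out = _fft.idctn(sol, type=2, norm="ortho")
    # pin the free constant so the surface agrees with the wrapped input
    # modulo 2π (any residual global offset is then a 2πk multiple)
    out += np.median(wrap(wrapped - out))
    return out


def unwrap_phase(pm: PhaseMap, method: str = "quality") -> PhaseMap:
    """Unwrap a (−π, π]-wrapped phase map into a continuous surface.

    ``method="quality"`` uses reliability-ordered region growing (robust
    default for smooth cell-like phases); ``method="lsq"`` solves the
    unweighted least-squares problem through a DCT Poisson solver.  Either
    way the result equals the true phase up to one global 2πk offset.
    """
    wrapped = pm.phase
    if method == "quality":
        out = np.asarray(_unwrap_reliability(wrapped))
    elif method == "lsq":
        out = _unwrap_lsq(wrapped)
    else:
        raise ValueError(f"unknown unwrapping method {method!r}")
    return replace(pm, phase=out)


def _fit_plane(phase: np.ndarray, region: np.ndarray) -> np.ndarray:
    n0, n1 = phase.shape
    y, x = np.mgrid[0:n0, 0:n1]
    a = np.column_stack(
        [np.ones(region.sum()), x[region].ravel(), y[region].ravel()]
    )
    coef, *_ = np.linalg.lstsq(a, phase[region].ravel(), rcond=None)
    return coef[0] + coef[1] * x + coef[2] * y


def subtract_background(
    pm: PhaseMap,
    cell_free_region: np.ndarray | str = "auto",
    percentile: float = 20.0,
    cell_exclusion: float = 0.1,
) -> PhaseMap:
    """Remove the instrumental background plane (tilt + offset).

    A least-squares plane is fitted to a cell-free region and subtracted;
    the region's residual median is nulled so the background sits at zero
    phase.  In "auto" mode the region is seeded by the pixels whose
    residual after a provisional full-image plane fit lies below the given
    percentile (surely dish background), then widened to every pixel whose
    provisionally corrected phase stays below ``cell_exclusion`` radians —
    using only the low tail for the final median would bias the zero level
    upward by the ripple half-width.
    """
    phase = pm.phase
    if isinstance(cell_free_region, str):
        if cell_free_region != "auto":
            raise ValueError("cell_free_region must be a boolean mask or 'auto'")
        resid = phase - _fit_plane(phase, np.ones_like(phase, dtype=bool))
        region = resid <= np.percentile(resid, percentile)
        rough = phase - _fit_plane(phase, region)
        rough -= np.median(rough[region])
        widened = rough < cell_exclusion
        if widened.any():
            region = widened
    else:
        region = np.asarray(cell_free_region, dtype=bool)
        if region.shape != phase.shape:
            raise ValueError("background mask shape does not match the phase map")
    if not region.any():
        raise ValueError("background region is empty")
    corrected = phase - _fit_plane(phase, region)
    corrected -= np.median(corrected[region])
    return replace(pm, phase=corrected, background_corrected=True)


def phase_rmse(a: np.ndarray, b: np.ndarray, border: int = 5) -> float:
    """RMSE between two phase maps, excluding a pixel border (edge effects
    of the sideband window make the outermost pixels unrepresentative)."""
    sl = (slice(border, -border or None), slice(border, -border or None))
    diff = np.asarray(a)[sl] - np.asarray(b)[sl]
    return float(np.sqrt(np.mean(diff**2)))
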