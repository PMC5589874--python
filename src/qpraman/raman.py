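"""Single-cell Raman spectral preprocessing and marker-band quantification.

The fixed preprocessing order is: fingerprint restriction (600–1800 cm⁻¹)
→ fluorescence-baseline removal (iteratively clipped 4th-order polynomial)
→ standard normal variate (SNV) scaling.  Marker-band intensities (window
means around 1000 and 1584 cm⁻¹) are read off the terminal SNV
representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import FINGERPRINT_HI, FINGERPRINT_LO

__all__ = [
    "RamanSpectrum",
    "SpectralDataset",
    "restrict_fingerprint",
    "remove_baseline",
    "snv",
    "band_intensity",
    "group_mean_spectra",
    "preprocess",
]


@dataclass
class RamanSpectrum:
    """One spectrum: intensities on a strictly increasing wavenumber grid."""

    wavenumber: np.ndarray  # cm⁻¹
    intensity: np.ndarray  # arbitrary counts
    group: str | None = None
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("wavenumber and intensity must be 1-D")
        if self.wavenumber.size != self.intensity.size:
            raise ValueError("wavenumber and intensity lengths differ")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")


@dataclass
class SpectralDataset:
    """Spectra-by-wavenumber matrix on one shared grid with group labels."""

    matrix: np.ndarray  # (n_spectra, n_wavenumbers)
    axis: np.ndarray  # shared grid, cm⁻¹
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.axis = np.asarray(self.axis, dtype=float)
        if self.matrix.shape[1] != self.axis.size:
            raise ValueError("matrix width does not match the wavenumber axis")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one group label per spectrum is required")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def spectra(self):
        """Iterate rows as :class:`RamanSpectrum` objects."""
        for row, lab in zip(self.matrix, self.labels):
            yield RamanSpectrum(self.axis, row, group=lab)

    @classmethod
    def from_spectra(cls, spectra: list[RamanSpectrum]) -> "SpectralDataset":
        """Stack spectra; off-grid spectra are linearly interpolated onto
        the first spectrum's grid (single-instrument assumption)."""
        if not spectra:
            raise ValueError("no spectra given")
        axis = spectra[0].wavenumber
        rows = []
        for s in spectra:
            if s.wavenumber.shape == axis.shape and np.allclose(s.wavenumber, axis):
                rows.append(s.intensity)
            else:
                rows.append(np.interp(axis, s.wavenumber, s.intensity))
        return cls(np.array(rows), axis, [s.group or "" for s in spectra])

    def concat(self, other: "SpectralDataset") -> "SpectralDataset":
        if self.axis.shape != other.axis.shape or not np.allclose(self.axis, other.axis):
            raise ValueError("datasets must share one wavenumber grid")
        return SpectralDataset(
            np.vstack([self.matrix, other.matrix]), self.axis, self.labels + other.labels
        )


def restrict_fingerprint(
    s: RamanSpectrum, lo: float = FINGERPRINT_LO, hi: float = FINGERPRINT_HI
) -> RamanSpectrum:
    """Clip a spectrum to the biological fingerprint region (inclusive)."""
    keep = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if not keep.any():
        raise ValueError(f"spectrum does not overlap [{lo}, {hi}] cm^-1")
    return replace(s, wavenumber=s.wavenumber[keep], intensity=s.intensity[keep])


def remove_baseline(
    s: RamanSpectrum,
    degree: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
    return_baseline: bool = False,
):
    """Subtract the fluorescence background by iteratively clipped
    polynomial fitting (modified-polyfit scheme).

    A degree-``degree`` polynomial is least-squares fitted; intensities
    above the fit are replaced by the fit value and the fit repeated until
    the clipped curve changes by less than ``tol`` × (intensity range) or
    ``max_iter`` passes.  Peaks are thereby excluded from the background
    estimate; the converged polynomial is subtracted from the *original*
    spectrum, so residuals near the noise floor may be negative.
    """
    y = s.intensity
    if y.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for a degree-{degree} baseline")
    span = float(np.ptp(s.wavenumber))
    if span == 0:
        raise ValueError("degenerate wavenumber grid")
    x = (s.wavenumber - s.wavenumber[0]) / span  # conditioning
    rng = float(np.ptp(y))
    if rng == 0:
        # constant spectrum: the baseline is the constant itself
        out = replace(s, intensity=np.zeros_like(y))
        return (out, y.copy()) if return_baseline else out
    work = y.astype(float).copy()
    fit = work
    for _ in range(max_iter):
        coefs = np.polynomial.polynomial.polyfit(x, work, degree)
        fit = np.polynomial.polynomial.polyval(x, coefs)
        clipped = np.minimum(work, fit)
        if np.max(np.abs(clipped - work)) < tol * rng:
            work = clipped
            break
        work = clipped
    out = replace(s, intensity=y - fit)
    return (out, fit) if return_baseline else out


def snv(s: RamanSpectrum) -> RamanSpectrum:
    """Standard normal variate: per-spectrum (x − mean)/SD, sample SD."""
    sd = float(np.std(s.intensity, ddof=1))
    if sd == 0:
        raise ValueError("constant spectrum: SNV undefined (zero standard deviation)")
    return replace(s, intensity=(s.intensity - s.intensity.mean()) / sd)


def band_intensity(s: RamanSpectrum, center: float, half_width: float = 5.0) -> float:
    """Mean intensity over the window [center − h, center + h]."""
    if not (s.wavenumber[0] <= center - half_width and center + half_width <= s.wavenumber[-1]):
        raise ValueError(
            f"band window {center}±{half_width} cm^-1 falls outside the spectral grid"
        )
    win = np.abs(s.wavenumber - center) <= half_width
    return float(s.intensity[win].mean())


def preprocess(
    ds: SpectralDataset,
    lo: float = FINGERPRINT_LO,
    hi: float = FINGERPRINT_HI,
    degree: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SpectralDataset:
    """Full pipeline on a dataset: restrict → baseline → SNV, per spectrum."""
    done = [snv(remove_baseline(restrict_fingerprint(s, lo, hi), degree, max_iter, tol))
            for s in ds.spectra()]
    return SpectralDataset.from_spectra(done)


def group_mean_spectra(ds: SpectralDataset):
    """Pointwise mean and sample SD per group.

    Returns ``{group: (mean, sd)}`` preserving first-appearance order.
    A group with a single spectrum gets an all-zero SD with a warning.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in dict.fromkeys(ds.labels):
        rows = ds.matrix[[i for i, lab in enumerate(ds.labels) if lab == g]]
        mean = rows.mean(axis=0)
        if rows.shape[0] < 2:
            warnings.warn(f"group {g!r} has a single spectrum; SD reported as 0")
            sd = np.zeros_like(mean)
        else:
            sd = rows.std(axis=0, ddof=1)
        out[g] = (mean, sd)
    return out
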