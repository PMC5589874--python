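"""Ground-truth-known synthetic data for both measurement arms.

Emulates the four-group UV-exposure design (control, T50, T100, T200 —
0/50/100/200 minutes at 1.02 W/m²) with:

* radially symmetric cell phantoms whose integrated phase, hence dry
  mass, has a closed form — embedded in off-axis carrier-fringe
  interferograms with configurable noise;
* single-cell Raman spectra composed of Lorentzian/Gaussian bands at the
  fibroblast assignment wavenumbers on a smooth degree-4 fluorescence
  baseline, with the 1000 and 1584 cm⁻¹ marker bands responding to dose;
* resazurin-assay absorbance tables (570/600 nm) whose corrected means
  decrease with dose.

Every generator is driven by an explicit seed; identical configuration
yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ALPHA_DEFAULT, DOSE_GROUPS, WAVELENGTH_DEFAULT
from .holography import Interferogram, PhaseMap
from .raman import RamanSpectrum, SpectralDataset

__all__ = [
    "CellPhantom",
    "SpectralGroupSpec",
    "SimulationConfig",
    "make_phase_map",
    "make_interferogram",
    "make_spectra",
    "make_viability_table",
    "default_spectral_groups",
    "default_qpi_groups",
]

PROFILES = ("uniform_disk", "smoothed_disk", "gaussian_cap")

#: gaussian_cap standard deviation as a fraction of the support radius
_GAUSS_SIGMA_FRACTION = 1.0 / 3.0


@dataclass
class CellPhantom:
    """Radially symmetric phase phantom with analytically known dry mass.

    Profiles (r = distance from centre, R = support radius, φ₀ = peak):

    * ``uniform_disk``  — φ(r) = φ₀ for r ≤ R
    * ``smoothed_disk`` — φ(r) = φ₀ (1 − (r/R)²)²
    * ``gaussian_cap``  — φ(r) = φ₀ exp(−r²/2σ²), σ = R/3, truncated at R

    ``true_dry_mass`` is the closed-form integral of the profile scaled by
    λ/(4πα) (pg); it is the ground truth every downstream mass estimate is
    judged against.
    """

    center: tuple[float, float]  # µm, (y, x) from the field origin
    radius: float  # µm
    peak_phase: float  # radians
    profile: str = "smoothed_disk"
    wavelength: float = WAVELENGTH_DEFAULT  # µm
    alpha: float = ALPHA_DEFAULT  # µm³/pg
    true_dry_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {PROFILES}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.peak_phase < 0:
            raise ValueError("peak_phase must be non-negative")
        if 0 < self.peak_phase <= 0.2:
            raise ValueError(
                "peak_phase must exceed the 0.2 rad segmentation threshold "
                "(or be exactly zero for the null phantom)"
            )
        self.true_dry_mass = (
            self.wavelength / (4.0 * math.pi * self.alpha) * self.integrated_phase()
        )

    def integrated_phase(self) -> float:
        """Closed-form ∬ φ dA over the support, rad·µm²."""
        r, p = self.radius, self.peak_phase
        if self.profile == "uniform_disk":
            return p * math.pi * r**2
        if self.profile == "smoothed_disk":
            # ∫₀^R φ₀(1−(r/R)²)² 2πr dr = φ₀ πR²/3
            return p * math.pi * r**2 / 3.0
        sigma = _GAUSS_SIGMA_FRACTION * r
        return p * 2.0 * math.pi * sigma**2 * (1.0 - math.exp(-(r**2) / (2.0 * sigma**2)))

    def phase_profile(self, dist: np.ndarray) -> np.ndarray:
        """Evaluate φ at radial distances ``dist`` (µm)."""
        inside = dist <= self.radius
        out = np.zeros_like(dist, dtype=float)
        if self.profile == "uniform_disk":
            out[inside] = self.peak_phase
        elif self.profile == "smoothed_disk":
            u = dist[inside] / self.radius
            out[inside] = self.peak_phase * (1.0 - u**2) ** 2
        else:
            sigma = _GAUSS_SIGMA_FRACTION * self.radius
            out[inside] = self.peak_phase * np.exp(-(dist[inside] ** 2) / (2.0 * sigma**2))
        return out


@dataclass
class SpectralGroupSpec:
    """Band composition of one dose group's synthetic Raman spectra."""

    group: str
    band_centers: list[float]  # cm⁻¹
    band_amplitudes: list[float]  # arbitrary intensity units
    band_widths: list[float]  # cm⁻¹ (HWHM for Lorentzian, SD for Gaussian)
    baseline_coeffs: list[float] = field(default_factory=lambda: [0.0] * 5)
    noise_sd: float = 0.02
    n_spectra: int = 15
    amplitude_jitter: float = 0.05  # per-spectrum multiplicative band variability
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.group not in DOSE_GROUPS:
            raise ValueError(f"group must be one of {DOSE_GROUPS}")
        if not (len(self.band_centers) == len(self.band_amplitudes) == len(self.band_widths)):
            raise ValueError("band_centers, band_amplitudes and band_widths must align")
        if any(a < 0 for a in self.band_amplitudes):
            raise ValueError("band amplitudes must be non-negative")
        if len(self.baseline_coeffs) != 5:
            raise ValueError("baseline_coeffs must hold 5 coefficients (degree 4)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be at least 1")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError("lineshape must be 'lorentzian' or 'gaussian'")

    def amplitude_at(self, center: float) -> float:
        """Configured amplitude of the band at ``center`` (exact match)."""
        for c, a in zip(self.band_centers, self.band_amplitudes):
            if c == center:
                return a
        raise KeyError(f"no band configured at {center} cm^-1")


@dataclass
class SimulationConfig:
    """Knobs of the full synthetic world; ``seed`` determines everything."""

    seed: int
    image_size: int = 512  # pixels (square field)
    pixel_size: float = 0.1  # µm/pixel (60x / 1.0 NA scale)
    wavelength: float = WAVELENGTH_DEFAULT  # µm
    carrier_frequency: tuple[float, float] = (0.25, 0.0)  # cycles/pixel
    fringe_background: float = 1.0  # A in I = A + B cos(...)
    fringe_amplitude: float = 0.8  # B
    noise_model: str = "gaussian"
    noise_sd: float = 0.0  # intensity units (gaussian) / unused for shot
    shot_scale: float = 1e4  # photons per intensity unit for shot noise
    alpha: float = ALPHA_DEFAULT
    groups: list[SpectralGroupSpec] = field(default_factory=lambda: default_spectral_groups())
    phantoms_per_group: int = 10

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        cmag = math.hypot(*self.carrier_frequency)
        if not 0.1 <= cmag <= 0.4:
            raise ValueError(
                "carrier frequency magnitude must lie in [0.1, 0.4] cycles/pixel "
                "(sidebands separable from DC, below Nyquist)"
            )
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64 pixels")
        if self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_size and wavelength must be positive")
        if self.fringe_background <= 0 or self.fringe_amplitude <= 0:
            raise ValueError("fringe background and amplitude must be positive")
        if self.noise_model not in ("gaussian", "shot"):
            raise ValueError("noise_model must be 'gaussian' or 'shot'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def field_of_view(self) -> float:
        """Lateral field extent, µm."""
        return self.image_size * self.pixel_size


def make_phase_map(phantom: CellPhantom, config: SimulationConfig) -> PhaseMap:
    """Rasterise a phantom into a ground-truth phase map (radians).

    The phase is zero outside the phantom support; its discrete integral
    converges to the closed-form mass as the grid refines (<1 % error at
    256² pixels for supports of ≥20 px radius).
    """
    fov = config.field_of_view
    cy, cx = phantom.center
    if not (
        phantom.radius <= cy <= fov - phantom.radius
        and phantom.radius <= cx <= fov - phantom.radius
    ):
        raise ValueError(
            f"phantom at {phantom.center} with radius {phantom.radius} um does not "
            f"fit inside the {fov:.1f} um field of view"
        )
    n = config.image_size
    # pixel-centre coordinates in µm
    coords = (np.arange(n) + 0.5) * config.pixel_size
    dist = np.hypot(coords[:, None] - cy, coords[None, :] - cx)
    return PhaseMap(
        phase=phantom.phase_profile(dist),
        pixel_size=config.pixel_size,
        wavelength=config.wavelength,
        background_corrected=True,
    )


def make_interferogram(
    phase: PhaseMap, config: SimulationConfig, seed: int | None = None
) -> Interferogram:
    """Embed a phase map in an off-axis carrier fringe with noise.

    I = A + B·cos(2π k·r + φ) plus additive Gaussian noise of SD
    ``config.noise_sd``, or Poisson shot noise at ``config.shot_scale``
    photons per intensity unit.  Negative excursions are clipped at zero
    to honour the non-negativity of measured intensity.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n0, n1 = phase.phase.shape
    k0, k1 = config.carrier_frequency
    i0 = np.arange(n0)[:, None]
    i1 = np.arange(n1)[None, :]
    fringe = config.fringe_background + config.fringe_amplitude * np.cos(
        2.0 * np.pi * (k0 * i0 + k1 * i1) + phase.phase
    )
    if config.noise_model == "gaussian":
        if config.noise_sd > 0:
            fringe = fringe + rng.normal(0.0, config.noise_sd, fringe.shape)
    else:
        fringe = rng.poisson(np.clip(fringe, 0, None) * config.shot_scale) / config.shot_scale
    return Interferogram(
        intensity=np.clip(fringe, 0.0, None),
        pixel_size=phase.pixel_size,
        wavelength=phase.wavelength,
        carrier_hint=(k0, k1),
    )


def _lineshape(axis: np.ndarray, center: float, width: float, kind: str) -> np.ndarray:
    if kind == "lorentzian":
        return width**2 / ((axis - center) ** 2 + width**2)
    return np.exp(-((axis - center) ** 2) / (2.0 * width**2))


def make_spectra(
    spec: SpectralGroupSpec, axis: np.ndarray, seed: int
) -> SpectralDataset:
    """Generate one dose group's spectra on a shared wavenumber grid.

    Each spectrum is Σ bands + degree-4 polynomial baseline + white noise.
    Band amplitudes receive per-spectrum multiplicative jitter emulating
    cell-to-cell and focus variability.  The baseline polynomial is
    evaluated on the axis rescaled to [0, 1] so coefficients are
    grid-independent.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 7 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be a strictly increasing 1-D grid")
    for c in spec.band_centers:
        if not (axis[0] <= c <= axis[-1]):
            raise ValueError(f"axis does not cover the configured band at {c} cm^-1")
    rng = np.random.default_rng(seed)
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(spec.baseline_coeffs))
    rows = []
    for _ in range(spec.n_spectra):
        y = baseline.copy()
        for c, a, w in zip(spec.band_centers, spec.band_amplitudes, spec.band_widths):
            amp = a * max(0.0, 1.0 + spec.amplitude_jitter * rng.standard_normal())
            y += amp * _lineshape(axis, c, w, spec.lineshape)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, axis.shape)
        rows.append(y)
    return SpectralDataset(
        matrix=np.array(rows), axis=axis, labels=[spec.group] * spec.n_spectra
    )


def default_spectral_groups(
    n_spectra: int = 15, noise_sd: float = 0.02, amplitude_jitter: float = 0.05
) -> list[SpectralGroupSpec]:
    """The stated four-group spectral world.

    Band set: nucleic acids (720, 1093, 1340, 1576 cm⁻¹), tyrosine (835),
    phenylalanine (1004), amide III (1250), CH₂ deformation (1440), amide I
    (1660), plus the two UV-response markers: 1000 cm⁻¹ rises through T100
    and dips at T200 (signal-to-noise loss in heavily damaged cells) while
    1584 cm⁻¹ increases strictly with dose.
    """
    centers = [720.0, 835.0, 1000.0, 1004.0, 1093.0, 1250.0, 1340.0, 1440.0, 1576.0, 1584.0, 1660.0]
    widths = [8.0, 9.0, 6.0, 6.0, 9.0, 14.0, 10.0, 9.0, 8.0, 8.0, 12.0]
    base = {
        720.0: 0.45, 835.0: 0.35, 1004.0: 1.0, 1093.0: 0.40, 1250.0: 0.55,
        1340.0: 0.50, 1440.0: 0.90, 1576.0: 0.55, 1660.0: 1.0,
    }
    marker_1000 = {"control": 0.30, "T50": 0.50, "T100": 0.70, "T200": 0.45}
    marker_1584 = {"control": 0.30, "T50": 0.45, "T100": 0.60, "T200": 0.75}
    # gentle fluorescence background decaying across the fingerprint region
    baseline = [6.0, -4.0, 1.5, -0.5, 0.2]
    groups = []
    for g in DOSE_GROUPS:
        amps = []
        for c in centers:
            if c == 1000.0:
                amps.append(marker_1000[g])
            elif c == 1584.0:
                amps.append(marker_1584[g])
            else:
                amps.append(base[c])
        groups.append(
            SpectralGroupSpec(
                group=g,
                band_centers=centers,
                band_amplitudes=amps,
                band_widths=widths,
                baseline_coeffs=list(baseline),
                noise_sd=noise_sd,
                n_spectra=n_spectra,
                amplitude_jitter=amplitude_jitter,
            )
        )
    return groups


#: Per-group dry-mass scale factors for the QPI phantom world: mass
#: decreases with dose (the exposed-group mass loss the phase arm detects).
QPI_MASS_SCALES = {"control": 1.0, "T50": 0.85, "T100": 0.70, "T200": 0.60}


def default_qpi_groups(
    config: SimulationConfig,
    base_radius: float = 15.0,
    base_peak_phase: float = 1.2,
    cv: float = 0.05,
    radius_cv: float = 0.05,
    profile: str = "uniform_disk",
) -> dict[str, list[CellPhantom]]:
    """Phantom populations for the four dose groups.

    ``phantoms_per_group`` cells per group, centred in the field with small
    seeded positional scatter.  Group scaling and the between-cell
    coefficient of variation ``cv`` act on *dry mass*: the cell radius
    varies independently (``radius_cv``) and the peak phase compensates
    quadratically, emulating cells of fixed mass spreading to different
    footprints.  Mass CV therefore equals ``cv`` exactly, which is what
    sets the power of the downstream group comparisons.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    fov = config.field_of_view
    out: dict[str, list[CellPhantom]] = {}
    for g in DOSE_GROUPS:
        scale = QPI_MASS_SCALES[g]
        cells = []
        for _ in range(config.phantoms_per_group):
            mass_factor = scale * max(0.3, 1.0 + cv * rng.standard_normal())
            radius = base_radius * max(0.5, 1.0 + radius_cv * rng.standard_normal())
            peak = base_peak_phase * mass_factor * (base_radius / radius) ** 2
            jitter = rng.uniform(-0.05, 0.05, size=2) * fov
            center = (fov / 2 + jitter[0], fov / 2 + jitter[1])
            cells.append(
                CellPhantom(
                    center=center,
                    radius=radius,
                    peak_phase=peak,
                    profile=profile,
                    wavelength=config.wavelength,
                    alpha=config.alpha,
                )
            )
        out[g] = cells
    return out


#: Default resazurin-assay world: corrected absorbance decreasing with dose.
VIABILITY_MEANS = {"control": 0.85, "T50": 0.70, "T100": 0.55, "T200": 0.35}
VIABILITY_BLANK_A600 = 0.10


def make_viability_table(
    groups: dict[str, float] | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    blank_a600: float = VIABILITY_BLANK_A600,
    noise_sd: float = 0.02,
):
    """Absorbance table of the resazurin viability assay.

    Each dose group contributes ``n_replicates`` sample rows (A570 and A600
    readings); blank rows carry the culture-medium background.  Configured
    group means are the corrected absorbances A570(sample) − A600(blank),
    so a zero-noise table reproduces them exactly.
    """
    import pandas as pd

    if groups is None:
        groups = dict(VIABILITY_MEANS)
    if any(v < 0 for v in groups.values()) or blank_a600 < 0:
        raise ValueError("configured absorbances must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for g, mean in groups.items():
        for r in range(n_replicates):
            a570 = mean + blank_a600 + rng.normal(0.0, noise_sd)
            a600 = blank_a600 + 0.05 + rng.normal(0.0, noise_sd)  # sample A600 unused
            rows.append({"group": g, "replicate": r, "is_blank": False,
                         "a570": a570, "a600": a600})
    for r in range(n_replicates):
        rows.append({"group": "blank", "replicate": r, "is_blank": True,
                     "a570": blank_a600 + 0.02 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                     "a600": blank_a600 + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)})
    return pd.DataFrame(rows)
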