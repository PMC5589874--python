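"""Reading and writing of the pipeline's on-disk formats.

Interferograms and phase maps travel as 32-bit-float single-channel TIFF
(image only) and/or HDF5 bundles (image + metadata: pixel size µm,
wavelength µm, optional group and ground-truth mass).  Spectra travel as
CSV with the wavenumber in the first column and one column per spectrum,
plus a companion labels CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .holography import Interferogram, PhaseMap
from .raman import SpectralDataset

__all__ = [
    "write_interferogram",
    "read_interferogram",
    "write_phase_map",
    "read_phase_map",
    "write_spectra_csv",
    "read_spectra_csv",
]


def write_interferogram(
    ig: Interferogram,
    h5_path: str | Path,
    tiff_path: str | Path | None = None,
    **attrs,
) -> None:
    """Write an interferogram as an HDF5 bundle and optionally a TIFF."""
    with h5py.File(h5_path, "w") as f:
        d = f.create_dataset("intensity", data=ig.intensity.astype(np.float32))
        d.attrs["pixel_size_um"] = ig.pixel_size
        d.attrs["wavelength_um"] = ig.wavelength
        if ig.carrier_hint is not None:
            d.attrs["carrier_cycles_per_px"] = np.asarray(ig.carrier_hint, dtype=float)
        for k, v in attrs.items():
            d.attrs[k] = v
    if tiff_path is not None:
        tifffile.imwrite(tiff_path, ig.intensity.astype(np.float32))


def read_interferogram(path: str | Path, pixel_size: float | None = None,
                       wavelength: float | None = None) -> Interferogram:
    """Read an interferogram from HDF5 (self-describing) or TIFF (metadata
    must be supplied by the caller)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["intensity"]
            hint = d.attrs.get("carrier_cycles_per_px")
            return Interferogram(
                intensity=d[...],
                pixel_size=float(d.attrs["pixel_size_um"]),
                wavelength=float(d.attrs["wavelength_um"]),
                carrier_hint=tuple(hint) if hint is not None else None,
            )
    if pixel_size is None or wavelength is None:
        raise ValueError("TIFF input needs explicit pixel_size and wavelength")
    return Interferogram(
        intensity=tifffile.imread(path), pixel_size=pixel_size, wavelength=wavelength
    )


def write_phase_map(pm: PhaseMap, h5_path: str | Path,
                    tiff_path: str | Path | None = None, **attrs) -> None:
    with h5py.File(h5_path, "w") as f:
        d = f.create_dataset("phase", data=pm.phase.astype(np.float32))
        d.attrs["pixel_size_um"] = pm.pixel_size
        d.attrs["wavelength_um"] = pm.wavelength
        d.attrs["background_corrected"] = pm.background_corrected
        for k, v in attrs.items():
            d.attrs[k] = v
    if tiff_path is not None:
        tifffile.imwrite(tiff_path, pm.phase.astype(np.float32))


def read_phase_map(path: str | Path) -> tuple[PhaseMap, dict]:
    """Read a phase-map HDF5 bundle; extra attributes come back as a dict."""
    with h5py.File(path, "r") as f:
        d = f["phase"]
        extra = {
            k: v
            for k, v in d.attrs.items()
            if k not in ("pixel_size_um", "wavelength_um", "background_corrected")
        }
        pm = PhaseMap(
            phase=d[...].astype(float),
            pixel_size=float(d.attrs["pixel_size_um"]),
            wavelength=float(d.attrs["wavelength_um"]),
            background_corrected=bool(d.attrs["background_corrected"]),
        )
    return pm, extra


def write_spectra_csv(ds: SpectralDataset, path: str | Path,
                      labels_path: str | Path | None = None) -> None:
    """Spectra CSV: column 1 is the wavenumber grid, then one column per
    spectrum (s0, s1, …); the labels CSV maps column name → group."""
    cols = {"wavenumber_cm1": ds.axis}
    for i, row in enumerate(ds.matrix):
        cols[f"s{i}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)
    if labels_path is not None:
        pd.DataFrame(
            {"spectrum": [f"s{i}" for i in range(len(ds))], "group": ds.labels}
        ).to_csv(labels_path, index=False)


def read_spectra_csv(path: str | Path, labels_path: str | Path | None = None) -> SpectralDataset:
    df = pd.read_csv(path)
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    matrix = df.iloc[:, 1:].to_numpy(dtype=float).T
    names = list(df.columns[1:])
    if labels_path is not None:
        lab = pd.read_csv(labels_path).set_index("spectrum")["group"]
        labels = [str(lab[n]) for n in names]
    else:
        labels = [""] * len(names)
    return SpectralDataset(matrix=matrix, axis=axis, labels=labels)
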