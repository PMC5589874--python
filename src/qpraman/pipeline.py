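"""End-to-end orchestration: simulate → reconstruct → quantify →
preprocess → discriminate → report, from one flat YAML config.

Both measurement arms are analytically independent; either can run alone.
A run is fully determined by the config (including its mandatory seed):
re-running with the same config yields bit-identical CSV outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import CellRecord, dry_mass, segment_cells, summarize_groups
from .chemometrics import dose_table, fit_pca, score_scatter_3d, viability_correct, welch_test
from .constants import DOSE_GROUPS, GROUP_MINUTES, UV_IRRADIANCE
from .holography import reconstruct_phase, subtract_background, unwrap_phase
from .io import write_interferogram, write_phase_map, write_spectra_csv
from .raman import band_intensity, group_mean_spectra, preprocess
from .synthetic import (
    SimulationConfig,
    default_qpi_groups,
    default_spectral_groups,
    make_interferogram,
    make_phase_map,
    make_spectra,
    make_viability_table,
)

__all__ = ["RunManifest", "DEFAULT_CONFIG", "load_config", "validate_config", "run_all"]

ARMS = ("qpi", "raman", "viability")

#: Shipped default configuration (the stated synthetic world).
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "arms": list(ARMS),
    # --- imaging / QPI arm ---
    "image_size": 512,
    "pixel_size": 0.1,  # µm/pixel
    "wavelength": 0.8,  # µm
    "carrier_frequency": [0.25, 0.0],  # cycles/pixel
    "noise_model": "gaussian",
    "noise_sd": 0.0,  # intensity units
    "alpha": 0.185,  # µm³/pg
    "phantoms_per_group": 10,
    "phantom_profile": "uniform_disk",
    "base_radius_um": 15.0,
    "base_peak_phase_rad": 1.2,
    "mass_cv": 0.05,
    "phase_threshold": 0.2,  # rad
    "min_pixels": 50,
    "unwrap_method": "quality",
    # --- Raman arm ---
    "raman_axis_lo": 400.0,
    "raman_axis_hi": 2000.0,
    "raman_axis_step": 1.0,
    "raman_n_spectra": 15,
    "raman_noise_sd": 0.02,
    "raman_amplitude_jitter": 0.05,
    "baseline_degree": 4,
    "n_components": 3,
    "band_centers": [1000.0, 1584.0],
    "band_half_width": 5.0,
    "all_pairs": False,
    # --- viability arm ---
    "viability_noise_sd": 0.02,
    "viability_replicates": 3,
}


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    stage_outputs: dict = field(default_factory=dict)
    version: str = __version__
    timestamps: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Shipped defaults, optionally updated from a YAML file and overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a YAML mapping")
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(loaded)
    if overrides:
        cfg.update(overrides)
    return cfg


def validate_config(config: dict | str | Path) -> list[str]:
    """Check every declared invariant; an empty list means the config is ok."""
    if not isinstance(config, dict):
        config = load_config(config)
    v: list[str] = []
    for key in DEFAULT_CONFIG:
        if key not in config:
            v.append(f"missing required key: {key}")
    if v:
        return v
    if not isinstance(config["seed"], int):
        v.append("seed must be an integer")
    cmag = float(np.hypot(*config["carrier_frequency"]))
    if not 0.1 <= cmag <= 0.4:
        v.append(
            f"carrier frequency magnitude {cmag:.3f} outside [0.1, 0.4] cycles/pixel "
            "(sideband separability / aliasing bound)"
        )
    if config["alpha"] <= 0:
        v.append("alpha must be positive")
    if config["image_size"] < 64:
        v.append("image_size must be at least 64")
    for key in ("pixel_size", "wavelength", "base_radius_um", "base_peak_phase_rad"):
        if config[key] <= 0:
            v.append(f"{key} must be positive")
    for key in ("noise_sd", "raman_noise_sd", "viability_noise_sd", "mass_cv",
                "raman_amplitude_jitter"):
        if config[key] < 0:
            v.append(f"{key} must be non-negative")
    if config["phase_threshold"] <= 0:
        v.append("phase_threshold must be positive")
    if config["noise_model"] not in ("gaussian", "shot"):
        v.append("noise_model must be 'gaussian' or 'shot'")
    if config["unwrap_method"] not in ("quality", "lsq"):
        v.append("unwrap_method must be 'quality' or 'lsq'")
    if config["phantoms_per_group"] < 2:
        v.append("phantoms_per_group must be at least 2 (group SDs need n >= 2)")
    if config["raman_n_spectra"] < config["n_components"] + 1:
        v.append("raman_n_spectra must exceed the number of PCA components")
    if not set(config["arms"]).issubset(ARMS):
        v.append(f"arms must be a subset of {ARMS}")
    if not config["raman_axis_lo"] < config["raman_axis_hi"]:
        v.append("raman axis bounds must satisfy lo < hi")
    if config["raman_axis_lo"] > 600 or config["raman_axis_hi"] < 1800:
        v.append("raman axis must cover the 600-1800 cm^-1 fingerprint region")
    # radius must fit the field with positional jitter margin
    fov = config["image_size"] * config["pixel_size"]
    if config["base_radius_um"] * 1.2 > 0.4 * fov:
        v.append("base_radius_um too large for the field of view")
    return v


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _sim_config(config: dict) -> SimulationConfig:
    return SimulationConfig(
        seed=int(config["seed"]),
        image_size=int(config["image_size"]),
        pixel_size=float(config["pixel_size"]),
        wavelength=float(config["wavelength"]),
        carrier_frequency=tuple(config["carrier_frequency"]),
        noise_model=config["noise_model"],
        noise_sd=float(config["noise_sd"]),
        alpha=float(config["alpha"]),
        groups=default_spectral_groups(
            n_spectra=int(config["raman_n_spectra"]),
            noise_sd=float(config["raman_noise_sd"]),
            amplitude_jitter=float(config["raman_amplitude_jitter"]),
        ),
        phantoms_per_group=int(config["phantoms_per_group"]),
    )


def _run_qpi(config: dict, outdir: Path, save_images: bool = False):
    sim = _sim_config(config)
    phantoms = default_qpi_groups(
        sim,
        base_radius=float(config["base_radius_um"]),
        base_peak_phase=float(config["base_peak_phase_rad"]),
        cv=float(config["mass_cv"]),
        profile=config["phantom_profile"],
    )
    records: list[CellRecord] = []
    truth_rows = []
    idx = 0
    for g in DOSE_GROUPS:
        for ph in phantoms[g]:
            image_id = f"{g}_{idx:03d}"
            pm_true = make_phase_map(ph, sim)
            sub_seed = int(np.random.SeedSequence([sim.seed, 7, idx]).generate_state(1)[0] % (2**31))
            ig = make_interferogram(pm_true, sim, seed=sub_seed)
            if save_images:
                write_interferogram(ig, outdir / f"{image_id}_hologram.h5",
                                    group=g, true_dry_mass_pg=ph.true_dry_mass)
            rec_pm = subtract_background(
                unwrap_phase(reconstruct_phase(ig, "auto"), config["unwrap_method"])
            )
            if save_images:
                write_phase_map(rec_pm, outdir / f"{image_id}_phase.h5", group=g)
            masks = segment_cells(
                rec_pm, threshold=float(config["phase_threshold"]),
                min_pixels=int(config["min_pixels"]),
            )
            for mk in masks:
                m = dry_mass(rec_pm, mk, alpha=float(config["alpha"]))
                records.append(
                    CellRecord(dry_mass=m, area=mk.area, group=g,
                               alpha=float(config["alpha"]),
                               image_id=image_id, component_id=mk.component_id)
                )
            truth_rows.append({"image_id": image_id, "group": g,
                               "true_dry_mass_pg": ph.true_dry_mass})
            idx += 1
    cells = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "component_id": [r.component_id for r in records],
            "group": [r.group for r in records],
            "area_um2": [r.area for r in records],
            "dry_mass_pg": [r.dry_mass for r in records],
            "matter_density_pg_per_um2": [r.matter_density for r in records],
        }
    )
    cells.to_csv(outdir / "cells.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "phantom_truth.csv", index=False)
    summary = summarize_groups(records)
    summary.to_csv(outdir / "group_summary.csv", index=False)

    pairs = (
        [(a, b) for i, a in enumerate(DOSE_GROUPS) for b in DOSE_GROUPS[i + 1:]]
        if config["all_pairs"]
        else [("control", g) for g in DOSE_GROUPS[1:]]
    )
    stat_rows = []
    for a, b in pairs:
        for col in ("dry_mass_pg", "matter_density_pg_per_um2"):
            wa = cells.loc[cells.group == a, col].to_numpy()
            wb = cells.loc[cells.group == b, col].to_numpy()
            w = welch_test(wa, wb, group_pair=(a, b))
            stat_rows.append({"quantity": col, "group_a": a, "group_b": b,
                              "t": w.t_statistic, "df": w.degrees_of_freedom,
                              "p_value": w.p_value})
    stats_df = pd.DataFrame(stat_rows)
    stats_df.to_csv(outdir / "welch_tests.csv", index=False)
    _plot_qpi_bars(summary, stats_df, outdir / "fig_biophysics.png")
    return cells, summary, stats_df


def _plot_qpi_bars(summary: pd.DataFrame, stats_df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, col, title in zip(
        axes,
        ("dry_mass_pg", "matter_density_pg_per_um2"),
        ("Dry mass (pg)", "Matter density (pg/um^2)"),
    ):
        ax.bar(summary["group"], summary[f"{col}_mean"], yerr=summary[f"{col}_std"],
               capsize=4, color="#7899c2")
        sig = stats_df[(stats_df.quantity == col) & (stats_df.p_value < 1e-4)]
        for _, row in sig.iterrows():
            ax.annotate("***", xy=(row["group_b"], summary.loc[
                summary.group == row["group_b"], f"{col}_mean"].iloc[0]),
                ha="center", va="bottom")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_raman(config: dict, outdir: Path):
    sim = _sim_config(config)
    axis = np.arange(config["raman_axis_lo"], config["raman_axis_hi"] + 1e-9,
                     config["raman_axis_step"])
    full = None
    for i, spec in enumerate(sim.groups):
        seed = int(np.random.SeedSequence([sim.seed, 11, i]).generate_state(1)[0] % (2**31))
        ds = make_spectra(spec, axis, seed=seed)
        full = ds if full is None else full.concat(ds)
    write_spectra_csv(full, outdir / "spectra_raw.csv", outdir / "labels.csv")
    proc = preprocess(full, degree=int(config["baseline_degree"]))
    write_spectra_csv(proc, outdir / "spectra_processed.csv")

    band_rows = []
    for center in config["band_centers"]:
        for g in DOSE_GROUPS:
            vals = np.array(
                [band_intensity(s, center, config["band_half_width"])
                 for s in proc.spectra() if s.group == g]
            )
            band_rows.append({"band_cm1": center, "group": g,
                              "mean": vals.mean(), "sd": vals.std(ddof=1),
                              "n": vals.size})
    bands = pd.DataFrame(band_rows)
    bands.to_csv(outdir / "band_intensities.csv", index=False)

    res = fit_pca(proc, n_components=int(config["n_components"]))
    pd.DataFrame(res.loadings.T, index=proc.axis,
                 columns=[f"PC{k+1}" for k in range(res.n_components)]
                 ).rename_axis("wavenumber_cm1").to_csv(outdir / "pca_loadings.csv")
    sc = pd.DataFrame(res.scores, columns=[f"PC{k+1}" for k in range(res.n_components)])
    sc.insert(0, "group", proc.labels)
    sc.to_csv(outdir / "pca_scores.csv", index=False)
    centroids, sil = score_scatter_3d(res, proc.labels, path=outdir / "fig_pca_scatter.png")
    centroids.to_csv(outdir / "pca_centroids.csv", index=False)
    _plot_mean_spectra(proc, outdir / "fig_mean_spectra.png")
    _plot_bands(bands, outdir / "fig_band_intensities.png")
    return proc, bands, res, sil


def _plot_mean_spectra(proc, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = group_mean_spectra(proc)
    fig, ax = plt.subplots(figsize=(8, 5))
    offset = 0.0
    for g, (mean, sd) in means.items():
        ax.fill_between(proc.axis, mean + offset - sd, mean + offset + sd, alpha=0.25)
        ax.plot(proc.axis, mean + offset, label=g)
        offset += 1.1 * float(np.ptp(mean))  # vertical offset for visibility
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("SNV intensity (offset)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_bands(bands: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = bands["band_cm1"].unique()
    fig, axes = plt.subplots(1, len(centers), figsize=(4.5 * len(centers), 4))
    axes = np.atleast_1d(axes)
    for ax, c in zip(axes, centers):
        sub = bands[bands.band_cm1 == c]
        ax.bar(sub["group"], sub["mean"], yerr=sub["sd"], capsize=4, color="#9c7fb8")
        ax.set_title(f"{c:g} cm$^{{-1}}$ band")
        ax.set_ylabel("mean SNV intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_viability(config: dict, outdir: Path):
    seed = int(np.random.SeedSequence([int(config["seed"]), 13]).generate_state(1)[0] % (2**31))
    table = make_viability_table(
        seed=seed,
        n_replicates=int(config["viability_replicates"]),
        noise_sd=float(config["viability_noise_sd"]),
    )
    table.to_csv(outdir / "viability_raw.csv", index=False)
    corrected = viability_correct(table)
    corrected.to_csv(outdir / "viability_corrected.csv", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(corrected["exposure_min"], corrected["mean"], yerr=corrected["std"],
                marker="o", capsize=4)
    ax.set_xlabel("UV exposure (min)")
    ax.set_ylabel("corrected absorbance A570 - A600(blank)")
    ax.set_title("Resazurin viability")
    fig.tight_layout()
    fig.savefig(outdir / "fig_viability.png", dpi=120)
    plt.close(fig)
    return corrected


def run_all(
    config: dict | str | Path,
    outdir: str | Path,
    only: str | None = None,
    save_images: bool = False,
) -> RunManifest:
    """Execute the configured arms in order and write a Markdown report.

    A failing stage aborts the run with the stage named; outputs of the
    stages that already completed stay on disk.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    arms = [only] if only else list(config["arms"])
    if only and only not in ARMS:
        raise ValueError(f"unknown arm {only!r}; choose from {ARMS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=int(config["seed"]))
    results: dict = {}
    for arm, runner in (("qpi", _run_qpi), ("raman", _run_raman),
                        ("viability", _run_viability)):
        if arm not in arms:
            continue
        arm_dir = outdir / arm
        arm_dir.mkdir(exist_ok=True)
        manifest.timestamps[f"{arm}_start"] = datetime.datetime.now().isoformat()
        try:
            if arm == "qpi":
                results[arm] = runner(config, arm_dir, save_images)
            else:
                results[arm] = runner(config, arm_dir)
        except Exception as e:  # noqa: BLE001 - re-raise with the stage named
            raise RuntimeError(f"pipeline stage '{arm}' failed: {e}") from e
        manifest.timestamps[f"{arm}_end"] = datetime.datetime.now().isoformat()
        manifest.stage_outputs[arm] = sorted(p.name for p in arm_dir.iterdir())
    dose_table(UV_IRRADIANCE).to_csv(outdir / "dosimetry.csv", index=False)
    _write_report(outdir, arms, results, manifest)
    manifest.write(outdir / "manifest.json")
    return manifest


def _write_report(outdir: Path, arms: list[str], results: dict,
                  manifest: RunManifest) -> None:
    lines = [
        "# Label-free UV-response profiling report",
        "",
        f"- config hash: `{manifest.config_hash}`, seed: {manifest.seed}, "
        f"version: {manifest.version}",
        "",
        "## Dosimetry",
        "",
        dose_table(UV_IRRADIANCE).to_markdown(index=False),
        "",
    ]
    if "viability" in arms:
        corrected = results["viability"]
        lines += ["## Viability (corrected absorbance)", "",
                  corrected.to_markdown(index=False), "",
                  "![viability](viability/fig_viability.png)", ""]
    else:
        lines += ["## Viability", "", "SKIPPED", ""]
    if "raman" in arms:
        _, bands, res, sil = results["raman"]
        evr = ", ".join(f"PC{k+1} {f:.1%}" for k, f in
                        enumerate(res.explained_variance_fraction))
        lines += ["## Raman chemometrics", "",
                  f"Explained variance: {evr}; 3-PC silhouette: {sil:.3f}", "",
                  bands.to_markdown(index=False), "",
                  "![mean spectra](raman/fig_mean_spectra.png)",
                  "![bands](raman/fig_band_intensities.png)",
                  "![pca](raman/fig_pca_scatter.png)", ""]
    else:
        lines += ["## Raman chemometrics", "", "SKIPPED", ""]
    if "qpi" in arms:
        _, summary, stats_df = results["qpi"]
        lines += ["## Biophysics (QPI)", "",
                  summary.to_markdown(index=False), "",
                  "### Welch tests", "",
                  stats_df.to_markdown(index=False), "",
                  "![biophysics](qpi/fig_biophysics.png)", ""]
    else:
        lines += ["## Biophysics (QPI)", "", "SKIPPED", ""]
    (outdir / "report.md").write_text("\n".join(lines))
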