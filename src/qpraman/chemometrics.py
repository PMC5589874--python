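"""PCA group discrimination, Welch-corrected testing, viability correction
and UV dosimetry.

PCA on SNV-preprocessed spectra (column mean-centring only — SNV already
row-standardises) keeps the first three components; group separation in
the 3-PC score space is summarised by the silhouette coefficient.  Group
differences in scalar readouts use the unpaired t-test with Welch
correction (unequal variances, Welch–Satterthwaite degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _PCA
from sklearn.metrics import silhouette_score

from .constants import DOSE_GROUPS, GROUP_MINUTES, UV_IRRADIANCE
from .raman import SpectralDataset

__all__ = [
    "PCAResult",
    "WelchResult",
    "DoseRecord",
    "fit_pca",
    "score_scatter_3d",
    "welch_test",
    "viability_correct",
    "fluence",
    "dose_table",
]


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance fractions of a PCA fit."""

    loadings: np.ndarray  # (n_components, n_wavenumbers)
    scores: np.ndarray  # (n_spectra, n_components)
    explained_variance_fraction: np.ndarray
    n_components: int
    mean: np.ndarray  # column means removed before decomposition

    def reconstruct(self) -> np.ndarray:
        """Project scores back through the loadings and restore the mean."""
        return self.scores @ self.loadings + self.mean


@dataclass
class WelchResult:
    """Unequal-variance two-sample t-test outcome."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    group_pair: tuple[str, str] = ("a", "b")


@dataclass
class DoseRecord:
    """One UV exposure condition; fluence is derived, J/cm²."""

    irradiance: float  # W/m²
    exposure_time: float  # s
    fluence: float = field(init=False)

    def __post_init__(self) -> None:
        if self.irradiance < 0 or self.exposure_time < 0:
            raise ValueError("irradiance and exposure time must be non-negative")
        self.fluence = self.irradiance * self.exposure_time / 1e4


def fit_pca(ds: SpectralDataset | np.ndarray, n_components: int = 3) -> PCAResult:
    """Principal components of a (preprocessed) spectral matrix.

    Column mean-centred, full SVD, components ordered by explained
    variance.  The sign of each component is fixed deterministically: its
    largest-magnitude loading element is made positive.
    """
    x = ds.matrix if isinstance(ds, SpectralDataset) else np.asarray(ds, dtype=float)
    if x.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} spectra to extract {n_components} components"
        )
    p = _PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(x)
    loadings = p.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=p.explained_variance_ratio_.copy(),
        n_components=n_components,
        mean=p.mean_.copy(),
    )


def score_scatter_3d(
    res: PCAResult,
    labels: list[str],
    path: str | None = None,
):
    """3-D PC-score scatter with per-group centroids and a silhouette
    separation summary.

    Returns ``(centroid_table, silhouette)``; when ``path`` is given a
    figure is also written there.  The silhouette coefficient on the
    3-PC scores quantifies what the scatter shows visually: values above
    ~0.3 indicate clearly separated dose groups.
    """
    if res.n_components < 3:
        raise ValueError("3-D score scatter requires at least 3 components")
    labels = list(labels)
    if len(labels) != res.scores.shape[0]:
        raise ValueError("one group label per spectrum is required")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("silhouette separation is undefined for a single group")
    pts = res.scores[:, :3]
    sil = float(silhouette_score(pts, labels))
    rows = []
    for g in uniq:
        sel = pts[[i for i, lab in enumerate(labels) if lab == g]]
        rows.append(
            {
                "group": g,
                "n": sel.shape[0],
                "pc1_mean": sel[:, 0].mean(),
                "pc2_mean": sel[:, 1].mean(),
                "pc3_mean": sel[:, 2].mean(),
                "spread": float(np.mean(np.linalg.norm(sel - sel.mean(axis=0), axis=1))),
            }
        )
    table = pd.DataFrame(rows)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for g in uniq:
            sel = pts[[i for i, lab in enumerate(labels) if lab == g]]
            ax.scatter(sel[:, 0], sel[:, 1], sel[:, 2], label=g, s=20)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_zlabel("PC3")
        ax.legend()
        ax.set_title(f"PC scores (silhouette = {sil:.2f})")
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return table, sil


def welch_test(a, b, group_pair: tuple[str, str] = ("a", "b")) -> WelchResult:
    """Unpaired t-test with Welch correction (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        group_pair=group_pair,
    )


def viability_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Correct resazurin-assay absorbances for the medium background.

    For every sample row the corrected absorbance is A570(sample) minus
    the mean A600 of the blank (reagent-only) rows.  Returns per-group
    mean ± sample SD in exposure order (unknown groups appended last).
    """
    required = {"group", "is_blank", "a570", "a600"}
    if not required.issubset(table.columns):
        raise ValueError(f"viability table must have columns {sorted(required)}")
    blanks = table[table["is_blank"]]
    if blanks.empty:
        raise ValueError("no blank rows: background correction impossible")
    background = float(blanks["a600"].mean())
    samples = table[~table["is_blank"]].copy()
    samples["corrected"] = samples["a570"] - background
    order = [g for g in DOSE_GROUPS if g in set(samples["group"])] + [
        g for g in samples["group"].unique() if g not in DOSE_GROUPS
    ]
    agg = (
        samples.groupby("group", sort=False)["corrected"]
        .agg(["mean", "std", "count"])
        .reindex(order)
        .reset_index()
    )
    agg["exposure_min"] = [GROUP_MINUTES.get(g, np.nan) for g in agg["group"]]
    return agg


def fluence(irradiance: float, minutes: float, paper_precision: bool = False) -> float:
    """UV fluence (J/cm²) delivered by ``irradiance`` W/m² over ``minutes``.

    J/m² = W/m² × s; divide by 10⁴ for J/cm².  With ``paper_precision``
    the value is rounded to one decimal, the precision dose protocols are
    commonly quoted at.
    """
    if irradiance < 0 or minutes < 0:
        raise ValueError("irradiance and exposure time must be non-negative")
    value = irradiance * minutes * 60.0 / 1e4
    return round(value, 1) if paper_precision else value


def dose_table(irradiance: float = UV_IRRADIANCE, paper_precision: bool = True) -> pd.DataFrame:
    """Fluence of each dose group at the instrument irradiance."""
    rows = [
        {
            "group": g,
            "exposure_min": GROUP_MINUTES[g],
            "irradiance_w_per_m2": irradiance,
            "fluence_j_per_cm2": fluence(irradiance, GROUP_MINUTES[g], paper_precision),
        }
        for g in DOSE_GROUPS
    ]
    return pd.DataFrame(rows)
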