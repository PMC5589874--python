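"""PCA discrimination, Welch testing, viability correction and dosimetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpraman.chemometrics import (
    DoseRecord,
    fit_pca,
    fluence,
    score_scatter_3d,
    viability_correct,
    welch_test,
)
from qpraman.raman import SpectralDataset


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(20)
        x = np.outer(rng.standard_normal(10), direction)
        res = fit_pca(x, n_components=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_against_covariance_eigendecomposition_oracle(self):
        """Loadings on a 5×10 toy matrix equal the covariance eigenvectors
        (computed independently) to 1e-8, up to sign."""
        rng = np.random.default_rng(12)
        x = rng.standard_normal((5, 10))
        res = fit_pca(x, n_components=3)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (x.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        for k in range(3):
            v = evecs[:, order[k]]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(res.loadings[k], v, atol=1e-8)
        total = np.trace(xc.T @ xc / (x.shape[0] - 1))
        np.testing.assert_allclose(
            res.explained_variance_fraction, np.sort(evals)[::-1][:3] / total, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        res = fit_pca(rng.standard_normal((30, 40)), n_components=3)
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(3), atol=1e-8)

    def test_explained_fractions_valid_and_ordered(self):
        rng = np.random.default_rng(9)
        res = fit_pca(rng.standard_normal((25, 12)), n_components=3)
        f = res.explained_variance_fraction
        assert np.all(f >= 0) and np.all(f <= 1) and f.sum() <= 1 + 1e-12
        assert np.all(np.diff(f) <= 1e-12)

    def test_isotropic_gaussian_splits_variance_equally(self):
        rng = np.random.default_rng(17)
        res = fit_pca(rng.standard_normal((4000, 3)), n_components=3)
        np.testing.assert_allclose(res.explained_variance_fraction, 1 / 3, atol=0.03)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((10, 6))
        res = fit_pca(x, n_components=2)
        for k in range(2):
            assert res.loadings[k, np.argmax(np.abs(res.loadings[k]))] > 0

    def test_reconstruction_error_equals_discarded_variance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 8)) @ np.diag([5, 3, 2, 1, 0.5, 0.3, 0.2, 0.1])
        res = fit_pca(x, n_components=3)
        xc = x - x.mean(axis=0)
        resid = xc - (res.scores @ res.loadings)
        discarded = 1.0 - res.explained_variance_fraction.sum()
        assert (resid**2).sum() / (xc**2).sum() == pytest.approx(discarded, rel=1e-8)

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_pca(np.zeros((3, 10)), n_components=3)


class TestScoreScatter:
    def _res(self, pts):
        return fit_pca(pts, n_components=3)

    def test_well_separated_groups_high_silhouette(self):
        rng = np.random.default_rng(1)
        groups, pts = [], []
        for i, g in enumerate(("control", "T50", "T100", "T200")):
            centre = np.zeros(6)
            centre[i] = 12.0
            pts.append(centre + 0.5 * rng.standard_normal((10, 6)))
            groups += [g] * 10
        res = self._res(np.vstack(pts))
        _, sil = score_scatter_3d(res, groups)
        assert sil > 0.5

    def test_degenerate_within_group_silhouette_near_one(self):
        pts = np.repeat(np.eye(3), 4, axis=0) * 10
        labels = [g for g in ("a", "b", "c") for _ in range(4)]
        res = fit_pca(pts + 1e-9 * np.arange(12)[:, None], n_components=3)
        _, sil = score_scatter_3d(res, labels)
        assert sil > 0.99

    def test_single_group_rejected(self):
        rng = np.random.default_rng(2)
        res = self._res(rng.standard_normal((8, 5)))
        with pytest.raises(ValueError, match="single group"):
            score_scatter_3d(res, ["control"] * 8)

    def test_label_count_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        res = self._res(rng.standard_normal((8, 5)))
        with pytest.raises(ValueError, match="label"):
            score_scatter_3d(res, ["control"] * 5)

    def test_centroid_table_and_figure(self, tmp_path):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.standard_normal((6, 4)), 8 + rng.standard_normal((6, 4))])
        labels = ["control"] * 6 + ["T200"] * 6
        res = self._res(pts)
        fig = tmp_path / "scatter.png"
        table, _ = score_scatter_3d(res, labels, path=str(fig))
        assert fig.exists()
        assert set(table["group"]) == {"control", "T200"}
        assert (table["n"] == 6).all()


class TestWelch:
    def test_identical_samples(self):
        res = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_rejects(self):
        res = welch_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert abs(res.t_statistic) > 50
        assert res.p_value < 1e-4

    def test_hand_worked_formulas(self):
        """a={10,12,14}, b={20,22,24}: t = −10/√(8/3) = −6.1237,
        Welch–Satterthwaite df = 4 (evaluated by hand beforehand)."""
        res = welch_test([10.0, 12.0, 14.0], [20.0, 22.0, 24.0])
        assert res.t_statistic == pytest.approx(-6.123724356957945, rel=1e-12)
        assert res.degrees_of_freedom == pytest.approx(4.0, rel=1e-12)
        assert res.p_value == pytest.approx(0.0036022326091040033, rel=1e-9)
        assert res.degrees_of_freedom > 0 and 0 <= res.p_value <= 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_test([1.0], [1.0, 2.0])

    def test_agreement_with_permutation_ranking(self):
        """Welch p-values order two-group problems the same way a
        brute-force permutation test does."""
        rng = np.random.default_rng(20)
        base = rng.normal(0, 1, 6)
        welch_ps, perm_ps = [], []
        for shift in (0.2, 1.0, 3.0):
            a, b = base, rng.normal(shift, 1, 6)
            welch_ps.append(welch_test(a, b).p_value)
            obs = abs(a.mean() - b.mean())
            pool = np.concatenate([a, b])
            count = 0
            n_perm = 2000
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                count += abs(perm[:6].mean() - perm[6:].mean()) >= obs
            perm_ps.append((count + 1) / (n_perm + 1))
        assert np.argsort(welch_ps).tolist() == np.argsort(perm_ps).tolist()


class TestViability:
    @staticmethod
    def _table(sample_570, blank_600, group="control"):
        return pd.DataFrame([
            {"group": group, "is_blank": False, "a570": sample_570, "a600": 0.2},
            {"group": "blank", "is_blank": True, "a570": 0.1, "a600": blank_600},
        ])

    def test_simple_subtraction(self):
        out = viability_correct(self._table(0.8, 0.1))
        assert out.loc[0, "mean"] == pytest.approx(0.7)

    def test_sample_equal_to_blank_gives_zero(self):
        out = viability_correct(self._table(0.1, 0.1))
        assert out.loc[0, "mean"] == pytest.approx(0.0)

    def test_missing_blank_rejected(self):
        t = self._table(0.8, 0.1)
        with pytest.raises(ValueError, match="blank"):
            viability_correct(t[~t["is_blank"]])


class TestDosimetry:
    def test_protocol_fluences_at_one_decimal(self):
        # 1.02 W/m² for 50/100/200 min → 0.3/0.6/1.2 J/cm²
        assert fluence(1.02, 50, paper_precision=True) == 0.3
        assert fluence(1.02, 100, paper_precision=True) == 0.6
        assert fluence(1.02, 200, paper_precision=True) == 1.2

    def test_full_precision_values(self):
        assert fluence(1.02, 50) == pytest.approx(0.306, rel=1e-12)

    def test_zero_time_zero_fluence(self):
        assert fluence(1.02, 0) == 0.0

    def test_unit_identity(self):
        # 1 W/m² × 10⁴ s = 10⁴ J/m² = 1 J/cm²
        assert fluence(1.0, 1e4 / 60.0) == pytest.approx(1.0, rel=1e-12)

    def test_linearity(self):
        assert fluence(2.0, 30) == pytest.approx(2 * fluence(1.0, 30))
        assert fluence(1.0, 60) == pytest.approx(2 * fluence(1.0, 30))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fluence(-1.0, 10)
        with pytest.raises(ValueError, match="non-negative"):
            DoseRecord(irradiance=1.0, exposure_time=-5.0)

    def test_dose_record_exact_conversion(self):
        rec = DoseRecord(irradiance=1.02, exposure_time=50 * 60)
        assert rec.fluence == 1.02 * 50 * 60 / 1e4

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0, 100, allow_nan=False), st.floats(0, 1000, allow_nan=False),
           st.floats(0.01, 10, allow_nan=False))
    def test_fluence_bilinear(self, irr, minutes, c):
        from hypothesis import assume

        assume(irr * minutes < 1e6)
        assert fluence(c * irr, minutes) == pytest.approx(c * fluence(irr, minutes), rel=1e-9)
        assert fluence(irr, c * minutes) == pytest.approx(c * fluence(irr, minutes), rel=1e-9)
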