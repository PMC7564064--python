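import numpy as np
import pytest

from ecoqsar.chem_core import Molecule3D
from ecoqsar.comsia import (
    AlignmentSpec,
    FieldGrid,
    GridSettings,
    PLSModel,
    align_to_template,
    compute_fields,
    contour_map,
    descriptor_matrix,
    field_fractions,
    loo_q2,
    make_grid,
    model_stats,
    pls_fit,
    relative_error_pct,
)
from ecoqsar.synthetic import SyntheticQSARSpec, generate_synthetic_qsar


def _toy(id_, coords, steric=None, charge=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    charges = np.zeros(n) if charge is None else np.asarray(charge, float)
    return Molecule3D(
        id=id_, symbols=["C"] * n, coords=coords,
        partial_charges=charges,
        steric_param=np.ones(n) if steric is None else np.asarray(steric, float),
        hydrophobic_param=np.full(n, 0.5),
        donor_flag=np.zeros(n, bool), acceptor_flag=np.ones(n, bool),
        formal_charge=0,
    )


def _rotation(theta, axis="z"):
    c, s = np.cos(theta), np.sin(theta)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


class TestAlignment:
    base = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0.7, 0.9, 1.1]])

    def test_template_aligned_to_itself_rmsd_zero(self):
        t = _toy("t", self.base)
        spec = AlignmentSpec("t", {})
        res = align_to_template([t], spec)
        assert res.rmsd["t"] == 0.0

    def test_known_rotation_recovered(self):
        t = _toy("t", self.base)
        R = _rotation(0.9)
        moved = _toy("m", self.base @ R.T + np.array([2.0, -1.0, 0.5]))
        spec = AlignmentSpec("t", {"m": [(i, i) for i in range(4)]})
        res = align_to_template([t, moved], spec)
        assert res.rmsd["m"] == pytest.approx(0.0, abs=1e-6)
        aligned = next(m for m in res.molecules if m.id == "m")
        np.testing.assert_allclose(aligned.coords, self.base, atol=1e-8)

    def test_too_few_pairs_rejected(self):
        t = _toy("t", self.base)
        m = _toy("m", self.base)
        spec = AlignmentSpec("t", {"m": [(0, 0), (1, 1)]})
        with pytest.raises(ValueError, match=">= 3"):
            align_to_template([t, m], spec)

    def test_noninjective_mapping_rejected(self):
        spec = AlignmentSpec("t", {"m": [(0, 0), (1, 0), (2, 2)]})
        with pytest.raises(ValueError, match="injective"):
            spec.validate()


class TestFields:
    def test_single_atom_closed_form(self):
        """Field = -w_probe * w_atom * exp(-alpha r^2) around a lone atom."""
        mol = _toy("one", [[0.0, 0.0, 0.0]], steric=[2.0])
        settings = GridSettings(spacing=1.0, margin=2.0, alpha=0.3)
        grid = compute_fields([mol], settings)
        pts = grid.points()
        expected = -2.0 * np.exp(-0.3 * (pts**2).sum(axis=1))
        np.testing.assert_allclose(grid.values["one"]["S"], expected, atol=1e-12)

    def test_empty_molecule_all_zero_fields(self):
        anchor = _toy("a", [[0.0, 0, 0], [1, 1, 1.0]])
        empty = Molecule3D(id="none", symbols=[], coords=np.zeros((0, 3)),
                           partial_charges=np.zeros(0), steric_param=np.zeros(0),
                           hydrophobic_param=np.zeros(0),
                           donor_flag=np.zeros(0, bool), acceptor_flag=np.zeros(0, bool))
        grid = compute_fields([anchor], GridSettings(spacing=1.0, margin=1.0))
        grid = compute_fields([empty], grid=grid)
        assert not np.any(grid.values["none"]["S"])

    def test_steric_field_linear_in_parameters(self):
        mol = _toy("m", [[0.0, 0, 0], [1.2, 0.3, -0.5]], steric=[1.0, 3.0])
        double = _toy("m2", [[0.0, 0, 0], [1.2, 0.3, -0.5]], steric=[2.0, 6.0])
        grid = compute_fields([mol], GridSettings(spacing=1.5, margin=2.0))
        grid = compute_fields([double], grid=grid)
        np.testing.assert_allclose(grid.values["m2"]["S"], 2 * grid.values["m"]["S"],
                                   rtol=1e-12)

    def test_rigid_motion_equivariance(self):
        """A 90-degree rotation of molecules and lattice leaves the field values intact."""
        mol = _toy("m", [[0.0, 0, 0], [1.0, 0.5, -0.3], [2.0, 1.0, 0.8]],
                   steric=[1.0, 2.0, 3.0])
        settings = GridSettings(spacing=1.0, margin=2.0)
        g1 = compute_fields([mol], settings)
        R = _rotation(np.pi / 2)
        rotated = mol.copy()
        rotated.coords = mol.coords @ R.T
        # rotate the lattice explicitly: same points, rotated with the molecule
        pts1 = g1.points()
        d2 = ((pts1 @ R.T)[:, None, :] - rotated.coords[None, :, :]) ** 2
        K = np.exp(-settings.alpha * d2.sum(axis=2))
        rotated_vals = -(K @ rotated.steric_param)
        np.testing.assert_allclose(rotated_vals, g1.values["m"]["S"], atol=1e-10)

    def test_grid_must_enclose_molecule(self):
        mol = _toy("m", [[0.0, 0, 0]])
        grid = compute_fields([mol], GridSettings(spacing=1.0, margin=1.0))
        outside = _toy("far", [[50.0, 0, 0]])
        with pytest.raises(ValueError, match="outside"):
            compute_fields([outside], grid=grid)

    def test_descriptor_matrix_layout(self):
        mol = _toy("m", [[0.0, 0, 0]])
        grid = compute_fields([mol], GridSettings(spacing=2.0, margin=2.0))
        X, labels = descriptor_matrix(grid, ["m"])
        assert X.shape == (1, 5 * grid.n_points)
        assert list(dict.fromkeys(labels)) == ["S", "E", "H", "D", "A"]


class TestPLS:
    def test_exact_linear_full_rank_r2_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        y = X @ rng.normal(size=5)
        model = pls_fit(X, y, 5)
        stats = model_stats(model, X, y)
        assert stats.r2 == pytest.approx(1.0, abs=1e-9)
        assert stats.SEE == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_coefficients_match_reference_implementation(self, n):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 40))
        y = X @ rng.normal(size=40) * 0.1 + rng.normal(size=15)
        ours = pls_fit(X, y, n)
        ref = PLSRegression(n_components=n, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)

    def test_r2_nondecreasing_in_components(self, synthetic_noisy):
        X, y = synthetic_noisy.X, synthetic_noisy.y
        r2s = [model_stats(pls_fit(X, y, n), X, y).r2 for n in range(1, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_n_components_bounds_enforced(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        with pytest.raises(ValueError, match="n_components"):
            pls_fit(X, y, 5)  # > m - 1
        with pytest.raises(ValueError, match="n_components"):
            pls_fit(X, y, 0)

    def test_predict_training_reproduces_fitted(self, synthetic_noisy):
        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 3)
        np.testing.assert_allclose(model.predict(synthetic_noisy.X), model.fitted,
                                   atol=1e-12)

    def test_mean_input_predicts_training_mean(self, synthetic_noisy):
        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 3)
        x_mean_row = synthetic_noisy.X.mean(axis=0, keepdims=True)
        assert model.predict(x_mean_row)[0] == pytest.approx(synthetic_noisy.y.mean(),
                                                             abs=1e-10)

    def test_model_json_roundtrip(self, tmp_path, synthetic_noisy):
        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 2,
                        field_labels=synthetic_noisy.field_labels)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSModel.from_json(path)
        np.testing.assert_allclose(back.predict(synthetic_noisy.X),
                                   model.predict(synthetic_noisy.X), atol=1e-12)


class TestLOO:
    def test_matches_explicit_refit_loop(self, synthetic_noisy):
        X, y = synthetic_noisy.X, synthetic_noisy.y
        q2, press = loo_q2(X, y, 2)
        brute_press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            m = pls_fit(X[keep], y[keep], 2)
            brute_press += float((m.predict(X[i : i + 1])[0] - y[i]) ** 2)
        brute_q2 = 1.0 - brute_press / float(((y - y.mean()) ** 2).sum())
        assert q2 == pytest.approx(brute_q2, abs=1e-10)

    def test_matches_independent_reference_loop(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 25))
        y = X[:, 0] * 0.5 + rng.normal(size=12) * 0.1
        q2, _ = loo_q2(X, y, 2)
        press = 0.0
        for i in range(12):
            keep = np.arange(12) != i
            ref = PLSRegression(n_components=2, scale=False).fit(X[keep], y[keep])
            press += float((ref.predict(X[i : i + 1]).ravel()[0] - y[i]) ** 2)
        ref_q2 = 1.0 - press / float(((y - y.mean()) ** 2).sum())
        assert q2 == pytest.approx(ref_q2, abs=1e-8)

    def test_strong_linear_fixture_high_q2(self, synthetic_noiseless):
        q2, _ = loo_q2(synthetic_noiseless.X, synthetic_noiseless.y, 4)
        assert q2 > 0.9

    def test_permuted_response_destroys_q2(self, synthetic_noiseless):
        X = synthetic_noiseless.X
        worst = -np.inf
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(synthetic_noiseless.y)
            q2, _ = loo_q2(X, y_perm, 2)
            worst = max(worst, q2)
        assert worst <= 0.2


class TestModelStats:
    def test_perfect_external_test(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0])
        model = pls_fit(X, y, 4)
        stats = model_stats(model, X, y, X, y)
        assert stats.r2_pred == pytest.approx(1.0, abs=1e-9)
        assert stats.SEP == pytest.approx(0.0, abs=1e-7)

    def test_underdetermined_dof_is_an_error(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 10))
        y = rng.normal(size=4)
        model = pls_fit(X, y, 3)
        with pytest.raises(ValueError, match="SEE/F undefined"):
            model_stats(model, X, y)

    def test_adequacy_thresholds(self):
        from ecoqsar.comsia import ModelStats

        good = ModelStats(q2=0.62, r2=0.99, SEE=0.01, F=100.0, r2_pred=0.66, SEP=0.16)
        assert good.predictive
        bad = ModelStats(q2=0.4, r2=0.99, SEE=0.01, F=100.0)
        assert not bad.predictive

    def test_relative_error_sign_convention(self):
        assert relative_error_pct(0.563, 0.526) == pytest.approx(7.03, abs=0.01)
        with pytest.raises(ValueError):
            relative_error_pct(1.0, 0.0)


class TestFieldFractionsAndMaps:
    def test_fractions_sum_to_100_and_order(self, synthetic_noisy):
        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 3,
                        field_labels=synthetic_noisy.field_labels)
        fr = field_fractions(model)
        assert sum(fr.values()) == pytest.approx(100.0, abs=0.1)
        assert list(fr) == ["S", "E", "H", "D", "A"]

    def test_single_field_model_gets_100(self, synthetic_noisy):
        n_pts = synthetic_noisy.grid.n_points
        X = synthetic_noisy.X[:, :n_pts]
        labels = synthetic_noisy.field_labels[:n_pts]
        model = pls_fit(X, synthetic_noisy.y, 2, field_labels=labels)
        fr = field_fractions(model)
        assert fr["S"] == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_coefficients_give_empty_masks(self, synthetic_noisy):
        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 1,
                        field_labels=synthetic_noisy.field_labels)
        model.coef = np.zeros_like(model.coef)
        cmap = contour_map(model, synthetic_noisy.grid, "S")
        assert not cmap.favored_mask.any()
        assert not cmap.disfavored_mask.any()

    def test_favored_mask_is_percentile_cut(self, synthetic_noisy):
        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 3,
                        field_labels=synthetic_noisy.field_labels)
        cmap = contour_map(model, synthetic_noisy.grid, "S", favored_percentile=80)
        pos = cmap.values[cmap.values > 0]
        assert cmap.favored_mask.sum() == int((pos > np.percentile(pos, 80)).sum())

    def test_planted_region_recovered_by_map(self, synthetic_noiseless):
        """The favored-region centroid lands near the planted steric hot spot."""
        data = synthetic_noiseless
        model = pls_fit(data.X, data.y, 4, field_labels=data.field_labels)
        cmap = contour_map(model, data.grid, "S", favored_percentile=80)
        pts = data.grid.points()
        # steric atom weights are positive and the field sign convention is
        # negative, so the planted bump pulls coefficients negative there
        strong = cmap.disfavored_mask
        assert strong.any()
        centroid = pts[strong].mean(axis=0)
        assert np.linalg.norm(centroid - data.planted_centers["S"]) <= 2 * data.grid.spacing

    def test_opendx_and_csv_export(self, tmp_path, synthetic_noisy):
        from ecoqsar.comsia import write_opendx, write_point_csv

        model = pls_fit(synthetic_noisy.X, synthetic_noisy.y, 2,
                        field_labels=synthetic_noisy.field_labels)
        cmap = contour_map(model, synthetic_noisy.grid, "H")
        dx = tmp_path / "map.dx"
        csv = tmp_path / "map.csv"
        write_opendx(cmap, dx)
        write_point_csv(cmap, csv)
        text = dx.read_text()
        assert "gridpositions" in text and f"items {cmap.values.size}" in text
        import pandas as pd

        df = pd.read_csv(csv)
        assert len(df) == synthetic_noisy.grid.n_points
        assert {"x", "y", "z", "stdev_coeff", "favored", "disfavored"} <= set(df.columns)
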