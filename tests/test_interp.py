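import numpy as np
import pytest

from biospat.errors import (
    ConfigError,
    DegenerateInputError,
    DroppedDataWarning,
    SchemaError,
)
from biospat.interp import (
    SampleSet,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    glm_fit,
    glm_predict_surface,
    nn_interpolate,
    ordinary_krige,
    read_samples,
    sampling_effort,
    tps_interpolate,
)
from biospat.io import OccurrenceTable
from biospat.io.raster import grid_from_bounds


def grid_with_centers_at(coords, pad=1.0, res=1.0):
    coords = np.asarray(coords, dtype=float)
    xmin = coords[:, 0].min() - pad
    ymin = coords[:, 1].min() - pad
    # shift so that sample coords fall exactly on cell centers
    xmin = coords[:, 0].min() - res / 2
    ymin = coords[:, 1].min() - res / 2
    xmax = coords[:, 0].max() + res / 2
    ymax = coords[:, 1].max() + res / 2
    return grid_from_bounds(xmin, ymin, xmax, ymax, res=res)


class TestReadSamples:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("dependent,x,y\n1.5,0,0\n2.5,1,1\n")
        s = read_samples(p)
        assert len(s) == 2
        np.testing.assert_allclose(s.values, [1.5, 2.5])

    def test_missing_column(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("value,x,y\n1,0,0\n")
        with pytest.raises(SchemaError, match="dependent"):
            read_samples(p)


class TestNNInterpolate:
    def test_single_sample_constant(self):
        s = SampleSet([5.0], [5.0], [3.25])
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        g = nn_interpolate(s, target)
        assert np.allclose(g.valid_values(), 3.25)

    def test_coincident_cell_gets_sample_value(self):
        s = SampleSet([0.5, 9.5], [0.5, 9.5], [1.0, 2.0])
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        g = nn_interpolate(s, target)
        assert g.values[9, 0] == 1.0  # cell center (0.5, 0.5)
        assert g.values[0, 9] == 2.0

    def test_midpoint_tie_goes_to_first_sample(self):
        # cell center (1.5, 0.5) is equidistant from both samples
        s = SampleSet([1.0, 2.0], [0.5, 0.5], [10.0, 20.0])
        target = grid_from_bounds(0, 0, 3, 1, res=1.0)
        g = nn_interpolate(s, target)
        assert g.values[0, 1] == 10.0


class TestTPS:
    def test_plane_reproduction(self):
        rng = np.random.default_rng(0)
        x, y = rng.uniform(0, 10, 25), rng.uniform(0, 10, 25)
        s = SampleSet(x, y, 2 * x + 3 * y + 1)
        target = grid_from_bounds(0, 0, 10, 10, res=0.5)
        g = tps_interpolate(s, target, smoothing=0.0)
        xs, ys = g.cell_centers()
        v = g.valid
        np.testing.assert_allclose(
            g.values[v], (2 * xs + 3 * ys + 1)[v].astype(np.float32), atol=1e-4
        )

    def test_exact_at_samples(self):
        rng = np.random.default_rng(1)
        coords = np.round(rng.uniform(1, 9, size=(12, 2))) + 0.5
        coords = np.unique(coords, axis=0)
        vals = rng.normal(size=len(coords))
        s = SampleSet(coords[:, 0], coords[:, 1], vals)
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        g = tps_interpolate(s, target, smoothing=0.0)
        sampled = g.sample(coords[:, 0], coords[:, 1])
        np.testing.assert_allclose(sampled, vals, atol=1e-5)

    def test_large_smoothing_approaches_plane(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 10, 40), rng.uniform(0, 10, 40)
        z = 1 + 0.5 * x - 0.2 * y + rng.normal(0, 0.5, 40)
        s = SampleSet(x, y, z)
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        g = tps_interpolate(s, target, smoothing=1e8)
        # least-squares plane oracle
        A = np.column_stack([np.ones(40), x, y])
        beta = np.linalg.lstsq(A, z, rcond=None)[0]
        xs, ys = g.cell_centers()
        plane = beta[0] + beta[1] * xs + beta[2] * ys
        np.testing.assert_allclose(g.values[g.valid], plane[g.valid], atol=0.05)

    def test_collinear_samples_error(self):
        s = SampleSet([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
        target = grid_from_bounds(0, 0, 3, 3, res=1.0)
        with pytest.raises(DegenerateInputError, match="smoothing"):
            tps_interpolate(s, target, smoothing=0.0)


class TestVariogram:
    def test_constant_field_zero(self):
        rng = np.random.default_rng(0)
        s = SampleSet(rng.uniform(0, 10, 30), rng.uniform(0, 10, 30), np.full(30, 7.0))
        table = empirical_variogram(s, n_bins=5)
        filled = table.dropna(subset=["semivariance"])
        assert (filled["semivariance"] == 0).all()

    def test_single_pair_value(self):
        s = SampleSet([0.0, 1.0], [0.0, 0.0], [0.0, 2.0])
        table = empirical_variogram(s, n_bins=1, max_dist=2.0)
        assert table["semivariance"].iloc[0] == pytest.approx(2.0)
        assert table["n_pairs"].iloc[0] == 1

    def test_white_noise_pure_nugget(self):
        rng = np.random.default_rng(3)
        n = 400
        sigma2 = 4.0
        s = SampleSet(
            rng.uniform(0, 100, n), rng.uniform(0, 100, n), rng.normal(0, 2.0, n)
        )
        table = empirical_variogram(s, n_bins=8)
        filled = table.dropna(subset=["semivariance"])
        se = sigma2 * np.sqrt(2.0 / filled["n_pairs"])
        assert (np.abs(filled["semivariance"] - sigma2) < 4 * se).all()

    def test_coincident_points_error(self):
        s = SampleSet([1.0, 1.0], [2.0, 2.0], [0.0, 1.0])
        with pytest.raises(DegenerateInputError):
            empirical_variogram(s)

    def test_fit_recovers_exponential(self):
        vm_true = VariogramModel("exponential", 0.5, 2.5, 20.0)
        h = np.linspace(1, 60, 30)
        import pandas as pd

        table = pd.DataFrame(
            {
                "lag": h,
                "semivariance": vm_true.semivariance(h),
                "n_pairs": np.full(30, 100),
            }
        )
        vm = fit_variogram(table, "exponential")
        assert vm.nugget == pytest.approx(0.5, abs=0.05)
        assert vm.sill == pytest.approx(2.5, abs=0.1)
        assert vm.range_ == pytest.approx(20.0, rel=0.1)

    def test_model_validation(self):
        with pytest.raises(ConfigError):
            VariogramModel("exponential", 1.0, 0.5, 10.0)
        with pytest.raises(ConfigError):
            VariogramModel("nope", 0.0, 1.0, 10.0)


class TestOrdinaryKrige:
    def test_exact_at_sample_locations_zero_nugget(self):
        rng = np.random.default_rng(4)
        coords = np.unique(rng.integers(0, 10, size=(25, 2)), axis=0) + 0.5
        vals = rng.normal(size=len(coords))
        s = SampleSet(coords[:, 0], coords[:, 1], vals)
        vm = VariogramModel("exponential", 0.0, 1.0, 5.0)
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        pred, var = ordinary_krige(s, vm, target)
        np.testing.assert_allclose(
            pred.sample(coords[:, 0], coords[:, 1]), vals, atol=1e-5
        )
        assert (var.valid_values() >= 0).all()

    def test_constant_samples(self):
        rng = np.random.default_rng(5)
        coords = np.unique(rng.integers(0, 10, size=(20, 2)), axis=0) + 0.5
        s = SampleSet(coords[:, 0], coords[:, 1], np.full(len(coords), 2.5))
        nugget = 0.4
        vm = VariogramModel("exponential", nugget, nugget + 1e-9, 5.0)
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        pred, var = ordinary_krige(s, vm, target)
        np.testing.assert_allclose(pred.valid_values(), 2.5, atol=1e-5)
        far = var.valid_values()
        assert np.abs(far - nugget).min() < nugget * 0.2

    def test_duplicates_averaged_with_warning(self):
        s = SampleSet([1.5, 1.5, 5.5, 8.5], [1.5, 1.5, 5.5, 8.5], [1.0, 3.0, 5.0, 7.0])
        vm = VariogramModel("exponential", 0.0, 1.0, 5.0)
        target = grid_from_bounds(0, 0, 10, 10, res=1.0)
        with pytest.warns(DroppedDataWarning, match="duplicate"):
            pred, _ = ordinary_krige(s, vm, target)
        assert pred.sample([1.5], [1.5])[0] == pytest.approx(2.0, abs=1e-5)

    def test_kriging_beats_nn_on_smooth_process(self):
        # 1-D transect from an exponential-covariance Gaussian process
        rng = np.random.default_rng(6)
        n = 80
        x = np.sort(rng.uniform(0, 100, n))
        y = np.zeros(n)
        h = np.abs(x[:, None] - x[None, :])
        cov = np.exp(-3 * h / 40.0)
        z = np.linalg.cholesky(cov + 1e-10 * np.eye(n)) @ rng.normal(size=n)
        hold = rng.choice(n, size=15, replace=False)
        train = np.setdiff1d(np.arange(n), hold)
        s = SampleSet(x[train], y[train] + 0.125, z[train])
        vm = VariogramModel("exponential", 0.0, 1.0, 40.0)
        target = grid_from_bounds(0, 0, 100, 0.25, res=0.25)
        pred_k, _ = ordinary_krige(s, vm, target)
        pred_n = nn_interpolate(s, target)
        mse_k = np.mean((pred_k.sample(x[hold], np.full(15, 0.125)) - z[hold]) ** 2)
        mse_n = np.mean((pred_n.sample(x[hold], np.full(15, 0.125)) - z[hold]) ** 2)
        assert mse_k < mse_n


class TestGLM:
    def _stack(self, stack_factory, seed=0, shape=(20, 20)):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, shape)
        b = rng.uniform(0, 1, shape)
        return stack_factory([a, b], names=["a", "b"])

    def test_gaussian_noiseless_recovery(self, stack_factory):
        import warnings

        stack = self._stack(stack_factory)
        xs, ys = stack.grids[0].cell_centers()
        rng = np.random.default_rng(1)
        sel = rng.choice(xs.size, 80, replace=False)
        px, py = xs.ravel()[sel], ys.ravel()[sel]
        a = stack["a"].sample(px, py)
        b = stack["b"].sample(px, py)
        yv = 2.0 + 1.5 * a - 0.75 * b
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = glm_fit(SampleSet(px, py, yv), stack, "gaussian")
        np.testing.assert_allclose(model.coefficients, [2.0, 1.5, -0.75], atol=1e-6)
        assert model.deviance_explained == pytest.approx(100.0, abs=1e-6)

    def test_intercept_only_predicts_mean(self, stack_factory):
        stack = self._stack(stack_factory)
        rng = np.random.default_rng(2)
        yv = rng.normal(5.0, 1.0, 30)
        px = rng.uniform(0, 20, 30)
        py = rng.uniform(0, 20, 30)
        model = glm_fit(SampleSet(px, py, yv), None, "gaussian")
        surface = glm_predict_surface(model, stack)
        np.testing.assert_allclose(surface.valid_values(), yv.mean(), atol=1e-5)

    def test_poisson_recovery(self, stack_factory):
        rng = np.random.default_rng(7)
        shape = (25, 25)
        stack = stack_factory([rng.uniform(-2, 2, shape)], names=["a"])
        xs, ys = stack.grids[0].cell_centers()
        sel = rng.choice(xs.size, 500, replace=False)
        px, py = xs.ravel()[sel], ys.ravel()[sel]
        a = stack["a"].sample(px, py)
        rate = np.exp(0.5 + 0.8 * a)
        counts = rng.poisson(rate)
        model = glm_fit(SampleSet(px, py, counts.astype(float)), stack, "poisson")
        assert abs(model.coefficients[1] - 0.8) < 0.05
        surface = glm_predict_surface(model, stack)
        assert (surface.valid_values() > 0).all()

    def test_collinear_bands_named(self, stack_factory):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (10, 10))
        stack = stack_factory([a, 2 * a], names=["a", "a2"])
        xs, ys = stack.grids[0].cell_centers()
        s = SampleSet(xs.ravel()[:50], ys.ravel()[:50], rng.normal(size=50))
        with pytest.raises(DegenerateInputError, match="a2"):
            glm_fit(s, stack, "gaussian")

    def test_too_few_samples(self, stack_factory):
        stack = self._stack(stack_factory)
        s = SampleSet([0.5, 1.5, 2.5], [0.5, 1.5, 2.5], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            glm_fit(s, stack, "gaussian")


class TestSamplingEffort:
    def test_mass_conservation_coincident(self):
        n = 25
        with pytest.warns(DroppedDataWarning, match="duplicate"):
            occ = OccurrenceTable(
                np.asarray(["a"] * n, dtype=object), np.full(n, 10.0), np.full(n, 10.0)
            )
        target = grid_from_bounds(0, 0, 20, 20, res=0.25)
        density = sampling_effort(occ, target, bandwidth=3.0)
        total = density.valid_values().sum() * density.cell_area
        assert total == pytest.approx(n, rel=0.02)

    def test_uniform_points_flat(self):
        rng = np.random.default_rng(8)
        n = 2000
        occ = OccurrenceTable(
            np.asarray(["a"] * n, dtype=object),
            rng.uniform(0, 50, n),
            rng.uniform(0, 50, n),
        )
        target = grid_from_bounds(0, 0, 50, 50, res=1.0)
        density = sampling_effort(occ, target, bandwidth=10.0)
        interior = density.values[15:35, 15:35].astype(float)
        assert interior.std() / interior.mean() < 0.2

    def test_bad_bandwidth(self):
        occ = OccurrenceTable(np.asarray(["a"], dtype=object), [0.0], [0.0])
        with pytest.raises(ConfigError):
            sampling_effort(occ, grid_from_bounds(0, 0, 1, 1, res=0.5), bandwidth=0.0)
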