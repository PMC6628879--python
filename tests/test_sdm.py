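import numpy as np
import pytest
import shapely.geometry as sgeom
from hypothesis import given, settings
from hypothesis import strategies as st

from biospat.errors import (
    ConfigError,
    DegenerateInputError,
    DroppedDataWarning,
    UndefinedStatisticError,
)
from biospat.io import OccurrenceTable
from biospat.io.raster import grid_from_bounds
from biospat.io.vector import StudyArea
from biospat.sdm import (
    ConfusionCounts,
    area_of_distribution,
    auc,
    bioclim_envelope,
    confusion_statistics,
    create_sample_points,
    extract_values_to_points,
    minimum_convex_hull,
    niche_overlap,
    pseudo_absences_evidence,
    pseudo_absences_random,
    rescale01,
    sum_of_maps,
    validate_binary,
)


def occ_of(x, y, name="sp"):
    return OccurrenceTable(np.asarray([name] * len(x), dtype=object), x, y)


class TestBioclim:
    def test_median_cell_scores_one(self, stack_factory):
        # band = column index; presences at columns 0..8 → median value 4
        band = np.tile(np.arange(9, dtype=float), (9, 1))
        stack = stack_factory([band], names=["env"])
        px = np.arange(9) + 0.5  # one presence per column, row 4
        py = np.full(9, 4.5)
        suit = bioclim_envelope(occ_of(px, py), stack)
        # cells in the median column have p = 0.5 → suitability 1
        assert np.allclose(suit.values.astype(float)[:, 4], 1.0)

    def test_envelope_and_interior(self, stack_factory):
        rng = np.random.default_rng(1)
        a = np.linspace(0, 100, 400).reshape(20, 20)
        stack = stack_factory([a], names=["env"])
        xs, ys = stack.grids[0].cell_centers()
        # presences on cells with values in [40, 60]
        inside = (a >= 40) & (a <= 60)
        sel = np.argwhere(inside)[rng.choice(inside.sum(), 30)]
        suit = bioclim_envelope(occ_of(xs[sel[:, 0], sel[:, 1]], ys[sel[:, 0], sel[:, 1]]), stack)
        vals = suit.values.astype(float)
        assert (vals[a < 39.9] == 0).all()
        assert (vals[a > 60.1] == 0).all()
        mid = np.abs(a - 50) < 2
        assert vals[mid].mean() > 0.5

    def test_cell_below_minimum_zero(self, stack_factory):
        a = np.arange(100, dtype=float).reshape(10, 10)
        stack = stack_factory([a], names=["env"])
        xs, ys = stack.grids[0].cell_centers()
        sel = a.ravel() >= 50
        suit = bioclim_envelope(occ_of(xs.ravel()[sel], ys.ravel()[sel]), stack)
        assert (suit.values.astype(float)[a < 50] == 0).all()

    def test_constant_band_skipped(self, stack_factory):
        a = np.arange(100, dtype=float).reshape(10, 10)
        stack = stack_factory([a, np.full((10, 10), 3.0)], names=["env", "flat"])
        xs, ys = stack.grids[0].cell_centers()
        with pytest.warns(DroppedDataWarning, match="flat"):
            suit = bioclim_envelope(
                occ_of(xs.ravel()[:30:3], ys.ravel()[:30:3]), stack
            )
        assert suit.valid.all()

    def test_box_construction(self, stack_factory):
        rng = np.random.default_rng(5)
        shape = (30, 30)
        stack = stack_factory(
            [rng.uniform(0, 1, shape), rng.uniform(0, 1, shape)], names=["u", "v"]
        )
        xs, ys = stack.grids[0].cell_centers()
        u = stack["u"].values.astype(float)
        v = stack["v"].values.astype(float)
        inbox = (u > 0.3) & (u < 0.7) & (v > 0.3) & (v < 0.7)
        sel = np.argwhere(inbox)[rng.choice(inbox.sum(), 40)]
        suit = bioclim_envelope(
            occ_of(xs[sel[:, 0], sel[:, 1]], ys[sel[:, 0], sel[:, 1]]), stack
        )
        vals = suit.values.astype(float)
        outside = (u < 0.25) | (u > 0.75) | (v < 0.25) | (v > 0.75)
        assert (vals[outside] == 0).all()
        held = inbox & ~outside
        assert vals[held].mean() > vals.mean()


class TestPseudoAbsences:
    def test_random_uniform_without_presences(self, square10):
        out = pseudo_absences_random(None, square10, n=10, seed=0)
        assert len(out) == 10
        assert square10.contains_xy(out.x, out.y).all()

    def test_min_dist_respected(self, square10):
        pres = occ_of(np.array([5.0]), np.array([5.0]))
        out = pseudo_absences_random(pres, square10, n=50, min_dist=2.0, seed=1)
        d = np.hypot(out.x - 5.0, out.y - 5.0)
        assert (d >= 2.0).all()

    def test_seed_determinism(self, square10):
        pres = occ_of(np.array([5.0]), np.array([5.0]))
        a = pseudo_absences_random(pres, square10, n=20, min_dist=1.0, seed=42)
        b = pseudo_absences_random(pres, square10, n=20, min_dist=1.0, seed=42)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_impossible_placement_reports_count(self, unit_square):
        pres = occ_of(np.array([0.5]), np.array([0.5]))
        with pytest.raises(DegenerateInputError, match="0 of 5"):
            pseudo_absences_random(pres, unit_square, n=5, min_dist=10.0, seed=0, max_tries=3)

    def test_evidence_concentrates_in_sampled_half(self):
        area = StudyArea(sgeom.box(0, 0, 20, 10))
        rng = np.random.default_rng(2)
        group = occ_of(rng.uniform(0, 10, 400), rng.uniform(0, 10, 400), "group")
        pres = occ_of(np.array([19.0]), np.array([9.0]))
        target = grid_from_bounds(0, 0, 20, 10, res=0.5)
        out = pseudo_absences_evidence(
            group, pres, area, target, n=100, bandwidth=3.0, seed=3
        )
        assert (out.x < 10 + 3.0).mean() >= 0.9

    def test_evidence_no_eligible_cells(self):
        area = StudyArea(sgeom.box(0, 0, 4, 4))
        rng = np.random.default_rng(4)
        group = occ_of(rng.uniform(0, 4, 50), rng.uniform(0, 4, 50), "group")
        # focal presences everywhere → every cell within min_dist of a presence
        xs, ys = np.meshgrid(np.arange(0.5, 4, 1.0), np.arange(0.5, 4, 1.0))
        pres = occ_of(xs.ravel(), ys.ravel())
        target = grid_from_bounds(0, 0, 4, 4, res=1.0)
        with pytest.raises(DegenerateInputError, match="eligible"):
            pseudo_absences_evidence(
                group, pres, area, target, n=5, bandwidth=2.0, min_dist=2.0, seed=0
            )

    def test_evidence_seed_determinism(self):
        area = StudyArea(sgeom.box(0, 0, 20, 10))
        rng = np.random.default_rng(5)
        group = occ_of(rng.uniform(0, 20, 300), rng.uniform(0, 10, 300), "group")
        pres = occ_of(np.array([1.0]), np.array([1.0]))
        target = grid_from_bounds(0, 0, 20, 10, res=0.5)
        kw = dict(n=40, bandwidth=3.0, seed=11)
        a = pseudo_absences_evidence(group, pres, area, target, **kw)
        b = pseudo_absences_evidence(group, pres, area, target, **kw)
        np.testing.assert_array_equal(a.x, b.x)

    def test_evidence_follows_density(self):
        # chi-square GOF of draw frequencies against the effort density
        area = StudyArea(sgeom.box(0, 0, 10, 10))
        rng = np.random.default_rng(6)
        group = occ_of(rng.uniform(0, 10, 500), rng.uniform(0, 10, 500), "group")
        pres = occ_of(np.array([-100.0]), np.array([-100.0]))
        target = grid_from_bounds(0, 0, 10, 10, res=2.0)
        from biospat.interp import sampling_effort

        effort = sampling_effort(group, target, area, bandwidth=4.0)
        counts = np.zeros(effort.values.shape)
        draws = 4_000
        per_call = 10
        for s in range(draws // per_call):
            out = pseudo_absences_evidence(
                group, pres, area, target, n=per_call, bandwidth=4.0, seed=s
            )
            rows, cols = effort.transform.rowcol(out.x, out.y)
            np.add.at(counts, (rows, cols), 1)
        dens = effort.values.astype(float)
        # within-replicate draws are without replacement, which only flattens
        # the expected frequencies slightly at n=10 of 25 cells; the GOF is a
        # sanity check at loose tolerance
        expected = dens / dens.sum() * counts.sum()
        mask = expected > 20
        chi2 = (((counts - expected) ** 2) / expected)[mask].sum()
        from scipy.stats import chi2 as chi2_dist

        # accept unless wildly off (without-replacement flattening inflates chi2)
        assert chi2 < 3 * chi2_dist.ppf(0.999, mask.sum() - 1)
        corr = np.corrcoef(counts[mask], expected[mask])[0, 1]
        assert corr > 0.9


class TestValidation:
    def test_worked_example(self):
        stats = confusion_statistics(ConfusionCounts(tp=40, fp=5, fn=10, tn=45))
        assert stats["accuracy"] == pytest.approx(0.85)
        assert stats["sensitivity"] == pytest.approx(0.8)
        assert stats["specificity"] == pytest.approx(0.9)
        assert stats["tss"] == pytest.approx(0.7)
        assert stats["kappa"] == pytest.approx(0.7)
        assert stats["precision"] == pytest.approx(8 / 9)

    def test_perfect_prediction(self):
        stats = confusion_statistics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
        for key in ("accuracy", "precision", "sensitivity", "specificity", "kappa", "tss"):
            assert stats[key] == pytest.approx(1.0)

    def test_constant_one_prediction(self, raster_factory):
        pred = raster_factory(np.ones((10, 10)))
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, size=(40, 2))
        labels = rng.integers(0, 2, 40)
        labels[0] = 0
        labels[1] = 1
        stats = validate_binary(xy, labels, pred)
        assert stats["specificity"] == 0.0
        assert stats["tss"] == pytest.approx(stats["sensitivity"] - 1.0)

    def test_undefined_ratio_is_none(self):
        stats = confusion_statistics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert stats["precision"] is None

    def test_class_symmetry_of_kappa_and_tss(self):
        a = confusion_statistics(ConfusionCounts(tp=30, fp=7, fn=13, tn=50))
        b = confusion_statistics(ConfusionCounts(tp=50, fp=13, fn=7, tn=30))
        assert a["kappa"] == pytest.approx(b["kappa"])
        assert a["tss"] == pytest.approx(b["tss"])

    def test_points_off_raster_dropped(self, raster_factory):
        pred = raster_factory(np.ones((5, 5)))
        xy = np.array([[2.5, 2.5], [100.0, 100.0]])
        stats = validate_binary(xy, np.array([1, 0]), pred)
        assert stats["n_dropped"] == 1


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_half(self):
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_worked_example(self):
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)

    def test_one_class_empty(self):
        with pytest.raises(UndefinedStatisticError):
            auc([1, 1], [0.3, 0.4])

    @given(
        st.lists(st.booleans(), min_size=2, max_size=60).filter(
            lambda lab: any(lab) and not all(lab)
        ),
        st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_brute_force_oracle(self, labels, data):
        scores = data.draw(
            st.lists(
                st.integers(0, 10),
                min_size=len(labels),
                max_size=len(labels),
            )
        )
        labels = np.asarray(labels, dtype=int)
        scores = np.asarray(scores, dtype=float)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        ) / (len(pos) * len(neg))
        assert auc(labels, scores) == pytest.approx(brute, abs=1e-12)


class TestNicheOverlap:
    def test_identical_rasters(self, raster_factory):
        a = raster_factory(np.random.default_rng(0).uniform(0, 1, (5, 5)))
        d, i = niche_overlap(a, a)
        assert d == pytest.approx(1.0)
        assert i == pytest.approx(1.0)

    def test_disjoint_support(self, raster_factory):
        a = np.zeros((4, 4))
        a[:2] = 1.0
        b = np.zeros((4, 4))
        b[2:] = 1.0
        d, _ = niche_overlap(raster_factory(a), raster_factory(b))
        assert d == pytest.approx(0.0)

    def test_hand_sum(self, raster_factory):
        a = raster_factory(np.array([[0.6, 0.4]]))
        b = raster_factory(np.array([[0.4, 0.6]]))
        d, _ = niche_overlap(a, b)
        assert d == pytest.approx(0.8)

    def test_zero_sum_error(self, raster_factory):
        a = raster_factory(np.zeros((2, 2)))
        b = raster_factory(np.ones((2, 2)))
        with pytest.raises(DegenerateInputError):
            niche_overlap(a, b)


class TestConvexHull:
    def test_unit_square_corners(self):
        occ = occ_of(np.array([0.0, 1, 1, 0]), np.array([0.0, 0, 1, 1]))
        hull = minimum_convex_hull(occ)
        assert hull.area == pytest.approx(1.0)

    def test_interior_points_ignored(self):
        occ = occ_of(np.array([0.0, 1, 1, 0, 0.5]), np.array([0.0, 0, 1, 1, 0.5]))
        assert minimum_convex_hull(occ).area == pytest.approx(1.0)

    def test_collinear_error(self):
        occ = occ_of(np.array([0.0, 1, 2]), np.array([0.0, 1, 2]))
        with pytest.raises(DegenerateInputError):
            minimum_convex_hull(occ)


class TestCreateSamplePoints:
    def test_unit_square_exact_count(self, unit_square):
        out = create_sample_points(unit_square, n=100)
        assert len(out) == 100
        assert unit_square.contains_xy(out.x, out.y).all()

    def test_tiny_patch_fallback(self, raster_factory):
        band = np.zeros((5, 5))
        band[2, 2] = 1.0
        with pytest.warns(DroppedDataWarning):
            out = create_sample_points(raster_factory(band), n=500)
        assert len(out) >= 1

    def test_two_patches_proportional(self):
        big = sgeom.box(0, 0, 8, 8)  # area 64
        small = sgeom.box(20, 0, 24, 4)  # area 16
        area = StudyArea(sgeom.MultiPolygon([big, small]))
        out = create_sample_points(area, n=200)
        frac_small = ((out.x >= 20) & (out.x <= 24)).mean()
        assert frac_small == pytest.approx(16 / 80, abs=0.08)


class TestRasterUtilities:
    def test_extract_at_cell_center(self, stack_factory):
        stack = stack_factory([np.arange(9, dtype=float).reshape(3, 3)], names=["v"])
        occ = occ_of(np.array([0.5]), np.array([2.5]))  # row 0, col 0
        table = extract_values_to_points(occ, stack)
        assert table["v"].iloc[0] == 0.0

    def test_extract_off_grid_nan(self, stack_factory):
        stack = stack_factory([np.zeros((3, 3))], names=["v"])
        occ = occ_of(np.array([99.0]), np.array([99.0]))
        assert np.isnan(extract_values_to_points(occ, stack)["v"].iloc[0])

    def test_sum_of_identical_binaries(self, stack_factory):
        band = np.zeros((4, 4))
        band[1:3, 1:3] = 1.0
        stack = stack_factory([band.copy() for _ in range(3)])
        total = sum_of_maps(stack)
        assert (total.values[1:3, 1:3] == 3.0).all()
        assert (total.values[0, :] == 0.0).all()

    def test_area_of_distribution(self, raster_factory):
        band = np.zeros((10, 10))
        band.ravel()[:10] = 1.0
        grid = raster_factory(band, res=0.5)
        assert area_of_distribution(grid) == pytest.approx(10 * 0.25)

    def test_area_requires_binary(self, raster_factory):
        with pytest.raises(ConfigError):
            area_of_distribution(raster_factory(np.full((2, 2), 0.7)))

    def test_rescale01(self, raster_factory):
        grid = raster_factory(np.array([[2.0, 4.0], [6.0, 10.0]]))
        out = rescale01(grid)
        np.testing.assert_allclose(out.values, [[0, 0.25], [0.5, 1.0]])

    def test_rescale_constant_error(self, raster_factory):
        with pytest.raises(DegenerateInputError):
            rescale01(raster_factory(np.ones((2, 2))))
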