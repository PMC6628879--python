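import numpy as np
import pytest
import shapely.geometry as sgeom

from biospat.io import (
    OccurrenceTable,
    SyntheticLandscapeConfig,
    generate_synthetic_landscape,
    tree_from_newick,
)
from biospat.io.raster import GridTransform, RasterGrid, RasterStack, grid_from_bounds
from biospat.io.vector import StudyArea
from biospat.tiling import CommunityMatrix


@pytest.fixture
def unit_square():
    return StudyArea(sgeom.box(0, 0, 1, 1))


@pytest.fixture
def square10():
    return StudyArea(sgeom.box(0, 0, 10, 10))


@pytest.fixture
def small_tree():
    # ((A:1,B:1):1,C:2); total branch length 5
    return tree_from_newick("((A:1,B:1):1,C:2);")


def community(incidence, species=None, counts=None, site_ids=None):
    """Bare community matrix helper (no geometry); silences pruning warnings."""
    import warnings

    from biospat.errors import DroppedDataWarning

    incidence = np.asarray(incidence, dtype=bool)
    if species is None:
        species = [f"s{j + 1}" for j in range(incidence.shape[1])]
    if counts is None:
        counts = incidence.astype(int)
    if site_ids is None:
        site_ids = np.arange(incidence.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DroppedDataWarning)
        return CommunityMatrix(np.asarray(site_ids), list(species), incidence, counts)


@pytest.fixture
def community_factory():
    return community


@pytest.fixture(scope="session")
def landscape3():
    """Three planted biotas, disjoint species sets, no noise (SCI recovery)."""
    cfg = SyntheticLandscapeConfig(
        n_regions=3,
        n_species_per_region=10,
        range_radius=16.0,
        block_size=40.0,
        n_points_per_species=80,
        noise_sd=0.0,
        seed=5,
    )
    return generate_synthetic_landscape(cfg)


@pytest.fixture(scope="session")
def landscape2_clusters():
    """Two congruent endemic clusters far apart (GIE recovery)."""
    cfg = SyntheticLandscapeConfig(
        n_regions=2,
        n_species_per_region=5,
        n_shared_species=2,  # widespread: r_s far exceeds every GIE scale
        range_radius=3.0,
        block_size=40.0,
        center_jitter=2.0,
        n_points_per_species=30,
        seed=11,
    )
    return generate_synthetic_landscape(cfg)


@pytest.fixture
def grid5x5():
    return grid_from_bounds(0, 0, 5, 5, res=1.0)


def make_grid(values, x0=0.0, y0=None, res=1.0, nodata=-9999.0):
    values = np.asarray(values, dtype=np.float32)
    if y0 is None:
        y0 = values.shape[0] * res
    return RasterGrid(values, GridTransform(x0, y0, res, -res), nodata=nodata)


@pytest.fixture
def raster_factory():
    return make_grid


@pytest.fixture
def occ_factory():
    def factory(records):
        sp, x, y = zip(*records)
        return OccurrenceTable(
            np.asarray(sp, dtype=object), np.asarray(x, float), np.asarray(y, float)
        )

    return factory


@pytest.fixture
def stack_factory():
    def factory(arrays, names=None, res=1.0, nodata=-9999.0):
        grids = [make_grid(a, res=res, nodata=nodata) for a in arrays]
        return RasterStack(grids, names)

    return factory
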