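import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lrckit.errors import ConfigError, InputError, UndefinedStatisticError
from lrckit.spatial import (
    P_VALUE_FLOOR,
    TissueMap,
    assign_region,
    cluster_summary,
    compartment_enrichment,
    dispersion_index,
    dispersion_test,
    image_lrc_threshold,
    poisson_gof,
    quadrat_partition,
)
from lrckit.synthetic import QuadratSimConfig, gen_quadrat_counts


def strip_map(width=400, height=200, boundary=150):
    """Simple tissue: medulla left of a straight vertical CMJ at x=boundary."""
    medulla = np.zeros((height, width), dtype=bool)
    medulla[:, :boundary] = True
    comp = np.where(medulla, 1, 2).astype(np.uint8)
    return TissueMap(
        points=np.empty((0, 2)),
        medulla=medulla,
        compartments=comp,
        tissue=np.ones((height, width), dtype=bool),
        pixel_size_um=1.0,
    )


class TestAssignRegion:
    def test_band_geometry(self):
        tmap = strip_map()
        pts = np.array(
            [
                [150.0, 10.0],  # on the CMJ
                [299.5, 10.0],  # ~150 um into cortex
                [250.0, 10.0],  # 100 um from the CMJ: inclusive boundary
                [10.5, 10.0],  # deep medulla
                [390.5, 10.0],  # deep cortex
            ]
        )
        regions = assign_region(pts, tmap, halfwidth_um=100.0)
        assert list(regions) == ["CMR", "cortex", "CMR", "medulla", "cortex"]

    def test_regions_partition_all_points(self, small_tissue_map):
        cfg, tmap = small_tissue_map
        regions = assign_region(tmap.points, tmap, cfg.cmr_halfwidth_um)
        fractions = [(regions == r).mean() for r in ("cortex", "medulla", "CMR")]
        assert sum(fractions) == pytest.approx(1.0)

    def test_point_outside_tissue_rejected(self):
        tmap = strip_map()
        tmap.tissue[:, :5] = False
        with pytest.raises(InputError):
            assign_region(np.array([[1.0, 1.0]]), tmap)


class TestQuadratPartition:
    def test_counts_conserve_points(self, rng):
        tmap = strip_map()
        tmap.points = rng.uniform((0, 0), (400, 200), size=(100, 2))
        grid, counts = quadrat_partition(tmap, 40)
        assert grid.n_sections == 40
        assert counts.sum() == 100

    def test_uniform_points_near_poisson(self, rng):
        tmap = strip_map()
        tmap.points = rng.uniform((0, 0), (400, 200), size=(8000, 2))
        _, counts = quadrat_partition(tmap, 40)
        assert dispersion_index(counts) == pytest.approx(1.0, abs=0.5)

    def test_all_points_in_one_section(self):
        tmap = strip_map()
        tmap.points = np.full((25, 2), 5.0)
        _, counts = quadrat_partition(tmap, 40)
        assert counts.max() == 25 and (counts > 0).sum() == 1

    def test_equal_areas(self):
        grid, _ = quadrat_partition(strip_map(), 45)
        widths = np.diff(grid.x_edges)
        heights = np.diff(grid.y_edges)
        areas = np.outer(heights, widths)
        assert np.allclose(areas, areas.flat[0])

    def test_too_few_sections_rejected(self):
        with pytest.raises(ConfigError):
            quadrat_partition(strip_map(), 1)


class TestDispersionIndex:
    def test_constant_counts(self):
        assert dispersion_index([7, 7, 7]) == 0.0

    def test_hand_computed_two_sections(self):
        # mean 16, (n-1)-variance 512 -> DI 32
        assert dispersion_index([0, 32]) == pytest.approx(32.0)

    def test_poisson_sample_near_one(self):
        cfg = QuadratSimConfig(family="poisson", dispersion_index=1, seed=0)
        values = [dispersion_index(gen_quadrat_counts(cfg, r)) for r in range(200)]
        assert np.mean(values) == pytest.approx(1.0, abs=0.15)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dispersion_index([0, 0, 0])


class TestPoissonGof:
    def test_overdispersed_counts_floor_the_p_value(self):
        counts = gen_quadrat_counts(QuadratSimConfig(seed=0))
        statistic, df, p = poisson_gof(counts)
        assert p == P_VALUE_FLOOR
        assert statistic > 100 and df >= 1

    def test_constant_counts_rejected_strongly(self):
        # zero variance is wildly un-Poisson for a mean of 16
        _, _, p = poisson_gof(np.full(178, 16))
        assert p < 1e-10

    def test_null_type_one_error_calibrated(self):
        cfg = QuadratSimConfig(family="poisson", dispersion_index=1, seed=42)
        rejections = sum(
            poisson_gof(gen_quadrat_counts(cfg, r))[2] < 0.05 for r in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_too_few_sections_rejected(self):
        with pytest.raises(InputError):
            poisson_gof(np.array([1, 2, 3]))

    def test_dispersion_test_agrees_on_clustering(self):
        counts = gen_quadrat_counts(QuadratSimConfig(seed=1))
        _, df, p = dispersion_test(counts)
        assert df == len(counts) - 1
        assert p == P_VALUE_FLOOR


class TestClusterSummary:
    def test_no_clusters(self):
        assert cluster_summary([1, 2, 3], threshold=32) == (0.0, 0.0)

    def test_hand_computed(self):
        lrc_frac, sec_frac = cluster_summary([10, 40], threshold=32)
        assert lrc_frac == pytest.approx(0.8)
        assert sec_frac == pytest.approx(0.5)

    def test_strict_inequality(self):
        assert cluster_summary([33], threshold=32) == (1.0, 1.0)
        assert cluster_summary([32, 1], threshold=32) == (0.0, 0.0)

    def test_empty_counts_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cluster_summary([0, 0])

    def test_clustered_defaults_put_half_of_cells_in_rare_clusters(self):
        """At the default overdispersion, high-count sections hold a large share
        of cells while remaining a small share of sections."""
        cfg = QuadratSimConfig(seed=0)
        lrc_fracs, sec_fracs = zip(
            *(cluster_summary(gen_quadrat_counts(cfg, r), 32) for r in range(200))
        )
        assert np.mean(lrc_fracs) > 0.4
        assert np.mean(sec_fracs) < 0.2


class TestEnrichment:
    def test_observed_k5k8_values(self):
        # 63% of cells on 26% of area
        assert compartment_enrichment(0.63, 0.26) == pytest.approx(2.423, abs=1e-3)

    def test_neutral_and_depleted(self):
        assert compartment_enrichment(0.4, 0.4) == 1.0
        assert compartment_enrichment(0.1, 0.5) == pytest.approx(0.2)

    def test_zero_area_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compartment_enrichment(0.5, 0.0)


class TestImageLrcThreshold:
    def test_four_times_max_rule(self):
        assert image_lrc_threshold([3.0, 10.0, 7.0]) == 40.0

    def test_strictly_above_convention(self):
        threshold = image_lrc_threshold([10.0])
        assert 41.0 > threshold  # called LRC
        assert not 40.0 > threshold  # exactly 4x max: not an LRC

    def test_empty_control_rejected(self):
        with pytest.raises(InputError):
            image_lrc_threshold([])


@settings(deadline=None, max_examples=50)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=60),
    threshold=st.integers(min_value=0, max_value=100),
)
def test_cluster_summary_fractions_bounded(counts, threshold):
    if sum(counts) == 0:
        return
    lrc_frac, sec_frac = cluster_summary(counts, threshold)
    assert 0.0 <= lrc_frac <= 1.0 and 0.0 <= sec_frac <= 1.0
    # cells in clusters imply sections above the threshold exist, and vice versa
    assert (lrc_frac > 0) == (sec_frac > 0)
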