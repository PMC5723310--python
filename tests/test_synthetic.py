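import dataclasses

import numpy as np
import pandas as pd
import pytest

from lrckit.errors import ConfigError, GenerationError
from lrckit.spatial import assign_compartment, assign_region
from lrckit.synthetic import (
    BrduSimConfig,
    ExprSimConfig,
    FlowSimConfig,
    QuadratSimConfig,
    TissueSimConfig,
    gen_brdu_records,
    gen_expression_table,
    gen_flow_events,
    gen_quadrat_counts,
    gen_tissue_map,
)


class TestFlowGenerator:
    def test_no_division_no_noise_gives_exact_pulse_intensity(self, default_decay):
        decay = dataclasses.replace(default_decay, chase_days=0.0)
        cfg = FlowSimConfig(
            n_events_per_subset=200,
            quiescent_fraction={"UEA1minus": 1.0},
            labeling_efficiency=1.0,
            noise_cv=0.0,
            decay=decay,
            seed=0,
        )
        events, _ = gen_flow_events(cfg)
        assert np.allclose(events["intensity"], decay.pulse_intensity_I0)

    def test_quiescent_fraction_recovered(self):
        cfg = FlowSimConfig(n_events_per_subset=100_000, seed=2)
        events, _ = gen_flow_events(cfg)
        minus = events[events.subset == "UEA1minus"]
        # binomial 3-sigma band around 0.055 at n = 100,000
        assert minus["quiescent"].mean() == pytest.approx(0.055, abs=3 * 0.00072)

    def test_unlabeled_generator_matches_control_distribution(self):
        cfg = FlowSimConfig(n_events_per_subset=20_000, labeling_efficiency=0.0, seed=4)
        events, control = gen_flow_events(cfg)
        from scipy.stats import ks_2samp

        p = ks_2samp(events["intensity"], control["intensity"]).pvalue
        assert p > 0.01

    def test_event_counts_conserved_per_subset(self):
        cfg = FlowSimConfig(n_events_per_subset=5000, seed=0)
        events, control = gen_flow_events(cfg)
        assert (events.groupby("subset").size() == 5000).all()
        assert (control.groupby("subset").size() == 5000).all()

    def test_control_never_carries_label_signal(self, default_decay):
        cfg = FlowSimConfig(n_events_per_subset=50_000, seed=0, decay=default_decay)
        _, control = gen_flow_events(cfg)
        # end-of-chase zero-division signal is ~39 a.u.; autofluorescence stays far below
        assert control["intensity"].max() < 39.0 / 2

    def test_determinism(self):
        cfg = FlowSimConfig(n_events_per_subset=1000, seed=9)
        a, ca = gen_flow_events(cfg)
        b, cb = gen_flow_events(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            FlowSimConfig(quiescent_fraction={"UEA1minus": 1.5})
        with pytest.raises(ConfigError):
            FlowSimConfig(labeling_efficiency=-0.1)


class TestQuadratGenerator:
    def test_poisson_moments(self):
        cfg = QuadratSimConfig(
            n_sections=10_000, family="poisson", dispersion_index=1, seed=1
        )
        counts = gen_quadrat_counts(cfg)
        assert counts.mean() == pytest.approx(16.11236, rel=0.02)
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_negative_binomial_moments(self):
        cfg = QuadratSimConfig(n_sections=10_000, seed=1)
        counts = gen_quadrat_counts(cfg)
        assert counts.mean() == pytest.approx(16.11236, rel=0.05)
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(34.81, rel=0.10)

    def test_zero_mean_gives_all_zero(self):
        cfg = QuadratSimConfig(n_sections=50, mean_count=0.0, seed=0)
        assert not gen_quadrat_counts(cfg).any()

    def test_family_di_consistency_enforced(self):
        with pytest.raises(ConfigError):
            QuadratSimConfig(family="poisson", dispersion_index=34.81)
        with pytest.raises(ConfigError):
            QuadratSimConfig(family="negative_binomial", dispersion_index=1.0)

    def test_determinism_and_replicate_independence(self):
        cfg = QuadratSimConfig(seed=3)
        assert (gen_quadrat_counts(cfg, 5) == gen_quadrat_counts(cfg, 5)).all()
        assert (gen_quadrat_counts(cfg, 5) != gen_quadrat_counts(cfg, 6)).any()


class TestTissueGenerator:
    def test_points_inside_footprint_and_area_target(self, small_tissue_map):
        cfg, tmap = small_tissue_map
        rr, cc = tmap.pixel_index(tmap.points)
        assert tmap.tissue[rr, cc].all()
        realized = (tmap.compartments == 3).sum() / tmap.tissue.sum()
        assert realized == pytest.approx(cfg.k5k8_area_fraction, abs=0.02)

    def test_empty_point_set_valid(self):
        tmap = gen_tissue_map(TissueSimConfig(n_lrc=0, seed=1))
        assert tmap.points.shape == (0, 2)
        assert tmap.compartments.max() == 3

    def test_uniform_bias_recovers_area_fractions(self):
        cfg = TissueSimConfig(
            n_lrc=20_000, parent_zone_probs=None, offspring_sigma_um=0.0, seed=2
        )
        tmap = gen_tissue_map(cfg)
        regions = assign_region(tmap.points, tmap, cfg.cmr_halfwidth_um)
        dist = tmap.cmj_distance_um()
        cmr_area = (dist[tmap.tissue] <= cfg.cmr_halfwidth_um).mean()
        assert (regions == "CMR").mean() == pytest.approx(cmr_area, abs=0.02)

    def test_default_bias_concentrates_points_at_cmj(self, small_tissue_map):
        cfg, tmap = small_tissue_map
        comps = assign_compartment(tmap.points, tmap)
        # K5+K8+ covers 26% of area but attracts well over half the points
        assert (comps == "K5K8").mean() > 0.5

    def test_unreachable_band_raises(self):
        with pytest.raises(GenerationError):
            # CMR halfwidth beyond the widest achievable K5K8 band
            gen_tissue_map(
                TissueSimConfig(width_um=300, height_um=300, cmr_halfwidth_um=250, seed=0)
            )

    def test_determinism(self):
        cfg = TissueSimConfig(n_lrc=200, seed=8)
        a = gen_tissue_map(cfg)
        b = gen_tissue_map(cfg)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.compartments, b.compartments)


class TestExpressionGenerator:
    def test_no_planted_effects_no_calls_at_zero_noise(self):
        cfg = ExprSimConfig(n_genes=500, frac_up=0, frac_down=0, noise_log2_sd=0.0, seed=1)
        table, truth = gen_expression_table(cfg)
        assert not truth["is_de"].any()
        ratios = np.log2(table["LRC"] / table["NonLRC"])
        assert np.allclose(ratios, 0.0)

    def test_planted_effects_exceed_one_log2_unit(self):
        cfg = ExprSimConfig(n_genes=2000, seed=2)
        _, truth = gen_expression_table(cfg)
        de = truth[truth["is_de"]]
        assert (de["planted_log2fc"].abs() >= 1.0).all()
        assert set(de["direction"]) == {"up", "down"}

    def test_single_gene_table_valid(self):
        table, truth = gen_expression_table(ExprSimConfig(n_genes=1, seed=0))
        assert table.shape == (1, 2)

    def test_fraction_validation(self):
        with pytest.raises(ConfigError):
            ExprSimConfig(frac_up=0.6, frac_down=0.6)

    def test_determinism(self):
        cfg = ExprSimConfig(n_genes=300, seed=7)
        a, ta = gen_expression_table(cfg)
        b, tb = gen_expression_table(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)


class TestBrduGenerator:
    def test_group_probabilities_recovered(self, brdu_records):
        cfg, records = brdu_records
        for (tp, subset, cls), p in cfg.brdu_probs.items():
            g = records[
                (records.timepoint == tp)
                & (records.subset == subset)
                & (records.gfp_class == cls)
            ]
            se = np.sqrt(max(p * (1 - p), 1e-6) / len(g))
            assert g["brdu"].mean() == pytest.approx(p, abs=4 * se + 1e-9)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            BrduSimConfig(brdu_probs={("day0", "UEA1minus", "GFPpos"): 1.2})
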