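"""Generative model: bivariate-Bernoulli labels, stack and mosaic rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from arcfish import (CapacityError, SimConfig, kappa_bounds, render_mosaic,
                     render_stack, simulate_labels, default_roi_layout,
                     calibrate_thresholds, measure_mosaic, ROI_NAMES)
from conftest import single_cell_config, single_cell_truth


class TestLabelModel:
    def test_infeasible_kappa_error_names_interval(self):
        with pytest.raises(ValueError, match="feasible interval"):
            SimConfig(p1=0.9, p2=0.9, kappa=-1.0)

    def test_kappa_one_nests_smaller_ensemble(self):
        cfg = SimConfig(n_cells=20000, p1=0.3, p2=0.3, kappa=1.0,
                        glia_fraction=0.0, seed=3)
        t = simulate_labels(cfg, place=False)
        # joint prob = min(p1, p2): epoch-2 actives are all epoch-1 active
        assert not (t["e2"] & ~t["e1"]).any()
        assert not (t["e1"] & ~t["e2"]).any()  # p1 == p2: sets coincide

    def test_kappa_zero_is_independence(self):
        """Empirical joint matches p1*p2 within 3 binomial standard errors."""
        n = 200_000
        cfg = SimConfig(n_cells=n, p1=0.3, p2=0.3, kappa=0.0,
                        glia_fraction=0.0, seed=5)
        t = simulate_labels(cfg, place=False)
        joint = (t["e1"] & t["e2"]).mean()
        se = np.sqrt(0.09 * 0.91 / n)
        assert abs(joint - 0.09) < 3 * se

    def test_double_fraction_montecarlo(self):
        """p1=.33, p2=.25, kappa=.5: joint = .0825 + .5*(.25-.0825) = .16625."""
        n = 1_000_000
        cfg = SimConfig(n_cells=n, p1=0.33, p2=0.25, kappa=0.5,
                        glia_fraction=0.0, seed=11)
        t = simulate_labels(cfg, place=False)
        expected = 0.0825 + 0.5 * (0.25 - 0.0825)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs((t["e1"] & t["e2"]).mean() - expected) < 3 * se

    def test_glia_never_active(self):
        cfg = SimConfig(n_cells=2000, glia_fraction=0.5, seed=2)
        t = simulate_labels(cfg, place=False)
        glia = t[~t["is_neuron"]]
        assert len(glia) > 0
        assert not glia["e1"].any() and not glia["e2"].any()

    def test_seed_determinism(self):
        cfg = SimConfig(n_cells=30, seed=9)
        a, b = simulate_labels(cfg), simulate_labels(cfg)
        pd.testing.assert_frame_equal(a, b)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_joint_within_frechet_bounds(self, p1, p2, u):
        lo, hi = kappa_bounds(p1, p2)
        kappa = lo + u * (hi - lo)
        p11 = p1 * p2 + kappa * (min(p1, p2) - p1 * p2)
        assert max(0.0, p1 + p2 - 1.0) - 1e-9 <= p11 <= min(p1, p2) + 1e-9

    def test_overcrowded_stack_raises_capacity_error(self):
        cfg = SimConfig(n_cells=100, stack_shape=(20, 64, 64), seed=0)
        with pytest.raises(CapacityError):
            simulate_labels(cfg)


class TestStackRendering:
    def test_render_determinism(self):
        cfg = SimConfig(n_cells=10, noise_sd=10.0, seed=4, stack_shape=(40, 128, 128))
        t = simulate_labels(cfg)
        a = render_stack(t, cfg)
        b = render_stack(t, cfg)
        assert np.array_equal(a.channels, b.channels)

    def test_nuclear_cell_has_exactly_two_foci_components(self):
        cfg = single_cell_config()
        truth = single_cell_truth(e2=True)
        stack = render_stack(truth, cfg)
        hot = stack.arc >= cfg.foci_amplitude / 2
        # components on the center plane, inside the nucleus
        lab, n = ndimage.label(hot[20])
        assert n == 2
        dy, dx = np.nonzero(hot[20])
        assert np.all(np.hypot(dy - 32, dx - 32) < cfg.nucleus_radius)

    def test_foci_span_matches_config(self):
        cfg = single_cell_config(foci_planes=4)
        stack = render_stack(single_cell_truth(e2=True), cfg)
        planes = np.unique(np.nonzero(stack.arc >= 100)[0])
        assert len(planes) == 4
        assert np.all(np.diff(planes) == 1)

    def test_ring_angular_coverage_near_target(self):
        """Rendered angular extent of the ring equals ring_coverage +- one sector."""
        cfg = single_cell_config(ring_coverage=0.7)
        stack = render_stack(single_cell_truth(e1=True), cfg)
        z = 20
        ys, xs = np.nonzero(stack.arc[z] >= 75)
        ang = np.sort(np.mod(np.arctan2(ys - 32.0, xs - 32.0), 2 * np.pi))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        covered = 2 * np.pi - gaps.max()
        assert covered / (2 * np.pi) == pytest.approx(0.7, abs=1 / 36)

    def test_no_active_cells_means_silent_arc_channel(self):
        cfg = single_cell_config()
        stack = render_stack(single_cell_truth(), cfg)
        assert stack.arc.max() < 75

    def test_glia_bright_and_uniform_neurons_dim_and_textured(self):
        cfg = SimConfig(n_cells=6, glia_fraction=0.5, noise_sd=0.0, seed=8,
                        stack_shape=(40, 128, 128))
        t = simulate_labels(cfg)
        stack = render_stack(t, cfg)
        for row in t.itertuples(index=False):
            z, y, x = int(round(row.z)), int(round(row.y)), int(round(row.x))
            patch = stack.counterstain[z, y - 3:y + 4, x - 3:x + 4]
            cv = patch.std() / patch.mean()
            if row.is_neuron:
                assert patch.mean() < 140 and cv > 0.05
            else:
                assert patch.mean() > 140 and cv < 0.01


class TestMosaicRendering:
    def test_fraction_limits_and_recovery(self):
        rois = default_roi_layout()[:4]
        fracs = {"SOd": 0.0, "SOm": 100.0, "SOp": 25.0, "SLd": 60.0}
        mosaic, realized = render_mosaic(rois, fracs, seed=3)
        thr = calibrate_thresholds(mosaic, rois)
        df = measure_mosaic(mosaic, rois, thr).set_index("roi_name")
        assert df.loc["SOd", "fraction"] == 0.0
        assert df.loc["SOm", "fraction"] == pytest.approx(100.0, abs=0.5)
        assert df.loc["SOp", "fraction"] == pytest.approx(25.0, abs=0.5)
        assert df.loc["SLd", "fraction"] == pytest.approx(60.0, abs=0.5)

    def test_fraction_out_of_range_rejected(self):
        rois = default_roi_layout()[:1]
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            render_mosaic(rois, {"SOd": 120.0}, seed=0)

    def test_all_fourteen_rois_have_names(self):
        names = [name for name, _ in default_roi_layout()]
        assert names == list(ROI_NAMES)
        assert len(names) == 14

    def test_mosaic_determinism(self):
        rois = default_roi_layout()[:2]
        fr = {"SOd": 10.0, "SOm": 20.0}
        a, _ = render_mosaic(rois, fr, seed=5)
        b, _ = render_mosaic(rois, fr, seed=5)
        assert np.array_equal(a.channels, b.channels)
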