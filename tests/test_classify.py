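"""Segmentation, neuron/glia rule, dissector, evidence extraction, labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arcfish import (CellRecord, ClassifyParams, ImageStack, SimConfig,
                     classify_cell, classify_stack, cyto_coverage, detect_foci,
                     is_neuron, optical_dissector, pool_counts, preprocess,
                     render_stack, segment_nuclei, simulate_labels, tabulate)
from conftest import single_cell_config, single_cell_truth


def evidence_record(spans=(), coverage=(), n_planes=40):
    """A bare record carrying only per-plane evidence, for classify_cell."""
    cov = np.zeros(n_planes)
    cov[: len(coverage)] = coverage
    rec = CellRecord(cell_id=0, bbox=(slice(0, 1),) * 3,
                     mask=np.ones((1, 1, 1), bool), centroid=(0.0, 0.0, 0.0))
    rec.focus_counts = np.zeros(n_planes, dtype=int)
    rec.focus_spans = list(spans)
    rec.coverage = cov
    return rec


class TestPreprocess:
    def test_radius_zero_is_identity(self):
        cfg = single_cell_config(noise_sd=5.0)
        stack = render_stack(single_cell_truth(e1=True), cfg)
        out = preprocess(stack, 0)
        assert np.array_equal(out.channels, stack.channels)

    def test_constant_stack_unchanged(self):
        stack = ImageStack(np.full((2, 10, 20, 20), 7.0), z_step=0.3)
        out = preprocess(stack, 2)
        assert np.array_equal(out.channels, stack.channels)

    def test_impulse_removed(self):
        chans = np.zeros((2, 5, 21, 21), dtype=np.float32)
        chans[0, 2, 10, 10] = 100.0
        out = preprocess(ImageStack(chans), 1)
        # median of the 3x3 neighborhood around an isolated impulse is 0
        assert out.channels[0, 2, 10, 10] == 0.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            preprocess(ImageStack(np.zeros((2, 5, 8, 8))), -1)


class TestSegmentation:
    def test_counts_and_centroids_match_truth(self, small_stack_with_truth):
        cfg, truth, stack, _ = small_stack_with_truth
        records = segment_nuclei(preprocess(stack, 1))
        assert len(records) == len(truth)
        for row in truth.itertuples(index=False):
            d = min(np.hypot(np.hypot(r.centroid[1] - row.y, r.centroid[2] - row.x),
                             (r.centroid[0] - row.z))
                    for r in records)
            assert d < 1.0

    def test_blank_stack_yields_no_records(self):
        assert segment_nuclei(ImageStack(np.zeros((2, 10, 32, 32)))) == []

    def test_touching_nuclei_split_by_markers(self):
        """Two spheres in contact but with distinct cores give two records."""
        chans = np.zeros((2, 30, 64, 64), dtype=np.float32)
        zz, yy, xx = np.ogrid[0:30, 0:64, 0:64]
        for yc in (24, 40):  # centers 16 px apart: spheres of r=8 touch
            m = (((zz - 15) / 6.0) ** 2 + ((yy - yc) / 8.0) ** 2
                 + ((xx - 32) / 8.0) ** 2) <= 1.0
            chans[0][m] = 100.0
        records = segment_nuclei(ImageStack(chans))
        assert len(records) == 2


class TestNeuronGliaRule:
    def test_synthetic_neuron_accepted_glia_rejected(self):
        cfg = SimConfig(n_cells=10, glia_fraction=0.5, noise_sd=0.0, seed=21,
                        stack_shape=(40, 128, 128))
        truth = simulate_labels(cfg)
        stack = preprocess(render_stack(truth, cfg), 1)
        records = segment_nuclei(stack)
        assert len(records) == 10
        for rec in records:
            truth_row = truth.iloc[
                ((truth.z - rec.centroid[0]) ** 2 + (truth.y - rec.centroid[1]) ** 2
                 + (truth.x - rec.centroid[2]) ** 2).idxmin()]
            assert is_neuron(rec, stack) == bool(truth_row.is_neuron)

    def test_degenerate_mask_excluded_with_warning(self):
        rec = CellRecord(cell_id=0, bbox=(slice(0, 1),) * 3,
                         mask=np.ones((1, 1, 1), bool), centroid=(0, 0, 0))
        stack = ImageStack(np.full((2, 3, 3, 3), 50.0))
        with pytest.warns(UserWarning, match="degenerate"):
            assert is_neuron(rec, stack) is False

    def test_zero_intensity_mask_is_not_neuron(self):
        rec = CellRecord(cell_id=0, bbox=(slice(0, 2), slice(0, 2), slice(0, 2)),
                         mask=np.ones((2, 2, 2), bool), centroid=(0.5, 0.5, 0.5))
        stack = ImageStack(np.zeros((2, 3, 3, 3)))
        assert is_neuron(rec, stack) is False  # cv undefined -> treated as 0


class TestOpticalDissector:
    @staticmethod
    def _rec(z):
        return CellRecord(cell_id=0, bbox=(slice(0, 1),) * 3,
                          mask=np.ones((1, 1, 1), bool), centroid=(z, 0.0, 0.0))

    def test_middle_30pct_window_of_40_planes(self):
        # ceil(40*.35)=14, floor(40*.65)=26: closed window 14..26
        kept = optical_dissector([self._rec(z) for z in (5, 13.9, 14, 20, 26, 26.1)], 40)
        assert [r.centroid[0] for r in kept] == [14, 20, 26]

    def test_fraction_one_keeps_everything(self):
        recs = [self._rec(z) for z in np.linspace(0, 39, 10)]
        assert len(optical_dissector(recs, 40, fraction=1.0)) == 10

    def test_boundary_centroid_kept(self):
        assert len(optical_dissector([self._rec(14.0)], 40, fraction=0.30)) == 1

    @given(st.lists(st.floats(0, 39), min_size=0, max_size=30),
           st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_kept_count_monotone_in_fraction(self, zs, f1, f2):
        recs = [self._rec(z) for z in zs]
        lo, hi = sorted((f1, f2))
        assert len(optical_dissector(recs, 40, lo)) <= len(optical_dissector(recs, 40, hi))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            optical_dissector([], 40, fraction=0.0)


class TestFocusDetection:
    def _classified_single(self, **cfg_kw):
        cfg = single_cell_config(**cfg_kw)
        truth = single_cell_truth(e2=True)
        return classify_stack(render_stack(truth, cfg), apply_dissector=False)[0]

    def test_two_tracks_spanning_foci_planes(self):
        rec = self._classified_single(foci_planes=4)
        assert sorted(rec.focus_spans) == [4, 4]
        assert rec.focus_counts.max() == 2

    def test_no_arc_signal_gives_zero_counts(self):
        cfg = single_cell_config()
        stack = render_stack(single_cell_truth(), cfg)
        rec = classify_stack(stack, apply_dissector=False)[0]
        assert rec.focus_counts.sum() == 0 and rec.focus_spans == []

    def test_truncated_foci_track_length_two(self):
        rec = self._classified_single(foci_planes=2)
        assert sorted(rec.focus_spans) == [2, 2]


class TestCytoCoverage:
    def test_full_ring_has_coverage_one(self):
        cfg = single_cell_config(ring_coverage=1.0)
        stack = render_stack(single_cell_truth(e1=True), cfg)
        rec = classify_stack(stack, apply_dissector=False)[0]
        ring = rec.coverage[rec.coverage > 0]
        assert len(ring) == cfg.ring_planes
        assert np.all(ring == 1.0)

    def test_partial_ring_measures_rendered_fraction(self):
        cfg = single_cell_config(ring_coverage=0.7)
        stack = render_stack(single_cell_truth(e1=True), cfg)
        rec = classify_stack(stack, apply_dissector=False)[0]
        ring = rec.coverage[rec.coverage > 0.3]
        assert len(ring) == cfg.ring_planes
        assert np.all(np.abs(ring - 0.7) <= 1 / 36 + 1e-9)

    def test_no_signal_means_zero_everywhere(self):
        cfg = single_cell_config()
        stack = render_stack(single_cell_truth(), cfg)
        rec = classify_stack(stack, apply_dissector=False)[0]
        assert np.all(rec.coverage == 0.0)


class TestClassifyCell:
    @pytest.mark.parametrize("spans, coverage, expected", [
        # focus-track span boundary: 3 consecutive planes required
        ((3, 3), (), "nuclear"),
        ((2, 2), (), "negative"),
        ((3, 2), (), "negative"),           # only one qualifying track
        # coverage boundary: strictly > 0.60, in >= 4 planes
        ((), (0.65,) * 4, "cytoplasmic"),
        ((), (0.60,) * 5, "negative"),      # 0.60 exactly fails the strict rule
        ((), (0.61,) * 4, "cytoplasmic"),
        ((), (0.65,) * 3, "negative"),      # 3 planes insufficient
        # conjunction
        ((3, 3), (0.65,) * 4, "double"),
        ((), (), "negative"),
    ])
    def test_criteria_boundaries(self, spans, coverage, expected):
        assert classify_cell(evidence_record(spans, coverage)) == expected

    def test_noncontiguous_coverage_planes_count_by_default(self):
        rec = evidence_record((), (0.7, 0.0, 0.7, 0.0, 0.7, 0.0, 0.7))
        assert classify_cell(rec) == "cytoplasmic"
        strict = ClassifyParams(coverage_consecutive=True)
        assert classify_cell(evidence_record((), (0.7, 0.0, 0.7, 0.0, 0.7, 0.0, 0.7)),
                             strict) == "negative"

    def test_missing_evidence_rejected(self):
        rec = CellRecord(cell_id=0, bbox=(slice(0, 1),) * 3,
                         mask=np.ones((1, 1, 1), bool), centroid=(0, 0, 0))
        with pytest.raises(ValueError, match="evidence"):
            classify_cell(rec)

    def test_relabeling_stored_evidence_is_bit_stable(self, small_stack_with_truth):
        *_, records = small_stack_with_truth
        for rec in records:
            assert classify_cell(rec) == rec.label


class TestTabulate:
    def test_tally_partition(self):
        recs = []
        for label, n in (("negative", 4), ("nuclear", 3), ("cytoplasmic", 2), ("double", 1)):
            for _ in range(n):
                r = evidence_record()
                r.label = label
                recs.append(r)
        c = tabulate(recs)
        assert (c.neg, c.nuc, c.cyt, c.dob) == (4, 3, 2, 1)
        assert c.total == 10

    def test_empty_records_all_zero(self):
        c = tabulate([])
        assert c.total == 0

    def test_unlabeled_record_is_integrity_error(self):
        with pytest.raises(ValueError, match="unlabeled"):
            tabulate([evidence_record()])

    def test_pooling_is_additive_across_stacks(self):
        def stack_counts(seed):
            cfg = SimConfig(n_cells=12, noise_sd=0.0, seed=seed, stack_shape=(40, 160, 160))
            recs = classify_stack(render_stack(simulate_labels(cfg), cfg),
                                  apply_dissector=False)
            return tabulate(recs, animal_id="a", region="CA1")
        a, b = stack_counts(31), stack_counts(32)
        pooled = pool_counts([a, b])
        assert (pooled.neg, pooled.nuc, pooled.cyt, pooled.dob) == (
            a.neg + b.neg, a.nuc + b.nuc, a.cyt + b.cyt, a.dob + b.dob)
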