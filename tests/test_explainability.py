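"""Per-feature performance, attention summaries, and mask/paste perturbation."""

import numpy as np
import pandas as pd
import pytest

from cinefuse.exam import VIEW_CHAMBERS, VIEWS, ChamberMaskSet
from cinefuse.explainability import (apply_mask, apply_paste,
                                     chamber_importance, dilate_mask,
                                     mean_attention_weights,
                                     per_feature_performance)
from cinefuse.network import ModelConfig, MultiViewCineNet


def brute_force_dilation(mask, sigma=4.0, radius=16):
    """O(n^2 k^2) oracle: explicit truncated-Gaussian convolution > 0."""
    h, w = mask.shape
    ax = np.arange(-radius, radius + 1)
    kern = np.exp(-(ax**2) / (2 * sigma**2))
    kern2 = np.outer(kern, kern)
    out = np.zeros_like(mask)
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        x0, x1 = max(0, x - radius), min(w, x + radius + 1)
        sub = kern2[y0 - y + radius:y1 - y + radius,
                    x0 - x + radius:x1 - x + radius]
        out[y0:y1, x0:x1] |= (sub > 0)
    return out.astype(np.uint8)


class TestDilateMask:
    def test_empty_mask_stays_empty(self):
        assert dilate_mask(np.zeros((20, 20), dtype=np.uint8)).sum() == 0

    def test_single_pixel_footprint_is_33_square(self):
        m = np.zeros((64, 64), dtype=np.uint8)
        m[32, 32] = 1
        d = dilate_mask(m)
        assert d.sum() == 33 * 33
        assert np.array_equal(d, brute_force_dilation(m))

    def test_matches_brute_force_on_random_blobs(self, rng):
        m = (rng.random((40, 40)) < 0.01).astype(np.uint8)
        assert np.array_equal(dilate_mask(m), brute_force_dilation(m))

    def test_monotone_and_superset(self, rng):
        m = (rng.random((50, 50)) < 0.02).astype(np.uint8)
        d1 = dilate_mask(m)
        d2 = dilate_mask(d1)
        assert np.all(d1 >= m)
        assert np.all(d2 >= d1)

    def test_symmetric_mask_centroid_preserved(self):
        m = np.zeros((65, 65), dtype=np.uint8)
        m[30:35, 28:37] = 1
        d = dilate_mask(m)
        ys, xs = np.nonzero(d)
        cy, cx = ys.mean(), xs.mean()
        ys0, xs0 = np.nonzero(m)
        assert abs(cy - ys0.mean()) < 1 and abs(cx - xs0.mean()) < 1

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            dilate_mask(np.full((4, 4), 0.5))


class TestMaskPaste:
    def test_complementarity_reconstructs_exam_exactly(self, rng):
        frames = rng.random((4, 5, 16, 16)).astype(np.float32)
        masks = {"SAX": (rng.random((5, 16, 16)) < 0.3).astype(np.uint8),
                 "2CH": (rng.random((16, 16)) < 0.4).astype(np.uint8)}
        total = apply_mask(frames, masks) + apply_paste(frames, masks)
        assert np.array_equal(total, frames)

    def test_empty_and_full_masks(self, rng):
        frames = rng.random((4, 3, 8, 8)).astype(np.float32)
        empty = {"SAX": np.zeros((8, 8), dtype=np.uint8)}
        full = {"SAX": np.ones((8, 8), dtype=np.uint8)}
        assert np.array_equal(apply_mask(frames, empty), frames)
        assert np.all(apply_mask(frames, full)[VIEWS.index("SAX")] == 0)
        # paste keeps only the selected view; everything else is black canvas
        pasted = apply_paste(frames, full)
        assert np.array_equal(pasted[VIEWS.index("SAX")], frames[VIEWS.index("SAX")])
        assert np.all(np.delete(pasted, VIEWS.index("SAX"), axis=0) == 0)

    def test_misaligned_mask_rejected(self, rng):
        frames = rng.random((4, 3, 8, 8)).astype(np.float32)
        with pytest.raises(ValueError):
            apply_mask(frames, {"SAX": np.ones((4, 4), dtype=np.uint8)})


@pytest.fixture()
def small_net():
    return MultiViewCineNet(
        ModelConfig(input_size=16, encoder_pool=1, feature_dim=8,
                    encoder_channels=(4, 8), n_phases=5), seed=1)


@pytest.fixture()
def small_data(rng):
    x = rng.random((12, 4, 5, 16, 16)).astype(np.float32)
    y = rng.normal(40, 10, size=12)
    return x, y


class TestPerFeaturePerformance:
    def test_row_count_and_identities(self, small_net, small_data):
        table = per_feature_performance(small_net, *small_data)
        assert len(table) == 4 * 5 + 5 + 4 + 1
        assert (table.level == "frame").sum() == 20
        assert (table.level == "spatial").sum() == 5
        assert (table.level == "temporal").sum() == 4
        assert (table.level == "final").sum() == 1

    def test_mean_weights_within_groups_sum_to_one(self, small_net, small_data):
        table = per_feature_performance(small_net, *small_data)
        frames = table[table.level == "frame"]
        for phase, grp in frames.groupby("phase"):
            assert grp.mean_view_weight.sum() == pytest.approx(1.0, abs=1e-5)
        for view, grp in frames.groupby("view"):
            assert grp.mean_phase_weight.sum() == pytest.approx(1.0, abs=1e-5)
        s2 = table.mean_stage2_weight.dropna()
        assert s2.sum() == pytest.approx(1.0, abs=1e-5)

    def test_constant_head_degenerates_gracefully(self, small_net, small_data):
        small_net.head.weight.data[:] = 0.0
        small_net.head.bias.data[:] = 42.0
        table = per_feature_performance(small_net, *small_data)
        assert np.all(np.isnan(table.pcc))
        assert np.allclose(table.mae, np.abs(small_data[1] - 42.0).mean())


class TestMeanAttentionWeights:
    def test_zero_scorer_gives_uniform_groups(self, small_net, small_data):
        small_net.affb.scorer.weight.data[:] = 0.0
        small_net.affb.scorer.bias.data[:] = 0.0
        w = mean_attention_weights(small_net, small_data[0])
        assert np.allclose(w["view_wise"], 1 / 4, atol=1e-6)
        assert np.allclose(w["phase_wise"], 1 / 5, atol=1e-6)
        assert np.allclose(w["stage2"], 1 / 9, atol=1e-6)

    def test_groups_sum_to_one_after_averaging(self, small_net, small_data):
        w = mean_attention_weights(small_net, small_data[0])
        assert np.allclose(w["view_wise"].sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(w["phase_wise"].sum(axis=1), 1.0, atol=1e-6)
        assert w["stage2"].sum() == pytest.approx(1.0, abs=1e-6)
        assert w["view_mean"].sum() == pytest.approx(1.0, abs=1e-6)


def _mask_set(rng, n_phases=5, size=16, p=0.2):
    masks = {
        view: {ch: (rng.random((n_phases, size, size)) < p).astype(np.uint8)
               for ch in VIEW_CHAMBERS[view]}
        for view in VIEWS
    }
    return ChamberMaskSet(masks, per_frame=True)


class TestChamberImportance:
    def test_grid_has_expected_cells(self, small_net, small_data, rng):
        x, y = small_data
        exams = [(x[i], _mask_set(rng)) for i in range(len(x))]
        grid = chamber_importance(small_net, exams, y)
        per_mode = grid.table[grid.table["mode"] == "mask"]
        single = per_mode[per_mode.view != "All views"]
        assert len(single) == 10  # 2+4+2+2 valid view/chamber pairs
        assert len(per_mode[per_mode.view == "All views"]) == 4
        assert set(grid.table["mode"]) == {"mask", "paste"}
        pivot = grid.pivot("mask")
        assert pivot.loc["2CH"].notna().sum() == 2
        assert np.isnan(pivot.loc["SAX", "LA"])

    def test_empty_masks_mask_mode_equals_intact(self, small_net, small_data, rng):
        x, y = small_data
        exams = [(x[i], _mask_set(rng, p=0.0)) for i in range(len(x))]
        grid = chamber_importance(small_net, exams, y)
        mask_cells = grid.table[grid.table["mode"] == "mask"].pcc
        assert np.allclose(mask_cells, grid.intact_pcc, atol=1e-5)
        # paste with an empty mask feeds an all-black input: constant
        # prediction, PCC undefined
        paste_cells = grid.table[grid.table["mode"] == "paste"].pcc
        assert np.all(np.isnan(paste_cells))
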