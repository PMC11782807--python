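"""Intensity normalisation, resampling, crop/pad, and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cinefuse.exam import FRAME_SIZE, N_PHASES, TARGET_SPACING, RawCineSeries
from cinefuse.preprocessing import (AugmentationParams, augment, crop_or_pad,
                                    normalize_intensity, preprocess_exam,
                                    preprocess_series, resample_to_spacing)


def make_series(rng, n=N_PHASES, h=100, w=120, spacing=1.5, view="2CH"):
    return RawCineSeries(rng.random((n, h, w)) * 300, spacing, view)


class TestNormalizeIntensity:
    def test_uniform_ramp_matches_percentile_affine_oracle(self):
        # 0..99 uniformly: clip at the 3rd/97th percentile then map min->0 max->1
        vals = np.arange(100, dtype=np.float64)
        frames = vals.reshape(4, 5, 5)
        p3, p97 = np.percentile(vals, [3, 97])
        expected = (np.clip(frames, p3, p97) - p3) / (p97 - p3)
        out = normalize_intensity(frames)
        assert np.allclose(out, expected, atol=1e-6)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_series_maps_to_zeros(self, caplog):
        out = normalize_intensity(np.full((3, 4, 4), 7.0))
        assert np.all(out == 0.0)

    def test_endpoints_reach_zero_and_one(self, rng):
        out = normalize_intensity(rng.random((5, 8, 8)) * 50)
        assert out.min() == pytest.approx(0.0, abs=1e-6)
        assert out.max() == pytest.approx(1.0, abs=1e-6)


class TestResample:
    def test_exact_double_ratio(self, rng):
        s = make_series(rng, h=128, w=128, spacing=1.88)
        out = resample_to_spacing(s)
        assert out.frames.shape == (N_PHASES, 256, 256)
        assert out.pixel_spacing == TARGET_SPACING

    def test_identity_when_already_at_target(self, rng):
        s = make_series(rng, h=256, w=256, spacing=0.94)
        out = resample_to_spacing(s)
        assert np.array_equal(out.frames, s.frames)

    def test_rounded_output_size(self, rng):
        s = make_series(rng, h=200, w=200, spacing=1.5)
        out = resample_to_spacing(s)
        assert out.frames.shape == (N_PHASES, 319, 319)  # round(200*1.5/0.94)

    def test_bilinear_values_match_independent_resampler(self, rng):
        from skimage.transform import resize

        frame = rng.random((40, 40)).astype(np.float32)
        s = RawCineSeries(np.stack([frame] * 2), 1.88, "SAX")
        out = resample_to_spacing(s)
        ref = resize(frame, (80, 80), order=1, anti_aliasing=False)
        # interiors agree; border conventions may differ by a pixel
        assert np.allclose(out.frames[0][2:-2, 2:-2], ref[2:-2, 2:-2], atol=5e-2)

    def test_rejects_nonpositive_spacing(self, rng):
        s = make_series(rng)
        with pytest.raises(ValueError):
            resample_to_spacing(s, target_spacing=0.0)


class TestCropOrPad:
    def test_central_crop(self):
        frames = np.zeros((2, 300, 300))
        frames[:, 150, 150] = 1.0
        out = crop_or_pad(frames)
        assert out.shape == (2, 256, 256)
        assert out[0, 128, 128] == 1.0

    def test_symmetric_pad_bands(self, rng):
        frames = rng.random((2, 200, 256))
        out = crop_or_pad(frames)
        assert out.shape == (2, 256, 256)
        assert np.all(out[:, :28] == 0) and np.all(out[:, -28:] == 0)
        assert np.array_equal(out[:, 28:228], frames)

    def test_crop_of_pad_roundtrip_identity(self, rng):
        frames = rng.random((3, 256, 256))
        padded = crop_or_pad(frames, size=300)
        assert np.array_equal(crop_or_pad(padded, size=256), frames)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    h=st.integers(60, 320),
    w=st.integers(60, 320),
    spacing=st.floats(0.5, 3.0),
)
def test_pipeline_always_yields_canonical_layout(h, w, spacing):
    rng = np.random.default_rng(h * 1000 + w)
    s = RawCineSeries(rng.random((N_PHASES, h, w)) * 100, spacing, "4CH")
    out = preprocess_series(s)
    assert out.frames.shape == (N_PHASES, FRAME_SIZE, FRAME_SIZE)
    assert out.frames.min() >= 0.0 and out.frames.max() <= 1.0
    assert out.pixel_spacing == TARGET_SPACING


def test_field_of_view_is_240mm_within_one_pixel():
    assert abs(FRAME_SIZE * TARGET_SPACING - 240.0) <= TARGET_SPACING


def test_masks_follow_frames_through_preprocessing(small_phantom):
    from cinefuse.evaluation import HemodynamicTriple
    from cinefuse.synthetic import generate_exam

    exam = generate_exam(small_phantom, HemodynamicTriple(45, 12, 7), seed=0)
    pre = preprocess_exam(exam)
    raw_mask = exam.masks.get_stack("SAX", "RV")[0]
    new_mask = pre.masks.get_stack("SAX", "RV")[0]
    assert new_mask.shape == (FRAME_SIZE, FRAME_SIZE)
    # 4x upsampling scales mask area by ~16
    assert new_mask.sum() == pytest.approx(16 * raw_mask.sum(), rel=0.05)
    # the dilated chamber region covers the bright blood pool in the frames
    inside = pre.series["SAX"].frames[0][new_mask == 1]
    outside_mean = pre.series["SAX"].frames[0][new_mask == 0].mean()
    assert inside.mean() > outside_mean


def test_wrong_phase_count_rejected(rng):
    with pytest.raises(ValueError, match="phases"):
        preprocess_series(make_series(rng, n=19))


class TestAugment:
    @staticmethod
    def _exam(rng):
        from cinefuse.exam import VIEWS, CineExam, PreprocessedCineSeries

        series = {
            v: PreprocessedCineSeries(
                rng.random((N_PHASES, FRAME_SIZE, FRAME_SIZE)).astype(np.float32), v)
            for v in VIEWS
        }
        return CineExam(series=series, exam_id="aug")

    def test_zero_magnitude_params_are_identity(self, rng):
        exam = self._exam(rng)
        out = augment(exam, AugmentationParams.identity(), rng=0)
        for v in exam.series:
            assert np.array_equal(out.series[v].frames, exam.series[v].frames)

    def test_same_seed_is_deterministic(self, rng):
        exam = self._exam(rng)
        params = AugmentationParams()
        a = augment(exam, params, rng=42)
        b = augment(exam, params, rng=42)
        for v in exam.series:
            assert np.array_equal(a.series[v].frames, b.series[v].frames)

    def test_flip_only_is_involution(self, rng):
        exam = self._exam(rng)
        params = AugmentationParams(flip_prob=1.0, max_shift_px=0,
                                    scale_range=(1.0, 1.0), max_rotation_deg=0)
        once = augment(exam, params, rng=1)
        twice = augment(once, params, rng=2)
        for v in exam.series:
            assert np.array_equal(once.series[v].frames,
                                  exam.series[v].frames[:, :, ::-1])
            assert np.allclose(twice.series[v].frames, exam.series[v].frames,
                               atol=1e-6)

    def test_transform_shared_across_phases_of_one_series(self, rng):
        # a constant-in-time series must stay constant in time after augmentation
        from cinefuse.exam import VIEWS, CineExam, PreprocessedCineSeries

        frame = rng.random((FRAME_SIZE, FRAME_SIZE)).astype(np.float32)
        series = {
            v: PreprocessedCineSeries(np.repeat(frame[None], N_PHASES, axis=0), v)
            for v in VIEWS
        }
        out = augment(CineExam(series=series, exam_id="x"), AugmentationParams(),
                      rng=3)
        for v in VIEWS:
            f = out.series[v].frames
            assert np.array_equal(f, np.repeat(f[:1], N_PHASES, axis=0))
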