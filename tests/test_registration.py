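"""Registration tests: brute-force NCC oracle, peak/tie-break contracts,
crop geometry, and recovery of planted camera jitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofoulmon import (
    GrayImage,
    ImageFrame,
    NCCMap,
    Offset,
    ScenarioConfig,
    TemplateROI,
    extract_template,
    locate_peak,
    ncc_map,
    register_frame,
    register_series,
    simulate_image_series,
    to_grayscale,
)
from biofoulmon.errors import (
    DimensionError,
    ExcessiveMotionError,
    FeaturelessTemplateError,
    InputError,
    UndefinedPeakError,
)


def brute_force_ncc(template: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Independent oracle: Pearson r per valid window, via a double loop."""
    th, tw = template.shape
    h, w = image.shape
    out = np.full((h - th + 1, w - tw + 1), np.nan)
    t = template - template.mean()
    sst = np.sum(t * t)
    for u in range(out.shape[0]):
        for v in range(out.shape[1]):
            win = image[u : u + th, v : v + tw]
            wc = win - win.mean()
            ssw = np.sum(wc * wc)
            if ssw > 0 and sst > 0:
                out[u, v] = np.sum(wc * t) / np.sqrt(ssw * sst)
    return out


class TestExtractTemplate:
    def test_whole_image_roi_is_identity(self, rng):
        img = GrayImage(rng.random((16, 20)))
        crop = extract_template(img, TemplateROI(0, 0, 16, 20))
        np.testing.assert_array_equal(crop.pixels, img.pixels)

    def test_constant_roi_is_featureless(self):
        img = GrayImage(np.ones((32, 32)))
        with pytest.raises(FeaturelessTemplateError, match="featureless"):
            extract_template(img, TemplateROI(4, 4, 8, 8))

    def test_roi_out_of_bounds_rejected(self, rng):
        img = GrayImage(rng.random((16, 16)))
        with pytest.raises(InputError):
            extract_template(img, TemplateROI(10, 10, 8, 8))

    def test_degenerate_roi_rejected(self):
        with pytest.raises(InputError):
            TemplateROI(0, 0, 4, 64)

    def test_self_match_peak_is_one_at_own_location(self):
        cfg = ScenarioConfig.scaled(128, 192, seed=4, duration_h=6, onset_h=999)
        frames, _, _ = simulate_image_series(cfg)
        gray = to_grayscale(frames[0])
        roi = TemplateROI(32, 64, 64, 64)
        template = extract_template(gray, roi)
        off = locate_peak(ncc_map(template, gray, origin=(roi.row0, roi.col0)))
        assert (off.drow, off.dcol) == (0, 0)
        assert off.peak_score == pytest.approx(1.0, abs=1e-9)


class TestNccMap:
    def test_perfect_match_scores_one(self, rng):
        img = rng.random((12, 14))
        template = GrayImage(img[3:8, 4:10].copy())
        nmap = ncc_map(template, GrayImage(img))
        assert nmap.scores[3, 4] == pytest.approx(1.0, abs=1e-10)

    def test_affine_illumination_invariance(self, rng):
        img = rng.random((20, 20))
        template = GrayImage(rng.random((6, 6)))
        m1 = ncc_map(template, GrayImage(img)).scores
        m2 = ncc_map(template, GrayImage(2.5 * img + 0.7)).scores
        np.testing.assert_allclose(m1, m2, atol=1e-8)

    def test_matches_brute_force_small_case(self, rng):
        template = rng.random((5, 5))
        image = rng.random((8, 8))
        got = ncc_map(GrayImage(template), GrayImage(image)).scores
        want = brute_force_ncc(template, image)
        assert got.shape == (4, 4)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        th=st.integers(4, 10),
        tw=st.integers(4, 10),
        pad=st.integers(1, 12),
    )
    def test_matches_brute_force_property(self, seed, th, tw, pad):
        r = np.random.default_rng(seed)
        template = r.random((th, tw))
        image = r.random((th + pad, tw + pad))
        got = ncc_map(GrayImage(template), GrayImage(image)).scores
        np.testing.assert_allclose(got, brute_force_ncc(template, image), atol=1e-8)
        assert np.nanmax(np.abs(got)) <= 1.0 + 1e-12

    def test_template_not_smaller_rejected(self, rng):
        img = GrayImage(rng.random((8, 8)))
        with pytest.raises(DimensionError):
            ncc_map(img, img)

    def test_zero_variance_windows_undefined(self, rng):
        image = np.zeros((12, 12))
        image[8:, 8:] = rng.random((4, 4))
        template = GrayImage(rng.random((4, 4)))
        scores = ncc_map(template, GrayImage(image)).scores
        assert np.isnan(scores[0, 0])  # constant window
        assert np.isfinite(scores[8, 8])


class TestLocatePeak:
    def test_unique_max(self):
        scores = np.zeros((6, 8))
        scores[2, 5] = 0.9
        off = locate_peak(NCCMap(scores))
        assert (off.drow, off.dcol) == (2, 5)
        assert off.peak_score == 0.9

    def test_tie_breaks_row_major(self):
        scores = np.zeros((6, 8))
        scores[3, 7] = 0.5
        scores[5, 2] = 0.5
        off = locate_peak(NCCMap(scores))
        assert (off.drow, off.dcol) == (3, 7)

    def test_all_undefined_raises(self):
        with pytest.raises(UndefinedPeakError):
            locate_peak(NCCMap(np.full((3, 3), np.nan)))

    def test_offset_relative_to_origin(self):
        scores = np.zeros((6, 8))
        scores[4, 1] = 1.0
        off = locate_peak(NCCMap(scores, origin=(2, 3)))
        assert (off.drow, off.dcol) == (2, -2)


class TestRegisterFrame:
    def test_paper_geometry_and_anchor(self):
        frame = ImageFrame(
            np.arange(2064 * 3088 * 3, dtype=np.uint64).astype(np.uint8).reshape(
                2064, 3088, 3
            ),
            time_h=0.0,
        )
        reg = register_frame(frame, Offset(0, 0), margins=(127, 175))
        assert reg.pixels.shape == (1937, 2913, 3)
        np.testing.assert_array_equal(
            reg.pixels, frame.pixels[63 : 63 + 1937, 87 : 87 + 2913]
        )

    def test_offset_compensation_aligns_features(self, rng):
        base = rng.integers(0, 256, size=(64, 80, 3), dtype=np.uint8)
        shifted = np.roll(base, shift=(3, -2), axis=(0, 1))
        r0 = register_frame(ImageFrame(base, 0.0), Offset(0, 0), margins=(16, 16))
        r1 = register_frame(ImageFrame(shifted, 1.0), Offset(3, -2), margins=(16, 16))
        np.testing.assert_array_equal(r0.pixels, r1.pixels)

    def test_excessive_motion_names_frame(self):
        frame = ImageFrame(
            np.zeros((200, 300, 3), dtype=np.uint8), time_h=0.0, source_id="f42"
        )
        with pytest.raises(ExcessiveMotionError, match="f42"):
            register_frame(frame, Offset(100, 0), margins=(127, 175))


class TestRegisterSeries:
    @pytest.fixture
    def clean_series(self):
        cfg = ScenarioConfig.scaled(
            128, 192, seed=12, duration_h=60.0, onset_h=999.0,
            frame_interval_h=6.0, noise_sd=0.0, illumination_drift=0.0,
        )
        frames, _, planted = simulate_image_series(cfg)
        return cfg, frames, planted

    def test_identical_frames_give_zero_offsets(self, rng):
        base = rng.integers(0, 256, size=(64, 96, 3), dtype=np.uint8)
        frames = [ImageFrame(base.copy(), float(t)) for t in range(4)]
        res = register_series(frames, TemplateROI(20, 30, 16, 16), margins=(8, 8))
        assert (res.offsets[["drow", "dcol"]] == 0).all().all()

    def test_noise_free_planted_jitter_recovered_exactly(self, clean_series):
        cfg, frames, planted = clean_series
        res = register_series(
            frames, TemplateROI(32, 64, 48, 48), margins=(16, 22)
        )
        recovered = list(zip(res.offsets["drow"], res.offsets["dcol"]))
        assert [tuple(x) for x in recovered] == planted
        assert (res.offsets["peak_score"] > 0.99).all()
        shapes = {f.pixels.shape for f in res.frames}
        assert shapes == {(128 - 16, 192 - 22, 3)}

    def test_drop_policy_shortens_series(self, clean_series, caplog):
        cfg, frames, planted = clean_series
        # margins too tight for the planted jitter of at least one frame
        biggest = max(max(abs(a), abs(b)) for a, b in planted)
        assert biggest >= 1
        tight = (2 * biggest - 1, 2 * biggest - 1)
        # widen the search beyond the (zero) movement room so the true peak
        # is observed and the failure policy, not the search bound, decides
        room = (4 * biggest, 4 * biggest)
        with pytest.raises(ExcessiveMotionError):
            register_series(
                frames, TemplateROI(32, 64, 48, 48), margins=tight,
                search_room=room,
            )
        res = register_series(
            frames, TemplateROI(32, 64, 48, 48), margins=tight,
            on_failure="drop", search_room=room,
        )
        assert 0 < len(res.frames) < len(frames)
        assert len(res.dropped) == len(frames) - len(res.frames)
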