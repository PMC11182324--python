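"""Signal-extraction stage: standardization, registration, column
projection, exclusion rules, and pre-stimulus mean subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iorg.extraction import (
    ConeSignalTable,
    apply_exclusion,
    affine_register_frames,
    compute_column_radius,
    correct_intraframe_distortion,
    exclude_short_acquisitions,
    extract_cone_signals,
    refine_coordinates,
    standardize_frames,
    subtract_prestim_mean,
)

from conftest import make_stack


def _textured_frame(shape=(64, 64), seed=0):
    """Smooth random texture with structure at several scales."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    return (img - img.min()) / (img.max() - img.min()) * 100 + 10


class TestExcludeShortAcquisitions:
    def test_half_boundary(self):
        # exactly half the original frames is retained; one fewer is dropped
        T = 176
        keep = make_stack(np.ones((T, 4, 4)), valid=np.r_[np.ones(88, bool), np.zeros(88, bool)])
        drop = make_stack(np.ones((T, 4, 4)), valid=np.r_[np.ones(87, bool), np.zeros(89, bool)])
        out = exclude_short_acquisitions([keep, drop], original_frame_count=T)
        assert out == [keep]

    def test_full_length_identity_and_empty(self):
        stacks = [make_stack(np.ones((10, 4, 4))) for _ in range(3)]
        assert exclude_short_acquisitions(stacks, 10) == stacks
        assert exclude_short_acquisitions([], 10) == []


class TestStandardizeFrames:
    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(10, 2, size=(3, 32, 32)) + 5  # strictly positive
        stack = make_stack(frames)
        out = standardize_frames(stack)
        for t in range(3):
            m = out.region_mask()[t]
            assert out.frames[t][m].mean() == pytest.approx(70, abs=1e-6)
            assert out.frames[t][m].std() == pytest.approx(35, rel=1e-6)
        again = standardize_frames(out)
        np.testing.assert_allclose(again.frames, out.frames, atol=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(50, 5, size=(2, 16, 16))
        region = np.ones_like(frames, dtype=bool)
        a = standardize_frames(make_stack(frames, image_region=region))
        b = standardize_frames(make_stack(3.0 * frames + 17.0, image_region=region))
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-9)

    def test_zero_variance_frame_flagged(self):
        frames = np.ones((2, 8, 8))
        out = standardize_frames(make_stack(frames))
        assert not out.valid.any()


class TestDistortionCorrection:
    def test_constant_strip_shift_removed(self):
        base = _textured_frame()
        shift = np.roll(base, 2, axis=1)  # 2 px horizontal shift everywhere
        frames = np.stack([base] + [shift] * 6)
        stack = make_stack(frames)
        out = correct_intraframe_distortion(stack, reference_frame=0, strip_height=16)
        # median shift is (0, -2); its inverse restores alignment with base
        interior = (slice(4, 60), slice(4, 60))
        resid = np.abs(out.frames[1][interior] - base[interior])
        assert np.median(resid) < np.median(np.abs(shift[interior] - base[interior]))

    def test_zero_motion_identity(self):
        frames = np.stack([_textured_frame()] * 5)
        out = correct_intraframe_distortion(make_stack(frames), 0, strip_height=16)
        np.testing.assert_allclose(out.frames, frames, atol=1e-9)

    def test_median_robust_to_outlier(self):
        base = _textured_frame()
        frames = np.stack([base] * 9 + [np.roll(base, 5, axis=0)])
        out = correct_intraframe_distortion(make_stack(frames), 0, strip_height=16)
        np.testing.assert_allclose(out.frames[:9], frames[:9], atol=1e-9)


class TestAffineRegistration:
    def test_identity_stack(self):
        base = _textured_frame()
        stack = make_stack(np.stack([base] * 3))
        out, transforms = affine_register_frames(stack, 0)
        for mat in transforms:
            np.testing.assert_allclose(mat, np.eye(3), atol=0.05)

    def test_recovers_translation(self):
        from scipy import ndimage

        base = _textured_frame()
        moved = ndimage.shift(base, (-3.0, 2.0), order=1, mode="nearest")
        stack = make_stack(np.stack([base, moved]))
        out, transforms = affine_register_frames(stack, 0)
        # frame was shifted by (dy, dx) = (-3, 2): registration undoes it
        assert transforms[1][0, 2] == pytest.approx(-3.0, abs=0.1)
        assert transforms[1][1, 2] == pytest.approx(2.0, abs=0.1)

    def test_recovers_rotation(self):
        from scipy import ndimage

        base = _textured_frame((96, 96), seed=3)
        rotated = ndimage.rotate(base, 1.0, reshape=False, order=1, mode="nearest")
        stack = make_stack(np.stack([base, rotated]))
        out, transforms = affine_register_frames(stack, 0)
        lin = transforms[1][:2, :2]
        # rotation angle of the recovered pull-back transform
        angle = np.degrees(np.arcsin((lin[1, 0] - lin[0, 1]) / 2))
        assert angle == pytest.approx(1.0, abs=0.1)


class TestRefineCoordinates:
    def test_climbs_to_peak(self):
        yy, xx = np.mgrid[0:21, 0:21]
        img = np.exp(-(((yy - 10.0) ** 2 + (xx - 10.0) ** 2) / 8.0))
        out = refine_coordinates(img, np.array([[9.0, 9.0]]), max_radius=2)
        np.testing.assert_array_equal(out, [[10, 10]])

    def test_at_peak_and_uniform_unchanged(self):
        yy, xx = np.mgrid[0:11, 0:11]
        img = np.exp(-(((yy - 5.0) ** 2 + (xx - 5.0) ** 2) / 4.0))
        assert refine_coordinates(img, np.array([[5.0, 5.0]]))[0].tolist() == [5, 5]
        flat = np.ones((11, 11))
        np.testing.assert_array_equal(
            refine_coordinates(flat, np.array([[3.0, 7.0]])), [[3, 7]]
        )


class TestColumnRadius:
    def test_hexagonal_arithmetic(self):
        from iorg.synthetic import MosaicSpec, generate_mosaic

        coords = generate_mosaic(MosaicSpec(spacing=10, jitter_sd=0, field_size=0.3,
                                            pixels_per_degree=291))
        assert compute_column_radius(coords, fwhm_fraction=0.6) == pytest.approx(3.0)

    def test_two_cones(self):
        coords = np.array([[0.0, 0.0], [8.0, 0.0]])
        assert compute_column_radius(coords, fwhm_fraction=0.5) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            compute_column_radius(coords[:1])

    def test_median_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 60, size=(40, 2))
        # O(n^2) oracle for the median nearest-neighbor spacing
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        med = np.median(d.min(axis=1))
        assert compute_column_radius(coords, fwhm_fraction=0.6) == pytest.approx(0.3 * med)


class TestExtractConeSignals:
    def test_uniform_frame(self):
        frames = np.full((4, 16, 16), 7.0)
        stack = make_stack(frames)
        table = extract_cone_signals(stack, np.array([[8.0, 8.0], [4.0, 11.0]]), 2.0)
        np.testing.assert_allclose(table.signal, 7.0)
        assert not table.missing.any()

    def test_invalid_frame_missing(self):
        frames = np.full((4, 16, 16), 7.0)
        valid = np.array([True, False, True, True])
        table = extract_cone_signals(make_stack(frames, valid=valid), np.array([[8.0, 8.0]]), 2.0)
        assert table.missing[0, 1] and not table.missing[0, 0]

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(9)
        frames = rng.uniform(1, 100, size=(3, 32, 32))
        coords = np.array([[10.3, 12.7], [20.0, 5.0], [29.5, 30.1]])
        radius = 2.5
        table = extract_cone_signals(make_stack(frames), coords, radius)
        for c, (x, y) in enumerate(coords):
            for t in range(3):
                vals = []
                for yy in range(32):
                    for xx in range(32):
                        if (yy - y) ** 2 + (xx - x) ** 2 <= radius**2:
                            vals.append(frames[t, yy, xx])
                assert table.signal[c, t] == np.mean(vals)


class TestExclusionRules:
    def _table(self, missing):
        C, T = missing.shape
        return ConeSignalTable(
            signal=np.zeros((C, T)), missing=missing, cone_ids=np.arange(C),
            stimulus_frame=10, frame_rate=29.4,
        )

    def test_window_rule(self):
        # 0.2 s at 29.4 Hz -> frames 10..16 inclusive (7 frames)
        missing = np.zeros((2, 40), dtype=bool)
        missing[0, 10:14] = True  # 4 of 7 missing (57% > 50%) -> excluded
        missing[1, 10:13] = True  # 3 of 7 (43%) -> retained
        out, report = apply_exclusion(self._table(missing))
        assert list(out.cone_ids) == [1]
        assert report.loc[0, "window_missing_gt_50pct"]

    def test_whole_acquisition_50pct_boundary_excluded(self):
        missing = np.zeros((1, 40), dtype=bool)
        missing[0, 20:] = True  # exactly 50% missing -> excluded
        out, _ = apply_exclusion(self._table(missing))
        assert out.n_cones == 0

    def test_acquisition_count_boundary_retained(self):
        missing = np.zeros((1, 40), dtype=bool)
        out, _ = apply_exclusion(
            self._table(missing),
            n_acquisitions_present=np.array([5]), n_acquisitions_total=10,
        )
        assert out.n_cones == 1  # exactly 50% of acquisitions is not "less than"
        out, _ = apply_exclusion(
            self._table(missing),
            n_acquisitions_present=np.array([4]), n_acquisitions_total=10,
        )
        assert out.n_cones == 0

    def test_rules_order_independent(self):
        rng = np.random.default_rng(3)
        missing = rng.random((30, 60)) < 0.45
        table = ConeSignalTable(
            signal=np.zeros((30, 60)), missing=missing, cone_ids=np.arange(30),
            stimulus_frame=30, frame_rate=29.4,
        )
        present = rng.integers(3, 10, size=30)
        combined, _ = apply_exclusion(table, present, 10)
        # apply each rule in isolation and intersect the survivors
        win = apply_exclusion(table)[0]
        survivors = set(win.cone_ids)
        survivors &= set(np.arange(30)[present >= 5])
        assert set(combined.cone_ids) == survivors


class TestSubtractPrestimMean:
    def test_constant_to_zero_and_arithmetic(self):
        sig = np.array([[1.0, 3.0, 5.0]])
        table = ConeSignalTable(sig, np.zeros_like(sig, bool), [0], 2, 29.4)
        out, _ = subtract_prestim_mean(table)
        np.testing.assert_allclose(out.signal, [[-1.0, 1.0, 3.0]])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_zero_prestim_mean_property(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.normal(5, 3, size=(6, 30))
        miss = rng.random((6, 30)) < 0.2
        miss[:, 0] = False  # guarantee a valid pre-stimulus frame
        table = ConeSignalTable(sig, miss, np.arange(6), 15, 29.4)
        out, dropped = subtract_prestim_mean(table)
        pre = np.where(out.missing[:, :15], np.nan, out.signal[:, :15])
        np.testing.assert_allclose(np.nanmean(pre, axis=1), 0.0, atol=1e-9)

    def test_no_prestim_cone_dropped(self):
        sig = np.ones((2, 6))
        miss = np.zeros((2, 6), bool)
        miss[1, :3] = True  # cone 1 has no valid pre-stimulus frames
        table = ConeSignalTable(sig, miss, np.arange(2), 3, 29.4)
        out, dropped = subtract_prestim_mean(table)
        assert list(out.cone_ids) == [0] and list(dropped) == [1]


def test_offset_invariance_of_downstream_rms(random_table):
    """A per-cone constant offset vanishes after mean subtraction."""
    from iorg.rms import population_rms

    base, _ = subtract_prestim_mean(random_table)
    shifted = ConeSignalTable(
        random_table.signal + np.arange(20)[:, None] * 3.7,
        random_table.missing, random_table.cone_ids,
        random_table.stimulus_frame, random_table.frame_rate,
    )
    other, _ = subtract_prestim_mean(shifted)
    np.testing.assert_allclose(
        population_rms(base).values, population_rms(other).values, atol=1e-9
    )
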