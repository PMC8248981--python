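"""Quantification pipeline: segmentation, level/activity estimators, gating,
focus scoring, and invariances."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from cdksize import synthetic as syn
from cdksize.errors import DegenerateCellError, SegmentationError
from cdksize.quantify import (
    CellImage,
    GateParams,
    MidlineProfile,
    activity_from_profile,
    estimate_background,
    gate_records,
    gradient_rms_focus,
    measure_level,
    midline_profile,
    quantify_image,
    segment_cell,
)


def _image_from(bf1, bf2, px=0.15):
    z = np.zeros_like(np.asarray(bf1, dtype=float))
    return CellImage(bf1=bf1, bf2=bf2, channels={"biosensor": z, "level": z},
                     pixel_size_um=px)


class TestSegmentation:
    def test_identical_brightfields_fail(self):
        bf = np.random.default_rng(0).normal(100, 10, (40, 80))
        with pytest.raises(SegmentationError):
            segment_cell(_image_from(bf, bf.copy()))

    def test_pure_noise_without_cell_fails(self, rng):
        bf1 = rng.normal(100, 2, (40, 80))
        bf2 = rng.normal(100, 2, (40, 80))
        with pytest.raises(SegmentationError):
            segment_cell(_image_from(bf1, bf2))

    def test_noiseless_cell_recovers_geometry(self):
        """Read-noise-free render: mask area within 10% of the true rod area
        and length within one pixel."""
        cfg = syn.SimConfig(
            seed=1, imaging=replace(syn.ImagingParams(), noise_sd_au=0.0)
        )
        row = pd.Series(
            {"true_length_um": 11.0, "true_radius_um": 1.75, "true_nc": 1.5,
             "true_level_au": 400.0, "cell_id": "c"}
        )
        img = syn.render_cell_image(row, cfg, rng=np.random.default_rng(2))
        mask = segment_cell(img)
        r, L = 1.75, 11.0
        true_area = (2 * r * (L - 2 * r) + np.pi * r**2) / cfg.imaging.pixel_size_um**2
        assert abs(mask.area_px2 / true_area - 1) < 0.10
        assert abs(mask.length_um - L) <= cfg.imaging.pixel_size_um

    def test_constant_offset_invariance(self, rendered_cell):
        img, _, _ = rendered_cell
        shifted = CellImage(
            bf1=np.asarray(img.bf1) + 500.0,
            bf2=np.asarray(img.bf2) + 500.0,
            channels=img.channels,
            pixel_size_um=img.pixel_size_um,
        )
        m1 = segment_cell(img)
        m2 = segment_cell(shifted)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert m1.length_um == pytest.approx(m2.length_um)

    def test_rotated_cell_is_straightened(self, rendered_cell):
        """A cell rotated in the frame is measured along its own long axis."""
        img, row, cfg = rendered_cell
        pad = 30
        deg = 20.0
        def rot(a, order):
            padded = np.pad(np.asarray(a, dtype=float), pad, mode="edge")
            return ndi.rotate(padded, deg, reshape=False, order=order, mode="nearest")
        rimg = CellImage(
            bf1=rot(img.bf1, 1), bf2=rot(img.bf2, 1),
            channels={k: rot(v, 1) for k, v in img.channels.items()},
            pixel_size_um=img.pixel_size_um,
        )
        mask = segment_cell(rimg)
        assert abs(abs(np.degrees(mask.orientation_rad)) - deg) < 3.0
        assert abs(mask.length_um - row["true_length_um"]) < 3 * cfg.imaging.pixel_size_um


class TestMeasureLevel:
    def test_uniform_channel_returns_value(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert measure_level(np.full((20, 20), 7.5), mask) == pytest.approx(7.5)

    def test_bright_block_found(self):
        ch = np.ones((20, 20))
        ch[8:11, 8:11] = 10.0
        mask = np.zeros((20, 20), dtype=bool)
        mask[4:16, 4:16] = True
        assert measure_level(ch, mask) == pytest.approx(10.0)

    def test_matches_exhaustive_window_scan(self, rng):
        """Block estimator equals a brute-force scan of every in-mask 3x3
        window on random rasters/masks."""
        for _ in range(100):
            h, w = rng.integers(8, 24, size=2)
            ch = rng.normal(50, 20, (h, w))
            mask = rng.uniform(size=(h, w)) < 0.7
            mask[1:4, 1:4] = True  # guarantee one valid window
            best = -np.inf
            for i in range(h - 2):
                for j in range(w - 2):
                    if mask[i : i + 3, j : j + 3].all():
                        best = max(best, ch[i : i + 3, j : j + 3].mean())
            assert measure_level(ch, mask) == pytest.approx(best)

    def test_brightest_pixels_variant(self, rng):
        ch = rng.normal(10, 3, (15, 15))
        mask = np.ones((15, 15), dtype=bool)
        expected = np.sort(ch.ravel())[-9:].mean()
        assert measure_level(ch, mask, method="pixels") == pytest.approx(expected)

    def test_no_window_fits_raises(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 2:8] = True  # 1-px-thin line
        with pytest.raises(DegenerateCellError):
            measure_level(np.ones((10, 10)), mask)

    def test_size_invariance_of_concentration(self, rng):
        """For a uniform concentration the estimate does not depend on how
        large the mask is."""
        ch = np.full((40, 60), 123.0)
        small = np.zeros_like(ch, dtype=bool)
        small[18:24, 25:35] = True
        large = np.zeros_like(ch, dtype=bool)
        large[5:35, 5:55] = True
        assert measure_level(ch, small) == measure_level(ch, large)


class TestMidlineAndActivity:
    def test_uniform_channel_gives_flat_profile(self, rendered_cell):
        img, _, _ = rendered_cell
        mask = segment_cell(img)
        prof = midline_profile(np.full(img.shape, 42.0), mask)
        assert np.allclose(prof.intensities, 42.0)

    def test_profile_matches_direct_indexing(self, rendered_cell):
        img, _, _ = rendered_cell
        mask = segment_cell(img)
        ch = np.asarray(img.channels["biosensor"], dtype=float)
        prof = midline_profile(ch, mask)
        r0, r, r1 = prof.band_rows
        cols = prof.positions.astype(int)
        # orientation is ~0 for this render, so direct indexing applies
        expected = ch[r0 : r1 + 1, cols].mean(axis=0)
        np.testing.assert_allclose(prof.intensities, expected)

    def test_flat_profile_activity_is_one(self):
        prof = MidlineProfile(np.arange(40.0), np.full(40, 100.0))
        assert activity_from_profile(prof) == 1.0

    @pytest.mark.parametrize("extremum,expected", [(300.0, 3.0), (50.0, 0.5)])
    def test_peak_and_dip_ratios(self, extremum, expected):
        y = np.full(41, 100.0)
        y[18:23] = extremum
        prof = MidlineProfile(np.arange(41.0), y)
        assert activity_from_profile(prof) == pytest.approx(expected)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        y = np.full(41, 100.0)
        y[19:22] = 250.0
        a1 = activity_from_profile(MidlineProfile(np.arange(41.0), y))
        a2 = activity_from_profile(MidlineProfile(np.arange(41.0), k * y))
        assert a2 == pytest.approx(a1)

    def test_short_profile_raises(self):
        with pytest.raises(DegenerateCellError):
            activity_from_profile(MidlineProfile(np.arange(5.0), np.ones(5)))

    def test_rendered_nc_recovered(self, rendered_cell):
        img, row, _ = rendered_cell
        mask = segment_cell(img)
        ch = np.asarray(img.channels["biosensor"], dtype=float)
        ch = ch - estimate_background(ch, mask)
        act = activity_from_profile(midline_profile(ch, mask))
        assert act == pytest.approx(row["true_nc"], rel=0.05)


class TestFocusAndGating:
    def test_constant_image_scores_zero(self):
        assert gradient_rms_focus(np.full((20, 20), 5.0)) == 0.0

    def test_blur_reduces_score(self, rng):
        img = rng.normal(0, 1, (50, 50))
        img[::2, ::2] += 4.0  # checkerboard-ish texture
        assert gradient_rms_focus(img) > gradient_rms_focus(ndi.gaussian_filter(img, 2))

    def test_matches_direct_formula(self, rng):
        img = rng.normal(0, 3, (30, 40))
        gy, gx = np.gradient(img)
        direct = np.sqrt(np.mean(gx**2 + gy**2))
        assert gradient_rms_focus(img, scale=1.0) == pytest.approx(direct)

    def test_gate_cut_is_strict(self):
        df = pd.DataFrame(
            {"focus_grad_rms": [64.9, 65.0, 65.1], "area_px2": [1.0] * 3,
             "length_um": [10.0] * 3, "radius_um": [2.0] * 3}
        )
        out = gate_records(df)
        assert list(out["gated"]) == [False, False, True]

    def test_infinite_gates_pass_everything(self, small_config):
        rec, _ = syn.simulate_population(small_config)
        out = gate_records(rec, GateParams(grad_rms_min=-np.inf))
        assert out["gated"].all()

    def test_gating_matches_direct_filter(self):
        cfg = syn.SimConfig(seed=11, n_cells=2000, doublet_frac=0.1, unfocused_frac=0.1)
        rec, truth = syn.simulate_population(cfg)
        # doublets have twice the length, i.e. aspect >= 4 at radius 1.75
        params = GateParams(grad_rms_min=65.0, area_range=(0.0, 2600.0),
                            aspect_range=(1.0, 3.99))
        out = gate_records(rec, params)
        aspect = rec["length_um"] / (2 * rec["radius_um"])
        direct = (
            (rec["focus_grad_rms"] > 65.0)
            & rec["area_px2"].between(0.0, 2600.0)
            & aspect.between(1.0, 3.99)
        )
        assert (out["gated"] == direct).all()
        # the doublets injected by the generator fall outside the windows
        assert not out.loc[truth["is_doublet"].to_numpy(), "gated"].any()


def test_quantify_image_record_fields(rendered_cell):
    img, row, cfg = rendered_cell
    rec = quantify_image(img)
    assert rec["cdk_level_au"] == pytest.approx(row["true_level_au"], rel=0.03)
    assert rec["activity_nc"] == pytest.approx(row["true_nc"], rel=0.05)
    assert rec["length_um"] == pytest.approx(
        row["true_length_um"], abs=cfg.imaging.pixel_size_um
    )
    assert rec["volume_fl"] == pytest.approx(
        np.pi * rec["radius_um"] ** 2 * rec["length_um"], rel=1e-6
    )
    assert rec["focus_grad_rms"] > 65.0
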