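"""Stack I/O, translation resampling, composites and the RMS diagnostic."""

import numpy as np
import pandas as pd
import pytest
import yaml

from mtalign.image_io import (ImageStack, TagImagePair, Translation,
                              apply_translation, mosaic_extent, read_stack,
                              rgb_composite, rms_channel_difference, write_image,
                              write_stack)


def _keys_oracle(img, dx, dy):
    """Independent per-pixel Keys cubic convolution (edge replication)."""
    a = -0.5

    def k(t):
        t = abs(t)
        if t <= 1:
            return (a + 2) * t**3 - (a + 3) * t**2 + 1
        if t < 2:
            return a * t**3 - 5 * a * t**2 + 8 * a * t - 4 * a
        return 0.0

    h, w = img.shape
    out = np.zeros_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            sy, sx = y - dy, x - dx
            by, bx = int(np.floor(sy)), int(np.floor(sx))
            acc = 0.0
            for m in range(by - 1, by + 3):
                wy = k(sy - m)
                for n in range(bx - 1, bx + 3):
                    acc += wy * k(sx - n) * img[np.clip(m, 0, h - 1), np.clip(n, 0, w - 1)]
            out[y, x] = acc
    return out


def _tiny_stack(n=3, h=24, w=30, seed=0):
    rng = np.random.default_rng(seed)
    pairs = [TagImagePair(f"tag{i}", rng.integers(0, 4096, (h, w)).astype(float),
                          rng.integers(0, 4096, (h, w)).astype(float),
                          index=i + 1, source_dtype=np.dtype(np.uint16))
             for i in range(n)]
    return ImageStack(pairs=pairs)


class TestStackIO:
    def test_write_read_roundtrip_preserves_order_and_values(self, tmp_path):
        stack = _tiny_stack()
        manifest = write_stack(stack, tmp_path)
        loaded = read_stack(manifest)
        assert loaded.n == 3
        assert loaded.tags == stack.tags
        for orig, back in zip(stack, loaded):
            np.testing.assert_array_equal(orig.phase, back.phase)
            np.testing.assert_array_equal(orig.fluorescence, back.fluorescence)

    def test_yaml_manifest_accepted(self, tmp_path):
        stack = _tiny_stack(n=2)
        write_stack(stack, tmp_path)
        rows = [{"tag": p.tag_name, "phase_path": f"{p.tag_name}_phase.tif",
                 "fluor_path": f"{p.tag_name}_fluor.tif"} for p in stack]
        ypath = tmp_path / "manifest.yaml"
        ypath.write_text(yaml.safe_dump(rows))
        loaded = read_stack(ypath)
        assert loaded.tags == stack.tags

    def test_single_tag_manifest_rejected(self, tmp_path):
        stack = _tiny_stack(n=2)
        write_stack(stack, tmp_path)
        pd.DataFrame([{"tag": "tag0", "phase_path": "tag0_phase.tif",
                       "fluor_path": "tag0_fluor.tif"}]).to_csv(
            tmp_path / "one.csv", index=False)
        with pytest.raises(ValueError, match="at least 2"):
            read_stack(tmp_path / "one.csv")

    def test_dimension_mismatch_names_the_offending_tag(self, tmp_path):
        stack = _tiny_stack(n=2)
        write_stack(stack, tmp_path)
        write_image(tmp_path / "odd.tif", np.zeros((10, 10)), dtype=np.dtype(np.uint16))
        pd.DataFrame([
            {"tag": "tag0", "phase_path": "tag0_phase.tif", "fluor_path": "tag0_fluor.tif"},
            {"tag": "bad", "phase_path": "odd.tif", "fluor_path": "odd.tif"},
        ]).to_csv(tmp_path / "mix.csv", index=False)
        with pytest.raises(ValueError, match="bad"):
            read_stack(tmp_path / "mix.csv")

    def test_missing_file_names_the_tag(self, tmp_path):
        pd.DataFrame([
            {"tag": "ghost", "phase_path": "nope.tif", "fluor_path": "nope.tif"},
            {"tag": "ghost2", "phase_path": "nope.tif", "fluor_path": "nope.tif"},
        ]).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(FileNotFoundError, match="ghost"):
            read_stack(tmp_path / "m.csv")


class TestApplyTranslation:
    def test_zero_shift_is_identity(self, texture):
        for interp in ("nearest", "bicubic"):
            out = apply_translation(texture, Translation(0, 0), interp)
            np.testing.assert_allclose(out, texture)

    def test_integer_shift_relocates_columns_exactly(self, texture):
        out = apply_translation(texture, Translation(3, 0), "nearest")
        np.testing.assert_array_equal(out[:, 3:], texture[:, :-3])
        assert np.all(out[:, :3] == 0)
        out_b = apply_translation(texture, Translation(3, 0), "bicubic")
        np.testing.assert_allclose(out_b[:, 3:], texture[:, :-3])

    def test_half_pixel_shift_of_ramp_matches_closed_form(self):
        ramp = np.tile(np.arange(30.0), (8, 1))
        out = apply_translation(ramp, Translation(0.5, 0.0), "bicubic")
        # a linear ramp is reproduced exactly by the cubic kernel (interior
        # only: edge replication bends the ramp within 2 px of the border)
        np.testing.assert_allclose(out[:, 3:-2], ramp[:, 3:-2] - 0.5, atol=1e-12)

    @pytest.mark.parametrize("dx,dy", [(0.3, 0.0), (-1.7, 2.25), (0.5, -0.5), (2.0, 1.3)])
    def test_matches_direct_convolution_oracle(self, dx, dy):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(12, 14))
        out = apply_translation(img, Translation(dx, dy), "bicubic")
        oracle = _keys_oracle(img, dx, dy)
        h, w = img.shape
        ys = slice(int(np.ceil(dy)) + 2, h + int(np.floor(dy)) - 2)
        xs = slice(int(np.ceil(dx)) + 2, w + int(np.floor(dx)) - 2)
        np.testing.assert_allclose(out[ys, xs], oracle[ys, xs], atol=1e-12)

    def test_forward_backward_roundtrip_on_interior(self, texture):
        t = Translation(4, -2)
        back = apply_translation(apply_translation(texture, t, "nearest"), -t, "nearest")
        np.testing.assert_allclose(back[10:-10, 10:-10], texture[10:-10, 10:-10], atol=1e-6)
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(texture, 3.0)  # band-limit: cubic roundtrip
        t = Translation(1.3, -0.7)              # error scales with curvature
        back = apply_translation(apply_translation(smooth, t), -t)
        rel = np.abs(back[10:-10, 10:-10] - smooth[10:-10, 10:-10]) / np.ptp(smooth)
        assert rel.max() <= 1e-3

    def test_output_always_finite(self, texture):
        for t in (Translation(0.123, -7.8), Translation(500, 500), Translation(-0.5, 0.5)):
            assert np.isfinite(apply_translation(texture, t)).all()


class TestComposites:
    def test_identical_channels_give_grey_composite(self, texture):
        comp = rgb_composite([texture, texture, texture])
        assert comp.shape == texture.shape + (3,)
        np.testing.assert_allclose(comp[..., 0], comp[..., 1])
        np.testing.assert_allclose(comp[..., 1], comp[..., 2])

    def test_constant_channels_give_constant_composite(self):
        const = np.full((5, 5), 7.0)
        comp = rgb_composite([const, const, const])
        assert np.all(comp == 0)

    def test_shifted_channel_creates_fringes(self, texture):
        shifted = apply_translation(texture, Translation(5, 0), "nearest")
        comp = rgb_composite([shifted, texture, texture])
        fringe = np.abs(comp[..., 0] - comp[..., 1])
        assert fringe.max() > 0.1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rgb_composite([np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 4))])


class TestRmsChannelDifference:
    def test_identical_channels_zero(self, texture):
        assert rms_channel_difference(texture, texture, texture) == 0.0

    def test_constant_offset_closed_form(self):
        b = np.arange(16.0).reshape(4, 4)
        c = 5.0
        # r=g=b+c: squared diffs per pixel are 0, c^2, c^2 -> RMS = c*sqrt(2/3)
        assert rms_channel_difference(b + c, b + c, b) == pytest.approx(c * np.sqrt(2 / 3))

    def test_2x2_toy_value_hand_computed(self):
        r = np.array([[1.0, 2.0], [3.0, 4.0]])
        g = np.array([[0.0, 2.0], [1.0, 4.0]])
        b = np.array([[1.0, 1.0], [3.0, 0.0]])
        # sum of squared pair differences = 5 + 22 + 17 = 44 over 3*4 pixel-pairs
        assert rms_channel_difference(r, g, b) == pytest.approx(np.sqrt(44 / 12))

    def test_invariant_under_channel_permutation(self):
        rng = np.random.default_rng(2)
        r, g, b = rng.normal(size=(3, 6, 6))
        ref = rms_channel_difference(r, g, b)
        assert rms_channel_difference(g, b, r) == pytest.approx(ref)
        assert rms_channel_difference(b, r, g) == pytest.approx(ref)

    def test_zero_iff_identical(self):
        rng = np.random.default_rng(3)
        r = rng.normal(size=(5, 5))
        assert rms_channel_difference(r, r, r + 1e-6) > 0


class TestMosaicExtent:
    def test_all_zero_translations(self):
        box = mosaic_extent((20, 30), [Translation(0, 0)] * 3)
        assert (box.x0, box.y0, box.width, box.height) == (0, 0, 30, 20)

    def test_single_positive_shift_widens_frame(self):
        box = mosaic_extent((20, 30), [Translation(0, 0), Translation(10, 0)])
        assert (box.width, box.height) == (40, 20)

    def test_matches_rasterised_union_oracle(self):
        rng = np.random.default_rng(4)
        h, w = 15, 11
        for _ in range(25):
            ts = [Translation(0, 0)] + [
                Translation(int(d[0]), int(d[1]))
                for d in rng.integers(-12, 13, size=(4, 2))]
            box = mosaic_extent((h, w), ts)
            x0 = min(t.dx for t in ts)
            y0 = min(t.dy for t in ts)
            canvas = np.zeros((60, 60), dtype=bool)
            for t in ts:
                canvas[int(t.dy - y0):int(t.dy - y0) + h,
                       int(t.dx - x0):int(t.dx - x0) + w] = True
            ys, xs = np.nonzero(canvas)
            assert box.width == xs.max() + 1 and box.height == ys.max() + 1
            assert box.x0 == x0 and box.y0 == y0
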