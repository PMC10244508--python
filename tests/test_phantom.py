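"""Phantom generator, augmentation, split and persistence contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acpseg import (PhantomSpec, generate_phantom, generate_dataset, augment,
                    split_dataset, write_dataset, read_dataset)
from acpseg.phantom import _tumor_mask


def clean_spec(**kw):
    """Noiseless, textureless spec: image should equal the mask exactly."""
    base = dict(noise_sigma=0.0, bias_field_amplitude=0.0,
                background_mean=0.0, background_amplitude=0.0,
                tumor_intensity=1.0)
    base.update(kw)
    return PhantomSpec(**base)


def test_noiseless_image_equals_mask():
    img, msk = generate_phantom(clean_spec(seed=3))
    assert np.array_equal(img.pixels, msk.labels.astype(float))


def test_mask_matches_brute_force_ellipse_rasterization():
    """Exhaustive per-pixel ellipse + stalk predicate reproduces the mask."""
    spec = PhantomSpec(height=48, width=48, tumor_center=(0.5, 0.4),
                       tumor_axes=(10.0, 6.0), tumor_angle=0.7,
                       canal_protrusion=True, canal_length=5.0, canal_width=3.0)
    mask = _tumor_mask(spec)
    cy, cx = spec.tumor_center[0] * 47, spec.tumor_center[1] * 47
    ca, sa = np.cos(spec.tumor_angle), np.sin(spec.tumor_angle)
    a, b = spec.tumor_axes
    ref = np.zeros((48, 48), dtype=np.uint8)
    for y in range(48):
        for x in range(48):
            u = (x - cx) * ca + (y - cy) * sa
            v = -(x - cx) * sa + (y - cy) * ca
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            stalk = 0 <= u <= a + spec.canal_length and abs(v) <= spec.canal_width / 2
            ref[y, x] = inside or stalk
    assert np.array_equal(mask, ref)


def test_ellipse_pixel_count_without_protrusion():
    spec = PhantomSpec(height=64, width=64, tumor_axes=(10.0, 6.0),
                       tumor_angle=0.0, canal_protrusion=False)
    mask = _tumor_mask(spec)
    cy, cx = 0.5 * 63, 0.3 * 63
    yy, xx = np.mgrid[0:64, 0:64]
    ref = ((xx - cx) / 10.0) ** 2 + ((yy - cy) / 6.0) ** 2 <= 1.0
    assert mask.sum() == ref.sum()


def test_generation_is_deterministic_in_seed():
    a1, m1 = generate_phantom(PhantomSpec(seed=7))
    a2, m2 = generate_phantom(PhantomSpec(seed=7))
    b, _ = generate_phantom(PhantomSpec(seed=8))
    assert np.array_equal(a1.pixels, a2.pixels)
    assert np.array_equal(m1.labels, m2.labels)
    assert not np.array_equal(a1.pixels, b.pixels)


def test_out_of_frame_tumor_rejected():
    with pytest.raises(ValueError, match="does not fit"):
        generate_phantom(PhantomSpec(tumor_center=(0.5, 0.05)))
    with pytest.raises(ValueError, match="16x16"):
        PhantomSpec(height=8).validate()


def test_intensities_clipped_to_unit_interval():
    img, _ = generate_phantom(PhantomSpec(noise_sigma=0.5, seed=1))
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0


def test_flip_is_involution_and_preserves_foreground():
    img, msk = generate_phantom(PhantomSpec(seed=2))
    for op in ("hflip", "vflip"):
        i1, m1 = augment(img, msk, [op])
        assert m1.labels.sum() == msk.labels.sum()
        i2, m2 = augment(i1, m1, [op])
        assert np.array_equal(i2.pixels, img.pixels)
        assert np.array_equal(m2.labels, msk.labels)


def test_inversion_flips_intensities_only():
    img, msk = generate_phantom(PhantomSpec(seed=2))
    img.pixels[:] = 0.3
    inv_img, inv_msk = augment(img, msk, ["invert"])
    assert np.allclose(inv_img.pixels, 0.7)
    assert np.array_equal(inv_msk.labels, msk.labels)


def test_unknown_augmentation_op_lists_supported():
    img, msk = generate_phantom(PhantomSpec(seed=2))
    with pytest.raises(ValueError, match="hflip"):
        augment(img, msk, ["rotate90"])


def test_split_300_items_8_1_1_gives_240_30_30():
    s = split_dataset(300, (8, 1, 1), seed=0)
    assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (240, 30, 30)


def test_split_10_items_gives_8_1_1():
    s = split_dataset(10, (8, 1, 1), seed=1)
    assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (8, 1, 1)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(n=st.integers(10, 500), seed=st.integers(0, 2 ** 16))
def test_split_is_a_partition(n, seed):
    s = split_dataset(n, (8, 1, 1), seed=seed)
    all_ids = set(s.train_ids) | set(s.val_ids) | set(s.test_ids)
    assert len(all_ids) == n
    assert len(s.train_ids) + len(s.val_ids) + len(s.test_ids) == n


def test_split_rejects_empty_subsets_and_bad_ratios():
    with pytest.raises(ValueError):
        split_dataset(2, (8, 1, 1))
    with pytest.raises(ValueError, match="positive"):
        split_dataset(100, (8, 0, 1))


def test_view_tags_round_robin():
    pairs = generate_dataset(6, size=64, seed=0)
    assert [p[1].view_tag for p in pairs] == ["cor", "sag", "tra"] * 2


def test_nifti_round_trip_is_bit_identical(tmp_path):
    pairs = generate_dataset(4, size=64, seed=5)
    write_dataset(pairs, tmp_path, fmt="nifti")
    back, _ = read_dataset(tmp_path)
    for (_, img, msk), (_, bimg, bmsk) in zip(pairs, back):
        assert np.array_equal(img.pixels, bimg.pixels)
        assert np.array_equal(msk.labels, bmsk.labels)
        assert img.spacing == bimg.spacing


def test_png_round_trip_masks_exact_images_quantized(tmp_path):
    pairs = generate_dataset(3, size=64, seed=6)
    write_dataset(pairs, tmp_path, fmt="png")
    back, _ = read_dataset(tmp_path)
    for (_, img, msk), (_, bimg, bmsk) in zip(pairs, back):
        assert np.array_equal(msk.labels, bmsk.labels)
        q = np.round(np.clip(img.pixels, 0, 1) * 255) / 255.0
        assert np.allclose(bimg.pixels, q)


def test_orphan_mask_file_reported_by_name(tmp_path):
    pairs = generate_dataset(3, size=64, seed=7)
    write_dataset(pairs, tmp_path, fmt="png")
    (tmp_path / "images" / "0001.png").unlink()
    with pytest.raises(ValueError, match="0001"):
        read_dataset(tmp_path)
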