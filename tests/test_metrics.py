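"""Dice and HD95 against brute-force oracles, plus report aggregation."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from acpseg import dice, hd95, evaluate, MaskSlice
from acpseg.metrics import boundary_points

rng = np.random.default_rng(33)


def blob_mask(size, n_blobs, rg):
    """Random union of filled ellipses — realistic connected masks."""
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.zeros((size, size), dtype=bool)
    for _ in range(n_blobs):
        cy, cx = rg.uniform(5, size - 5, 2)
        a, b = rg.uniform(2, size / 4, 2)
        m |= ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return m.astype(np.uint8)


def brute_boundary(m):
    pts = []
    H, W = m.shape
    for y in range(H):
        for x in range(W):
            if not m[y, x]:
                continue
            nbrs = [m[y - 1, x] if y > 0 else 0, m[y + 1, x] if y < H - 1 else 0,
                    m[y, x - 1] if x > 0 else 0, m[y, x + 1] if x < W - 1 else 0]
            if not all(nbrs):
                pts.append((y, x))
    return np.array(pts)


def brute_hd95(a, b, spacing=(1.0, 1.0)):
    pa = brute_boundary(a) * np.asarray(spacing)
    pb = brute_boundary(b) * np.asarray(spacing)
    d = cdist(pa, pb)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def test_dice_worked_cases():
    a = np.zeros((8, 8), dtype=np.uint8)
    b = np.zeros((8, 8), dtype=np.uint8)
    a[0, :4] = 1          # |A| = 4
    b[0, 1:4] = 1         # overlap 3
    b[1, :3] = 1          # |B| = 6
    assert dice(a, b) == pytest.approx(2 * 3 / (4 + 6))  # 0.6
    assert dice(a, a) == 1.0
    disjoint = np.zeros_like(a)
    disjoint[7, :] = 1
    assert dice(a, disjoint) == 0.0
    assert dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0


def test_dice_shape_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        dice(np.zeros((4, 4)), np.zeros((5, 4)))


def test_hd95_identical_masks_zero():
    m = blob_mask(32, 2, np.random.default_rng(1))
    assert hd95(m, m) == 0.0


def test_hd95_single_pixels_five_apart():
    a = np.zeros((16, 16), dtype=np.uint8)
    b = np.zeros((16, 16), dtype=np.uint8)
    a[4, 3] = 1
    b[4, 8] = 1
    assert hd95(a, b, spacing=(1.0, 1.0)) == pytest.approx(5.0)


def test_hd95_shifted_square_matches_brute_force():
    a = np.zeros((32, 32), dtype=np.uint8)
    a[10:18, 10:18] = 1
    b = np.roll(a, 3, axis=1)
    got = hd95(a, b, spacing=(0.5, 0.5))
    assert got == pytest.approx(brute_hd95(a, b, (0.5, 0.5)))


@pytest.mark.parametrize("seed", range(12))
def test_hd95_matches_all_pairs_oracle_on_random_blobs(seed):
    rg = np.random.default_rng(seed)
    size = int(rg.integers(16, 64))
    a = blob_mask(size, int(rg.integers(1, 3)), rg)
    b = blob_mask(size, int(rg.integers(1, 3)), rg)
    if not (a.any() and b.any()):
        return
    sp = (float(rg.uniform(0.3, 2.0)),) * 2
    assert hd95(a, b, sp) == pytest.approx(brute_hd95(a, b, sp))


def test_metrics_symmetry_translation_and_spacing_scale():
    rg = np.random.default_rng(5)
    a = blob_mask(48, 2, rg)
    b = blob_mask(48, 2, rg)
    assert dice(a, b) == dice(b, a)
    assert hd95(a, b) == pytest.approx(hd95(b, a))
    # translation away from borders
    at, bt = np.roll(a, 2, axis=0), np.roll(b, 2, axis=0)
    if not (a[-2:].any() or b[-2:].any()):
        assert dice(at, bt) == pytest.approx(dice(a, b))
        assert hd95(at, bt) == pytest.approx(hd95(a, b))
    # doubling spacing doubles hd95, dice unchanged
    assert hd95(a, b, (2.0, 2.0)) == pytest.approx(2 * hd95(a, b, (1.0, 1.0)))


def test_hd95_empty_mask_policies():
    e = np.zeros((8, 8), dtype=np.uint8)
    m = e.copy()
    m[4, 4] = 1
    assert hd95(e, e) == 0.0
    assert math.isnan(hd95(m, e))
    assert math.isnan(hd95(e, m))


def test_boundary_excludes_interior():
    m = np.zeros((10, 10), dtype=np.uint8)
    m[2:8, 2:8] = 1
    pts = {tuple(p) for p in boundary_points(m)}
    assert (2, 2) in pts and (7, 7) in pts and (4, 4) not in pts
    assert pts == {tuple(p) for p in brute_boundary(m)}


def test_max_directed_variant_at_least_pooled_on_example():
    rg = np.random.default_rng(9)
    a, b = blob_mask(32, 2, rg), blob_mask(32, 2, rg)
    assert hd95(a, b, method="max_directed") >= 0.0
    with pytest.raises(ValueError, match="method"):
        hd95(a, b, method="hausdorff")


def test_evaluate_aggregates_and_views():
    refs, preds = {}, {}
    vals = {}
    for i, view in enumerate(["cor", "sag", "tra"]):
        rg = np.random.default_rng(100 + i)
        ref = blob_mask(32, 2, rg)
        pred = blob_mask(32, 2, rg)
        id_ = f"{i:04d}"
        refs[id_] = MaskSlice(ref, (1.0, 1.0), view)
        preds[id_] = pred
        vals[id_] = (dice(pred, ref), hd95(pred, ref))
    rep = evaluate(preds, refs)
    # single item per view: per-view rows equal the item values
    for id_, view in zip(sorted(vals), ["cor", "sag", "tra"]):
        assert rep.per_view[view]["dice_pct"] == pytest.approx(100 * vals[id_][0])
        assert rep.per_view[view]["hd95_mm"] == pytest.approx(vals[id_][1])
    assert rep.overall["dice_pct"] == pytest.approx(
        100 * np.mean([v[0] for v in vals.values()]))
    assert rep.overall["hd95_mm"] == pytest.approx(
        np.mean([v[1] for v in vals.values()]))


def test_evaluate_perfect_predictions():
    rg = np.random.default_rng(3)
    refs = {f"{i}": MaskSlice(blob_mask(24, 1, rg), (1.0, 1.0), "cor")
            for i in range(3)}
    preds = {k: v.labels for k, v in refs.items()}
    rep = evaluate(preds, refs)
    assert rep.overall["dice_pct"] == 100.0
    assert rep.overall["hd95_mm"] == 0.0
    assert rep.n_hd95_undefined == 0


def test_evaluate_id_mismatch_lists_missing():
    refs = {"a": MaskSlice(np.ones((4, 4), dtype=np.uint8))}
    with pytest.raises(ValueError, match="'a'"):
        evaluate({}, refs)


def test_report_csv_row_shape(tmp_path):
    rg = np.random.default_rng(8)
    refs, preds = {}, {}
    for i, view in enumerate(["cor", "sag", "tra"]):
        m = blob_mask(24, 1, rg)
        refs[str(i)] = MaskSlice(m, (1.0, 1.0), view)
        preds[str(i)] = m
    rep = evaluate(preds, refs)
    path = tmp_path / "table.csv"
    rep.write_csv(path, model_name="acp")
    lines = path.read_text().strip().split("\n")
    assert lines[0].split(",")[:3] == ["model", "dice_pct", "hd95_mm"]
    cells = lines[1].split(",")
    assert cells[0] == "acp"
    assert cells[1] == "100.00" and cells[2] == "0.0000"
    assert len(cells) == 9  # overall + three views x two metrics
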