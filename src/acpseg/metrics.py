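"""Segmentation metrics: Dice similarity and the 95th-percentile Hausdorff
distance (HD95, in mm), plus overall and per-view report aggregation.

Dice is the usual overlap ratio 2|A n B| / (|A| + |B|); two empty masks
score 1.0 by convention. HD95 extracts boundary pixels (foreground pixels
with a 4-neighbour background), collects nearest-neighbour boundary
distances in both directions, scaled to millimetres by the pixel spacing,
and takes the 95th percentile of the pooled distance multiset (linear
interpolation). Pooling both directions makes the metric symmetric by
construction; the alternative "max of the two directed 95th percentiles"
is available via ``method="max_directed"``.

If both masks are empty HD95 is 0; if exactly one is empty the surface
distance is undefined and the item is excluded from HD95 aggregates (with
a recorded count) rather than assigned an arbitrary penalty.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .phantom import MaskSlice, VIEW_TAGS

__all__ = ["dice", "hd95", "boundary_points", "evaluate", "MetricsReport"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _as_binary(m) -> np.ndarray:
    a = m.labels if isinstance(m, MaskSlice) else np.asarray(m)
    if a.ndim != 2:
        raise ValueError("masks must be 2-D")
    return a.astype(bool)


def dice(pred, ref) -> float:
    """Dice Similarity Coefficient in [0, 1]; both-empty convention: 1.0."""
    a, b = _as_binary(pred), _as_binary(ref)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of foreground pixels with a 4-neighbour
    background (image border counts as background)."""
    m = _as_binary(mask)
    interior = binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(m & ~interior)


def hd95(pred, ref, spacing: tuple[float, float] = (1.0, 1.0),
         method: str = "pooled") -> float:
    """95th-percentile symmetric boundary distance in mm.

    Returns ``nan`` when exactly one mask is empty (undefined), 0.0 when
    both are.
    """
    a, b = _as_binary(pred), _as_binary(ref)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if method not in ("pooled", "max_directed"):
        raise ValueError(f"unknown method {method!r}")
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        return math.nan
    pa = boundary_points(a) * np.asarray(spacing)
    pb = boundary_points(b) * np.asarray(spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    if method == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


@dataclasses.dataclass
class MetricsReport:
    """Per-item metrics and their overall / per-view aggregates.

    ``dice`` aggregates are in percent; ``hd95`` in mm. Items with
    undefined HD95 are excluded from HD95 means and counted in
    ``n_hd95_undefined``.
    """

    per_item: dict[str, dict]
    overall: dict[str, float]
    per_view: dict[str, dict[str, float]]
    n_hd95_undefined: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, allow_nan=True)

    def write_csv(self, path, model_name: str = "model") -> None:
        """One summary row shaped like the paper-style comparison tables:
        overall Dice%/HD95 plus cor/sag/tra columns."""
        path = Path(path)
        header = ["model", "dice_pct", "hd95_mm",
                  "dice_pct_cor", "dice_pct_sag", "dice_pct_tra",
                  "hd95_mm_cor", "hd95_mm_sag", "hd95_mm_tra"]
        row = self.summary_row(model_name)
        write_header = not path.exists()
        with open(path, "a", newline="") as fh:
            w = csv.writer(fh)
            if write_header:
                w.writerow(header)
            w.writerow(row)

    def summary_row(self, model_name: str = "model") -> list:
        def fmt_d(v):
            return f"{v:.2f}" if v == v else ""

        def fmt_h(v):
            return f"{v:.4f}" if v == v else ""

        row = [model_name, fmt_d(self.overall["dice_pct"]),
               fmt_h(self.overall["hd95_mm"])]
        row += [fmt_d(self.per_view.get(v, {}).get("dice_pct", math.nan))
                for v in VIEW_TAGS]
        row += [fmt_h(self.per_view.get(v, {}).get("hd95_mm", math.nan))
                for v in VIEW_TAGS]
        return row


def _aggregate(items: list[dict]) -> dict[str, float]:
    d = [it["dice"] for it in items]
    h = [it["hd95"] for it in items if it["hd95"] == it["hd95"]]
    return {"dice_pct": 100.0 * float(np.mean(d)) if d else math.nan,
            "hd95_mm": float(np.mean(h)) if h else math.nan,
            "n": len(items)}


def evaluate(preds: dict[str, np.ndarray], refs: dict[str, MaskSlice],
             hd95_method: str = "pooled") -> MetricsReport:
    """Score a set of predictions against references with matching ids.

    `refs` carry the spacing and view tag; `preds` are binary arrays.
    """
    missing = sorted(set(refs) - set(preds))
    extra = sorted(set(preds) - set(refs))
    if missing or extra:
        raise ValueError(f"id mismatch: missing predictions {missing}, "
                         f"unmatched predictions {extra}")
    per_item: dict[str, dict] = {}
    for id_ in sorted(refs):
        ref = refs[id_]
        d = dice(preds[id_], ref)
        h = hd95(preds[id_], ref, spacing=ref.spacing, method=hd95_method)
        per_item[id_] = {"dice": d, "hd95": h, "view": ref.view_tag}
    items = list(per_item.values())
    overall = _aggregate(items)
    per_view = {v: _aggregate([it for it in items if it["view"] == v])
                for v in VIEW_TAGS
                if any(it["view"] == v for it in items)}
    n_undef = sum(1 for it in items if it["hd95"] != it["hd95"])
    return MetricsReport(per_item=per_item, overall=overall,
                         per_view=per_view, n_hd95_undefined=n_undef)
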