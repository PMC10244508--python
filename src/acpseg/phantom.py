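"""Synthetic cerebellopontine-angle (CPA) phantom slices.

The clinical material this package targets — contrast-enhanced T1 MRI
slices of acoustic neuromas (vestibular schwannomas) — is private, so the
test bench runs on phantoms that reproduce the geometry the model cares
about: a bright, roughly elliptical tumor sitting near one lateral edge of
the slice (the CPA), optionally extended by a thin protrusion emulating
growth into the internal auditory canal, on top of smooth brain-like
background texture, a low-order intensity bias field and additive Gaussian
noise.

Every generated pair is a pure function of its :class:`PhantomSpec`
(including the seed), which is what makes the downstream training and
evaluation pipeline exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec", "ImageSlice", "MaskSlice", "DatasetSplit",
    "generate_phantom", "generate_dataset", "augment", "split_dataset",
    "write_dataset", "read_dataset", "VIEW_TAGS", "AUGMENT_OPS",
]

VIEW_TAGS = ("cor", "sag", "tra")
AUGMENT_OPS = ("hflip", "vflip", "invert")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic CPA slice.

    Intensities live in [0, 1]; geometry in pixels; spacing in mm/pixel.
    ``tumor_center`` is fractional (row, col) in [0, 1]^2 — the default puts
    the lesion near the left lateral edge, the typical CPA position.
    """

    height: int = 64
    width: int = 64
    spacing: tuple[float, float] = (1.0, 1.0)
    tumor_center: tuple[float, float] = (0.5, 0.3)
    tumor_axes: tuple[float, float] = (9.0, 6.0)
    tumor_angle: float = 0.35
    canal_protrusion: bool = True
    canal_length: float = 6.0
    canal_width: float = 3.0
    tumor_intensity: float = 0.85
    background_mean: float = 0.3
    background_amplitude: float = 0.12
    background_texture_scale: float = 6.0
    noise_sigma: float = 0.03
    bias_field_amplitude: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("frame must be at least 16x16 pixels")
        a, b = self.tumor_axes
        if a < 1 or b < 1:
            raise ValueError("tumor semi-axes must be >= 1 px")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("pixel spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.tumor_intensity <= 1.0):
            raise ValueError("tumor_intensity must lie in [0, 1]")
        cy = self.tumor_center[0] * (self.height - 1)
        cx = self.tumor_center[1] * (self.width - 1)
        r = max(a, b) + (self.canal_length if self.canal_protrusion else 0.0)
        if cy - r < 0 or cy + r > self.height - 1 or cx - r < 0 or cx + r > self.width - 1:
            raise ValueError(
                f"tumor (center ({cy:.1f},{cx:.1f}) px, reach {r:.1f} px) "
                f"does not fit inside the {self.height}x{self.width} frame")


@dataclasses.dataclass
class ImageSlice:
    """2-D grayscale slice with physical pixel spacing (mm/px)."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    view_tag: str = "tra"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.view_tag not in VIEW_TAGS:
            raise ValueError(f"view_tag must be one of {VIEW_TAGS}")


@dataclasses.dataclass
class MaskSlice:
    """Binary label grid aligned to an :class:`ImageSlice`."""

    labels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    view_tag: str = "tra"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.labels = self.labels.astype(np.uint8)


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split subsets must be pairwise disjoint")


def _tumor_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    cy = spec.tumor_center[0] * (h - 1)
    cx = spec.tumor_center[1] * (w - 1)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # rotate into the tumor frame
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(spec.tumor_angle), np.sin(spec.tumor_angle)
    u = dx * ca + dy * sa        # along the major axis
    v = -dx * sa + dy * ca
    a, b = spec.tumor_axes
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.canal_protrusion:
        # thin rectangular stalk extending beyond the ellipse tip along +u
        stalk = ((u >= 0) & (u <= a + spec.canal_length)
                 & (np.abs(v) <= spec.canal_width / 2.0))
        mask |= stalk
    return mask.astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageSlice, MaskSlice]:
    """Render one phantom slice and its ground-truth mask.

    The image is background texture outside the tumor, ``tumor_intensity``
    inside, plus a polynomial bias field and white Gaussian noise, clipped
    to [0, 1]. Identical specs (same seed) give bit-identical arrays.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = _tumor_mask(spec)

    # correlated background texture (smoothed white noise, renormalised)
    bg = np.full((h, w), spec.background_mean)
    if spec.background_amplitude > 0:
        tex = rng.standard_normal((h, w))
        tex = gaussian_filter(tex, spec.background_texture_scale, mode="reflect")
        std = tex.std()
        if std > 0:
            tex /= std
        bg = bg + spec.background_amplitude * tex
    else:
        rng.standard_normal((h, w))  # keep the stream position stable

    img = np.where(mask.astype(bool), spec.tumor_intensity, bg)

    if spec.bias_field_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        y = yy / max(h - 1, 1) - 0.5
        x = xx / max(w - 1, 1) - 0.5
        c = rng.uniform(-1, 1, size=5)
        field = c[0] * x + c[1] * y + c[2] * x * y + c[3] * x * x + c[4] * y * y
        img = img + spec.bias_field_amplitude * field
    else:
        rng.uniform(-1, 1, size=5)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))

    img = np.clip(img, 0.0, 1.0)
    view = "tra"
    return (ImageSlice(img, spec.spacing, view), MaskSlice(mask, spec.spacing, view))


def generate_dataset(n: int, size: int = 64, seed: int = 0,
                     spacing: tuple[float, float] = (1.0, 1.0),
                     **overrides) -> list[tuple[str, ImageSlice, MaskSlice]]:
    """Generate `n` varied phantoms with round-robin cor/sag/tra view tags.

    Tumor position, size, orientation and canal growth are jittered per
    slice from a master seed, emulating inter-patient variability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        side = master.choice([0, 1])  # left or right CPA
        a = master.uniform(0.10, 0.18) * size
        b = a * master.uniform(0.5, 0.85)
        reach = a + 0.14 * size  # leave room for the canal stalk
        margin = (reach + 1.5) / (size - 1)
        cx = margin + master.uniform(0.0, 0.08)
        if side:
            cx = 1.0 - cx
        angle = master.uniform(-0.5, 0.5) + (np.pi if side else 0.0)
        spec = PhantomSpec(
            height=size, width=size, spacing=spacing,
            tumor_center=(float(master.uniform(0.35, 0.65)), float(cx)),
            tumor_axes=(float(a), float(b)),
            tumor_angle=float(angle),
            canal_protrusion=bool(master.random() < 0.7),
            canal_length=float(master.uniform(0.06, 0.12) * size),
            canal_width=float(master.uniform(0.03, 0.06) * size),
            tumor_intensity=float(master.uniform(0.75, 0.95)),
            seed=int(master.integers(0, 2 ** 31 - 1)),
            **overrides,
        )
        img, msk = generate_phantom(spec)
        tag = VIEW_TAGS[i % 3]
        img.view_tag = tag
        msk.view_tag = tag
        out.append((f"{i:04d}", img, msk))
    return out


def augment(image: ImageSlice, mask: MaskSlice, ops: list[str],
            p: float = 1.0, seed: int | None = None
            ) -> tuple[ImageSlice, MaskSlice]:
    """Apply augmentation ops in order: flips (image+mask) and inversion.

    ``hflip``/``vflip`` mirror image and mask identically; ``invert`` maps
    pixel intensities to 1-x and leaves the mask untouched. With ``p < 1``
    each listed op fires independently with probability p (seeded).
    """
    unknown = [o for o in ops if o not in AUGMENT_OPS]
    if unknown:
        raise ValueError(f"unknown augmentation op(s) {unknown}; "
                         f"supported: {list(AUGMENT_OPS)}")
    rng = np.random.default_rng(seed)
    img = image.pixels.copy()
    lab = mask.labels.copy()
    for op in ops:
        if p < 1.0 and rng.random() >= p:
            continue
        if op == "hflip":
            img = img[:, ::-1]
            lab = lab[:, ::-1]
        elif op == "vflip":
            img = img[::-1, :]
            lab = lab[::-1, :]
        elif op == "invert":
            img = 1.0 - img
    return (ImageSlice(np.ascontiguousarray(img), image.spacing, image.view_tag),
            MaskSlice(np.ascontiguousarray(lab), mask.spacing, mask.view_tag))


def split_dataset(n_items: int, ratios: tuple[float, float, float] = (8, 1, 1),
                  seed: int = 0) -> DatasetSplit:
    """Shuffled disjoint train/val/test assignment of ids "0000".."nnnn".

    Rounding rule: val and test sizes are floored, the remainder goes to
    train — so 300 items at 8:1:1 split 240/30/30.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to populate three subsets")
    if any(r <= 0 for r in ratios):
        raise ValueError("all ratios must be positive")
    total = float(sum(ratios))
    n_val = int(n_items * ratios[1] / total)
    n_test = int(n_items * ratios[2] / total)
    n_train = n_items - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split {n_train}/{n_val}/{n_test} leaves an empty subset; "
            f"increase n_items or rebalance ratios")
    ids = [f"{i:04d}" for i in range(n_items)]
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    return DatasetSplit(tuple(ids[:n_train]),
                        tuple(ids[n_train:n_train + n_val]),
                        tuple(ids[n_train + n_val:]))


# ---------------------------------------------------------------------------
# persistence


def write_dataset(pairs: list[tuple[str, ImageSlice, MaskSlice]], dirpath,
                  fmt: str = "png", split: DatasetSplit | None = None) -> None:
    """Persist pairs as images/{id} + masks/{id} + meta.json.

    PNG stores images as 8-bit grayscale (documented quantisation: round to
    255 levels) and masks as {0, 255}; NIfTI stores float32 images losslessly
    with spacing in the header. meta.json records spacing, view tags and the
    optional split.
    """
    if fmt not in ("png", "nifti"):
        raise ValueError(f"format must be 'png' or 'nifti', got {fmt!r}")
    dirpath = Path(dirpath)
    (dirpath / "images").mkdir(parents=True, exist_ok=True)
    (dirpath / "masks").mkdir(parents=True, exist_ok=True)
    meta: dict = {"format": fmt, "items": {}}
    for id_, img, msk in pairs:
        if img.pixels.shape != msk.labels.shape:
            raise ValueError(f"item {id_}: image/mask shape mismatch")
        if fmt == "png":
            from PIL import Image
            arr = np.round(np.clip(img.pixels, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(dirpath / "images" / f"{id_}.png")
            Image.fromarray((msk.labels * 255).astype(np.uint8), mode="L").save(
                dirpath / "masks" / f"{id_}.png")
        else:
            import nibabel as nib
            for sub, arr in (("images", img.pixels.astype(np.float64)),
                             ("masks", msk.labels.astype(np.uint8))):
                ni = nib.Nifti1Image(arr, affine=np.diag(
                    [img.spacing[0], img.spacing[1], 1.0, 1.0]))
                ni.header.set_zooms((img.spacing[0], img.spacing[1]))
                nib.save(ni, dirpath / sub / f"{id_}.nii")
        meta["items"][id_] = {"spacing": list(img.spacing), "view_tag": img.view_tag}
    if split is not None:
        meta["split"] = {"train": list(split.train_ids),
                         "val": list(split.val_ids),
                         "test": list(split.test_ids)}
    (dirpath / "meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(dirpath) -> tuple[list[tuple[str, ImageSlice, MaskSlice]],
                                   DatasetSplit | None]:
    """Load a dataset directory written by :func:`write_dataset`."""
    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "meta.json").read_text())
    fmt = meta["format"]
    ext = "png" if fmt == "png" else "nii"
    img_files = {p.stem: p for p in (dirpath / "images").glob(f"*.{ext}")}
    msk_files = {p.stem: p for p in (dirpath / "masks").glob(f"*.{ext}")}
    orphans = sorted(set(img_files) ^ set(msk_files))
    if orphans:
        which = [str((msk_files | img_files)[o]) for o in orphans]
        raise ValueError(f"unpaired image/mask file(s): {which}")
    pairs = []
    for id_ in sorted(img_files):
        info = meta["items"][id_]
        spacing = tuple(info["spacing"])
        view = info["view_tag"]
        if fmt == "png":
            from PIL import Image
            px = np.asarray(Image.open(img_files[id_]), dtype=np.float64) / 255.0
            lb = (np.asarray(Image.open(msk_files[id_])) > 127).astype(np.uint8)
        else:
            import nibabel as nib
            px = np.asarray(nib.load(img_files[id_]).dataobj, dtype=np.float64)
            lb = (np.asarray(nib.load(msk_files[id_]).dataobj) > 0.5).astype(np.uint8)
        if px.shape != lb.shape:
            raise ValueError(f"shape mismatch between {img_files[id_]} "
                             f"and {msk_files[id_]}")
        pairs.append((id_, ImageSlice(px, spacing, view), MaskSlice(lb, spacing, view)))
    split = None
    if "split" in meta:
        s = meta["split"]
        split = DatasetSplit(tuple(s["train"]), tuple(s["val"]), tuple(s["test"]))
    return pairs, split
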