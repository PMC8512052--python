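"""Bladder segmentation: a minimal 2-class U-Net plus a classical fallback.

The network follows a minimal configuration: 5 successive blocks per
path, 6 channels in the first layer doubling per level (96 channels at
the bottleneck), inputs down-sampled to 528 x 352 single-channel, batch
size 4, learning rate 2e-5, converging within a 400-epoch cap. A
fan-aware augmentation expands every image 20-fold: 5 geometric variants
(original, each fan side aligned to its image border, and two
half-alignments) times 4 flip states, with masks transformed identically
so that no augmented mask leaves its variant's fan region.

Training at desk scale uses reduced rasters and a shallower
configuration; the full-size configuration is reached purely through
:class:`UNetConfig`.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import skimage.measure
import skimage.morphology
import skimage.transform
from skimage.filters import threshold_otsu

from .nn import Adam, UNet, softmax_cross_entropy
from .phantoms import FanGeometry

__all__ = [
    "UNetConfig",
    "SegModel",
    "unet_channel_plan",
    "preprocess",
    "augment",
    "train_unet",
    "segment",
    "classical_segment",
]

NATIVE_SHAPE = (720, 1056)  # (H, W) of the original rasters
MODEL_SHAPE = (352, 528)  # (H, W) after preprocessing


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    """Hyperparameters of the segmentation network."""

    depth: int = 5
    first_channels: int = 6
    growth: int = 2
    input_hw: tuple = MODEL_SHAPE
    classes: int = 2
    batch_size: int = 4
    learning_rate: float = 2e-5
    max_epochs: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.first_channels < 1:
            raise ValueError("depth and first_channels must be >= 1")
        if self.classes != 2:
            raise ValueError("the segmenter is a fixed 2-class network")
        div = 2 ** (self.depth - 1)
        h, w = self.input_hw
        if h % div or w % div:
            raise ValueError(f"input sides must be divisible by {div}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "UNetConfig":
        d = json.loads(s)
        d["input_hw"] = tuple(d["input_hw"])
        return cls(**d)


@dataclasses.dataclass
class SegModel:
    """A trained network together with its config and loss history."""

    net: UNet
    config: UNetConfig
    history: list

    def save(self, path) -> None:
        """Single-file self-describing checkpoint (npz with embedded config)."""
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(
            path,
            __config__=np.bytes_(self.config.to_json().encode()),
            __history__=np.asarray(self.history, dtype=float),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(path) as f:
            config = UNetConfig.from_json(bytes(f["__config__"]).decode())
            history = f["__history__"].tolist()
            arrays = [f[f"p{i}"] for i in range(sum(1 for k in f.files if k.startswith("p")))]
        net = _build_net(config)
        net.load_state_arrays(arrays)
        return cls(net, config, history)


def unet_channel_plan(first_channels: int, depth: int) -> list:
    """Per-level channel counts: ``first_channels * 2**k`` for each level."""
    if first_channels < 1 or depth < 1:
        raise ValueError("first_channels and depth must be >= 1")
    return [first_channels * 2**k for k in range(depth)]


def _build_net(config: UNetConfig) -> UNet:
    return UNet(
        in_channels=1,
        n_classes=config.classes,
        depth=config.depth,
        first_channels=config.first_channels,
        growth=config.growth,
        seed=config.seed,
    )


def preprocess(image: np.ndarray) -> np.ndarray:
    """Down-sample a native-resolution image to the 528 x 352 x 1 model input.

    Accepts grayscale or multi-channel rasters of at least 1056 x 720;
    colour is reduced to a single channel by averaging, the raster is
    scaled to 528 x 360 and centre-cropped by 4 rows top and bottom, and
    values end up in [0, 1]. Deterministic.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError("expected a 2-D raster or an (H, W, C) image")
    if img.shape[0] < NATIVE_SHAPE[0] or img.shape[1] < NATIVE_SHAPE[1]:
        raise ValueError(f"input must be at least {NATIVE_SHAPE[1]} x {NATIVE_SHAPE[0]}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    else:
        img = np.clip(img.astype(float), 0.0, 1.0)
    small = skimage.transform.resize(
        img, (360, 528), order=1, anti_aliasing=True, preserve_range=True
    )
    return small[4:356, :, None]


def _variant_transform(fan: FanGeometry, side: str, fraction: float, width: int) -> np.ndarray:
    """Forward affine (3x3, (x, y) homogeneous) for one fan-alignment variant."""
    phi = fan.half_angle_rad
    if side == "none":
        return np.eye(3)
    if side == "left":
        alpha = -phi * fraction
        shift = (0.0 - fan.apex_x) * fraction
    elif side == "right":
        alpha = phi * fraction
        shift = (width - 1 - fan.apex_x) * fraction
    else:
        raise ValueError(side)
    c, s = np.cos(alpha), np.sin(alpha)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    to_apex = np.array([[1, 0, -fan.apex_x], [0, 1, -fan.apex_y], [0, 0, 1.0]])
    back = np.array([[1, 0, fan.apex_x + shift], [0, 1, fan.apex_y], [0, 0, 1.0]])
    return back @ rot @ to_apex


def _warp(img: np.ndarray, matrix: np.ndarray, order: int) -> np.ndarray:
    tf = skimage.transform.AffineTransform(matrix=np.linalg.inv(matrix))
    out = skimage.transform.warp(
        img.astype(float), tf, order=order, mode="constant", cval=0.0, preserve_range=True
    )
    return out


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    fan: FanGeometry,
    include_fan: bool = False,
) -> list:
    """Fan-aware 20-fold augmentation of one (image, mask) pair.

    Five geometric variants -- the original, the left fan side aligned to
    the left image border, the right fan side to the right border, and
    the two half-alignments -- each combined with the four flip states
    (none, horizontal, vertical, both). Masks undergo exactly the same
    transform as the images (nearest-neighbour resampling), so every
    output mask stays inside its variant's fan region.

    Returns 20 ``(image, mask)`` pairs, or ``(image, mask, fan_mask)``
    triples when ``include_fan`` is set.
    """
    image = np.asarray(image)
    mask = np.asarray(mask).astype(float)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes must match")
    h, w = image.shape
    if not (0 <= fan.apex_x < w):
        raise ValueError("fan geometry inconsistent with image size")
    fan_raster = fan.raster(image.shape).astype(float)
    variants = [("none", 0.0), ("left", 1.0), ("right", 1.0), ("left", 0.5), ("right", 0.5)]
    out = []
    for side, frac in variants:
        if side == "none":
            gi, gm, gf = image.astype(float), mask, fan_raster
        else:
            m = _variant_transform(fan, side, frac, w)
            gi = _warp(image, m, order=1)
            gm = _warp(mask, m, order=0)
            gf = _warp(fan_raster, m, order=0)
        for flip in ("none", "h", "v", "hv"):
            fi, fm, ff = gi, gm, gf
            if "h" in flip:
                fi, fm, ff = fi[:, ::-1], fm[:, ::-1], ff[:, ::-1]
            if "v" in flip:
                fi, fm, ff = fi[::-1, :], fm[::-1, :], ff[::-1, :]
            pair = (fi.copy(), fm.astype(bool))
            if include_fan:
                out.append(pair + (ff.astype(bool),))
            else:
                out.append(pair)
    return out


def train_unet(dataset, config: UNetConfig) -> SegModel:
    """Train the segmentation network with pixelwise cross-entropy and Adam.

    ``dataset`` is a sequence of ``(image, mask)`` pairs of preprocessed
    rasters matching ``config.input_hw`` (image values in [0, 1], mask in
    {0, 1}). Records the mean per-epoch loss and stops early once the
    loss has plateaued (relative improvement < 1e-4 over 20 epochs).
    Seeded runs are reproducible.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    h, w = config.input_hw
    X = np.stack([np.asarray(im, dtype=np.float32).reshape(h, w) for im, _ in dataset])
    Y = np.stack([np.asarray(mk).reshape(h, w).astype(np.int64) for _, mk in dataset])
    X = X[:, None]  # (M, 1, H, W)
    net = _build_net(config)
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    m = X.shape[0]
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(m)
        total = 0.0
        for start in range(0, m, config.batch_size):
            idx = perm[start : start + config.batch_size]
            net.zero_grad()
            logits = net.forward(X[idx])
            loss, dlogits = softmax_cross_entropy(logits, Y[idx])
            net.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        history.append(total / m)
        if len(history) > 20:
            prev = history[-21]
            if prev - min(history[-20:]) < 1e-4 * abs(prev):
                break
    return SegModel(net, config, history)


def segment(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax segmentation of one preprocessed image; values in {0, 1}."""
    h, w = model.config.input_hw
    x = np.asarray(image, dtype=np.float32).reshape(1, 1, h, w)
    logits = model.net.forward(x)
    return logits.argmax(axis=1)[0].astype(np.uint8)


def classical_segment(
    image: np.ndarray,
    fan: np.ndarray,
    near_margin: float = 0.12,
    opening_radius: int = 2,
) -> np.ndarray:
    """Deterministic baseline: dark-region thresholding inside the fan.

    Otsu threshold over fan-valid intensities, morphological opening, and
    the largest dark connected component whose mean depth lies beyond a
    near-field exclusion margin (a fraction of the fan height). Returns
    an empty mask for featureless images. Output is always a subset of
    the fan.
    """
    img = np.asarray(image, dtype=float)
    fan = np.asarray(fan, dtype=bool)
    if img.shape != fan.shape:
        raise ValueError("image and fan shapes must match")
    if not fan.any():
        raise ValueError("empty fan mask")
    vals = img[fan]
    if np.ptp(vals) == 0:
        return np.zeros_like(fan)
    thr = threshold_otsu(vals)
    dark = (img < thr) & fan
    dark = skimage.morphology.opening(dark, skimage.morphology.disk(opening_radius))
    dark &= fan
    labels = skimage.measure.label(dark)
    rows = fan.any(axis=1).nonzero()[0]
    fan_top, fan_height = rows[0], max(rows[-1] - rows[0], 1)
    best, best_area = None, 0
    for region in skimage.measure.regionprops(labels):
        depth_frac = (region.centroid[0] - fan_top) / fan_height
        if depth_frac < near_margin:
            continue
        if region.area > best_area:
            best, best_area = region.label, region.area
    if best is None:
        return np.zeros_like(fan)
    return labels == best
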