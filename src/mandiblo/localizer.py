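"""Heatmap-regression landmark localizer.

A stacked hourglass-style fully convolutional network regresses one
heatmap per contour point (96) plus a mandible mask (97 output channels).
Point coordinates are decoded from the predicted maps with soft-argmax,
giving sub-pixel estimates. Training minimizes per-pixel mean-squared
error against Gaussian target heatmaps (point channels up-weighted
against the much higher-energy mask channel) with intermediate
supervision on every stack.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .contour import MandibleContour
from .heatmaps import decode_stack, make_target_heatmaps
from .network import Adam, StackedHourglassNet, mse_loss

N_OUTPUTS = 97


@dataclass
class LocalizerConfig:
    """Architecture and training settings.

    Defaults follow the full-scale setup (256x512 input, hourglass depth 4,
    64 initial filters); tests and small experiments shrink everything.
    ``sigma_frac`` expresses the target-Gaussian standard deviation as a
    fraction of image width so heatmaps behave identically across
    resolutions.
    """

    height: int = 256
    width: int = 512
    stacks: int = 2
    depth: int = 4
    channels: int = 64
    sigma_frac: float = 0.01
    threshold_frac: float = 0.1   # decode-time background suppression
    seed: int = 0
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    val_fraction: float = 0.15
    point_loss_weight: float = 10.0   # point channels vs mask in the loss
    warmup_fraction: float = 0.1      # fraction of steps with linear LR ramp

    def __post_init__(self):
        if self.sigma_frac <= 0:
            raise ValueError("sigma_frac must be > 0")
        if self.depth < 1:
            raise ValueError("hourglass depth must be >= 1")
        if self.height % 2**self.depth or self.width % 2**self.depth:
            raise ValueError(
                f"input size {self.height}x{self.width} must be divisible "
                f"by 2^depth = {2**self.depth}"
            )


@dataclass
class LocalizerModel:
    net: StackedHourglassNet
    config: LocalizerConfig
    history: list = field(default_factory=list)

    @property
    def n_outputs(self) -> int:
        return self.net.n_out

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))
        np.savez(directory / "weights.npz", **self.net.state_arrays())
        (directory / "history.json").write_text(json.dumps(self.history))

    @classmethod
    def load(cls, directory) -> "LocalizerModel":
        directory = Path(directory)
        cfg = LocalizerConfig(**json.loads((directory / "config.json").read_text()))
        model = build_localizer(cfg)
        with np.load(directory / "weights.npz") as z:
            model.net.load_state_arrays(dict(z))
        hist = directory / "history.json"
        if hist.exists():
            model.history = json.loads(hist.read_text())
        return model


def build_localizer(cfg: LocalizerConfig) -> LocalizerModel:
    """Seeded construction of the untrained network."""
    rng = np.random.default_rng(cfg.seed)
    net = StackedHourglassNet(
        depth=cfg.depth, channels=cfg.channels, stacks=cfg.stacks,
        n_out=N_OUTPUTS, rng=rng,
    )
    return LocalizerModel(net=net, config=cfg)


def scale_points(pts: np.ndarray, from_hw: tuple, to_hw: tuple) -> np.ndarray:
    """Map pixel-center coordinates between image resolutions."""
    fh, fw = from_hw
    th, tw = to_hw
    sx, sy = tw / fw, th / fh
    out = np.asarray(pts, dtype=float).copy()
    out[..., 0] = (out[..., 0] + 0.5) * sx - 0.5
    out[..., 1] = (out[..., 1] + 0.5) * sy - 0.5
    return out


def _prepare_image(image: np.ndarray, cfg: LocalizerConfig) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    if img.shape != (cfg.height, cfg.width):
        img = resize(img, (cfg.height, cfg.width), anti_aliasing=True)
    return img


def train_localizer(
    images: list, contours: list, cfg: LocalizerConfig
) -> LocalizerModel:
    """Fit the localizer on paired images and 96-point contours.

    Images and contours at any common resolution are rescaled to the
    configured input size. An internal seeded split (``val_fraction``)
    selects the epoch with the lowest validation loss; with fewer than
    seven pairs all data is used for training and selection falls back to
    the training loss.
    """
    if len(images) != len(contours):
        raise ValueError("images and contours must be paired (equal length)")
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 training pairs")
    cfg_hw = (cfg.height, cfg.width)
    xs = np.stack([
        _prepare_image(img, cfg) for img in images
    ])[:, None, :, :]
    ts = []
    for img, c in zip(images, contours):
        pts = scale_points(c.points, np.asarray(img).shape, cfg_hw)
        ts.append(
            make_target_heatmaps(
                MandibleContour(pts, scheme=c.scheme), cfg_hw, cfg.sigma_frac
            )
        )
    ts = np.stack(ts)

    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(n)
    n_val = int(round(n * cfg.val_fraction)) if n >= 7 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]

    model = build_localizer(cfg)
    opt = Adam(model.net, lr=cfg.learning_rate)
    weights = np.full(N_OUTPUTS, cfg.point_loss_weight)
    weights[-1] = 1.0                        # mandible mask channel
    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / cfg.batch_size)))
    warmup_steps = max(1, int(cfg.warmup_fraction * cfg.epochs * steps_per_epoch))
    step = 0
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(train_idx)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            model.net.zero_grad()
            preds = model.net.forward(xs[idx])
            loss, grads = mse_loss(preds, ts[idx], channel_weights=weights)
            model.net.backward(grads)
            step += 1
            opt.lr = cfg.learning_rate * min(1.0, step / warmup_steps)
            opt.step()
            ep_loss += loss
            n_batches += 1
        ep_loss /= max(n_batches, 1)
        if n_val:
            vpreds = model.net.forward(xs[val_idx])
            val_loss, _ = mse_loss(vpreds, ts[val_idx],
                                   channel_weights=weights)
        else:
            val_loss = ep_loss
        model.history.append(
            {"epoch": epoch, "train_loss": ep_loss, "val_loss": val_loss}
        )
        if val_loss < best[0]:
            best = (val_loss, {k: v.copy() for k, v in model.net.state_arrays().items()})
    if best[1] is not None:
        model.net.load_state_arrays(best[1])
    return model


def predict_contour(
    model: LocalizerModel, image: np.ndarray, return_heatmaps: bool = False
):
    """Predict the 96-point contour of a grayscale radiograph.

    The image is rescaled to the network input size; last-stack heatmaps
    are rectified, normalized, decoded with soft-argmax and mapped back to
    the original image coordinates. Degenerate heatmaps flag their point
    index in ``contour.flags``.
    """
    cfg = model.config
    orig_hw = np.asarray(image).shape
    x = _prepare_image(image, cfg)[None, None]
    stack = model.net.forward(x)[-1][0]          # last stack, (97, h, w)
    pts, flagged = decode_stack(stack, cfg.threshold_frac)
    pts = scale_points(pts, (cfg.height, cfg.width), orig_hw)
    contour = MandibleContour(pts, flags=flagged)
    if return_heatmaps:
        return contour, stack
    return contour
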