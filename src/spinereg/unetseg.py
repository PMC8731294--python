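"""U-net semantic segmentation trained with a soft-Dice objective.

A small encoder-decoder CNN with skip connections between the
contraction and expansion paths: per level two 3x3 convolutions each
followed by a ReLU, 2x2 max-pooling on the way down, nearest-neighbour
upsampling followed by a channel-halving convolution and skip
concatenation on the way up, and a final 1x1 convolution producing
per-pixel class scores s_a(z). Scores become probabilities through the
softmax energy

    h_a(z) = exp(s_a(z)) / sum_a' exp(s_a'(z))

and the training objective replaces cross-entropy with a soft-Dice loss:

    loss = 1 - mean_{foreground classes c} (2 sum p_c t_c + eps)
                                           / (sum p_c + sum t_c + eps)

The network, backpropagation, and the Adam optimizer are implemented
directly in numpy (im2col convolutions), sized for desk-scale training
on 64x64 phantom slices. Convolutions use "same" padding so output
shapes match input shapes; training is fully deterministic for a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .exceptions import ConfigError
from .io import ImageVolume, LabelMask

__all__ = ["SegNetConfig", "ScoreMap", "softmax_energy", "dice_loss",
           "UNetSegmenter", "train", "segment"]


# ---------------------------------------------------------------------------
# public math ops


def softmax_energy(scores, axis: int = 0) -> np.ndarray:
    """Softmax h_a = exp(s_a) / sum_a' exp(s_a') along the class axis.

    Shift-invariant and numerically stable; requires finite scores and
    at least two classes along ``axis``.
    """
    s = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if s.shape[axis] < 2:
        raise ValueError("softmax needs at least 2 classes")
    s = s - s.max(axis=axis, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class ScoreMap:
    """Per-pixel raw class scores and their softmax probabilities."""

    scores: np.ndarray  # (n_classes, H, W)
    probs: np.ndarray   # (n_classes, H, W), rows of the simplex


def dice_loss(probs, target, eps: float = 1.0) -> float:
    """Soft-Dice loss between class probabilities and integer labels.

    ``probs`` carries a leading class axis: ``(K, H, W)`` for one image
    or ``(N, K, H, W)`` for a batch; ``target`` holds the matching
    integer label maps (``(H, W)`` / ``(N, H, W)``). The loss is 1 minus
    the mean soft Dice over the foreground classes (c >= 1) and lies in
    [0, 1] up to the eps smoothing.
    """
    p = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target)
    if p.ndim != t.ndim + 1 or p.shape[-t.ndim:] != t.shape:
        raise ValueError(f"probs shape {p.shape} does not match target "
                         f"shape {t.shape} plus a class axis")
    if t.ndim == 2:  # single image -> batch of one
        p = p[None]
        t = t[None]
    n_classes = p.shape[1]
    if t.min() < 0 or t.max() >= n_classes:
        raise ValueError("target label out of range")
    onehot = np.moveaxis(np.eye(n_classes)[t], -1, 1)  # (N, K, H, W)
    axes = (0, 2, 3)
    inter = (p * onehot).sum(axis=axes)
    sums = p.sum(axis=axes) + onehot.sum(axis=axes)
    dice_c = (2.0 * inter + eps) / (sums + eps)
    return float(1.0 - dice_c[1:].mean())


# ---------------------------------------------------------------------------
# layers


class _Conv:
    """2D convolution with 'same' padding, im2col implementation."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(N, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        N, C, H, W = x_shape
        k = self.k
        p = k // 2
        g = dout.transpose(0, 2, 3, 1).reshape(N * H * W, self.c_out)
        self.dW = g.T @ cols
        self.db = g.sum(axis=0)
        dcols = (g @ self.W).reshape(N, H, W, C, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, H, W, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j]
        self._cache = None
        return dxp[:, :, p:p + H, p:p + W] if p else dxp

    def parameters(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            # split gradient among ties to keep backward well defined
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout[:, :, :, None, :, None] * self._mask
        return d.reshape(self._shape)


class _Upsample2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = dout.shape
        return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class _Block:
    """conv3-ReLU-conv3-ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [_Conv(c_in, c_out, 3, rng), _ReLU(),
                       _Conv(c_out, c_out, 3, rng), _ReLU()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def convs(self):
        return [l for l in self.layers if isinstance(l, _Conv)]


class _UNet:
    """The full network graph with explicit forward/backward."""

    def __init__(self, n_classes: int, depth: int, base: int,
                 rng: np.random.Generator):
        self.depth = depth
        self.enc = []
        c_in = 1
        for i in range(depth):
            self.enc.append(_Block(c_in, base * 2 ** i, rng))
            c_in = base * 2 ** i
        self.pools = [_MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(c_in, base * 2 ** depth, rng)
        self.ups = []
        self.upconvs = []
        self.dec = []
        for i in reversed(range(depth)):
            c_coarse = base * 2 ** (i + 1)
            c_fine = base * 2 ** i
            self.ups.append(_Upsample2())
            self.upconvs.append(_Conv(c_coarse, c_fine, 3, rng))
            self.dec.append(_Block(2 * c_fine, c_fine, rng))
        self.head = _Conv(base, n_classes, 1, rng)
        self.n_classes = n_classes

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, upconv, block, skip in zip(self.ups, self.upconvs, self.dec,
                                           reversed(skips)):
            x = up.forward(x, train)
            x = upconv.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dscores: np.ndarray) -> None:
        d = self.head.backward(dscores)
        dskips = []
        for up, upconv, block, c_skip in zip(reversed(self.ups),
                                             reversed(self.upconvs),
                                             reversed(self.dec),
                                             reversed(self._skip_channels)):
            d = block.backward(d)
            dskips.append(d[:, :c_skip])
            d = upconv.backward(d[:, c_skip:])
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips[j] is the gradient flowing into skips[j]; the encoder
        # unwinds deepest-first, so pair with reversed(dskips)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            d = pool.backward(d)
            d = block.backward(d + dskip)

    def conv_layers(self) -> list[_Conv]:
        convs = []
        for block in self.enc:
            convs += block.convs()
        convs += self.bottleneck.convs()
        convs += self.upconvs
        for block in self.dec:
            convs += block.convs()
        convs.append(self.head)
        return convs


# ---------------------------------------------------------------------------
# training


@dataclass
class SegNetConfig:
    """Hyperparameters of the toy segmenter."""

    n_classes: int = 2
    depth: int = 3
    base_channels: int = 8
    epochs: int = 12
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0 \
                or self.base_channels < 1:
            raise ConfigError("training hyperparameters must be positive")


class UNetSegmenter(BaseEstimator):
    """sklearn-style wrapper around the numpy U-net.

    ``fit(X, y)`` trains on a stack of 2D images (``(n, H, W)`` array or
    a list of :class:`ImageVolume`) against integer label maps; the
    fitted attributes are ``model_``, ``loss_curve_`` (epoch-mean Dice
    loss) and the normalization constants. ``predict`` returns per-pixel
    argmax labels; ``predict_proba`` the softmax maps.
    """

    def __init__(self, n_classes: int = 2, depth: int = 3,
                 base_channels: int = 8, epochs: int = 12,
                 batch_size: int = 8, learning_rate: float = 1e-3,
                 dice_eps: float = 1.0, seed: int = 0):
        self.n_classes = n_classes
        self.depth = depth
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dice_eps = dice_eps
        self.seed = seed

    # -- data plumbing ------------------------------------------------------

    @staticmethod
    def _stack(X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            arr = X.astype(np.float64)
        else:
            imgs = [x.data if isinstance(x, ImageVolume) else np.asarray(x)
                    for x in X]
            arr = np.stack(imgs).astype(np.float64)
        if arr.ndim != 3:
            raise ValueError("expected a stack of 2D images")
        return arr

    @staticmethod
    def _stack_labels(y) -> np.ndarray:
        if isinstance(y, np.ndarray) and y.ndim == 3:
            return y.astype(np.int64)
        masks = [m.labels if isinstance(m, LabelMask) else np.asarray(m)
                 for m in y]
        return np.stack(masks).astype(np.int64)

    def _check_shape(self, arr: np.ndarray) -> None:
        H, W = arr.shape[-2:]
        div = 2 ** self.depth
        if H % div or W % div:
            raise ConfigError(
                f"image shape {(H, W)} must be divisible by 2^depth = {div}")

    # -- estimator API --------------------------------------------------------

    # restart-on-plateau: soft-Dice training occasionally starts in a bad
    # basin; a run whose epoch-mean loss is still above the threshold
    # after the probe epochs is abandoned and reinitialized from the next
    # derived seed. Fully deterministic given `seed`.
    _PROBE_EPOCHS = 5
    _RESTART_LOSS = 0.12
    _MAX_RESTARTS = 3

    def fit(self, X, y) -> "UNetSegmenter":
        SegNetConfig(self.n_classes, self.depth, self.base_channels,
                     self.epochs, self.batch_size, self.learning_rate,
                     self.seed)  # validate
        images = self._stack(X)
        labels = self._stack_labels(y)
        if images.shape != labels.shape:
            raise ValueError("images and labels must align")
        if labels.max() >= self.n_classes:
            raise ValueError("target label out of range for n_classes")
        self._check_shape(images)
        self.norm_mean_ = float(images.mean())
        self.norm_std_ = float(images.std()) or 1.0
        x = (images - self.norm_mean_) / self.norm_std_

        probe = min(self._PROBE_EPOCHS, self.epochs)
        best = None
        for attempt in range(self._MAX_RESTARTS + 1):
            model, curve = self._train_attempt(x, labels, attempt, probe)
            if len(curve) == self.epochs:  # ran to completion
                best = (model, curve, attempt)
                break
            if best is None or curve[-1] < best[1][-1]:
                best = (model, curve, attempt)
        model, curve, attempt = best
        if len(curve) < self.epochs:  # every probe stalled: finish the best
            model, curve = self._train_attempt(x, labels, attempt,
                                               probe=self.epochs)
        self.model_ = model
        self.loss_curve_ = curve
        self.n_restarts_ = attempt
        self.classes_ = np.arange(self.n_classes)
        return self

    def _train_attempt(self, x, labels, attempt: int, probe: int):
        """One Adam training run; aborts after ``probe`` epochs if stuck."""
        rng = np.random.default_rng([self.seed, attempt])
        model = _UNet(self.n_classes, self.depth, self.base_channels, rng)
        convs = model.conv_layers()
        adam_m = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in convs]
        adam_v = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in convs]
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        step = 0
        n = x.shape[0]
        curve: list[float] = []
        for epoch in range(self.epochs):
            # step decay: fast early progress, stable late refinement
            lr_epoch = self.learning_rate * 0.5 ** (epoch // 4)
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = x[idx][:, None]  # (B, 1, H, W)
                tb = labels[idx]
                scores = model.forward(xb, train=True)
                probs = softmax_energy(scores, axis=1)
                loss, dprobs = self._dice_loss_grad(probs, tb)
                epoch_losses.append(loss)
                # softmax Jacobian: ds = p * (g - sum_c g_c p_c)
                inner = (dprobs * probs).sum(axis=1, keepdims=True)
                dscores = probs * (dprobs - inner)
                model.backward(dscores)
                step += 1
                lr_t = lr_epoch * \
                    np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
                for ci, conv in enumerate(convs):
                    for pname, g in (("W", conv.dW), ("b", conv.db)):
                        pi = 0 if pname == "W" else 1
                        m = adam_m[ci][pi]
                        v = adam_v[ci][pi]
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        param = getattr(conv, pname)
                        param -= lr_t * m / (np.sqrt(v) + adam_eps)
            curve.append(float(np.mean(epoch_losses)))
            if epoch + 1 == probe and probe < self.epochs \
                    and curve[-1] > self._RESTART_LOSS:
                break
        return model, curve

    def _dice_loss_grad(self, probs: np.ndarray, target: np.ndarray):
        """Batch soft-Dice loss and its gradient w.r.t. the probabilities."""
        eps = self.dice_eps
        K = probs.shape[1]
        onehot = np.moveaxis(np.eye(K)[target], -1, 1)
        axes = (0, 2, 3)
        inter = (probs * onehot).sum(axis=axes)
        psum = probs.sum(axis=axes)
        tsum = onehot.sum(axis=axes)
        den = psum + tsum + eps
        num = 2.0 * inter + eps
        dice_c = num / den
        loss = float(1.0 - dice_c[1:].mean())
        n_fg = K - 1
        dprobs = np.zeros_like(probs)
        for c in range(1, K):
            ddice_dp = (2.0 * onehot[:, c] * den[c] - num[c]) / den[c] ** 2
            dprobs[:, c] = -ddice_dp / n_fg
        return loss, dprobs

    def _scores(self, image: np.ndarray) -> np.ndarray:
        x = (image - self.norm_mean_) / self.norm_std_
        return self.model_.forward(x[None, None], train=False)[0]

    def predict_scores(self, volume) -> ScoreMap:
        """Raw class scores and softmax probabilities for one 2D image."""
        if not hasattr(self, "model_"):
            raise AttributeError("fit must be called before predict")
        img = volume.data if isinstance(volume, ImageVolume) else \
            np.asarray(volume, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("expected a single 2D image")
        self._check_shape(img)
        scores = self._scores(img)
        return ScoreMap(scores=scores, probs=softmax_energy(scores, axis=0))

    def predict_proba(self, X) -> np.ndarray:
        images = self._stack(X)
        return np.stack([self.predict_scores(im).probs for im in images])

    def predict(self, X) -> np.ndarray:
        """Per-pixel argmax labels for a stack of 2D images."""
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence ----------------------------------------------------------

    def weights_hash(self) -> str:
        """SHA-256 over all trained weights (determinism checks)."""
        h = hashlib.sha256()
        for conv in self.model_.conv_layers():
            h.update(np.ascontiguousarray(conv.W).tobytes())
            h.update(np.ascontiguousarray(conv.b).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        """Self-describing model container (config + weights), version 1."""
        meta = {"format": "spinereg-unet", "version": 1,
                "params": self.get_params(),
                "norm_mean": self.norm_mean_, "norm_std": self.norm_std_,
                "loss_curve": self.loss_curve_}
        arrays = {}
        for i, conv in enumerate(self.model_.conv_layers()):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format") != "spinereg-unet":
                raise ValueError("not a spinereg model file")
            est = cls(**meta["params"])
            est.norm_mean_ = meta["norm_mean"]
            est.norm_std_ = meta["norm_std"]
            est.loss_curve_ = meta["loss_curve"]
            model = _UNet(est.n_classes, est.depth, est.base_channels,
                          np.random.default_rng(0))
            for i, conv in enumerate(model.conv_layers()):
                conv.W = data[f"W{i}"]
                conv.b = data[f"b{i}"]
            est.model_ = model
            est.classes_ = np.arange(est.n_classes)
        return est


def train(dataset, config: SegNetConfig | None = None) -> UNetSegmenter:
    """Train a segmenter on (ImageVolume, LabelMask) pairs."""
    config = config or SegNetConfig()
    X = [v for v, _ in dataset]
    y = [m for _, m in dataset]
    est = UNetSegmenter(n_classes=config.n_classes, depth=config.depth,
                        base_channels=config.base_channels,
                        epochs=config.epochs, batch_size=config.batch_size,
                        learning_rate=config.learning_rate, seed=config.seed)
    return est.fit(X, y)


def segment(model: UNetSegmenter, volume: ImageVolume) -> LabelMask:
    """Argmax segmentation of a single 2D volume."""
    score_map = model.predict_scores(volume)
    labels = score_map.probs.argmax(axis=0).astype(np.int32)
    return LabelMask(labels, volume.spacing, volume.origin)
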