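"""A small trainable fully convolutional network for semantic segmentation.

The network assigns a class to every pixel of a fluorescence image.  It is
deliberately compact: five convolutional layers joined by ReLU activations
with a per-pixel softmax output, plus a 1x1 convolution between feature maps
2 and 3 that reduces the kernel count by ``reduction_factor`` (default 4),
cutting the parameter count of the following convolution by a factor of 16.
There is no downsampling, striding or pooling anywhere, so the output class
map has exactly the input resolution and fine structures (sub-micron RNAscope
dots) survive.  Mirror (reflection) padding preserves spatial dimensions at
every layer; the stacked receptive field equals ``patch_size`` so the class
of a pixel depends only on the surrounding ``patch_size x patch_size`` patch.

Training minimises pixel-wise cross-entropy on randomly cropped
``patch_size**2`` patches with the Adam optimizer (alpha = 0.001,
beta1 = 0.9, beta2 = 0.999, eps = 1e-8) and stops early once the held-out
pixel error stops improving.  The train/test split is done at the level of
whole images, never patches, to avoid leakage between sets.

Everything runs in NumPy on the CPU; forward convolutions are computed by
im2col + tensordot with row chunking to bound memory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import LabelMask, MultiChannelImage

__all__ = [
    "FCNConfig",
    "ClassMetrics",
    "TrainedModel",
    "TrainingDiverged",
    "build_fcn",
    "split_dataset",
    "train",
    "predict",
    "evaluate",
    "dot_task_config",
]

# im2col buffers above this many elements are processed in row chunks.
_COLS_BUDGET = 32_000_000


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, message: str, log: list):
        super().__init__(message)
        self.log = log


@dataclass
class FCNConfig:
    """Architecture and optimisation settings.

    ``layer_widths`` are the output widths of convolutions 1-4 (convolution 5
    maps to ``n_classes``); ``kernel_sizes`` are the spatial extents of the
    five convolutions.  The 1x1 reduction sits between convolutions 2 and 3
    and divides ``layer_widths[1]`` by ``reduction_factor``.  The stacked
    receptive field, ``sum(k - 1) + 1``, must equal ``patch_size``.
    """

    n_classes: int = 2
    patch_size: int = 63
    layer_widths: tuple[int, ...] = (16, 32, 32, 64)
    kernel_sizes: tuple[int, ...] = (13, 13, 13, 13, 15)
    reduction_factor: int = 4
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_epochs: int = 200
    patience: int = 10
    patches_per_image: int = 64
    batch_size: int = 16
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.patch_size % 2 != 1:
            raise ValueError("patch_size must be odd")
        if len(self.layer_widths) != 4 or any(w < 1 for w in self.layer_widths):
            raise ValueError("layer_widths must be 4 positive ints")
        if len(self.kernel_sizes) != 5 or any(k % 2 != 1 for k in self.kernel_sizes):
            raise ValueError("kernel_sizes must be 5 odd ints")
        if self.layer_widths[1] % self.reduction_factor != 0:
            raise ValueError("reduction_factor must divide layer_widths[1]")
        rf = sum(k - 1 for k in self.kernel_sizes) + 1
        if rf != self.patch_size:
            raise ValueError(
                f"receptive field {rf} != patch_size {self.patch_size}; "
                "choose kernel_sizes with sum(k-1)+1 == patch_size")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def receptive_radius(self) -> int:
        return (self.patch_size - 1) // 2

    def layer_plan(self, in_channels: int) -> list[tuple[int, int, int]]:
        """(kernel, c_in, c_out) for each convolution, 1x1 reduction included."""
        w = self.layer_widths
        k = self.kernel_sizes
        red = w[1] // self.reduction_factor
        return [
            (k[0], in_channels, w[0]),
            (k[1], w[0], w[1]),
            (1, w[1], red),
            (k[2], red, w[2]),
            (k[3], w[2], w[3]),
            (k[4], w[3], self.n_classes),
        ]


def dot_task_config(seed: int = 0, n_classes: int = 2) -> FCNConfig:
    """A compact configuration for the synthetic RNAscope dot task.

    Dots are a few pixels wide, so a 15-px receptive field suffices; the
    narrow layers keep CPU training in the minutes range.  Inverse-frequency
    class weighting is on because the dot class covers ~1% of pixels.
    """
    return FCNConfig(
        n_classes=n_classes,
        patch_size=15,
        layer_widths=(8, 16, 16, 16),
        kernel_sizes=(5, 5, 1, 5, 3),
        reduction_factor=4,
        max_epochs=60,
        patience=8,
        class_weighting=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _reflect_index(n: int, pad: int) -> np.ndarray:
    """Source index for each position of a reflect-padded axis (no edge dup)."""
    return np.pad(np.arange(n), pad, mode="reflect")


def _conv_same_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                       want_cols: bool):
    """'Same' convolution with reflect padding.

    x : (B, H, W, Cin); W : (k, k, Cin, Cout).  Returns (out, cols, xp) with
    cols/xp kept only when needed for the backward pass.
    """
    k = W.shape[0]
    p = (k - 1) // 2
    if p:
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="reflect")
    else:
        xp = x
    B, Hp, Wp, Cin = xp.shape
    H, Wd = Hp - k + 1, Wp - k + 1
    size = B * H * Wd * k * k * Cin
    if want_cols or size <= _COLS_BUDGET:
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # B,H,W,Cin,k,k
        out = np.tensordot(cols, W, axes=([3, 4, 5], [2, 0, 1])) + b
        return out, (cols if want_cols else None), (xp if want_cols else None)
    # row-chunked inference path
    out = np.empty((B, H, Wd, W.shape[3]))
    rows = max(1, _COLS_BUDGET // max(1, B * Wd * k * k * Cin))
    for r0 in range(0, H, rows):
        r1 = min(H, r0 + rows)
        chunk = sliding_window_view(xp[:, r0:r1 + k - 1], (k, k), axis=(1, 2))
        out[:, r0:r1] = np.tensordot(chunk, W, axes=([3, 4, 5], [2, 0, 1])) + b
    return out, None, None


def _conv_same_backward(dout: np.ndarray, cols: np.ndarray, xp: np.ndarray,
                        W: np.ndarray, in_shape: tuple):
    """Gradients of the 'same' reflect-padded convolution."""
    k = W.shape[0]
    p = (k - 1) // 2
    dW = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))  # Cin,k,k,Cout
    dW = dW.transpose(1, 2, 0, 3)
    db = dout.sum(axis=(0, 1, 2))
    # full correlation of dout with the flipped kernel -> gradient w.r.t. xp
    if k > 1:
        zp = np.pad(dout, ((0, 0), (k - 1, k - 1), (k - 1, k - 1), (0, 0)))
    else:
        zp = dout
    colsd = sliding_window_view(zp, (k, k), axis=(1, 2))  # B,Hp,Wp,Cout,k,k
    Wf = W[::-1, ::-1]  # (k, k, Cin, Cout)
    dxp = np.tensordot(colsd, Wf, axes=([4, 5, 3], [0, 1, 3]))  # B,Hp,Wp,Cin
    if p == 0:
        return dW, db, dxp
    B, H, Wd, Cin = in_shape
    ir = _reflect_index(H, p)
    ic = _reflect_index(Wd, p)
    tmp = np.zeros((B, H, dxp.shape[2], Cin))
    np.add.at(tmp, (slice(None), ir), dxp)
    dx = np.zeros((B, H, Wd, Cin))
    np.add.at(dx, (slice(None), slice(None), ic), tmp)
    return dW, db, dx


class FCN:
    """The network: weights plus forward/backward passes."""

    def __init__(self, config: FCNConfig, in_channels: int,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.in_channels = in_channels
        rng = rng or np.random.default_rng(config.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for k, cin, cout in config.layer_plan(in_channels):
            scale = np.sqrt(2.0 / (k * k * cin))  # He initialisation
            self.weights.append(rng.normal(0.0, scale, size=(k, k, cin, cout)))
            self.biases.append(np.zeros(cout))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x : (B, H, W, C) -> per-pixel class probabilities (B, H, W, K)."""
        cache = []
        h = x
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out, cols, xp = _conv_same_forward(h, W, b, want_cache)
            last = i == self.n_layers - 1
            if want_cache:
                cache.append((h.shape, cols, xp, out if not last else None))
            h = out if last else np.maximum(out, 0.0)
        # softmax over classes
        z = h - h.max(axis=3, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=3, keepdims=True)
        return (probs, cache) if want_cache else probs

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       class_weights: np.ndarray | None = None):
        """Cross-entropy loss, gradients, and batch pixel error.

        y : (B, H, W) integer class labels.
        """
        probs, cache = self.forward(x, want_cache=True)
        B, H, Wd, K = probs.shape
        flat = probs.reshape(-1, K)
        yf = y.reshape(-1)
        py = np.clip(flat[np.arange(yf.size), yf], 1e-12, None)
        w = (class_weights[yf] if class_weights is not None
             else np.ones(yf.size))
        wsum = w.sum()
        loss = float(-(w * np.log(py)).sum() / wsum)
        pixel_err = float(np.mean(flat.argmax(axis=1) != yf))
        # d loss / d logits for weighted softmax cross-entropy
        onehot = np.zeros_like(flat)
        onehot[np.arange(yf.size), yf] = 1.0
        dlogits = ((flat - onehot) * w[:, None] / wsum).reshape(B, H, Wd, K)
        grads_W = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        dout = dlogits
        for i in range(self.n_layers - 1, -1, -1):
            in_shape, cols, xp, preact = cache[i]
            if preact is not None:  # ReLU between hidden layers
                pass
            dW, db, dx = _conv_same_backward(dout, cols, xp, self.weights[i],
                                             in_shape)
            grads_W[i], grads_b[i] = dW, db
            if i > 0:
                prev_preact = cache[i - 1][3]
                dout = dx * (prev_preact > 0.0)
        return loss, grads_W, grads_b, pixel_err

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference on a single (H, W, C) image -> (H, W, K) probabilities."""
        return self.forward(x[None])[0]


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def _image_array(img) -> np.ndarray:
    if isinstance(img, MultiChannelImage):
        return img.pixels
    arr = np.asarray(img, dtype=float)
    return arr[:, :, None] if arr.ndim == 2 else arr


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.labels
    return np.asarray(mask)


def split_dataset(images: Sequence, fraction: float = 0.8,
                  seed: int = 0) -> tuple[list, list]:
    """Split (image, mask) pairs into train/test at the image level.

    The split never mixes patches from one image across the two sets, which
    would leak nearly identical pixels into the held-out data.  Deterministic
    for a given seed.
    """
    items = list(images)
    if len(items) < 2:
        raise ValueError("need at least 2 images to split")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = int(round(fraction * len(items)))
    n_train = min(max(n_train, 1), len(items))
    train_set = [items[i] for i in order[:n_train]]
    test_set = [items[i] for i in order[n_train:]]
    if not test_set:
        warnings.warn("empty test set: every image assigned to training")
    return train_set, test_set


def build_fcn(config: FCNConfig, in_channels: int = 3) -> FCN:
    """Construct an untrained network for images with ``in_channels``."""
    return FCN(config, in_channels)


@dataclass
class TrainedModel:
    """A trained network with its config, class names and training log."""

    model: FCN
    config: FCNConfig
    class_names: list[str]
    log: list[dict] = field(default_factory=list)
    stop_epoch: int = 0

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config JSON plus the weight arrays."""
        arrays = {}
        for i, (W, b) in enumerate(zip(self.model.weights, self.model.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        header = json.dumps({
            "config": asdict(self.config),
            "class_names": self.class_names,
            "in_channels": self.model.in_channels,
            "log": self.log,
            "stop_epoch": self.stop_epoch,
        })
        np.savez(str(path), header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(str(path)) as data:
            header = json.loads(bytes(data["header"]).decode())
            cfg = dict(header["config"])
            cfg["layer_widths"] = tuple(cfg["layer_widths"])
            cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
            config = FCNConfig(**cfg)
            model = FCN(config, header["in_channels"])
            model.weights = [data[f"W{i}"] for i in range(model.n_layers)]
            model.biases = [data[f"b{i}"] for i in range(model.n_layers)]
        return cls(model=model, config=config,
                   class_names=header["class_names"], log=header["log"],
                   stop_epoch=header["stop_epoch"])


def _sample_patches(arrays: list[tuple[np.ndarray, np.ndarray]], n_per_image: int,
                    patch: int, rng: np.random.Generator):
    xs, ys = [], []
    for img, msk in arrays:
        H, Wd = img.shape[:2]
        if H < patch or Wd < patch:
            raise ValueError(f"image {img.shape[:2]} smaller than patch {patch}")
        r = rng.integers(0, H - patch + 1, size=n_per_image)
        c = rng.integers(0, Wd - patch + 1, size=n_per_image)
        for ri, ci in zip(r, c):
            xs.append(img[ri:ri + patch, ci:ci + patch])
            ys.append(msk[ri:ri + patch, ci:ci + patch])
    return np.stack(xs), np.stack(ys)


def _dataset_pixel_error(model: FCN, arrays) -> float:
    wrong = total = 0
    for img, msk in arrays:
        pred = model.predict_proba(img).argmax(axis=2)
        wrong += int(np.sum(pred != msk))
        total += msk.size
    return wrong / total if total else float("nan")


def train(model: FCN, train_set: Sequence, test_set: Sequence,
          config: FCNConfig | None = None,
          class_names: Sequence[str] | None = None) -> TrainedModel:
    """Train by Adam on random patch crops with early stopping.

    ``train_set``/``test_set`` are sequences of (image, mask) pairs.  The
    held-out pixel error is evaluated on full test images after every epoch;
    training stops once it has not improved for ``patience`` epochs, and the
    weights from the best epoch are restored.  With an empty test set the
    training pixel error is used for stopping instead (with a warning).
    All randomness (crops) comes from ``config.seed``.
    """
    config = config or model.config
    if len(train_set) == 0:
        raise ValueError("empty training set")
    tr = [(_image_array(i), _mask_array(m)) for i, m in train_set]
    te = [(_image_array(i), _mask_array(m)) for i, m in test_set]
    if not te:
        warnings.warn("no held-out images: early stopping uses training error")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    class_weights = None
    if config.class_weighting:
        counts = np.zeros(config.n_classes)
        for _, msk in tr:
            counts += np.bincount(msk.ravel(), minlength=config.n_classes)
        freq = np.clip(counts / counts.sum(), 1e-6, None)
        class_weights = (1.0 / freq) / np.sum(1.0 / freq) * config.n_classes

    m_W = [np.zeros_like(W) for W in model.weights]
    v_W = [np.zeros_like(W) for W in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    step = 0
    log: list[dict] = []
    best_err = np.inf
    best_epoch = 0
    best_weights = None
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        X, Y = _sample_patches(tr, config.patches_per_image, config.patch_size,
                               rng)
        order = rng.permutation(len(X))
        ep_loss = 0.0
        ep_err = 0.0
        n_batches = 0
        for b0 in range(0, len(X), config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            loss, gW, gb, perr = model.loss_and_grads(X[idx], Y[idx],
                                                      class_weights)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}", log)
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - config.beta2 ** step) / (1 - config.beta1 ** step))
            for params, grads, ms, vs in (
                    (model.weights, gW, m_W, v_W),
                    (model.biases, gb, m_b, v_b)):
                for i in range(model.n_layers):
                    ms[i] = config.beta1 * ms[i] + (1 - config.beta1) * grads[i]
                    vs[i] = config.beta2 * vs[i] + (1 - config.beta2) * grads[i] ** 2
                    params[i] -= lr_t * ms[i] / (np.sqrt(vs[i]) + config.epsilon)
            ep_loss += loss
            ep_err += perr
            n_batches += 1
        train_err = ep_err / n_batches
        test_err = _dataset_pixel_error(model, te) if te else train_err
        log.append({"epoch": epoch, "loss": ep_loss / n_batches,
                    "train_pixel_error": train_err,
                    "test_pixel_error": test_err})
        if test_err < best_err - 1e-12:
            best_err = test_err
            best_epoch = epoch
            best_weights = ([W.copy() for W in model.weights],
                            [b.copy() for b in model.biases])
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    if best_weights is not None:
        model.weights, model.biases = best_weights
    names = list(class_names) if class_names else [
        f"class_{i}" for i in range(config.n_classes)]
    return TrainedModel(model=model, config=config, class_names=names,
                        log=log, stop_epoch=best_epoch)


def predict(trained: TrainedModel | FCN, image,
            excluded_channel: str | None = None):
    """Semantic segmentation of one image.

    Returns (LabelMask, probability map).  ``excluded_channel`` zeroes the
    named channel before the forward pass (see ``postprocess.zero_channel``);
    the caller keeps the original image for quantification.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    class_names = (trained.class_names if isinstance(trained, TrainedModel)
                   else [f"class_{i}" for i in range(model.config.n_classes)])
    if excluded_channel is not None:
        if not isinstance(image, MultiChannelImage):
            raise ValueError("excluded_channel needs a MultiChannelImage")
        from .postprocess import zero_channel
        image = zero_channel(image, excluded_channel)
    arr = _image_array(image)
    if arr.shape[2] != model.in_channels:
        raise ValueError(
            f"image has {arr.shape[2]} channels, model expects "
            f"{model.in_channels}")
    probs = model.predict_proba(arr)
    mask = LabelMask(probs.argmax(axis=2).astype(np.int32), kind="semantic",
                     class_names=class_names)
    return mask, probs


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    """Per-class confusion rates in % of total pixels, plus pixel error.

    specificity = TN / (TN + FP); sensitivity = TP / (TP + FN).  A metric
    with an empty denominator is NaN (undefined), never silently 0.
    """

    class_names: list[str]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    pixel_error: float

    def _ratio(self, num: np.ndarray, den: np.ndarray) -> np.ndarray:
        out = np.full(len(self.class_names), np.nan)
        ok = den > 0
        out[ok] = 100.0 * num[ok] / den[ok]
        return out

    @property
    def specificity(self) -> np.ndarray:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def sensitivity(self) -> np.ndarray:
        return self._ratio(self.tp, self.tp + self.fn)

    def for_class(self, name: str) -> dict:
        i = self.class_names.index(name)
        return {"TP": self.tp[i], "TN": self.tn[i], "FP": self.fp[i],
                "FN": self.fn[i], "specificity": self.specificity[i],
                "sensitivity": self.sensitivity[i]}


def evaluate(pred, truth, n_classes: int | None = None,
             class_names: Sequence[str] | None = None) -> ClassMetrics:
    """Confusion-rate metrics of a prediction against ground truth.

    ``pred``/``truth`` may be single masks or equal-length lists of masks;
    rates are percentages of the total pixel count pooled over the set.
    """
    preds = pred if isinstance(pred, (list, tuple)) else [pred]
    truths = truth if isinstance(truth, (list, tuple)) else [truth]
    if len(preds) != len(truths):
        raise ValueError("pred/truth lists differ in length")
    names = list(class_names) if class_names else None
    if names is None:
        for p in preds:
            if isinstance(p, LabelMask) and p.class_names:
                names = list(p.class_names)
                break
    total = 0
    K = n_classes or (len(names) if names else None)
    parr, tarr = [], []
    for p, t in zip(preds, truths):
        pa, ta = _mask_array(p), _mask_array(t)
        if pa.shape != ta.shape:
            raise ValueError(f"shape mismatch {pa.shape} vs {ta.shape}")
        parr.append(pa.ravel())
        tarr.append(ta.ravel())
        total += pa.size
    pa = np.concatenate(parr)
    ta = np.concatenate(tarr)
    if K is None:
        K = int(max(pa.max(initial=0), ta.max(initial=0))) + 1
    if names is None:
        names = [f"class_{i}" for i in range(K)]
    tp = np.zeros(K)
    tn = np.zeros(K)
    fp = np.zeros(K)
    fn = np.zeros(K)
    for c in range(K):
        is_p = pa == c
        is_t = ta == c
        tp[c] = np.sum(is_p & is_t)
        fp[c] = np.sum(is_p & ~is_t)
        fn[c] = np.sum(~is_p & is_t)
        tn[c] = total - tp[c] - fp[c] - fn[c]
    pct = 100.0 / total
    return ClassMetrics(
        class_names=names, tp=tp * pct, tn=tn * pct, fp=fp * pct, fn=fn * pct,
        pixel_error=float(100.0 * np.sum(pa != ta) / total),
    )
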