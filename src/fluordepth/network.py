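"""Two-arm ("Siamese") convolutional network for depth/concentration maps.

The network maps per-pixel optical properties (2 channels) and the
six-frequency fluorescence stack to a tumor depth map (mm) and a fluorophore
concentration map (ug/mL), both 101 x 101.  The property arm applies 2-D
convolutions and a residual block; the fluorescence arm applies one
volumetric 3 x 3 x 6 convolution spanning the whole frequency axis (followed
by the reshape that collapses the collapsed frequency dimension into
channels), two 2-D convolutions and a residual block; the arms are
concatenated, passed through a separable convolution and a residual block,
and split into two reducing convolutional heads.  All convolutions use 3 x 3
kernels, unit stride and zero padding, so every layer preserves the lateral
image dimensions; hidden activations are leaky rectifiers (see LEAKY_SLOPE)
and the final head convolutions are linear, with physical non-negativity
applied as a clamp at prediction time.

Layers, backpropagation and the Adam optimizer are implemented directly on
numpy (float32, channels-last): inference-time prediction is a pure function
of the inputs and weights, and seeded training is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import DatasetManifest, Normalizer, manifest_to_arrays

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "DepthConcPrediction",
    "SiameseCNN",
    "build_model",
    "train",
    "predict",
    "TARGET_PARAMETER_COUNT",
]

#: Trainable parameter count of the committed full-scale filter schedule.
TARGET_PARAMETER_COUNT = 920_514


@dataclass(frozen=True)
class ModelConfig:
    """Filter schedule of the two-arm network.

    The default schedule is the committed full-scale architecture whose
    trainable parameter count is exactly 920,514.  ``scaled`` produces a
    narrow variant with the same topology for CPU-scale training runs.
    """

    nx: int = 101
    ny: int = 101
    n_fx: int = 6
    prop_channels: tuple = (32, 112)  # property-arm convolutions
    fluor_entry: int = 32  # filters of the 3 x 3 x 6 volumetric entry
    fluor_channels: tuple = (96, 112)  # fluorescence-arm 2-D convolutions
    trunk_channels: int = 112  # separable conv output + trunk ResBlock
    head_channels: tuple = (24, 16)  # reducing head convolutions

    @classmethod
    def scaled(cls, width_factor: float) -> "ModelConfig":
        f = lambda c: max(2, int(round(c * width_factor)))
        return cls(
            prop_channels=(f(32), f(112)),
            fluor_entry=f(32),
            fluor_channels=(f(96), f(112)),
            trunk_channels=f(112),
            head_channels=(f(24), f(16)),
        )

    def parameter_count(self) -> int:
        """Closed-form per-layer parameter accounting."""
        def conv(cin, cout, k=9):
            return k * cin * cout + cout

        p1, p2 = self.prop_channels
        f2, f3 = self.fluor_channels
        total = conv(2, p1) + conv(p1, p2) + 2 * conv(p2, p2)  # prop arm + res
        total += (
            9 * self.n_fx * self.fluor_entry + self.fluor_entry  # 3x3x6 entry
            + conv(self.fluor_entry, f2)
            + conv(f2, f3)
            + 2 * conv(f3, f3)
        )
        c = p2 + f3
        total += (9 * c + c) + (c * self.trunk_channels + self.trunk_channels)
        total += 2 * conv(self.trunk_channels, self.trunk_channels)
        h1, h2 = self.head_channels
        total += 2 * (conv(self.trunk_channels, h1) + conv(h1, h2) + conv(h2, 1))
        return total


@dataclass
class TrainConfig:
    """Training recipe: Adam with exponentially decaying learning rate
    (initial 5e-5, x0.95 per epoch), at most 100 epochs, early stopping on
    validation loss with patience 10 and best-weight restore."""

    learning_rate: float = 5.0e-5
    lr_decay: float = 0.95
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 16
    seed: int = 0
    loss_weights: tuple = (1.0, 1.0)  # (depth, concentration) on normalized maps
    #: optional square random-crop side (pixels) for training batches; the
    #: network is fully convolutional, so crop-trained weights apply to full
    #: frames at prediction time.  None trains on full frames.
    crop_size: int | None = None
    #: epoch index from which to accumulate a stochastic weight average; the
    #: returned model carries the equal-weight mean of all epoch-end weights
    #: from this epoch on, which removes the sizeable epoch-to-epoch jitter
    #: of any single late checkpoint.  None keeps best-validation weights.
    swa_start: int | None = None


@dataclass
class DepthConcPrediction:
    """Predicted per-pixel depth (mm) and concentration (ug/mL) maps."""

    depth_mm: np.ndarray
    concentration: np.ndarray


# ---------------------------------------------------------------------------
# layers (channels-last float32)
# ---------------------------------------------------------------------------


class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class _Conv2d:
    """3 x 3 same-padding convolution via nine shifted matmuls.

    On a single CPU at these channel counts the BLAS-backed shifted-matmul
    formulation outperforms both an im2col single-matmul and fused direct
    loops, so it is the only implementation.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * cin))
        self.w = _Param(rng.normal(0.0, std, size=(3, 3, cin, cout)))
        self.b = _Param(np.zeros(cout))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, wdt, cin = x.shape
        self._x_pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.broadcast_to(self.b.value, (n, h, wdt, self.b.value.size)).copy()
        for dy in range(3):
            for dx in range(3):
                patch = self._x_pad[:, dy : dy + h, dx : dx + wdt, :]
                out += (patch.reshape(-1, cin) @ self.w.value[dy, dx]).reshape(out.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, wdt, cout = grad.shape
        cin = self.w.value.shape[2]
        g2 = grad.reshape(-1, cout)
        self.b.grad += g2.sum(axis=0)
        dx_pad = np.zeros_like(self._x_pad)
        for dy in range(3):
            for dx in range(3):
                patch = self._x_pad[:, dy : dy + h, dx : dx + wdt, :].reshape(-1, cin)
                self.w.grad[dy, dx] += patch.T @ g2
                dx_pad[:, dy : dy + h, dx : dx + wdt, :] += (
                    g2 @ self.w.value[dy, dx].T
                ).reshape(n, h, wdt, cin)
        self._x_pad = None
        return dx_pad[:, 1:-1, 1:-1, :]


class _DepthwiseConv:
    """3 x 3 per-channel (depthwise) convolution."""

    def __init__(self, c: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / 9.0)
        self.w = _Param(rng.normal(0.0, std, size=(3, 3, c)))
        self.b = _Param(np.zeros(c))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, wdt, c = x.shape
        self._x_pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.broadcast_to(self.b.value, x.shape).copy()
        for dy in range(3):
            for dx in range(3):
                out += self._x_pad[:, dy : dy + h, dx : dx + wdt, :] * self.w.value[dy, dx]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, wdt, c = grad.shape
        self.b.grad += grad.sum(axis=(0, 1, 2))
        dx_pad = np.zeros_like(self._x_pad)
        for dy in range(3):
            for dx in range(3):
                patch = self._x_pad[:, dy : dy + h, dx : dx + wdt, :]
                self.w.grad[dy, dx] += (patch * grad).sum(axis=(0, 1, 2))
                dx_pad[:, dy : dy + h, dx : dx + wdt, :] += grad * self.w.value[dy, dx]
        self._x_pad = None
        return dx_pad[:, 1:-1, 1:-1, :]


class _Pointwise:
    """1 x 1 convolution (per-pixel linear map across channels)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = _Param(rng.normal(0.0, std, size=(cin, cout)))
        self.b = _Param(np.zeros(cout))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cin, cout = self.w.value.shape
        self.w.grad += self._x.reshape(-1, cin).T @ grad.reshape(-1, cout)
        self.b.grad += grad.reshape(-1, cout).sum(axis=0)
        self._x = None
        return grad @ self.w.value.T


#: Negative-side slope of the rectifier activations.  A small leak keeps a
#: gradient path through inactive units; with a hard rectifier the reducing
#: heads can die wholesale early in training and never recover.
LEAKY_SLOPE = 0.1


class _ReLU:
    """Leaky rectifier (identical parameter count to a hard rectifier)."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, LEAKY_SLOPE * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, grad, LEAKY_SLOPE * grad)
        self._mask = None
        return out


class _Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)
        self.params = [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class _ResBlock:
    """Two convolutions with a skip connection: relu(x + conv(relu(conv(x))))."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.body = _Sequential(_Conv2d(c, c, rng), _ReLU(), _Conv2d(c, c, rng))
        self.out_relu = _ReLU()
        self.params = self.body.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.out_relu.forward(x + self.body.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.out_relu.backward(grad)
        return grad + self.body.backward(grad)


# ---------------------------------------------------------------------------
# the two-arm model
# ---------------------------------------------------------------------------


class SiameseCNN:
    """Two-arm convolutional regressor for depth + concentration maps."""

    def __init__(self, config: ModelConfig, seed: int = 0, strict: bool = False):
        count = config.parameter_count()
        if count != TARGET_PARAMETER_COUNT:
            msg = (
                f"configured schedule has {count:,} trainable parameters, "
                f"not the committed {TARGET_PARAMETER_COUNT:,}"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)
        self.config = config
        rng = np.random.default_rng(seed)
        p1, p2 = config.prop_channels
        f2, f3 = config.fluor_channels
        t = config.trunk_channels
        h1, h2 = config.head_channels
        self.prop_arm = _Sequential(
            _Conv2d(2, p1, rng), _ReLU(),
            _Conv2d(p1, p2, rng), _ReLU(),
            _ResBlock(p2, rng),
        )
        # the 3x3x6 volumetric entry spans the whole frequency axis, so after
        # the reshape it is algebraically a 2-D convolution over 6 channels
        self.fluor_arm = _Sequential(
            _Conv2d(config.n_fx, config.fluor_entry, rng), _ReLU(),
            _Conv2d(config.fluor_entry, f2, rng), _ReLU(),
            _Conv2d(f2, f3, rng), _ReLU(),
            _ResBlock(f3, rng),
        )
        self.trunk = _Sequential(
            _DepthwiseConv(p2 + f3, rng),
            _Pointwise(p2 + f3, t, rng), _ReLU(),
            _ResBlock(t, rng),
        )
        # the final convolution is linear: physical non-negativity is applied
        # as a clamp at prediction time (a rectifier here can silence the
        # head's gradient entirely early in training)
        self.depth_head = _Sequential(
            _Conv2d(t, h1, rng), _ReLU(),
            _Conv2d(h1, h2, rng), _ReLU(),
            _Conv2d(h2, 1, rng),
        )
        self.conc_head = _Sequential(
            _Conv2d(t, h1, rng), _ReLU(),
            _Conv2d(h1, h2, rng), _ReLU(),
            _Conv2d(h2, 1, rng),
        )
        self.params = (
            self.prop_arm.params
            + self.fluor_arm.params
            + self.trunk.params
            + self.depth_head.params
            + self.conc_head.params
        )
        self.normalizer: Normalizer | None = None

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.params)

    # -- forward/backward ---------------------------------------------------

    def forward(self, props: np.ndarray, fluor: np.ndarray) -> np.ndarray:
        """props (N, 2, H, W), fluor (N, n_fx, H, W) -> (N, 2, H, W) heads."""
        xp = np.ascontiguousarray(np.moveaxis(props, 1, -1), dtype=np.float32)
        xf = np.ascontiguousarray(np.moveaxis(fluor, 1, -1), dtype=np.float32)
        a = self.prop_arm.forward(xp)
        b = self.fluor_arm.forward(xf)
        self._split = a.shape[-1]
        z = self.trunk.forward(np.concatenate([a, b], axis=-1))
        d = self.depth_head.forward(z)
        c = self.conc_head.forward(z)
        return np.moveaxis(np.concatenate([d, c], axis=-1), -1, 1)

    def backward(self, grad: np.ndarray) -> None:
        g = np.moveaxis(grad, 1, -1).astype(np.float32)
        gz = self.depth_head.backward(g[..., :1]) + self.conc_head.backward(g[..., 1:])
        gab = self.trunk.backward(gz)
        self.prop_arm.backward(gab[..., : self._split])
        self.fluor_arm.backward(gab[..., self._split :])

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    # -- checkpointing ------------------------------------------------------

    def get_weights(self) -> list:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params, weights):
            p.value[...] = w

    def save(self, path) -> None:
        """Self-describing checkpoint: weights + config + normalization."""
        import json
        from dataclasses import asdict

        meta = {"config": asdict(self.config)}
        if self.normalizer is not None:
            meta["normalizer"] = self.normalizer.to_dict()
        arrays = {f"p{i:04d}": p.value for i, p in enumerate(self.params)}
        np.savez_compressed(
            path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays
        )

    @classmethod
    def load(cls, path) -> "SiameseCNN":
        import json

        with np.load(path) as f:
            meta = json.loads(f["meta"].tobytes().decode())
            cfg = meta["config"]
            cfg["prop_channels"] = tuple(cfg["prop_channels"])
            cfg["fluor_channels"] = tuple(cfg["fluor_channels"])
            cfg["head_channels"] = tuple(cfg["head_channels"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = cls(ModelConfig(**cfg))
            model.set_weights([f[f"p{i:04d}"] for i in range(len(model.params))])
            if meta.get("normalizer"):
                model.normalizer = Normalizer.from_dict(meta["normalizer"])
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0, strict: bool = False) -> SiameseCNN:
    """Instantiate the two-arm network under the given filter schedule."""
    return SiameseCNN(config or ModelConfig(), seed=seed, strict=strict)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.value -= self.lr * corr * m / (np.sqrt(v) + self.eps)


def _composite_loss(pred, target, weights):
    """Weighted MSE over the two normalized heads; returns (loss, grad)."""
    diff = (pred - target).astype(np.float32)
    w = np.array(weights, dtype=np.float32).reshape(1, 2, 1, 1)
    n = diff[:, 0].size
    loss = float((w * diff**2).sum() / n)
    grad = 2.0 * w * diff / n
    return loss, grad


def train(
    model: SiameseCNN,
    manifest: DatasetManifest,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> dict:
    """Optimize the model on a manifest's train split; early-stop on val loss.

    Returns a history dict with per-epoch train/val losses; the model is left
    holding the best-validation weights.
    """
    config = config or TrainConfig()
    xp_tr, xf_tr, y_tr = manifest_to_arrays(manifest, "train")
    xp_va, xf_va, y_va = manifest_to_arrays(manifest, "val")
    model.normalizer = manifest.normalizer
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, model.get_weights(), -1)
    swa_sum, swa_count = None, 0
    n = xp_tr.shape[0]
    for epoch in range(config.max_epochs):
        opt.lr = config.learning_rate * config.lr_decay**epoch
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            bp, bf, by = xp_tr[idx], xf_tr[idx], y_tr[idx]
            if config.crop_size is not None:
                c = config.crop_size
                y0 = rng.integers(0, bp.shape[2] - c + 1)
                x0 = rng.integers(0, bp.shape[3] - c + 1)
                bp = bp[:, :, y0 : y0 + c, x0 : x0 + c]
                bf = bf[:, :, y0 : y0 + c, x0 : x0 + c]
                by = by[:, :, y0 : y0 + c, x0 : x0 + c]
            pred = model.forward(bp, bf)
            loss, grad = _composite_loss(pred, by, config.loss_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step()
            total += loss * idx.size
        train_loss = total / n
        val_loss = _evaluate_loss(model, xp_va, xf_va, y_va, config)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch:3d}: train {train_loss:.5f} val {val_loss:.5f}", flush=True)
        if config.swa_start is not None and epoch >= config.swa_start:
            w = model.get_weights()
            if swa_sum is None:
                swa_sum = w
            else:
                for s, v in zip(swa_sum, w):
                    s += v
            swa_count += 1
        if val_loss < best[0]:
            best = (val_loss, model.get_weights(), epoch)
        elif epoch - best[2] >= config.patience:
            break
    if swa_count:
        model.set_weights([s / swa_count for s in swa_sum])
        history["swa_epochs"] = swa_count
    else:
        model.set_weights(best[1])
    history["best_epoch"] = best[2]
    history["best_val_loss"] = best[0]
    return history


def _evaluate_loss(model, xp, xf, y, config) -> float:
    if xp.shape[0] == 0:
        return np.nan
    total = 0.0
    for start in range(0, xp.shape[0], config.batch_size):
        sl = slice(start, start + config.batch_size)
        pred = model.forward(xp[sl], xf[sl])
        loss, _ = _composite_loss(pred, y[sl], config.loss_weights)
        total += loss * (min(start + config.batch_size, xp.shape[0]) - start)
    return total / xp.shape[0]


def predict(
    model: SiameseCNN,
    props: np.ndarray,
    fluor: np.ndarray,
    flip_average: bool = False,
) -> DepthConcPrediction:
    """Denormalized, non-negative depth/concentration maps for one sample.

    ``props``/``fluor`` are the normalized network inputs of shape
    (2, H, W) and (n_fx, H, W).  With ``flip_average`` the prediction is the
    mean over the four lateral mirror images (the physics is
    mirror-symmetric, so averaging the flips only removes estimator
    variance).
    """
    if model.normalizer is None:
        raise ValueError("model has no normalization constants; train or load first")
    if props.shape[0] != 2 or fluor.shape[0] != model.config.n_fx:
        raise ValueError("input channel counts do not match the model config")
    flips = [(False, False)]
    if flip_average:
        flips = [(fy, fx) for fy in (False, True) for fx in (False, True)]
    acc = None
    for fy, fx in flips:
        p, f = props, fluor
        if fy:
            p, f = p[:, ::-1], f[:, ::-1]
        if fx:
            p, f = p[:, :, ::-1], f[:, :, ::-1]
        out = model.forward(
            np.ascontiguousarray(p)[None], np.ascontiguousarray(f)[None]
        )[0]
        if fx:
            out = out[:, :, ::-1]
        if fy:
            out = out[:, ::-1]
        acc = out if acc is None else acc + out
    depth, conc = model.normalizer.denormalize_targets(acc / len(flips))
    return DepthConcPrediction(
        depth_mm=np.maximum(depth, 0.0), concentration=np.maximum(conc, 0.0)
    )
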