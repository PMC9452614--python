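"""Small from-scratch CNN baseline on 2D lesion crops.

The network is the classic compact topology for small binary imaging
problems: three blocks of [3x3 convolution -> batch normalisation ->
ReLU -> 2x2 max pooling -> dropout], a flatten, a dense layer of 32
ReLU units, a final dropout and a single sigmoid output giving the
malignancy probability.  It trains with Adam on class-weighted binary
cross-entropy, with simple flip/zoom/rotate/shift augmentation.

The whole engine is NumPy: layers implement ``forward``/``backward``
explicitly, which keeps the model runnable on a single CPU and makes
the training loop fully deterministic given a seed.  Slices from one
case always share a CV fold, and a case's score is the mean of its
slice probabilities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from lipomics.evaluate import CVPlan


# ----------------------------------------------------------------------
# layers


class Conv2D:
    """3x3 same-padding convolution, stride 1, via one im2col matmul."""

    name = "conv"

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (n, c, h, w, 3, 3) -> (n*h*w, c*9)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        self._cols = np.ascontiguousarray(cols)
        self._shape = (n, c, h, w)
        out = self._cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        f = dout.shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.dW = (dflat.T @ self._cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        self.grads = [self.dW, self.db]
        dcols = dflat @ self.W.reshape(f, -1)  # (n*h*w, c*9)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm:
    name = "batchnorm"

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._shape = shape
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        self._m = x.size // x.shape[1]
        self._training = training
        return self.gamma.reshape(shape) * self._xhat + self.beta.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape = self._shape
        axes = (0, 2, 3) if dout.ndim == 4 else (0,)
        self.dgamma = (dout * self._xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        self.grads = [self.dgamma, self.dbeta]
        dxhat = dout * self.gamma.reshape(shape)
        if not self._training:
            return dxhat / self._std.reshape(shape)
        m = self._m
        return (
            dxhat - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)
        ) / self._std.reshape(shape)


class ReLU:
    name = "relu"
    params: list = []

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        self.grads = []
        return dout * self._mask


class MaxPool2x2:
    name = "maxpool"
    params: list = []

    def forward(self, x, training):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._inshape = x.shape
        return out

    def backward(self, dout):
        self.grads = []
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        d = self._mask * dout[:, :, :, None, :, None]
        # split ties evenly
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        d = d / counts
        dx = np.zeros(self._inshape, dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = d.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class Dropout:
    name = "dropout"
    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        self.grads = []
        return dout if self._mask is None else dout * self._mask


class Flatten:
    name = "flatten"
    params: list = []

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        self.grads = []
        return dout.reshape(self._shape)


class Dense:
    name = "dense"

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias_init: float = 0.0):
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32)
        # a small positive bias before a ReLU guards against dying units
        self.b = np.full(d_out, bias_init, dtype=np.float32)
        self.params = [("W", self.W), ("b", self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self.grads = [self.dW, self.db]
        return dout @ self.W.T


# ----------------------------------------------------------------------
# model


@dataclasses.dataclass(frozen=True)
class CNNConfig:
    input_size: int = 224
    widths: tuple[int, int, int] = (4, 8, 16)
    dropout_conv: float = 0.25
    dropout_dense: float = 0.5
    dense_units: int = 32
    optimizer: str = "sgd"  # 'sgd' (momentum 0.9) or 'adam'
    learning_rate: float = 1e-2
    adam_eps: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 10


class SmallCNN:
    """3 x [conv -> batchnorm -> ReLU -> maxpool -> dropout] -> flatten
    -> dense(32, ReLU) -> dropout -> dense(1, sigmoid)."""

    def __init__(self, config: CNNConfig | None = None, seed: int = 0):
        self.config = cfg = config or CNNConfig()
        self.rng = np.random.default_rng(seed)
        c_in = 1
        size = cfg.input_size
        self.layers: list = []
        for w in cfg.widths:
            self.layers += [
                Conv2D(c_in, w, self.rng),
                BatchNorm(w),
                ReLU(),
                MaxPool2x2(),
                Dropout(cfg.dropout_conv, self.rng),
            ]
            c_in = w
            size //= 2
        self.layers += [
            Flatten(),
            Dense(size * size * c_in, cfg.dense_units, self.rng, bias_init=0.1),
            ReLU(),
            Dropout(cfg.dropout_dense, self.rng),
            Dense(cfg.dense_units, 1, self.rng),
        ]
        self._adam_state: dict | None = None

    # -- introspection ------------------------------------------------
    def layer_names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    # -- forward/backward ---------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x.astype(np.float32)
        if h.ndim == 3:
            h = h[:, None]
        for lyr in self.layers:
            h = lyr.forward(h, training)
        return 1.0 / (1.0 + np.exp(-h[:, 0]))  # sigmoid probability

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return np.concatenate(
            [self.forward(x[i : i + batch_size], training=False) for i in range(0, len(x), batch_size)]
        )

    def train_step(self, x: np.ndarray, y: np.ndarray, class_weights: dict[int, float]) -> float:
        p = self.forward(x, training=True)
        y = y.astype(np.float32)
        w = np.where(y == 1, class_weights[1], class_weights[0]).astype(np.float32)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-(w * (y * np.log(pc) + (1 - y) * np.log(1 - pc))).mean())
        # d loss / d logit for sigmoid + weighted BCE
        dlogit = (w * (p - y) / len(y)).astype(np.float32)[:, None]
        d = dlogit
        for lyr in reversed(self.layers):
            d = lyr.backward(d)
        if self.config.optimizer == "adam":
            self._adam_update()
        else:
            self._sgd_update()
        return loss

    def _sgd_update(self):
        params, grads = [], []
        for lyr in self.layers:
            if lyr.params:
                for (_, p), g in zip(lyr.params, lyr.grads):
                    params.append(p)
                    grads.append(g)
        if self._adam_state is None:
            self._adam_state = {"t": 0, "m": [np.zeros_like(p) for p in params], "v": None}
        st = self._adam_state
        st["t"] += 1
        lr, mom = self.config.learning_rate, self.config.momentum
        for i, (p, g) in enumerate(zip(params, grads)):
            st["m"][i] = mom * st["m"][i] + g
            p -= lr * st["m"][i]

    def _adam_update(self, beta1=0.9, beta2=0.999, eps=None):
        # a fairly large default epsilon damps the per-parameter step
        # normalization on near-zero gradients; with tiny batches and
        # dropout noise the tighter classic value lets coherent micro-
        # gradients silence whole layers (constant-output collapse)
        if eps is None:
            eps = self.config.adam_eps
        params, grads = [], []
        for lyr in self.layers:
            if lyr.params:
                for (_, p), g in zip(lyr.params, lyr.grads):
                    params.append(p)
                    grads.append(g)
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        lr = self.config.learning_rate
        for i, (p, g) in enumerate(zip(params, grads)):
            st["m"][i] = beta1 * st["m"][i] + (1 - beta1) * g
            st["v"][i] = beta2 * st["v"][i] + (1 - beta2) * g * g
            mhat = st["m"][i] / (1 - beta1 ** st["t"])
            vhat = st["v"][i] / (1 - beta2 ** st["t"])
            p -= lr * mhat / (np.sqrt(vhat) + eps)


# ----------------------------------------------------------------------
# augmentation


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    flip: bool = True
    zoom: float = 0.10
    rotate_deg: float = 15.0
    shift: float = 0.10


def augment(image: np.ndarray, seed_or_rng, config: AugmentConfig | None = None) -> np.ndarray:
    """Random flip/zoom/rotate/shift of a 2D image, shape-preserving.

    Deterministic per seed; with all ranges zero and ``flip=False`` the
    image is returned unchanged.
    """
    cfg = config or AugmentConfig()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = np.asarray(image, dtype=np.float64)
    if cfg.flip:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if cfg.rotate_deg > 0:
        ang = rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)
        out = ndimage.rotate(out, ang, reshape=False, order=1, mode="reflect")
    if cfg.zoom > 0:
        z = rng.uniform(1.0 - cfg.zoom, 1.0 + cfg.zoom)
        h, w = out.shape
        zoomed = ndimage.zoom(out, z, order=1, mode="reflect")
        if zoomed.shape[0] >= h:
            y0 = (zoomed.shape[0] - h) // 2
            x0 = (zoomed.shape[1] - w) // 2
            out = zoomed[y0 : y0 + h, x0 : x0 + w]
        else:
            py = h - zoomed.shape[0]
            px = w - zoomed.shape[1]
            out = np.pad(zoomed, ((py // 2, py - py // 2), (px // 2, px - px // 2)), mode="reflect")
    if cfg.shift > 0:
        h, w = out.shape
        dy = rng.uniform(-cfg.shift, cfg.shift) * h
        dx = rng.uniform(-cfg.shift, cfg.shift) * w
        out = ndimage.shift(out, (dy, dx), order=1, mode="reflect")
    return np.ascontiguousarray(out)


# ----------------------------------------------------------------------
# training


def class_weights_from(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights normalized to mean 1 over slices."""
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    w = {}
    for c in (0, 1):
        nc = int((labels == c).sum())
        if nc == 0:
            raise ValueError(f"class {c} absent")
        w[c] = n / (2.0 * nc)
    return w


def fit_cnn(
    images: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
    seed: int = 0,
    augment_config: AugmentConfig | None = None,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    target_train_accuracy: float | None = None,
) -> tuple[SmallCNN, dict]:
    """Train the small CNN on z-scored slices.

    Early stopping watches validation loss when a validation set is
    given, else training loss; ``target_train_accuracy`` additionally
    stops as soon as the (clean-pass) training accuracy reaches it.
    Returns the model and a history dict.
    """
    cfg = config or CNNConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC11]))
    model = SmallCNN(cfg, seed=seed)
    cw = class_weights_from(labels)
    n = len(images)
    majority = max((labels == 1).mean(), (labels == 0).mean())
    history = {"loss": [], "train_accuracy": [], "val_loss": [], "restarts": 0}
    best, wait = np.inf, 0
    restarts = 0
    accs_since_restart: list[float] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            batch = np.stack(
                [
                    augment(images[j], rng, augment_config) if augment_config else images[j]
                    for j in idx
                ]
            )
            losses.append(model.train_step(batch, labels[idx], cw))
        history["loss"].append(float(np.mean(losses)))
        acc = float(((model.predict_proba(images) >= 0.5).astype(int) == labels).mean())
        history["train_accuracy"].append(acc)
        accs_since_restart.append(acc)
        if target_train_accuracy is not None and acc >= target_train_accuracy:
            break
        # tiny nets occasionally fall into a constant-output basin
        # (every unit of the dense layer silenced); detect the stall and
        # reinitialize rather than burn the remaining epochs there
        if (
            len(accs_since_restart) >= 6
            and restarts < 3
            and max(accs_since_restart[-6:]) <= majority + 0.08
        ):
            restarts += 1
            history["restarts"] = restarts
            model = SmallCNN(cfg, seed=seed + 1000 * restarts)
            best, wait = np.inf, 0
            accs_since_restart = []
            continue
        if val_images is not None:
            pv = np.clip(model.predict_proba(val_images), 1e-7, 1 - 1e-7)
            vl = float(-np.mean(val_labels * np.log(pv) + (1 - val_labels) * np.log(1 - pv)))
            history["val_loss"].append(vl)
            monitor = vl
        else:
            monitor = history["loss"][-1]
        if monitor < best - 1e-4:
            best, wait = monitor, 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    return model, history


def train_cnn_cv(
    images: np.ndarray,
    case_ids: np.ndarray,
    labels: np.ndarray,
    plan: CVPlan,
    config: CNNConfig | None = None,
    seed: int = 0,
    augment_config: AugmentConfig | None = None,
) -> pd.DataFrame:
    """Grouped cross-validation of the CNN at slice level.

    Slices of one case always share a fold (taken from ``plan``); the
    held-out case score is the mean of its slice probabilities.
    Returns a case-level DataFrame with columns case_id, label, fold,
    score.
    """
    case_ids = np.asarray(case_ids)
    labels = np.asarray(labels).astype(int)
    fold = plan.fold_of(case_ids)
    rows = []
    for f in sorted(set(fold)):
        tr, te = fold != f, fold == f
        if len(np.unique(labels[tr])) < 2:
            raise ValueError(f"training folds for fold {f} contain a single class")
        model, _ = fit_cnn(
            images[tr], labels[tr], config=config, seed=seed, augment_config=augment_config
        )
        probs = model.predict_proba(images[te])
        df = pd.DataFrame({"case_id": case_ids[te], "label": labels[te], "score": probs})
        for cid, grp in df.groupby("case_id"):
            rows.append(
                {
                    "case_id": cid,
                    "label": int(grp.label.iloc[0]),
                    "fold": int(f),
                    "score": float(grp.score.mean()),
                }
            )
    return pd.DataFrame(rows)
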