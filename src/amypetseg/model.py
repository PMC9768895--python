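"""The 2D U-Net and its scikit-learn style estimator wrapper.

The network is the classic encoder-decoder with skip concatenation: each
contracting stage applies two same-padded 3x3 convolutions with element-wise
ReLU followed by 2x2 max pooling; the expanding path upsamples with 2x2
stride-2 transposed convolutions, concatenates the skip features from the
matching encoder stage, and applies two more 3x3 conv+ReLU pairs; a final
1x1 convolution maps the features to two classes (lesion / background), and a
per-pixel softmax turns the scores into a probability map.

The default test-scale configuration is depth 2 / base 8, which has the
standard 11 convolutional layers (4 encoder + 2 bottleneck + 4 decoder + 1
final); channel widths are this package's choice.

:class:`UNetSegmenter` wraps network construction and Adam training behind
the scikit-learn estimator protocol (``fit`` / ``predict`` /
``predict_proba`` / ``score``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore) so it composes with sklearn model
selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import losses
from .nn import Adam, Conv2d, ConvTranspose2d, MaxPool2d, Param, ReLU
from .preprocess import augment, sample_augmentation

__all__ = ["UNetConfig", "UNet", "build_unet", "forward", "UNetSegmenter",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of pooling stages; input spatial dims must be
    divisible by ``2**depth``.  ``n_classes`` is fixed at 2 (lesion vs
    background).
    """

    depth: int = 2
    base_channels: int = 8
    in_channels: int = 1
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.n_classes != 2:
            raise ValueError("the segmenter is two-class (lesion vs background)")


class UNet:
    """Encoder-decoder network assembled from the NumPy primitives."""

    def __init__(self, cfg: UNetConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool2d] = []
        in_ch = cfg.in_channels
        for i in range(cfg.depth):
            ch = c * 2**i
            self.enc_blocks.append(
                [
                    Conv2d(in_ch, ch, rng=rng, name=f"enc{i}.conv1"),
                    ReLU(),
                    Conv2d(ch, ch, rng=rng, name=f"enc{i}.conv2"),
                    ReLU(),
                ]
            )
            self.pools.append(MaxPool2d())
            in_ch = ch
        bch = c * 2**cfg.depth
        self.bottleneck = [
            Conv2d(in_ch, bch, rng=rng, name="bottleneck.conv1"),
            ReLU(),
            Conv2d(bch, bch, rng=rng, name="bottleneck.conv2"),
            ReLU(),
        ]
        self.upconvs: list[ConvTranspose2d] = []
        self.dec_blocks: list[list] = []
        for i in reversed(range(cfg.depth)):
            ch = c * 2**i
            self.upconvs.append(ConvTranspose2d(ch * 2, ch, rng=rng, name=f"up{i}"))
            self.dec_blocks.append(
                [
                    Conv2d(ch * 2, ch, rng=rng, name=f"dec{i}.conv1"),
                    ReLU(),
                    Conv2d(ch, ch, rng=rng, name=f"dec{i}.conv2"),
                    ReLU(),
                ]
            )
        self.final = Conv2d(c, cfg.n_classes, kernel_size=1, rng=rng, name="final")

    # -- introspection -------------------------------------------------
    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for block in self.enc_blocks:
            for layer in block:
                params.extend(layer.params)
        for layer in self.bottleneck:
            params.extend(layer.params)
        for up, block in zip(self.upconvs, self.dec_blocks):
            params.extend(up.params)
            for layer in block:
                params.extend(layer.params)
        params.extend(self.final.params)
        return params

    def parameter_count(self) -> int:
        """Total number of trainable scalars."""
        return sum(p.size for p in self.parameters())

    def conv_layer_count(self) -> int:
        """Number of (non-transposed) convolutional layers."""
        return 4 * self.cfg.depth + 2 + 1

    # -- forward / backward --------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N, {self.cfg.in_channels}, H, W), got {x.shape}")
        div = 2**self.cfg.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims {x.shape[2]}x{x.shape[3]} must be divisible by {div}"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return per-pixel class logits of shape (N, n_classes, H, W)."""
        x = self._check_input(x)
        self._skips = []
        h = x
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h)
            self._skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(self._skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=1)
            for layer in block:
                h = layer.forward(h)
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the logits; accumulates into params."""
        g = self.final.backward(dlogits)
        skip_grads: list[np.ndarray] = []
        for up, block in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            for layer in reversed(block):
                g = layer.backward(g)
            n_skip = g.shape[1] // 2
            skip_grads.append(g[:, :n_skip])
            g = up.backward(g[:, n_skip:])
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # skip_grads were collected shallowest-first; encoders unwind deepest-first
        for pool, block, sg in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = g + sg
            for layer in reversed(block):
                g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax probability maps, (N, n_classes, H, W); sums to 1 per pixel."""
        return losses.softmax(self.forward(x), axis=1)

    # -- state ----------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            if p.value.shape != v.shape:
                raise ValueError("checkpoint does not match architecture")
            p.value[...] = v


def build_unet(cfg: UNetConfig) -> UNet:
    """Construct a seeded U-Net from its configuration."""
    return UNet(cfg)


def forward(network: UNet, batch: np.ndarray) -> np.ndarray:
    """Probability maps for a batch of slices (softmax over the class axis)."""
    return network.predict_proba(batch)


def save_checkpoint(network: UNet, path) -> None:
    """Persist weights with the architecture config embedded."""
    path = Path(path)
    arrays = {f"param_{i}": v for i, v in enumerate(network.get_state())}
    np.savez(path, config=json.dumps(asdict(network.cfg)), **arrays)


def load_checkpoint(path) -> UNet:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"),
                 allow_pickle=False) as data:
        cfg = UNetConfig(**json.loads(str(data["config"])))
        net = UNet(cfg)
        n = len(net.parameters())
        net.set_state([data[f"param_{i}"] for i in range(n)])
    return net


def _binary_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.count_nonzero(pred & truth)
    union = np.count_nonzero(pred | truth)
    return 1.0 if union == 0 else inter / union


class UNetSegmenter(BaseEstimator):
    """Two-class amyloid-lesion segmenter trained with the soft-IoU loss.

    Parameters
    ----------
    depth, base_channels
        U-Net architecture (see :class:`UNetConfig`).
    learning_rate, batch_size, max_epochs
        Adam optimization budget.  The clinical-scale defaults are a learning
        rate of 1e-5, batch size 4 and up to 2000 epochs; desk-scale phantom
        runs use a larger rate and far fewer epochs.
    augment_data
        Apply one randomly sampled geometric augmentation (rotation,
        translation, shear within the stated ranges) to each training slice
        per epoch, online.
    standardize_inputs
        Normalize inputs to the mean/std of the training set; the fitted
        statistics (``mean_``, ``std_``) are reused at prediction time.
    early_stopping_patience
        Stop when validation IoU has not improved for this many epochs
        (None disables; the clinical procedure trains the full budget).
    random_state
        Seeds weight init, batching and augmentation; fits are reproducible.

    Attributes
    ----------
    network_ : UNet
        The trained network (best-validation weights when a validation set
        was given).
    history_ : pandas.DataFrame
        Per-epoch train/validation loss and IoU.
    mean_, std_ : float
        Training-set intensity statistics.
    n_parameters_ : int
        Trainable parameter count.
    """

    def __init__(
        self,
        depth: int = 2,
        base_channels: int = 8,
        learning_rate: float = 1e-5,
        batch_size: int = 4,
        max_epochs: int = 2000,
        augment_data: bool = False,
        standardize_inputs: bool = True,
        early_stopping_patience: int | None = None,
        random_state: int = 0,
    ) -> None:
        self.depth = depth
        self.base_channels = base_channels
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.augment_data = augment_data
        self.standardize_inputs = standardize_inputs
        self.early_stopping_patience = early_stopping_patience
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be (n_slices, H, W), got shape {X.shape}")
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape:
                raise ValueError("X and y shapes differ")
            if not np.all(np.isin(np.unique(y), (0, 1))):
                raise ValueError("y must be binary masks")
            y = y.astype(np.float64)
        return X, y

    def _batch_loss_and_grad(self, logits: np.ndarray, g: np.ndarray):
        """Mean per-slice soft-IoU loss and gradient w.r.t. the logits."""
        p = losses.softmax(logits, axis=1)
        n = logits.shape[0]
        loss = 0.0
        dp = np.zeros_like(p)
        for i in range(n):
            loss += losses.iou_loss(p[i, 1], g[i])
            dp[i, 1] = losses.iou_loss_grad(p[i, 1], g[i]) / n
        # softmax backward: dz = p * (dp - sum_c dp_c p_c)
        dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
        return loss / n, dz

    def _epoch_pass(self, net, opt, X, y, rng):
        order = rng.permutation(len(X))
        losses_acc, ious_acc = [], []
        for start in range(0, len(order), self.batch_size):
            idx = order[start : start + self.batch_size]
            xb, yb = X[idx], y[idx]
            if self.augment_data:
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    params = sample_augmentation(rng)
                    xi, yi = augment(xb[j], yb[j], params)
                    xb[j], yb[j] = xi, yi.astype(np.float64)
            logits = net.forward(xb)
            loss, dz = self._batch_loss_and_grad(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at step {opt.t}; "
                    "lower the learning rate or check input scaling"
                )
            opt.zero_grad()
            net.backward(dz)
            opt.step()
            pred = losses.softmax(logits, axis=1)[:, 1] > 0.5
            for j in range(len(idx)):
                ious_acc.append(_binary_iou(pred[j], yb[j] > 0.5))
            losses_acc.append(loss * len(idx))
        return float(np.sum(losses_acc) / len(order)), float(np.mean(ious_acc))

    def _evaluate(self, net, X, y):
        loss_sum, ious = 0.0, []
        for start in range(0, len(X), max(self.batch_size, 8)):
            xb = X[start : start + max(self.batch_size, 8)]
            yb = y[start : start + max(self.batch_size, 8)]
            p = net.predict_proba(xb)
            for j in range(len(xb)):
                loss_sum += losses.iou_loss(p[j, 1], yb[j])
                ious.append(_binary_iou(p[j, 1] > 0.5, yb[j] > 0.5))
        return loss_sum / len(X), float(np.mean(ious))

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (slices, masks); optionally track a validation split."""
        import pandas as pd

        X, y = self._validate_xy(X, y)
        if len(X) == 0:
            raise ValueError("empty training set")
        have_val = X_val is not None
        if have_val:
            X_val, y_val = self._validate_xy(X_val, y_val)

        if self.standardize_inputs:
            self.mean_ = float(X.mean())
            self.std_ = float(X.std())
            if self.std_ <= 0:
                raise ValueError("training set has zero intensity variance")
        else:
            self.mean_, self.std_ = 0.0, 1.0
        Xs = (X - self.mean_) / self.std_
        Xvs = (X_val - self.mean_) / self.std_ if have_val else None

        cfg = UNetConfig(
            depth=self.depth, base_channels=self.base_channels, seed=self.random_state
        )
        net = build_unet(cfg)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state + 1)

        rows = []
        best_state, best_val, best_epoch = None, -np.inf, -1
        stale = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-vs-empty IoU warnings in-loop
            for epoch in range(self.max_epochs):
                tr_loss, tr_iou = self._epoch_pass(net, opt, Xs, y, rng)
                row = {"epoch": epoch, "train_loss": tr_loss, "train_iou": tr_iou}
                if have_val:
                    va_loss, va_iou = self._evaluate(net, Xvs, y_val)
                    row |= {"val_loss": va_loss, "val_iou": va_iou}
                    if va_iou > best_val:
                        best_val, best_state, best_epoch = va_iou, net.get_state(), epoch
                        stale = 0
                    else:
                        stale += 1
                        if (
                            self.early_stopping_patience is not None
                            and stale >= self.early_stopping_patience
                        ):
                            rows.append(row)
                            break
                rows.append(row)

        if have_val and best_state is not None:
            net.set_state(best_state)
        self.network_ = net
        self.history_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch if have_val else (self.max_epochs - 1)
        self.n_parameters_ = net.parameter_count()
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probability maps, shape (n, 2, H, W)."""
        self._check_fitted()
        X, _ = self._validate_xy(X)
        Xs = (X - self.mean_) / self.std_
        out = []
        for start in range(0, len(Xs), 16):
            out.append(self.network_.predict_proba(Xs[start : start + 16]))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Binary lesion masks (foreground probability > 0.5)."""
        return self.predict_proba(X)[:, 1] > 0.5

    def score(self, X, y) -> float:
        """Mean per-slice IoU against the gold-standard masks."""
        _, y = self._validate_xy(X, y)
        pred = self.predict(X)
        return float(np.mean([_binary_iou(pred[i], y[i] > 0.5) for i in range(len(y))]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("this UNetSegmenter instance is not fitted yet")
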