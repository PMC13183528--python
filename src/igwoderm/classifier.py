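"""Compact CNN classifier for lesion images, with the training protocol.

Architecture: three convolutional blocks (3x3 kernels, same padding, ReLU,
2x2 max-pool with floor division) with ``f1, f2, f3`` filters, then flatten,
a 128-unit ReLU dense layer, dropout and a softmax output — the standard
small backbone for binary dermoscopy classification.  Training minimises
class-weighted categorical cross-entropy (weights inversely proportional to
class frequency, ``w_c = n / (k * n_c)``), optionally plus an L2 weight
penalty ``wp/2 * sum(omega^2)``, with RMSprop (lr 1e-3, rho 0.9, eps 1e-7),
batch size 32, and early stopping on validation loss with a patience window;
the best-validation checkpoint is restored.

The network is implemented directly in numpy (im2col convolutions with
manual backpropagation), sized for desk-scale experiments (32x32 inputs by
default; the full-scale protocol uses 225x225).  :class:`CNNClassifier`
exposes the scikit-learn estimator API, so it composes with pipelines and
model selection.

The module also houses the dataset plumbing the protocol requires:
patient-grouped stratified train/val/test splitting, patient-grouped k-fold
cross-validation, inverse-frequency class weights and the sum-of-squares
prediction error metric.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedGroupKFold

__all__ = [
    "CNNHyperparams",
    "CNNArchitecture",
    "TrainConfig",
    "CNNClassifier",
    "build_cnn",
    "count_parameters",
    "class_weights",
    "split_dataset",
    "kfold_patient",
    "softmax",
    "cnn_error",
]

FILTER_BOUNDS = (16, 256)
DROPOUT_BOUNDS = (0.2, 0.8)


@dataclass(frozen=True)
class CNNHyperparams:
    """Searchable hyperparameters: three filter counts and the dropout rate."""

    f1: int
    f2: int
    f3: int
    d: float

    def __post_init__(self) -> None:
        for f in (self.f1, self.f2, self.f3):
            if not (isinstance(f, (int, np.integer)) and
                    FILTER_BOUNDS[0] <= f <= FILTER_BOUNDS[1]):
                raise ValueError(f"filter counts must be integers in {FILTER_BOUNDS}")
        if not DROPOUT_BOUNDS[0] <= self.d <= DROPOUT_BOUNDS[1]:
            raise ValueError(f"dropout must lie in {DROPOUT_BOUNDS}")

    @property
    def filters(self) -> tuple[int, int, int]:
        return (int(self.f1), int(self.f2), int(self.f3))


def count_parameters(filters, input_size=(225, 225, 3), dense_units: int = 128,
                     n_classes: int = 2) -> int:
    """Closed-form trainable parameter count of the architecture.

    Per conv block: ``9 * c_in * f + f`` (3x3 kernels, same padding), spatial
    dims floor-halved by each pool; then ``flat * dense + dense`` and the
    output layer.
    """
    h, w, c = input_size
    total = 0
    for f in filters:
        total += 9 * c * f + f
        c = f
        h //= 2
        w //= 2
    flat = h * w * c
    total += flat * dense_units + dense_units
    total += dense_units * n_classes + n_classes
    return total


@dataclass(frozen=True)
class CNNArchitecture:
    """Static description of the network for a hyperparameter choice."""

    input_size: tuple[int, int, int]
    filters: tuple[int, int, int]
    dropout: float
    dense_units: int
    n_classes: int
    param_count: int


def build_cnn(h: CNNHyperparams, input_size=(225, 225, 3),
              dense_units: int = 128, n_classes: int = 2) -> CNNArchitecture:
    """Architecture description for hyperparameters ``h``.

    Raises if the input is too small for three 2x2 pooling stages.
    """
    if len(input_size) == 2:
        input_size = (*input_size, 1)
    if input_size[0] // 8 < 1 or input_size[1] // 8 < 1:
        raise ValueError("input too small for three 2x2 pooling stages")
    return CNNArchitecture(
        input_size=tuple(input_size), filters=h.filters, dropout=float(h.d),
        dense_units=dense_units, n_classes=n_classes,
        param_count=count_parameters(h.filters, input_size, dense_units, n_classes))


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol settings (RMSprop, batching, early stopping)."""

    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    batch_size: int = 32
    epochs: int = 50
    patience: int = 10
    weight_penalty: float = 0.0
    class_weighted: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.weight_penalty < 0 or self.patience < 0:
            raise ValueError("weight_penalty and patience must be non-negative")


def class_weights(labels) -> dict:
    """Inverse-frequency class weights ``w_c = n_total / (k * n_c)``.

    The weighted mean of per-sample weights is exactly 1.  Raises if only one
    class is present.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("class weighting requires at least two classes")
    n = labels.size
    k = classes.size
    return {c: n / (k * cnt) for c, cnt in zip(classes, counts)}


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax ``y_j = exp(g_j) / sum_i exp(g_i)``."""
    g = np.asarray(logits, dtype=float)
    g = g - g.max(axis=-1, keepdims=True)
    e = np.exp(g)
    return e / e.sum(axis=-1, keepdims=True)


def cnn_error(pred, targets) -> float:
    """Sum-of-squares prediction error ``E = (1/T) sum_i sum_j (f_ji - y_ji)^2``.

    ``pred`` holds per-sample class probabilities; ``targets`` may be one-hot
    rows or integer class indices.
    """
    y = np.asarray(pred, dtype=float)
    f = np.asarray(targets)
    if f.ndim == 1:
        onehot = np.zeros_like(y)
        onehot[np.arange(f.size), f.astype(int)] = 1.0
        f = onehot
    if f.shape != y.shape:
        raise ValueError("prediction and target shapes differ")
    return float(((f - y) ** 2).sum() / y.shape[0])


# ---------------------------------------------------------------------------
# dataset splitting


def split_dataset(records: pd.DataFrame, ratios=(0.70, 0.15, 0.15),
                  seed: int | None = None) -> pd.DataFrame:
    """Patient-grouped stratified train/val/test split.

    Whole patients are assigned to splits by a relative-need allocator in
    the spirit of iterative stratification: patients carrying the rare
    malignant class are placed first, each going to the split with the
    largest relative malignant deficit; the remaining patients then fill the
    split with the largest relative image-count deficit.  No patient
    straddles splits.  Returns a copy of ``records`` with a ``split`` column
    in {train, val, test}.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size != 3 or abs(ratios.sum() - 1.0) > 1e-9 or (ratios <= 0).any():
        raise ValueError("ratios must be three positive numbers summing to 1")
    if not {"label", "patient_id"} <= set(records.columns):
        raise ValueError("records need 'label' and 'patient_id' columns")
    groups = records.groupby("patient_id")
    stats = pd.DataFrame({
        "n": groups.size(),
        "n_mal": groups["label"].apply(lambda s: int((s == "malignant").sum())),
    })
    if len(stats) < 3:
        raise ValueError("need at least as many patients as splits")
    rng = np.random.default_rng(seed)
    order = stats.index.to_numpy()[rng.permutation(len(stats))]
    # malignant-bearing patients first (largest malignant load first), then
    # the rest by size; stable so the shuffled order breaks ties
    key = np.lexsort((-stats.loc[order, "n"].to_numpy(),
                      -stats.loc[order, "n_mal"].to_numpy()))
    order = order[key]
    total_n = stats["n"].sum()
    total_m = max(stats["n_mal"].sum(), 1)
    target_n = ratios * total_n
    target_m = ratios * total_m
    got_n = np.zeros(3)
    got_m = np.zeros(3)
    names = np.array(["train", "val", "test"])
    assign: dict = {}
    for pid in order:
        n_i = stats.at[pid, "n"]
        m_i = stats.at[pid, "n_mal"]
        if m_i > 0:
            need = (target_m - got_m) / target_m
        else:
            need = (target_n - got_n) / target_n
        best = int(np.argmax(need))
        got_n[best] += n_i
        got_m[best] += m_i
        assign[pid] = names[best]
    out = records.copy()
    out["split"] = out["patient_id"].map(assign)
    return out


def kfold_patient(records: pd.DataFrame, k: int = 5, seed: int | None = None):
    """Patient-grouped, class-stratified k-fold partition.

    Returns a list of ``(train_idx, holdout_idx)`` integer index pairs; every
    patient appears in exactly one holdout fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n_patients = records["patient_id"].nunique()
    if k > n_patients:
        raise ValueError("more folds than patients")
    sgkf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    y = (records["label"] == "malignant").astype(int).to_numpy()
    groups = records["patient_id"].to_numpy()
    return list(sgkf.split(np.zeros(len(records)), y, groups))


# ---------------------------------------------------------------------------
# the numpy network


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Net:
    """Parameter container + forward/backward for the fixed topology."""

    def __init__(self, input_shape, filters, dense_units, n_classes, rng):
        h, w, c = input_shape
        self.filters = filters
        self.params = {}
        cin = c
        for i, f in enumerate(filters, start=1):
            self.params[f"Wc{i}"] = _he_init(rng, (9 * cin, f), 9 * cin)
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            cin = f
            h //= 2
            w //= 2
        self.flat = h * w * cin
        self.params["W4"] = _he_init(rng, (self.flat, dense_units), self.flat)
        self.params["b4"] = np.zeros(dense_units, dtype=np.float32)
        self.params["W5"] = _he_init(rng, (dense_units, n_classes), dense_units)
        self.params["b5"] = np.zeros(n_classes, dtype=np.float32)

    @staticmethod
    def _conv_forward(x, W, b):
        B, H, Wd, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        # (B, H, W, C, 3, 3) -> (B*H*W, 3*3*C) with kernel-major ordering
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * Wd, 9 * C)
        z = (cols @ W + b).reshape(B, H, Wd, -1)
        return z, cols

    @staticmethod
    def _conv_backward(dz, cols, W, x_shape):
        B, H, Wd, C = x_shape
        dzf = dz.reshape(-1, dz.shape[-1])
        dW = cols.T @ dzf
        db = dzf.sum(axis=0)
        dcols = (dzf @ W.T).reshape(B, H, Wd, 3, 3, C)
        dxp = np.zeros((B, H + 2, Wd + 2, C), dtype=dz.dtype)
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + H, dj:dj + Wd, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, 1:-1, 1:-1, :], dW, db

    @staticmethod
    def _pool_forward(x):
        B, H, W, C = x.shape
        Hc, Wc = H - H % 2, W - W % 2
        xc = x[:, :Hc, :Wc, :].reshape(B, Hc // 2, 2, Wc // 2, 2, C)
        out = xc.max(axis=(2, 4))
        mask = xc == out[:, :, None, :, None, :]
        count = mask.sum(axis=(2, 4))
        return out, (mask, count, x.shape)

    @staticmethod
    def _pool_backward(dout, cache):
        mask, count, x_shape = cache
        B, H, W, C = x_shape
        Hc, Wc = H - H % 2, W - W % 2
        share = (dout / count)[:, :, None, :, None, :]
        dxc = (mask * share).reshape(B, Hc, Wc, C)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dx[:, :Hc, :Wc, :] = dxc
        return dx

    def forward(self, x, train=False, dropout=0.0, rng=None):
        cache = {"x": x}
        h = x
        for i in range(1, 4):
            z, cols = self._conv_forward(h, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            a = np.maximum(z, 0.0)
            p, pc = self._pool_forward(a)
            cache[f"h{i}"] = h
            cache[f"cols{i}"] = cols
            cache[f"z{i}"] = z
            cache[f"pool{i}"] = pc
            h = p
        B = x.shape[0]
        flat = h.reshape(B, -1)
        z4 = flat @ self.params["W4"] + self.params["b4"]
        a4 = np.maximum(z4, 0.0)
        if train and dropout > 0.0:
            keep = (rng.random(a4.shape) >= dropout).astype(a4.dtype)
            a4d = a4 * keep / (1.0 - dropout)
        else:
            keep = None
            a4d = a4
        logits = a4d @ self.params["W5"] + self.params["b5"]
        cache.update(h3_shape=h.shape, flat=flat, z4=z4, a4=a4, keep=keep,
                     a4d=a4d, dropout=dropout)
        return logits, cache

    def backward(self, dlogits, cache):
        grads = {}
        grads["W5"] = cache["a4d"].T @ dlogits
        grads["b5"] = dlogits.sum(axis=0)
        da4d = dlogits @ self.params["W5"].T
        if cache["keep"] is not None:
            da4 = da4d * cache["keep"] / (1.0 - cache["dropout"])
        else:
            da4 = da4d
        dz4 = da4 * (cache["z4"] > 0)
        grads["W4"] = cache["flat"].T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        dflat = dz4 @ self.params["W4"].T
        dh = dflat.reshape(cache["h3_shape"])
        for i in range(3, 0, -1):
            da = self._pool_backward(dh, cache[f"pool{i}"])
            dz = da * (cache[f"z{i}"] > 0)
            dh, dW, db = self._conv_backward(
                dz, cache[f"cols{i}"], self.params[f"Wc{i}"],
                cache[f"h{i}"].shape)
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return grads


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the compact numpy CNN.

    Parameters mirror the training protocol; ``filters`` and ``dropout`` are
    the searchable hyperparameters.  ``X`` is an ``(n, H, W)`` or
    ``(n, H, W, C)`` stack; 8-bit input is rescaled to [0, 1].  Pass
    ``validation_data=(X_val, y_val)`` to ``fit`` to enable early stopping on
    validation loss (patience epochs without improvement; the best-validation
    weights are restored).  Fitted attributes: ``classes_``, ``history_``
    (per-epoch train/val loss), ``n_params_``, ``best_epoch_``.
    """

    def __init__(self, filters=(32, 64, 128), dropout=0.5, dense_units=128,
                 learning_rate=1e-3, rho=0.9, epsilon=1e-7, batch_size=32,
                 epochs=50, patience=10, weight_penalty=0.0,
                 class_weighted=True, random_state=None):
        self.filters = filters
        self.dropout = dropout
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.rho = rho
        self.epsilon = epsilon
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.weight_penalty = weight_penalty
        self.class_weighted = class_weighted
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _prep_x(X):
        x = np.asarray(X, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4:
            raise ValueError("X must be (n, H, W) or (n, H, W, C)")
        if x.max() > 1.5:
            x = x / 255.0
        return x

    def _encode_y(self, y):
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        if (idx >= self.classes_.size).any() or (self.classes_[idx] != y).any():
            raise ValueError("y contains labels unseen at fit time")
        return idx

    def _loss_and_grad(self, net, xb, yb, sample_w, rng):
        logits, cache = net.forward(xb, train=True, dropout=self.dropout, rng=rng)
        probs = softmax(logits)
        B = xb.shape[0]
        eps = 1e-12
        loss = float(-(sample_w * np.log(probs[np.arange(B), yb] + eps)).sum() / B)
        dlogits = probs.copy()
        dlogits[np.arange(B), yb] -= 1.0
        dlogits *= (sample_w / B)[:, None]
        grads = net.backward(dlogits.astype(np.float32), cache)
        wp = self.weight_penalty
        if wp > 0:
            for k, v in net.params.items():
                if k.startswith(("W", "Wc")) and not k.startswith("b"):
                    loss += 0.5 * wp * float((v.astype(float) ** 2).sum())
                    grads[k] = grads[k] + wp * v
        return loss, grads

    def batch_loss(self, X, y, weighted=True):
        """Training-objective value on a fixed batch (no dropout sampling)."""
        x = self._prep_x(X)
        yi = self._encode_y(y)
        logits, _ = self._net_.forward(x, train=False)
        probs = softmax(logits)
        if weighted and self.class_weighted:
            w = self._class_w_[yi]
        else:
            w = np.ones(yi.size)
        loss = float(-(w * np.log(probs[np.arange(yi.size), yi] + 1e-12)).sum()
                     / yi.size)
        if self.weight_penalty > 0:
            for k, v in self._net_.params.items():
                if k.startswith("W"):
                    loss += 0.5 * self.weight_penalty * float((v.astype(float) ** 2).sum())
        return loss

    def _eval_loss(self, net, x, y):
        # unweighted CE on held-out data (class weights shape only training)
        losses = []
        for i in range(0, x.shape[0], 256):
            logits, _ = net.forward(x[i:i + 256], train=False)
            probs = softmax(logits)
            b = logits.shape[0]
            losses.append(-np.log(probs[np.arange(b), y[i:i + 256]] + 1e-12).sum())
        return float(np.sum(losses) / x.shape[0])

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y, validation_data=None):
        x = self._prep_x(X)
        y = np.asarray(y)
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        if x.shape[1] // 8 < 1 or x.shape[2] // 8 < 1:
            raise ValueError("input too small for three 2x2 pooling stages")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        yi = self._encode_y(y)
        if self.class_weighted:
            cw = class_weights(y)
            self._class_w_ = np.array([cw[c] for c in self.classes_])
        else:
            self._class_w_ = np.ones(self.classes_.size)
        rng = np.random.default_rng(self.random_state)
        net = _Net(x.shape[1:], tuple(self.filters), self.dense_units,
                   self.classes_.size, rng)
        self.n_params_ = count_parameters(tuple(self.filters), x.shape[1:],
                                          self.dense_units, self.classes_.size)
        caches = {k: np.zeros_like(v, dtype=np.float32)
                  for k, v in net.params.items()}
        has_val = validation_data is not None
        if has_val:
            xv = self._prep_x(validation_data[0])
            yv = self._encode_y(np.asarray(validation_data[1]))
        history = {"train_loss": [], "val_loss": []}
        best_val, best_params, best_epoch, wait = np.inf, None, -1, 0
        n = x.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_loss, seen = 0.0, 0
            for i in range(0, n, self.batch_size):
                idx = order[i:i + self.batch_size]
                xb, yb = x[idx], yi[idx]
                sw = self._class_w_[yb] if self.class_weighted else np.ones(idx.size)
                loss, grads = self._loss_and_grad(net, xb, yb, sw, rng)
                for k in net.params:
                    g = grads[k].astype(np.float32)
                    caches[k] = self.rho * caches[k] + (1.0 - self.rho) * g * g
                    net.params[k] -= (self.learning_rate * g
                                      / (np.sqrt(caches[k]) + self.epsilon))
                ep_loss += loss * idx.size
                seen += idx.size
            history["train_loss"].append(ep_loss / seen)
            if has_val:
                vl = self._eval_loss(net, xv, yv)
                history["val_loss"].append(vl)
                if vl < best_val - 1e-12:
                    best_val, best_epoch, wait = vl, epoch, 0
                    best_params = copy.deepcopy(net.params)
                else:
                    wait += 1
                    if wait > self.patience:
                        break
        if has_val and best_params is not None:
            net.params = best_params
        self.best_epoch_ = best_epoch if has_val else self.epochs - 1
        self.history_ = history
        self._net_ = net
        return self

    def decision_function(self, X):
        if not hasattr(self, "_net_"):
            raise AttributeError("CNNClassifier is not fitted")
        x = self._prep_x(X)
        out = []
        for i in range(0, x.shape[0], 256):
            logits, _ = self._net_.forward(x[i:i + 256], train=False)
            out.append(logits)
        return np.concatenate(out, axis=0)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ------------------------------------------------------
    def save(self, path):
        """Save fitted weights + settings to an ``.npz`` archive."""
        if not hasattr(self, "_net_"):
            raise AttributeError("CNNClassifier is not fitted")
        meta = dict(self.get_params())
        meta["classes"] = list(map(str, self.classes_))
        meta["input_shape"] = list(self._net_.params["Wc1"].shape)
        np.savez(path, __meta__=np.array([repr(meta)]),
                 **{k: v for k, v in self._net_.params.items()},
                 __classes__=self.classes_.astype(str),
                 __flat__=np.array([self._net_.flat]))

    @classmethod
    def load(cls, path, input_shape, **params):
        """Restore a fitted classifier saved with :meth:`save`."""
        data = np.load(path, allow_pickle=False)
        clf = cls(**params)
        clf.classes_ = data["__classes__"]
        rng = np.random.default_rng(0)
        net = _Net(input_shape, tuple(clf.filters), clf.dense_units,
                   clf.classes_.size, rng)
        for k in net.params:
            net.params[k] = data[k]
        clf._net_ = net
        clf._class_w_ = np.ones(clf.classes_.size)
        return clf
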