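"""A small 1-D convolutional network over windowed band-power sequences.

Architecture (fixed, mirroring the study design): two blocks of
(1-D convolution, 16 filters, kernel 4, ReLU -> max-pool of size/stride 2),
then channel-wise batch normalization, a dense layer of 40 units with an
L1 weight penalty of 0.001, and a 2-unit softmax output. Trained with
categorical cross-entropy under Adam, with 10% of the training data held
out for validation and early stopping (patience of 50 epochs on
validation loss, best-validation weights restored).

The network is implemented directly in NumPy — forward and backward
passes, Adam, batch-norm and early stopping — which keeps it dependency-
free and bit-reproducible from its seed. Inputs are (n_epochs, n_windows,
n_bands) tensors from :func:`wakeqeeg.models.windowed_features`; temporal
length shrinks as floor(L/2) per pool, e.g. 119 -> 116 -> 58 -> 55 -> 27
for 1-min epochs, 239 -> ... -> 57 for 2-min, 479 -> ... -> 117 for 4-min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-5


def conv_output_length(length: int, kernel: int = 4) -> int:
    return length - kernel + 1


def pool_output_length(length: int) -> int:
    return length // 2


def forward_shapes(n_windows: int, kernel: int = 4) -> dict[str, int]:
    """Temporal lengths after each layer, for documentation and checks."""
    c1 = conv_output_length(n_windows, kernel)
    p1 = pool_output_length(c1)
    c2 = conv_output_length(p1, kernel)
    p2 = pool_output_length(c2)
    return {"conv1": c1, "pool1": p1, "conv2": c2, "pool2": p2}


def _conv1d(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    # X (N, L, C), W (K, C, F) -> (N, L-K+1, F)
    K = W.shape[0]
    L_out = X.shape[1] - K + 1
    out = np.tensordot(X[:, 0:L_out, :], W[0], axes=([2], [0]))
    for dt in range(1, K):
        out += np.tensordot(X[:, dt : dt + L_out, :], W[dt], axes=([2], [0]))
    return out + b


def _conv1d_backward(X, W, dout):
    K = W.shape[0]
    L_out = dout.shape[1]
    dW = np.empty_like(W)
    dX = np.zeros_like(X)
    for dt in range(K):
        dW[dt] = np.einsum("nlc,nlf->cf", X[:, dt : dt + L_out, :], dout)
        dX[:, dt : dt + L_out, :] += dout @ W[dt].T
    db = dout.sum(axis=(0, 1))
    return dX, dW, db


def _maxpool2(x: np.ndarray):
    # size-2, stride-2 pooling over the time axis; odd tail dropped
    N, L, C = x.shape
    L2 = L // 2
    blocks = x[:, : 2 * L2, :].reshape(N, L2, 2, C)
    arg = blocks.argmax(axis=2)
    out = blocks.max(axis=2)
    return out, arg


def _maxpool2_backward(dout, arg, in_shape):
    N, L, C = in_shape
    L2 = dout.shape[1]
    dblocks = np.zeros((N, L2, 2, C))
    n_idx, l_idx, c_idx = np.meshgrid(
        np.arange(N), np.arange(L2), np.arange(C), indexing="ij"
    )
    dblocks[n_idx, l_idx, arg, c_idx] = dout
    dx = np.zeros(in_shape)
    dx[:, : 2 * L2, :] = dblocks.reshape(N, 2 * L2, C)
    return dx


@dataclass
class _Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CnnClassifier:
    """Binary classifier over (n_windows, n_bands) sequences.

    Parameters other than ``seed`` default to the fixed architecture and
    training recipe described in the module docstring; ``max_epochs`` caps
    training if early stopping never triggers.
    """

    def __init__(
        self,
        n_filters: int = 16,
        kernel: int = 4,
        dense_units: int = 40,
        l1: float = 1e-3,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 500,
        patience: int = 50,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel = kernel
        self.dense_units = dense_units
        self.l1 = l1
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None
        self.history_: dict[str, list[float]] = {}

    # ----- initialization ---------------------------------------------------

    def _init_params(self, n_windows: int, n_bands: int, rng) -> None:
        k, F, D = self.kernel, self.n_filters, self.dense_units
        p2 = forward_shapes(n_windows, k)["pool2"]
        if p2 < 1:
            raise ValueError(f"input of {n_windows} windows too short for the network")
        flat = p2 * F

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((k, n_bands, F), k * n_bands),
            "b1": np.zeros(F),
            "W2": he((k, F, F), k * F),
            "b2": np.zeros(F),
            "gamma": np.ones(F),
            "beta": np.zeros(F),
            "Wd": he((flat, D), flat),
            "bd": np.zeros(D),
            "Wo": rng.normal(0.0, np.sqrt(1.0 / D), size=(D, 2)),
            "bo": np.zeros(2),
        }
        self._bn_mean = np.zeros(F)
        self._bn_var = np.ones(F)
        self.n_features_in_ = (n_windows, n_bands)
        self.classes_ = np.array([0, 1])

    # ----- forward / backward -----------------------------------------------

    def _forward(self, X: np.ndarray, train: bool):
        p = self.params
        cache: dict = {"X": X}
        z1 = _conv1d(X, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        pool1, arg1 = _maxpool2(a1)
        z2 = _conv1d(pool1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        pool2, arg2 = _maxpool2(a2)

        if train:
            mu = pool2.mean(axis=(0, 1))
            var = pool2.var(axis=(0, 1))
            self._bn_mean = 0.9 * self._bn_mean + 0.1 * mu
            self._bn_var = 0.9 * self._bn_var + 0.1 * var
        else:
            mu, var = self._bn_mean, self._bn_var
        xhat = (pool2 - mu) / np.sqrt(var + _EPS)
        bn = p["gamma"] * xhat + p["beta"]

        flat = bn.reshape(bn.shape[0], -1)
        zd = flat @ p["Wd"] + p["bd"]
        ad = np.maximum(zd, 0.0)
        logits = ad @ p["Wo"] + p["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        proba = expl / expl.sum(axis=1, keepdims=True)

        cache.update(
            z1=z1, a1=a1, arg1=arg1, pool1=pool1, z2=z2, a2=a2, arg2=arg2,
            pool2=pool2, xhat=xhat, var=var, flat=flat, zd=zd, ad=ad, proba=proba,
        )
        return proba, cache

    def _loss(self, proba: np.ndarray, y: np.ndarray) -> float:
        nll = -np.mean(np.log(proba[np.arange(y.size), y] + 1e-12))
        return float(nll + self.l1 * np.abs(self.params["Wd"]).sum())

    def _backward(self, cache, y: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        N = y.size
        dlogits = cache["proba"].copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N

        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = cache["ad"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dad = dlogits @ p["Wo"].T
        dzd = dad * (cache["zd"] > 0)
        grads["Wd"] = cache["flat"].T @ dzd + self.l1 * np.sign(p["Wd"])
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ p["Wd"].T
        dbn = dflat.reshape(cache["pool2"].shape)

        xhat = cache["xhat"]
        grads["gamma"] = (dbn * xhat).sum(axis=(0, 1))
        grads["beta"] = dbn.sum(axis=(0, 1))
        m = xhat.shape[0] * xhat.shape[1]
        dxhat = dbn * p["gamma"]
        std = np.sqrt(cache["var"] + _EPS)
        dpool2 = (
            dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).mean(axis=(0, 1))
        ) / std

        da2 = _maxpool2_backward(dpool2, cache["arg2"], cache["a2"].shape)
        dz2 = da2 * (cache["z2"] > 0)
        dpool1, grads["W2"], grads["b2"] = _conv1d_backward(cache["pool1"], p["W2"], dz2)
        da1 = _maxpool2_backward(dpool1, cache["arg1"], cache["a1"].shape)
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv1d_backward(cache["X"], p["W1"], dz1)
        return grads

    # ----- training ---------------------------------------------------------

    def _split(self, y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        """Stratified train/validation index split."""
        val_idx = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            n_val = max(1, int(round(self.val_fraction * idx.size)))
            if n_val >= idx.size:
                raise ValueError(
                    f"validation split would leave class {cls} empty in training"
                )
            val_idx.append(rng.permutation(idx)[:n_val])
        val = np.concatenate(val_idx)
        train = np.setdiff1d(np.arange(y.size), val)
        return train, val

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CnnClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be (n_epochs, n_windows, n_bands)")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], X.shape[2], rng)
        tr_idx, val_idx = self._split(y, rng)
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        opt = _Adam(lr=self.lr)
        best_loss = np.inf
        best_state = None
        best_bn = None
        wait = 0
        self.history_ = {"train_loss": [], "val_loss": [], "val_acc": []}

        for _epoch in range(self.max_epochs):
            order = rng.permutation(ytr.size)
            epoch_loss = 0.0
            for start in range(0, ytr.size, self.batch_size):
                batch = order[start : start + self.batch_size]
                proba, cache = self._forward(Xtr[batch], train=True)
                epoch_loss += self._loss(proba, ytr[batch]) * batch.size
                grads = self._backward(cache, ytr[batch])
                opt.step(self.params, grads)
            proba_val, _ = self._forward(Xval, train=False)
            val_loss = self._loss(proba_val, yval)
            self.history_["train_loss"].append(epoch_loss / ytr.size)
            self.history_["val_loss"].append(val_loss)
            self.history_["val_acc"].append(
                float(np.mean(proba_val.argmax(axis=1) == yval))
            )
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_state = {k: v.copy() for k, v in self.params.items()}
                best_bn = (self._bn_mean.copy(), self._bn_var.copy())
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_state is not None:
            self.params = best_state
            self._bn_mean, self._bn_var = best_bn
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1:] != self.n_features_in_:
            raise ValueError(
                f"input shape {X.shape[1:]} != fitted shape {self.n_features_in_}"
            )
        proba, _ = self._forward(X, train=False)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
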