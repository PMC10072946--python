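"""CNN-LSTM classifier for early-warning-signal detection, in pure NumPy.

The detector is a small hybrid network: two one-dimensional convolutional
layers (20 filters of width 8 each, ReLU) slide along the time axis over all
indicator channels, followed by 10% dropout, max pooling with stride 2, a
single LSTM layer with 20 memory cells, a second dropout, and a dense softmax
head with 2 (transition/null) or 3 (null / first-order / second-order)
outputs.  The recurrent state lets the network encode a baseline of the
series against which rising indicator trends stand out.

Forward pass, backpropagation (including backprop through time), Adam and
early stopping are implemented here directly on NumPy arrays; training is
fully deterministic given the seeds.  Gradients are validated against
numerical differentiation in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "CNNLSTMClassifier",
    "build_model",
    "train",
    "predict_proba",
    "train_threeway",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer dimensions of the CNN-LSTM detector (defaults are canonical)."""

    input_length: int = 600
    n_channels: int = 12
    n_conv_layers: int = 2
    filters_per_layer: int = 20
    filter_width: int = 8
    dropout_rate: float = 0.10
    pool_stride: int = 2
    lstm_cells: int = 20
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if self.n_outputs not in (2, 3):
            raise ValueError("n_outputs must be 2 or 3")
        conv_len = self.input_length - self.n_conv_layers * (self.filter_width - 1)
        if conv_len < self.pool_stride:
            raise ValueError("input too short for the convolutional stack")

    @property
    def lstm_steps(self) -> int:
        conv_len = self.input_length - self.n_conv_layers * (self.filter_width - 1)
        return conv_len // self.pool_stride


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (none are reported with the method; these
    are conventional defaults, all recorded in the model manifest)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    validation_fraction: float = 0.1
    clip_norm: float = 5.0
    seed: int = 0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNLSTMClassifier:
    """Binary or three-way CNN-LSTM detector over indicator time series.

    Follows the scikit-learn estimator idiom: construct, :meth:`fit`,
    :meth:`predict_proba`.  ``channel_subset`` records which indicator
    columns ("full", "spatial", "temporal") the model expects; inputs to
    fit/predict must already be projected accordingly.
    """

    def __init__(
        self,
        arch: ArchitectureSpec = ArchitectureSpec(),
        *,
        channel_subset: Literal["full", "spatial", "temporal"] = "full",
        class_names: Optional[Sequence[str]] = None,
        seed: int = 0,
    ) -> None:
        self.arch = arch
        self.channel_subset = channel_subset
        if class_names is None:
            class_names = (
                ("null", "transition")
                if arch.n_outputs == 2
                else ("null", "first", "second")
            )
        if len(class_names) != arch.n_outputs:
            raise ValueError("class_names length must match n_outputs")
        self.class_names = tuple(class_names)
        self.seed = seed
        self.history: dict = {}
        self.manifest: dict = {"architecture": asdict(arch), "seed": seed}
        self.params = self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------------ init

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        a = self.arch
        K, F, H = a.filter_width, a.filters_per_layer, a.lstm_cells
        p: dict[str, np.ndarray] = {}
        c_in = a.n_channels
        for layer in range(a.n_conv_layers):
            p[f"convW{layer}"] = _glorot(rng, (K, c_in, F), K * c_in, K * F)
            p[f"convb{layer}"] = np.zeros(F)
            c_in = F
        p["lstmWx"] = _glorot(rng, (F, 4 * H), F, 4 * H)
        p["lstmWh"] = _glorot(rng, (H, 4 * H), H, 4 * H)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
        p["lstmb"] = b
        p["denseW"] = _glorot(rng, (H, a.n_outputs), H, a.n_outputs)
        p["denseb"] = np.zeros(a.n_outputs)
        return p

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # --------------------------------------------------------------- forward

    def _forward(
        self,
        X: np.ndarray,
        *,
        train_mode: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[np.ndarray, dict]:
        a, p = self.arch, self.params
        cache: dict = {"conv": []}
        h = np.asarray(X, dtype=np.float64)
        if h.ndim != 3 or h.shape[1] != a.input_length or h.shape[2] != a.n_channels:
            raise ValueError(
                f"expected input of shape (batch, {a.input_length}, "
                f"{a.n_channels}), got {h.shape}"
            )
        for layer in range(a.n_conv_layers):
            W, b = p[f"convW{layer}"], p[f"convb{layer}"]
            win = sliding_window_view(h, a.filter_width, axis=1)  # (B, L', C, K)
            z = np.einsum("blck,kcf->blf", win, W, optimize=True) + b
            act = np.maximum(z, 0.0)
            cache["conv"].append((win, z > 0))
            h = act

        if train_mode and a.dropout_rate > 0:
            keep = 1.0 - a.dropout_rate
            m1 = (rng.random(h.shape) < keep) / keep
            h = h * m1
            cache["drop1"] = m1

        Lp = h.shape[1] // a.pool_stride
        pooled_in = h[:, : Lp * a.pool_stride].reshape(
            h.shape[0], Lp, a.pool_stride, h.shape[2]
        )
        amax = pooled_in.argmax(axis=2)
        h = np.take_along_axis(pooled_in, amax[:, :, None, :], axis=2)[:, :, 0, :]
        cache["pool"] = (amax, pooled_in.shape)

        # LSTM over the pooled sequence; final hidden state only
        H = a.lstm_cells
        B, Tp, _ = h.shape
        Wx, Wh, bl = p["lstmWx"], p["lstmWh"], p["lstmb"]
        hs = np.zeros((B, H))
        cs = np.zeros((B, H))
        steps = []
        x_seq = h
        for t in range(Tp):
            z = x_seq[:, t, :] @ Wx + hs @ Wh + bl
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * cs + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((i, f, g, o, cs, tc, hs))
            hs, cs = h_new, c_new
        cache["lstm"] = (x_seq, steps)

        if train_mode and a.dropout_rate > 0:
            keep = 1.0 - a.dropout_rate
            m2 = (rng.random(hs.shape) < keep) / keep
            hs = hs * m2
            cache["drop2"] = m2

        cache["dense_in"] = hs
        logits = hs @ p["denseW"] + p["denseb"]
        return logits, cache

    # -------------------------------------------------------------- backward

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        a, p = self.arch, self.params
        grads: dict[str, np.ndarray] = {}
        hs = cache["dense_in"]
        grads["denseW"] = hs.T @ dlogits
        grads["denseb"] = dlogits.sum(axis=0)
        dh = dlogits @ p["denseW"].T
        if "drop2" in cache:
            dh = dh * cache["drop2"]

        x_seq, steps = cache["lstm"]
        H = a.lstm_cells
        Wx, Wh = p["lstmWx"], p["lstmWh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbl = np.zeros_like(p["lstmb"])
        dx_seq = np.empty_like(x_seq)
        dc = np.zeros_like(dh)
        for t in range(len(steps) - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_seq[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            dbl += dz.sum(axis=0)
            dx_seq[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        grads["lstmWx"], grads["lstmWh"], grads["lstmb"] = dWx, dWh, dbl

        amax, pool_shape = cache["pool"]
        dpool = np.zeros(pool_shape)
        np.put_along_axis(dpool, amax[:, :, None, :], dx_seq[:, :, None, :], axis=2)
        B, Lp, S, F = pool_shape
        dconv = np.zeros((B, cache["conv"][-1][1].shape[1], F))
        dconv[:, : Lp * S] = dpool.reshape(B, Lp * S, F)
        if "drop1" in cache:
            dconv = dconv * cache["drop1"]

        dout = dconv
        for layer in range(a.n_conv_layers - 1, -1, -1):
            win, relu_mask = cache["conv"][layer]
            dz = dout * relu_mask
            grads[f"convW{layer}"] = np.einsum("blck,blf->kcf", win, dz, optimize=True)
            grads[f"convb{layer}"] = dz.sum(axis=(0, 1))
            if layer > 0:
                W = p[f"convW{layer}"]
                L_in = win.shape[1] + a.filter_width - 1
                dx = np.zeros((dz.shape[0], L_in, W.shape[1]))
                for k in range(a.filter_width):
                    dx[:, k : k + dz.shape[1], :] += dz @ W[k].T
                dout = dx
        return grads

    # ------------------------------------------------------------------- fit

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: Optional[TrainingConfig] = None,
        *,
        validation_data: Optional[tuple[np.ndarray, np.ndarray]] = None,
    ) -> "CNNLSTMClassifier":
        """Train with Adam, early stopping on validation loss.

        ``y`` holds integer class labels.  If ``validation_data`` is not
        given, a stratified fraction of the training set is held out.  The
        parameter state with the best validation loss is restored at the
        end.  Raises if fewer than two classes are present; warns on strong
        class imbalance (the training recipe assumes balanced classes).
        """
        config = config or TrainingConfig()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain at least two classes")
        counts = np.bincount(y, minlength=self.arch.n_outputs)
        if counts.max() > 2 * max(1, counts[counts > 0].min()):
            import warnings

            warnings.warn(
                f"strong class imbalance {counts.tolist()}; the detector is "
                "designed for balanced classes",
                stacklevel=2,
            )

        rng = np.random.default_rng(config.seed)
        if validation_data is None:
            X, y, Xv, yv = _stratified_split(X, y, config.validation_fraction, rng)
        else:
            Xv, yv = validation_data
            Xv = np.asarray(Xv, dtype=np.float64)
            yv = np.asarray(yv, dtype=np.int64)

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        best_loss = np.inf
        best_params = {k: p.copy() for k, p in self.params.items()}
        bad_epochs = 0
        step = 0
        history = {"train_loss": [], "val_loss": [], "val_accuracy": []}

        n = X.shape[0]
        for epoch in range(config.max_epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = perm[start : start + config.batch_size]
                xb, yb = X[idx], y[idx]
                logits, cache = self._forward(xb, train_mode=True, rng=rng)
                probs = _softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
                epoch_loss += loss * len(yb)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = self._backward(dlogits, cache)
                _clip_global_norm(grads, config.clip_norm)
                step += 1
                b1, b2 = 0.9, 0.999
                for k in self.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] -= config.learning_rate * mhat / (
                        np.sqrt(vhat) + 1e-8
                    )

            val_probs = self.predict_proba(Xv)
            val_loss = -np.mean(
                np.log(val_probs[np.arange(len(yv)), yv] + 1e-12)
            )
            val_acc = float((val_probs.argmax(axis=1) == yv).mean())
            history["train_loss"].append(epoch_loss / n)
            history["val_loss"].append(float(val_loss))
            history["val_accuracy"].append(val_acc)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.patience:
                    break

        self.params = best_params
        self.history = history
        self.manifest.update(
            {
                "training": asdict(config),
                "n_train": int(n),
                "n_val": int(len(yv)),
                "epochs_run": len(history["val_loss"]),
                "best_val_loss": float(best_loss),
                "channel_subset": self.channel_subset,
                "class_names": list(self.class_names),
            }
        )
        return self

    # --------------------------------------------------------------- predict

    def predict_proba(self, X: np.ndarray, *, batch_size: int = 128) -> np.ndarray:
        """Class probabilities; dropout is inactive at inference."""
        X = np.asarray(X, dtype=np.float64)
        out = np.empty((X.shape[0], self.arch.n_outputs))
        for start in range(0, X.shape[0], batch_size):
            logits, _ = self._forward(X[start : start + batch_size])
            out[start : start + batch_size] = _softmax(logits)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def transition_score(self, X: np.ndarray) -> np.ndarray:
        """Probability assigned to the 'transition' class (binary models)."""
        if self.arch.n_outputs != 2:
            raise ValueError("transition_score is defined for binary models")
        return self.predict_proba(X)[:, 1]

    # --------------------------------------------------------------- io

    def save(self, path) -> None:
        """Single-file checkpoint: parameters plus a JSON manifest."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload["manifest"] = np.frombuffer(
            json.dumps(self.manifest).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **payload)

    @classmethod
    def load(cls, path) -> "CNNLSTMClassifier":
        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            arch = ArchitectureSpec(**manifest["architecture"])
            model = cls(
                arch,
                channel_subset=manifest.get("channel_subset", "full"),
                class_names=manifest.get("class_names"),
                seed=manifest.get("seed", 0),
            )
            model.params = {
                k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
            }
            model.manifest = manifest
        return model


def _stratified_split(X, y, fraction, rng):
    """Hold out a stratified validation fraction; returns Xtr, ytr, Xv, yv."""
    val_idx = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(fraction * idx.size)))
        val_idx.append(idx[:n_val])
    val_idx = np.concatenate(val_idx)
    mask = np.ones(len(y), dtype=bool)
    mask[val_idx] = False
    return X[mask], y[mask], X[val_idx], y[val_idx]


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale


# ------------------------------------------------------------ functional API


def build_model(
    arch: ArchitectureSpec = ArchitectureSpec(), **kwargs
) -> CNNLSTMClassifier:
    """Construct an untrained detector with the given architecture."""
    return CNNLSTMClassifier(arch, **kwargs)


def train(
    model: CNNLSTMClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[TrainingConfig] = None,
    **kwargs,
) -> CNNLSTMClassifier:
    return model.fit(X, y, config, **kwargs)


def predict_proba(model: CNNLSTMClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def train_threeway(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[TrainingConfig] = None,
    *,
    input_length: int = 600,
    n_channels: int = 12,
    seed: int = 0,
) -> CNNLSTMClassifier:
    """Train the 3-way null / first-order / second-order classifier."""
    arch = ArchitectureSpec(
        input_length=input_length, n_channels=n_channels, n_outputs=3
    )
    model = CNNLSTMClassifier(arch, seed=seed)
    return model.fit(X, y, config)
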