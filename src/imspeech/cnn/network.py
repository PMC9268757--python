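"""Minimal NumPy CNN engine for C×C feature-matrix inputs.

Implements exactly the network family the architecture grid needs: valid
stride-1 2-D convolutions (im2col + BLAS), tanh/relu activations, dense
layers, a softmax output with categorical cross-entropy, the Adam optimizer,
and early stopping on validation loss.  All arithmetic is float32; every
source of randomness (init, shuffling) flows from one seeded Generator.
"""

from __future__ import annotations

import numpy as np

from .arch import ArchSpec

__all__ = ["SequentialCNN", "build_model", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax; rows sum to 1 and entries lie in [0, 1]."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(x) if kind == "tanh" else np.maximum(x, 0.0)


def _act_grad(out: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the activation output
    return 1.0 - out * out if kind == "tanh" else (out > 0).astype(np.float32)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

        self._scratch = [np.empty_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v, s in zip(self.params, grads, self.m, self.v,
                                 self._scratch):
            # in-place update; s is reused scratch to avoid large temporaries
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=s)
            m += s
            v *= self.b2
            np.multiply(g, g, out=s)
            s *= 1.0 - self.b2
            v += s
            np.divide(v, b2t, out=s)
            np.sqrt(s, out=s)
            s += self.eps
            np.divide(m, s, out=s)
            s *= self.lr / b1t
            p -= s


class _Conv2D:
    """Valid k×k stride-1 convolution, NHWC layout.

    Computed by shift-and-sum: one GEMM per kernel position (k² small GEMMs)
    instead of an explicit im2col buffer, which keeps the working set small
    and the BLAS calls dense.
    """

    def __init__(self, in_ch: int, filters: int, k: int, activation: str,
                 rng: np.random.Generator):
        self.k, self.activation = k, activation
        fan_in = k * k * in_ch
        self.w = _glorot(rng, (k, k, in_ch, filters), fan_in, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _cols(self, x: np.ndarray) -> np.ndarray:
        """Column matrix (B·Ho·Wo, k²·C), built from k² contiguous slab copies."""
        k = self.k
        b, h, w, c = x.shape
        ho, wo = h - k + 1, w - k + 1
        cols = np.empty((b * ho * wo, k * k * c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                blk = (i * k + j) * c
                cols[:, blk:blk + c] = \
                    x[:, i:i + ho, j:j + wo, :].reshape(-1, c)
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        b, h, w, c = x.shape
        ho, wo = h - k + 1, w - k + 1
        cols = self._cols(x)
        z = cols @ self.w.reshape(k * k * c, -1)
        z += self.b
        out = _act(z, self.activation).reshape(b, ho, wo, -1)
        if train:
            self._cols_cache, self._in_shape, self._out = cols, x.shape, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        b, h, w, c = self._in_shape
        ho, wo = h - k + 1, w - k + 1
        f = self.w.shape[-1]
        dz = dout * _act_grad(self._out, self.activation)
        dzf = dz.reshape(-1, f)
        self.db = dzf.sum(axis=0)
        self.dw = (self._cols_cache.T @ dzf).reshape(self.w.shape)
        dcols = dzf @ self.w.reshape(k * k * c, f).T
        dx = np.zeros((b, h, w, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                blk = (i * k + j) * c
                dx[:, i:i + ho, j:j + wo, :] += \
                    dcols[:, blk:blk + c].reshape(b, ho, wo, c)
        del self._cols_cache, self._out
        return dx

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]


class _Dense:
    def __init__(self, fan_in: int, units: int, activation: str | None,
                 rng: np.random.Generator):
        self.activation = activation
        self.w = _glorot(rng, (fan_in, units), fan_in, units)
        self.b = np.zeros(units, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x @ self.w + self.b
        out = _act(z, self.activation) if self.activation else z
        if train:
            self._in, self._out = x, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * _act_grad(self._out, self.activation) \
            if self.activation else dout
        self.dw = self._in.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.w.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]


class SequentialCNN:
    """CNN over single-channel C×C inputs per an :class:`ArchSpec`.

    conv(k×k, nF_l, conv_activation) per layer → flatten → dense(tanh) per
    hidden dense layer → dense(output_units, softmax).
    """

    def __init__(self, arch: ArchSpec, input_side: int, seed: int = 0):
        if input_side < arch.kernel_size:
            raise ValueError(
                f"input side {input_side} smaller than kernel "
                f"{arch.kernel_size}"
            )
        side = arch.output_side(input_side)  # validates depth too
        self.arch = arch
        self.input_side = input_side
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv2D] = []
        in_ch = 1
        for f in arch.conv_filters:
            self.convs.append(
                _Conv2D(in_ch, f, arch.kernel_size, arch.conv_activation, rng))
            in_ch = f
        self.denses: list[_Dense] = []
        fan_in = side * side * in_ch
        for d in arch.dense_units:
            self.denses.append(_Dense(fan_in, d, arch.dense_activation, rng))
            fan_in = d
        self.denses.append(_Dense(fan_in, arch.output_units, None, rng))

    # -- plumbing -----------------------------------------------------------

    @property
    def _layers(self):
        return [*self.convs, *self.denses]

    @property
    def parameter_count(self) -> int:
        return sum(int(p.size) for layer in self._layers for p in layer.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self._layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self._layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    def save(self, path) -> None:
        """Checkpoint weights plus the architecture metadata (.npz)."""
        from .arch import format_arch

        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(
            path, __arch__=format_arch(self.arch),
            __meta__=np.array([self.input_side, self.arch.kernel_size]),
            __conv_activation__=self.arch.conv_activation, **arrays)

    @classmethod
    def load(cls, path) -> "SequentialCNN":
        from .arch import parse_arch

        with np.load(path, allow_pickle=False) as data:
            arch = parse_arch(
                str(data["__arch__"]),
                conv_activation=str(data["__conv_activation__"]),
                kernel_size=int(data["__meta__"][1]))
            model = cls(arch, int(data["__meta__"][0]))
            n = sum(len(layer.params) for layer in model._layers)
            model.set_weights([data[f"w{i}"] for i in range(n)])
        return model

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[1] != self.input_side \
                or x.shape[2] != self.input_side or x.shape[3] != 1:
            raise ValueError(
                f"expected (batch, {self.input_side}, {self.input_side}[, 1]) "
                f"input, got {x.shape}"
            )
        return x

    def _logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for conv in self.convs:
            out = conv.forward(out, train)
        out = out.reshape(out.shape[0], -1)
        if train:
            self._flat_shape = out.shape
        for dense in self.denses:
            out = dense.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities, row-stochastic, order preserved."""
        x = self._check_input(x)
        chunks = [
            softmax(self._logits(x[i:i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def _train_step(self, x: np.ndarray, y: np.ndarray,
                    opt: _Adam) -> float:
        proba = softmax(self._logits(x, train=True))
        n = len(y)
        loss = float(-np.log(np.clip(proba[np.arange(n), y], 1e-12, None)).mean())
        dlogits = proba
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= np.float32(n)
        dout = dlogits
        for dense in reversed(self.denses):
            dout = dense.backward(dout)
        dout = dout.reshape(len(x), *self._conv_out_shape)
        for conv in reversed(self.convs):
            dout = conv.backward(dout)
        opt.step([g for layer in self._layers for g in layer.grads])
        return loss

    @property
    def _conv_out_shape(self) -> tuple[int, int, int]:
        side = self.arch.output_side(self.input_side)
        return (side, side, self.arch.conv_filters[-1])

    def evaluate(self, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 64) -> tuple[float, float]:
        """(categorical cross-entropy, accuracy) on a labelled set."""
        proba = self.predict_proba(x, batch_size)
        y = np.asarray(y)
        loss = float(-np.log(
            np.clip(proba[np.arange(len(y)), y], 1e-12, None)).mean())
        acc = float((proba.argmax(axis=1) == y).mean())
        return loss, acc

    def fit(self, x: np.ndarray, y: np.ndarray,
            x_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None,
            epochs: int = 50, batch_size: int = 32,
            learning_rate: float = 1e-4,
            patience: int = 10, seed: int = 0,
            verbose: bool = False) -> dict[str, list[float]]:
        """Adam + categorical cross-entropy, early stopping on val loss.

        With a validation set, training stops after ``patience`` epochs
        without improvement and the best-validation-loss weights are
        restored.  Reproducible under (seed, data, config).
        """
        x = self._check_input(x)
        y = np.asarray(y, dtype=np.int64)
        opt = _Adam([p for layer in self._layers for p in layer.params],
                    lr=learning_rate)
        rng = np.random.default_rng(seed)
        history: dict[str, list[float]] = {"loss": [], "val_loss": [],
                                           "val_accuracy": []}
        best_val = np.inf
        best_weights = None
        stall = 0
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), batch_size):
                idx = order[i:i + batch_size]
                losses.append(self._train_step(x[idx], y[idx], opt))
            history["loss"].append(float(np.mean(losses)))
            if x_val is not None and y_val is not None and len(x_val):
                val_loss, val_acc = self.evaluate(x_val, y_val)
                history["val_loss"].append(val_loss)
                history["val_accuracy"].append(val_acc)
                if verbose:
                    print(f"epoch {epoch + 1}: loss {history['loss'][-1]:.4f} "
                          f"val_loss {val_loss:.4f} val_acc {val_acc:.4f}")
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = self.get_weights()
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
            elif verbose:
                print(f"epoch {epoch + 1}: loss {history['loss'][-1]:.4f}")
        if best_weights is not None:
            self.set_weights(best_weights)
        return history


def build_model(arch: ArchSpec, input_side: int, seed: int = 0) -> SequentialCNN:
    """Build the CNN an :class:`ArchSpec` describes for C×C inputs."""
    return SequentialCNN(arch, input_side, seed=seed)
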