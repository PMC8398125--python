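"""Bi-LSTM feature extractor with temporal max-pooling and an FCNN classifier.

The network reads the length-``L`` token sequence of an activity instance
through a (bi)directional LSTM.  The per-time-step outputs form the feature
matrix ``B`` (feature dimension x L; 120 x 20 in the reference
configuration, because bidirectionality doubles the 60 recurrent nodes).
Temporal max-pooling takes the maximum of each feature across time,

    m_k = max_j B[k, j],

removing the time-step dependency, and the pooled vector is concatenated with
the external context ``e = [p^T, t_s]`` (previous-activity one-hot and scaled
begin hour) to form ``d = [m^T, e^T]``.  A fully connected classifier maps

    a_h = ReLU(W_h d + b_h),      a_o = sigmoid(W_o a_h + b_o),

and the predicted class is the argmax of the nine sigmoid outputs.  Training
minimizes per-class binary cross-entropy against one-hot targets (a softmax
variant is available behind ``spec.loss``).

Implemented directly in NumPy: forward pass, backpropagation through time and
through the pooling argmax, and Adam updates are all hand-derived here, with
every source of randomness driven by one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .features import EncodedSample

__all__ = ["ModelSpec", "Model", "build_model", "pool_features", "train_model", "predict"]


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters.

    ``recurrent_nodes`` is the per-direction LSTM width; the extracted
    feature dimension is ``2 * recurrent_nodes`` when bidirectional.  The
    classifier input dimension is the feature dimension plus 9 when
    ``use_prev`` and plus 1 when ``use_ts``.
    """

    recurrent_nodes: int = 60
    bidirectional: bool = True
    sequence_length: int = 20
    hidden_units: int = 50
    n_classes: int = 9
    use_prev: bool = True
    use_ts: bool = True
    epochs: int = 60
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    loss: str = "bce"  # "bce" (sigmoid outputs) or "softmax"

    @property
    def feature_dim(self) -> int:
        return (2 if self.bidirectional else 1) * self.recurrent_nodes

    @property
    def classifier_input_dim(self) -> int:
        return self.feature_dim + 9 * self.use_prev + 1 * self.use_ts

    def validate(self) -> None:
        if self.recurrent_nodes < 1 or self.n_classes < 1 or self.hidden_units < 1:
            raise ValueError("nodes, hidden units and classes must all be >= 1")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.loss not in ("bce", "softmax"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _glorot(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_lstm(rng: np.random.Generator, vocab_size: int, nodes: int) -> dict:
    H = nodes
    p = {
        "Wx": _glorot(rng, (vocab_size, 4 * H)),
        "Wh": _glorot(rng, (H, 4 * H)),
        "b": np.zeros(4 * H),
    }
    p["b"][H:2 * H] = 1.0  # forget-gate bias: remember by default
    return p


class Model:
    """A built (possibly trained) network; see module docstring for the math.

    Parameters live in ``self.params`` as plain arrays:
    ``fwd``/``bwd`` LSTM gate weights (input rows indexed by token, gate
    order input/forget/cell/output), and the classifier ``Wh, bh, Wo, bo``.
    """

    def __init__(self, spec: ModelSpec, vocab_size: int):
        spec.validate()
        if vocab_size < 2:
            raise ValueError("vocab_size must count at least pad + one token")
        self.spec = spec
        self.vocab_size = vocab_size
        rng = np.random.default_rng(spec.seed)
        self.params = {"fwd": _init_lstm(rng, vocab_size, spec.recurrent_nodes)}
        if spec.bidirectional:
            self.params["bwd"] = _init_lstm(rng, vocab_size, spec.recurrent_nodes)
        D, Hc, C = spec.classifier_input_dim, spec.hidden_units, spec.n_classes
        self.params["Wh"] = _glorot(rng, (D, Hc))
        self.params["bh"] = np.zeros(Hc)
        self.params["Wo"] = _glorot(rng, (Hc, C))
        self.params["bo"] = np.zeros(C)
        self.loss_history: List[float] = []
        self._adam: Optional[dict] = None
        self._adam_t = 0

    # ------------------------------------------------------------------ LSTM

    def _lstm_forward(self, which: str, tokens: np.ndarray) -> Tuple[np.ndarray, dict]:
        """Run one direction over ``tokens`` (N, T); returns H (N, T, nodes)
        and the cache needed for backpropagation through time."""
        p = self.params[which]
        N, T = tokens.shape
        Hn = self.spec.recurrent_nodes
        Xw = p["Wx"][tokens]  # (N, T, 4H) — one-hot input times Wx
        h = np.zeros((N, Hn))
        c = np.zeros((N, Hn))
        Hs = np.empty((N, T, Hn))
        cache = {"tokens": tokens, "gates": [], "c_prev": [], "tanh_c": [], "h_prev": []}
        for t in range(T):
            z = Xw[:, t] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :Hn])
            f = _sigmoid(z[:, Hn:2 * Hn])
            g = np.tanh(z[:, 2 * Hn:3 * Hn])
            o = _sigmoid(z[:, 3 * Hn:])
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            cache["gates"].append((i, f, g, o))
            cache["tanh_c"].append(tc)
            Hs[:, t] = h
        return Hs, cache

    def _lstm_backward(self, which: str, cache: dict, dH: np.ndarray, grads: dict) -> None:
        p = self.params[which]
        tokens = cache["tokens"]
        N, T = tokens.shape
        Hn = self.spec.recurrent_nodes
        g_Wx = np.zeros_like(p["Wx"])
        g_Wh = np.zeros_like(p["Wh"])
        g_b = np.zeros_like(p["b"])
        dh_next = np.zeros((N, Hn))
        dc_next = np.zeros((N, Hn))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["gates"][t]
            tc = cache["tanh_c"][t]
            c_prev = cache["c_prev"][t]
            h_prev = cache["h_prev"][t]
            dh = dH[:, t] + dh_next
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = np.concatenate(
                [
                    dc * g * i * (1.0 - i),          # input gate
                    dc * c_prev * f * (1.0 - f),     # forget gate
                    dc * i * (1.0 - g * g),          # candidate
                    dh * tc * o * (1.0 - o),         # output gate
                ],
                axis=1,
            )
            g_b += dz.sum(axis=0)
            g_Wh += h_prev.T @ dz
            np.add.at(g_Wx, tokens[:, t], dz)
            dh_next = dz @ p["Wh"].T
            dc_next = dc * f
        grads[which] = {"Wx": g_Wx, "Wh": g_Wh, "b": g_b}

    # --------------------------------------------------------------- forward

    def extract_features(self, tokens: np.ndarray) -> Tuple[np.ndarray, dict]:
        """Feature tensor B for a token batch: (N, feature_dim, T)."""
        tokens = np.atleast_2d(tokens)
        Hf, cache_f = self._lstm_forward("fwd", tokens)
        caches = {"fwd": cache_f}
        if self.spec.bidirectional:
            Hb_rev, cache_b = self._lstm_forward("bwd", tokens[:, ::-1])
            caches["bwd"] = cache_b
            B = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
        else:
            B = Hf
        return B.transpose(0, 2, 1), caches  # (N, feat, T)

    def _assemble_d(self, m: np.ndarray, P: np.ndarray, ts: np.ndarray) -> np.ndarray:
        parts = [m]
        if self.spec.use_prev:
            parts.append(P)
        if self.spec.use_ts:
            parts.append(ts[:, None])
        return np.concatenate(parts, axis=1)

    def forward_batch(
        self, tokens: np.ndarray, P: np.ndarray, ts: np.ndarray, train: bool = False
    ):
        """Class scores for a batch; with ``train`` also the backprop cache."""
        B, caches = self.extract_features(tokens)
        argmax = B.argmax(axis=2)  # (N, feat): pooling winners
        m = np.take_along_axis(B, argmax[:, :, None], axis=2)[:, :, 0]
        d = self._assemble_d(m, P, ts)
        zh = d @ self.params["Wh"] + self.params["bh"]
        ah = np.maximum(zh, 0.0)
        zo = ah @ self.params["Wo"] + self.params["bo"]
        if self.spec.loss == "softmax":
            zs = zo - zo.max(axis=1, keepdims=True)
            ez = np.exp(zs)
            ao = ez / ez.sum(axis=1, keepdims=True)
        else:
            ao = _sigmoid(zo)
        if not train:
            return ao
        return ao, {"caches": caches, "argmax": argmax, "B_shape": B.shape,
                    "d": d, "ah": ah}

    def forward(self, sample: EncodedSample) -> np.ndarray:
        """Scores a^o for one encoded sample (vector of n_classes in (0,1))."""
        if len(sample.i) != self.spec.sequence_length:
            raise ValueError(
                f"sample encoded with length {len(sample.i)}, model expects "
                f"{self.spec.sequence_length}"
            )
        if sample.i.max() >= self.vocab_size:
            raise ValueError("sample token outside the model vocabulary")
        return self.forward_batch(
            sample.i[None, :], sample.p[None, :], np.array([sample.t_s])
        )[0]

    # -------------------------------------------------------------- training

    def _backward(self, tokens, dZo, cache, grads):
        spec = self.spec
        grads["Wo"] = cache["ah"].T @ dZo
        grads["bo"] = dZo.sum(axis=0)
        dah = dZo @ self.params["Wo"].T
        dzh = dah * (cache["ah"] > 0.0)
        grads["Wh"] = cache["d"].T @ dzh
        grads["bh"] = dzh.sum(axis=0)
        dd = dzh @ self.params["Wh"].T
        dm = dd[:, : spec.feature_dim]
        dB = np.zeros(cache["B_shape"])  # (N, feat, T)
        np.put_along_axis(dB, cache["argmax"][:, :, None], dm[:, :, None], axis=2)
        dB = dB.transpose(0, 2, 1)  # (N, T, feat)
        Hn = spec.recurrent_nodes
        self._lstm_backward("fwd", cache["caches"]["fwd"], dB[:, :, :Hn], grads)
        if spec.bidirectional:
            self._lstm_backward(
                "bwd", cache["caches"]["bwd"], dB[:, ::-1, Hn:], grads
            )

    def _adam_step(self, grads: dict) -> None:
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        if self._adam is None:
            self._adam = _tree_map(np.zeros_like, self.params), _tree_map(
                np.zeros_like, self.params
            )
        self._adam_t += 1
        t = self._adam_t
        mom, vel = self._adam
        for key, g in _tree_items(grads):
            p = _tree_get(self.params, key)
            m = _tree_get(mom, key)
            v = _tree_get(vel, key)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # ------------------------------------------------------------ checkpoint

    def save(self, path: str) -> None:
        flat = {"/".join(k): v for k, v in _tree_items(self.params)}
        np.savez(path, __spec__=json.dumps(asdict(self.spec)),
                 __vocab_size__=self.vocab_size, **flat)

    @classmethod
    def load(cls, path: str) -> "Model":
        with np.load(path, allow_pickle=False) as data:
            spec = ModelSpec(**json.loads(str(data["__spec__"])))
            model = cls(spec, int(data["__vocab_size__"]))
            for name in data.files:
                if name.startswith("__"):
                    continue
                key = tuple(name.split("/"))
                target = _tree_get(model.params, key)
                target[...] = data[name]
        return model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _tree_items(tree: dict, prefix: Tuple[str, ...] = ()):
    for k, v in tree.items():
        if isinstance(v, dict):
            yield from _tree_items(v, prefix + (k,))
        else:
            yield prefix + (k,), v


def _tree_get(tree: dict, key: Tuple[str, ...]):
    node = tree
    for k in key:
        node = node[k]
    return node


def _tree_map(fn, tree: dict) -> dict:
    return {
        k: _tree_map(fn, v) if isinstance(v, dict) else fn(v)
        for k, v in tree.items()
    }


def build_model(spec: ModelSpec, vocab_size: int) -> Model:
    """Construct a model with seed-derived initial weights."""
    return Model(spec, vocab_size)


def pool_features(B: np.ndarray) -> np.ndarray:
    """Temporal max-pooling: the maximum of each feature row across time.

    ``B`` is (feature_dim, T) for one sample or (N, feature_dim, T) for a
    batch; the result drops the time axis.
    """
    B = np.asarray(B)
    if B.size == 0:
        raise ValueError("cannot pool an empty feature matrix")
    return B.max(axis=-1)


def _stack(samples: Sequence[EncodedSample]):
    tokens = np.stack([s.i for s in samples])
    P = np.stack([s.p for s in samples])
    ts = np.array([s.t_s for s in samples])
    y = np.array([s.y for s in samples], dtype=np.int64)
    return tokens, P, ts, y


def train_model(
    model: Model, samples: Sequence[EncodedSample], verbose: bool = False
) -> List[float]:
    """Mini-batch training with Adam; returns the per-epoch mean loss history.

    Fully reproducible: shuffling uses a generator derived from the model
    seed, so two models built and trained identically have bitwise-equal
    histories.  Raises if any class has no training sample.
    """
    spec = model.spec
    if not samples:
        raise ValueError("empty training set")
    tokens, P, ts, y = _stack(samples)
    present = np.bincount(y, minlength=spec.n_classes)
    if (present == 0).any():
        missing = np.flatnonzero(present == 0).tolist()
        raise ValueError(f"training set has no samples for class indices {missing}")
    Y = np.eye(spec.n_classes)[y]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xADF]))
    N = len(samples)
    for epoch in range(spec.epochs):
        order = rng.permutation(N)
        epoch_loss = 0.0
        for start in range(0, N, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            ao, cache = model.forward_batch(tokens[idx], P[idx], ts[idx], train=True)
            Yb = Y[idx]
            eps = 1e-12
            if spec.loss == "softmax":
                loss = -np.mean(np.sum(Yb * np.log(ao + eps), axis=1))
                dZo = (ao - Yb) / len(idx)
            else:
                loss = -np.mean(
                    Yb * np.log(ao + eps) + (1 - Yb) * np.log(1 - ao + eps)
                )
                dZo = (ao - Yb) / (len(idx) * spec.n_classes)
            grads: dict = {}
            model._backward(tokens[idx], dZo, cache, grads)
            model._adam_step(grads)
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / N)
        if verbose:
            print(f"epoch {epoch + 1}/{spec.epochs}  loss {model.loss_history[-1]:.4f}")
    return model.loss_history


def predict(model: Model, samples: Sequence[EncodedSample]) -> np.ndarray:
    """Predicted class indices (argmax of the scores; ties break low)."""
    if not samples:
        return np.empty(0, dtype=np.int64)
    tokens, P, ts, _ = _stack(samples)
    out = np.empty(len(samples), dtype=np.int64)
    for start in range(0, len(samples), 512):
        sl = slice(start, start + 512)
        ao = model.forward_batch(tokens[sl], P[sl], ts[sl])
        out[sl] = ao.argmax(axis=1)
    return out
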