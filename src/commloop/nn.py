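"""Layers, parameter store, and the Adam optimizer used by the structure module.

Parameters live in a flat ``dict[str, Tensor]`` keyed by a hierarchical name
("crossover/qkv/w", ...).  Layers are thin namespaces over that dict so the
whole parameter set can be counted, saved, and optimized uniformly.
"""

from __future__ import annotations

import json
import zlib

import numpy as np

from .autodiff import Tensor, concat

CHECKPOINT_VERSION = 1


class ParamStore:
    """Flat named parameter container with deterministic initialization."""

    def __init__(self, rng: np.random.Generator):
        self.params: dict[str, Tensor] = {}
        self.rng = rng

    def param(self, name: str, shape: tuple, init: str = "lecun") -> Tensor:
        if name in self.params:
            return self.params[name]
        if init == "zeros":
            data = np.zeros(shape)
        elif init == "ones":
            data = np.ones(shape)
        elif init == "lecun":
            fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
            data = self.rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown init {init!r}")
        t = Tensor(data, requires_grad=True, name=name)
        self.params[name] = t
        return t

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64).reshape(v.shape)

    # -- checkpoint I/O (self-describing npz archive) -------------------
    def save(self, path, meta: dict | None = None) -> None:
        meta = dict(meta or {})
        meta["checkpoint_version"] = CHECKPOINT_VERSION
        arrays = {k.replace("/", "__"): v for k, v in self.state_dict().items()}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def read(path) -> tuple[dict[str, np.ndarray], dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            state = {k.replace("__", "/"): z[k] for k in z.files if k != "__meta__"}
        if meta.get("checkpoint_version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        return state, meta

    def checksum(self) -> int:
        h = 0
        for k in sorted(self.params):
            h = zlib.crc32(self.params[k].data.tobytes(), h)
        return h


class Linear:
    def __init__(self, store: ParamStore, name: str, d_in: int, d_out: int,
                 bias: bool = True, init: str = "lecun"):
        self.w = store.param(f"{name}/w", (d_in, d_out), init=init)
        self.b = store.param(f"{name}/b", (d_out,), init="zeros") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y

    @property
    def zeroed(self) -> bool:
        return not np.any(self.w.data) and (self.b is None or not np.any(self.b.data))


class LayerNorm:
    def __init__(self, store: ParamStore, name: str, dim: int, eps: float = 1e-5):
        self.g = store.param(f"{name}/g", (dim,), init="ones")
        self.b = store.param(f"{name}/b", (dim,), init="zeros")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class Adam:
    """Standard Adam with bias correction, operating on a ParamStore."""

    def __init__(self, store: ParamStore, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, grad_clip: float | None = 10.0):
        self.store = store
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {k: np.zeros(p.shape) for k, p in store.params.items()}
        self.v = {k: np.zeros(p.shape) for k, p in store.params.items()}

    def zero_grad(self) -> None:
        for p in self.store.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.grad_clip is not None:
            total = 0.0
            for p in self.store.params.values():
                if p.grad is not None:
                    total += float((p.grad ** 2).sum())
            norm = np.sqrt(total)
            scale = min(1.0, self.grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        for k, p in self.store.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mlp_transition(store: ParamStore, name: str, dim: int, n_layers: int = 3):
    """Structure-module style transition: n relu-separated square linears."""
    layers = [Linear(store, f"{name}/l{i}", dim, dim) for i in range(n_layers)]

    def apply(x: Tensor) -> Tensor:
        h = x
        for i, lin in enumerate(layers):
            h = lin(h)
            if i < len(layers) - 1:
                h = h.relu()
        return x + h

    return apply
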