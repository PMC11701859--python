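"""Neural-network building blocks on top of the autodiff engine.

Modules follow a light torch-like convention: parameters are
``requires_grad`` tensors discoverable through :meth:`Module.parameters`,
``train()``/``eval()`` toggle batch-statistics behaviour, and weights are
initialized from an explicit ``numpy`` generator so every model is
reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import _gru_kernels, autodiff
from .autodiff import DTYPE, Tensor, concatenate

#: use the JIT-compiled recurrence kernels when numba is importable
USE_GRU_KERNELS = _gru_kernels.HAVE_NUMBA

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "MLP",
    "BatchNorm1d",
    "BiGRU",
    "release_workspaces",
]


def release_workspaces(module: "Module") -> None:
    """Free the recurrence workspace pools held by a trained model.

    Call after training finishes when the model is kept around (e.g. in CV
    fold artifacts); inference-mode forwards never allocate workspaces.
    """
    stack = [module]
    while stack:
        m = stack.pop()
        if hasattr(m, "_pool"):
            m._pool = {}
        for value in m.__dict__.values():
            stack.extend(_modules_of(value))


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _params_of(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def train(self) -> "Module":
        self.training = True
        for value in self.__dict__.values():
            for m in _modules_of(value):
                m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for value in self.__dict__.values():
            for m in _modules_of(value):
                m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        _collect_state(self, "", out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        _collect_params(self, "", own)
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=DTYPE).reshape(p.data.shape)


def _params_of(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _params_of(v)


def _modules_of(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _modules_of(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _modules_of(v)


def _collect_state(obj, prefix, out):
    for key, value in obj.__dict__.items():
        _walk_state(value, f"{prefix}{key}", out, lambda p: p.data.copy())


def _collect_params(obj, prefix, out):
    for key, value in obj.__dict__.items():
        _walk_state(value, f"{prefix}{key}", out, lambda p: p)


def _walk_state(value, name, out, fn):
    if isinstance(value, Parameter):
        out[name] = fn(value)
    elif isinstance(value, Module):
        _collect_or(value, name, out, fn)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _walk_state(v, f"{name}.{i}", out, fn)
    elif isinstance(value, dict):
        for k, v in value.items():
            _walk_state(v, f"{name}.{k}", out, fn)


def _collect_or(module, prefix, out, fn):
    for key, value in module.__dict__.items():
        _walk_state(value, f"{prefix}.{key}", out, fn)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Perceptron with tanh hidden activations and a linear head."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "tanh"):
        super().__init__()
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh() if self.activation == "tanh" else x.relu()
        return x


class BatchNorm1d(Module):
    """Batch normalization over the leading (batch) axis."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            if x.shape[0] < 2:
                raise ValueError(
                    "BatchNorm1d requires a batch of >=2 in training mode; "
                    "switch the module to eval() for single-sample inference"
                )
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class _GRUDirection(Module):
    """One direction of a GRU over scalar-feature sequences.

    The whole unrolled forward/backward-through-time pass is implemented as a
    single fused tape node: only the per-step gate activations are retained,
    which keeps memory and Python overhead far below composing the recurrence
    from elementary ops.  Gate order follows the (reset, update, candidate)
    convention with the candidate gate applied as
    ``n = tanh(W_in x + b_in + r * (W_hn h + b_hn))``.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.w_ih = Parameter(glorot(rng, in_dim, 3 * hidden))
        self.w_hh = Parameter(glorot(rng, hidden, 3 * hidden))
        self.b_ih = Parameter(np.zeros(3 * hidden, dtype=DTYPE))
        self.b_hh = Parameter(np.zeros(3 * hidden, dtype=DTYPE))
        # Workspace pool reused across forward/backward cycles of the same
        # batch shape: avoids re-faulting hundreds of MB of fresh pages
        # every training epoch.  A workspace is popped at forward time and
        # returned once its backward pass has consumed the caches, so
        # overlapping forwards can never clobber each other.
        self._pool: dict[tuple, list] = {}

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        """Run the recurrence over ``x`` of shape (batch, time, in_dim).

        Returns the final hidden state, shape (batch, hidden).
        """
        data = x.data
        B, T, in_dim = data.shape
        H = self.hidden
        order = range(T - 1, -1, -1) if reverse else range(T)

        w_ih, w_hh = self.w_ih, self.w_hh
        b_ih, b_hh = self.b_ih, self.b_hh

        if not autodiff.is_grad_enabled():
            return Tensor(self._infer(data, reverse))
        if USE_GRU_KERNELS and autodiff.DTYPE == np.float32:
            return self._fused(x, reverse)

        # Scalar inputs are the common case; broadcasting beats a degenerate
        # inner-dimension-1 BLAS call by a wide margin.
        if in_dim == 1:
            gi_all = data * w_ih.data.ravel() + b_ih.data
        else:
            gi_all = (data.reshape(B * T, in_dim) @ w_ih.data
                      + b_ih.data).reshape(B, T, 3 * H)

        h = np.zeros((B, H), dtype=DTYPE)
        cache = []  # (t, h_prev, r, z, n, gh_n)
        for t in order:
            gh = h @ w_hh.data + b_hh.data
            gi = gi_all[:, t]
            r = _sigmoid(gi[:, :H] + gh[:, :H])
            z = _sigmoid(gi[:, H:2 * H] + gh[:, H:2 * H])
            n = np.tanh(gi[:, 2 * H:] + r * gh[:, 2 * H:])
            h_new = (1.0 - z) * n + z * h
            cache.append((t, h, r, z, n, gh[:, 2 * H:]))
            h = h_new

        parents = [w_ih, w_hh, b_ih, b_hh, x]

        def backward(g):
            dh = g.astype(DTYPE).copy()
            d_wih = np.zeros_like(w_ih.data)
            d_whh = np.zeros_like(w_hh.data)
            d_bih = np.zeros_like(b_ih.data)
            d_bhh = np.zeros_like(b_hh.data)
            dgi_all = np.zeros((B, T, 3 * H), dtype=DTYPE) if x.requires_grad else None
            for t, h_prev, r, z, n, gh_n in reversed(cache):
                dn = dh * (1.0 - z)
                dz = dh * (h_prev - n)
                dh_prev = dh * z
                dgn = dn * (1.0 - n * n)
                dr = dgn * gh_n
                dgh_n = dgn * r
                dgz = dz * z * (1.0 - z)
                dgr = dr * r * (1.0 - r)
                dgates_i = np.concatenate([dgr, dgz, dgn], axis=1)
                dgates_h = np.concatenate([dgr, dgz, dgh_n], axis=1)
                d_whh += h_prev.T @ dgates_h
                d_bhh += dgates_h.sum(axis=0)
                d_bih += dgates_i.sum(axis=0)
                if dgi_all is not None:
                    dgi_all[:, t] = dgates_i
                else:
                    d_wih += data[:, t].T @ dgates_i
                dh = dh_prev + dgates_h @ w_hh.data.T
            if dgi_all is not None:
                flat = dgi_all.reshape(B * T, 3 * H)
                d_wih += data.reshape(B * T, -1).T @ flat
                x._accum((flat @ w_ih.data.T).reshape(data.shape))
            w_ih._accum(d_wih)
            w_hh._accum(d_whh)
            b_ih._accum(d_bih)
            b_hh._accum(d_bhh)

        return Tensor._result(h, parents, backward)

    def _infer(self, data: np.ndarray, reverse: bool) -> np.ndarray:
        """Streaming inference-mode recurrence: no caches retained."""
        B, T, in_dim = data.shape
        H = self.hidden
        w_ih, b_ih = self.w_ih.data, self.b_ih.data
        w_hh, b_hh = self.w_hh.data, self.b_hh.data
        order = range(T - 1, -1, -1) if reverse else range(T)
        h = np.zeros((B, H), dtype=DTYPE)
        for t in order:
            if in_dim == 1:
                gi = data[:, t, :] * w_ih.reshape(1, -1) + b_ih
            else:
                gi = data[:, t, :] @ w_ih + b_ih
            gh = h @ w_hh + b_hh
            r = _sigmoid(gi[:, :H] + gh[:, :H])
            z = _sigmoid(gi[:, H:2 * H] + gh[:, H:2 * H])
            n = np.tanh(gi[:, 2 * H:] + r * gh[:, 2 * H:])
            h = (1.0 - z) * n + z * h
        return h

    def _fused(self, x: Tensor, reverse: bool) -> Tensor:
        """Fast path: time-major vectorized forward, JIT backward kernel."""
        data = x.data
        B, T, in_dim = data.shape
        H = self.hidden
        w_ih, w_hh = self.w_ih, self.w_hh
        b_ih, b_hh = self.b_ih, self.b_hh

        key = (B, T, in_dim)
        pool = self._pool.setdefault(key, [])
        if pool:
            ws = pool.pop()
        else:
            ws = {name: np.empty((T, B, H), dtype=DTYPE)
                  for name in ("hprev", "r", "z", "n", "ghn")}
            ws["data_t"] = np.empty((T, B, in_dim), dtype=DTYPE)
            ws["gi_t"] = np.empty((T, B, 3 * H), dtype=DTYPE)
            # gi is only read in the forward pass, so the backward pass can
            # reuse its storage for the gate gradients.
            ws["dgi_t"] = ws["gi_t"]

        data_t = ws["data_t"]
        data_t[...] = data.transpose(1, 0, 2)
        gi_t = ws["gi_t"]
        if in_dim == 1:
            np.multiply(data_t.reshape(T * B, 1), w_ih.data.reshape(1, -1),
                        out=gi_t.reshape(T * B, 3 * H))
            gi_t += b_ih.data
        else:
            np.matmul(data_t.reshape(T * B, in_dim), w_ih.data,
                      out=gi_t.reshape(T * B, 3 * H))
            gi_t += b_ih.data

        order = range(T - 1, -1, -1) if reverse else range(T)
        h = np.zeros((B, H), dtype=DTYPE)
        c_hprev, c_r, c_z = ws["hprev"], ws["r"], ws["z"]
        c_n, c_ghn = ws["n"], ws["ghn"]
        for s, t in enumerate(order):
            gh = h @ w_hh.data
            gh += b_hh.data
            gi = gi_t[t]
            r = _sigmoid(gi[:, :H] + gh[:, :H])
            z = _sigmoid(gi[:, H:2 * H] + gh[:, H:2 * H])
            ghn = gh[:, 2 * H:]
            n = np.tanh(gi[:, 2 * H:] + r * ghn)
            c_hprev[s] = h
            c_r[s] = r
            c_z[s] = z
            c_n[s] = n
            c_ghn[s] = ghn
            h = (1.0 - z) * n + z * h

        def backward(g):
            dgi_t = ws["dgi_t"]
            d_whh, d_bhh = _gru_kernels.gru_backward(
                np.ascontiguousarray(g, dtype=DTYPE), c_hprev, c_r, c_z, c_n,
                c_ghn, w_hh.data, reverse, dgi_t)
            flat = dgi_t.reshape(T * B, 3 * H)
            w_ih._accum(data_t.reshape(T * B, in_dim).T @ flat)
            b_ih._accum(flat.sum(axis=0))
            w_hh._accum(d_whh)
            b_hh._accum(d_bhh)
            if x.requires_grad:
                dx_t = (flat @ w_ih.data.T).reshape(T, B, in_dim)
                x._accum(dx_t.transpose(1, 0, 2))
            pool.append(ws)

        return Tensor._result(h, (w_ih, w_hh, b_ih, b_hh, x), backward)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


class BiGRU(Module):
    """Bidirectional GRU returning the concatenated final hidden states.

    Output width is ``2 * hidden``: the forward pass's last state next to the
    backward pass's last state (which has consumed the sequence reversed).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _GRUDirection(in_dim, hidden, rng)
        self.bwd = _GRUDirection(in_dim, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return concatenate([self.fwd(x), self.bwd(x, reverse=True)], axis=1)
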