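"""Layer/module abstractions over the autodiff engine.

A :class:`Module` discovers parameters and submodules by inspecting its
attributes (including lists of modules), supports train/eval switching and
flat, name-addressed state dicts for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, dropout, relu, sigmoid


class Module:
    def __init__(self):
        self.training = True

    # attribute walk: Tensors with requires_grad are parameters,
    # Modules (also inside lists/tuples) are children
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:") :]]
                buf[...] = arr
            else:
                p = params[key]
                if p.data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {p.data.shape} vs {arr.shape}"
                    )
                p.data = np.asarray(arr, dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 same-padding convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, kernel=3, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = c_in * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running-statistics decay.

    ``momentum`` is the decay applied to the running estimates
    (running = momentum * running + (1 - momentum) * batch), 0.99 by default.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        from .tensor import Tensor as T, _make  # local to avoid import cycle noise

        xd = x.data
        if self.training:
            mu = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu[:, None, None]) * inv[:, None, None]
        out_data = self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]
        gamma, beta, training = self.gamma, self.beta, self.training

        def bwd(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = g * gamma.data[:, None, None]
                if training:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (inv[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)
                else:
                    dx = dxhat * inv[:, None, None]
                x._accumulate(dx)

        return _make(out_data, (x, gamma, beta), bwd)


class Dropout(Module):
    def __init__(self, p: float, *, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        return dropout(x, self.p, self.rng, self.training)


class ConvBnRelu(Module):
    """3x3 conv -> batch norm -> ReLU, the workhorse block of the network."""

    def __init__(self, c_in: int, c_out: int, kernel=3, *, bn_momentum: float = 0.99,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out, momentum=bn_momentum)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class GatingUnit(Module):
    """Feature gate: x * sigmoid(dropout-regularized 1x1 conv + batch norm).

    Suppresses responses in regions the 1x1 projection deems irrelevant while
    keeping the feature's shape.
    """

    def __init__(self, channels: int, dropout_rate: float = 0.5, *,
                 bn_momentum: float = 0.99, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(channels, channels, 1, rng=rng)
        self.bn = BatchNorm2d(channels, momentum=bn_momentum)
        self.drop = Dropout(dropout_rate, rng=rng)
        from .tensor import mul  # noqa: F401 (documents dependency)

    def forward(self, x):
        from .tensor import mul

        gate = self.drop(sigmoid(self.bn(self.conv(x))))
        return mul(x, gate)
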