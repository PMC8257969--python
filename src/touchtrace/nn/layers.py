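"""Neural-network layers built on the autodiff core.

Provides the pieces the behavioral-to-discharge model is assembled
from: dense and 2D convolutional layers, batch normalization, LSTM
layers with recurrent dropout, the two frame extractors (a compact
4-block strided CNN and a ResNet-50 adapted to 50x50x2 probability
grids) and the Adam optimizer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Dense",
    "Conv2d",
    "BatchNorm2d",
    "LSTMLayer",
    "SmallExtractor",
    "ResNet50Extractor",
    "Adam",
]


class Module:
    """Base class: parameter registry and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, child in self._children.items():
            out.extend(child.named_parameters(prefix + name + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for child in self._children.values():
            out.extend(child.modules())
        return out

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        out = {k: v.data for k, v in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            for bname, arr in getattr(m, "_buffers", {}).items():
                out[f"__buf{i}.{bname}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        for k, v in self.named_parameters():
            v.data = np.asarray(state[k], dtype=np.float32)
        for i, m in enumerate(self.modules()):
            bufs = getattr(m, "_buffers", None)
            if bufs:
                for bname in bufs:
                    bufs[bname] = np.asarray(state[f"__buf{i}.{bname}"], dtype=np.float32)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        super().__init__()
        self.W = self.add_param("W", _glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = self.add_param("b", np.zeros(n_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv2d(Module):
    """3x3-style convolution via im2col; weight shape (C_in*k*k, C_out)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        self.W = self.add_param("W", _glorot(rng, fan_in, c_out, (fan_in, c_out)))
        self.b = self.add_param("b", np.zeros(c_out, dtype=np.float32)) if bias else None
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        out_h = (H + 2 * self.pad - self.kernel) // self.stride + 1
        out_w = (W + 2 * self.pad - self.kernel) // self.stride + 1
        cols = x.unfold2d(self.kernel, self.stride, self.pad)  # (B, P, C*k*k)
        flat = cols.reshape(B * out_h * out_w, -1) @ self.W
        if self.b is not None:
            flat = flat + self.b
        return flat.reshape(B, out_h, out_w, self.c_out).transpose(0, 3, 1, 2)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = centered.square().mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.ravel()
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.ravel()
            xhat = centered / (var + self.eps).sqrt()
        else:
            mu = self._buffers["running_mean"].reshape(1, -1, 1, 1)
            sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LSTMLayer(Module):
    """Single LSTM layer unrolled over a fixed number of steps."""

    def __init__(self, rng, n_in: int, n_units: int):
        super().__init__()
        self.n_units = n_units
        self.Wx = self.add_param("Wx", _glorot(rng, n_in, 4 * n_units, (n_in, 4 * n_units)))
        self.Wh = self.add_param("Wh", _glorot(rng, n_units, 4 * n_units, (n_units, 4 * n_units)))
        b = np.zeros(4 * n_units, dtype=np.float32)
        b[n_units : 2 * n_units] = 1.0  # forget-gate bias
        self.b = self.add_param("b", b)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        B = xs[0].shape[0]
        n = self.n_units
        h = Tensor(np.zeros((B, n), dtype=np.float32))
        c = Tensor(np.zeros((B, n), dtype=np.float32))
        outs = []
        for x in xs:
            z = x @ self.Wx + h @ self.Wh + self.b
            i = z[:, :n].sigmoid()
            f = z[:, n : 2 * n].sigmoid()
            g = z[:, 2 * n : 3 * n].tanh()
            o = z[:, 3 * n :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs


class SmallExtractor(Module):
    """Compact 4-block strided CNN mapping a 50x50x2 grid pair to a 128-d embedding.

    Used for desk-scale training and tests; same interface as the
    ResNet-50 extractor.
    """

    embedding_dim = 128

    def __init__(self, rng, batch_norm: bool = True):
        super().__init__()
        chans = [2, 16, 32, 64, 128]
        self.convs = []
        self.bns = []
        for i in range(4):
            conv = Conv2d(rng, chans[i], chans[i + 1], kernel=3, stride=2)
            setattr(self, f"conv{i}", conv)
            self.convs.append(conv)
            bn = BatchNorm2d(chans[i + 1]) if batch_norm else None
            if bn is not None:
                setattr(self, f"bn{i}", bn)
            self.bns.append(bn)

    def __call__(self, x: Tensor) -> Tensor:
        for conv, bn in zip(self.convs, self.bns):
            x = conv(x)
            if bn is not None:
                x = bn(x)
            x = x.relu()
        return x.mean(axis=(2, 3))  # global average pool -> (B, 128)

    def conv_params(self) -> list[Tensor]:
        return [c.W for c in self.convs]


class _Bottleneck(Module):
    def __init__(self, rng, c_in, c_mid, c_out, stride, batch_norm=True):
        super().__init__()
        self.conv1 = Conv2d(rng, c_in, c_mid, kernel=1, stride=1, pad=0, bias=False)
        self.conv2 = Conv2d(rng, c_mid, c_mid, kernel=3, stride=stride, bias=False)
        self.conv3 = Conv2d(rng, c_mid, c_out, kernel=1, stride=1, pad=0, bias=False)
        self.bn1 = BatchNorm2d(c_mid) if batch_norm else None
        self.bn2 = BatchNorm2d(c_mid) if batch_norm else None
        self.bn3 = BatchNorm2d(c_out) if batch_norm else None
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = Conv2d(rng, c_in, c_out, kernel=1, stride=stride, pad=0, bias=False)
            self.down_bn = BatchNorm2d(c_out) if batch_norm else None

    def __call__(self, x: Tensor) -> Tensor:
        idn = x
        out = self.conv1(x)
        if self.bn1 is not None:
            out = self.bn1(out)
        out = out.relu()
        out = self.conv2(out)
        if self.bn2 is not None:
            out = self.bn2(out)
        out = out.relu()
        out = self.conv3(out)
        if self.bn3 is not None:
            out = self.bn3(out)
        if self.down is not None:
            idn = self.down(x)
            if self.down_bn is not None:
                idn = self.down_bn(idn)
        return (out + idn).relu()


class ResNet50Extractor(Module):
    """ResNet-50 backbone adapted to 50x50x2 inputs, 1024-d embedding.

    Adaptations from the stock 224x224 network: the stem convolution is
    3x3 stride 1 on 2 input channels and the initial max-pool is removed
    (a 50x50 grid leaves no room for aggressive early downsampling); the
    pooled 2048-d feature is projected to a 1024-d embedding per frame.
    Trained from random initialization.
    """

    embedding_dim = 1024

    def __init__(self, rng, batch_norm: bool = True):
        super().__init__()
        self.stem = Conv2d(rng, 2, 64, kernel=3, stride=1, bias=False)
        self.stem_bn = BatchNorm2d(64) if batch_norm else None
        self.blocks = []
        cfg = [(64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)]
        c_in = 64
        idx = 0
        for c_mid, c_out, n_blocks, first_stride in cfg:
            for b in range(n_blocks):
                stride = first_stride if b == 0 else 1
                block = _Bottleneck(rng, c_in, c_mid, c_out, stride, batch_norm)
                setattr(self, f"block{idx}", block)
                self.blocks.append(block)
                c_in = c_out
                idx += 1
        self.proj = Dense(rng, 2048, 1024)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        if self.stem_bn is not None:
            x = self.stem_bn(x)
        x = x.relu()
        for block in self.blocks:
            x = block(x)
        return self.proj(x.mean(axis=(2, 3)))

    def conv_params(self) -> list[Tensor]:
        out = [self.stem.W]
        for block in self.blocks:
            out.extend([block.conv1.W, block.conv2.W, block.conv3.W])
            if block.down is not None:
                out.append(block.down.W)
        return out


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
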