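"""Layer modules built on the autodiff core.

Conventions follow the image-translation literature: convolutions are 4-wide
with padding 1, instance normalization is per-sample per-channel, parameter
initialization is zero-mean Gaussian with standard deviation 0.02 and is fully
seedable.
"""

from __future__ import annotations

import logging

import numpy as np

from .tensor import Tensor, conv2d, conv_transpose2d, leaky_relu, relu, tanh

log = logging.getLogger(__name__)

INIT_STD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal container with parameter traversal and train/eval modes."""

    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, p in self._params.items():
            state[prefix + k] = p.data
        for k, b in self._buffers.items():
            state[prefix + k] = b
        for k, m in self._modules.items():
            state.update(m.named_state(prefix + k + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=np.float32)
        for k in self._buffers:
            self._buffers[k] = np.asarray(state[prefix + k])
        for k, m in self._modules.items():
            m.load_state(state, prefix + k + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(
            rng.normal(0.0, INIT_STD, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(
            rng.normal(0.0, INIT_STD, (in_channels, out_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learned affine terms."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones((1, channels, 1, 1)))
        self.bias = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.weight + self.bias


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Tanh(Module):
    def forward(self, x):
        return tanh(x)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from a shared rng so a
    fixed model seed reproduces an entire training run."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


def spectral_sigma(
    wmat: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    n_power_iterations: int = 1,
    eps: float = 1e-12,
    converge_tol: float | None = None,
    max_iterations: int = 500,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Power-iterate the largest singular value of a 2-D matrix view.

    Runs ``n_power_iterations`` steps; if ``converge_tol`` is set, continues
    (up to ``max_iterations``) until the sigma estimate is relatively stable,
    which guards against slow convergence when the top singular values are
    close.  Returns the sigma estimate and the updated left/right vectors.
    """
    sigma = 0.0
    for it in range(max_iterations if converge_tol is not None else n_power_iterations):
        v = wmat.T @ u
        v = v / (np.linalg.norm(v) + eps)
        u = wmat @ v
        u = u / (np.linalg.norm(u) + eps)
        new_sigma = float(u @ wmat @ v)
        done = it + 1 >= n_power_iterations
        if (
            converge_tol is not None
            and done
            and abs(new_sigma - sigma) <= converge_tol * abs(new_sigma)
        ):
            sigma = new_sigma
            break
        sigma = new_sigma
    return sigma, u, v


class SpectralConv2d(Module):
    """Convolution whose weight is divided by its largest singular value
    (estimated by persistent power iteration) before every application,
    keeping the layer 1-Lipschitz."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 1,
        padding: int = 0,
        n_power_iterations: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.n_power_iterations = n_power_iterations
        self.weight = Parameter(
            rng.normal(0.0, INIT_STD, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels))
        k = in_channels * kernel_size * kernel_size
        self.register_buffer("u", _unit(rng.normal(size=out_channels)))
        self.register_buffer("v", _unit(rng.normal(size=k)))

    def forward(self, x):
        cout = self.weight.data.shape[0]
        wmat_data = self.weight.data.reshape(cout, -1)
        if self.training:
            sigma_est, u, v = spectral_sigma(
                wmat_data, self._buffers["u"], self._buffers["v"],
                self.n_power_iterations,
            )
        else:  # verification mode: iterate to convergence
            sigma_est, u, v = spectral_sigma(
                wmat_data, self._buffers["u"], self._buffers["v"],
                max(self.n_power_iterations, 20), converge_tol=1e-8,
            )
        if abs(sigma_est) < 1e-20:
            log.warning("spectral norm: weight is all-zero, left unnormalized")
            return conv2d(x, self.weight, self.bias, self.stride, self.padding)
        self._buffers["u"], self._buffers["v"] = u, v
        # Differentiable sigma with u, v treated as constants (standard rule).
        wmat = self.weight.reshape(cout, -1)
        wv = (wmat * Tensor(v[None, :].astype(np.float32))).sum(axis=1)
        sigma = (wv * Tensor(u.astype(np.float32))).sum()
        w_norm = self.weight * (sigma**-1.0)
        return conv2d(x, w_norm, self.bias, self.stride, self.padding)


def _unit(x: np.ndarray) -> np.ndarray:
    return x / (np.linalg.norm(x) + 1e-12)
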