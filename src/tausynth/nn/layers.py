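"""Network building blocks on top of the autodiff engine.

Conventions: activations are PReLU unless noted; instance normalization is
non-affine; dropout is active only in training mode and draws from the
module's own Generator so training runs are reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Lightweight parameter container with train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def _modules(self):
        out = []

        def collect(obj):
            if isinstance(obj, Module):
                out.append(obj)
                for v in obj.__dict__.values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        for v in self.__dict__.values():
            collect(v)
        return out

    def train(self):
        self.training = True
        for m in self._modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self._modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state mismatch: {len(arrays)} arrays for {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"parameter shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _param(rng: np.random.Generator, shape, fan_in: int | None = None, zero: bool = False) -> Tensor:
    if zero:
        return Tensor(np.zeros(shape), requires_grad=True)
    fan = fan_in if fan_in is not None else int(np.prod(shape[1:]))
    scale = np.sqrt(2.0 / max(fan, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv3d(Module):
    """Stride-1 'same' 3D convolution.

    ``zero_init`` starts the kernel and bias at zero: the following PReLU,
    dropout and instance-norm stages all map an exact-zero field to exact
    zero, giving the modulation path a residual-identity start (gradients
    stay alive through the ReLU subgradient at 0).
    """

    def __init__(self, rng, in_ch: int, out_ch: int, k: int = 3, zero_init: bool = False):
        super().__init__()
        self.weight = _param(rng, (out_ch, in_ch, k, k, k), zero=zero_init)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias)


class PReLU(Module):
    """Per-channel parametric ReLU: y = relu(x) - a * relu(-x)."""

    def __init__(self, channels: int, init_slope: float = 0.25):
        super().__init__()
        self.slope = Tensor(np.full((1, channels, 1, 1, 1), init_slope), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(x) - self.slope * ad.relu(-x)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes (non-affine)."""

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        return xc * ((var + self.eps) ** -0.5)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class ConvStage(Module):
    """conv -> PReLU -> dropout -> instance norm."""

    def __init__(self, rng, in_ch, out_ch, dropout, drop_rng, k=3, zero_init=False):
        super().__init__()
        self.conv = Conv3d(rng, in_ch, out_ch, k=k, zero_init=zero_init)
        self.act = PReLU(out_ch)
        self.drop = Dropout(dropout, drop_rng)
        self.norm = InstanceNorm3d()

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.drop(self.act(self.conv(x))))


class ConvBlocks(Module):
    """Three convolutional stages, each conv -> PReLU -> dropout -> instance norm.

    With ``zero_init_last`` the final conv starts at zero so the whole block
    emits zeros at initialization (residual-identity start for the prompt
    modulation path: normalizing an all-zero map returns zero).
    """

    def __init__(self, rng, in_ch, out_ch, dropout, drop_rng, zero_init_last=False):
        super().__init__()
        mid = max(out_ch, 4)
        self.stages = [
            ConvStage(rng, in_ch, mid, dropout, drop_rng),
            ConvStage(rng, mid, mid, dropout, drop_rng),
            ConvStage(rng, mid, out_ch, dropout, drop_rng, zero_init=zero_init_last),
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for s in self.stages:
            x = s(x)
        return x


class DoubleConv(Module):
    """Standard two-conv U-Net level block."""

    def __init__(self, rng, in_ch, out_ch, dropout, drop_rng):
        super().__init__()
        self.a = ConvStage(rng, in_ch, out_ch, dropout, drop_rng)
        self.b = ConvStage(rng, out_ch, out_ch, dropout, drop_rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.b(self.a(x))


class AttentionGate(Module):
    """Additive attention gate for skip connections.

    Both the skip features x and the (already upsampled) gating features g are
    projected to an intermediate channel count with 1x1x1 convolutions; their
    sum passes through ReLU and a 1x1x1 conv + sigmoid to give a coefficient
    map in [0, 1] that multiplies the skip.
    """

    def __init__(self, rng, skip_ch: int, gate_ch: int, inter_ch: int | None = None):
        super().__init__()
        inter = inter_ch or max(skip_ch // 2, 1)
        self.theta = Conv3d(rng, skip_ch, inter, k=1)
        self.phi = Conv3d(rng, gate_ch, inter, k=1)
        self.psi = Conv3d(rng, inter, 1, k=1)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        if skip.shape[2:] != gate.shape[2:]:
            raise ValueError(f"attention gate level mismatch: skip {skip.shape[2:]} vs gate {gate.shape[2:]}")
        return ad.sigmoid(self.psi(ad.relu(self.theta(skip) + self.phi(gate))))

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        return skip * self.coefficients(skip, gate)


class CondConv3d(Module):
    """Conditionally parameterized convolution.

    Holds a bank of expert kernels; per subject, softmax routing weights
    computed from the conditioning vector mix the experts into one kernel,
    which is applied as an ordinary stride-1 'same' convolution. With
    ``conditioning=None`` the experts are mixed uniformly (the ablated,
    covariate-free behaviour).
    """

    def __init__(self, rng, in_ch: int, out_ch: int, cond_dim: int, n_experts: int = 4, k: int = 3):
        super().__init__()
        self.n_experts = n_experts
        self.cond_dim = cond_dim
        self.experts = _param(rng, (n_experts, out_ch, in_ch, k, k, k),
                              fan_in=in_ch * k ** 3)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.route_w = _param(rng, (cond_dim, n_experts), fan_in=cond_dim)
        self.route_b = Tensor(np.zeros(n_experts), requires_grad=True)

    def routing(self, conditioning: Tensor) -> Tensor:
        if conditioning.shape[-1] != self.cond_dim:
            raise ValueError(f"conditioning dim {conditioning.shape[-1]} != expected {self.cond_dim}")
        return ad.softmax(conditioning @ self.route_w + self.route_b, axis=-1)

    def __call__(self, x: Tensor, conditioning: Tensor | None) -> Tensor:
        n = x.shape[0]
        if conditioning is None:
            r = Tensor(np.full((n, self.n_experts), 1.0 / self.n_experts))
        else:
            r = self.routing(conditioning)
        # mix expert kernels per sample: (N,E) x (E, Co*Ci*k^3)
        e = self.experts
        flat = e.reshape(self.n_experts, -1)
        mixed = (r @ flat).reshape((n,) + e.shape[1:])
        return ad.conv3d_persample(x, mixed, self.bias)
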