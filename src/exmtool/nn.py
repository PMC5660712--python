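"""Compact CPU ConvNet engine for voxelwise boundary classification.

Implements exactly what the boundary detector needs: valid-mode 3-D
convolutions (evaluated as one GEMM per kernel offset), in-plane 2x2
max-pooling, ReLU, and a softmax head, trained patch-by-patch with
stochastic gradient descent plus momentum.

Dense (whole-volume) inference is sliding-window equivalent: pooling
becomes a stride-1 max filter and every downstream layer's kernel offsets
are dilated by 2 per preceding pool (the classic shift-and-stitch /
max-filtering construction), so the dense output at voxel p equals the
patch prediction centered at p, voxel-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetConfig", "ConvNet", "full_config", "small_config", "make_2d_config", "transfer_weights"]


@dataclass
class NetConfig:
    """Architecture description.

    ``conv_channels[i]`` filters of size ``conv_kernels[i]`` (kz, ky, kx),
    ReLU after each; 2x2 in-plane max-pooling after the (1-based) conv
    layers listed in ``pool_after``.  ``fc_widths`` are fully-connected
    layers realised as convolutions (the first spans whatever spatial
    extent remains), followed by a 2-way softmax.  ``patch_shape`` is
    (z, y, x); ``slice_stride`` is the sampling stride along z (every
    ``slice_stride``-th slice of the volume forms the patch depth).
    """

    conv_channels: tuple[int, ...]
    conv_kernels: tuple[tuple[int, int, int], ...]
    pool_after: tuple[int, ...]
    fc_widths: tuple[int, ...]
    patch_shape: tuple[int, int, int]
    slice_stride: int = 1
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_channels) != len(self.conv_kernels):
            raise ValueError("conv_channels and conv_kernels length mismatch")

    def to_dict(self) -> dict:
        return {
            "conv_channels": list(self.conv_channels),
            "conv_kernels": [list(k) for k in self.conv_kernels],
            "pool_after": list(self.pool_after),
            "fc_widths": list(self.fc_widths),
            "patch_shape": list(self.patch_shape),
            "slice_stride": self.slice_stride,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        return cls(
            conv_channels=tuple(d["conv_channels"]),
            conv_kernels=tuple(tuple(k) for k in d["conv_kernels"]),
            pool_after=tuple(d["pool_after"]),
            fc_widths=tuple(d["fc_widths"]),
            patch_shape=tuple(d["patch_shape"]),
            slice_stride=int(d["slice_stride"]),
            n_classes=int(d["n_classes"]),
        )

    def spatial_after_convs(self) -> tuple[int, int, int]:
        z, y, x = self.patch_shape
        for i, (kz, ky, kx) in enumerate(self.conv_kernels, start=1):
            z, y, x = z - kz + 1, y - ky + 1, x - kx + 1
            if min(z, y, x) < 1:
                raise ValueError("patch too small for conv stack")
            if i in self.pool_after:
                y, x = y // 2, x // 2
        return z, y, x


def full_config() -> NetConfig:
    """Full-scale preset: nine convs, three pools, two FC layers, softmax.

    Channel widths follow the VD2D3D lineage; the last three conv layers
    carry depth-3 kernels (the 3-D part), the rest are in-plane.  Input
    patches are 85 x 85 x 7 with every third z slice sampled.
    """
    return NetConfig(
        conv_channels=(24, 24, 36, 36, 48, 48, 60, 60, 100),
        conv_kernels=(
            (1, 3, 3), (1, 3, 3), (1, 3, 3), (1, 3, 3), (1, 3, 3), (1, 3, 3),
            (3, 3, 3), (3, 3, 3), (3, 3, 3),
        ),
        pool_after=(2, 4, 6),
        fc_widths=(100,),
        patch_shape=(7, 85, 85),
        slice_stride=3,
    )


def small_config() -> NetConfig:
    """Reduced preset for CPU-only runs: 5 convs, 1 pool, 19x19x5 patches."""
    return NetConfig(
        conv_channels=(8, 8, 12, 12, 12),
        conv_kernels=((1, 3, 3), (1, 3, 3), (1, 3, 3), (3, 3, 3), (3, 3, 3)),
        pool_after=(2,),
        fc_widths=(32,),
        patch_shape=(5, 19, 19),
        slice_stride=1,
    )


def make_2d_config(config: NetConfig) -> NetConfig:
    """The in-plane pre-training variant: depth-1 kernels, single-slice input."""
    return NetConfig(
        conv_channels=config.conv_channels,
        conv_kernels=tuple((1, ky, kx) for (_, ky, kx) in config.conv_kernels),
        pool_after=config.pool_after,
        fc_widths=config.fc_widths,
        patch_shape=(1, config.patch_shape[1], config.patch_shape[2]),
        slice_stride=1,
        n_classes=config.n_classes,
    )


class _Conv:
    def __init__(self, rng, in_ch, out_ch, kernel):
        kz, ky, kx = kernel
        fan_in = in_ch * kz * ky * kx
        self.w = (rng.standard_normal((out_ch, in_ch, kz, ky, kx)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)

    @property
    def kernel(self):
        return self.w.shape[2:]

    def forward(self, x):
        self._x = x
        kz, ky, kx = self.kernel
        B, C, Z, Y, X = x.shape
        Zo, Yo, Xo = Z - kz + 1, Y - ky + 1, X - kx + 1
        out = np.empty((B, self.w.shape[0], Zo, Yo, Xo), dtype=np.float32)
        out[:] = self.b[None, :, None, None, None]
        for dz in range(kz):
            for dy in range(ky):
                for dx in range(kx):
                    xs = x[:, :, dz:dz + Zo, dy:dy + Yo, dx:dx + Xo]
                    out += np.einsum(
                        "oc,bczyx->bozyx", self.w[:, :, dz, dy, dx], xs, optimize=True
                    )
        return out

    def backward(self, g):
        x = self._x
        kz, ky, kx = self.kernel
        Zo, Yo, Xo = g.shape[2:]
        self.gw = np.zeros_like(self.w)
        self.gb = g.sum(axis=(0, 2, 3, 4))
        gx = np.zeros_like(x)
        for dz in range(kz):
            for dy in range(ky):
                for dx in range(kx):
                    xs = x[:, :, dz:dz + Zo, dy:dy + Yo, dx:dx + Xo]
                    self.gw[:, :, dz, dy, dx] = np.einsum(
                        "bozyx,bczyx->oc", g, xs, optimize=True
                    )
                    gx[:, :, dz:dz + Zo, dy:dy + Yo, dx:dx + Xo] += np.einsum(
                        "oc,bozyx->bczyx", self.w[:, :, dz, dy, dx], g, optimize=True
                    )
        return gx

    def forward_dense(self, x, dil):
        # x: (C, Z, Y, X); dil: per-axis dilation of kernel offsets
        kz, ky, kx = self.kernel
        dz_, dy_, dx_ = dil
        C, Z, Y, X = x.shape
        Zo, Yo, Xo = Z - (kz - 1) * dz_, Y - (ky - 1) * dy_, X - (kx - 1) * dx_
        out = np.empty((self.w.shape[0], Zo, Yo, Xo), dtype=np.float32)
        out[:] = self.b[:, None, None, None]
        for dz in range(kz):
            for dy in range(ky):
                for dx in range(kx):
                    xs = x[
                        :,
                        dz * dz_: dz * dz_ + Zo,
                        dy * dy_: dy * dy_ + Yo,
                        dx * dx_: dx * dx_ + Xo,
                    ]
                    out += np.einsum(
                        "oc,czyx->ozyx", self.w[:, :, dz, dy, dx], xs, optimize=True
                    )
        return out, dil

    def step(self, lr, momentum):
        self.vw = momentum * self.vw - lr * self.gw
        self.vb = momentum * self.vb - lr * self.gb
        self.w += self.vw
        self.b += self.vb


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, 0)

    def backward(self, g):
        return g * self._m

    def forward_dense(self, x, dil):
        return np.where(x > 0, x, 0), dil


class _MaxPool:
    """2x2 in-plane pooling; stride 2 on patches, max filter + dilation densely."""

    def forward(self, x):
        B, C, Z, Y, X = x.shape
        Y2, X2 = Y // 2, X // 2
        xc = x[:, :, :, : Y2 * 2, : X2 * 2]
        self._in_shape = x.shape
        r = xc.reshape(B, C, Z, Y2, 2, X2, 2)
        mx_x = r.max(axis=6)
        self._arg_x = r.argmax(axis=6)
        out = mx_x.max(axis=4)
        self._arg_y = mx_x.argmax(axis=4)
        return out

    def backward(self, g):
        B, C, Z, Y, X = self._in_shape
        Y2, X2 = Y // 2, X // 2
        g_mx = np.zeros((B, C, Z, Y2, 2, X2), dtype=g.dtype)
        np.put_along_axis(g_mx, self._arg_y[:, :, :, None, :], g[:, :, :, None, :], axis=4)
        gx = np.zeros((B, C, Z, Y2, 2, X2, 2), dtype=g.dtype)
        np.put_along_axis(gx, self._arg_x[..., None], g_mx[..., None], axis=6)
        out = np.zeros(self._in_shape, dtype=g.dtype)
        out[:, :, :, : Y2 * 2, : X2 * 2] = gx.reshape(B, C, Z, Y2 * 2, X2 * 2)
        return out

    def forward_dense(self, x, dil):
        # x: (C, Z, Y, X)
        dz_, dy_, dx_ = dil
        a = np.maximum(x[:, :, : x.shape[2] - dy_, :], x[:, :, dy_:, :])
        a = np.maximum(a[:, :, :, : a.shape[3] - dx_], a[:, :, :, dx_:])
        return a, (dz_, dy_ * 2, dx_ * 2)


class ConvNet:
    """Sequential ConvNet with a 2-way softmax head.

    ``forward_patch`` maps a batch (B, 1, z, y, x) of standardized image
    patches to class logits (B, 2); ``forward_dense`` maps a whole
    single-channel volume to a per-voxel boundary probability map.
    """

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list = []
        self.conv_layers: list[_Conv] = []
        in_ch = 1
        for i, (ch, kern) in enumerate(zip(config.conv_channels, config.conv_kernels), start=1):
            conv = _Conv(rng, in_ch, ch, kern)
            self.layers += [conv, _ReLU()]
            self.conv_layers.append(conv)
            in_ch = ch
            if i in config.pool_after:
                self.layers.append(_MaxPool())
        rem = config.spatial_after_convs()
        widths = list(config.fc_widths) + [config.n_classes]
        for j, w in enumerate(widths):
            kern = rem if j == 0 else (1, 1, 1)
            conv = _Conv(rng, in_ch, w, kern)
            self.layers.append(conv)
            self.conv_layers.append(conv)
            if j < len(widths) - 1:
                self.layers.append(_ReLU())
            in_ch = w

    # -- training ---------------------------------------------------------
    def forward_patch(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        return h.reshape(h.shape[0], self.config.n_classes)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward_patch(x)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        n = len(y)
        loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
        g = p
        g[np.arange(n), y] -= 1.0
        g = (g / n).astype(np.float32).reshape(n, self.config.n_classes, 1, 1, 1)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    def sgd_step(self, lr: float = 0.001, momentum: float = 0.9) -> None:
        for conv in self.conv_layers:
            conv.step(lr, momentum)

    # -- inference --------------------------------------------------------
    def forward_dense(self, volume: np.ndarray) -> np.ndarray:
        """Boundary probability for every valid position of ``volume`` (Z, Y, X)."""
        h = volume.astype(np.float32)[None]
        dil = (self.config.slice_stride, 1, 1)
        for layer in self.layers:
            h, dil = layer.forward_dense(h, dil)
        z = h - h.max(axis=0, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=0, keepdims=True)
        return p[1]

    def margins(self) -> tuple[int, int, int]:
        """Half-extent of the receptive field per axis, in volume voxels."""
        pz, py, px = self.config.patch_shape
        s = self.config.slice_stride
        return ((pz - 1) * s) // 2, (py - 1) // 2, (px - 1) // 2

    # -- (de)serialization -------------------------------------------------
    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(c.w.copy(), c.b.copy()) for c in self.conv_layers]

    def set_weights(self, weights) -> None:
        for conv, (w, b) in zip(self.conv_layers, weights):
            if conv.w.shape != w.shape:
                raise ValueError("weight shape mismatch")
            conv.w = w.astype(np.float32).copy()
            conv.b = b.astype(np.float32).copy()


def transfer_weights(net2d: ConvNet, net3d: ConvNet, n_layers: int | None = None) -> None:
    """Initialize the 3-D net's first conv layers from the trained 2-D net.

    Shape-matching layers are copied bitwise.  Where the 3-D layer has a
    deeper kernel (3x3x3 vs 3x3x1) the 2-D kernel is embedded at the
    central depth slice with zeros elsewhere, so the transferred layer
    initially computes the same function on the central slice.
    """
    if n_layers is None:
        n_layers = len(net3d.config.conv_channels) - 1
    for i in range(n_layers):
        c2, c3 = net2d.conv_layers[i], net3d.conv_layers[i]
        if c2.w.shape == c3.w.shape:
            c3.w = c2.w.copy()
        else:
            if c2.w.shape[2] != 1 or c2.w.shape[:2] != c3.w.shape[:2] or c2.w.shape[3:] != c3.w.shape[3:]:
                raise ValueError(f"cannot transfer conv layer {i + 1}: {c2.w.shape} -> {c3.w.shape}")
            w = np.zeros_like(c3.w)
            w[:, :, c3.w.shape[2] // 2] = c2.w[:, :, 0]
            c3.w = w
        c3.b = c2.b.copy()
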