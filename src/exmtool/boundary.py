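"""Boundary detection: patch sampling, 2D->3D transfer training, dense inference.

The detector is a pair of ConvNets with identical architecture, one fed
xy-oriented patches and one fed patches whose thin axis lies in-plane
(the xz/yz orientation, realised by transposing the volume).  Inference
produces three boundary probability maps (xy, xz, yz); their voxelwise
median, followed by a 3-D median filter, is the final BPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import ConvNet, NetConfig, make_2d_config, transfer_weights
from .simulate import ImageStack
from .volume import LabelVolume, extract_membrane

__all__ = [
    "BoundaryProbabilityMap",
    "boundary_on_image_grid",
    "PatchSampler",
    "make_training_set",
    "train_2d_then_3d",
    "train_detector_ensemble",
    "infer_bpm",
]


@dataclass
class BoundaryProbabilityMap:
    """Per-voxel boundary probability on the image grid (1 = boundary)."""

    prob: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.prob)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.prob = p


def boundary_on_image_grid(
    volume: LabelVolume, z_step_vox: int, window_vox: int | None = None
) -> np.ndarray:
    """Ground-truth boundary labels on the anisotropic image grid.

    The fine-grid membrane mask is max-pooled into each image voxel: the
    xy pitch matches the fine grid, and each image z plane covers a slab
    of ``z_step_vox`` fine slices.  By default the pooling window is the
    whole slab; ``window_vox`` restricts it to that many fine slices
    centered on the focal plane — matching the window to the PSF's axial
    support keeps the labels aligned with what the image can actually
    show (a membrane at the far edge of a 120 nm slab is invisible to a
    ~30 nm axial PSF, and labeling it boundary is label noise).
    """
    mem = extract_membrane(volume).mask
    nz = mem.shape[0] // z_step_vox
    half = (z_step_vox if window_vox is None else min(window_vox, z_step_vox)) // 2
    out = np.zeros((nz,) + mem.shape[1:], dtype=bool)
    for k in range(nz):
        center = k * z_step_vox + z_step_vox // 2
        lo = max(center - half, 0)
        hi = min(center + half + 1, mem.shape[0])
        out[k] = mem[lo:hi].any(axis=0)
    return out


def _standardize(data: np.ndarray) -> np.ndarray:
    sd = data.std()
    return ((data - data.mean()) / (sd if sd > 0 else 1.0)).astype(np.float32)


def _pad_to(data: np.ndarray, pads: tuple[int, int, int]) -> np.ndarray:
    """Symmetric padding, applied in rounds so pads may exceed axis sizes."""
    out = data
    remaining = list(pads)
    while any(r > 0 for r in remaining):
        step = [min(r, s) for r, s in zip(remaining, out.shape)]
        out = np.pad(out, [(p, p) for p in step], mode="symmetric")
        remaining = [r - p for r, p in zip(remaining, step)]
    return out


_DIHEDRAL = [(k, f) for k in range(4) for f in (False, True)]


def _dihedral(patch: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(patch, k, axes=(1, 2))
    if flip:
        out = out[:, :, ::-1]
    return out


class PatchSampler:
    """Class-balanced patch sampler with dihedral augmentation.

    Volumes are symmetric-padded by the receptive-field margins so every
    voxel is a valid patch center; batches are drawn 1:1 from boundary and
    non-boundary centers, each patch optionally transformed by a random
    element of the in-plane dihedral group (4 rotations x mirror).
    """

    def __init__(
        self,
        images: list[np.ndarray],
        boundaries: list[np.ndarray],
        config: NetConfig,
        rng: np.random.Generator,
        augment: bool = True,
    ):
        if len(images) != len(boundaries) or not images:
            raise ValueError("need matching, non-empty image/boundary lists")
        pz, py, px = config.patch_shape
        s = config.slice_stride
        self.mz, self.my, self.mx = ((pz - 1) * s) // 2, (py - 1) // 2, (px - 1) // 2
        self.config = config
        self.rng = rng
        self.augment = augment
        self.padded = []
        self.pos: list[np.ndarray] = []
        self.neg: list[np.ndarray] = []
        for img, bnd in zip(images, boundaries):
            if img.shape != bnd.shape:
                raise ValueError("image/boundary shape mismatch")
            self.padded.append(_pad_to(_standardize(img), (self.mz, self.my, self.mx)))
            flat = bnd.ravel()
            self.pos.append(np.flatnonzero(flat))
            self.neg.append(np.flatnonzero(~flat))
        if all(p.size == 0 for p in self.pos) or all(n.size == 0 for n in self.neg):
            raise ValueError("need both boundary and non-boundary voxels to sample")
        self.shapes = [img.shape for img in images]

    def _extract(self, vol_idx: int, flat_center: int) -> np.ndarray:
        z, y, x = np.unravel_index(flat_center, self.shapes[vol_idx])
        pz, py, px = self.config.patch_shape
        s = self.config.slice_stride
        pd = self.padded[vol_idx]
        # padded coords: center shifts by the margins
        zc, yc, xc = z + self.mz, y + self.my, x + self.mx
        return pd[
            zc - self.mz: zc + self.mz + 1: s,
            yc - self.my: yc + self.my + 1,
            xc - self.mx: xc + self.mx + 1,
        ]

    def batch(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """A balanced batch: (n, 1, pz, py, px) patches and 0/1 labels."""
        labels = np.zeros(n, dtype=np.int64)
        labels[: n // 2] = 1
        self.rng.shuffle(labels)
        pz, py, px = self.config.patch_shape
        out = np.empty((n, 1, pz, py, px), dtype=np.float32)
        vols_with_pos = [i for i, p in enumerate(self.pos) if p.size]
        vols_with_neg = [i for i, p in enumerate(self.neg) if p.size]
        for i, lab in enumerate(labels):
            v = int(self.rng.choice(vols_with_pos if lab else vols_with_neg))
            pool = self.pos[v] if lab else self.neg[v]
            c = int(pool[self.rng.integers(pool.size)])
            patch = self._extract(v, c)
            if self.augment:
                k, f = _DIHEDRAL[self.rng.integers(8)]
                patch = _dihedral(patch, k, f)
            out[i, 0] = patch
        return out, labels


def make_training_set(
    stacks: list[ImageStack],
    gt: list[LabelVolume],
    config: NetConfig,
    rng: np.random.Generator,
    augment: bool = True,
    orientation: str = "xy",
    boundary_window_vox: int | None = None,
) -> PatchSampler:
    """Build the labeled patch sampler from simulated stacks + ground truth.

    Center-voxel boundary labels come from the fine-grid membrane mask
    max-pooled onto the image grid.  ``orientation='zx'`` transposes
    volumes so the net's thin axis lies in the imaging plane (the xz/yz
    detector of the ensemble).
    """
    images, bounds = [], []
    for stack, vol in zip(stacks, gt):
        z_step_vox = int(round(stack.z_step / vol.voxel_size))
        bnd = boundary_on_image_grid(vol, z_step_vox, boundary_window_vox)
        img = stack.data
        if bnd.shape != img.shape:
            raise ValueError("stack and ground truth grids disagree")
        if orientation == "zx":
            img = img.transpose(1, 0, 2)
            bnd = bnd.transpose(1, 0, 2)
        elif orientation != "xy":
            raise ValueError("orientation must be 'xy' or 'zx'")
        images.append(np.asarray(img, dtype=np.float32))
        bounds.append(bnd)
    return PatchSampler(images, bounds, config, rng, augment=augment)


def train_2d_then_3d(
    sampler: PatchSampler,
    sampler2d: PatchSampler,
    config: NetConfig,
    lr: float = 0.001,
    momentum: float = 0.9,
    batch: int = 100,
    steps_2d: int = 300,
    steps_3d: int = 400,
    seed: int = 0,
) -> tuple[ConvNet, list[float]]:
    """Train the boundary classifier with 2-D pre-training then 3-D fine-tuning.

    An in-plane (depth-1 kernel) variant is trained first; its conv
    weights initialize the corresponding layers of the 3-D net, which is
    then trained end to end.  SGD with momentum; raises on divergence.
    """
    cfg2d = make_2d_config(config)
    net2d = ConvNet(cfg2d, seed=seed)
    losses: list[float] = []
    for step in range(steps_2d):
        x, y = sampler2d.batch(batch)
        loss = net2d.loss_and_grad(x, y)
        if not np.isfinite(loss):
            raise ArithmeticError(f"2-D training diverged at step {step}")
        net2d.sgd_step(lr, momentum)
        losses.append(loss)
    net3d = ConvNet(config, seed=seed + 1)
    transfer_weights(net2d, net3d)
    for step in range(steps_3d):
        x, y = sampler.batch(batch)
        loss = net3d.loss_and_grad(x, y)
        if not np.isfinite(loss):
            raise ArithmeticError(f"3-D training diverged at step {step}")
        net3d.sgd_step(lr, momentum)
        losses.append(loss)
    return net3d, losses


def train_detector_ensemble(
    stacks: list[ImageStack],
    gt: list[LabelVolume],
    config: NetConfig,
    rng: np.random.Generator,
    boundary_window_vox: int | None = None,
    **train_kw,
) -> dict[str, ConvNet]:
    """Train the xy net and the xz/yz net (on transposed volumes)."""
    nets = {}
    for orientation in ("xy", "zx"):
        seed = int(rng.integers(2**31 - 1))
        s3 = make_training_set(stacks, gt, config, np.random.default_rng(seed), orientation=orientation,
                               boundary_window_vox=boundary_window_vox)
        cfg2d = make_2d_config(config)
        s2 = make_training_set(stacks, gt, cfg2d, np.random.default_rng(seed + 1), orientation=orientation,
                               boundary_window_vox=boundary_window_vox)
        nets[orientation], _ = train_2d_then_3d(s3, s2, config, seed=seed + 2, **train_kw)
    return nets


def _dense_map(net: ConvNet, volume: np.ndarray) -> np.ndarray:
    padded = _pad_to(volume, net.margins())
    out = net.forward_dense(padded)
    # pooling floors can leave a trailing surplus voxel per axis; the map is
    # start-aligned with the volume, so crop the tail
    if any(o < s for o, s in zip(out.shape, volume.shape)):
        raise ValueError(f"dense map {out.shape} smaller than volume {volume.shape}")
    return out[: volume.shape[0], : volume.shape[1], : volume.shape[2]]


def infer_bpm(
    stack: ImageStack | np.ndarray,
    nets: dict[str, ConvNet],
    median_filter_size: int = 3,
) -> BoundaryProbabilityMap:
    """Dense multi-orientation inference with median combination.

    Three maps are computed — the xy net on the volume, the xz/yz net on
    the volume transposed twice (thin axis along y, then along x) — then
    combined by the voxelwise median and smoothed with a 3-D median
    filter.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    vol = _standardize(np.asarray(data, dtype=np.float32))
    maps = [_dense_map(nets["xy"], vol)]
    if "zx" in nets:
        maps.append(_dense_map(nets["zx"], vol.transpose(1, 0, 2)).transpose(1, 0, 2))
        maps.append(_dense_map(nets["zx"], vol.transpose(2, 0, 1)).transpose(1, 2, 0))
    for m in maps:
        if m.shape != vol.shape:
            raise ValueError(f"dense map shape {m.shape} != volume shape {vol.shape}")
    combined = np.median(np.stack(maps), axis=0)
    if median_filter_size and median_filter_size > 1:
        combined = ndimage.median_filter(combined, size=median_filter_size)
    prob = np.clip(combined, 0.0, 1.0)
    return BoundaryProbabilityMap(prob=prob, provenance=f"median of {len(maps)} orientations")
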