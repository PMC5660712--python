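"""Ground-truth label volumes for densely packed neural tissue.

A :class:`LabelVolume` is a dense 3-D array of neuron IDs on an isotropic
nanometre grid (axis order ``(z, y, x)``, 0 = unassigned/extracellular).
The synthetic generator emulates cortical neuropil as seen in volume EM:
tubular neurites of varying caliber following smooth random space curves,
a few ellipsoidal somata/boutons, and the remaining space assigned to the
nearest structure so the tissue is space-filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelVolume",
    "MembraneMask",
    "generate_ground_truth",
    "resample_isotropic",
    "extract_membrane",
]


@dataclass
class LabelVolume:
    """Dense segmentation on a regular 3-D grid.

    Parameters
    ----------
    labels : ndarray of uint, shape (Z, Y, X)
        Non-negative neuron IDs; 0 is reserved for "none".
    voxel_size : float
        Edge length of a voxel in nm (isotropic grid).
    origin : tuple of float
        nm offset of voxel (0, 0, 0), order (z, y, x).
    """

    labels: np.ndarray
    voxel_size: float = 6.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_nm(self) -> np.ndarray:
        """Physical size of the volume in nm, order (z, y, x)."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    def n_segments(self) -> int:
        """Number of distinct nonzero labels present."""
        u = np.unique(self.labels)
        return int((u > 0).sum())


@dataclass
class MembraneMask:
    """Boolean membrane mask on the grid of a parent :class:`LabelVolume`.

    A voxel is membrane iff its label differs from at least one
    face-adjacent (6-connected) neighbor.  ``owner`` is the parent voxel's
    label, so membrane voxels remain attributable to their neuron.
    """

    mask: np.ndarray
    owner: np.ndarray
    voxel_size: float = 6.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


def extract_membrane(volume: LabelVolume) -> MembraneMask:
    """Detect boundary voxels of every segment (6-connectivity).

    A voxel belongs to the membrane of its segment when any of its six
    face neighbors carries a different label.  Volume faces do not create
    membrane (out-of-bounds neighbors are ignored), so a uniform volume
    has an empty mask.
    """
    lab = volume.labels
    if lab.size == 0:
        raise ValueError("empty volume")
    mask = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        diff = lab[tuple(sl_a)] != lab[tuple(sl_b)]
        mask[tuple(sl_a)] |= diff
        mask[tuple(sl_b)] |= diff
    return MembraneMask(mask=mask, owner=lab.copy(), voxel_size=volume.voxel_size)


def resample_isotropic(volume: LabelVolume, target_voxel: float) -> LabelVolume:
    """Nearest-neighbor resampling onto an isotropic grid of ``target_voxel`` nm.

    Each output voxel takes the label of the input voxel containing its
    center.  The label set can shrink (small segments may vanish on
    downsampling) but never grows.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    src = volume.voxel_size
    if target_voxel == src:
        return LabelVolume(volume.labels.copy(), voxel_size=src, origin=volume.origin)
    out_shape = tuple(
        max(1, int(np.floor(s * src / target_voxel))) for s in volume.shape
    )
    idx = []
    for n_out, n_in in zip(out_shape, volume.shape):
        centers = (np.arange(n_out) + 0.5) * target_voxel
        j = np.floor(centers / src).astype(np.intp)
        idx.append(np.clip(j, 0, n_in - 1))
    out = volume.labels[np.ix_(*idx)]
    return LabelVolume(out.copy(), voxel_size=float(target_voxel), origin=volume.origin)


def _persistent_walk(rng, start, direction, step, persistence, bounds, max_steps):
    """Smooth random space curve: unit direction relaxes toward noise."""
    pts = [np.asarray(start, dtype=float)]
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    for _ in range(max_steps):
        noise = rng.standard_normal(3)
        d = persistence * d + (1.0 - persistence) * noise
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            d = rng.standard_normal(3)
            nrm = np.linalg.norm(d)
        d = d / nrm
        nxt = pts[-1] + step * d
        pts.append(nxt)
        if np.any(nxt < -bounds * 0.2) or np.any(nxt > bounds * 1.2):
            break
    return np.asarray(pts)


def _paint_ball(labels: np.ndarray, center_vox: np.ndarray, radius_vox: float, value: int) -> None:
    """Write ``value`` into all voxels within ``radius_vox`` of ``center_vox``."""
    r = max(radius_vox, 0.0)
    lo = np.maximum(np.floor(center_vox - r).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + r).astype(int) + 1, labels.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (
        (zz - center_vox[0]) ** 2
        + (yy - center_vox[1]) ** 2
        + (xx - center_vox[2]) ** 2
    )
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[d2 <= r * r] = value


def generate_ground_truth(
    shape_vox: tuple[int, int, int],
    voxel_size: float = 6.0,
    neurite_params: dict | None = None,
    seed: int = 0,
    extracellular_gap_nm: float = 0.0,
) -> LabelVolume:
    """Generate a dense, space-filling synthetic neuropil label volume.

    Neurites are tubes along persistent random walks, dilated to radii
    sampled log-uniformly from ``radius_range``; a fraction of structures
    are ellipsoidal blobs standing in for somata/boutons.  Voxels not
    covered by any tube are assigned to the nearest structure, so by
    default the tissue fully tiles the volume (as in cortical neuropil).

    Parameters
    ----------
    shape_vox : (Z, Y, X), each >= 16.
    voxel_size : nm per voxel edge.
    neurite_params : dict with keys
        ``count`` (number of structures), ``radius_range`` (nm, low/high),
        ``tortuosity`` (0 = straight .. 1 = diffusive), ``soma_fraction``.
    seed : RNG seed; output is bit-reproducible for a fixed seed.
    extracellular_gap_nm : if > 0, carve a label-0 gap of roughly this
        width along all inter-segment boundaries.
    """
    shape_vox = tuple(int(s) for s in shape_vox)
    if len(shape_vox) != 3 or any(s < 16 for s in shape_vox):
        raise ValueError("shape_vox must be three ints, each >= 16")
    params = dict(count=12, radius_range=(50.0, 400.0), tortuosity=0.15, soma_fraction=0.1)
    if neurite_params:
        unknown = set(neurite_params) - set(params)
        if unknown:
            raise ValueError(f"unknown neurite_params: {sorted(unknown)}")
        params.update(neurite_params)
    count = int(params["count"])
    if count < 0:
        raise ValueError("count must be >= 0")
    labels = np.zeros(shape_vox, dtype=np.uint32)
    if count == 0:
        return LabelVolume(labels, voxel_size=voxel_size)

    r_lo, r_hi = (float(r) for r in params["radius_range"])
    extent = np.asarray(shape_vox, dtype=float) * voxel_size
    if not (voxel_size < r_lo <= r_hi < extent.min()):
        raise ValueError("radius_range must lie within (voxel_size, volume extent)")
    tort = float(np.clip(params["tortuosity"], 0.0, 1.0))
    persistence = 1.0 - 0.9 * tort

    rng = np.random.default_rng(seed)
    radii = np.exp(rng.uniform(np.log(r_lo), np.log(r_hi), size=count))
    is_soma = rng.random(count) < float(params["soma_fraction"])
    # keep structure 1 a tube so thin processes are always present
    if count > 0:
        is_soma[0] = False

    curves: list[np.ndarray] = []  # voxel coordinates, (z, y, x)
    for i in range(count):
        r_vox = radii[i] / voxel_size
        if is_soma[i]:
            c = rng.uniform(0.2, 0.8, size=3) * np.asarray(shape_vox)
            curves.append(c[None, :])
            continue
        start = rng.uniform(0.0, 1.0, size=3) * np.asarray(shape_vox)
        direction = rng.standard_normal(3)
        step = max(1.0, r_vox / 2.0)
        max_steps = int(3 * max(shape_vox) / step) + 8
        curves.append(
            _persistent_walk(
                rng, start, direction, step, persistence,
                np.asarray(shape_vox, dtype=float), max_steps,
            )
        )

    # paint thick structures first so thin ones survive crossings
    order = np.argsort(-radii, kind="stable")
    for i in order:
        r_vox = radii[i] / voxel_size
        if is_soma[i]:
            r_vox *= 2.0  # somata/boutons are blobs a few calibers wide
        for p in curves[i]:
            _paint_ball(labels, p, r_vox, i + 1)
    # re-assert skeletons (thin-first order = reverse of paint order)
    for i in order[::-1]:
        for p in curves[i]:
            _paint_ball(labels, p, 1.0, i + 1)

    # guarantee every structure owns at least one voxel
    present = np.zeros(count + 1, dtype=bool)
    present[np.unique(labels)] = True
    for i in range(count):
        if not present[i + 1]:
            c = np.clip(curves[i][0], 1, np.asarray(shape_vox) - 2)
            _paint_ball(labels, c, 2.0, i + 1)

    # space-filling: unlabeled voxels join the nearest labeled structure
    if np.any(labels == 0):
        _, (iz, iy, ix) = ndimage.distance_transform_edt(
            labels == 0, return_indices=True
        )
        labels = labels[iz, iy, ix]

    if extracellular_gap_nm > 0:
        vol = LabelVolume(labels, voxel_size=voxel_size)
        mem = extract_membrane(vol).mask
        half = max(1, int(round(extracellular_gap_nm / (2 * voxel_size))))
        if half > 1:
            mem = ndimage.binary_dilation(mem, iterations=half - 1)
        labels = labels.copy()
        labels[mem] = 0

    return LabelVolume(labels.astype(np.uint32), voxel_size=voxel_size)
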