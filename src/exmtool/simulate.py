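"""Forward model of expansion-microscopy confocal imaging.

Pipeline: stochastic fluorophore labeling of membranes and cytosol ->
per-point Gaussian puncta (fluorophore clusters on antibodies) -> raster
onto the fine ground-truth grid -> convolution with the expansion-scaled
confocal PSF -> sampling at the confocal pixel pitch and z step ->
Poisson shot noise and Gaussian read noise.

All lengths and densities are in pre-expansion sample units; expansion is
carried entirely by the scaled PSF.  Internal point coordinates are
``(z, y, x)`` nm; the barcode CSV interface uses ``x_nm, y_nm, z_nm``
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .optics import PSFKernel
from .volume import LabelVolume, MembraneMask

__all__ = [
    "FluorophoreField",
    "ImageStack",
    "BarcodeSet",
    "label_membranes",
    "label_volume_compartment",
    "apply_puncta",
    "assign_brainbow_colors",
    "assign_channels",
    "place_barcodes",
    "rasterize_field",
    "render_stack",
    "combined_localization_sd",
    "IMAGING_DEFAULTS",
]

# Default simulation parameter ranges (pre-expansion units).
IMAGING_DEFAULTS = {
    "magnification": 40.0,
    "na": 1.15,
    "physical_pixel_pitch_um": 4.8,
    "z_step_nm": 120.0,
    "snr_read": (50.0, 100.0),
    "snr_poisson": (7.0, 12.0),
    "expansion_factor": 20.0,
    "density_membrane_per_um2": (4000.0, 10000.0),
    "density_cytosol_per_um3": (2000.0, 4000.0),
    "density_background_per_um3": (1000.0, 2000.0),
    "density_barcodes_per_um3": (5.0, 300.0),
    "localization_sd_nm": 20.0,
    "cluster_sd_nm": (1.0, 48.0),
}

CHANNELS = ("R", "G", "B")


@dataclass
class FluorophoreField:
    """Continuous-coordinate fluorophore puncta.

    ``points`` is (N, 3) nm in (z, y, x); ``owner`` is the parent neuron
    label per point (0 for background), ``cluster_sigma`` the per-point
    Gaussian cluster SD in nm, ``channel`` an index into ``CHANNELS``.
    """

    points: np.ndarray
    amplitude: np.ndarray
    owner: np.ndarray
    cluster_sigma: np.ndarray
    channel: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        n = len(self.points)
        self.amplitude = np.broadcast_to(np.asarray(self.amplitude, dtype=float), (n,)).copy()
        self.owner = np.broadcast_to(np.asarray(self.owner, dtype=np.int64), (n,)).copy()
        self.cluster_sigma = np.broadcast_to(
            np.asarray(self.cluster_sigma, dtype=float), (n,)
        ).copy()
        self.channel = np.broadcast_to(np.asarray(self.channel, dtype=np.int8), (n,)).copy()
        if n and self.amplitude.min() <= 0:
            raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls) -> "FluorophoreField":
        z = np.zeros(0)
        return cls(z.reshape(0, 3), z, z.astype(int), z, z.astype(int))

    @classmethod
    def concatenate(cls, fields: list["FluorophoreField"]) -> "FluorophoreField":
        fields = [f for f in fields if len(f)]
        if not fields:
            return cls.empty()
        return cls(
            np.concatenate([f.points for f in fields]),
            np.concatenate([f.amplitude for f in fields]),
            np.concatenate([f.owner for f in fields]),
            np.concatenate([f.cluster_sigma for f in fields]),
            np.concatenate([f.channel for f in fields]),
        )


@dataclass
class ImageStack:
    """Simulated confocal stack; ``data`` is (z, y, x), pitches pre-expansion nm."""

    data: np.ndarray
    xy_pitch: float
    z_step: float
    snr_poisson: float | None = None
    snr_read: float | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BarcodeSet:
    """Error-free cell-identity barcodes: positions (z, y, x) nm + identities."""

    points: np.ndarray
    identity: np.ndarray
    density: float  # barcodes / um^3 (requested)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.identity = np.asarray(self.identity, dtype=np.int64).reshape(-1)
        if len(self.points) != len(self.identity):
            raise ValueError("points and identity length mismatch")

    def __len__(self) -> int:
        return len(self.points)


def combined_localization_sd(*sds: float) -> float:
    """Root-sum-square of independent localization error SDs (nm).

    The default membrane label is delivered by a primary plus a secondary
    antibody, each contributing ~14 nm of independent positional error;
    their combination is sqrt(14^2 + 14^2) ~ 20 nm, the default
    ``localization_sd``.
    """
    if not sds:
        sds = (14.0, 14.0)
    return float(np.sqrt(np.sum(np.square(sds))))


def _draw_densities(rng, density_range, n):
    lo, hi = (float(d) for d in density_range)
    if lo > hi:
        raise ValueError("density range inverted")
    return rng.uniform(lo, hi, size=n)


def label_membranes(
    mask: MembraneMask,
    density_range: tuple[float, float] = IMAGING_DEFAULTS["density_membrane_per_um2"],
    jitter_sd: float = IMAGING_DEFAULTS["localization_sd_nm"],
    per_neuron: bool = True,
    rng: np.random.Generator | None = None,
) -> FluorophoreField:
    """Poisson membrane labeling with finite localization accuracy.

    Each neuron draws its own areal density uniformly from
    ``density_range`` (puncta/um^2), modeling neuron-to-neuron variation
    in label expression; with ``per_neuron=False`` a single draw is shared.
    The expected count per neuron is density x membrane area (membrane
    voxel count x voxel face area); realized counts are Poisson.  Points
    sit at membrane-voxel centers plus isotropic Gaussian jitter of SD
    ``jitter_sd`` nm (antibody-stack localization accuracy).
    """
    rng = np.random.default_rng() if rng is None else rng
    vox = mask.voxel_size
    mem_idx = np.flatnonzero(mask.mask.ravel())
    if mem_idx.size == 0:
        return FluorophoreField.empty()
    owners = mask.owner.ravel()[mem_idx]
    labels = np.unique(owners)
    face_area_um2 = (vox * 1e-3) ** 2

    shared = _draw_densities(rng, density_range, 1)[0]
    parts = []
    for lab in labels:
        sel = mem_idx[owners == lab]
        dens = _draw_densities(rng, density_range, 1)[0] if per_neuron else shared
        lam = dens * sel.size * face_area_um2
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        pick = rng.choice(sel, size=n, replace=True)
        zyx = np.stack(np.unravel_index(pick, mask.shape), axis=1).astype(float)
        pts = (zyx + 0.5) * vox + rng.normal(0.0, jitter_sd, size=(n, 3))
        parts.append(
            FluorophoreField(pts, np.ones(n), np.full(n, lab), np.zeros(n), np.zeros(n))
        )
    return FluorophoreField.concatenate(parts)


def label_volume_compartment(
    region: np.ndarray,
    density_range: tuple[float, float],
    voxel_size: float,
    owner: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> FluorophoreField:
    """Uniform volumetric labeling of a boolean region (puncta/um^3).

    Models cytosolic label and non-specific background/auto-fluorescence.
    Points are uniform within the region's voxels; the realized count is
    Poisson with mean density x region volume.
    """
    rng = np.random.default_rng() if rng is None else rng
    region = np.asarray(region, dtype=bool)
    idx = np.flatnonzero(region.ravel())
    if idx.size == 0:
        return FluorophoreField.empty()
    vol_um3 = idx.size * (voxel_size * 1e-3) ** 3
    dens = _draw_densities(rng, density_range, 1)[0]
    n = int(rng.poisson(dens * vol_um3))
    if n == 0:
        return FluorophoreField.empty()
    pick = rng.choice(idx, size=n, replace=True)
    zyx = np.stack(np.unravel_index(pick, region.shape), axis=1).astype(float)
    pts = (zyx + rng.uniform(0.0, 1.0, size=(n, 3))) * voxel_size
    own = np.zeros(n, dtype=np.int64) if owner is None else owner.ravel()[pick]
    return FluorophoreField(pts, np.ones(n), own, np.zeros(n), np.zeros(n))


def apply_puncta(
    field: FluorophoreField,
    cluster_sd_range: tuple[float, float] = IMAGING_DEFAULTS["cluster_sd_nm"],
    rng: np.random.Generator | None = None,
) -> FluorophoreField:
    """Assign each fluorophore a random Gaussian cluster size (puncta).

    The per-point sigma is drawn uniformly from ``cluster_sd_range`` nm;
    rasterization later spreads the point's amplitude with that Gaussian,
    conserving total amplitude.
    """
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = (float(s) for s in cluster_sd_range)
    if lo > hi or lo < 0:
        raise ValueError("bad cluster_sd_range")
    sig = rng.uniform(lo, hi, size=len(field))
    return FluorophoreField(
        field.points.copy(), field.amplitude.copy(), field.owner.copy(), sig, field.channel.copy()
    )


def assign_brainbow_colors(
    volume: LabelVolume, rng: np.random.Generator | None = None
) -> dict[int, np.ndarray]:
    """Random average color per neuron: a point on the RGB simplex."""
    rng = np.random.default_rng() if rng is None else rng
    labels = np.unique(volume.labels)
    labels = labels[labels > 0]
    mixes = rng.dirichlet(np.ones(3), size=labels.size)
    return {int(l): mixes[i] for i, l in enumerate(labels)}


def assign_channels(
    field: FluorophoreField,
    mixtures: dict[int, np.ndarray],
    rng: np.random.Generator | None = None,
) -> FluorophoreField:
    """Assign each fluorophore exactly one channel, multinomially per neuron.

    Mutually exclusive channel assignment (each point is R, G or B) with
    probabilities given by its neuron's color mixture; points without a
    neuron (owner 0) use a uniform mixture.
    """
    rng = np.random.default_rng() if rng is None else rng
    chan = np.zeros(len(field), dtype=np.int8)
    uniform = np.ones(3) / 3.0
    for lab in np.unique(field.owner):
        sel = field.owner == lab
        mix = np.asarray(mixtures.get(int(lab), uniform), dtype=float)
        mix = mix / mix.sum()
        chan[sel] = rng.choice(3, size=int(sel.sum()), p=mix)
    out = FluorophoreField(
        field.points.copy(), field.amplitude.copy(), field.owner.copy(),
        field.cluster_sigma.copy(), chan,
    )
    return out


def place_barcodes(
    volume: LabelVolume,
    density: float,
    rng: np.random.Generator | None = None,
) -> BarcodeSet:
    """Uniform random cell-identity barcodes throughout the volume.

    Positions are uniform over the whole volume; each barcode's identity
    is the ground-truth label of the voxel containing it (error-free
    readout).  Points landing on label 0 (no neuron) are discarded.
    Expected total count = density x volume (barcodes/um^3).
    """
    rng = np.random.default_rng() if rng is None else rng
    if density < 0:
        raise ValueError("density must be >= 0")
    ext = volume.extent_nm
    vol_um3 = float(np.prod(ext)) * 1e-9
    n = int(rng.poisson(density * vol_um3))
    pts = rng.uniform(0.0, 1.0, size=(n, 3)) * ext
    if n:
        vox = np.minimum((pts / volume.voxel_size).astype(int), np.asarray(volume.shape) - 1)
        ident = volume.labels[vox[:, 0], vox[:, 1], vox[:, 2]].astype(np.int64)
        keep = ident > 0
        pts, ident = pts[keep], ident[keep]
    else:
        ident = np.zeros(0, dtype=np.int64)
    return BarcodeSet(points=pts, identity=ident, density=float(density))


def rasterize_field(
    field: FluorophoreField,
    shape: tuple[int, int, int],
    voxel_size: float,
    n_sigma_bins: int = 8,
) -> np.ndarray:
    """Deposit puncta onto the fine grid and apply their Gaussian spread.

    Sub-voxel positions are handled by trilinear (cloud-in-cell)
    deposition; the per-point cluster sigma is quantized into
    ``n_sigma_bins`` bins, each bin blurred with its central sigma.  Total
    amplitude is conserved up to boundary truncation.
    """
    img = np.zeros(shape, dtype=np.float64)
    if len(field) == 0:
        return img
    pos = field.points / voxel_size - 0.5  # voxel-center coordinates
    base = np.floor(pos).astype(np.int64)
    frac = pos - base
    sig_vox = field.cluster_sigma / voxel_size

    edges = np.linspace(sig_vox.min(), sig_vox.max(), n_sigma_bins + 1)
    bin_of = np.clip(np.digitize(sig_vox, edges) - 1, 0, n_sigma_bins - 1)
    for b in range(n_sigma_bins):
        sel = np.flatnonzero(bin_of == b)
        if sel.size == 0:
            continue
        raster = np.zeros(shape, dtype=np.float64)
        for dz in (0, 1):
            for dy in (0, 1):
                for dx in (0, 1):
                    w = (
                        (frac[sel, 0] if dz else 1 - frac[sel, 0])
                        * (frac[sel, 1] if dy else 1 - frac[sel, 1])
                        * (frac[sel, 2] if dx else 1 - frac[sel, 2])
                    ) * field.amplitude[sel]
                    zz = base[sel, 0] + dz
                    yy = base[sel, 1] + dy
                    xx = base[sel, 2] + dx
                    ok = (
                        (zz >= 0) & (zz < shape[0])
                        & (yy >= 0) & (yy < shape[1])
                        & (xx >= 0) & (xx < shape[2])
                    )
                    np.add.at(raster, (zz[ok], yy[ok], xx[ok]), w[ok])
        sigma = float(sig_vox[sel].mean())
        if sigma > 1e-3:
            raster = ndimage.gaussian_filter(raster, sigma, mode="constant", truncate=4.0)
        img += raster
    return img


def _convolve_psf(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Frequency-domain convolution with reflective edge padding."""
    pad = [min(k // 2, s) for k, s in zip(kernel.shape, img.shape)]
    padded = np.pad(img, [(p, p) for p in pad], mode="reflect")
    out = signal.fftconvolve(padded, kernel, mode="same")
    slc = tuple(slice(p, p + s) for p, s in zip(pad, img.shape))
    return np.clip(out[slc], 0, None)


def render_stack(
    fields: FluorophoreField | list[FluorophoreField],
    psf: PSFKernel,
    volume_shape: tuple[int, int, int],
    voxel_size: float = 6.0,
    z_step: float = IMAGING_DEFAULTS["z_step_nm"],
    snr_poisson_range: tuple[float, float] | None = IMAGING_DEFAULTS["snr_poisson"],
    snr_read_range: tuple[float, float] | None = IMAGING_DEFAULTS["snr_read"],
    rng: np.random.Generator | None = None,
    read_sd: float | None = None,
) -> ImageStack:
    """Project fluorophores onto a confocal image stack.

    Steps: rasterize puncta on the fine (ground-truth) grid; convolve with
    the expansion-scaled PSF (resampled to that grid if its pitch
    differs); sample focal planes every ``z_step`` nm; scale so the
    brightest pixel's expected photon count equals snr_poisson^2, apply
    Poisson sampling, then add Gaussian read noise with SD = brightest
    expected value / snr_read, clipping at zero.  Pass ``None`` for a
    noise range to skip that noise source.
    """
    rng = np.random.default_rng() if rng is None else rng
    flist = fields if isinstance(fields, list) else [fields]
    merged = FluorophoreField.concatenate(flist)

    fine = rasterize_field(merged, tuple(volume_shape), voxel_size)

    kernel = psf.intensity
    if not np.allclose(psf.voxel_pitch, (voxel_size,) * 3, rtol=1e-6):
        from .optics import resample_psf

        kernel = resample_psf(psf, (voxel_size,) * 3).intensity
    blurred = _convolve_psf(fine, kernel)

    step_vox = max(1, int(round(z_step / voxel_size)))
    z_planes = np.arange(step_vox // 2, volume_shape[0], step_vox)
    expected = blurred[z_planes]

    peak = float(expected.max())
    snr_p = snr_r = None
    if snr_poisson_range is not None and peak > 0:
        snr_p = float(rng.uniform(*snr_poisson_range))
        expected = expected * (snr_p**2 / peak)
        data = rng.poisson(expected).astype(np.float64)
    else:
        data = expected.copy()
    if snr_read_range is not None:
        snr_r = float(rng.uniform(*snr_read_range))
        bright = float(expected.max())
        sd = read_sd if read_sd is not None else (bright / snr_r if bright > 0 else 0.0)
        if read_sd is not None and bright == 0:
            sd = read_sd
        data = data + rng.normal(0.0, sd, size=data.shape) if sd > 0 else data
    data = np.clip(data, 0, None)
    return ImageStack(
        data=data, xy_pitch=voxel_size, z_step=step_vox * voxel_size,
        snr_poisson=snr_p, snr_read=snr_r,
    )
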