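"""File interfaces: HDF5 / multi-page TIFF volumes, barcode CSV, YAML configs.

All voxel arrays are stored z-major (z, y, x), 0-based; barcode tables use
``x_nm, y_nm, z_nm, identity`` columns (column order follows the common
point-table convention, internal arrays stay (z, y, x)).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .boundary import BoundaryProbabilityMap
from .optics import PSFKernel
from .simulate import BarcodeSet, ImageStack
from .volume import LabelVolume

__all__ = [
    "save_labels_h5", "load_labels_h5", "save_labels_tiff", "load_labels_tiff",
    "save_stack_h5", "load_stack_h5", "save_stack_tiff",
    "save_psf_h5", "load_psf_h5",
    "save_bpm_h5", "load_bpm_h5",
    "save_barcodes_csv", "load_barcodes_csv",
    "save_detector", "load_detector",
    "save_yaml", "load_yaml",
]


def save_labels_h5(path, volume: LabelVolume) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=volume.labels, compression="gzip")
        d.attrs["voxel_size_nm"] = volume.voxel_size
        d.attrs["origin_nm"] = volume.origin


def load_labels_h5(path) -> LabelVolume:
    with h5py.File(path, "r") as f:
        d = f["labels"]
        return LabelVolume(
            labels=d[()],
            voxel_size=float(d.attrs.get("voxel_size_nm", 6.0)),
            origin=tuple(d.attrs.get("origin_nm", (0.0, 0.0, 0.0))),
        )


def save_labels_tiff(path, volume: LabelVolume) -> None:
    tifffile.imwrite(path, volume.labels.astype(np.uint32))


def load_labels_tiff(path, voxel_size: float = 6.0) -> LabelVolume:
    return LabelVolume(labels=tifffile.imread(path).astype(np.uint32), voxel_size=voxel_size)


def save_stack_h5(path, stack: ImageStack) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("image", data=stack.data.astype(np.float32), compression="gzip")
        d.attrs["xy_pitch_nm"] = stack.xy_pitch
        d.attrs["z_step_nm"] = stack.z_step
        if stack.snr_poisson is not None:
            d.attrs["snr_poisson"] = stack.snr_poisson
        if stack.snr_read is not None:
            d.attrs["snr_read"] = stack.snr_read


def load_stack_h5(path) -> ImageStack:
    with h5py.File(path, "r") as f:
        d = f["image"]
        return ImageStack(
            data=d[()].astype(np.float64),
            xy_pitch=float(d.attrs["xy_pitch_nm"]),
            z_step=float(d.attrs["z_step_nm"]),
            snr_poisson=float(d.attrs["snr_poisson"]) if "snr_poisson" in d.attrs else None,
            snr_read=float(d.attrs["snr_read"]) if "snr_read" in d.attrs else None,
        )


def save_stack_tiff(path, stack: ImageStack) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")


def save_psf_h5(path, psf: PSFKernel) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("psf", data=psf.intensity, compression="gzip")
        d.attrs["voxel_pitch_nm"] = psf.voxel_pitch
        d.attrs["na"] = psf.na
        d.attrs["wavelength_ex_nm"] = psf.wavelength_ex
        d.attrs["wavelength_em_nm"] = psf.wavelength_em
        d.attrs["expansion_factor"] = psf.expansion_factor


def load_psf_h5(path) -> PSFKernel:
    with h5py.File(path, "r") as f:
        d = f["psf"]
        return PSFKernel(
            intensity=d[()],
            voxel_pitch=tuple(d.attrs["voxel_pitch_nm"]),
            na=float(d.attrs["na"]),
            wavelength_ex=float(d.attrs["wavelength_ex_nm"]),
            wavelength_em=float(d.attrs["wavelength_em_nm"]),
            expansion_factor=float(d.attrs["expansion_factor"]),
        )


def save_bpm_h5(path, bpm: BoundaryProbabilityMap) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("bpm", data=bpm.prob.astype(np.float32), compression="gzip")
        d.attrs["provenance"] = bpm.provenance


def load_bpm_h5(path) -> BoundaryProbabilityMap:
    with h5py.File(path, "r") as f:
        d = f["bpm"]
        return BoundaryProbabilityMap(prob=d[()].astype(np.float64),
                                      provenance=str(d.attrs.get("provenance", "")))


def save_barcodes_csv(path, barcodes: BarcodeSet) -> None:
    pd.DataFrame(
        {
            "x_nm": barcodes.points[:, 2],
            "y_nm": barcodes.points[:, 1],
            "z_nm": barcodes.points[:, 0],
            "identity": barcodes.identity,
        }
    ).to_csv(path, index=False)


def load_barcodes_csv(path, density: float = float("nan")) -> BarcodeSet:
    df = pd.read_csv(path)
    pts = np.stack([df["z_nm"], df["y_nm"], df["x_nm"]], axis=1)
    return BarcodeSet(points=pts, identity=df["identity"].to_numpy(), density=density)


def save_detector(path, nets: dict) -> None:
    """Portable detector checkpoint: one .npz with configs and weights."""
    import json

    from .nn import ConvNet

    arrays: dict[str, np.ndarray] = {}
    meta = {}
    for name, net in nets.items():
        meta[name] = net.config.to_dict()
        for i, (w, b) in enumerate(net.get_weights()):
            arrays[f"{name}/w{i}"] = w
            arrays[f"{name}/b{i}"] = b
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_detector(path) -> dict:
    import json

    from .nn import ConvNet, NetConfig

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        nets = {}
        for name, cfg in meta.items():
            net = ConvNet(NetConfig.from_dict(cfg), seed=0)
            weights = []
            i = 0
            while f"{name}/w{i}" in data:
                weights.append((data[f"{name}/w{i}"], data[f"{name}/b{i}"]))
                i += 1
            net.set_weights(weights)
            nets[name] = net
    return nets


def save_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
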