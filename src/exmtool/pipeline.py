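"""End-to-end orchestration: simulate -> detect -> segment -> consolidate -> evaluate.

Mirrors the train/test protocol of the study design: several simulated
images from a set of training ground-truth volumes train the boundary
detector and the merge policy; one image from a held-out ground-truth
volume is reconstructed and scored.  Emits three score tables:

* ``watershed``  — the precision-recall-style sweep of the H-minima
  threshold (direct watershed segmentation quality),
* ``tree_levels`` — every hierarchy level (agglomeration without barcodes),
* ``barcodes``   — the consolidation sweep over barcode densities.

Every stochastic stage derives its RNG from the master seed plus a stage
tag, so a fixed master seed reproduces the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcodes as bc
from . import boundary as bd
from . import nn
from . import optics
from . import segmentation as seg
from . import simulate as sim
from .evaluation import score
from .volume import LabelVolume, extract_membrane, generate_ground_truth

__all__ = ["RunConfig", "run_experiment", "gt_on_image_grid", "simulate_image"]

_STAGES = {"groundtruth": 1, "simulate": 2, "train": 3, "policy": 4, "sweep": 5, "barcodes": 6}


@dataclass
class RunConfig:
    """Full parameterization of one experiment.

    Defaults follow the reference imaging conditions (see
    :data:`exmtool.simulate.IMAGING_DEFAULTS`); the ``preset`` constructors choose
    problem sizes: ``ci`` for routine CPU runs, ``mini`` for quick
    multi-seed checks, ``full`` for full-scale volumes (~3 um at 6 nm).
    """

    seed: int = 0
    preset: str = "ci"
    # ground truth
    gt_shape: tuple[int, int, int] = (320, 128, 128)
    voxel_size: float = 6.0
    neurite_count: int = 18
    radius_range: tuple[float, float] = (50.0, 200.0)
    tortuosity: float = 0.15
    soma_fraction: float = 0.1
    n_train_volumes: int = 2
    images_per_volume: int = 2
    # optics
    na: float = optics.DEFAULT_NA
    wavelength_ex: float = optics.DEFAULT_WAVELENGTH_EX
    wavelength_em: float = optics.DEFAULT_WAVELENGTH_EM
    expansion_factor: float = sim.IMAGING_DEFAULTS["expansion_factor"]
    # simulation (pre-expansion units)
    z_step: float = sim.IMAGING_DEFAULTS["z_step_nm"]
    density_membrane: tuple[float, float] = sim.IMAGING_DEFAULTS["density_membrane_per_um2"]
    density_cytosol: tuple[float, float] = sim.IMAGING_DEFAULTS["density_cytosol_per_um3"]
    density_background: tuple[float, float] = sim.IMAGING_DEFAULTS["density_background_per_um3"]
    localization_sd: float = sim.IMAGING_DEFAULTS["localization_sd_nm"]
    cluster_sd: tuple[float, float] = sim.IMAGING_DEFAULTS["cluster_sd_nm"]
    snr_poisson: tuple[float, float] = sim.IMAGING_DEFAULTS["snr_poisson"]
    snr_read: tuple[float, float] = sim.IMAGING_DEFAULTS["snr_read"]
    # detector
    boundary_window_nm: float | None = None  # axial pooling window for boundary labels (None = full slab)
    net_preset: str = "small"
    steps_2d: int = 250
    steps_3d: int = 350
    batch_size: int = 100
    learning_rate: float = 0.001
    momentum: float = 0.9
    # segmentation
    h_min: float = seg.DEFAULT_H_MIN
    h_min_sweep: tuple[float, ...] = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3)
    thresholds: tuple[float, ...] = seg.DEFAULT_THRESHOLDS
    policy_rounds: int = 3
    # barcodes
    barcode_densities: tuple[float, ...] = (5.0, 10.0, 30.0, 100.0, 300.0)
    barcode_trials: int = 5
    exclusion_nm: float = bc.DEFAULT_EXCLUSION_NM

    @classmethod
    def ci(cls, seed: int = 0) -> "RunConfig":
        return cls(seed=seed, preset="ci")

    @classmethod
    def mini(cls, seed: int = 0) -> "RunConfig":
        """Smallest end-to-end configuration, for multi-seed smoke runs."""
        return cls(
            seed=seed,
            preset="mini",
            gt_shape=(240, 96, 96),
            neurite_count=12,
            radius_range=(50.0, 160.0),
            n_train_volumes=1,
            images_per_volume=2,
            steps_2d=200,
            steps_3d=300,
            h_min_sweep=(0.003, 0.01, 0.1),
            barcode_densities=(5.0, 30.0, 300.0),
            barcode_trials=3,
        )

    @classmethod
    def full(cls, seed: int = 0) -> "RunConfig":
        """Full-scale conditions: ~3 um volumes, the nine-conv detector."""
        return cls(
            seed=seed,
            preset="full",
            gt_shape=(500, 500, 500),
            neurite_count=60,
            radius_range=(50.0, 400.0),
            n_train_volumes=3,
            images_per_volume=4,
            net_preset="full",
            steps_2d=5000,
            steps_3d=10000,
        )

    def net_config(self) -> nn.NetConfig:
        return nn.full_config() if self.net_preset == "full" else nn.small_config()

    def stage_rng(self, stage: str, index: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGES[stage], index])

    def stage_seed(self, stage: str, index: int = 0) -> int:
        return int(self.stage_rng(stage, index).integers(2**31 - 1))

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v

        return {k: plain(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kw and isinstance(kw[f.name], list):
                kw[f.name] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in kw[f.name]
                )
        return cls(**kw)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(sorted(self.to_dict().items())).encode()).hexdigest()[:12]


def split_at_matched_merge(levels: pd.DataFrame, merge_value: float, kind: str = "rand") -> float:
    """Split score of the agglomeration curve at a given merge score.

    The hierarchy levels trace a precision-recall-style curve in
    (merge, split) space; this interpolates the split score linearly at
    ``merge_value`` so a barcode-consolidated operating point can be
    compared against the no-barcode curve at matched merge.  Outside the
    curve's merge range the nearest endpoint is used.
    """
    m = levels[f"{kind}_merge"].to_numpy(dtype=float)
    s = levels[f"{kind}_split"].to_numpy(dtype=float)
    ok = ~(np.isnan(m) | np.isnan(s))
    m, s = m[ok], s[ok]
    order = np.argsort(m)
    return float(np.interp(merge_value, m[order], s[order]))


def gt_on_image_grid(volume: LabelVolume, z_step_vox: int) -> LabelVolume:
    """Ground-truth labels sampled at the confocal focal planes."""
    planes = np.arange(z_step_vox // 2, volume.shape[0], z_step_vox)
    return LabelVolume(
        volume.labels[planes].copy(),
        voxel_size=volume.voxel_size,
        origin=volume.origin,
    )


def simulate_image(
    volume: LabelVolume,
    psf: optics.PSFKernel,
    config: RunConfig,
    rng: np.random.Generator,
) -> sim.ImageStack:
    """One simulated membrane-channel confocal stack from a label volume."""
    mask = extract_membrane(volume)
    mem = sim.label_membranes(
        mask, config.density_membrane, config.localization_sd, per_neuron=True, rng=rng
    )
    cytosol_region = (volume.labels > 0) & ~mask.mask
    cyt = sim.label_volume_compartment(
        cytosol_region, config.density_cytosol, volume.voxel_size,
        owner=volume.labels, rng=rng,
    )
    bg = sim.label_volume_compartment(
        np.ones(volume.shape, dtype=bool), config.density_background,
        volume.voxel_size, rng=rng,
    )
    merged = sim.FluorophoreField.concatenate([mem, cyt, bg])
    merged = sim.apply_puncta(merged, config.cluster_sd, rng=rng)
    return sim.render_stack(
        merged, psf, volume.shape, voxel_size=volume.voxel_size,
        z_step=config.z_step, snr_poisson_range=config.snr_poisson,
        snr_read_range=config.snr_read, rng=rng,
    )


def _make_psf(config: RunConfig) -> optics.PSFKernel:
    pitch_optical = (config.voxel_size * config.expansion_factor,) * 3
    psf = optics.render_confocal_psf(
        na=config.na,
        wavelength_ex=config.wavelength_ex,
        wavelength_em=config.wavelength_em,
        voxel_pitch=pitch_optical,
    )
    return optics.scale_psf(psf, config.expansion_factor)


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns score tables and a summary dict.

    Returns a dict with keys ``watershed``, ``tree_levels``, ``barcodes``
    (DataFrames), ``summary`` (headline F-scores without/with barcodes)
    and ``provenance``.  With ``outdir`` set, all tables, the config and
    provenance are written there as CSV/YAML.
    """
    z_step_vox = int(round(config.z_step / config.voxel_size))
    psf = _make_psf(config)

    # --- ground truth + simulation ---------------------------------------
    n_vols = config.n_train_volumes + 1
    volumes = [
        generate_ground_truth(
            config.gt_shape,
            config.voxel_size,
            dict(
                count=config.neurite_count,
                radius_range=config.radius_range,
                tortuosity=config.tortuosity,
                soma_fraction=config.soma_fraction,
            ),
            seed=config.stage_seed("groundtruth", i),
        )
        for i in range(n_vols)
    ]
    train_vols, test_vol = volumes[:-1], volumes[-1]

    train_stacks, train_gt = [], []
    for i, vol in enumerate(train_vols):
        for j in range(config.images_per_volume):
            rng = config.stage_rng("simulate", i * 1000 + j)
            train_stacks.append(simulate_image(vol, psf, config, rng))
            train_gt.append(vol)
    test_stack = simulate_image(
        test_vol, psf, config, config.stage_rng("simulate", 999_999)
    )

    # --- boundary detection ----------------------------------------------
    net_cfg = config.net_config()
    window_vox = (
        None
        if config.boundary_window_nm is None
        else max(1, int(round(config.boundary_window_nm / config.voxel_size)))
    )
    nets = bd.train_detector_ensemble(
        train_stacks, train_gt, net_cfg, config.stage_rng("train"),
        boundary_window_vox=window_vox,
        lr=config.learning_rate, momentum=config.momentum,
        batch=config.batch_size, steps_2d=config.steps_2d, steps_3d=config.steps_3d,
    )
    test_bpm = bd.infer_bpm(test_stack, nets)
    gt_test_img = gt_on_image_grid(test_vol, z_step_vox)

    # --- (a) watershed H-minima sweep -------------------------------------
    ws_rows = []
    for h in config.h_min_sweep:
        sv_h = seg.oversegment(test_bpm.prob, h_min=h)
        rep = score(sv_h.labels, gt_test_img, strict=False)
        ws_rows.append({"h_min": h, "n_supervoxels": sv_h.count, **rep.as_dict()})
    watershed_df = pd.DataFrame(ws_rows)

    # --- merge policy on the training volumes -----------------------------
    Xs, ys = [], []
    for stack, vol in zip(train_stacks, train_gt):
        bpm_i = bd.infer_bpm(stack, nets)
        sv_i = seg.oversegment(bpm_i.prob, h_min=config.h_min)
        if sv_i.count < 2:
            continue
        gt_img = gt_on_image_grid(vol, z_step_vox)
        X_i, y_i = seg.collect_training_examples(
            sv_i, bpm_i.prob, stack.data, gt_img.labels, n_rounds=config.policy_rounds
        )
        Xs.append(X_i)
        ys.append(y_i)
    if not Xs:
        raise RuntimeError("no usable training volumes for the merge policy")
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(
        n_estimators=100, random_state=config.stage_seed("policy"), n_jobs=1
    )
    clf.fit(np.vstack(Xs), np.concatenate(ys))
    policy = seg.MergePolicy(clf)

    # --- (b) hierarchy levels without barcodes ----------------------------
    sv = seg.oversegment(test_bpm.prob, h_min=config.h_min)
    tree = seg.build_hierarchy(sv, policy, test_bpm.prob, test_stack.data,
                               thresholds=config.thresholds)
    lvl_rows = []
    for t in config.thresholds:
        lv = tree.level_volume(t, sv.labels)
        rep = score(lv, gt_test_img, strict=False)
        lvl_rows.append({"threshold": t, "n_segments": len(np.unique(lv)), **rep.as_dict()})
    levels_df = pd.DataFrame(lvl_rows)

    # --- (c) barcode consolidation over the density grid ------------------
    vsize_zyx = (config.z_step, config.voxel_size, config.voxel_size)
    barcodes_df = bc.density_sweep(
        tree, sv, test_vol, gt_test_img, vsize_zyx,
        densities=config.barcode_densities, trials=config.barcode_trials,
        rng=config.stage_rng("barcodes"), exclusion_nm=config.exclusion_nm,
        top_threshold=max(config.thresholds),
    )

    best_lvl = levels_df.loc[levels_df["rand_f"].idxmax()]
    bc30 = barcodes_df[barcodes_df["density"] >= 30.0]
    summary = {
        "rand_f_no_barcodes": float(best_lvl["rand_f"]),
        "vi_f_no_barcodes": float(levels_df["vi_f"].max()),
        "rand_f_barcodes": float(bc30["rand_f"].mean()) if len(bc30) else float("nan"),
        "vi_f_barcodes": float(bc30["vi_f"].mean()) if len(bc30) else float("nan"),
        "n_supervoxels": int(sv.count),
        "n_test_voxels": int(gt_test_img.labels.size),
    }
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "psf_pitch_nm": list(psf.voxel_pitch),
    }
    results = {
        "watershed": watershed_df,
        "tree_levels": levels_df,
        "barcodes": barcodes_df,
        "summary": summary,
        "provenance": provenance,
        "artifacts": {
            "tree": tree,
            "supervoxels": sv,
            "bpm": test_bpm,
            "gt_image": gt_test_img,
            "test_volume": test_vol,
            "psf": psf,
        },
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        watershed_df.to_csv(out / "watershed_sweep.csv", index=False)
        levels_df.to_csv(out / "tree_levels.csv", index=False)
        barcodes_df.to_csv(out / "barcode_sweep.csv", index=False)
        from .io import save_yaml

        save_yaml(out / "config.yaml", config.to_dict())
        save_yaml(out / "provenance.yaml", provenance)
        save_yaml(out / "summary.yaml", summary)
    return results
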