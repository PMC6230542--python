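"""End-to-end study orchestration.

One call chains the whole loop: simulate phantoms → acquire attenuated,
noisy sinograms → reconstruct NAC PET → condition slices → train the
encoder-decoder → synthesise pseudo-CTs on held-out phantoms → convert
them to μ-maps → reconstruct attenuation-corrected PET → score
pseudo-CT anatomy (Dice, MAE) and PET quantification (percent error,
ROI statistics) against the CT-corrected reference.

The same driver backs the command-line ``full-run``, the test-suite's
recovery checks, and the acceptance script.  A single master seed fans
out into named substreams (phantom geometry, projection noise, weight
initialisation, epoch shuffling), so every artifact is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from pseudoct._seeding import rng_for, substream
from pseudoct.evaluation import (
    TISSUE_NAMES, discretize_ct, dice, error_map, mae, roi_statistics)
from pseudoct.nn import EncoderDecoder, NetworkSpec, build_network, save_checkpoint
from pseudoct.phantom import (
    ActivityMap, CTVolume, PhantomSpec, generate_phantom, split_indices)
from pseudoct.physics import (
    MuMap, PETImage, ReconConfig, ScanGeometry, Sinogram, ct_to_mu,
    default_geometry, forward_project, reconstruct_osem)
from pseudoct.preprocess import (
    PreprocessConfig, build_slice_pairs, crop_bounding_box, inverse_softsign,
    normalize_pet, resample_bilinear, restore_to_source, softsign)
from pseudoct.training import LossCurve, TrainConfig, train

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_study", "predict_pseudo_ct",
           "head_mask", "full_run"]


@dataclass(frozen=True)
class StudyConfig:
    """Complete, seedable description of a desk-scale study.

    Defaults run the 64×64 recovery study: 40 training and 8 held-out
    phantoms, a reduced three-stage network, and the 24-iteration /
    3-subset OSEM protocol with a 4 mm post filter.
    """

    master_seed: int = 0
    n_train: int = 40
    n_test: int = 8
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_angles: int = 120
    count_scale: float = 0.0023  # ≈2×10⁵ expected counts per default head slice
    recon: ReconConfig = field(default_factory=ReconConfig)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(target_matrix=(64, 64)))
    network: NetworkSpec = field(default_factory=NetworkSpec.reduced)
    training: TrainConfig = field(
        default_factory=lambda: TrainConfig(n_epochs=60))
    oracle_pseudo_ct: bool = False  # replace the network output by the true CT

    @staticmethod
    def full_scale(master_seed: int = 0) -> "StudyConfig":
        """Full-scale settings: 200×180 matrix, 13-conv-layer encoder,
        batch 12 / lr 0.001 / 50 epochs, 100 train / 28 test."""
        return StudyConfig(
            master_seed=master_seed, n_train=100, n_test=28,
            phantom=PhantomSpec(grid_size=200, n_slices=16, pixel_size=1.2,
                                seed=master_seed),
            preprocess=PreprocessConfig(target_matrix=(200, 180)),
            network=NetworkSpec(),
            training=TrainConfig(n_epochs=50, batch_size=12, learning_rate=0.001),
        )


@dataclass
class StudyResult:
    metrics: dict
    roi_table: object  # pandas DataFrame
    loss_curve: LossCurve
    network: EncoderDecoder
    test_artifacts: list[dict] = field(default_factory=list)


def head_mask(ct: CTVolume) -> np.ndarray:
    """Object mask: non-air tissue with internal cavities filled, per slice."""
    labels = discretize_ct(ct).labels
    solid = labels != TISSUE_NAMES["air"]
    filled = np.empty_like(solid)
    for k in range(solid.shape[2]):
        filled[..., k] = ndimage.binary_fill_holes(solid[..., k])
    return filled


def _acquire(ct: CTVolume, act: ActivityMap, geometry: ScanGeometry,
             count_scale: float, noise_seed: int | None) -> Sinogram:
    mu_true = ct_to_mu(ct)
    return forward_project(act, mu_true, geometry, count_scale=count_scale,
                           seed=noise_seed)


def _recon_nac(sino: Sinogram, cfg: ReconConfig, grid: int, px: float,
               spacing) -> PETImage:
    nac_cfg = replace(cfg, use_attenuation=False)
    return reconstruct_osem(sino, mu=None, config=nac_cfg, grid_size=grid,
                            pixel_size=px, spacing=spacing, provenance="NAC")


def predict_pseudo_ct(net: EncoderDecoder, nac: PETImage,
                      cfg: PreprocessConfig) -> CTVolume:
    """Synthesise a pseudo-CT volume from a NAC PET volume.

    Applies the forward conditioning (normalise → crop → resample →
    Softsign) to each axial slice, runs the network, and carries the
    prediction back through the exact inverse chain onto the source
    grid, with air outside the cropped field of view.
    """
    pet_n = normalize_pet(nac, cfg)
    _, box = crop_bounding_box(pet_n, cfg)
    r0, c0, r1, c1 = box
    n_slices = pet_n.shape[2]
    inputs = np.stack([
        softsign(resample_bilinear(pet_n[r0:r1, c0:c1, k], cfg.target_matrix))
        for k in range(n_slices)])
    preds = net.predict(inputs)  # Softsign domain
    out = np.empty(pet_n.shape)
    for k in range(n_slices):
        pk = preds[k].astype(np.float64)
        normed = inverse_softsign(np.clip(pk, -1 + 1e-9, 1 - 1e-9))
        out[..., k] = restore_to_source(normed, box, pet_n.shape[:2], fill_value=0.0)
    hu = out * cfg.ct_scale - cfg.ct_offset
    return CTVolume(voxels=hu, spacing=nac.spacing)


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None,
              keep_test_artifacts: bool = False) -> StudyResult:
    """Run the full loop and score the held-out phantoms."""
    t0 = time.time()
    log.info("study config (auditable parameter trail): %s", cfg)
    total = cfg.n_train + cfg.n_test
    spec = replace(cfg.phantom, seed=cfg.phantom.seed + cfg.master_seed)
    geometry = default_geometry(spec.grid_size, spec.pixel_size, cfg.n_angles)
    train_idx, test_idx = split_indices(spec.seed, cfg.n_train, cfg.n_test)
    noise_root = substream(cfg.master_seed, "projection-noise")

    log.info("simulating %d phantoms and reconstructing NAC PET", total)
    phantoms: dict[int, tuple[CTVolume, ActivityMap]] = {}
    sinos: dict[int, Sinogram] = {}
    nacs: dict[int, PETImage] = {}
    for i in range(total):
        ct, act = generate_phantom(spec, i)
        noise_seed = int(substream(cfg.master_seed, "projection-noise", i)
                         .generate_state(1)[0] % (2**31))
        sino = _acquire(ct, act, geometry, cfg.count_scale, noise_seed)
        nac = _recon_nac(sino, cfg.recon, spec.grid_size, spec.pixel_size, ct.spacing)
        phantoms[i], sinos[i], nacs[i] = (ct, act), sino, nac

    log.info("building slice pairs and training the encoder-decoder")
    pairs = []
    for i in train_idx:
        ct, _ = phantoms[i]
        pairs.extend(build_slice_pairs(nacs[i], ct, cfg.preprocess,
                                       source_id=f"phantom_{i:04d}"))
    init_seed = int(substream(cfg.master_seed, "weight-init")
                    .generate_state(1)[0] % (2**31))
    train_cfg = replace(cfg.training, seed=cfg.master_seed)
    div = 2 ** len(cfg.network.stages)
    net_shape = tuple(int(np.ceil(s / div)) * div
                      for s in cfg.preprocess.target_matrix)
    net = build_network(cfg.network, net_shape, seed=init_seed)
    net, curve = train(net, pairs, train_cfg)
    log.info("training done: best epoch %d, loss %.5f",
             curve.best_epoch, min(curve.selection_curve))

    # held-out evaluation
    dices = {"soft": [], "bone": [], "air": [], "air_cavity": []}
    maes, maes_baseline = [], []
    err_pct_pseudo, err_pct_nac = [], []
    err_maps, pets_pseudo, pets_ctac, roi_vols = [], [], [], []
    artifacts = []
    for i in test_idx:
        ct, act = phantoms[i]
        if cfg.oracle_pseudo_ct:
            pseudo = CTVolume(voxels=ct.voxels.copy(), spacing=ct.spacing)
        else:
            pseudo = predict_pseudo_ct(net, nacs[i], cfg.preprocess)

        lab_true = discretize_ct(ct)
        lab_pred = discretize_ct(pseudo)
        hmask = head_mask(ct)
        for tissue in ("soft", "bone", "air"):
            dices[tissue].append(dice(lab_true, lab_pred, tissue))
        dices["air_cavity"].append(dice(lab_true, lab_pred, "air", mask=hmask))

        maes.append(mae(pseudo, ct, mask=hmask))
        baseline = np.full_like(ct.voxels, spec.hu_values["soft"])
        maes_baseline.append(mae(baseline, ct, mask=hmask))

        ctac = reconstruct_osem(sinos[i], ct_to_mu(ct), cfg.recon,
                                provenance="CTAC")
        pac = reconstruct_osem(sinos[i], ct_to_mu(pseudo), cfg.recon,
                               provenance="pseudoAC")
        em_pac = error_map(pac, ctac, mask=hmask)
        em_nac = error_map(nacs[i], ctac, mask=hmask)
        err_pct_pseudo.append(float(em_pac.abs_err[em_pac.mask].mean()))
        err_pct_nac.append(float(em_nac.abs_err[em_nac.mask].mean()))
        err_maps.append(em_pac)
        pets_pseudo.append(pac)
        pets_ctac.append(ctac)
        roi_vols.append(act.label_map)
        if keep_test_artifacts:
            artifacts.append({"index": i, "ct": ct, "pseudo_ct": pseudo,
                              "nac": nacs[i], "ctac": ctac, "pseudo_ac": pac})

    roi_names = {k + 1: n for k, n in
                 enumerate(phantoms[test_idx[0]][1].roi_names[1:])}
    roi_table = roi_statistics(err_maps, roi_vols, pets_pseudo, pets_ctac,
                               roi_names=roi_names)

    metrics = {
        "dice_soft": float(np.mean(dices["soft"])),
        "dice_bone": float(np.mean(dices["bone"])),
        "dice_air": float(np.mean(dices["air"])),
        "dice_air_cavity": float(np.mean(dices["air_cavity"])),
        "mae_hu": float(np.mean(maes)),
        "mae_hu_baseline_all_soft": float(np.mean(maes_baseline)),
        "pet_abs_err_pct_pseudo_ac": float(np.mean(err_pct_pseudo)),
        "pet_abs_err_pct_nac": float(np.mean(err_pct_nac)),
        "nac_to_pseudo_error_ratio": float(np.mean(err_pct_nac)
                                           / max(np.mean(err_pct_pseudo), 1e-12)),
        "best_epoch": curve.best_epoch,
        "final_train_loss": curve.train_loss[-1],
        "n_train": cfg.n_train,
        "n_test": cfg.n_test,
        "wall_time_s": time.time() - t0,
    }

    result = StudyResult(metrics=metrics, roi_table=roi_table,
                         loss_curve=curve, network=net, test_artifacts=artifacts)
    if out_dir is not None:
        _write_outputs(result, cfg, Path(out_dir))
    return result


def _write_outputs(result: StudyResult, cfg: StudyConfig, out_dir: Path) -> None:
    from pseudoct.io import save_volume

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "metrics.json", "w") as f:
        json.dump(result.metrics, f, indent=2)
    import numpy as _np

    import pseudoct
    manifest = {
        "package_version": pseudoct.__version__,
        "numpy_version": _np.__version__,
        "master_seed": cfg.master_seed,
        "n_train": cfg.n_train,
        "n_test": cfg.n_test,
        "phantom": {k: str(v) for k, v in vars(cfg.phantom).items()},
        "network_spec": cfg.network.to_dict(),
        "training": {"learning_rate": cfg.training.learning_rate,
                     "batch_size": cfg.training.batch_size,
                     "n_epochs": cfg.training.n_epochs},
        "recon": vars(cfg.recon),
        "wall_time_s": result.metrics["wall_time_s"],
    }
    with open(out_dir / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    result.roi_table.to_csv(out_dir / "roi_statistics.tsv", sep="\t", index=False)
    result.loss_curve.to_frame().to_csv(out_dir / "loss_curve.tsv", sep="\t",
                                        index=False)
    save_checkpoint(result.network, out_dir / "network_best.npz")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        frame = result.loss_curve.to_frame()
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(frame["epoch"], frame["train_loss"], label="training loss")
        if "holdout_loss" in frame:
            ax.plot(frame["epoch"], frame["holdout_loss"], label="holdout loss")
        ax.axvline(result.loss_curve.best_epoch, ls="--", c="gray",
                   label=f"selected epoch {result.loss_curve.best_epoch}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean MSE (Softsign domain)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_dir / "loss_curve.png", dpi=120)
        plt.close(fig)
    except Exception:  # plotting is best-effort
        log.warning("loss-curve plot failed", exc_info=True)
    for art in result.test_artifacts:
        i = art["index"]
        save_volume(art["pseudo_ct"].voxels, art["pseudo_ct"].spacing,
                    out_dir / f"phantom_{i:04d}_pseudo_ct.nii.gz")
        save_volume(art["pseudo_ac"].voxels, art["pseudo_ac"].spacing,
                    out_dir / f"phantom_{i:04d}_pet_pseudo_ac.nii.gz")
        save_volume(art["ctac"].voxels, art["ctac"].spacing,
                    out_dir / f"phantom_{i:04d}_pet_ctac.nii.gz")


def full_run(cfg: StudyConfig, out_dir: str | Path) -> StudyResult:
    """CLI umbrella: run the study and persist every stage's outputs."""
    return run_study(cfg, out_dir=out_dir, keep_test_artifacts=True)
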