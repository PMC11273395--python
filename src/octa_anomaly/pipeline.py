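"""End-to-end orchestration: generate -> preprocess -> train -> score -> evaluate.

Two pipelines mirror the two detection methods:

* :func:`run_vqvae_ar_pipeline` — VQ-VAE + AR prior.  Scan-wise scores sum
  latent NLL above t_ar (95th percentile of healthy-validation cell NLLs);
  pixel-wise segmentations threshold the upscaled ALM at t_al (calibrated as
  a percentile of healthy-validation ALM cells) and refine morphologically.
* :func:`run_bayes_unet_pipeline` — Bayesian U-Net.  Monte-Carlo-dropout
  uncertainty maps give pixel scores thresholded at t_un (default 0: any
  nonzero uncertainty is anomalous) and scan scores as the sum above t_un.

Every run writes its resolved config, manifest, per-stage artifacts and
metric reports under ``output_dir/run_id``; rerunning with the same config
and seed reproduces the manifest byte-identically.  Vessel enhancement is
applied only on the segmentation (U-Net) path by default; both paths expose
the flag.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import ar_prior, bayes_unet, postprocess, preprocess, vqvae
from .errors import PipelineStageError
from .imgio import read_image, read_mask, write_image, write_mask
from .synthetic import DatasetManifest, ManifestRecord, PhantomConfig, make_dataset


@dataclass
class RunConfig:
    """Fully-serializable run description; unset model knobs fall back to
    scale-preset defaults ('desk' = 128 px, 'clinical' = 480 px)."""

    run_id: str = "run"
    output_dir: str = "runs"
    global_seed: int = 0
    scale: str = "desk"
    n_healthy: int = 40
    n_diseased: int = 10
    phantom: Dict = field(default_factory=dict)
    vqvae: Dict = field(default_factory=dict)
    ar: Dict = field(default_factory=dict)
    unet: Dict = field(default_factory=dict)
    postprocess: Dict = field(default_factory=dict)
    enhance_vqvae: bool = False
    enhance_unet: bool = True
    t_ar_percentile: float = 95.0
    t_al_percentile: float = 98.0
    t_un: float = 0.0
    mc_samples: int = 20

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    # -- resolved sub-configs ------------------------------------------------
    @property
    def image_size(self) -> int:
        if self.scale == "clinical":
            return 480
        return int(self.phantom.get("image_size", 128))

    def phantom_config(self) -> PhantomConfig:
        base = dict(image_size=480 if self.scale == "clinical" else 128)
        base.update(self.phantom)
        base["rng_seed"] = int(base.get("rng_seed", self.global_seed))
        if "vessel_width_range" in base:
            base["vessel_width_range"] = tuple(base["vessel_width_range"])
        return PhantomConfig(**base)

    def preprocess_config(self, enhance: bool) -> preprocess.PreprocessConfig:
        size = self.image_size
        if self.scale == "clinical":
            return preprocess.PreprocessConfig(resize_to=512, crop_to=480,
                                               enhance=enhance)
        return preprocess.PreprocessConfig(resize_to=size, crop_to=size,
                                           vesselness_scales=(1.0, 2.0, 4.0),
                                           enhance=enhance)

    def vqvae_config(self) -> vqvae.VqVaeConfig:
        base = dataclasses.asdict(
            vqvae.clinical_preset() if self.scale == "clinical"
            else vqvae.VqVaeConfig(image_size=self.image_size))
        base.update(self.vqvae)
        base.setdefault("rng_seed", self.global_seed + 1)
        base["channels"] = tuple(base["channels"])
        return vqvae.VqVaeConfig(**base)

    def ar_config(self, codebook_size: int) -> ar_prior.ArConfig:
        base = dataclasses.asdict(ar_prior.ArConfig(codebook_size=codebook_size))
        if self.scale == "clinical":
            base.update(dict(epochs=300, n_blocks=4, use_attention=True,
                             learning_rate=5e-4, batch_size=4))
        base.update(self.ar)
        base.setdefault("rng_seed", self.global_seed + 2)
        return ar_prior.ArConfig(**base)

    def unet_config(self) -> bayes_unet.UnetConfig:
        base = dataclasses.asdict(
            bayes_unet.clinical_preset() if self.scale == "clinical"
            else bayes_unet.UnetConfig())
        base.update(self.unet)
        base.setdefault("rng_seed", self.global_seed + 3)
        return bayes_unet.UnetConfig(**base)

    def postprocess_config(self, threshold: float) -> postprocess.PostprocessConfig:
        scale = self.image_size / 480.0
        base = dict(threshold=threshold,
                    opening_radius=max(0, int(round(1 * max(scale, 1)))),
                    dilation_radius=max(1, int(round(2 * max(scale, 1)))),
                    min_area=max(1, int(round(64 * scale * scale))))
        over = dict(self.postprocess)
        over.pop("threshold", None)
        base.update(over)
        return postprocess.PostprocessConfig(**base)


# ---------------------------------------------------------------------------
# shared stages
# ---------------------------------------------------------------------------

logger = logging.getLogger(__name__)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            start = time.perf_counter()
            try:
                out = fn(*a, **k)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
            logger.info("stage %-14s %6.1f s", name, time.perf_counter() - start)
            return out
        return wrapped
    return deco


@_stage("generate")
def _generate(cfg: RunConfig, run_dir: Path) -> DatasetManifest:
    return make_dataset(cfg.n_healthy, cfg.n_diseased, cfg.phantom_config(),
                        run_dir / "data")


@_stage("standardize")
def _standardize(cfg: RunConfig, run_dir: Path, manifest: DatasetManifest,
                 enhance: bool, tag: str) -> DatasetManifest:
    pcfg = cfg.preprocess_config(enhance)
    out = run_dir / f"preprocessed_{tag}"
    (out / "images").mkdir(parents=True, exist_ok=True)
    records: List[ManifestRecord] = []
    for r in manifest.records:
        img = preprocess.standardize(read_image(manifest.resolve(r.image)), pcfg)
        if pcfg.enhance:
            img = preprocess.vesselness_enhance(img, pcfg)
        name = Path(r.image).name
        write_image(out / "images" / name, img)
        records.append(ManifestRecord(
            image=f"images/{name}",
            vessel_mask=str((manifest.root / r.vessel_mask).resolve())
            if r.vessel_mask else "",
            anomaly_mask=str((manifest.root / r.anomaly_mask).resolve())
            if r.anomaly_mask else "",
            label=r.label, split=r.split))
    m = DatasetManifest(records=records, root=out)
    m.to_csv(out / "MANIFEST.csv")
    return m


def _load_pairs(manifest: DatasetManifest, split: str, label: Optional[str] = None):
    recs = manifest.subset(split=split, label=label)
    return recs, [read_image(manifest.resolve(r.image)) for r in recs]


# ---------------------------------------------------------------------------
# VQ-VAE + AR pipeline
# ---------------------------------------------------------------------------

def run_vqvae_ar_pipeline(cfg: RunConfig):
    """Returns (ScanEvalReport, PixelEvalReport, artifacts dict)."""
    run_dir = Path(cfg.output_dir) / cfg.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "resolved_config.yaml")

    manifest = _generate(cfg, run_dir)
    pm = _standardize(cfg, run_dir, manifest, cfg.enhance_vqvae, "vqvae")

    @_stage("train_vqvae")
    def _train():
        return vqvae.train_vqvae(pm, cfg.vqvae_config())
    model = _train()
    pd.DataFrame(model.train_log).to_csv(run_dir / "vqvae_train_log.csv", index=False)
    vqvae.save_vqvae(model, run_dir / "vqvae.npz")

    @_stage("encode")
    def _encode(images):
        lat, alms = [], []
        for img in images:
            feats = vqvae.encode(img, model)
            idx, _, alm = vqvae.quantize(feats, model.codebook.data)
            lat.append(idx)
            alms.append(alm)
        return lat, alms

    train_recs, train_imgs = _load_pairs(pm, "train")
    val_recs, val_imgs = _load_pairs(pm, "val", "healthy")
    test_recs, test_imgs = _load_pairs(pm, "test")
    train_lat, _ = _encode(train_imgs)
    val_lat, val_alms = _encode(val_imgs)
    test_lat, test_alms = _encode(test_imgs)

    @_stage("train_ar")
    def _train_ar():
        return ar_prior.train_ar(train_lat, cfg.ar_config(model.cfg.codebook_size))
    prior = _train_ar()
    pd.DataFrame(prior.train_log).to_csv(run_dir / "ar_train_log.csv", index=False)
    ar_prior.save_ar(prior, run_dir / "ar_prior.npz")

    @_stage("calibrate")
    def _calibrate():
        val_nll = np.concatenate([ar_prior.nll_map(z, prior).ravel()
                                  for z in val_lat])
        t_ar = ar_prior.calibrate_t_ar(val_nll, cfg.t_ar_percentile)
        val_alm_cells = np.concatenate([a.ravel() for a in val_alms])
        t_al = float(np.percentile(val_alm_cells, cfg.t_al_percentile))
        return t_ar, t_al
    t_ar, t_al = _calibrate()

    @_stage("score")
    def _score():
        rows = []
        for r, z in zip(test_recs, test_lat):
            nll = ar_prior.nll_map(z, prior)
            rows.append({"image": r.image,
                         "scan_score": ar_prior.scan_score(nll, t_ar),
                         "label": 1 if r.label == "diseased" else 0})
        df = pd.DataFrame(rows)
        df.to_csv(run_dir / "scan_scores.csv", index=False)
        return df
    scores = _score()

    @_stage("segment")
    def _segment():
        seg_dir = run_dir / "segmentations"
        seg_dir.mkdir(exist_ok=True)
        ppcfg = cfg.postprocess_config(t_al)
        pairs = []
        for r, alm in zip(test_recs, test_alms):
            if r.label != "diseased":
                continue
            up = vqvae.alignment_loss_map_upscaled(alm, cfg.image_size)
            seg = postprocess.refine(postprocess.binarize(up, t_al), ppcfg)
            name = Path(r.image).name
            write_mask(seg_dir / name, seg)
            gt = read_mask(pm.resolve(r.anomaly_mask))
            pairs.append((name, seg, gt))
        return pairs
    pairs = _segment()

    @_stage("evaluate")
    def _evaluate():
        scan_rep = postprocess.scan_eval(scores.scan_score.values,
                                         scores.label.values)
        pixel_rep = postprocess.pixel_eval(pairs)
        _write_reports(run_dir, scan_rep, pixel_rep,
                       extra={"t_ar": t_ar, "t_al": t_al})
        return scan_rep, pixel_rep
    scan_rep, pixel_rep = _evaluate()

    artifacts = {"run_dir": run_dir, "t_ar": t_ar, "t_al": t_al,
                 "scores": scores, "model": model, "prior": prior,
                 "manifest": pm}
    return scan_rep, pixel_rep, artifacts


# ---------------------------------------------------------------------------
# Bayesian U-Net pipeline
# ---------------------------------------------------------------------------

def run_bayes_unet_pipeline(cfg: RunConfig):
    """Returns (ScanEvalReport, PixelEvalReport, artifacts dict)."""
    run_dir = Path(cfg.output_dir) / cfg.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "resolved_config.yaml")

    manifest = _generate(cfg, run_dir)
    pm = _standardize(cfg, run_dir, manifest, cfg.enhance_unet, "unet")

    @_stage("train_unet")
    def _train():
        return bayes_unet.train_unet(pm, cfg.unet_config())
    model = _train()
    pd.DataFrame(model.train_log).to_csv(run_dir / "unet_train_log.csv", index=False)
    bayes_unet.save_unet(model, run_dir / "unet.npz")

    test_recs, test_imgs = _load_pairs(pm, "test")

    @_stage("mc_predict")
    def _uncertainty():
        if cfg.unet_config().dropout_p <= 0:
            raise ValueError("dropout_p is 0: epistemic uncertainty is undefined")
        maps = []
        for i, img in enumerate(test_imgs):
            stack = bayes_unet.mc_predict(img, model, cfg.mc_samples,
                                          seed=cfg.global_seed + 1000 + i)
            maps.append(bayes_unet.epistemic_uncertainty(stack))
        return maps
    u_maps = _uncertainty()

    @_stage("score")
    def _score():
        rows = []
        for r, u in zip(test_recs, u_maps):
            rows.append({"image": r.image,
                         "scan_score": postprocess.scanwise_from_map(u, cfg.t_un),
                         "label": 1 if r.label == "diseased" else 0})
        df = pd.DataFrame(rows)
        df.to_csv(run_dir / "scan_scores.csv", index=False)
        return df
    scores = _score()

    @_stage("segment")
    def _segment():
        seg_dir = run_dir / "segmentations"
        seg_dir.mkdir(exist_ok=True)
        ppcfg = cfg.postprocess_config(cfg.t_un)
        pairs, loc = [], []
        for r, u in zip(test_recs, u_maps):
            if r.label != "diseased":
                continue
            seg = postprocess.refine(postprocess.binarize(u, cfg.t_un), ppcfg)
            name = Path(r.image).name
            write_mask(seg_dir / name, seg)
            gt = read_mask(pm.resolve(r.anomaly_mask))
            pairs.append((name, seg, gt))
            loc.append(float(u[gt].mean() > u[~gt].mean()))
        return pairs, loc
    pairs, loc = _segment()

    @_stage("evaluate")
    def _evaluate():
        scan_rep = postprocess.scan_eval(scores.scan_score.values,
                                         scores.label.values)
        pixel_rep = postprocess.pixel_eval(pairs)
        # vessel segmentation quality on healthy held-out images
        vessel_dice = []
        for r in pm.subset(split="test", label="healthy"):
            proba = bayes_unet.predict_proba(read_image(pm.resolve(r.image)), model)
            pred = proba[1] > 0.5
            gt = read_mask(pm.resolve(r.vessel_mask))
            vessel_dice.append(postprocess.dice(pred, gt))
        extra = {"t_un": cfg.t_un,
                 "vessel_dice_mean": float(np.mean(vessel_dice)),
                 "uncertainty_localization_fraction": float(np.mean(loc))}
        _write_reports(run_dir, scan_rep, pixel_rep, extra=extra)
        return scan_rep, pixel_rep, extra
    scan_rep, pixel_rep, extra = _evaluate()

    artifacts = {"run_dir": run_dir, "scores": scores, "model": model,
                 "manifest": pm, "uncertainty_maps": u_maps, **extra}
    return scan_rep, pixel_rep, artifacts


def _write_reports(run_dir: Path, scan_rep, pixel_rep, extra: Dict) -> None:
    df = pixel_rep.per_image.copy()
    if len(df):
        summary_row = {"image": "mean±sd"}
        for m, (mu, sd) in pixel_rep.summary.items():
            summary_row[m] = f"{mu:.4f}±{sd:.4f}"
        df = pd.concat([df, pd.DataFrame([summary_row])], ignore_index=True)
    df.to_csv(run_dir / "metrics.csv", index=False)
    summary = {"scan": dataclasses.asdict(scan_rep),
               "pixel": {k: {"mean": v[0], "sd": v[1]}
                         for k, v in pixel_rep.summary.items()},
               **extra}
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
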