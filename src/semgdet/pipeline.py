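"""End-to-end pipeline orchestration.

Stages: simulate -> preprocess -> render -> train-classifier ->
train-detector -> predict -> decode-angle -> evaluate.  Each stage
writes versioned artifacts (tagged with the config hash) into the
output directory and a summary report aggregates losses, mAP figures
and decoded angles.  A stage whose upstream artifact is missing fails
with a dependency error naming the stage.
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import channels, detector, evaluation, imaging, mgnet, preprocess, synth
from .angle import AngleSpec, angle_from_detection, joint_of_motion
from .config import PipelineConfig
from .errors import ConfigError, DependencyError

STAGES = ("simulate", "preprocess", "render", "train-classifier",
          "train-detector", "predict", "decode-angle", "evaluate")


def _manifest_path(out: Path) -> Path:
    return out / "manifest.json"


def _load_manifest(out: Path, stage: str, needs: str) -> dict:
    path = _manifest_path(out)
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs artifacts from {needs!r}; none found in {out}")
    manifest = json.loads(path.read_text())
    if needs not in manifest.get("stages", {}):
        raise DependencyError(
            f"stage {stage!r} needs {needs!r} to run first")
    return manifest


def _update_manifest(out: Path, config: PipelineConfig, stage: str,
                     payload: dict) -> None:
    path = _manifest_path(out)
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_hash": config.hash, "stages": {}}
    if manifest["config_hash"] != config.hash:
        raise ConfigError(
            "output directory holds artifacts from a different config "
            f"(hash {manifest['config_hash']} != {config.hash})")
    manifest["stages"][stage] = payload
    path.write_text(json.dumps(manifest, indent=1))


def _synth_config(config: PipelineConfig) -> synth.SynthConfig:
    c = config["synth"]
    return synth.SynthConfig(
        fs=c["fs"], duration=c["duration"],
        burst_start=c["burst"][0], burst_end=c["burst"][1],
        peak_amplitude=c["peak_amplitude"],
        mains_amplitude=c["mains_amplitude"],
        drift_amplitude=c["drift_amplitude"],
        noise_floor=c["noise_floor"], seed=config["seed"])


def run_pipeline(config: PipelineConfig, stages=STAGES,
                 out_dir=None) -> dict:
    """Run the requested stages in order; returns the summary report."""
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    report: dict = {"config_hash": config.hash}
    for stage in stages:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        _RUNNERS[stage](config, out, ctx, report)
        report.setdefault("timings_s", {})[stage] = round(
            time.perf_counter() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _stage_simulate(config, out, ctx, report):
    scfg = _synth_config(config)
    records = synth.generate_dataset(config["synth"]["n_per_class"], config=scfg)
    rec_dir = out / "records"
    rec_dir.mkdir(exist_ok=True)
    entries = []
    for i, r in enumerate(records):
        path = rec_dir / f"rec{i:04d}.csv"
        synth.write_csv(r, path)
        entries.append({"file": path.name, "motion": r.motion.id,
                        "angle_fraction": r.angle_fraction,
                        "burst": list(r.burst_extent), "peak": r.peak})
    ctx["records"] = records
    _update_manifest(out, config, "simulate", {"n": len(records)})
    report["simulate"] = {"n_records": len(records)}


def _stage_preprocess(config, out, ctx, report):
    if "records" not in ctx:
        _load_manifest(out, "preprocess", "simulate")
        raise DependencyError(
            "stage 'preprocess' needs in-memory records; run 'simulate' "
            "in the same invocation")
    f = config["filter"]
    spec = preprocess.FilterSpec(band_low=f["band"][0], band_high=f["band"][1],
                                 notch_freq=f["notch"], notch_q=f["notch_q"],
                                 filter_order=f["order"])
    ctx["records"] = [preprocess.denoise(r, spec) for r in ctx["records"]]
    if config["imaging"]["segment_before_render"]:
        w = config["segment"]["window"]
        ctx["records"] = [preprocess.segment_active_window(r, w[0], w[1])
                          for r in ctx["records"]]
    _update_manifest(out, config, "preprocess", {"filter": f})
    report["preprocess"] = {"band": f["band"], "notch": f["notch"]}


def _stage_render(config, out, ctx, report):
    if "records" not in ctx:
        raise DependencyError("stage 'render' needs records; run 'simulate'")
    weights = config["fusion"]["weights"]
    names = tuple(config["channels"]["retained"])
    fw = (channels.FusionWeights(weights) if weights
          else channels.FusionWeights.uniform(names))
    fused = [channels.fuse_channels(r, fw) for r in ctx["records"]]
    amp = imaging.dataset_amp_range(fused)
    size = config["imaging"]["size"]
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    images, labels = [], []
    for i, rec in enumerate(fused):
        img = imaging.render_signal_image(rec, size=size, amp_range=amp)
        name = f"img{i:04d}.png"
        img.save(img_dir / name)
        labels.append(imaging.auto_label(img, rec, image_path=name))
        images.append(img)
    imaging.write_labels_json(labels, out / "labels.json")
    ctx.update(images=images, labels=labels, fused=fused, amp_range=amp)
    _update_manifest(out, config, "render",
                     {"n": len(images), "size": size, "amp_range": amp})
    report["render"] = {"n_images": len(images), "amp_range": amp}


def _stage_train_classifier(config, out, ctx, report):
    if "images" not in ctx:
        raise DependencyError("stage 'train-classifier' needs rendered images")
    m = config["mgnet"]
    targets = [mgnet.ClassifierTarget(l.class_id, 2.0 * l.half_w,
                                      2.0 * l.half_h) for l in ctx["labels"]]
    size = m["input_size"]
    images = ctx["images"]
    if images[0].size[0] != size:
        from PIL import Image
        images = [np.asarray(Image.fromarray(im.pixels).resize((size, size)))
                  for im in images]
        scale = size / ctx["images"][0].size[0]
        targets = [mgnet.ClassifierTarget(t.class_id, t.action_width * scale,
                                          t.action_peak * scale)
                   for t in targets]
    hyper = mgnet.TrainSpec(
        lr=m["lr"], batch_size=m["batch_size"], max_epochs=m["max_epochs"],
        checkpoint_every=m["checkpoint_every"], out_dir=str(out / "ckpt"),
        seed=config["seed"], width_multiplier=m["width_multiplier"],
        input_size=size,
        loss_weights=mgnet.LossWeights(alpha=m["alpha"], beta=m["beta"]))
    net, history = mgnet.train_classifier(list(zip(images, targets)), hyper)
    mgnet.save_checkpoint(net, out / "mgnet.npz")
    ctx["classifier"] = net
    _update_manifest(out, config, "train-classifier",
                     {"epochs": len(history["epoch_loss"])})
    report["train_classifier"] = {
        "final_loss": history["epoch_loss"][-1],
        "epochs": len(history["epoch_loss"])}


def _stage_train_detector(config, out, ctx, report):
    if "images" not in ctx:
        raise DependencyError("stage 'train-detector' needs rendered images")
    d = config["detector"]
    hyper = detector.DetectorTrainSpec(
        input_size=d["input_size"], width_multiplier=d["width_multiplier"],
        neck_channels=d["neck_channels"], iterations=d["iterations"],
        lr=d["lr"], seed=config["seed"], mosaic=d["mosaic"],
        conf_threshold=d["conf_threshold"])
    dataset = list(zip(ctx["images"], ctx["labels"]))
    net, dcfg, history = detector.train_detector(dataset, hyper)
    ctx["detector"] = (net, dcfg)
    _update_manifest(out, config, "train-detector",
                     {"iterations": d["iterations"]})
    report["train_detector"] = {
        "final_box_loss": history["box_loss"][-1],
        "final_cls_loss": history["cls_loss"][-1]}


def _stage_predict(config, out, ctx, report):
    if "detector" not in ctx:
        raise DependencyError(
            "stage 'predict' needs trained detector weights; run "
            "'train-detector' first")
    net, dcfg = ctx["detector"]
    paths = [l.image_path for l in ctx["labels"]]
    per_image = detector.predict(net, ctx["images"], dcfg, image_paths=paths)
    dets = [d for dd in per_image for d in dd]
    payload = [{"image_path": d.image_path, "class_id": d.class_id,
                "confidence": d.confidence, "cx": d.box.cx, "cy": d.box.cy,
                "half_h": d.box.half_h, "half_w": d.box.half_w}
               for d in dets]
    (out / "detections.json").write_text(json.dumps(payload, indent=1))
    ctx["detections"] = dets
    _update_manifest(out, config, "predict", {"n": len(dets)})
    report["predict"] = {"n_detections": len(dets)}


def _stage_decode_angle(config, out, ctx, report):
    if "detections" not in ctx:
        raise DependencyError("stage 'decode-angle' needs detections")
    spec = AngleSpec(dict(config["angles"]))
    by_image = {l.image_path: l for l in ctx["labels"]}
    size = ctx["images"][0].size[0]
    baseline = (size - 1) / 2.0
    det_size = config["detector"]["input_size"]
    scale = size / det_size
    angles = []
    for d in ctx["detections"]:
        ref = by_image.get(d.image_path)
        if ref is None:
            continue
        joint = joint_of_motion(d.class_id)
        box = replace(d.box, cx=d.box.cx * scale, cy=d.box.cy * scale,
                      half_w=d.box.half_w * scale, half_h=d.box.half_h * scale)
        ang = angle_from_detection(
            box, ref_box=detector.Box.from_label(ref),
            baseline_row=baseline, spec=spec, joint=joint)
        angles.append({"image_path": d.image_path, "class_id": d.class_id,
                       "joint": joint, "angle_deg": ang})
    (out / "angles.json").write_text(json.dumps(angles, indent=1))
    ctx["angles"] = angles
    _update_manifest(out, config, "decode-angle", {"n": len(angles)})
    report["decode_angle"] = {"n_angles": len(angles)}


def _stage_evaluate(config, out, ctx, report):
    if "detections" not in ctx:
        raise DependencyError("stage 'evaluate' needs detections")
    res = evaluation.mean_ap(ctx["detections"], ctx["labels"])
    true_by_image = {l.image_path: l.class_id for l in ctx["labels"]}
    best = {}
    for d in ctx["detections"]:
        if (d.image_path not in best
                or d.confidence > best[d.image_path].confidence):
            best[d.image_path] = d
    pairs = [(best[p].class_id, c) for p, c in true_by_image.items()
             if p in best]
    acc = (evaluation.accuracy([p for p, _ in pairs], [t for _, t in pairs])
           if pairs else float("nan"))
    payload = {"map50": res.map50, "map50_95": res.map50_95,
               "top1_accuracy": acc,
               "ap50": {str(k): v for k, v in res.ap[0.5].items()}}
    (out / "eval.json").write_text(json.dumps(payload, indent=1, default=float))
    report["evaluate"] = payload
    _update_manifest(out, config, "evaluate", {"map50": res.map50})


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "render": _stage_render,
    "train-classifier": _stage_train_classifier,
    "train-detector": _stage_train_detector,
    "predict": _stage_predict,
    "decode-angle": _stage_decode_angle,
    "evaluate": _stage_evaluate,
}


def demo_config(seed: int = 0, out_dir: str = "semgdet_demo") -> PipelineConfig:
    """Desk-scale profile: small images, thin network, a couple of
    minutes of CPU; the default entry point for end-to-end runs."""
    return PipelineConfig.from_dict({
        "seed": seed,
        "out_dir": out_dir,
        "synth": {"n_per_class": 2},
        "imaging": {"size": 160},
        "mgnet": {"width_multiplier": 0.25, "input_size": 64,
                  "max_epochs": 10, "batch_size": 4},
        "detector": {"input_size": 160, "width_multiplier": 0.25,
                     "neck_channels": 32, "iterations": 300},
    })
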