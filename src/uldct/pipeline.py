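"""End-to-end orchestration: simulate -> train -> enhance -> evaluate.

Each stage is a plain function on a configuration dictionary plus a
working directory, rerunnable and seed-deterministic; the command-line
interface is a thin wrapper over these.  The default configuration is
the *smoke profile* — a scaled-down experiment (64 x 64 images, 8 + 8
training images, 30 epochs, width multiplier 0.25) that runs on one CPU
in minutes; the *full profile* mirrors the clinical-scale setup
(512 x 512, 250 epochs) and is practical only with serious compute.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
from pathlib import Path

import numpy as np

from . import io as uio
from .iqa import evaluate, reports_to_frame, roi_stats, locate_catphan_rois
from .model import (
    LossWeights,
    ModelBundle,
    TrainSchedule,
    generate,
    history_to_csv,
    train,
)
from .phantom import (
    CTImage,
    LOW_DOSE_PROTOCOL,
    NORMAL_DOSE_PROTOCOL,
    PhantomSpec,
    default_phantom,
    effective_dose,
    make_unpaired_dataset,
    render_phantom,
    round_sig,
    simulate_dose,
    small_phantom,
)
from .preprocess import AugmentationPolicy

log = logging.getLogger("uldct")

#: Desk-scale default configuration (the smoke profile).
SMOKE_CONFIG: dict = {
    "seed": 0,
    "phantom": {"profile": "small", "body_hu": 0.0},
    "protocol": {
        "low": {"tube_current_mAs": 24.0, "dlp_mGy_cm": 44.67},
        "high": {"tube_current_mAs": 200.0, "dlp_mGy_cm": 466.67},
    },
    "simulate": {
        "n_per_domain": 8,
        "n_test": 3,
        "matrix_size": 64,
        "spacing_mm": 1.0,
        "noise_method": "fbp",
        "format": "npz",
    },
    "train": {
        "epochs_total": 30,
        "epochs_constant_lr": 18,
        "lr_initial": 2e-4,
        "batch_size": 4,
        "patch_size": 32,
        "patches_per_image": 16,
        "width_multiplier": 0.25,
        "d_width_multiplier": 1.0,
        "n_res_blocks": 2,
        "lambda_cyc": 20.0,
        "lambda_iden": 0.5,
        "rotation_right_angles": True,
        "d_warmup_steps": 300,
    },
}

#: Clinical-scale configuration (GPU-scale compute; documented, not CI-run).
FULL_CONFIG: dict = copy.deepcopy(SMOKE_CONFIG)
FULL_CONFIG.update(
    {
        "phantom": {"profile": "catphan", "body_hu": 0.0},
        "simulate": {
            "n_per_domain": 68,
            "n_test": 8,
            "matrix_size": 512,
            "spacing_mm": 0.9765,
            "noise_method": "fbp",
            "format": "dicom",
        },
        "train": {
            "epochs_total": 250,
            "epochs_constant_lr": 150,
            "lr_initial": 2e-4,
            "batch_size": 4,
            "patch_size": 256,
            "patches_per_image": 4,
            "width_multiplier": 1.0,
            "d_width_multiplier": 1.0,
            "n_res_blocks": 6,
            "lambda_cyc": 20.0,
            "lambda_iden": 0.5,
            "rotation_right_angles": False,
            "d_warmup_steps": 0,
        },
    }
)


def config_with_defaults(cfg: dict | None = None) -> dict:
    merged = copy.deepcopy(SMOKE_CONFIG)
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def phantom_from(cfg: dict, uniform: bool = False) -> PhantomSpec:
    pcfg = cfg.get("phantom", {})
    if "inserts" in pcfg:
        spec = uio.phantom_from_config(pcfg)
        if uniform:
            from dataclasses import replace

            spec = replace(spec, uniform_module=True)
        return spec
    maker = small_phantom if pcfg.get("profile", "small") == "small" else default_phantom
    return maker(body_hu=float(pcfg.get("body_hu", 0.0)), uniform_module=uniform)


def _writer(fmt: str):
    return uio.write_npz if fmt == "npz" else uio.write_dicom


def _suffix(fmt: str) -> str:
    return ".npz" if fmt == "npz" else ".dcm"


def cmd_simulate(cfg: dict, workdir: str | Path) -> dict:
    """Generate the unpaired corpora, held-out test triplets and
    uniformity images; write a manifest CSV."""
    cfg = config_with_defaults(cfg)
    workdir = Path(workdir)
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    low = float(cfg["protocol"]["low"]["tube_current_mAs"])
    high = float(cfg["protocol"]["high"]["tube_current_mAs"])
    spec = phantom_from(cfg)
    fmt = sim.get("format", "npz")
    write = _writer(fmt)
    sfx = _suffix(fmt)

    dom_a, dom_b = make_unpaired_dataset(
        spec,
        int(sim["n_per_domain"]),
        low,
        high,
        seed=seed,
        matrix_size=int(sim["matrix_size"]),
        spacing_mm=float(sim["spacing_mm"]),
        method=sim.get("noise_method", "fbp"),
    )
    manifest = []
    for name, images in (("domain_a", dom_a), ("domain_b", dom_b)):
        d = workdir / name
        d.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(images):
            fn = d / f"{name}_{i:03d}{sfx}"
            write(img, fn)
            manifest.append(
                {"file": str(fn.relative_to(workdir)), "dose_mAs": img.dose_mAs,
                 "seed": img.seed, "role": name}
            )

    # held-out test triplets: clean ground truth + both dose realizations
    clean = render_phantom(spec, int(sim["matrix_size"]), float(sim["spacing_mm"]))
    tdir = workdir / "test"
    tdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed).spawn(3)[2]
    test_rng = np.random.default_rng(ss)
    for i in range(int(sim.get("n_test", 3))):
        for tag, dose in (("low", low), ("high", high)):
            s = int(test_rng.integers(0, 2**31 - 1))
            img = simulate_dose(clean, dose, high, seed=s,
                                method=sim.get("noise_method", "fbp"))
            fn = tdir / f"test_{i:03d}_{tag}{sfx}"
            write(img, fn)
            manifest.append({"file": str(fn.relative_to(workdir)),
                             "dose_mAs": dose, "seed": s, "role": f"test_{tag}"})
    write(clean, tdir / f"test_clean{sfx}")
    manifest.append({"file": f"test/test_clean{sfx}", "dose_mAs": "",
                     "seed": "", "role": "test_clean"})

    # uniformity module at both doses (NPS / uniformity measurements)
    uspec = phantom_from(cfg, uniform=True)
    uclean = render_phantom(uspec, int(sim["matrix_size"]), float(sim["spacing_mm"]))
    udir = workdir / "uniform"
    udir.mkdir(parents=True, exist_ok=True)
    for tag, dose in (("low", low), ("high", high)):
        s = int(test_rng.integers(0, 2**31 - 1))
        img = simulate_dose(uclean, dose, high, seed=s,
                            method=sim.get("noise_method", "fbp"))
        fn = udir / f"uniform_{tag}{sfx}"
        write(img, fn)
        manifest.append({"file": str(fn.relative_to(workdir)),
                         "dose_mAs": dose, "seed": s, "role": f"uniform_{tag}"})

    with open(workdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["file", "dose_mAs", "seed", "role"])
        writer.writeheader()
        writer.writerows(manifest)
    uio.dump_config(cfg, workdir / "config_used.yaml")
    log.info("simulated %d images into %s", len(manifest), workdir)
    return {"n_images": len(manifest), "workdir": str(workdir)}


def _load_dir(d: Path) -> list[CTImage]:
    return [uio.read_image(p) for p in sorted(d.iterdir()) if p.suffix in (".npz", ".dcm")]


def cmd_train(cfg: dict, workdir: str | Path, resume: bool = False) -> ModelBundle:
    """Train the enhancement model on the simulated corpora.

    With ``resume=True`` and an existing checkpoint, training continues
    from the epoch recorded in the loss history and appends to it.
    """
    cfg = config_with_defaults(cfg)
    workdir = Path(workdir)
    tc = cfg["train"]
    dom_a = _load_dir(workdir / "domain_a")
    dom_b = _load_dir(workdir / "domain_b")
    initial_bundle = None
    start_epoch = 0
    prior_rows: list[str] = []
    ckpt = workdir / "checkpoint.npz"
    loss_csv = workdir / "loss_history.csv"
    if resume and ckpt.exists():
        initial_bundle = ModelBundle.load(ckpt)
        if loss_csv.exists():
            prior_rows = loss_csv.read_text().strip().splitlines()[1:]
            start_epoch = len(prior_rows)
    schedule = TrainSchedule(
        epochs_total=int(tc["epochs_total"]),
        epochs_constant_lr=int(tc["epochs_constant_lr"]),
        lr_initial=float(tc["lr_initial"]),
        batch_size=int(tc["batch_size"]),
        seed=int(cfg["seed"]),
    )
    weights = LossWeights(float(tc["lambda_cyc"]), float(tc["lambda_iden"]))

    def log_epoch(epoch, lr, report):
        log.info("epoch %d lr %.2e adv %.3f/%.3f cyc %.4f iden %.4f",
                 epoch, lr, report.adv_A, report.adv_B, report.cyc, report.iden)

    bundle, history = train(
        dom_a,
        dom_b,
        schedule,
        weights,
        patch_size=int(tc["patch_size"]),
        patches_per_image=int(tc["patches_per_image"]),
        augmentation=AugmentationPolicy(
            rotation_right_angles=bool(tc.get("rotation_right_angles", True))
        ),
        width_multiplier=float(tc["width_multiplier"]),
        d_width_multiplier=float(tc.get("d_width_multiplier", 1.0)),
        n_res_blocks=int(tc["n_res_blocks"]),
        residual=bool(tc.get("residual", True)),
        d_warmup_steps=0 if initial_bundle is not None
        else int(tc.get("d_warmup_steps", 0)),
        initial_bundle=initial_bundle,
        start_epoch=start_epoch,
        log_fn=log_epoch,
    )
    bundle.save(ckpt)
    history_to_csv(history, loss_csv)
    if prior_rows:
        # prepend the earlier epochs so numbering continues seamlessly
        lines = loss_csv.read_text().strip().splitlines()
        fixed = [lines[0]] + prior_rows + [
            ",".join([str(start_epoch + i)] + row.split(",")[1:])
            for i, row in enumerate(lines[1:])
        ]
        loss_csv.write_text("\n".join(fixed) + "\n")
    (workdir / "normalizer.json").write_text(bundle.normalizer.to_json())
    return bundle


def cmd_enhance(cfg: dict, workdir: str | Path,
                bundle: ModelBundle | None = None) -> list[Path]:
    """Apply the trained enhancer to the held-out low-dose images."""
    cfg = config_with_defaults(cfg)
    workdir = Path(workdir)
    if bundle is None:
        bundle = ModelBundle.load(workdir / "checkpoint.npz")
    fmt = cfg["simulate"].get("format", "npz")
    write = _writer(fmt)
    outdir = workdir / "enhanced"
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    inputs = sorted((workdir / "test").glob(f"test_*_low{_suffix(fmt)}"))
    inputs += sorted((workdir / "uniform").glob(f"uniform_low{_suffix(fmt)}"))
    for p in inputs:
        img = uio.read_image(p)
        out = generate(bundle, img)
        fn = outdir / p.name.replace("low", "dlr")
        write(out, fn)
        outputs.append(fn)
    # provenance: which checkpoint produced these outputs
    import hashlib

    ckpt = workdir / "checkpoint.npz"
    model_hash = (hashlib.sha256(ckpt.read_bytes()).hexdigest()[:16]
                  if ckpt.exists() else None)
    (outdir / "provenance.json").write_text(json.dumps({
        "model_sha256_16": model_hash,
        "inputs": [p.name for p in inputs],
        "outputs": [p.name for p in outputs],
    }, indent=2))
    log.info("enhanced %d images into %s", len(outputs), outdir)
    return outputs


def cmd_evaluate(cfg: dict, workdir: str | Path) -> dict:
    """Objective report (CNR/LCV/UI/MTF/NPS/MAE/MSE) for the LDCT, DLR
    and NDCT test images, plus the protocol effective doses."""
    cfg = config_with_defaults(cfg)
    workdir = Path(workdir)
    spec = phantom_from(cfg)
    fmt = cfg["simulate"].get("format", "npz")
    sfx = _suffix(fmt)
    clean = uio.read_image(workdir / "test" / f"test_clean{sfx}")
    images = {
        "LDCT": uio.read_image(workdir / "test" / f"test_000_low{sfx}"),
        "NDCT": uio.read_image(workdir / "test" / f"test_000_high{sfx}"),
    }
    uniform = {
        "LDCT": uio.read_image(workdir / "uniform" / f"uniform_low{sfx}"),
        "NDCT": uio.read_image(workdir / "uniform" / f"uniform_high{sfx}"),
    }
    dlr = workdir / "enhanced" / f"test_000_dlr{sfx}"
    if dlr.exists():
        images["DLR"] = uio.read_image(dlr)
        udlr = workdir / "enhanced" / f"uniform_dlr{sfx}"
        if udlr.exists():
            uniform["DLR"] = uio.read_image(udlr)
    reports = evaluate(images, clean, spec, uniform_images=uniform)

    frame = reports_to_frame(reports)
    outdir = workdir / "reports"
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "iqa_report.csv")

    from .iqa import ROIError, extract_nps_rois, mtf as iqa_mtf, nps as iqa_nps
    from .iqa import plot_mtf, plot_nps
    from .phantom import ParameterError

    try:
        nps_results = {
            label: iqa_nps(extract_nps_rois(img), img.spacing_mm)
            for label, img in uniform.items()
        }
        plot_nps(nps_results, outdir / "nps_radial.png")
    except ParameterError:
        pass
    curves = {}
    for label, img in images.items():
        try:
            ins = spec.insert("teflon")
            curves[label] = iqa_mtf(img, ins.center_xy_mm, ins.diameter_mm / 2.0)
        except (KeyError, ROIError):
            pass
    if curves:
        plot_mtf(curves, outdir / "mtf_curves.png")
    doses = {
        "effective_dose_normal_mSv": round_sig(
            effective_dose(float(cfg["protocol"]["high"]["dlp_mGy_cm"])), 2
        ),
        "effective_dose_low_mSv": round_sig(
            effective_dose(float(cfg["protocol"]["low"]["dlp_mGy_cm"])), 2
        ),
    }
    payload = {
        "reports": {k: r.to_dict() for k, r in reports.items()},
        "doses": doses,
    }
    (outdir / "iqa_report.json").write_text(json.dumps(payload, indent=2))
    log.info("evaluation written to %s", outdir)
    return payload


def run_smoke_trial(seed: int, cfg: dict | None = None) -> dict:
    """One in-memory end-to-end trial at the smoke profile.

    Simulates unpaired corpora, trains the enhancement model, applies it
    to held-out low-dose images of the unjittered phantom, and measures
    uniform-ROI noise and acrylic-insert CNR before and after
    enhancement.  Returns the summary metrics.
    """
    from .iqa import cnr as iqa_cnr
    from .iqa import locate_catphan_rois as locate
    from .iqa import roi_stats as stats

    cfg = config_with_defaults(cfg)
    cfg["seed"] = int(seed)
    sim = cfg["simulate"]
    tc = cfg["train"]
    spec = phantom_from(cfg)
    low = float(cfg["protocol"]["low"]["tube_current_mAs"])
    high = float(cfg["protocol"]["high"]["tube_current_mAs"])
    dom_a, dom_b = make_unpaired_dataset(
        spec, int(sim["n_per_domain"]), low, high, seed=int(seed),
        matrix_size=int(sim["matrix_size"]), spacing_mm=float(sim["spacing_mm"]),
        method=sim.get("noise_method", "fbp"),
    )
    schedule = TrainSchedule(
        epochs_total=int(tc["epochs_total"]),
        epochs_constant_lr=int(tc["epochs_constant_lr"]),
        lr_initial=float(tc["lr_initial"]),
        batch_size=int(tc["batch_size"]),
        seed=int(seed),
    )
    bundle, history = train(
        dom_a, dom_b, schedule,
        LossWeights(float(tc["lambda_cyc"]), float(tc["lambda_iden"])),
        patch_size=int(tc["patch_size"]),
        patches_per_image=int(tc["patches_per_image"]),
        augmentation=AugmentationPolicy(
            rotation_right_angles=bool(tc.get("rotation_right_angles", True))
        ),
        width_multiplier=float(tc["width_multiplier"]),
        d_width_multiplier=float(tc.get("d_width_multiplier", 1.0)),
        n_res_blocks=int(tc["n_res_blocks"]),
        residual=bool(tc.get("residual", True)),
        d_warmup_steps=int(tc.get("d_warmup_steps", 0)),
    )
    clean = render_phantom(spec, int(sim["matrix_size"]), float(sim["spacing_mm"]))
    from .iqa import lcv as iqa_lcv

    held_out_rng = np.random.default_rng(np.random.SeedSequence(int(seed)).spawn(4)[3])
    sig_in, sig_out, cnr_in, cnr_out, lcv_in, lcv_out = [], [], [], [], [], []
    for _ in range(int(sim.get("n_test", 3))):
        s = int(held_out_rng.integers(0, 2**31 - 1))
        test = simulate_dose(clean, low, high, seed=s,
                             method=sim.get("noise_method", "fbp"))
        enhanced = generate(bundle, test)
        rois = locate(test, spec)
        bg = rois["background"]
        sig_in.append(stats(test, bg).sigma_hu)
        sig_out.append(stats(enhanced, bg).sigma_hu)
        cnr_in.append(iqa_cnr(test, rois["acrylic"], bg))
        cnr_out.append(iqa_cnr(enhanced, rois["acrylic"], bg))
        lcv_in.append(iqa_lcv(test, rois["ldpe"], rois["polystyrene"]))
        lcv_out.append(iqa_lcv(enhanced, rois["ldpe"], rois["polystyrene"]))
    sigma_reduction = 100.0 * (1.0 - float(np.mean(sig_out)) / float(np.mean(sig_in)))
    return {
        "seed": int(seed),
        "sigma_ldct_hu": float(np.mean(sig_in)),
        "sigma_dlr_hu": float(np.mean(sig_out)),
        "sigma_reduction_percent": sigma_reduction,
        "cnr_acrylic_ldct": float(np.mean(cnr_in)),
        "cnr_acrylic_dlr": float(np.mean(cnr_out)),
        "lcv_ldct": float(np.mean(lcv_in)),
        "lcv_dlr": float(np.mean(lcv_out)),
        "final_cycle_loss": history[-1].cyc,
        "first_cycle_loss": history[0].cyc,
    }


def run_all(cfg: dict, workdir: str | Path) -> dict:
    """simulate -> train -> enhance -> evaluate in one call."""
    cmd_simulate(cfg, workdir)
    bundle = cmd_train(cfg, workdir)
    cmd_enhance(cfg, workdir, bundle)
    return cmd_evaluate(cfg, workdir)
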