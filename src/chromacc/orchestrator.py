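"""End-to-end experiment recipes: generate -> train -> evaluate -> analyze.

A YAML config describes one experiment (catalog, illuminants, scenes,
model, training, evaluation, rsa).  ``run_experiment`` executes the whole
desk-scale workflow — build the calibrated catalog and illuminant sets,
train classifier instances on the varying-illumination (CC) and D65-only
datasets, evaluate them under the scene-manipulation conditions, run the
classical baselines and the representational analysis — and writes CSV
tables plus a provenance record (config hash, seeds, package version)
into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import baseline_summary, run_baseline_suite
from .catalog import build_synthetic_catalog
from .evaluation import (
    evaluate_condition,
    make_eval_manifest,
    per_illuminant_cci,
    summarize,
)
from .models import ArchitectureSpec, ReadoutSpec, build_classifier
from .rsa import rsa_pipeline
from .scenes import (
    IlluminantSet,
    build_dataset_manifest,
    default_scene_config,
    make_test_illuminants,
    make_training_illuminants,
    render_manifest,
)
from .training import (
    TrainConfig,
    default_input_scale,
    split_dataset,
    train_classifier,
    train_readouts,
    TrainedInstance,
)

REQUIRED_SECTIONS = (
    "seed",
    "catalog",
    "illuminants",
    "scenes",
    "model",
    "training",
    "evaluation",
)


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict):
    missing = [s for s in REQUIRED_SECTIONS if s not in cfg]
    if missing:
        raise ValueError(f"config missing sections: {missing}")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]


def recipe_path(name: str) -> Path:
    from importlib import resources

    return Path(str(resources.files("chromacc.recipes").joinpath(f"{name}.yaml")))


# ---------------------------------------------------------------------------
# building blocks reused by the CLI and the acceptance script


@dataclass
class Workspace:
    """Everything an experiment run shares: catalog, illuminants, scenes."""

    cfg: dict
    catalog: object
    train_illums: IlluminantSet
    test_illums: IlluminantSet
    d65_only: IlluminantSet
    scene_cfg: object
    input_scale: np.ndarray
    labels: dict


def build_workspace(cfg: dict) -> Workspace:
    validate_config(cfg)
    cat_cfg = cfg["catalog"]
    catalog = build_synthetic_catalog(
        n_hues=cat_cfg.get("n_hues", 10),
        n_values=cat_cfg.get("n_values", 4),
        n_chromas=cat_cfg.get("n_chromas", 4),
        spacing_target=cat_cfg.get("spacing_target", 7.3),
        seed=cfg["seed"],
    )
    ctx = catalog.ctx
    ill = cfg["illuminants"]
    train_illums = make_training_illuminants(
        n_dseries=ill.get("n_dseries", 5),
        n_jittered=ill.get("n_jittered", 35),
        spread_target=ill.get("spread_target", 8.55),
        seed=cfg["seed"],
        ctx=ctx,
    )
    test_illums = make_test_illuminants(ill.get("test_distance", 10.0), ctx)
    d65_only = IlluminantSet(["D65"], {}, {}, {}, ctx)
    image_size = tuple(cfg["scenes"].get("image_size", [32, 32]))
    scene_cfg = default_scene_config(catalog, image_size)
    labels = {cid: i for i, cid in enumerate(catalog.class_ids)}
    return Workspace(
        cfg,
        catalog,
        train_illums,
        test_illums,
        d65_only,
        scene_cfg,
        default_input_scale(ctx),
        labels,
    )


def _labels_of(ws: Workspace, manifest: pd.DataFrame) -> np.ndarray:
    return manifest["object_class_id"].map(ws.labels).to_numpy()


def render_split(ws: Workspace, variant: str, seed_offset: int = 0):
    """Rendered train/val arrays for the CC or D65 dataset variant."""
    sc = ws.cfg["scenes"]
    if variant == "CC":
        illums = ws.train_illums
        per_cell = sc.get("images_per_cell", 1)
        holdout = True
    elif variant == "D65":
        illums = ws.d65_only
        per_cell = sc.get("d65_images_per_cell", len(ws.train_illums))
        holdout = False
    else:
        raise ValueError(f"unknown dataset variant {variant!r}")
    manifest = build_dataset_manifest(
        ws.catalog,
        illums,
        per_cell,
        "normal",
        seed=ws.cfg["seed"] + 100 + seed_offset,
        image_size=ws.scene_cfg.image_size,
    )
    tr, va, split = split_dataset(
        manifest, seed=ws.cfg["seed"], holdout_illums=holdout
    )
    Xt, _ = render_manifest(tr, ws.catalog, illums, ws.scene_cfg)
    Xv, _ = render_manifest(va, ws.catalog, illums, ws.scene_cfg)
    return (Xt, _labels_of(ws, tr)), (Xv, _labels_of(ws, va)), split


def train_instances(ws: Workspace, variant: str, verbose=False) -> list[TrainedInstance]:
    t = ws.cfg["training"]
    n_inst = t.get("n_instances", 3)
    train_data, val_data, _ = render_split(ws, variant)
    arch = ArchitectureSpec(
        n_classes=len(ws.catalog),
        width_scale=ws.cfg["model"].get("width_scale", 0.5),
        dropout_rate=ws.cfg["model"].get("dropout_rate", 0.4),
    )
    out = []
    for i in range(n_inst):
        cfg = TrainConfig(
            epochs=t.get("epochs", 36),
            lr=t.get("lr", 1e-3),
            lr_decay_every=t.get("lr_decay_every", 12),
            batch_size=t.get("batch_size", 128),
            seed=ws.cfg["seed"] + i,
            n_instances=n_inst,
        )
        model = build_classifier(
            arch, ws.scene_cfg.image_size, seed=ws.cfg["seed"] + i
        )
        out.append(
            train_classifier(model, train_data, val_data, cfg, ws.input_scale, verbose)
        )
    return out


# ---------------------------------------------------------------------------


def run_experiment(config_path, out_dir, verbose: bool = False) -> Path:
    """Execute the full recipe; returns the report directory."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"

    def log(event, **kw):
        rec = {"t": round(time.time() - t_start, 1), "event": event, **kw}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        if verbose:
            print(rec)

    t_start = time.time()
    provenance = {
        "config_hash": config_hash(cfg),
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))

    log("workspace.build")
    ws = build_workspace(cfg)
    log(
        "workspace.ready",
        n_classes=len(ws.catalog),
        n_train_illums=len(ws.train_illums),
        median_spacing=ws.catalog.meta["realized_median_spacing"],
        illum_sd=ws.train_illums.chromatic_sd(),
    )

    log("train.cc")
    cc = train_instances(ws, "CC", verbose)
    log("train.d65")
    d65 = train_instances(ws, "D65", verbose)
    pd.DataFrame(
        {
            "variant": ["CC"] * len(cc) + ["D65"] * len(d65),
            "instance": list(range(len(cc))) + list(range(len(d65))),
            "final_val_acc": [t.final_val_accuracy for t in cc + d65],
            "best_val_acc": [t.best_val_accuracy for t in cc + d65],
        }
    ).to_csv(out / "training_summary.csv", index=False)

    ev = cfg["evaluation"]
    eman = make_eval_manifest(
        ws.catalog,
        ws.test_illums,
        replicates=ev.get("replicates", 10),
        seed=cfg["seed"] + 500,
        image_size=ws.scene_cfg.image_size,
    )
    conditions = ev.get("conditions", ["normal", "no_patch", "wrong_background"])
    summaries = []
    all_records = []
    for variant, insts in (("CC", cc), ("D65", d65)):
        for i, inst in enumerate(insts):
            for cond in conditions:
                log("evaluate", variant=variant, instance=i, condition=cond)
                rec = evaluate_condition(
                    inst, eman, ws.catalog, ws.test_illums, ws.scene_cfg, cond
                )
                rec["variant"], rec["instance"] = variant, i
                all_records.append(rec)
                summaries.append(
                    {"variant": variant, "instance": i, "condition": cond}
                    | summarize(rec)
                )
    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(out / "eval_records.csv", index=False)
    pd.DataFrame(summaries).to_csv(out / "eval_summary.csv", index=False)

    normal_cc = records[
        (records["variant"] == "CC") & (records["condition"] == "normal")
    ]
    per_illuminant_cci(normal_cc).to_csv(out / "per_illuminant_cci.csv", index=False)

    log("baselines")
    base = run_baseline_suite(
        eman.groupby(["object_class_id", "illum_id"]).head(
            ev.get("baseline_replicates", 2)
        ),
        ws.catalog,
        ws.test_illums,
        ws.scene_cfg,
    )
    base.to_csv(out / "baseline_records.csv", index=False)
    baseline_summary(base).to_csv(out / "baseline_summary.csv", index=False)

    if "rsa" in cfg:
        log("rsa")
        rcfg = cfg["rsa"]
        illums5 = _with_d65(ws)
        aman = make_eval_manifest(
            ws.catalog,
            illums5,
            replicates=rcfg.get("replicates", 2),
            seed=cfg["seed"] + 700,
            image_size=ws.scene_cfg.image_size,
        )
        Xa, _ = render_manifest(aman, ws.catalog, illums5, ws.scene_cfg)
        sub_labels = {c: i for i, c in enumerate(ws.catalog.eval_subset)}
        ya = aman["object_class_id"].map(sub_labels).to_numpy()
        rand = [
            TrainedInstance(
                build_classifier(
                    ArchitectureSpec(
                        n_classes=len(ws.catalog),
                        width_scale=cfg["model"].get("width_scale", 0.5),
                    ),
                    ws.scene_cfg.image_size,
                    seed=cfg["seed"] + 900 + i,
                ),
                pd.DataFrame(),
                cc[0].cfg,
                ws.input_scale,
            )
            for i in range(len(cc))
        ]
        report = rsa_pipeline(
            cc,
            Xa,
            ya,
            ws.catalog,
            ws.catalog.eval_subset,
            taps=tuple(rcfg.get("taps", ["conv1", "conv2", "conv3", "fc1", "fc2"])),
            reference=rcfg.get("reference", "munsell"),
            random_instances=rand if rcfg.get("include_random_control", True) else None,
        )
        report.to_csv(out / "rsa_explained_variance.csv", index=False)

    log("done")
    return out


def _with_d65(ws: Workspace) -> IlluminantSet:
    """Test illuminants augmented with D65 (activation-recording set)."""
    t = ws.test_illums
    ids = ["D65"] + list(t.ids)
    spectra = {"D65": ws.catalog.ctx.d65, **t.spectra}
    chroma = {
        "D65": ws.catalog.ctx.illuminant_chromaticity(ws.catalog.ctx.d65),
        **t.chromaticity,
    }
    prov = {"D65": "reference", **t.provenance}
    return IlluminantSet(ids, spectra, chroma, prov, ws.catalog.ctx)
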