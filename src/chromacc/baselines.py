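"""Classical illuminant-estimation baselines with von Kries correction.

Three low-level estimators produce a single global LMS triplet for the
scene illuminant: Gray World (scene mean), White Patch (per-channel
maximum) and a simplified adaptive-surround pooling (ASM) that averages a
contrast-dependent fraction of the brightest pixels.  Each estimate is
coupled with a global von Kries correction (channel-wise division), the
segmented object's mean chromaticity is compared against the same object
rendered under the reference D65 illumination, and the error is reported
as dE and CCI.  A `perfect` mode uses the ground-truth illuminant (the
upper bound of any estimate-then-divide scheme) and `none` skips
correction entirely (a perfect segmenter with no constancy, CCI = 0 by
construction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import ClassCatalog
from .colorimetry import Triplet, delta_e, project
from .evaluation import ChipChromaticities
from .scenes import (
    IlluminantSet,
    LMSImage,
    SceneConfig,
    render_scene,
    spec_from_row,
    _LMSCache,
)

CORRECTIONS = ("grayworld", "whitepatch", "asm", "perfect", "none")


def gray_world(image: LMSImage) -> Triplet:
    """Scene-mean LMS as the illuminant estimate."""
    if image.pixels.size == 0:
        raise ValueError("empty image")
    return Triplet("LMS", image.pixels.reshape(-1, 3).mean(axis=0))


def white_patch(image: LMSImage) -> Triplet:
    """Per-channel maximum over pixels (max-LMS convention)."""
    if image.pixels.size == 0:
        raise ValueError("empty image")
    return Triplet("LMS", image.pixels.reshape(-1, 3).max(axis=0))


def asm(
    image: LMSImage,
    pool_range: tuple[float, float] = (0.01, 0.20),
    gradient_norm: float = 0.5,
) -> Triplet:
    """Contrast-adaptive pooling of the brightest pixels.

    The pooled fraction interpolates from ``pool_range[1]`` (flat images)
    down to ``pool_range[0]`` as the mean local gradient magnitude of the
    brightness map (relative to its mean, scaled by ``gradient_norm``)
    grows; the estimate is the mean of the pooled brightest pixels.
    """
    px = image.pixels.reshape(-1, 3)
    if px.size == 0:
        raise ValueError("empty image")
    bright = image.pixels.sum(axis=2)
    gy, gx = np.gradient(bright)
    mean_b = float(bright.mean())
    contrast = float(np.hypot(gy, gx).mean() / (mean_b + 1e-12)) / gradient_norm
    frac = pool_range[1] - (pool_range[1] - pool_range[0]) * min(contrast, 1.0)
    n = max(1, int(round(frac * len(px))))
    idx = np.argsort(bright.ravel(), kind="stable")[-n:]
    return Triplet("LMS", px[idx].mean(axis=0))


def von_kries_correct(image: LMSImage, estimate: Triplet) -> LMSImage:
    """Channel-wise division by the illuminant estimate."""
    if estimate.space != "LMS":
        raise ValueError("estimate must be an LMS triplet")
    if np.any(estimate.values <= 0):
        raise ValueError("estimate channels must be positive")
    return LMSImage(image.pixels / estimate.values, image.object_mask)


def _mean_object_lab(ctx, pixels, mask):
    # anchored chromaticity: estimates carry no absolute scale, so the
    # object's mean cone excitation is compared at a fixed luminance
    if not mask.any():
        raise ValueError("empty object mask")
    return ctx.chromaticity_of_lms(pixels[mask].mean(axis=0))


def object_color_error(
    image: LMSImage,
    reference_image_d65: LMSImage,
    correction: str,
    illum_lms: np.ndarray,
    d65_lms: np.ndarray,
    ctx,
) -> tuple[float, float]:
    """(dE, CCI) of the segmented object's corrected mean chromaticity.

    The corrected image is mapped back to D65 units (divide by the
    estimate, multiply by the D65 illuminant LMS) so its object mean is
    directly comparable to the matched D65 render.  CCI uses the measured
    chromaticities: the denominator is the object's raw shift between the
    test and reference renders.  Returns nan CCI when that shift vanishes.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    est = {
        "grayworld": lambda: gray_world(image).values,
        "whitepatch": lambda: white_patch(image).values,
        "asm": lambda: asm(image).values,
        "perfect": lambda: illum_lms,
        "none": lambda: d65_lms,  # divide and re-multiply cancel: identity
    }[correction]()
    corrected = image.pixels * (d65_lms / est)
    lab = _mean_object_lab(ctx, corrected, image.object_mask)
    ref_lab = _mean_object_lab(
        ctx, reference_image_d65.pixels, reference_image_d65.object_mask
    )
    raw_lab = _mean_object_lab(ctx, image.pixels, image.object_mask)
    err = delta_e(lab, ref_lab)
    shift = delta_e(raw_lab, ref_lab)
    cci_val = float("nan") if shift < 1e-6 else 1.0 - err / shift
    return err, cci_val


def run_baseline_suite(
    eval_manifest: pd.DataFrame,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    scene_cfg: SceneConfig,
    corrections: tuple[str, ...] = CORRECTIONS,
) -> pd.DataFrame:
    """dE/CCI distributions per correction over an evaluation manifest.

    Every trial is rendered twice — under its test illuminant and, with
    the identical object shape and position, under D65 — so any residual
    error is attributable to the estimation + correction alone.
    """
    ctx = catalog.ctx
    cache = _LMSCache(catalog, illums)
    illum_lms = {
        iid: project(illums.get(iid) * ctx.white_reflectance, ctx.lms_sensors).values
        for iid in list(illums.ids) + ["D65"]
    }
    rows = []
    for _, row in eval_manifest.iterrows():
        spec = spec_from_row(row, "normal")
        img = render_scene(spec, catalog, illums, scene_cfg, cache)
        ref_spec = spec_from_row(row, "normal")
        ref = render_scene(
            type(spec)(
                illum_id="D65",
                object_class_id=spec.object_class_id,
                object_shape_seed=spec.object_shape_seed,
                object_center=spec.object_center,
                condition="normal",
            ),
            catalog,
            illums,
            scene_cfg,
            cache,
        )
        for corr in corrections:
            err, c = object_color_error(
                img, ref, corr, illum_lms[spec.illum_id], illum_lms["D65"], ctx
            )
            rows.append(
                {
                    "illum_id": spec.illum_id,
                    "true_class": spec.object_class_id,
                    "correction": corr,
                    "delta_e": err,
                    "cci": c,
                }
            )
    return pd.DataFrame(rows)


def baseline_summary(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.groupby("correction")
        .agg(median_delta_e=("delta_e", "median"), median_cci=("cci", "median"))
        .reset_index()
    )
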