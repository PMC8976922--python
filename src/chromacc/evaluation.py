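"""Metric suite: top-k / Muns3 accuracies, selected-chromaticity dE, CCI.

The continuous error of a classifier is measured by converting its
selected class into CIELab chromaticity (the class's reference Lab under
D65) and taking the 1976 dE to the true class's chromaticity.  The Color
Constancy Index relates the model's error to the chromaticity shift the
illuminant induced on the chip:

    CCI = 1 - ||C_I^N - C_I^M|| / ||C_D65^M - C_I^M||

where C_I^M is the Lab chromaticity of the true chip M under the test
illuminant I, C_D65^M the same chip under D65, and C_I^N the chip the
model selected, under I.  CCI is 1 for a correct answer, 0 for a model
that ignores the illuminant entirely, negative for errors larger than the
illuminant shift, and undefined (excluded, counted) when the illuminant
shift is smaller than ``eps``.

Chip chromaticities C_I^M are computed from flat, unshaded renderings of
the chip reflectance under the illuminant spectrum, so the index is a
property of (chip, illuminant), not of a particular scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import CHROMA_STEP_UNITS, ClassCatalog, MunsellCoord
from .colorimetry import Triplet, delta_e, project, xyz_to_lab
from .scenes import (
    IlluminantSet,
    SceneConfig,
    build_dataset_manifest,
    render_manifest,
)

CCI_EPS = 1e-6


@dataclass(frozen=True)
class EvalRecord:
    """One evaluated trial."""

    true_class: int
    predicted_ranking: tuple[int, ...]
    illum_id: str
    condition: str
    delta_e_error: float
    cci: float  # nan marks an undefined index (denominator < eps)


# ---------------------------------------------------------------------------
# elementary metrics


def ranking_from_logits(logits: np.ndarray, class_ids: np.ndarray) -> np.ndarray:
    """Class ids ordered by descending logit; ties broken by ascending id."""
    order = np.argsort(-logits, axis=-1, kind="stable")
    return np.asarray(class_ids)[order]


def topk_hit(ranking, true_class, k: int) -> bool:
    if k < 1:
        raise ValueError("k must be >= 1")
    ranking = list(ranking)
    if not ranking:
        raise ValueError("empty ranking")
    return true_class in ranking[:k]


def muns3_hit(
    predicted: MunsellCoord, true: MunsellCoord, catalog: ClassCatalog
) -> bool:
    """Within a cube of side 3 in Munsell space centered on the true chip.

    One grid step in each coordinate: circular hue distance <= 1 (ignored
    when either chip is neutral), value within one row of the catalog's
    value grid, chroma within one (even) chroma step.
    """
    values = list(catalog.value_steps)
    try:
        dv = abs(values.index(predicted.value_step) - values.index(true.value_step))
    except ValueError as exc:
        raise ValueError("coordinate not on this catalog's value grid") from exc
    if dv > 1:
        return False
    if abs(predicted.chroma_step - true.chroma_step) > CHROMA_STEP_UNITS:
        return False
    if predicted.hue_index > 0 and true.hue_index > 0:
        H = catalog.n_hues
        dh = abs(predicted.hue_index - true.hue_index)
        if min(dh, H - dh) > 1:
            return False
    return True


def selected_chromaticity(predicted_class: int, catalog: ClassCatalog) -> Triplet:
    """Reference (D65) Lab chromaticity of the class the model selected."""
    return catalog.reference_lab(predicted_class)


class ChipChromaticities:
    """Cache of flat-chip Lab values under each illuminant."""

    def __init__(self, catalog: ClassCatalog, illums: IlluminantSet):
        self.catalog = catalog
        self.illums = illums
        self._cache: dict[tuple[str, int], Triplet] = {}

    def lab(self, illum_id: str, class_id: int) -> Triplet:
        key = (illum_id, class_id)
        if key not in self._cache:
            ctx = self.catalog.ctx
            e = self.illums.get(illum_id)
            r = self.catalog.reflectance(class_id)
            self._cache[key] = xyz_to_lab(project(e * r, ctx.xyz_sensors), ctx.white)
        return self._cache[key]


def cci(
    predicted_class: int,
    true_class: int,
    illum_id: str,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    chips: ChipChromaticities | None = None,
    eps: float = CCI_EPS,
) -> float:
    """Color Constancy Index of one trial; nan when undefined."""
    chips = chips or ChipChromaticities(catalog, illums)
    c_i_m = chips.lab(illum_id, true_class)
    c_d65_m = chips.lab("D65", true_class)
    c_i_n = chips.lab(illum_id, predicted_class)
    denom = delta_e(c_d65_m, c_i_m)
    if denom < eps:
        return float("nan")
    return 1.0 - delta_e(c_i_n, c_i_m) / denom


# ---------------------------------------------------------------------------
# condition evaluation


def evaluate_records(
    instance,
    X: np.ndarray,
    manifest: pd.DataFrame,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    condition: str,
) -> pd.DataFrame:
    """Score pre-rendered trials: one record row per image."""
    class_ids = np.asarray(catalog.class_ids)
    label_of = {cid: i for i, cid in enumerate(class_ids)}
    logits = instance.predict_logits(X)
    rankings = ranking_from_logits(logits, class_ids)
    chips = ChipChromaticities(catalog, illums)
    rows = []
    for k, (_, row) in enumerate(manifest.iterrows()):
        true = int(row["object_class_id"])
        rk = rankings[k]
        pred = int(rk[0])
        true_lab = catalog.reference_lab(true)
        rows.append(
            {
                "true_class": true,
                "predicted_class": pred,
                "illum_id": row["illum_id"],
                "condition": condition,
                "top1": pred == true,
                "top5": true in rk[:5],
                "muns3": muns3_hit(catalog.coord(pred), catalog.coord(true), catalog),
                "delta_e_error": delta_e(
                    selected_chromaticity(pred, catalog), true_lab
                ),
                "cci": cci(pred, true, row["illum_id"], catalog, illums, chips),
            }
        )
    return pd.DataFrame(rows)


def evaluate_condition(
    instance,
    manifest: pd.DataFrame,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    scene_cfg: SceneConfig,
    condition: str = "normal",
) -> pd.DataFrame:
    """Render a manifest under a scene condition and score every trial."""
    X, _ = render_manifest(manifest, catalog, illums, scene_cfg, condition)
    return evaluate_records(instance, X, manifest, catalog, illums, condition)


def metrics_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(class, illuminant) rates and error medians over replicates."""
    g = records.groupby(["true_class", "illum_id"])
    out = g.agg(
        top1=("top1", "mean"),
        top5=("top5", "mean"),
        muns3=("muns3", "mean"),
        median_delta_e=("delta_e_error", "median"),
        median_cci=("cci", "median"),
        n=("top1", "size"),
        n_cci_undefined=("cci", lambda s: int(s.isna().sum())),
    ).reset_index()
    return out


def summarize(records: pd.DataFrame) -> dict:
    """Distribution summaries in the style of the evaluation figures."""
    cells = metrics_table(records)
    return {
        "median_top1": float(cells["top1"].median()),
        "median_top5": float(cells["top5"].median()),
        "median_muns3": float(cells["muns3"].median()),
        "median_delta_e": float(records["delta_e_error"].median()),
        "median_cci": float(records["cci"].median()),
        "q1_cci": float(records["cci"].quantile(0.25)),
        "n_images": int(len(records)),
        "n_cci_undefined": int(records["cci"].isna().sum()),
    }


def per_illuminant_cci(records: pd.DataFrame) -> pd.DataFrame:
    """Mean CCI per (illuminant, class); undefined values excluded."""
    missing = set(("Y", "B", "G", "R")) - set(records["illum_id"].unique())
    if missing:
        import warnings

        warnings.warn(f"records missing test illuminants: {sorted(missing)}")
    out = (
        records.groupby(["illum_id", "true_class"])
        .agg(mean_cci=("cci", "mean"), n_undefined=("cci", lambda s: int(s.isna().sum())))
        .reset_index()
    )
    return out


def patch_ablation(
    instance,
    manifest: pd.DataFrame,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    scene_cfg: SceneConfig,
) -> pd.DataFrame:
    """Top-1 accuracy loss when masking each cue patch, vs the normal scene."""
    normal = evaluate_condition(instance, manifest, catalog, illums, scene_cfg, "normal")
    base = float(normal["top1"].mean())
    rows = []
    for i in range(6):
        rec = evaluate_condition(
            instance, manifest, catalog, illums, scene_cfg, f"mask_patch_{i}"
        )
        rows.append(
            {
                "patch": i,
                "normal_top1": base,
                "masked_top1": float(rec["top1"].mean()),
                "loss": base - float(rec["top1"].mean()),
            }
        )
    return pd.DataFrame(rows)


def make_eval_manifest(
    catalog: ClassCatalog,
    test_illums: IlluminantSet,
    replicates: int = 10,
    seed: int = 1234,
    image_size=(32, 32),
) -> pd.DataFrame:
    """The evaluation set: eval-subset classes x test illuminants x replicates."""
    return build_dataset_manifest(
        catalog,
        test_illums,
        images_per_cell=replicates,
        condition="normal",
        seed=seed,
        image_size=image_size,
        class_ids=catalog.eval_subset,
    )
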