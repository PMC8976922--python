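"""Synthetic scene stage: illuminant sets, Lambertian rendering, manifests.

The renderer emulates the statistical structure of the study's rendered
room scenes at desk scale: a fixed "room" (ceiling, back wall, floor, two
side walls) whose back wall carries six constant colorful cue patches, and
a procedurally shaped object floating in front, carrying the reflectance
of the class to be reported.  Every pixel is direct illumination only:

    pixel_LMS = project(illuminant * region_reflectance, LMS) * shading

with a smooth shading field, no interreflections and no cast shadows.
The contextual regions therefore carry exactly the information the study
manipulates: their chromaticities identify the illuminant, and the
object's chromaticity confounds surface and illuminant.

Illuminants come in two sets: a training set concentrated on the daylight
locus (D-series spectra plus jittered daylight-basis spectra emulating
measured forest illuminations, calibrated to a stated chromatic spread)
and four test illuminants Y/B/G/R at a fixed chromatic distance from the
gray point, two along the locus and two orthogonal to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .catalog import ClassCatalog
from .colorimetry import (
    ColorContext,
    Spectrum,
    Triplet,
    daylight_chromaticity_xy,
    daylight_spectrum_from_weights,
    daylight_weights_for_xy,
    normalize,
    project,
)

D65_ID = "D65"
TEST_IDS = ("Y", "B", "G", "R")
CONDITIONS = ("normal", "no_patch", "wrong_patch", "wrong_background") + tuple(
    f"mask_patch_{i}" for i in range(6)
)


# ---------------------------------------------------------------------------
# illuminant sets


@dataclass
class IlluminantSet:
    """Named illuminant spectra with their anchored Lab chromaticities."""

    ids: list[str]
    spectra: dict[str, Spectrum]
    chromaticity: dict[str, Triplet]
    provenance: dict[str, str]
    ctx: ColorContext

    def get(self, illum_id: str) -> Spectrum:
        if illum_id == D65_ID and illum_id not in self.spectra:
            return self.ctx.d65
        return self.spectra[illum_id]

    def chroma_ab(self, illum_id: str) -> np.ndarray:
        if illum_id == D65_ID and illum_id not in self.chromaticity:
            return self.ctx.illuminant_chromaticity(self.ctx.d65).values[1:]
        return self.chromaticity[illum_id].values[1:]

    def __len__(self):
        return len(self.ids)

    def chromatic_sd(self) -> float:
        """RMS (a*, b*) deviation from the set's mean chromaticity."""
        ab = np.array([self.chromaticity[i].values[1:] for i in self.ids])
        dev = ab - ab.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def _set_from_weights(weights, ids, provenance, ctx, norm_mode, norm_target):
    spectra, chroma, prov = {}, {}, {}
    for (m1, m2), iid, p in zip(weights, ids, provenance):
        s = daylight_spectrum_from_weights(m1, m2, ctx.grid)
        s = normalize(s, norm_mode, norm_target)
        spectra[iid] = s
        chroma[iid] = ctx.illuminant_chromaticity(s)
        prov[iid] = p
    return IlluminantSet(list(ids), spectra, chroma, prov, ctx)


def make_training_illuminants(
    n_dseries: int = 43,
    n_jittered: int = 236,
    spread_target: float = 8.55,
    seed: int = 0,
    ctx: ColorContext | None = None,
    cct_range: tuple[float, float] = (4000.0, 12000.0),
) -> IlluminantSet:
    """Training illuminants: D-series plus jittered daylight emulants.

    ``n_dseries`` spectra sit at evenly spaced correlated color temperatures
    over ``cct_range``; ``n_jittered`` spectra perturb the D65 daylight-basis
    weights with a Gaussian jitter whose amplitude is calibrated so the
    whole set's (a*, b*) chromaticity s.d. equals ``spread_target`` +/- 3%.
    All spectra are peak-normalized to 100.
    """
    if n_dseries < 2 or spread_target <= 0:
        raise ValueError("need n_dseries >= 2 and spread_target > 0")
    ctx = ColorContext.default() if ctx is None else ctx

    ccts = np.linspace(cct_range[0], cct_range[1], n_dseries)
    d_weights = [daylight_weights_for_xy(*daylight_chromaticity_xy(t)) for t in ccts]
    d_ids = [f"D{i:03d}" for i in range(n_dseries)]

    m0 = np.array(daylight_weights_for_xy(*daylight_chromaticity_xy(6504.0)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_jittered, 2))
    j_ids = [f"J{i:03d}" for i in range(n_jittered)]

    def build(alpha):
        w = list(d_weights) + [tuple(m0 + alpha * zi) for zi in z]
        return _set_from_weights(
            w,
            d_ids + j_ids,
            ["dseries"] * n_dseries + ["jittered"] * n_jittered,
            ctx,
            "peak",
            100.0,
        )

    if n_jittered == 0:
        return build(0.0)

    def spread_err(alpha):
        return build(alpha).chromatic_sd() - spread_target

    lo = 0.0
    err0 = spread_err(lo)
    if err0 > 0.03 * spread_target:
        raise ValueError(
            "spread target unreachable: D-series spread alone exceeds it"
        )
    if err0 >= 0:  # already within tolerance without any jitter
        return build(0.0)
    hi = 0.05
    while spread_err(hi) < 0 and hi < 10:
        hi *= 2
    if spread_err(hi) < 0:
        raise ValueError("spread target unreachable: jitter cannot widen enough")
    alpha = brentq(spread_err, lo, hi, xtol=1e-5)
    out = build(alpha)
    assert abs(out.chromatic_sd() - spread_target) <= 0.03 * spread_target
    return out


def _locus_tangent_ab(ctx: ColorContext) -> np.ndarray:
    """Unit tangent of the daylight locus in (a*, b*) at the gray point,
    oriented toward yellow (positive b*)."""

    def ab(cct):
        m = daylight_weights_for_xy(*daylight_chromaticity_xy(cct))
        s = daylight_spectrum_from_weights(*m, ctx.grid)
        return ctx.illuminant_chromaticity(s).values[1:]

    t = ab(6304.0) - ab(6704.0)  # lower CCT = yellower
    return t / np.linalg.norm(t)


def make_test_illuminants(
    distance: float = 10.0, ctx: ColorContext | None = None
) -> IlluminantSet:
    """The four evaluation illuminants Y/B/G/R.

    Each is a daylight-basis spectrum placed by numerical search at
    ``distance`` dE from the gray point in the (a*, b*) plane: Y and B along
    the daylight-locus tangent, G and R along the orthogonal direction.
    Areas under curve are equalized (to the D65 spectrum's area) so the
    four differ minimally in lightness.
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    ctx = ColorContext.default() if ctx is None else ctx
    tangent = _locus_tangent_ab(ctx)
    ortho = np.array([-tangent[1], tangent[0]])
    if ortho[0] < 0:  # orient toward positive a* (reddish) for R
        ortho = -ortho
    targets = {
        "Y": distance * tangent,
        "B": -distance * tangent,
        "R": distance * ortho,
        "G": -distance * ortho,
    }
    m0 = np.array(daylight_weights_for_xy(*daylight_chromaticity_xy(6504.0)))

    def ab_of(m):
        s = daylight_spectrum_from_weights(m[0], m[1], ctx.grid)
        return ctx.illuminant_chromaticity(s).values[1:]

    weights = []
    for iid in TEST_IDS:
        res = least_squares(
            lambda m: ab_of(m) - targets[iid], m0, xtol=1e-14, ftol=1e-14
        )
        if np.linalg.norm(res.fun) > 1e-6:
            raise RuntimeError(
                f"test illuminant {iid} search did not converge; "
                f"residual={res.fun}"
            )
        weights.append(tuple(res.x))

    area = ctx.d65.integral()
    return _set_from_weights(
        weights,
        list(TEST_IDS),
        [f"test{i}" for i in TEST_IDS],
        ctx,
        "area",
        area,
    )


# ---------------------------------------------------------------------------
# scene geometry


@dataclass(frozen=True)
class SceneConfig:
    """Fixed per-dataset scene layout: room surfaces and cue patches."""

    image_size: tuple[int, int] = (32, 32)
    room_class_ids: tuple[int, ...] = ()  # back wall, ceiling, floor, L, R
    patch_class_ids: tuple[int, ...] = ()  # six fixed colorful patches
    object_radius_frac: float = 0.20

    def __post_init__(self):
        if len(self.room_class_ids) != 5 or len(self.patch_class_ids) != 6:
            raise ValueError("need 5 room surfaces and 6 patches")


def default_scene_config(
    catalog: ClassCatalog, image_size: tuple[int, int] = (32, 32)
) -> SceneConfig:
    """Near-neutral room surfaces and six maximally spread cue patches.

    Patches cover red/yellow/green/blue hue directions plus a light and a
    dark neutral, mirroring the constant colorful cues of the study design.
    """
    labs = {i: catalog.reference_lab(i).values for i in catalog.class_ids}
    neutrals = sorted(
        (i for i in catalog.class_ids if catalog.coord(i).hue_index == 0),
        key=lambda i: labs[i][0],
    )
    chromatic = [i for i in catalog.class_ids if catalog.coord(i).hue_index > 0]

    def pick(angle_deg):
        ang = np.deg2rad(angle_deg)
        u = np.array([np.cos(ang), np.sin(ang)])
        return max(chromatic, key=lambda i: labs[i][1:] @ u)

    patches = (pick(25), pick(90), pick(140), pick(260), neutrals[-1], neutrals[0])
    # room: low-chroma mid chips: nearest to gray at mid lightness
    by_sat = sorted(chromatic, key=lambda i: np.hypot(*labs[i][1:]))
    room = (neutrals[-2], neutrals[-1], by_sat[0], by_sat[1], by_sat[2])
    return SceneConfig(image_size, room, patches)


@dataclass(frozen=True)
class SceneSpec:
    """One rendered trial."""

    illum_id: str
    object_class_id: int
    object_shape_seed: int
    object_center: tuple[float, float]  # (row, col) fractions of H, W
    condition: str = "normal"

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class LMSImage:
    pixels: np.ndarray  # H x W x 3 float32, no gamut clipping
    object_mask: np.ndarray  # H x W bool

    def __post_init__(self):
        if np.any(self.pixels < 0):
            raise ValueError("LMS pixels must be nonnegative")


class _Geometry:
    """Region codes for one image size.

    Codes: 0 back wall, 1 ceiling, 2 floor, 3 left wall, 4 right wall,
    10 + i for cue patch i.
    """

    def __init__(self, image_size):
        H, W = image_size
        code = np.zeros((H, W), dtype=np.int16)
        r_ceil = max(2, int(0.15 * H))
        r_floor = int(0.55 * H)
        code[:r_ceil, :] = 1
        code[r_floor:, :] = 2
        wside = max(2, int(0.10 * W))
        code[r_ceil:, :wside] = 3
        code[r_ceil:, W - wside :] = 4
        p_top = int(0.20 * H)
        p_h = max(2, int(0.12 * H))
        p_w = max(2, int(0.08 * W))
        usable = W - 2 * wside - 2
        centers = wside + 1 + (np.arange(6) + 0.5) / 6.0 * usable
        self.patch_boxes = []
        for i, c in enumerate(centers):
            c0 = int(round(c - p_w / 2))
            box = (p_top, p_top + p_h, c0, c0 + p_w)
            code[box[0] : box[1], box[2] : box[3]] = 10 + i
            self.patch_boxes.append(box)
        self.code = code
        self.patch_bottom = p_top + p_h
        # smooth, illumination-independent shading per background pixel
        rr = np.linspace(0.0, 1.0, H)[:, None] * np.ones((1, W))
        shade = 0.85 + 0.15 * rr
        shade[:r_ceil, :] = 1.0
        self.shading = shade.astype(np.float32)
        # admissible object-center band (fractions): below the patches,
        # object bounding box inside the border
        # bounding margin: max blob radius (1.25 x nominal) plus one pixel
        margin = 0.20 * 1.25 + 1.5 / H
        self.center_rows = ((self.patch_bottom / H) + margin, 1.0 - margin)
        self.center_cols = (margin, 1.0 - margin)


_GEOMS: dict[tuple[int, int], _Geometry] = {}


def get_geometry(image_size) -> _Geometry:
    key = tuple(image_size)
    if key not in _GEOMS:
        _GEOMS[key] = _Geometry(key)
    return _GEOMS[key]


def object_blob(
    shape_seed: int,
    center: tuple[float, float],
    image_size,
    radius_frac: float,
):
    """Procedural blob mask and pseudo-3D shading field."""
    H, W = image_size
    rng = np.random.default_rng(shape_seed)
    k = np.arange(2, 5)
    amps = rng.uniform(0.1, 1.0, size=3)
    amps *= 0.25 / amps.sum()  # radial modulation bounded by 25%
    phases = rng.uniform(0, 2 * np.pi, size=3)
    light_phase = rng.uniform(0, 2 * np.pi)
    cy, cx = center[0] * H, center[1] * W
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    radius = radius_frac * H * (
        1.0 + sum(a * np.cos(kk * theta + p) for a, kk, p in zip(amps, k, phases))
    )
    dist = np.hypot(dy, dx)
    mask = dist <= radius
    rel = np.clip(dist / np.maximum(radius, 1e-9), 0.0, 1.0)
    shade = 0.45 + 0.55 * np.sqrt(np.clip(1.0 - rel**2, 0.0, 1.0))
    shade *= 1.0 + 0.12 * np.cos(theta - light_phase)
    return mask, np.clip(shade, 0.3, 1.1).astype(np.float32)


class _LMSCache:
    """project(E * R) for (illuminant, class) pairs, computed once."""

    def __init__(self, catalog: ClassCatalog, illums: IlluminantSet):
        self.catalog = catalog
        self.illums = illums
        self.ctx = catalog.ctx
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    def lms(self, illum_id: str, class_id: int) -> np.ndarray:
        key = (illum_id, class_id)
        if key not in self._cache:
            e = self.illums.get(illum_id)
            r = self.catalog.reflectance(class_id)
            self._cache[key] = project(e * r, self.ctx.lms_sensors).values
        return self._cache[key]


def render_scene(
    spec: SceneSpec,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    scene_cfg: SceneConfig,
    _cache: _LMSCache | None = None,
) -> LMSImage:
    """Render one trial to cone excitations.

    Conditions: ``no_patch`` replaces the cue patches by the back-wall
    surface; ``wrong_patch`` renders the patches under D65 instead of the
    trial illuminant; ``wrong_background`` renders everything outside the
    object mask under D65; ``mask_patch_i`` replaces patch i only.
    """
    cache = _cache or _LMSCache(catalog, illums)
    geom = get_geometry(scene_cfg.image_size)
    H, W = scene_cfg.image_size
    cond = spec.condition

    back, ceil, floor, left, right = scene_cfg.room_class_ids
    region_class = {0: back, 1: ceil, 2: floor, 3: left, 4: right}
    for i, pc in enumerate(scene_cfg.patch_class_ids):
        region_class[10 + i] = pc
    if cond == "no_patch":
        for i in range(6):
            region_class[10 + i] = back
    if cond.startswith("mask_patch_"):
        region_class[10 + int(cond.split("_")[-1])] = back

    bg_illum = {c: spec.illum_id for c in region_class}
    if cond == "wrong_patch":
        for i in range(6):
            bg_illum[10 + i] = D65_ID
    if cond == "wrong_background":
        bg_illum = {c: D65_ID for c in region_class}

    pixels = np.empty((H, W, 3), dtype=np.float32)
    for c, cls in region_class.items():
        sel = geom.code == c
        if not sel.any():
            continue
        pixels[sel] = cache.lms(bg_illum[c], cls)
    pixels *= geom.shading[:, :, None]

    mask, shade = object_blob(
        spec.object_shape_seed,
        spec.object_center,
        scene_cfg.image_size,
        scene_cfg.object_radius_frac,
    )
    obj_lms = cache.lms(spec.illum_id, spec.object_class_id)
    pixels[mask] = obj_lms * shade[mask, None]
    return LMSImage(pixels, mask)


# ---------------------------------------------------------------------------
# manifests and datasets


def build_dataset_manifest(
    catalog: ClassCatalog,
    illums: IlluminantSet,
    images_per_cell: int = 1,
    condition: str = "normal",
    seed: int = 0,
    image_size: tuple[int, int] = (32, 32),
    class_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Full factorial (class x illuminant x replicate) trial manifest."""
    if images_per_cell < 1:
        raise ValueError("images_per_cell must be >= 1")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    geom = get_geometry(image_size)
    class_ids = list(catalog.class_ids) if class_ids is None else list(class_ids)
    rng = np.random.default_rng(seed)
    n = len(class_ids) * len(illums) * images_per_cell
    rows = {
        "object_class_id": np.repeat(class_ids, len(illums) * images_per_cell),
        "illum_id": np.tile(
            np.repeat(illums.ids, images_per_cell), len(class_ids)
        ),
        "replicate": np.tile(np.arange(images_per_cell), len(class_ids) * len(illums)),
        "object_shape_seed": rng.integers(0, 2**31, size=n),
        "center_row": rng.uniform(*geom.center_rows, size=n),
        "center_col": rng.uniform(*geom.center_cols, size=n),
    }
    df = pd.DataFrame(rows)
    df["condition"] = condition
    return df


def spec_from_row(row, condition: str | None = None) -> SceneSpec:
    return SceneSpec(
        illum_id=row["illum_id"],
        object_class_id=int(row["object_class_id"]),
        object_shape_seed=int(row["object_shape_seed"]),
        object_center=(float(row["center_row"]), float(row["center_col"])),
        condition=condition or row["condition"],
    )


def render_manifest(
    manifest: pd.DataFrame,
    catalog: ClassCatalog,
    illums: IlluminantSet,
    scene_cfg: SceneConfig,
    condition: str | None = None,
):
    """Render all trials of a manifest into dense arrays."""
    H, W = scene_cfg.image_size
    n = len(manifest)
    X = np.empty((n, H, W, 3), dtype=np.float32)
    masks = np.empty((n, H, W), dtype=bool)
    cache = _LMSCache(catalog, illums)
    for k, (_, row) in enumerate(manifest.iterrows()):
        img = render_scene(
            spec_from_row(row, condition), catalog, illums, scene_cfg, cache
        )
        X[k] = img.pixels
        masks[k] = img.object_mask
    return X, masks


def write_dataset(path, images, masks, manifest: pd.DataFrame, config: dict | None = None):
    """HDF5 container for pixels/masks plus CSV+JSON sidecars."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("pixels", data=images)
        fh.create_dataset("object_mask", data=masks)
    manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)
    if config is not None:
        path.with_suffix(".config.json").write_text(json.dumps(config, indent=1))
    return path


def read_dataset(path):
    import h5py

    path = Path(path)
    try:
        with h5py.File(path, "r") as fh:
            images = fh["pixels"][...]
            masks = fh["object_mask"][...]
    except OSError as exc:
        raise OSError(f"cannot read dataset container {path}: {exc}") from exc
    manifest = pd.read_csv(path.with_suffix(".manifest.csv"))
    return images, masks, manifest
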