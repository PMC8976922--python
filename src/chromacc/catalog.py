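"""Munsell-style reflectance catalog: the label space of the classifier.

The catalog is a gamut-limited cylindrical grid of smooth reflectance
spectra: hue maps to angle in the CIELab (a*, b*) plane, chroma to radius,
value to L*.  The grid is calibrated so that the median CIELab distance
between adjacent classes matches a perceptual spacing target (default
7.3 dE, the spacing of the measured Munsell set), with every adjacent pair
above the ~2.3 dE just-noticeable difference.

Reflectances are parameterized as a logistic squash of three smooth basis
functions, which keeps them in (0, 1) at every band; a class whose Lab
target cannot be reached by such a spectrum is dropped (the "limited
gamut" of a physical chip set).  Measured chip spectra can be loaded from
per-chip CSV files instead.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .colorimetry import (
    ColorContext,
    Spectrum,
    Triplet,
    delta_e,
)

#: Munsell chroma units per grid step (the measured set samples even chromas).
CHROMA_STEP_UNITS = 2


@dataclass(frozen=True)
class MunsellCoord:
    """Hue/Value/Chroma coordinate. ``hue_index`` 0 marks a neutral chip."""

    hue_index: int
    value_step: float
    chroma_step: int

    def __post_init__(self):
        if self.chroma_step < 0 or self.chroma_step % CHROMA_STEP_UNITS:
            raise ValueError("chroma_step must be a nonnegative even integer")
        if (self.hue_index == 0) != (self.chroma_step == 0):
            raise ValueError("hue_index 0 is reserved for neutral (chroma 0) chips")


@dataclass(frozen=True)
class CatalogEntry:
    class_id: int
    coord: MunsellCoord
    reflectance: Spectrum
    reference_lab: Triplet


@dataclass
class ClassCatalog:
    """Bijection class id <-> coordinate <-> reflectance <-> D65 Lab."""

    entries: list[CatalogEntry]
    ctx: ColorContext
    n_hues: int
    value_steps: tuple[float, ...]
    eval_subset: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {e.class_id: e for e in self.entries}
        self._by_coord = {e.coord: e.class_id for e in self.entries}
        if len(self._by_id) != len(self.entries) or len(self._by_coord) != len(
            self.entries
        ):
            raise ValueError("class ids and coordinates must be bijective")

    def __len__(self):
        return len(self.entries)

    @property
    def class_ids(self) -> list[int]:
        return [e.class_id for e in self.entries]

    def entry(self, class_id: int) -> CatalogEntry:
        return self._by_id[class_id]

    def reflectance(self, class_id: int) -> Spectrum:
        return self._by_id[class_id].reflectance

    def reference_lab(self, class_id: int) -> Triplet:
        return self._by_id[class_id].reference_lab

    def coord(self, class_id: int) -> MunsellCoord:
        return self._by_id[class_id].coord

    def id_of(self, coord: MunsellCoord) -> int | None:
        return self._by_coord.get(coord)

    def labels(self) -> np.ndarray:
        """Dense 0..n-1 label for each class id (training target space)."""
        return np.arange(len(self.entries))

    def label_of(self, class_id: int) -> int:
        return self.class_ids.index(class_id)


# ---------------------------------------------------------------------------
# smooth reflectance model


def _basis(grid: np.ndarray) -> np.ndarray:
    """Three smooth basis functions: offset + two broad spectral bumps."""
    g1 = np.exp(-0.5 * ((grid - 610.0) / 80.0) ** 2)
    g2 = np.exp(-0.5 * ((grid - 460.0) / 60.0) ** 2)
    return np.stack([np.ones_like(grid), g1, g2])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class _LabSolver:
    """Fast D65 Lab evaluation for candidate reflectance vectors."""

    def __init__(self, ctx: ColorContext):
        g = ctx.grid
        w = np.gradient(g)
        w[0] = (g[1] - g[0]) / 2
        w[-1] = (g[-1] - g[-2]) / 2
        # trapezoid quadrature weights on a uniform grid
        self.A = ctx.xyz_sensors.matrix() * (ctx.d65.power * w)
        self.ctx = ctx
        self.B = _basis(g)

    def lab_of_r(self, r: np.ndarray) -> np.ndarray:
        from .colorimetry import WhitePoint, _lab_f  # noqa: F401

        xyz = self.A @ r
        from .colorimetry import _lab_f as f

        fx, fy, fz = f(xyz / self.ctx.white.xyz.values)
        return np.array(
            [116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)]
        )

    def solve(self, target_lab: np.ndarray, x0: np.ndarray):
        res = least_squares(
            lambda w: self.lab_of_r(_sigmoid(self.B.T @ w)) - target_lab,
            x0,
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
        )
        return res.x, float(np.linalg.norm(res.fun))


# ---------------------------------------------------------------------------
# synthetic catalog


def build_synthetic_catalog(
    n_hues: int = 10,
    n_values: int = 4,
    n_chromas: int = 4,
    spacing_target: float = 7.3,
    seed: int = 0,
    ctx: ColorContext | None = None,
    value_span: tuple[float, float] = (3.5, 8.0),
    chroma_unit: float = 8.0,
    value_unit: float = 10.0,
    fit_tol: float = 0.5,
    max_clip_fraction: float = 0.3,
) -> ClassCatalog:
    """Build the calibrated synthetic chip grid.

    ``value_span`` gives the Munsell value range of the grid rows;
    ``chroma_unit`` and ``value_unit`` are the pre-calibration Lab radii per
    chroma grid step and L* per Munsell value.  A global scale factor on
    the chromatic radius and the L* spread is then iterated so the realized
    median adjacent-pair distance hits ``spacing_target`` within 2%.
    """
    if n_hues < 2 or n_values < 2 or n_chromas < 2:
        raise ValueError("grid sizes must be >= 2")
    if spacing_target <= 0:
        raise ValueError("spacing_target must be > 0")
    ctx = ColorContext.default() if ctx is None else ctx
    values = tuple(np.linspace(value_span[0], value_span[1], n_values))

    # analytic initial scale from the target-grid adjacency geometry
    s = spacing_target / _median_target_spacing(
        n_hues, values, n_chromas, chroma_unit, value_unit
    )
    catalog = None
    for _ in range(4):
        catalog = _build_at_scale(
            n_hues, values, n_chromas, s, ctx, chroma_unit, value_unit,
            fit_tol, seed,
        )
        clipped = catalog.meta["n_clipped"]
        if clipped > max_clip_fraction * (n_hues * n_values * n_chromas):
            raise ValueError(
                "spacing target infeasible: too many reflectances leave [0, 1];"
                " try a smaller grid or spacing_target"
            )
        med = median_adjacent_delta_e(catalog)
        if abs(med - spacing_target) <= 0.02 * spacing_target:
            break
        s *= spacing_target / med
    catalog.meta.update(
        spacing_target=spacing_target,
        realized_median_spacing=median_adjacent_delta_e(catalog),
        scale=s,
        seed=seed,
        adjacency_convention="single-coordinate grid steps; hue circular; "
        "neutral chips adjacent only along the value column",
    )
    catalog.eval_subset = select_eval_subset(catalog)
    return catalog


def _median_target_spacing(n_hues, values, n_chromas, chroma_unit, value_unit):
    d = []
    dl = (values[1] - values[0]) * value_unit
    for c in range(1, n_chromas + 1):
        arc = 2 * c * chroma_unit * np.sin(np.pi / n_hues)
        d += [arc] * n_hues * len(values)
    d += [chroma_unit] * (n_hues * len(values) * (n_chromas - 1))
    d += [dl] * (n_hues * n_chromas * (len(values) - 1) + (len(values) - 1))
    return float(np.median(d))


def _build_at_scale(
    n_hues, values, n_chromas, s, ctx, chroma_unit, value_unit, fit_tol, seed
):
    solver = _LabSolver(ctx)
    l_center = float(np.mean(values)) * value_unit
    entries = []
    n_clipped = 0
    class_id = 0

    def l_target(v):
        return l_center + s * (v * value_unit - l_center)

    # neutral column first: flat spectra solved analytically in level
    from .colorimetry import _lab_finv

    wp_y = ctx.white.xyz.values[1]
    flat_white = ctx.white_reflectance.power
    for v in values:
        L = l_target(v)
        # Y/Yn from L*, flat chip scales the white chip's spectrum
        y_ratio = float(_lab_finv(np.array([(L + 16.0) / 116.0]))[0])
        refl = Spectrum(ctx.grid, flat_white * y_ratio)
        lab = ctx.lab_of_reflectance(refl)
        entries.append(
            CatalogEntry(class_id, MunsellCoord(0, float(v), 0), refl, lab)
        )
        class_id += 1

    for hi in range(1, n_hues + 1):
        theta = 2 * np.pi * (hi - 1) / n_hues
        for v in values:
            x0 = np.array([-0.5, 0.0, 0.0])
            for c in range(1, n_chromas + 1):
                radius = s * chroma_unit * c
                target = np.array(
                    [l_target(v), radius * np.cos(theta), radius * np.sin(theta)]
                )
                w, resid = solver.solve(target, x0)
                if resid > fit_tol:
                    n_clipped += 1
                    continue
                x0 = w
                refl = Spectrum(ctx.grid, _sigmoid(solver.B.T @ w))
                lab = ctx.lab_of_reflectance(refl)
                entries.append(
                    CatalogEntry(
                        class_id,
                        MunsellCoord(hi, float(v), c * CHROMA_STEP_UNITS),
                        refl,
                        lab,
                    )
                )
                class_id += 1

    return ClassCatalog(
        entries,
        ctx,
        n_hues,
        tuple(values),
        meta={"n_clipped": n_clipped},
    )


# ---------------------------------------------------------------------------
# adjacency and spacing


def adjacent_pairs(catalog: ClassCatalog) -> list[tuple[int, int]]:
    """Unordered pairs one grid step apart in exactly one coordinate.

    Hue wraps circularly; neutral chips (chroma 0) form their own value
    column and are not counted as chroma neighbors of chromatic chips.
    """
    if not len(catalog):
        raise ValueError("catalog is empty")
    values = sorted(set(e.coord.value_step for e in catalog.entries))
    vstep = {v: i for i, v in enumerate(values)}
    pairs = set()
    for e in catalog.entries:
        h, v, c = e.coord.hue_index, e.coord.value_step, e.coord.chroma_step
        vi = vstep[v]
        cand = []
        if h > 0:
            for dh in (-1, 1):
                hh = (h - 1 + dh) % catalog.n_hues + 1
                cand.append(MunsellCoord(hh, v, c))
            for dc in (-CHROMA_STEP_UNITS, CHROMA_STEP_UNITS):
                if c + dc >= CHROMA_STEP_UNITS:
                    cand.append(MunsellCoord(h, v, c + dc))
        if vi + 1 < len(values):
            cand.append(MunsellCoord(h, values[vi + 1], c))
        if vi > 0:
            cand.append(MunsellCoord(h, values[vi - 1], c))
        for cc in cand:
            j = catalog.id_of(cc)
            if j is not None and j != e.class_id:
                pairs.add(tuple(sorted((e.class_id, j))))
    return sorted(pairs)


def median_adjacent_delta_e(catalog: ClassCatalog) -> float:
    d = [
        delta_e(catalog.reference_lab(i), catalog.reference_lab(j))
        for i, j in adjacent_pairs(catalog)
    ]
    return float(np.median(d))


def select_eval_subset(catalog: ClassCatalog, n: int | None = None) -> list[int]:
    """Deterministic WCS-like sheet: most saturated chip per (hue, value)
    cell plus the neutral column; optionally truncated/extended to ``n``."""
    if n is not None and n > len(catalog):
        raise ValueError(f"n={n} exceeds catalog size {len(catalog)}")
    best: dict[tuple[int, float], CatalogEntry] = {}
    neutrals = []
    for e in catalog.entries:
        if e.coord.hue_index == 0:
            neutrals.append(e)
            continue
        key = (e.coord.hue_index, e.coord.value_step)
        if key not in best or e.coord.chroma_step > best[key].coord.chroma_step:
            best[key] = e
    sheet = sorted(
        [e.class_id for e in best.values()] + [e.class_id for e in neutrals]
    )
    if n is None or n == len(sheet):
        return sheet
    if n < len(sheet):
        return sheet[:n]
    rest = sorted(
        (e for e in catalog.entries if e.class_id not in set(sheet)),
        key=lambda e: (-e.coord.chroma_step, e.class_id),
    )
    return sorted(sheet + [e.class_id for e in rest[: n - len(sheet)]])


# ---------------------------------------------------------------------------
# persistence


def save_catalog(catalog: ClassCatalog, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_hues": catalog.n_hues,
        "value_steps": list(catalog.value_steps),
        "eval_subset": catalog.eval_subset,
        "meta": {k: v for k, v in catalog.meta.items()},
        "classes": [
            {
                "class_id": e.class_id,
                "hue": e.coord.hue_index,
                "value": e.coord.value_step,
                "chroma": e.coord.chroma_step,
                "reference_lab": [float(x) for x in e.reference_lab.values],
            }
            for e in catalog.entries
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    grid = catalog.ctx.grid
    with open(out / "spectra.csv", "w") as fh:
        fh.write("class_id," + ",".join(f"{w:.2f}" for w in grid) + "\n")
        for e in catalog.entries:
            fh.write(
                f"{e.class_id},"
                + ",".join(f"{p:.8g}" for p in e.reflectance.power)
                + "\n"
            )
    return out


_CHIP_NAME = re.compile(r"h(\d+)_v([\d.]+)_c(\d+)\.csv$")


def load_catalog(spectra_dir, ctx: ColorContext | None = None) -> ClassCatalog:
    """Load measured chip spectra from per-chip CSVs.

    Filenames must encode the coordinate as ``h<hue>_v<value>_c<chroma>.csv``
    (hue 0 and chroma 0 for neutrals).  Reference Lab values are computed
    under D65 at load time.
    """
    ctx = ColorContext.default() if ctx is None else ctx
    from .colorimetry import read_spectrum_csv

    files = sorted(Path(spectra_dir).glob("*.csv"))
    if not files:
        raise ValueError(f"no chip spectra found in {spectra_dir}")
    errors = []
    entries = []
    hues = set()
    values = set()
    for class_id, f in enumerate(files):
        m = _CHIP_NAME.search(f.name)
        if not m:
            errors.append(f"{f.name}: unparseable filename")
            continue
        try:
            refl = read_spectrum_csv(f, ctx.grid)
            if not refl.is_reflectance(tol=1e-3):
                raise ValueError("values exceed 1: not a reflectance")
            coord = MunsellCoord(int(m[1]), float(m[2]), int(m[3]))
            entries.append(
                CatalogEntry(class_id, coord, refl, ctx.lab_of_reflectance(refl))
            )
            if coord.hue_index > 0:
                hues.add(coord.hue_index)
            values.add(coord.value_step)
        except ValueError as exc:
            errors.append(f"{f.name}: {exc}")
    if errors:
        raise ValueError("catalog load failed:\n" + "\n".join(errors))
    cat = ClassCatalog(
        entries,
        ctx,
        n_hues=max(hues) if hues else 1,
        value_steps=tuple(sorted(values)),
        meta={"source": str(spectra_dir), "n_clipped": 0},
    )
    cat.eval_subset = select_eval_subset(cat)
    return cat
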