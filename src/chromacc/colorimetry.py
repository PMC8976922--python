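"""Spectral and colorimetric primitives.

Everything downstream (reflectance catalogs, scene rendering, metrics) is
built on four small pieces: sampled spectra on a common wavelength grid,
projection of spectra onto sensor curves (cone fundamentals or CIE 1931
color-matching functions), CIE daylight synthesis from the S0/S1/S2
principal components, and CIELab conversion against a scene-defined white
point.

Conventions
-----------
* The working grid has 20 equally spaced samples spanning 380-830 nm; all
  bundled sensor tables are resampled onto the requested grid at load time.
* Integrals use trapezoidal quadrature on the grid.
* LMS cone curves are defined as the Hunt-Pointer-Estevez linear transform
  of the bundled 1931 2-deg color-matching functions (small negative side
  lobes of the transform are clipped at zero).  This keeps LMS and XYZ
  colorimetry consistent through an exact 3x3 matrix.
* The CIELab gray point is the white point's chromaticity, i.e. a*=b*=0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

WL_MIN = 380.0
WL_MAX = 830.0
N_BANDS = 20

#: Hunt-Pointer-Estevez XYZ -> LMS matrix (equal-energy normalized).
M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.0, 0.0, 1.0],
    ]
)
M_HPE_INV = np.linalg.inv(M_HPE)


def default_grid(n_bands: int = N_BANDS) -> np.ndarray:
    """The working wavelength grid: ``n_bands`` samples on 380-830 nm."""
    return np.linspace(WL_MIN, WL_MAX, n_bands)


# ---------------------------------------------------------------------------
# core containers


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral power (or reflectance) distribution.

    Parameters
    ----------
    wavelengths_nm:
        Strictly ascending sample wavelengths.
    power:
        Nonnegative sample values; relative energy for illuminants or a
        reflectance fraction in [0, 1] for surfaces.
    """

    wavelengths_nm: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if wl.ndim != 1 or p.shape != wl.shape:
            raise ValueError("wavelengths and power must be 1-D and matched")
        if len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(p < -1e-9):
            raise ValueError("spectral power must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "power", np.clip(p, 0.0, None))

    def is_reflectance(self, tol: float = 1e-6) -> bool:
        return bool(np.all(self.power <= 1.0 + tol))

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid`` (endpoint values extended)."""
        grid = np.asarray(grid, dtype=float)
        if np.array_equal(grid, self.wavelengths_nm):
            return self
        return Spectrum(grid, np.interp(grid, self.wavelengths_nm, self.power))

    def integral(self) -> float:
        return float(np.trapezoid(self.power, self.wavelengths_nm))

    def __mul__(self, other: "Spectrum") -> "Spectrum":
        if not isinstance(other, Spectrum):
            return NotImplemented
        other = other.resample(self.wavelengths_nm)
        return Spectrum(self.wavelengths_nm, self.power * other.power)

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.power * k)


@dataclass(frozen=True)
class Triplet:
    """Three sensor/color coordinates tagged with their space."""

    space: str  # one of {"LMS", "XYZ", "Lab"}
    values: np.ndarray

    def __post_init__(self):
        if self.space not in ("LMS", "XYZ", "Lab"):
            raise ValueError(f"unknown space {self.space!r}")
        v = np.asarray(self.values, dtype=float).reshape(3)
        if self.space in ("LMS", "XYZ") and np.any(v < -1e-9):
            raise ValueError(f"{self.space} values must be nonnegative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class WhitePoint:
    """Reference white as an XYZ triplet (all components > 0)."""

    xyz: Triplet

    def __post_init__(self):
        if self.xyz.space != "XYZ":
            raise ValueError("white point must be an XYZ triplet")
        if np.any(self.xyz.values <= 0):
            raise ValueError("white point components must be positive")


@dataclass(frozen=True)
class SensorSet:
    """Three sensor curves sharing one wavelength grid."""

    label: str  # "LMS" or "XYZ"
    curves: tuple[Spectrum, Spectrum, Spectrum]

    def __post_init__(self):
        if self.label not in ("LMS", "XYZ"):
            raise ValueError(f"unknown sensor label {self.label!r}")
        g = self.curves[0].wavelengths_nm
        for c in self.curves[1:]:
            if not np.array_equal(c.wavelengths_nm, g):
                raise ValueError("sensor curves must share one grid")

    @property
    def grid(self) -> np.ndarray:
        return self.curves[0].wavelengths_nm

    def matrix(self) -> np.ndarray:
        """Curves stacked as a 3 x N array."""
        return np.stack([c.power for c in self.curves])

    @staticmethod
    def xyz(grid: np.ndarray | None = None) -> "SensorSet":
        """CIE 1931 2-deg color-matching functions on ``grid``."""
        wl, cols = _load_table("cie_1931_cmf_2deg.csv", 3)
        grid = default_grid() if grid is None else np.asarray(grid, float)
        curves = tuple(
            Spectrum(wl, c).resample(grid) for c in cols
        )
        return SensorSet("XYZ", curves)

    @staticmethod
    def lms(grid: np.ndarray | None = None) -> "SensorSet":
        """Cone fundamentals via the HPE transform of the 1931 CMFs."""
        wl, cols = _load_table("cie_1931_cmf_2deg.csv", 3)
        lms = np.clip(M_HPE @ np.stack(cols), 0.0, None)
        grid = default_grid() if grid is None else np.asarray(grid, float)
        curves = tuple(Spectrum(wl, row).resample(grid) for row in lms)
        return SensorSet("LMS", curves)


def _load_table(name: str, n_cols: int):
    path = resources.files("chromacc.data").joinpath(name)
    with path.open() as fh:
        rows = list(csv.reader(fh))
    data = np.array(rows[1:], dtype=float)
    return data[:, 0], [data[:, i + 1] for i in range(n_cols)]


# ---------------------------------------------------------------------------
# spectra I/O (two-column CSV with a header line)


def read_spectrum_csv(path, grid: np.ndarray | None = None) -> Spectrum:
    with open(path) as fh:
        rows = list(csv.reader(fh))
    if not rows or any(_is_number(v) for v in rows[0]):
        raise ValueError(f"{path}: expected a header line then numeric rows")
    data = np.array(rows[1:], dtype=float)
    s = Spectrum(data[:, 0], data[:, 1])
    return s if grid is None else s.resample(grid)


def write_spectrum_csv(path, spectrum: Spectrum, value_name: str = "value"):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength_nm", value_name])
        for wl, p in zip(spectrum.wavelengths_nm, spectrum.power):
            w.writerow([f"{wl:.2f}", f"{p:.8g}"])


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# daylight synthesis

CCT_MIN, CCT_MAX = 4000.0, 25000.0


def daylight_chromaticity_xy(cct_kelvin: float) -> tuple[float, float]:
    """CIE daylight-locus chromaticity (x, y) for a correlated color temp."""
    t = float(cct_kelvin)
    if t <= 7000.0:
        x = (
            -4.6070e9 / t**3 + 2.9678e6 / t**2 + 0.09911e3 / t + 0.244063
        )
    else:
        x = (
            -2.0064e9 / t**3 + 1.9018e6 / t**2 + 0.24748e3 / t + 0.23704
        )
    y = -3.000 * x * x + 2.870 * x - 0.275
    return x, y


def daylight_basis(grid: np.ndarray | None = None):
    """The S0, S1, S2 daylight component spectra on ``grid``."""
    wl, cols = _load_table("cie_daylight_components.csv", 3)
    grid = default_grid() if grid is None else np.asarray(grid, float)
    # S1/S2 take small negative values; keep them (they are basis vectors,
    # not physical spectra) by bypassing the Spectrum nonnegativity check.
    out = []
    for c in cols:
        out.append(np.interp(grid, wl, c))
    return grid, out[0], out[1], out[2]


def daylight_weights_for_xy(x: float, y: float) -> tuple[float, float]:
    """M1, M2 weights of the CIE daylight reconstruction for (x, y)."""
    denom = 0.0241 + 0.2562 * x - 0.7341 * y
    m1 = (-1.3515 - 1.7703 * x + 5.9114 * y) / denom
    m2 = (0.0300 - 31.4424 * x + 30.0717 * y) / denom
    return m1, m2


def daylight_spectrum_from_weights(
    m1: float, m2: float, grid: np.ndarray | None = None
) -> Spectrum:
    """S0 + m1*S1 + m2*S2 on ``grid``, clipped at zero."""
    g, s0, s1, s2 = daylight_basis(grid)
    return Spectrum(g, np.clip(s0 + m1 * s1 + m2 * s2, 0.0, None))


def make_daylight_spectrum(
    cct_kelvin: float, grid: np.ndarray | None = None
) -> Spectrum:
    """CIE D-series illuminant spectrum for a correlated color temperature.

    Raises
    ------
    ValueError
        If ``cct_kelvin`` lies outside the defined 4000-25000 K interval.
    """
    if not CCT_MIN <= cct_kelvin <= CCT_MAX:
        raise ValueError(
            f"cct_kelvin={cct_kelvin} outside the valid interval "
            f"[{CCT_MIN:.0f}, {CCT_MAX:.0f}] K"
        )
    x, y = daylight_chromaticity_xy(cct_kelvin)
    m1, m2 = daylight_weights_for_xy(x, y)
    return daylight_spectrum_from_weights(m1, m2, grid)


# ---------------------------------------------------------------------------
# projection and CIELab


def project(spectrum: Spectrum, sensors: SensorSet) -> Triplet:
    """Integrate a spectrum against three sensor curves.

    The sensor curves are resampled onto the spectrum's grid; the result is
    linear in the spectrum.
    """
    lo = max(spectrum.wavelengths_nm[0], sensors.grid[0])
    hi = min(spectrum.wavelengths_nm[-1], sensors.grid[-1])
    if lo >= hi:
        raise ValueError("spectrum and sensors have disjoint wavelength support")
    g = spectrum.wavelengths_nm
    vals = [
        np.trapezoid(spectrum.power * c.resample(g).power, g)
        for c in sensors.curves
    ]
    return Triplet(sensors.label, np.array(vals))


_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(
        t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0
    )


def _lab_finv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > _DELTA, u**3, 3 * _DELTA**2 * (u - 4.0 / 29.0))


def xyz_to_lab(xyz: Triplet, white: WhitePoint) -> Triplet:
    """CIE 1976 L*a*b* with the standard cube-root transfer."""
    if xyz.space != "XYZ":
        raise ValueError("xyz_to_lab expects an XYZ triplet")
    fx, fy, fz = _lab_f(xyz.values / white.xyz.values)
    return Triplet(
        "Lab", np.array([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)])
    )


def lab_to_xyz(lab: Triplet, white: WhitePoint) -> Triplet:
    if lab.space != "Lab":
        raise ValueError("lab_to_xyz expects a Lab triplet")
    L, a, b = lab.values
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    return Triplet("XYZ", _lab_finv(np.array([fx, fy, fz])) * white.xyz.values)


def lms_to_xyz(lms: np.ndarray) -> np.ndarray:
    """Exact inverse of the HPE transform, applied along the last axis."""
    return np.asarray(lms, dtype=float) @ M_HPE_INV.T


def delta_e(a: Triplet, b: Triplet) -> float:
    """CIE 1976 color difference: Euclidean distance in L*a*b*."""
    if a.space != "Lab" or b.space != "Lab":
        raise ValueError("delta_e expects Lab triplets")
    return float(np.linalg.norm(a.values - b.values))


def chromatic_distance(a: Triplet, b: Triplet) -> float:
    """Euclidean distance in the (a*, b*) chromatic plane, ignoring L*."""
    if a.space != "Lab" or b.space != "Lab":
        raise ValueError("chromatic_distance expects Lab triplets")
    return float(np.linalg.norm(a.values[1:] - b.values[1:]))


def normalize(spectrum: Spectrum, mode: str, target: float) -> Spectrum:
    """Rescale a spectrum so its peak or its integral equals ``target``."""
    if mode == "peak":
        ref = float(np.max(spectrum.power))
    elif mode == "area":
        ref = spectrum.integral()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.scaled(target / ref)


def compute_white_point(
    max_value_reflectance: Spectrum, d65: Spectrum, sensors: SensorSet
) -> WhitePoint:
    """White point: XYZ of the brightest neutral chip lit by D65."""
    if sensors.label != "XYZ":
        raise ValueError("white point requires XYZ sensors")
    xyz = project(d65 * max_value_reflectance, sensors)
    if np.any(xyz.values <= 0):
        raise ValueError("product spectrum projects to a degenerate white")
    return WhitePoint(xyz)


# ---------------------------------------------------------------------------
# colorimetric context


@dataclass(frozen=True)
class ColorContext:
    """Grid, sensors, D65 and white point bundled for the whole pipeline."""

    grid: np.ndarray
    xyz_sensors: SensorSet
    lms_sensors: SensorSet
    d65: Spectrum
    white: WhitePoint
    white_reflectance: Spectrum

    @staticmethod
    def default(
        grid: np.ndarray | None = None,
        white_reflectance: Spectrum | None = None,
    ) -> "ColorContext":
        grid = default_grid() if grid is None else np.asarray(grid, float)
        xyz = SensorSet.xyz(grid)
        lms = SensorSet.lms(grid)
        d65 = normalize(make_daylight_spectrum(6504.0, grid), "peak", 100.0)
        if white_reflectance is None:
            white_reflectance = Spectrum(grid, np.full(len(grid), 0.9))
        white = compute_white_point(white_reflectance, d65, xyz)
        return ColorContext(grid, xyz, lms, d65, white, white_reflectance)

    def lab_of_reflectance(self, refl: Spectrum, illum: Spectrum | None = None) -> Triplet:
        """Lab of a surface under an illuminant (default D65)."""
        illum = self.d65 if illum is None else illum
        return xyz_to_lab(project(illum * refl, self.xyz_sensors), self.white)

    #: luminance factor at which illuminant chromaticities are measured:
    #: a mid-gray (18%) reference surface, i.e. the lightness regime of the
    #: chip set itself.  The cube-root Lab transfer compresses chromatic
    #: differences as luminance falls, so anchoring at the white's L*=100
    #: would understate the shifts an illuminant actually induces on chips.
    GRAY_ANCHOR = 0.18

    def illuminant_chromaticity(self, illum: Spectrum) -> Triplet:
        """Lab of an illuminant at the mid-gray anchored luminance.

        Scaling a spectrum changes a*/b* through the cube-root transfer, so
        illuminant chromaticities are always measured with Y pinned to
        ``GRAY_ANCHOR`` times the white point's Y; the result has constant
        L* and carries chromatic information in (a*, b*) only.  D65 itself
        maps to a* = b* = 0 (the gray point) at any anchor.
        """
        xyz = project(illum * self.white_reflectance, self.xyz_sensors)
        y = xyz.values[1]
        if y <= 0:
            raise ValueError("illuminant projects to zero luminance")
        scaled = Triplet(
            "XYZ", xyz.values * (self.GRAY_ANCHOR * self.white.xyz.values[1] / y)
        )
        return xyz_to_lab(scaled, self.white)

    def lab_of_lms(self, lms: np.ndarray) -> Triplet:
        """Lab of an LMS triplet via the exact HPE inverse."""
        return xyz_to_lab(Triplet("XYZ", np.clip(lms_to_xyz(lms), 0, None)), self.white)

    def chromaticity_of_lms(self, lms: np.ndarray) -> Triplet:
        """Lab of an LMS triplet at the anchored mid-gray luminance.

        Scale-invariant: only the chromatic composition of the input
        matters, so estimates of arbitrary magnitude are comparable.
        """
        xyz = np.clip(lms_to_xyz(lms), 0, None)
        if xyz[1] <= 0:
            raise ValueError("zero-luminance LMS value")
        xyz = xyz * (self.GRAY_ANCHOR * self.white.xyz.values[1] / xyz[1])
        return xyz_to_lab(Triplet("XYZ", xyz), self.white)
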