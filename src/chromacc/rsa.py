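"""Representational analysis: RDMs, classical MDS, Procrustes alignment.

For each layer of a trained classifier, class-mean activation vectors are
compared pairwise with the correlation distance to form a representational
dissimilarity matrix (RDM).  Classical (Torgerson) MDS of the RDM yields a
low-dimensional embedding whose first three dimensions are aligned to the
reference Munsell-style cylindrical coordinates (or CIELab coordinates) by
ordinary Procrustes analysis — rotation/reflection, translation and
isotropic scaling — and the percentage of explained variance quantifies
how closely the learned similarity structure mirrors perceptual color
space.  Random-weight instances of the same architecture serve as the
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .catalog import ClassCatalog, MunsellCoord
from .models import TAPS, ArchitectureSpec, ConvClassifier


@dataclass(frozen=True)
class RDM:
    distances: np.ndarray  # n x n correlation distances
    class_ids: tuple[int, ...]

    def __post_init__(self):
        d = self.distances
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("RDM must be symmetric with zero diagonal")
        if d.min() < -1e-9 or d.max() > 2 + 1e-9:
            raise ValueError("correlation distances must lie in [0, 2]")


@dataclass(frozen=True)
class MDSEmbedding:
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # positive spectrum, descending
    variance_fractions: np.ndarray  # over the positive spectrum


@dataclass(frozen=True)
class ProcrustesResult:
    rotation: np.ndarray  # orthogonal 3x3 (may include reflection)
    translation: np.ndarray
    scale: float
    explained_variance_pct: float


# ---------------------------------------------------------------------------


def class_mean_activations(
    instance,
    X: np.ndarray,
    labels: np.ndarray,
    tap_layer: str,
    batch_size: int = 256,
) -> np.ndarray:
    """Mean post-ReLU activation vector per class at a tap.

    ``labels`` are dense 0..n-1 class indices per image; every class must
    be represented.
    """
    model: ConvClassifier = instance.model
    scale = instance.input_scale
    feats = []
    for k in range(0, len(X), batch_size):
        xb = X[k : k + batch_size]
        if scale is not None:
            xb = xb / scale
        _, acts = model.forward(xb, train=False, taps=[tap_layer])
        feats.append(acts[tap_layer])
    feats = np.concatenate(feats)
    n_classes = int(labels.max()) + 1
    out = np.zeros((n_classes, feats.shape[1]))
    counts = np.bincount(labels, minlength=n_classes)
    if np.any(counts == 0):
        missing = np.where(counts == 0)[0]
        raise ValueError(f"classes with no images: {missing.tolist()}")
    np.add.at(out, labels, feats)
    return out / counts[:, None]


def compute_rdm(activations: np.ndarray, class_ids=None) -> RDM:
    """Pairwise correlation distance (1 - Pearson r) between class rows."""
    acts = np.asarray(activations, dtype=float)
    if acts.shape[0] < 2:
        raise ValueError("need at least two classes")
    sd = acts.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        raise ValueError(f"constant activation rows for classes {bad.tolist()}")
    d = squareform(pdist(acts, metric="correlation"))
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    ids = tuple(range(len(acts))) if class_ids is None else tuple(class_ids)
    return RDM(d, ids)


def classical_mds(rdm: RDM | np.ndarray, k: int = 3) -> MDSEmbedding:
    """Torgerson MDS: double-center -D^2/2, keep top-k positive eigenpairs."""
    d = rdm.distances if isinstance(rdm, RDM) else np.asarray(rdm, float)
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    w_pos = w[pos]
    k_eff = min(k, int(pos.sum()))
    if k_eff < k:
        import warnings

        warnings.warn(
            f"positive spectrum supports only {k_eff} of {k} requested dims"
        )
    coords = v[:, :k_eff] * np.sqrt(w[:k_eff])
    fractions = w_pos / w_pos.sum()
    return MDSEmbedding(coords, w_pos, fractions)


def munsell_to_cartesian(
    coord: MunsellCoord, n_hues: int, value_scale: float = 2.0
) -> np.ndarray:
    """Cylindrical embedding of a Munsell-style coordinate.

    Hue becomes angle (circular), chroma the radius, value the vertical
    axis scaled by ``value_scale`` (a recorded convention).
    """
    theta = 2 * np.pi * coord.hue_index / n_hues
    c = coord.chroma_step
    return np.array(
        [c * np.cos(theta), c * np.sin(theta), value_scale * coord.value_step]
    )


def procrustes_fit(source: np.ndarray, target: np.ndarray) -> ProcrustesResult:
    """Ordinary Procrustes: align source onto target by similarity transform.

    Allows rotation, reflection, translation and isotropic scaling; the
    explained variance is 100 * (1 - SS_res / SS_total) with SS_total the
    centered sum of squares of the target.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.shape[0] < 4:
        raise ValueError("need matched n x k configurations with n >= 4")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - mx, Y - my
    if np.linalg.matrix_rank(X0) < 2:
        raise ValueError("degenerate (rank < 2) source configuration")
    u, s, vt = np.linalg.svd(X0.T @ Y0)
    rot = u @ vt
    ssx = (X0**2).sum()
    scale = s.sum() / ssx
    resid = ((Y0 - scale * X0 @ rot) ** 2).sum()
    sst = (Y0**2).sum()
    ev = 100.0 * (1.0 - resid / sst)
    translation = my - scale * mx @ rot
    return ProcrustesResult(rot, translation, float(scale), float(ev))


# ---------------------------------------------------------------------------
# pipeline


def reference_coordinates(
    catalog: ClassCatalog, class_ids, reference: str = "munsell", value_scale: float = 2.0
) -> np.ndarray:
    if reference == "munsell":
        return np.stack(
            [
                munsell_to_cartesian(catalog.coord(c), catalog.n_hues, value_scale)
                for c in class_ids
            ]
        )
    if reference == "cielab":
        return np.stack([catalog.reference_lab(c).values for c in class_ids])
    raise ValueError(f"unknown reference {reference!r}")


def layer_explained_variance(
    instance,
    X: np.ndarray,
    labels: np.ndarray,
    tap: str,
    reference_coords: np.ndarray,
) -> float:
    acts = class_mean_activations(instance, X, labels, tap)
    emb = classical_mds(compute_rdm(acts), k=3)
    return procrustes_fit(emb.coordinates, reference_coords).explained_variance_pct


def rsa_pipeline(
    instances: list,
    X: np.ndarray,
    labels: np.ndarray,
    catalog: ClassCatalog,
    class_ids,
    taps=TAPS,
    reference: str = "munsell",
    random_instances: list | None = None,
) -> pd.DataFrame:
    """Explained variance per (instance, tap), trained vs random control.

    ``X``/``labels`` hold the activation-recording images: the evaluation
    classes under D65 plus the four test illuminants.
    """
    ref = reference_coordinates(catalog, class_ids, reference)
    rows = []
    for kind, insts in (("trained", instances), ("random", random_instances or [])):
        for i, inst in enumerate(insts):
            for tap in taps:
                rows.append(
                    {
                        "model": kind,
                        "instance": i,
                        "tap": tap,
                        "explained_variance_pct": layer_explained_variance(
                            inst, X, labels, tap, ref
                        ),
                    }
                )
    return pd.DataFrame(rows)


def input_space_control(
    catalog: ClassCatalog, class_ids, reference: str = "munsell"
) -> float:
    """Procrustes fit from raw chip LMS chromaticities to the reference.

    The degenerate, no-network case of the pipeline: how well the input
    space alone already aligns with perceptual coordinates.
    """
    from .colorimetry import project

    ctx = catalog.ctx
    lms = np.stack(
        [
            project(ctx.d65 * catalog.reflectance(c), ctx.lms_sensors).values
            for c in class_ids
        ]
    )
    ref = reference_coordinates(catalog, class_ids, reference)
    return procrustes_fit(lms, ref).explained_variance_pct


def export_mds_scatter(embedding: MDSEmbedding, labs: np.ndarray, path):
    """2-D scatter of the first MDS dimensions colored by approximate sRGB."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = _lab_to_srgb_approx(labs)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    dims = [(0, 1), (1, 2)] if embedding.coordinates.shape[1] > 2 else [(0, 1)]
    for ax, (i, j) in zip(axes, dims):
        ax.scatter(
            embedding.coordinates[:, i], embedding.coordinates[:, j], c=rgb, s=18
        )
        ax.set_xlabel(f"dim {i + 1}")
        ax.set_ylabel(f"dim {j + 1}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _lab_to_srgb_approx(labs: np.ndarray) -> np.ndarray:
    """Rough Lab -> sRGB for display only."""
    from .colorimetry import Triplet, WhitePoint, lab_to_xyz

    white = WhitePoint(Triplet("XYZ", np.array([0.9505, 1.0, 1.089])))
    m = np.array(
        [
            [3.2406, -1.5372, -0.4986],
            [-0.9689, 1.8758, 0.0415],
            [0.0557, -0.2040, 1.0570],
        ]
    )
    out = []
    for lab in labs:
        xyz = lab_to_xyz(Triplet("Lab", lab), white).values
        rgb = np.clip(m @ xyz, 0, None)
        rgb = np.where(rgb <= 0.0031308, 12.92 * rgb, 1.055 * rgb ** (1 / 2.4) - 0.055)
        out.append(np.clip(rgb, 0, 1))
    return np.array(out)
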