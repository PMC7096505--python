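"""Per-pixel histologic segmentation of FT-IR cubes.

Spectra are converted to a small vector of spectral metrics (peak heights,
band areas, peak locations and ratios thereof) and each pixel is assigned one
of six tissue classes — epithelium, fibroblast, myofibroblast, collagen,
blood, necrosis — by a Gaussian-Bayes classifier trained on labeled pixels.
A seventh background class is assigned up front to pixels whose amide-I
intensity falls below a floor, so whole-slide label rasters are total.

The classifier is a re-implementation choice, not a reproduction of any
previously published model: per-class multivariate Gaussians with ridge-
stabilized maximum-likelihood covariances and frequency priors.  It is
validated against synthetic ground truth only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .hyperio import HyperspectralCube, WavenumberAxis
from .synthcohort import TISSUE_CLASS_NAMES

logger = logging.getLogger(__name__)

#: Full label set of a class map: background first, then the tissue classes.
MAP_CLASS_NAMES = ["background"] + TISSUE_CLASS_NAMES


class TrainingError(ValueError):
    """Histology-classifier training failed."""


@dataclass(frozen=True)
class MetricDefinition:
    """One spectral metric.

    kind ``peak_height`` / ``band_area`` / ``peak_location`` use a band window
    (center ± half_width cm⁻¹); ``ratio`` references two previously defined
    metrics by name (acyclic by construction: references must point backwards
    in the definition list).
    """

    name: str
    kind: str                       # peak_height | band_area | peak_location | ratio
    center: float = 0.0
    half_width: float = 0.0
    numerator: str = ""
    denominator: str = ""

    def __post_init__(self):
        if self.kind not in ("peak_height", "band_area", "peak_location", "ratio"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "ratio" and not (self.numerator and self.denominator):
            raise ValueError("ratio metric needs numerator and denominator names")


def default_metric_definitions() -> list[MetricDefinition]:
    """Metric set spanning the bands used by the synthetic templates."""
    return [
        MetricDefinition("h1080", "peak_height", 1080.0, 20.0),
        MetricDefinition("h1236", "peak_height", 1236.0, 20.0),
        MetricDefinition("h1546", "peak_height", 1546.0, 20.0),
        MetricDefinition("h1656", "peak_height", 1656.0, 20.0),
        MetricDefinition("area1000_1140", "band_area", 1070.0, 70.0),
        MetricDefinition("area1500_1700", "band_area", 1600.0, 100.0),
        MetricDefinition("loc1200_1300", "peak_location", 1250.0, 50.0),
        MetricDefinition("r1080_1656", "ratio", numerator="h1080",
                         denominator="h1656"),
        MetricDefinition("r1236_1546", "ratio", numerator="h1236",
                         denominator="h1546"),
    ]


def compute_metrics(spectra: np.ndarray, axis: WavenumberAxis,
                    defs: list[MetricDefinition] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Metric matrix for 1-D or (N, B) spectra.

    Returns (metrics (N, M), flagged (N,)) where flagged marks pixels with a
    zero ratio denominator (the metric is set to +inf there).
    """
    if defs is None:
        defs = default_metric_definitions()
    Y = np.atleast_2d(np.asarray(spectra, dtype=float))
    v = axis.values
    cols: dict[str, np.ndarray] = {}
    flagged = np.zeros(Y.shape[0], dtype=bool)
    for d in defs:
        if d.kind == "ratio":
            if d.numerator not in cols or d.denominator not in cols:
                raise ValueError(
                    f"ratio '{d.name}' references undefined metrics "
                    f"({d.numerator}, {d.denominator})")
            den = cols[d.denominator]
            zero = den == 0
            with np.errstate(divide="ignore", invalid="ignore"):
                val = cols[d.numerator] / den
            val[zero] = np.inf
            flagged |= zero
            cols[d.name] = val
            continue
        mask = (v >= d.center - d.half_width) & (v <= d.center + d.half_width)
        if not mask.any():
            raise ValueError(f"metric '{d.name}' window outside the axis")
        seg = Y[:, mask]
        if d.kind == "peak_height":
            cols[d.name] = seg.max(axis=1)
        elif d.kind == "band_area":
            cols[d.name] = np.trapezoid(seg, v[mask], axis=1)
        else:  # peak_location
            cols[d.name] = v[mask][np.argmax(seg, axis=1)]
    M = np.column_stack([cols[d.name] for d in defs])
    return (M, flagged)


@dataclass
class HistologyModel:
    """Per-class Gaussians on metric space with frequency priors."""

    metric_defs: list[MetricDefinition]
    class_names: list[str]
    means: np.ndarray               # (C, M)
    covariances: np.ndarray         # (C, M, M)
    priors: np.ndarray              # (C,)
    _chol: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        if not self._chol:
            self._chol = [cho_factor(S) for S in self.covariances]

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        """(N, C) Gaussian log densities."""
        X = np.atleast_2d(X)
        out = np.empty((X.shape[0], len(self.class_names)))
        for c, (mu, chol) in enumerate(zip(self.means, self._chol)):
            diff = X - mu
            solved = cho_solve(chol, diff.T).T
            maha = np.einsum("ij,ij->i", diff, solved)
            logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
            out[:, c] = -0.5 * (maha + logdet + X.shape[1] * np.log(2 * np.pi))
        return out

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        logp = self.log_likelihoods(X) + np.log(self.priors)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def train_histology_classifier(metrics: np.ndarray, labels: np.ndarray,
                               metric_defs: list[MetricDefinition] | None = None,
                               ridge: float = 1e-6) -> HistologyModel:
    """Per-class Gaussian MLE with covariance ridge; priors = class frequencies.

    Requires ≥ 2 classes and, per class, at least (metric dim + 1) examples.
    The ridge adds ``ridge · mean-diagonal · I`` to each covariance; a class
    whose covariance is still not positive definite raises
    :class:`TrainingError` naming it.
    """
    if metric_defs is None:
        metric_defs = default_metric_definitions()
    X = np.atleast_2d(np.asarray(metrics, dtype=float))
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    if len(names) < 2:
        raise TrainingError("need at least two classes to train")
    M = X.shape[1]
    means, covs, priors = [], [], []
    for name in names:
        sub = X[labels == name]
        if sub.shape[0] < M + 1:
            raise TrainingError(
                f"class '{name}' has {sub.shape[0]} examples; needs ≥ {M + 1}")
        mu = sub.mean(axis=0)
        centered = sub - mu
        S = centered.T @ centered / sub.shape[0]
        S = S + ridge * (np.trace(S) / M if np.trace(S) > 0 else 1.0) * np.eye(M)
        try:
            cho_factor(S)
        except LinAlgError as exc:
            raise TrainingError(
                f"singular covariance for class '{name}' after ridge") from exc
        means.append(mu)
        covs.append(S)
        priors.append(sub.shape[0])
    priors = np.array(priors, dtype=float)
    return HistologyModel(metric_defs=metric_defs, class_names=list(names),
                          means=np.array(means), covariances=np.array(covs),
                          priors=priors / priors.sum())


@dataclass
class TissueClassMap:
    """Per-pixel histologic labels and posteriors (background included)."""

    labels: np.ndarray              # (H, W) int codes into class_names
    posteriors: np.ndarray          # (H, W, C) rows sum to 1
    class_names: list[str]

    def label_name(self, r: int, c: int) -> str:
        return self.class_names[self.labels[r, c]]

    def mask(self, class_name: str) -> np.ndarray:
        return self.labels == self.class_names.index(class_name)

    def counts(self) -> dict[str, int]:
        return {n: int((self.labels == i).sum())
                for i, n in enumerate(self.class_names)}


def classify_pixels(cube: HyperspectralCube, model: HistologyModel,
                    background_mask: np.ndarray | None = None
                    ) -> TissueClassMap:
    """Label every pixel of a (preprocessed) cube.

    ``background_mask`` marks pixels decided as background before
    classification (amide-I floor, applied during preprocessing and carried in
    the cube's inverted valid mask by default).  Pixels whose metric
    extraction fails (non-finite metrics) are labeled background and counted
    in the log.
    """
    H, W, B = cube.shape
    if background_mask is None:
        background_mask = ~cube.valid_mask
    class_names = ["background"] + model.class_names
    n_classes = len(class_names)

    flat = cube.flat_spectra()
    bg = background_mask.reshape(-1).copy()
    X, flagged = compute_metrics(flat, cube.axis, model.metric_defs)
    bad = flagged | ~np.all(np.isfinite(X), axis=1)
    n_failed = int((bad & ~bg).sum())
    if n_failed:
        logger.info("classify_pixels: %d pixels with failed metric extraction "
                    "labeled background", n_failed)
    bg |= bad

    post = np.zeros((H * W, n_classes))
    post[bg, 0] = 1.0
    if (~bg).any():
        post[~bg, 1:] = model.posteriors(X[~bg])
    labels = np.argmax(post, axis=1)
    return TissueClassMap(labels=labels.reshape(H, W),
                          posteriors=post.reshape(H, W, n_classes),
                          class_names=class_names)


def extract_class_spectra(cube: HyperspectralCube, class_map: TissueClassMap,
                          class_name: str
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Spectra (K, B) and (row, col) coordinates (K, 2) of one class's pixels.

    An absent class yields empty arrays with a warning, not an error.
    """
    mask = class_map.mask(class_name)
    coords = np.argwhere(mask)
    if coords.size == 0:
        logger.warning("extract_class_spectra: class '%s' absent from map",
                       class_name)
        return np.empty((0, cube.shape[2])), coords
    spectra = cube.data[coords[:, 0], coords[:, 1], :]
    return spectra, coords
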