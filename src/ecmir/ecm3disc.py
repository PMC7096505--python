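"""ECM3 spectral discriminant.

Pipeline: per-patient mean collagen spectra on the 872–1320 cm⁻¹ window →
PCA (first 20 components, centering only) → two-class linear discriminant with
a shrunk pooled covariance and coefficient thresholding, tuned by stratified
5-fold cross-validation over a (gamma, delta) grid, evaluated by an ROC on the
out-of-fold posteriors.

Model definition.  With pooled within-class covariance S, shrinkage weight
gamma ∈ [0, 1] and threshold delta ≥ 0:

    S_gamma = (1 − gamma) · S + gamma · diag(S)
    w       = S_gamma⁻¹ (μ₊ − μ₋),   entries with |w_j| ≤ delta zeroed
    b       = −wᵀ(μ₊ + μ₋)/2 + log(π₊/π₋)
    P(+|x)  = sigmoid(wᵀx + b)

Shrink-to-diagonal is the package's reading of a generic "regularization
parameter"; shrink-to-spherical is available via ``shrink_target``.  The
threshold delta acts on the coefficients in the fitting space (PC space).
PCA is refit inside every CV training fold by default to avoid leakage; a
``pca_before_cv`` flag instead fits PCA once on all rows before splitting, so the
leakier but simpler ordering is also reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError, svd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "ECM3"

#: Hyperparameter grids: gamma 10^-4..10^0 (9 log steps), delta {0} ∪ 10^-6..10^-1.
DEFAULT_GAMMA_GRID = tuple(np.logspace(-4, 0, 9))
DEFAULT_DELTA_GRID = (0.0,) + tuple(np.logspace(-6, -1, 11))


class FitError(ValueError):
    """Discriminant fitting failed (e.g. singular covariance at gamma=0)."""


# --------------------------------------------------------------------------
# Training matrix and PCA
# --------------------------------------------------------------------------

def build_training_matrix(patient_spectra: dict[str, np.ndarray],
                          patient_labels: dict[str, str]
                          ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-patient mean collagen spectra as rows.

    ``patient_spectra`` maps patient id → (K_i, B) cleaned, preprocessed
    collagen-pixel spectra restricted to the training window.  Patients with
    zero surviving pixels are excluded with a logged warning.  Returns
    (matrix, labels, kept patient ids).
    """
    rows, labels, ids = [], [], []
    for pid, spectra in patient_spectra.items():
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if spectra.shape[0] == 0:
            logger.warning("build_training_matrix: patient %s has no surviving "
                           "collagen pixels; excluded", pid)
            continue
        rows.append(spectra.mean(axis=0))
        labels.append(patient_labels[pid])
        ids.append(pid)
    if not rows:
        raise ValueError("no patients with collagen pixels")
    return np.vstack(rows), np.array(labels), ids


@dataclass
class PCAModel:
    """Centering-only PCA with a deterministic sign convention."""

    center: np.ndarray              # (B,)
    loadings: np.ndarray            # (B, K) orthonormal columns
    explained_variances: np.ndarray  # (K,) non-increasing

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.center) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.loadings.T + self.center


def fit_pca(matrix: np.ndarray, n_components: int = 20) -> PCAModel:
    """SVD of the row-centered matrix; no variance scaling.

    Components are ordered by non-increasing variance; each loading column is
    signed so its largest-magnitude entry is positive.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, B = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for PCA")
    max_k = min(n - 1, B)
    if n_components > max_k:
        raise ValueError(
            f"n_components={n_components} too large; maximum is {max_k} "
            f"for a {n}×{B} matrix")
    center = X.mean(axis=0)
    U, s, Vt = svd(X - center, full_matrices=False)
    loadings = Vt[:n_components].T.copy()
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var = (s[:n_components] ** 2) / (n - 1)
    return PCAModel(center=center, loadings=loadings, explained_variances=var)


# --------------------------------------------------------------------------
# Regularized, thresholded linear discriminant
# --------------------------------------------------------------------------

@dataclass
class RldaModel:
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    pooled_cov: np.ndarray
    gamma: float
    delta: float
    priors: tuple[float, float]     # (π₊, π₋)
    w: np.ndarray                   # thresholded linear weights
    b: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.b

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(positive class | x) under the shared-covariance Gaussian model."""
        return expit(self.decision_values(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.posterior(X) >= 0.5


def fit_rlda(scores: np.ndarray, labels: np.ndarray, gamma: float,
             delta: float, positive: str = POSITIVE_LABEL,
             shrink_target: str = "diagonal") -> RldaModel:
    """Fit the shrunk, coefficient-thresholded two-class linear discriminant."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos < 2 or n_neg < 2:
        raise FitError("each class needs at least 2 rows")
    mu_pos = X[pos].mean(axis=0)
    mu_neg = X[~pos].mean(axis=0)
    centered = np.where(pos[:, None], X - mu_pos, X - mu_neg)
    S = centered.T @ centered / (X.shape[0] - 2)
    if shrink_target == "diagonal":
        target = np.diag(np.diag(S))
    elif shrink_target == "spherical":
        target = (np.trace(S) / S.shape[0]) * np.eye(S.shape[0])
    else:
        raise ValueError(f"unknown shrink target {shrink_target!r}")
    S_gamma = (1.0 - gamma) * S + gamma * target
    try:
        chol = cho_factor(S_gamma)
    except LinAlgError as exc:
        raise FitError(
            "regularized covariance is singular; use gamma > 0 when the class "
            "counts do not exceed the dimension") from exc
    w = cho_solve(chol, mu_pos - mu_neg)
    w = np.where(np.abs(w) <= delta, 0.0, w)
    priors = (n_pos / X.shape[0], n_neg / X.shape[0])
    b = float(-0.5 * w @ (mu_pos + mu_neg) + np.log(priors[0] / priors[1]))
    return RldaModel(mean_pos=mu_pos, mean_neg=mu_neg, pooled_cov=S,
                     gamma=float(gamma), delta=float(delta), priors=priors,
                     w=w, b=b)


# --------------------------------------------------------------------------
# Cross-validation and hyperparameter search
# --------------------------------------------------------------------------

@dataclass
class CvResult:
    fold_of_patient: np.ndarray     # (n,) test-fold index per row
    oof_posterior: np.ndarray       # (n,) out-of-fold P(positive) at chosen point
    cv_loss: np.ndarray             # (G,) misclassification rate per grid point
    grid: list[tuple[float, float]]  # (gamma, delta) per grid point
    chosen: tuple[float, float]
    chosen_index: int


def cross_validate(matrix: np.ndarray, labels: np.ndarray,
                   gamma_grid=DEFAULT_GAMMA_GRID,
                   delta_grid=DEFAULT_DELTA_GRID,
                   k: int = 5, seed: int = 0, n_components: int = 20,
                   pca_before_cv: bool = False,
                   positive: str = POSITIVE_LABEL) -> CvResult:
    """Stratified k-fold grid search minimizing out-of-fold misclassification.

    The CV loss is the error rate of out-of-fold predictions at the 0.5
    posterior threshold.  Ties on the loss resolve to the smallest gamma, then
    the smallest delta.  PCA is refit inside each training fold unless
    ``pca_before_cv`` (PCA fit once on all rows first).
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows; cannot stratify into "
            f"{k} folds")
    grid = [(float(g), float(d)) for g in sorted(gamma_grid)
            for d in sorted(delta_grid)]
    n = X.shape[0]
    folds = np.empty(n, dtype=int)
    oof = np.full((len(grid), n), np.nan)

    global_pca = fit_pca(X, n_components) if pca_before_cv else None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train, test) in enumerate(skf.split(X, labels)):
        folds[test] = fold
        if pca_before_cv:
            pca = global_pca
        else:
            pca = fit_pca(X[train], min(n_components, len(train) - 1))
        Ztr, Zte = pca.transform(X[train]), pca.transform(X[test])
        for gi, (g, d) in enumerate(grid):
            try:
                model = fit_rlda(Ztr, labels[train], g, d, positive=positive)
            except FitError:
                continue  # leaves NaN posteriors → infinite loss
            oof[gi, test] = model.posterior(Zte)

    is_pos = labels == positive
    losses = np.empty(len(grid))
    for gi in range(len(grid)):
        p = oof[gi]
        if np.isnan(p).any():
            losses[gi] = np.inf
        else:
            losses[gi] = float(np.mean((p >= 0.5) != is_pos))
    best = int(np.argmin(losses))  # grid sorted by (gamma, delta): ties resolve
    return CvResult(fold_of_patient=folds, oof_posterior=oof[best],
                    cv_loss=losses, grid=grid, chosen=grid[best],
                    chosen_index=best)


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    optimal_threshold: float
    optimal_point: tuple[float, float]  # (FPR, TPR) at the Youden maximizer


def _roc_points(scores: np.ndarray, is_pos: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    thr = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    P, N = is_pos.sum(), (~is_pos).sum()
    tpr = np.array([np.sum(is_pos & (scores >= t)) / P for t in thr])
    fpr = np.array([np.sum(~is_pos & (scores >= t)) / N for t in thr])
    return thr, fpr, tpr


def roc_curve(scores: np.ndarray, labels: np.ndarray,
              positive: str = POSITIVE_LABEL, n_boot: int = 2000,
              seed: int = 0) -> RocResult:
    """ROC over the unique-score threshold sweep.

    AUC by trapezoid over the stored curve (equal to the concordant-pair
    fraction with ties counted half).  The optimal operating point maximizes
    the Youden index TPR − FPR, ties resolving to the lower FPR.  The 95% CI
    is a seeded patient-level bootstrap (percentile, ``n_boot`` resamples).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    if is_pos.all() or not is_pos.any():
        raise ValueError("ROC undefined: both classes must be present")

    thr, fpr, tpr = _roc_points(scores, is_pos)
    auc = float(np.trapezoid(tpr, fpr))

    youden = tpr - fpr
    best = np.lexsort((fpr, -youden))[0]
    optimal = float(thr[best])

    rng = np.random.default_rng(seed)
    n = scores.size
    boot = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            bp = is_pos[idx]
            if bp.any() and not bp.all():
                break
        _, bf, bt = _roc_points(scores[idx], bp)
        boot[i] = np.trapezoid(bt, bf)
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, auc_ci=ci,
                     optimal_threshold=optimal,
                     optimal_point=(float(fpr[best]), float(tpr[best])))


# --------------------------------------------------------------------------
# Pixel projection
# --------------------------------------------------------------------------

def predict_pixels(pca: PCAModel, rlda: RldaModel, spectra: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Project pixel spectra with the final PCA and apply the final model.

    Spectra must be preprocessed with the training manifest and restricted to
    the training window.  Returns (labels, posteriors): label True iff
    P(positive) ≥ 0.5.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != pca.center.size:
        raise ValueError(
            f"pixel spectra have {X.shape[1]} bands; the model was trained "
            f"on {pca.center.size}")
    post = rlda.posterior(pca.transform(X))
    return post >= 0.5, post
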